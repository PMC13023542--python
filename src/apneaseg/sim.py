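"""Seeded synthetic nights: effort belts, events, radar cubes, annotations.

The generator is a statistical stand-in for clinical cohorts: two-channel
quasi-periodic respiration (0.15-0.4 Hz) with slow amplitude/frequency
wander, apnea/hypopnea events realized as multiplicative amplitude
suppression (apnea to <= 10 % of baseline, hypopnea to 1 - reduction) with
raised-cosine 2 s onset/offset ramps, and a radar range-bin cube whose
per-bin complex phase encodes a convex mixture of chest and abdominal
displacement plus static clutter and phase noise.

All randomness flows from one integer seed through named per-stream
generators (waveform, events, codes, radar) so components can be regenerated
independently and every generator is bit-reproducible per seed.
"""

from __future__ import annotations

import csv
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from apneaseg.events import (
    APNEA_CODES,
    CODE_HYPOPNEA,
    CODE_NAMES,
    EventInterval,
)
from apneaseg.radar_dsp import DEFAULT_WAVELENGTH_M, RangeBinCube

APNEA_SUPPRESSION = 0.05   # residual amplitude fraction inside apnea
RAMP_S = 2.0               # raised-cosine transition at event edges
EDGE_MARGIN_S = 15.0       # event-free margin at night edges
MIN_GAP_S = 10.0           # inter-event gap floor (> the 6 s merge horizon)


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named child generator: independent, reproducible sub-stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class SimParams:
    """Night-level generation parameters (amplitudes in arbitrary belt units)."""

    duration_s: float = 3600.0
    fs: float = 10.0
    resp_freq_hz: float = 0.25
    amplitude: float = 1.0
    chest_abd_amp_ratio: float = 0.8
    chest_abd_phase_lag: float = 0.3
    target_ahi: float = 10.0
    apnea_fraction: float = 0.5
    hypopnea_reduction: float = 0.5
    event_duration_range_s: tuple[float, float] = (10.0, 60.0)
    noise_sd: float = 0.05
    baseline_drift_amp: float = 0.1
    freq_wander: float = 0.05
    amp_wander: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not 0.15 - 1e-9 <= self.resp_freq_hz <= 0.4 + 1e-9:
            raise ValueError("resp_freq_hz outside the 0.15-0.4 Hz band")
        if self.event_duration_range_s[0] < 10.0:
            raise ValueError("event durations must be >= 10 s")
        if not 0.0 < self.hypopnea_reduction < 1.0:
            raise ValueError("hypopnea_reduction must lie in (0,1)")
        if not 0.0 <= self.apnea_fraction <= 1.0:
            raise ValueError("apnea_fraction must lie in [0,1]")


@dataclass
class RadarSimParams:
    """Radar-cube generation parameters (60 GHz carrier, 50 Hz slow time)."""

    n_bins: int = 40
    slow_time_fs: float = 50.0
    carrier_freq_hz: float = 60e9
    per_bin_gain: np.ndarray | None = None
    per_bin_mix: np.ndarray | None = None
    clutter_amp: float = 0.5
    phase_noise_sd: float = 0.01
    disp_scale_m: float = 4e-4   # belt units -> meters of chest-wall motion
    seed: int = 0

    @property
    def wavelength_m(self) -> float:
        # derived, never stored independently
        return 299_792_458.0 / self.carrier_freq_hz


def _smooth_unit_noise(rng: np.random.Generator, n: int, fs: float,
                       cutoff_s: float = 20.0) -> np.ndarray:
    """Slow zero-mean unit-variance modulation for amplitude/frequency wander."""
    raw = rng.standard_normal(n)
    sm = gaussian_filter1d(raw, sigma=cutoff_s * fs, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else np.zeros(n)


def simulate_respiration(params: SimParams,
                         fs: float | None = None
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-channel quasi-periodic respiration.

    The abdominal channel is an amplitude-scaled, phase-lagged copy of the
    thoracic oscillation (shared envelope and frequency wander) plus
    independent noise.  Returns (chest, abd, fs).
    """
    fs = float(fs if fs is not None else params.fs)
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(params.duration_s * fs))
    rng = stream_rng(params.seed, "waveform")
    t = np.arange(n) / fs

    f_inst = params.resp_freq_hz * (
        1.0 + params.freq_wander * _smooth_unit_noise(rng, n, fs))
    phase = 2.0 * np.pi * np.cumsum(f_inst) / fs
    envelope = params.amplitude * (
        1.0 + params.amp_wander * _smooth_unit_noise(rng, n, fs))
    envelope = np.clip(envelope, 0.1 * params.amplitude, None)

    drift = params.baseline_drift_amp * np.sin(
        2.0 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))

    chest = envelope * np.sin(phase) + drift
    abd = (params.chest_abd_amp_ratio
           * envelope * np.sin(phase - params.chest_abd_phase_lag) + drift)
    chest = chest + params.noise_sd * rng.standard_normal(n)
    abd = abd + params.noise_sd * rng.standard_normal(n)
    return chest, abd, fs


def plan_events(params: SimParams) -> list[EventInterval]:
    """Plan non-overlapping events at the modelling rate ``params.fs``.

    The night carries round(target_ahi * hours) events with durations drawn
    from ``event_duration_range_s`` and gaps kept above 10 s (so that the
    6 s post-processing merge can never fuse two distinct truths).  Raises
    when the requested AHI cannot be packed into the night.
    """
    if params.target_ahi < 0:
        raise ValueError("target_ahi must be non-negative")
    n_events = int(round(params.target_ahi * params.duration_s / 3600.0))
    if n_events == 0:
        return []
    rng_d = stream_rng(params.seed, "events")
    rng_c = stream_rng(params.seed, "codes")
    lo, hi = params.event_duration_range_s
    durations = rng_d.uniform(lo, hi, size=n_events)
    occupied = durations.sum() + (n_events - 1) * MIN_GAP_S + 2 * EDGE_MARGIN_S
    if occupied > params.duration_s:
        raise ValueError(
            f"cannot pack {n_events} events ({occupied:.0f} s incl. gaps) "
            f"into {params.duration_s:.0f} s; lower target_ahi")
    slack = params.duration_s - occupied
    extra = rng_d.dirichlet(np.ones(n_events + 1)) * slack
    starts_s = []
    t = EDGE_MARGIN_S + extra[0]
    for k in range(n_events):
        starts_s.append(t)
        t += durations[k] + MIN_GAP_S + extra[k + 1]

    events = []
    for s, d in zip(starts_s, durations):
        if rng_c.uniform() < params.apnea_fraction:
            code = int(rng_c.choice(APNEA_CODES))
        else:
            code = CODE_HYPOPNEA
        a = int(np.floor(s * params.fs))
        b = int(np.ceil((s + d) * params.fs))
        events.append(EventInterval(a, b, code))
    return events


def event_envelope(events: list[EventInterval], n: int, fs: float,
                   hypopnea_reduction: float) -> np.ndarray:
    """Multiplicative suppression envelope with raised-cosine 2 s ramps."""
    env = np.ones(n)
    ramp = max(int(round(RAMP_S * fs)), 1)
    for e in events:
        depth = (APNEA_SUPPRESSION if e.code in APNEA_CODES
                 else 1.0 - hypopnea_reduction)
        a, b = max(e.start, 0), min(e.end, n)
        if b <= a:
            continue
        r = min(ramp, (b - a) // 2)
        core = np.full(b - a, depth)
        if r > 0:
            x = np.linspace(0.0, np.pi, r)
            down = depth + (1.0 - depth) * (1.0 + np.cos(x)) / 2.0
            core[:r] = down
            core[-r:] = down[::-1]
        env[a:b] = np.minimum(env[a:b], core)
    return env


def inject_events(chest: np.ndarray, abd: np.ndarray,
                  events: list[EventInterval], params: SimParams,
                  fs: float | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Suppress breathing amplitude inside events and rasterize labels.

    Returns (chest, abd, labels) with labels matching the events exactly.
    """
    fs = float(fs if fs is not None else params.fs)
    n = len(chest)
    ev_sorted = sorted(events, key=lambda e: e.start)
    for a, b in zip(ev_sorted, ev_sorted[1:]):
        if b.start < a.end:
            raise ValueError("overlapping events passed to inject_events")
    for e in events:
        if e.start < 0 or e.end > n:
            raise ValueError(f"event [{e.start},{e.end}) outside waveform [0,{n})")
    env = event_envelope(ev_sorted, n, fs, params.hypopnea_reduction)
    labels = np.zeros(n, dtype=np.int64)
    for e in ev_sorted:
        labels[e.start:e.end] = e.code
    return chest * env, abd * env, labels


def simulate_radar_cube(chest_disp_m: np.ndarray, abd_disp_m: np.ndarray,
                        rparams: RadarSimParams) -> RangeBinCube:
    """Complex range-bin cube from chest/abd displacement trajectories.

    Bin b carries ``gain_b * exp(j (4 pi / lambda) d_b(t) + j theta_b)``
    with ``d_b = mix_b * chest + (1 - mix_b) * abd``, plus a static complex
    clutter offset and Gaussian phase noise.
    """
    n = len(chest_disp_m)
    if len(abd_disp_m) != n:
        raise ValueError("chest and abd displacement lengths differ")
    rng = stream_rng(rparams.seed, "radar")
    B = rparams.n_bins
    gain = (np.asarray(rparams.per_bin_gain, dtype=float)
            if rparams.per_bin_gain is not None
            else rng.uniform(0.5, 1.5, size=B))
    mix = (np.asarray(rparams.per_bin_mix, dtype=float)
           if rparams.per_bin_mix is not None
           else rng.uniform(0.0, 1.0, size=B))
    if gain.shape != (B,) or mix.shape != (B,):
        raise ValueError("per_bin_gain/per_bin_mix must have n_bins entries")
    lam = rparams.wavelength_m
    amp = max(np.max(np.abs(chest_disp_m), initial=0.0),
              np.max(np.abs(abd_disp_m), initial=0.0))
    if amp > lam / 4.0:
        warnings.warn(
            f"displacement amplitude {amp:.2e} m exceeds lambda/4 = "
            f"{lam / 4:.2e} m: phase unwrap ambiguity possible",
            RuntimeWarning, stacklevel=2)
    d = np.outer(chest_disp_m, mix) + np.outer(abd_disp_m, 1.0 - mix)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=B)
    phase = (4.0 * np.pi / lam) * d + theta
    if rparams.phase_noise_sd > 0:
        phase = phase + rng.normal(0.0, rparams.phase_noise_sd, size=(n, B))
    z = gain * np.exp(1j * phase)
    if rparams.clutter_amp > 0:
        clut_mag = rng.uniform(0.0, rparams.clutter_amp, size=B)
        clut_ph = rng.uniform(0.0, 2.0 * np.pi, size=B)
        z = z + clut_mag * np.exp(1j * clut_ph)
    return RangeBinCube(z=z, fs=rparams.slow_time_fs)


def write_annotation_csv(events: list[EventInterval], fs: float,
                         path: str | Path) -> None:
    """Write events as an (epoch, time, duration, event) table.

    Event strings alternate between the two prefixes seen in the wild
    ("Respiratory Event X" / "RespEvent X") to exercise the robust parser.
    """
    ev = sorted(events, key=lambda e: e.start)
    for a, b in zip(ev, ev[1:]):
        if b.start < a.end:
            raise ValueError("overlapping events cannot be written")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "time", "duration", "event"])
        for k, e in enumerate(ev):
            t0 = e.start / fs
            dur = e.length / fs
            prefix = "Respiratory Event" if k % 2 == 0 else "RespEvent"
            w.writerow([int(t0 // 30) + 1, f"{t0:.3f}", f"{dur:.3f}",
                        f"{prefix} {CODE_NAMES[e.code]}"])


@dataclass
class SyntheticNight:
    """One simulated night across both modalities with ground truth."""

    chest: np.ndarray                 # belt-like, 10 Hz
    abd: np.ndarray
    fs: float
    labels: np.ndarray                # per-sample integer codes at fs
    events: list[EventInterval]       # at fs
    target_ahi: float
    cube: RangeBinCube | None = None  # radar side, 50 Hz
    chest_hi: np.ndarray | None = None  # master-rate belts (cube rate)
    abd_hi: np.ndarray | None = None
    night_id: str = ""

    @property
    def true_ahi(self) -> float:
        hours = len(self.labels) / self.fs / 3600.0
        return len(self.events) / hours


def simulate_night(params: SimParams,
                   rparams: RadarSimParams | None = None,
                   night_id: str = "") -> SyntheticNight:
    """Generate one night; with ``rparams`` the radar cube is produced from
    the same underlying motion sampled at the radar slow-time rate."""
    master_fs = rparams.slow_time_fs if rparams is not None else params.fs
    chest_hi, abd_hi, _ = simulate_respiration(params, fs=master_fs)
    events10 = plan_events(params)
    factor = int(round(master_fs / params.fs))
    events_hi = [EventInterval(e.start * factor, e.end * factor, e.code)
                 for e in events10]
    chest_hi, abd_hi, _ = inject_events(chest_hi, abd_hi, events_hi, params,
                                        fs=master_fs)
    if factor > 1:
        from apneaseg.radar_dsp import decimate_signal
        chest = decimate_signal(chest_hi, master_fs, params.fs)
        abd = decimate_signal(abd_hi, master_fs, params.fs)
    else:
        chest, abd = chest_hi, abd_hi
    n10 = int(round(params.duration_s * params.fs))
    labels = np.zeros(n10, dtype=np.int64)
    for e in events10:
        labels[e.start:e.end] = e.code
    cube = None
    if rparams is not None:
        cube = simulate_radar_cube(chest_hi * rparams.disp_scale_m,
                                   abd_hi * rparams.disp_scale_m, rparams)
    return SyntheticNight(chest=chest[:n10], abd=abd[:n10], fs=params.fs,
                          labels=labels, events=events10,
                          target_ahi=params.target_ahi, cube=cube,
                          chest_hi=chest_hi, abd_hi=abd_hi, night_id=night_id)


# severity mix of the 35-night target cohort (Normal/Mild/Moderate/Severe)
COHORT_SEVERITY_PROBS = (17 / 35, 12 / 35, 3 / 35, 3 / 35)
SEVERITY_AHI_RANGES = ((0.5, 5.0), (5.0, 15.0), (15.0, 30.0), (30.0, 45.0))


def cohort_params(n_nights: int, seed: int,
                  base: SimParams | None = None) -> list[SimParams]:
    """Per-night parameter draws emulating a severity-mixed cohort.

    Nights vary in breathing frequency (0.18-0.38 Hz), amplitude and target
    AHI; the severity mix follows the 48.6/34.3/8.6/8.6 % composition of the
    target radar cohort.
    """
    base = base or SimParams()
    rng = stream_rng(seed, "cohort")
    out = []
    for k in range(n_nights):
        sev = int(rng.choice(4, p=COHORT_SEVERITY_PROBS))
        lo, hi = SEVERITY_AHI_RANGES[sev]
        out.append(replace(
            base,
            resp_freq_hz=float(rng.uniform(0.18, 0.38)),
            amplitude=float(base.amplitude * rng.uniform(0.7, 1.4)),
            target_ahi=float(rng.uniform(lo, hi)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out


def simulate_cohort(n_nights: int, seed: int,
                    base: SimParams | None = None,
                    rparams: RadarSimParams | None = None,
                    prefix: str = "night") -> list[SyntheticNight]:
    """Simulate a cohort of independent nights (optionally with radar cubes)."""
    nights = []
    for k, p in enumerate(cohort_params(n_nights, seed, base)):
        rp = None
        if rparams is not None:
            rp = replace(rparams, seed=p.seed + 1)
        nights.append(simulate_night(p, rp, night_id=f"{prefix}_{k:03d}"))
    return nights
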