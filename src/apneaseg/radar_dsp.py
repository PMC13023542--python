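"""FMCW range-bin cube to chest/abdomen respiration waveforms.

A 60 GHz FMCW front end yields, per torso-related range bin, a complex
slow-time sequence z_b(t) whose phase is modulated by chest-wall motion:
``delta_phi = 4 pi d(t) / lambda``.  This module recovers per-bin displacement
(mean removal, angle, unwrap, scale by lambda/4pi), band-passes it to the
respiration band, and projects the 40-bin displacement matrix onto two
waveforms approximating thoracic and abdominal motion via ridge regressions
whose weight vectors are pushed toward mutual orthogonality.  Weights are
estimated in overlapping 120 s windows (30 s stride) and merged by
overlap-add averaging; the result is decimated from 50 Hz to the 10 Hz
modelling rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

SPEED_OF_LIGHT = 299_792_458.0  # m/s
DEFAULT_CARRIER_HZ = 60e9
DEFAULT_WAVELENGTH_M = SPEED_OF_LIGHT / DEFAULT_CARRIER_HZ


@dataclass
class RangeBinCube:
    """Complex slow-time matrix (time x B bins) at sampling rate fs."""

    z: np.ndarray
    fs: float = 50.0
    night_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z)
        if self.z.ndim != 2:
            raise ValueError("cube must be 2D (time x bins)")
        if not np.iscomplexobj(self.z):
            self.z = self.z.astype(np.complex128)

    @property
    def n_samples(self) -> int:
        return self.z.shape[0]

    @property
    def n_bins(self) -> int:
        return self.z.shape[1]


@dataclass
class RidgeConfig:
    """Orthogonal-ridge projection parameters.

    alpha_ridge   : L2 penalty on column-standardized displacements
    n_ortho_iters : alternating re-solve/project passes
    window_s      : weight-estimation window length (120 s)
    stride_s      : window stride (30 s)
    """

    alpha_ridge: float = 1.0
    n_ortho_iters: int = 2
    window_s: float = 120.0
    stride_s: float = 30.0
    low_hz: float = 0.1
    high_hz: float = 0.6

    def __post_init__(self) -> None:
        if self.alpha_ridge <= 0:
            raise ValueError("alpha_ridge must be positive (regularization is "
                             "mandatory for the multicollinear bin matrix)")
        if self.window_s <= self.stride_s:
            raise ValueError("window_s must exceed stride_s")


@dataclass
class DisplacementMatrix:
    """Real displacement matrix (time x bins), meters."""

    X: np.ndarray
    fs: float


def _circle_center(z: np.ndarray) -> complex:
    """Least-squares (Kasa) circle-center fit to a complex trajectory.

    A phase-modulated return with a static clutter offset traces a circle
    centred at the offset; fitting the centre cancels the offset exactly in
    the noiseless limit, whereas subtracting the raw complex mean leaves a
    Bessel-weighted bias of the phase modulation on the circle.
    """
    x, y = z.real, z.imag
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return complex(x.mean(), y.mean())
    return complex(sol[0], sol[1])


def phase_to_displacement(cube: RangeBinCube,
                          wavelength_m: float = DEFAULT_WAVELENGTH_M
                          ) -> DisplacementMatrix:
    """Per-bin phase demodulation: static-offset removal, unwrapped angle,
    lambda/(4 pi) scaling.

    The static (clutter/DC) component is estimated per bin as the complex
    mean refined by a least-squares circle-centre fit, then subtracted
    before taking the unwrapped argument.  Bins with no temporal variation
    (pure static reflectors) are emitted as zero displacement and flagged
    in the log.
    """
    if cube.n_samples == 0 or cube.n_bins == 0:
        raise ValueError("empty cube")
    if wavelength_m <= 0:
        raise ValueError("wavelength must be positive")
    z = np.nan_to_num(cube.z, nan=0.0)
    mean = z.mean(axis=0, keepdims=True)
    spread = np.max(np.abs(z - mean), axis=0)
    dead = spread < 1e-9 * (np.abs(mean[0]) + 1.0)
    if np.any(dead):
        logger.info("%d all-static bins emitted as zeros: %s",
                    int(dead.sum()), np.flatnonzero(dead).tolist())
    X = np.zeros(z.shape, dtype=float)
    for b in np.flatnonzero(~dead):
        center = _circle_center(z[:, b])
        phase = np.unwrap(np.angle(z[:, b] - center))
        X[:, b] = phase * (wavelength_m / (4.0 * np.pi))
    return DisplacementMatrix(X=X, fs=cube.fs)


def bandpass_respiration(x: np.ndarray, fs: float,
                         low_hz: float = 0.1, high_hz: float = 0.6,
                         order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(f"invalid band [{low_hz}, {high_hz}] at fs={fs}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=fs, output="sos")
    x = np.asarray(x, dtype=float)
    # sosfiltfilt needs a minimum length for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for filter warm-up "
            f"({padlen} samples)")
    return sps.sosfiltfilt(sos, x, axis=-1)


def ridge_solve(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form ridge solution (X'X + alpha I)^-1 X'y."""
    _, B = X.shape
    return np.linalg.solve(X.T @ X + alpha * np.eye(B), X.T @ y)


def orthogonal_ridge_weights(X: np.ndarray, y_chest: np.ndarray,
                             y_abd: np.ndarray, cfg: RidgeConfig
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Ridge weights for chest and abdomen with alternating orthogonalization.

    Both weight vectors first solve their ridge problems; then, for
    ``n_ortho_iters`` passes, each is re-solved in the orthogonal complement
    of the other (column space projected off the competing direction), which
    drives down |cos(w_c, w_a)| and disentangles the two motion sources.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(y_chest) or X.shape[0] != len(y_abd):
        raise ValueError("targets must align with X rows")
    w_c = ridge_solve(X, np.asarray(y_chest, dtype=float), cfg.alpha_ridge)
    w_a = ridge_solve(X, np.asarray(y_abd, dtype=float), cfg.alpha_ridge)
    for _ in range(cfg.n_ortho_iters):
        w_c = _ridge_in_complement(X, y_chest, w_a, cfg.alpha_ridge, w_c)
        w_a = _ridge_in_complement(X, y_abd, w_c, cfg.alpha_ridge, w_a)
    return w_c, w_a


def _ridge_in_complement(X: np.ndarray, y: np.ndarray, other: np.ndarray,
                         alpha: float, fallback: np.ndarray) -> np.ndarray:
    """Re-solve ridge with the solution constrained orthogonal to ``other``."""
    nrm = np.linalg.norm(other)
    if nrm < 1e-12:
        return fallback
    u = other / nrm
    P = np.eye(len(u)) - np.outer(u, u)       # projector onto complement
    Xp = X @ P
    w = ridge_solve(Xp, np.asarray(y, dtype=float), alpha)
    return P @ w


def project_windows_overlap_add(X: np.ndarray, y_chest: np.ndarray,
                                y_abd: np.ndarray, fs: float,
                                cfg: RidgeConfig
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Windowed orthogonal-ridge projection merged by overlap-add averaging.

    Weights are estimated per 120 s window (30 s stride); each window
    predicts yhat = X w over its span and overlapping predictions are
    averaged sample-wise by coverage count (unbiased mean).  Nights shorter
    than one window fall back to a single global fit.
    """
    X = np.asarray(X, dtype=float)
    L = X.shape[0]
    T = int(round(cfg.window_s * fs))
    S = int(round(cfg.stride_s * fs))
    if L < T:
        logger.info("night shorter than one window (%d < %d): global fit", L, T)
        starts = [0]
        T = L
    else:
        starts = list(range(0, L - T + 1, S))
        if starts[-1] + T < L:          # tail window to guarantee coverage
            starts.append(L - T)
    acc_c = np.zeros(L)
    acc_a = np.zeros(L)
    cov = np.zeros(L)
    for s in starts:
        sl = slice(s, s + T)
        w_c, w_a = orthogonal_ridge_weights(X[sl], y_chest[sl], y_abd[sl], cfg)
        acc_c[sl] += X[sl] @ w_c
        acc_a[sl] += X[sl] @ w_a
        cov[sl] += 1
    return acc_c / cov, acc_a / cov


def decimate_signal(x: np.ndarray, from_fs: float, to_fs: float) -> np.ndarray:
    """Integer-factor decimation with zero-phase anti-aliasing filtering.

    Output length is ceil(len(x) / q); covers both the 200->10 Hz belt
    conversion (q=20) and the 50->10 Hz radar conversion (q=5).
    """
    factor = from_fs / to_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"{from_fs}->{to_fs} Hz is not an integer factor")
    q = int(round(factor))
    y = np.asarray(x, dtype=float)
    if q == 1:
        return y.copy()
    # zero-phase FIR anti-aliasing: unit DC gain and a flat passband, with
    # odd-extension edge handling so constants decimate to constants
    n_taps = 20 * q + 1
    h = sps.firwin(n_taps, 0.8 / q)
    if y.shape[-1] <= 3 * n_taps:
        raise ValueError(
            f"signal length {y.shape[-1]} too short to decimate by {q}")
    return sps.filtfilt(h, [1.0], y)[..., ::q]


def align_and_trim(chest: np.ndarray, abd: np.ndarray, labels: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tail-trim the three sequences to their common minimum length."""
    if min(len(chest), len(abd), len(labels)) == 0:
        raise ValueError("empty input sequence")
    L = min(len(chest), len(abd), len(labels))
    return chest[:L], abd[:L], labels[:L]


def extract_radar_respiration(cube: RangeBinCube, y_chest: np.ndarray,
                              y_abd: np.ndarray, cfg: RidgeConfig | None = None,
                              wavelength_m: float = DEFAULT_WAVELENGTH_M,
                              to_fs: float = 10.0
                              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Full radar chain: phase -> band-pass -> orthogonal ridge -> decimate.

    ``y_chest``/``y_abd`` are the synchronized reference belt targets at the
    cube rate.  Returns (radar_chest, radar_abd, fs) at ``to_fs``.
    """
    cfg = cfg or RidgeConfig()
    disp = phase_to_displacement(cube, wavelength_m)
    Xf = bandpass_respiration(disp.X.T, cube.fs, cfg.low_hz, cfg.high_hz).T
    # column standardization so one alpha suits all bins
    sd = Xf.std(axis=0)
    sd[sd < 1e-15] = 1.0
    Xs = Xf / sd
    n = min(len(y_chest), len(y_abd), Xs.shape[0])
    rc, ra = project_windows_overlap_add(
        Xs[:n], np.asarray(y_chest)[:n], np.asarray(y_abd)[:n], cube.fs, cfg)
    rc = bandpass_respiration(rc, cube.fs, cfg.low_hz, cfg.high_hz)
    ra = bandpass_respiration(ra, cube.fs, cfg.low_hz, cfg.high_hz)
    return (decimate_signal(rc, cube.fs, to_fs),
            decimate_signal(ra, cube.fs, to_fs), to_fs)


def surrogate_targets(X: np.ndarray, n_components: int = 2
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Reference-free surrogate targets: first two principal components of X.

    Provided for deployments without synchronized belts; this is an
    extension beyond the synchronized-reference design and is not used by
    the default pipeline.
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    pcs = Xc @ Vt[:n_components].T
    return pcs[:, 0], pcs[:, 1]
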