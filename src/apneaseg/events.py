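"""Half-open sample-index event intervals and interval utilities.

All intervals in the package are 0-based half-open ``[start, end)`` in sample
indices, matching the convention used for event matching.  Seconds are
converted to samples with ``floor(start * fs)`` / ``ceil(end * fs)`` so that a
partially covered sample at either edge is included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

# Respiratory event codebook.  Codes 1-4 are the positive (apnea/hypopnea)
# class for the binary segmentation task; 5 is retained for bookkeeping only.
CODE_NORMAL = 0
CODE_OBSTRUCTIVE_APNEA = 1
CODE_CENTRAL_APNEA = 2
CODE_MIXED_APNEA = 3
CODE_HYPOPNEA = 4
CODE_OTHER_RESP = 5

APNEA_CODES = (CODE_OBSTRUCTIVE_APNEA, CODE_CENTRAL_APNEA, CODE_MIXED_APNEA)
POSITIVE_CODES = APNEA_CODES + (CODE_HYPOPNEA,)

CODE_NAMES = {
    CODE_NORMAL: "Normal",
    CODE_OBSTRUCTIVE_APNEA: "ObstructiveApnea",
    CODE_CENTRAL_APNEA: "CentralApnea",
    CODE_MIXED_APNEA: "MixedApnea",
    CODE_HYPOPNEA: "Hypopnea",
    CODE_OTHER_RESP: "OtherRespEvent",
}


@dataclass(frozen=True)
class EventInterval:
    """Half-open sample-index interval ``[start, end)`` carrying an event code."""

    start: int
    end: int
    code: int = CODE_OBSTRUCTIVE_APNEA

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def duration_s(self, fs: float) -> float:
        return self.length / fs


def seconds_to_interval(start_s: float, duration_s: float, fs: float,
                        code: int = CODE_OBSTRUCTIVE_APNEA) -> EventInterval:
    """Convert a (start, duration) pair in seconds to a sample interval."""
    start = math.floor(start_s * fs)
    end = math.ceil((start_s + duration_s) * fs)
    return EventInterval(start=start, end=end, code=code)


def intervals_sorted_disjoint(events: list[EventInterval]) -> bool:
    """True when the list is sorted by start and pairwise non-overlapping."""
    for a, b in zip(events, events[1:]):
        if b.start < a.end:
            return False
    return True
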