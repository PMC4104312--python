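"""Transmembrane helix detection from hydropathy, with cryptic-peak recovery.

PIN proteins carry ten transmembrane helices, five per transmembrane
domain.  Standard single-sequence predictors rarely call all ten
unambiguously, but the weaker ("cryptic") helices appear as sub-threshold
hydropathy maxima that can be recovered by relaxing the detection cutoff
until the expected count is reached.  This module implements that logic
transparently: a Kyte-Doolittle sliding-window profile, peak detection at a
starting cutoff, and stepwise cutoff relaxation down to a floor, flagging
the helices recovered below the starting cutoff as cryptic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: Kyte & Doolittle residue hydropathy values; X (unknown) scored neutral.
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass
class HydropathyProfile:
    """Centred moving-average hydropathy; ends truncated, no padding.

    ``scores[i]`` is the window average centred on residue ``offset + i``
    (0-based).
    """

    scores: np.ndarray
    offset: int
    window: int

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class Helix:
    """One predicted helix interval, 0-based half-open residue coordinates."""

    start: int
    end: int
    peak: float
    cryptic: bool = False


@dataclass
class HelixPrediction:
    helices: List[Helix]
    floor_reached: bool = False

    def __len__(self) -> int:
        return len(self.helices)


@dataclass(frozen=True)
class HelixParams:
    expected: int = 5
    window: int = 19
    start_cutoff: float = 1.6
    floor: float = 0.5
    step: float = 0.1
    min_run: int = 7
    min_gap: int = 3


def hydropathy_profile(seq: str, window: int = 19) -> HydropathyProfile:
    """Centred moving average of Kyte-Doolittle values over an odd window."""
    if window % 2 == 0 or window < 7:
        raise ValueError("window must be odd and >= 7")
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} shorter than window {window}")
    values = np.array([KYTE_DOOLITTLE[res] for res in seq])
    kernel = np.ones(window) / window
    scores = np.convolve(values, kernel, mode="valid")
    return HydropathyProfile(scores=scores, offset=window // 2, window=window)


def _runs_above(profile: HydropathyProfile, cutoff: float,
                min_run: int, min_gap: int) -> List[Tuple[int, int]]:
    """Maximal runs above cutoff, merged across gaps < min_gap, length-filtered.

    Runs are in residue coordinates (0-based half-open).
    """
    above = profile.scores >= cutoff
    runs: List[Tuple[int, int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged: List[Tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    out = [(a + profile.offset, b + profile.offset) for a, b in merged
           if b - a >= min_run]
    return out


def detect_helices(profile: HydropathyProfile,
                   params: HelixParams = HelixParams()) -> HelixPrediction:
    """Detect up to ``expected`` helices with cryptic-peak recovery.

    Peaks found at the starting cutoff are primary.  While fewer than
    ``expected`` peaks are found, the cutoff is lowered by ``step`` and any
    newly appearing runs that do not overlap an existing helix are added as
    cryptic, until the expected count is reached or the cutoff floor is
    hit (flagged).  With more peaks than expected, the ``expected``
    highest-peaked ones are kept.  Lowering the cutoff never removes a
    peak, so the detected count is monotone in the cutoff.
    """
    if params.expected < 1:
        raise ValueError("expected must be >= 1")

    def peak_height(a: int, b: int) -> float:
        lo = max(0, a - profile.offset)
        hi = min(len(profile.scores), b - profile.offset)
        return float(profile.scores[lo:hi].max())

    helices: List[Helix] = []
    cutoff = params.start_cutoff
    for a, b in _runs_above(profile, cutoff, params.min_run, params.min_gap):
        helices.append(Helix(a, b, peak_height(a, b), cryptic=False))

    floor_reached = False
    while len(helices) < params.expected:
        cutoff = round(cutoff - params.step, 10)
        if cutoff < params.floor - 1e-9:
            floor_reached = True
            break
        for a, b in _runs_above(profile, cutoff, params.min_run, params.min_gap):
            if any(a < h.end and h.start < b for h in helices):
                continue
            helices.append(Helix(a, b, peak_height(a, b), cryptic=True))

    helices.sort(key=lambda h: -h.peak)
    helices = helices[: params.expected]
    helices.sort(key=lambda h: h.start)
    return HelixPrediction(helices=helices, floor_reached=floor_reached)


def modal_helix_positions(
    predictions: Sequence[HelixPrediction],
) -> Tuple[List[Tuple[int, int]], int]:
    """Modal (start, end) per helix index across sequences.

    Aggregates only over predictions carrying the modal helix count (a
    warning-style second return gives that coverage count).  Ties in the
    mode resolve to the smaller coordinate.
    """
    if len(predictions) < 3:
        raise ValueError("need at least 3 predictions for modal positions")
    counts = Counter(len(p) for p in predictions)
    modal_count = min(sorted(counts, key=lambda k: (-counts[k], k))[:1])
    usable = [p for p in predictions if len(p) == modal_count]
    modal: List[Tuple[int, int]] = []
    for i in range(modal_count):
        starts = Counter(p.helices[i].start for p in usable)
        ends = Counter(p.helices[i].end for p in usable)
        s = sorted(starts, key=lambda k: (-starts[k], k))[0]
        e = sorted(ends, key=lambda k: (-ends[k], k))[0]
        modal.append((s, e))
    return modal, len(usable)
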