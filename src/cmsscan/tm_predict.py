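"""Hydropathy-based transmembrane segment prediction.

A self-contained Kyte-Doolittle sliding-window predictor: candidate
membrane-spanning segments are maximal runs of window-averaged hydropathy
above a threshold.  The canonical published choice for detecting
transmembrane helices — window 19, threshold 1.6 — is the default.  This is
deliberately simpler than an HMM topology predictor: it reports segment
locations and counts, not membrane orientation, which is all the candidate
screen consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Kyte & Doolittle hydropathy scale
KD_SCALE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class TmResult:
    orf_id: str
    segments: list[tuple[int, int]]  # half-open residue intervals
    count: int


def hydropathy_profile(protein: str, window: int = 19) -> np.ndarray:
    """Centered moving-average Kyte-Doolittle profile.

    ``profile[p]`` is the mean hydropathy of residues ``[p, p+window)``;
    only full windows are reported, so the profile has
    ``len(protein) - window + 1`` values.  Unknown residues (X) score 0.
    """
    if len(protein) < window:
        warnings.warn(
            f"protein ({len(protein)} aa) shorter than window ({window}); "
            "empty hydropathy profile"
        )
        return np.empty(0)
    values = np.array([KD_SCALE.get(a, 0.0) for a in protein.upper()])
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")


def predict_tm(
    protein: str,
    threshold: float = 1.6,
    window: int = 19,
    min_segment_length: int = 19,
    merge_gap: int = 5,
    orf_id: str = "",
) -> TmResult:
    """Predict membrane-spanning segments of one protein.

    Each profile position above ``threshold`` marks its full window of
    residues as hydrophobic; overlapping windows merge, runs separated by
    fewer than ``merge_gap`` residues merge, and only segments of at least
    ``min_segment_length`` residues are kept.
    """
    profile = hydropathy_profile(protein, window)
    segments: list[list[int]] = []
    for p in np.flatnonzero(profile >= threshold):
        s, e = int(p), int(p) + window
        if segments and s - segments[-1][1] < merge_gap:
            segments[-1][1] = max(segments[-1][1], e)
        else:
            segments.append([s, e])
    kept = [(s, e) for s, e in segments if e - s >= min_segment_length]
    return TmResult(orf_id=orf_id, segments=kept, count=len(kept))
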