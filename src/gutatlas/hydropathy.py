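"""Kyte-Doolittle transmembrane-segment prediction.

A sliding window of mean hydropathy calls membrane-spanning helices:
maximal runs of windows whose mean exceeds a threshold become segments,
and segments separated by short gaps are merged.  This is a
deterministic hydropathy caller in the classic Kyte-Doolittle style;
polytopic transporter candidates are required to carry at least three
such segments.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy scale.
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.6
MERGE_GAP = 5  # segments separated by < this many residues are merged


def hydropathy_profile(sequence: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Mean hydropathy per window start position (len - window + 1 values)."""
    values = np.empty(len(sequence))
    for i, aa in enumerate(sequence):
        if aa not in KD_SCALE:
            logger.warning("unknown residue %r: hydropathy 0 assumed", aa)
        values[i] = KD_SCALE.get(aa, 0.0)
    if len(sequence) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def predict_tm(
    sequence: str,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[tuple[int, int]]:
    """Predicted TM segments as 0-based inclusive (start, end) residue spans.

    Maximal runs of above-threshold windows form segments spanning from
    the first window start to the last window end; segments separated
    by fewer than 5 residues are merged.
    """
    means = hydropathy_profile(sequence, window)
    above = means > threshold
    segments: list[tuple[int, int]] = []
    run_start: int | None = None
    for i, hot in enumerate(above):
        if hot and run_start is None:
            run_start = i
        elif not hot and run_start is not None:
            segments.append((run_start, i - 1 + window - 1))
            run_start = None
    if run_start is not None:
        segments.append((run_start, len(above) - 1 + window - 1))

    merged: list[tuple[int, int]] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] - 1 < MERGE_GAP:
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(seg)
    return merged


def count_tm(sequence: str, window: int = DEFAULT_WINDOW,
             threshold: float = DEFAULT_THRESHOLD) -> int:
    return len(predict_tm(sequence, window, threshold))
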