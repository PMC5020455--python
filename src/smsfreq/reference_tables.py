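"""Published cluster-agreement tables from the original SMS study.

The original weekly-SMS low back pain study that this pipeline
re-implements reported, for each reduced measurement design B-F, the
4x4 contingency table crossing its clusters with the reference
design A's clusters (rows: reduced design's clusters, columns:
reference clusters, both ordered from fast improvers to indifferent),
together with the raw and quadratic-weighted kappa.  Those printed
counts and statistics are transcribed here verbatim; they are the
ground truth for the kappa verification mode.

Every table totals 129 subjects and shares the reference column
margins (17, 63, 23, 26).
"""

from __future__ import annotations

import numpy as np

#: rows = reduced design's clusters 1-4, columns = reference clusters 1-4
PUBLISHED_TABLES: dict[str, np.ndarray] = {
    "B": np.array(
        [[11, 12, 0, 1],
         [5, 29, 8, 0],
         [1, 9, 9, 13],
         [0, 13, 6, 12]]
    ),
    "C": np.array(
        [[15, 3, 0, 0],
         [0, 23, 2, 5],
         [0, 33, 7, 0],
         [2, 4, 14, 21]]
    ),
    "D": np.array(
        [[14, 4, 0, 0],
         [1, 52, 8, 2],
         [0, 1, 8, 2],
         [2, 6, 7, 22]]
    ),
    "E": np.array(
        [[16, 15, 0, 0],
         [1, 45, 7, 3],
         [0, 1, 13, 0],
         [0, 2, 3, 23]]
    ),
    "F": np.array(
        [[15, 1, 1, 0],
         [0, 47, 3, 1],
         [0, 7, 8, 1],
         [2, 8, 11, 24]]
    ),
}

#: printed (raw kappa, quadratic-weighted kappa) per design
PUBLISHED_KAPPA: dict[str, tuple[float, float]] = {
    "B": (0.272, 0.548),
    "C": (0.348, 0.611),
    "D": (0.618, 0.720),
    "E": (0.642, 0.823),
    "F": (0.611, 0.708),
}

#: reference design A's printed cluster sizes (fast, normal, slow, indifferent)
REFERENCE_MARGINS: tuple[int, ...] = (17, 63, 23, 26)
N_SUBJECTS: int = 129
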