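"""Published reference measurements used to parameterize scenes and benchmarks.

``ANTHRO_TABLE`` holds the pairwise bar-to-bar distance measurements of the
physical trunk-phantom accuracy study: for each unordered pair of the five
bar targets, the manually measured ("real") centre distance, the distance
measured on the guidance display ("virtual"), and their absolute difference,
all in mm.

Note the real distances are mutually inconsistent as Euclidean point
distances (e.g. d(3,5) = 156.0 exceeds d(3,4) + d(4,5) = 152.9), presumably
from manual-measurement error, so no 3D configuration reproduces them
exactly; the scene factory embeds them in the least-squares sense.
"""

from __future__ import annotations

# (bar_i, bar_j) -> (real_mm, virtual_mm, abs_diff_mm)
ANTHRO_TABLE: dict[tuple[int, int], tuple[float, float, float]] = {
    (1, 2): (13.5, 12.0, 1.5),
    (1, 3): (28.0, 29.3, 1.3),
    (1, 4): (76.0, 78.5, 2.5),
    (1, 5): (184.5, 181.5, 3.0),
    (2, 3): (15.5, 17.0, 1.5),
    (2, 4): (64.5, 66.3, 1.8),
    (2, 5): (167.5, 170.5, 3.0),
    (3, 4): (48.4, 47.2, 1.2),
    (3, 5): (156.0, 157.5, 1.5),
    (4, 5): (104.5, 106.8, 2.3),
}

ANTHRO_REAL_DISTANCES_MM: dict[tuple[int, int], float] = {
    pair: row[0] for pair, row in ANTHRO_TABLE.items()
}

ANTHRO_ABS_DIFFERENCES_MM: list[float] = [row[2] for row in ANTHRO_TABLE.values()]

#: Target depths below the needle entry point (mm), porcine study.
PORCINE_TARGET_DEPTHS_MM: dict[str, float] = {
    "kidney": 107.6,
    "liver1": 123.7,
    "liver2": 92.5,
}

#: Lesion diameters (mm) and depths below the entry point (mm), cadaver study.
CADAVER_LESIONS: dict[str, dict[str, float]] = {
    "lesion_segIV": {"diameter_mm": 18.0, "depth_mm": 50.6},
    "lesion_segVI": {"diameter_mm": 30.0, "depth_mm": 91.2},
}

#: Accuracy threshold used by all experiments (mm).
ACCURACY_THRESHOLD_MM: float = 5.0

#: Needle length: fixed offset from the tracked handle frame to the tip (mm).
NEEDLE_LENGTH_MM: float = 170.0
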