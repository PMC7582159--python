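"""Bundled bench-validation dataset: bifurcation angles.

Bifurcation angles (degrees) measured on five patient-specific silicone
bifurcation phantoms, once on the OCT/angiography-based 3D reconstruction and
once on the contrast-enhanced micro-CT reference reconstruction of the same
phantom.  Angle A is between the proximal MV and the SB, angle B between the
distal MV and the SB, angle C between the distal and proximal MV.

These 15 paired measurements are the standard worked example for the
agreement statistics in :mod:`bifurcate3d.metrics` (regression with the
micro-CT value as response, Bland-Altman on OCT - micro-CT differences).
"""

from __future__ import annotations

import numpy as np

__all__ = ["BENCH_ANGLES", "angle_pairs"]

#: (phantom id, angle name, OCT-based value, micro-CT value), degrees
BENCH_ANGLES = [
    (1, "A", 148.60, 147.36),
    (2, "A", 141.24, 138.77),
    (3, "A", 160.13, 162.55),
    (4, "A", 152.76, 154.95),
    (5, "A", 153.06, 160.25),
    (1, "B", 59.73, 64.12),
    (2, "B", 69.90, 73.22),
    (3, "B", 39.88, 35.11),
    (4, "B", 54.41, 50.33),
    (5, "B", 50.95, 41.94),
    (1, "C", 151.67, 148.50),
    (2, "C", 148.85, 148.01),
    (3, "C", 159.93, 162.34),
    (4, "C", 152.82, 154.73),
    (5, "C", 156.00, 157.69),
]


def angle_pairs() -> tuple[np.ndarray, np.ndarray]:
    """All 15 (OCT, micro-CT) angle pairs as two arrays (degrees)."""
    arr = np.array([(o, u) for _, _, o, u in BENCH_ANGLES])
    return arr[:, 0], arr[:, 1]
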