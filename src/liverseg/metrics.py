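"""Segmentation quality metrics and challenge scoring.

Implements the five standard liver-segmentation error measures between
a ground-truth mask A and a result mask B — volumetric overlap error
(VOE), relative volume difference (RVD), and the average / RMS /
maximum symmetric surface distances (ASD, RMSD, MSD) in millimetres —
plus the linear score conversion used by the MICCAI 2007 liver
segmentation Grand Challenge, where 100 is a perfect result and ~75
matches the reference human inter-observer error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: Grand Challenge reference errors (score 75): VOE %, RVD %, ASD mm, RMSD mm, MSD mm
SCORE_REFERENCE_ERRORS = {
    "voe": 6.4,
    "rvd": 4.7,
    "asd": 1.0,
    "rmsd": 1.8,
    "msd": 19.0,
}


@dataclass(frozen=True)
class MaskPair:
    """Ground truth A and result B with physical pixel spacing (mm)."""

    A: np.ndarray
    B: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.A.shape != self.B.shape:
            raise ValueError(f"mask shapes differ: {self.A.shape} vs {self.B.shape}")
        if len(self.spacing) != self.A.ndim:
            raise ValueError("one spacing entry per axis required")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for name, m in (("A", self.A), ("B", self.B)):
            if not np.all(np.isin(np.unique(m), [0, 1])):
                raise ValueError(f"mask {name} must be binary")


@dataclass(frozen=True)
class SurfaceMetrics:
    voe: float  # fraction in [0, 1]
    rvd: float  # fraction (unsigned set-difference form)
    asd: float  # mm
    rmsd: float  # mm
    msd: float  # mm


@dataclass(frozen=True)
class ScoreCard:
    """Per-metric challenge scores (0..100) and their rounded mean."""

    voe: int
    rvd: int
    asd: int
    rmsd: int
    msd: int
    total: int


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of foreground voxels with a face-adjacent background
    (or out-of-image) neighbor.  Voxels on the image border count as
    surface: outside the image is treated as background."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    interior = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(mask.ndim, 1))
    return np.argwhere(mask & ~interior)


def _surface_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    interior = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(mask.ndim, 1))
    return mask & ~interior


def voe(pair: MaskPair) -> float:
    """Volumetric overlap error: 1 - |A n B| / |A u B|."""
    A, B = pair.A.astype(bool), pair.B.astype(bool)
    union = np.logical_or(A, B).sum()
    if union == 0:
        return 0.0
    return 1.0 - np.logical_and(A, B).sum() / union


def rvd(pair: MaskPair, signed: bool = False) -> float:
    """Relative volume difference.

    Default (unsigned) form: vol(A \\ B) / vol(B).  With ``signed=True``
    the challenge's signed variant (vol(B) - vol(A)) / vol(A) is
    returned instead.
    """
    vol_a = int(pair.A.astype(bool).sum())
    vol_b = int(pair.B.astype(bool).sum())
    if signed:
        if vol_a == 0:
            raise ValueError("signed RVD undefined for empty ground truth")
        return (vol_b - vol_a) / vol_a
    if vol_b == 0:
        raise ValueError("RVD undefined for empty result mask")
    diff = np.logical_and(pair.A.astype(bool), ~pair.B.astype(bool)).sum()
    return diff / vol_b


def surface_distances(pair: MaskPair) -> tuple[np.ndarray, np.ndarray]:
    """Minimum surface-to-surface distances, in mm.

    Returns (d(s_A, S(B)) for every surface voxel of A,
             d(s_B, S(A)) for every surface voxel of B).
    Distances are Euclidean with anisotropic spacing, computed with a
    distance transform of each surface set.
    """
    sA = _surface_mask(pair.A)
    sB = _surface_mask(pair.B)
    if not sA.any() or not sB.any():
        raise ValueError("both masks must be nonempty to compare surfaces")
    dt_to_B = ndimage.distance_transform_edt(~sB, sampling=pair.spacing)
    dt_to_A = ndimage.distance_transform_edt(~sA, sampling=pair.spacing)
    return dt_to_B[sA], dt_to_A[sB]


def asd(pair: MaskPair) -> float:
    """Average symmetric surface distance (mm)."""
    dA, dB = surface_distances(pair)
    return float((dA.sum() + dB.sum()) / (dA.size + dB.size))


def rmsd(pair: MaskPair) -> float:
    """Root-mean-square symmetric surface distance (mm)."""
    dA, dB = surface_distances(pair)
    return float(np.sqrt((np.square(dA).sum() + np.square(dB).sum()) / (dA.size + dB.size)))


def msd(pair: MaskPair) -> float:
    """Maximum symmetric surface distance (symmetric Hausdorff, mm)."""
    dA, dB = surface_distances(pair)
    return float(max(dA.max(), dB.max()))


def evaluate(pair: MaskPair) -> SurfaceMetrics:
    """All five metrics at once."""
    dA, dB = surface_distances(pair)
    n = dA.size + dB.size
    return SurfaceMetrics(
        voe=voe(pair),
        rvd=rvd(pair),
        asd=float((dA.sum() + dB.sum()) / n),
        rmsd=float(np.sqrt((np.square(dA).sum() + np.square(dB).sum()) / n)),
        msd=float(max(dA.max(), dB.max())),
    )


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice overlap coefficient (used for phantom benchmarking only)."""
    A, B = np.asarray(A).astype(bool), np.asarray(B).astype(bool)
    denom = A.sum() + B.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(A, B).sum() / denom


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def challenge_scores(
    m: SurfaceMetrics | dict[str, float], percent_inputs: bool = False
) -> ScoreCard:
    """Grand Challenge score conversion.

    Each metric maps to ``max(0, 100 - 25 * error / reference_error)``
    with the reference errors of :data:`SCORE_REFERENCE_ERRORS`; the
    total is the rounded mean of the five unrounded scores.  VOE and RVD
    are fractions unless ``percent_inputs`` is set (then they are given
    in percent, as printed in challenge tables).
    """
    if isinstance(m, SurfaceMetrics):
        vals = {"voe": m.voe, "rvd": m.rvd, "asd": m.asd, "rmsd": m.rmsd, "msd": m.msd}
    else:
        vals = dict(m)
    if not percent_inputs:
        vals = {**vals, "voe": 100.0 * vals["voe"], "rvd": 100.0 * abs(vals["rvd"])}
    else:
        vals = {**vals, "rvd": abs(vals["rvd"])}
    raw = {
        k: max(0.0, 100.0 - 25.0 * vals[k] / SCORE_REFERENCE_ERRORS[k])
        for k in SCORE_REFERENCE_ERRORS
    }
    total = _round_half_away(float(np.mean(list(raw.values()))))
    return ScoreCard(
        voe=_round_half_away(raw["voe"]),
        rvd=_round_half_away(raw["rvd"]),
        asd=_round_half_away(raw["asd"]),
        rmsd=_round_half_away(raw["rmsd"]),
        msd=_round_half_away(raw["msd"]),
        total=total,
    )
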