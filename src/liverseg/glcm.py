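"""Gray-level co-occurrence matrix (GLCM) appearance features.

A GLCM is the normalized joint histogram of quantized intensity pairs
``(a, b)`` observed at a fixed pixel offset (distance ``d``, direction
``theta``) inside a local patch.  Twelve summary statistics of each GLCM
describe the patch texture; concatenating them over a set of offsets
yields the per-pixel appearance vector used by the classifier cascade.

Conventions pinned here (and shared with the context-feature module):

* coordinates are 0-based ``(row, col)``;
* angles are measured counterclockwise with 0 deg pointing along +col,
  so with rows growing downward the offset for angle ``theta`` is
  ``(-d*sin(theta), d*cos(theta))``.  Diagonal offsets step the full
  distance ``d`` on both axes (chessboard metric), the usual Haralick
  convention: 45 deg at d=1 is the offset (-1, +1);
* GLCM feature formulas use the bin indices ``a, b in {0..Q-1}``;
* entropy uses the natural logarithm, with ``0*log 0 = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: the 12 texture statistics, in the fixed output order
FEATURE_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "homogeneity",
    "entropy",
    "autocorrelation",
    "dissimilarity",
    "cluster_shade",
    "cluster_tendency",
    "max_probability",
    "variance",
    "sum_mean",
)

N_FEATURES = len(FEATURE_NAMES)  # 12

_VALID_ANGLES = (0, 45, 90, 135)

#: default offset set: distances {1, 2} at the four standard directions
DEFAULT_OFFSETS = tuple((d, a) for d in (1, 2) for a in _VALID_ANGLES)


def _offset_vector(d: int, angle: int) -> tuple[int, int]:
    """(row, col) step for one co-occurrence offset (chessboard diagonals)."""
    if angle == 0:
        return (0, d)
    if angle == 45:
        return (-d, d)
    if angle == 90:
        return (-d, 0)
    if angle == 135:
        return (-d, -d)
    raise ValueError(f"angle must be one of {_VALID_ANGLES}, got {angle}")


@dataclass(frozen=True)
class GLCMConfig:
    """Parameters of the GLCM appearance descriptor.

    Attributes
    ----------
    quant_levels:
        Number of intensity bins Q; the GLCM is Q x Q.
    offsets:
        Sequence of ``(distance, angle_deg)`` pairs; angles restricted to
        {0, 45, 90, 135}.
    patch_radius:
        The local patch is the ``(2r+1) x (2r+1)`` window centered on the
        pixel.
    symmetric:
        Count each pixel pair in both directions (the GLCM then equals
        its transpose).
    intensity_range:
        ``(lo, hi)`` used for quantization, or ``None`` to take the
        0.5th-99.5th percentile of each image (CT slices carry extreme
        air/bone values that would otherwise crush the bin resolution).
    """

    quant_levels: int = 16
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    patch_radius: int = 7
    symmetric: bool = True
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.quant_levels < 2:
            raise ValueError(f"quant_levels must be >= 2, got {self.quant_levels}")
        if len(self.offsets) < 1:
            raise ValueError("at least one (distance, angle) offset is required")
        side = 2 * self.patch_radius + 1
        for d, a in self.offsets:
            if d < 1:
                raise ValueError(f"offset distance must be >= 1, got {d}")
            if a not in _VALID_ANGLES:
                raise ValueError(f"angle must be one of {_VALID_ANGLES}, got {a}")
            if d >= side:
                raise ValueError(
                    f"offset distance {d} does not fit in a {side}x{side} patch"
                )
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.intensity_range is not None:
            lo, hi = self.intensity_range
            if not lo < hi:
                raise ValueError(f"intensity_range must satisfy lo < hi, got {lo}, {hi}")

    @property
    def n_offsets(self) -> int:
        return len(self.offsets)

    @property
    def n_features(self) -> int:
        """Length of the appearance vector: 12 per offset."""
        return N_FEATURES * self.n_offsets

    def schema(self) -> list[tuple[str, int, int]]:
        """Ordered ``(feature_name, distance, angle)`` labels."""
        return [(name, d, a) for (d, a) in self.offsets for name in FEATURE_NAMES]

    def schema_table(self) -> str:
        """The feature schema as a plain-text (TSV) table for inspection."""
        lines = ["index\tfeature\tdistance\tangle_deg"]
        lines += [f"{i}\t{n}\t{d}\t{a}" for i, (n, d, a) in enumerate(self.schema())]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GLCM:
    """One normalized co-occurrence matrix."""

    probs: np.ndarray  # (Q, Q), sums to 1
    offset: tuple[int, int]  # (distance, angle_deg)
    pair_count: int

    def __post_init__(self) -> None:
        if self.pair_count > 0 and abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise ValueError("GLCM probabilities must sum to 1")


@dataclass(frozen=True)
class AppearanceVector:
    """Concatenated 12-feature texture descriptor over all offsets."""

    values: np.ndarray  # (12 * J,)
    schema: list[tuple[str, int, int]] = field(repr=False)


def resolve_range(image: np.ndarray, cfg: GLCMConfig) -> tuple[float, float]:
    """Quantization range: explicit config range, else robust percentiles."""
    if cfg.intensity_range is not None:
        return cfg.intensity_range
    lo, hi = np.percentile(image, [0.5, 99.5])
    if lo == hi:  # constant image: any range containing the value works
        lo, hi = float(lo), float(lo) + 1.0
    return float(lo), float(hi)


def quantize(image: np.ndarray, cfg: GLCMConfig) -> np.ndarray:
    """Linear binning of clipped intensities into Q equal-width bins.

    Returns an integer image in ``[0, Q-1]`` of the same shape.
    """
    image = np.asarray(image, dtype=float)
    bad = ~np.isfinite(image)
    if bad.any():
        loc = tuple(int(c) for c in np.argwhere(bad)[0])
        raise ValueError(f"non-finite pixel at {loc}")
    lo, hi = resolve_range(image, cfg)
    q = (np.clip(image, lo, hi) - lo) / (hi - lo) * cfg.quant_levels
    return np.clip(q.astype(np.int64), 0, cfg.quant_levels - 1)


def compute_glcm(patch: np.ndarray, d: int, angle: int, cfg: GLCMConfig) -> GLCM:
    """Co-occurrence matrix of one quantized patch at one offset.

    Counts ordered pairs ``(p, p + offset)`` that lie fully inside the
    patch; adds the transposed counts when ``cfg.symmetric``.
    """
    patch = np.asarray(patch)
    if not np.issubdtype(patch.dtype, np.integer):
        raise TypeError("patch must be quantized (integer dtype)")
    dr, dc = _offset_vector(d, angle)
    h, w = patch.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset ({dr},{dc}) does not fit in a {h}x{w} patch")
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    a = patch[r0:r1, c0:c1].ravel()
    b = patch[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    if a.size == 0:
        raise ValueError("offset yields zero pixel pairs")
    Q = cfg.quant_levels
    counts = np.zeros((Q, Q), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    if cfg.symmetric:
        counts = counts + counts.T
    total = int(counts.sum())
    return GLCM(probs=counts / total, offset=(d, angle), pair_count=int(a.size))


def _glcm_features(p: np.ndarray) -> np.ndarray:
    """The 12 statistics for a stack of GLCMs.

    ``p`` has shape (Q, Q, K) with the matrix axes first; returns an
    array of shape (12, K).  Degenerate matrices (zero marginal
    variance) get correlation 0.
    """
    Q = p.shape[0]
    a = np.arange(Q, dtype=float)[:, None, None]
    b = np.arange(Q, dtype=float)[None, :, None]
    ax = (0, 1)

    energy = (p**2).sum(axis=ax)
    contrast = ((a - b) ** 2 * p).sum(axis=ax)
    homogeneity = (p / (1.0 + np.abs(a - b))).sum(axis=ax)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    entropy = -plogp.sum(axis=ax)
    autocorr = (a * b * p).sum(axis=ax)
    dissim = (np.abs(a - b) * p).sum(axis=ax)
    max_prob = p.max(axis=ax)

    mu_a = (a * p).sum(axis=ax)
    mu_b = (b * p).sum(axis=ax)
    var_a = (a**2 * p).sum(axis=ax) - mu_a**2
    var_b = (b**2 * p).sum(axis=ax) - mu_b**2
    cov = autocorr - mu_a * mu_b
    sigma = np.sqrt(np.clip(var_a, 0, None) * np.clip(var_b, 0, None))
    correlation = np.where(sigma > 0, cov / np.where(sigma > 0, sigma, 1.0), 0.0)

    # central moments of (a + b)
    s = a + b
    s1 = (s * p).sum(axis=ax)
    s2 = (s**2 * p).sum(axis=ax)
    s3 = (s**3 * p).sum(axis=ax)
    mu_s = mu_a + mu_b
    cluster_tendency = s2 - 2 * mu_s * s1 + mu_s**2
    cluster_shade = s3 - 3 * mu_s * s2 + 3 * mu_s**2 * s1 - mu_s**3

    # variance about the grand mean (a- and b-marginals pooled)
    mu = 0.5 * (mu_a + mu_b)
    variance = (a**2 * p).sum(axis=ax) - 2 * mu * mu_a + mu**2
    sum_mean = 0.5 * s1

    return np.stack(
        [
            energy,
            contrast,
            correlation,
            homogeneity,
            entropy,
            autocorr,
            dissim,
            cluster_shade,
            cluster_tendency,
            max_prob,
            variance,
            sum_mean,
        ]
    )


def haralick12(g: GLCM) -> np.ndarray:
    """The 12 named texture statistics of one GLCM, in schema order."""
    p = np.asarray(g.probs, dtype=float)
    mu_a = (np.arange(p.shape[0]) * p.sum(axis=1)).sum()
    var_a = ((np.arange(p.shape[0]) - mu_a) ** 2 * p.sum(axis=1)).sum()
    mu_b = (np.arange(p.shape[1]) * p.sum(axis=0)).sum()
    var_b = ((np.arange(p.shape[1]) - mu_b) ** 2 * p.sum(axis=0)).sum()
    if var_a * var_b == 0.0:
        warnings.warn("degenerate GLCM (zero marginal variance): correlation set to 0")
    return _glcm_features(p[..., None])[:, 0]


def appearance_vector(image: np.ndarray, x: tuple[int, int], cfg: GLCMConfig) -> AppearanceVector:
    """Appearance descriptor of the patch centered on pixel ``x``.

    The image is reflect-padded by ``patch_radius`` so border pixels have
    a full patch.  Features for all offsets are concatenated in config
    order, 12 per offset.
    """
    image = np.asarray(image, dtype=float)
    r, c = x
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise IndexError(f"pixel {x} outside image of shape {image.shape}")
    rad = cfg.patch_radius
    q = np.pad(quantize(image, cfg), rad, mode="reflect")
    patch = q[r : r + 2 * rad + 1, c : c + 2 * rad + 1]
    parts = [haralick12(compute_glcm(patch, d, a, cfg)) for d, a in cfg.offsets]
    return AppearanceVector(values=np.concatenate(parts), schema=cfg.schema())


def appearance_feature_map(image: np.ndarray, cfg: GLCMConfig) -> np.ndarray:
    """Per-pixel appearance vectors for a whole image, shape (H, W, 12*J).

    Equivalent to calling :func:`appearance_vector` at every pixel but
    computed with integral images: for each offset, co-occurring pairs
    are encoded as a channel index ``a*Q + b`` and patch-local pair
    counts are read off summed-area tables, one per channel.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    rad = cfg.patch_radius
    Q = cfg.quant_levels
    q = np.pad(quantize(image, cfg), rad, mode="reflect")
    out = np.empty((H, W, cfg.n_features), dtype=np.float64)

    for j, (d, angle) in enumerate(cfg.offsets):
        dr, dc = _offset_vector(d, angle)
        r0, c0 = max(0, -dr), max(0, -dc)
        Hp, Wp = q.shape
        # pair-start positions: S[i,jj] is the channel of the pair starting
        # at padded pixel (i + r0, jj + c0)
        a = q[r0 : Hp - max(0, dr), c0 : Wp - max(0, dc)]
        b = q[r0 + dr : Hp - max(0, dr) + dr, c0 + dc : Wp - max(0, dc) + dc]
        S = a * Q + b
        onehot = S[None, :, :] == np.arange(Q * Q, dtype=S.dtype)[:, None, None]
        ii = np.zeros((Q * Q, S.shape[0] + 1, S.shape[1] + 1), dtype=np.int32)
        ii[:, 1:, 1:] = onehot.cumsum(axis=1, dtype=np.int32).cumsum(axis=2, dtype=np.int32)
        # for output pixel (y, x): start rows y .. y+2rad-|dr|, cols x .. x+2rad-|dc|
        hh = 2 * rad + 1 - abs(dr)
        ww = 2 * rad + 1 - abs(dc)
        counts = (
            ii[:, hh : hh + H, ww : ww + W]
            - ii[:, hh : hh + H, 0:W]
            - ii[:, 0:H, ww : ww + W]
            + ii[:, 0:H, 0:W]
        ).reshape(Q, Q, H, W).astype(np.float64)
        if cfg.symmetric:
            counts = counts + counts.transpose(1, 0, 2, 3)
        total = counts.sum(axis=(0, 1))
        p = (counts / total).reshape(Q, Q, H * W)
        feats = _glcm_features(p)  # (12, H*W)
        out[:, :, j * N_FEATURES : (j + 1) * N_FEATURES] = feats.T.reshape(H, W, N_FEATURES)
    return out
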