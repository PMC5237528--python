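"""Auto-context cascade of boosted pixel classifiers.

A first AdaBoost classifier is trained on GLCM appearance features
alone.  Each later round augments the appearance vector with *context
features*: liver probabilities sampled from the previous round's
probability map along 8 rays at 45-degree intervals, at a fixed radius
ladder.  Because the context encodes where high-probability tissue lies
relative to the pixel, confuser structures that share the liver's
intensity and texture but not its spatial configuration are suppressed
round by round.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .boosting import BoostedClassifier, Stump, margin_to_prob, train_boost
from .glcm import GLCMConfig, N_FEATURES, appearance_feature_map

logger = logging.getLogger(__name__)

ARCHIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingCase:
    """One training image with its binary liver label map."""

    image: np.ndarray
    label_map: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        if self.image.shape != self.label_map.shape:
            raise ValueError(f"case {self.id!r}: image and label_map shapes differ")
        vals = np.unique(self.label_map)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"case {self.id!r}: label_map must be binary")


@dataclass(frozen=True)
class ContextConfig:
    """Geometry of the 8-ray context sampling pattern.

    ``radii`` is the ladder of sampling distances (pixels) along each
    ray; with ``include_center`` the pixel's own probability is
    prepended.  Feature order is fixed: center, then ray-major
    (ray 0 at 0 deg counterclockwise, ... ray 7 at 315 deg), radii in
    config order within each ray.
    """

    radii: tuple[int, ...] = (3, 6, 9, 12, 15)
    include_center: bool = True
    n_rays: int = 8  # fixed by the sampling pattern
    angle_step: float = 45.0

    def __post_init__(self) -> None:
        if self.n_rays != 8 or self.angle_step != 45.0:
            raise ValueError("the context pattern is fixed at 8 rays / 45 deg")
        if len(self.radii) < 1 or any(r < 1 for r in self.radii):
            raise ValueError("radii must be positive integers")

    @property
    def n_features(self) -> int:
        return self.n_rays * len(self.radii) + (1 if self.include_center else 0)

    def offsets(self) -> np.ndarray:
        """(n_features, 2) integer (drow, dcol) sample offsets, in feature order."""
        out = []
        if self.include_center:
            out.append((0, 0))
        for k in range(self.n_rays):
            ang = np.deg2rad(k * self.angle_step)
            for r in self.radii:
                # counterclockwise angles, 0 deg = +col, rows grow downward
                out.append((-int(np.rint(r * np.sin(ang))), int(np.rint(r * np.cos(ang)))))
        return np.array(out, dtype=int)


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-pixel liver probability in [0, 1] after ``iteration`` cascade stages."""

    probs: np.ndarray
    iteration: int

    def __post_init__(self) -> None:
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ClassifierCascade:
    """The trained stage sequence H_0 ... H_U plus its feature configs."""

    stages: tuple[BoostedClassifier, ...]
    glcm_config: GLCMConfig
    context_config: ContextConfig

    def __post_init__(self) -> None:
        n_app = self.glcm_config.n_features
        n_ctx = self.context_config.n_features
        if self.stages[0].n_features != n_app:
            raise ValueError("stage 0 must consume appearance features only")
        for u, st in enumerate(self.stages[1:], start=1):
            if st.n_features != n_app + n_ctx:
                raise ValueError(f"stage {u} must consume appearance+context features")

    @property
    def n_iterations(self) -> int:
        """U: number of context-augmented stages."""
        return len(self.stages) - 1


def sample_training_pixels(
    case: TrainingCase, n_per_class: int, rng_seed: int
) -> list[tuple[tuple[int, int], int]]:
    """Balanced random pixel sample, ``n_per_class`` from each class.

    Sampling is without replacement; a class smaller than
    ``n_per_class`` is used whole (with a warning).  Deterministic for a
    given seed.
    """
    rng = np.random.default_rng(rng_seed)
    out: list[tuple[tuple[int, int], int]] = []
    for label in (1, 0):
        coords = np.argwhere(case.label_map == label)
        if coords.size == 0:
            raise ValueError(f"case {case.id!r}: class {label} absent from label_map")
        if len(coords) < n_per_class:
            logger.warning(
                "case %r: class %d has only %d pixels (< %d requested); using all",
                case.id, label, len(coords), n_per_class,
            )
            chosen = coords
        else:
            chosen = coords[rng.choice(len(coords), size=n_per_class, replace=False)]
        out.extend(((int(r), int(c)), label) for r, c in chosen)
    return out


def context_features(pm: ProbabilityMap, x: tuple[int, int], cfg: ContextConfig) -> np.ndarray:
    """Context vector at one pixel; samples leaving the image read as 0."""
    r, c = x
    H, W = pm.probs.shape
    if not (0 <= r < H and 0 <= c < W):
        raise IndexError(f"pixel {x} outside map of shape {pm.probs.shape}")
    out = np.zeros(cfg.n_features)
    for i, (dr, dc) in enumerate(cfg.offsets()):
        rr, cc = r + dr, c + dc
        if 0 <= rr < H and 0 <= cc < W:
            out[i] = pm.probs[rr, cc]
    return out


def context_feature_map(pm: ProbabilityMap, cfg: ContextConfig) -> np.ndarray:
    """Context vectors for every pixel, shape (H, W, n_ctx)."""
    H, W = pm.probs.shape
    offs = cfg.offsets()
    out = np.zeros((H, W, len(offs)))
    for i, (dr, dc) in enumerate(offs):
        src_r0, src_r1 = max(0, dr), min(H, H + dr)
        src_c0, src_c1 = max(0, dc), min(W, W + dc)
        dst_r0, dst_r1 = max(0, -dr), min(H, H - dr)
        dst_c0, dst_c1 = max(0, -dc), min(W, W - dc)
        out[dst_r0:dst_r1, dst_c0:dst_c1, i] = pm.probs[src_r0:src_r1, src_c0:src_c1]
    return out


def _stage_map(stage: BoostedClassifier, features: np.ndarray, iteration: int) -> ProbabilityMap:
    H, W, F = features.shape
    p = stage.predict_proba(features.reshape(H * W, F)).reshape(H, W)
    return ProbabilityMap(probs=p, iteration=iteration)


def train_cascade(
    cases: list[TrainingCase],
    U: int = 4,
    glcm_config: GLCMConfig | None = None,
    context_config: ContextConfig | None = None,
    n_per_class: int = 2000,
    n_rounds: int = 100,
    rng_seed: int = 0,
    n_folds: int = 3,
) -> ClassifierCascade:
    """Train the full auto-context cascade (stage 0 appearance-only,
    stages 1..U appearance+context).

    Between stages, each training image's probability map is recomputed
    over *all* pixels so that context features are well defined
    everywhere.  The maps are *cross-fitted*: cases are split into
    ``n_folds`` groups and each case's map comes from a classifier
    trained with that case's fold held out.  Resubstitution maps would
    be nearly perfect, so later stages would learn to trust context far
    more than test-time maps warrant and the cascade would amplify its
    own mistakes; cross-fitting keeps training-time context as
    imperfect as test-time context.  (With a single training case the
    resubstitution map is used, with a warning.)
    """
    if U < 0:
        raise ValueError("U must be >= 0")
    if not cases:
        raise ValueError("at least one training case required")
    gcfg = glcm_config or GLCMConfig()
    ccfg = context_config or ContextConfig()

    seeds = np.random.SeedSequence(rng_seed).generate_state(len(cases))
    samples = []  # per case: (coords (n,2), labels (n,))
    app_maps = []
    app_feats = []
    for case, s in zip(cases, seeds):
        pix = sample_training_pixels(case, n_per_class, int(s) % (2**31))
        coords = np.array([p for p, _ in pix])
        labels = np.array([y for _, y in pix])
        samples.append((coords, labels))
        amap = appearance_feature_map(case.image, gcfg)
        app_maps.append(amap)
        app_feats.append(amap[coords[:, 0], coords[:, 1]])

    n_cases = len(cases)
    labels_per_case = [lab for _, lab in samples]
    y = np.concatenate(labels_per_case)
    case_of_sample = np.concatenate(
        [np.full(len(lab), k) for k, lab in enumerate(labels_per_case)]
    )
    k_folds = min(n_folds, n_cases)
    if k_folds < 2:
        logger.warning(
            "cross-fitting needs >= 2 training cases; falling back to "
            "resubstitution probability maps"
        )
    fold_of_case = np.arange(n_cases) % k_folds

    def fit(X: np.ndarray, stage: int, rows=slice(None)) -> BoostedClassifier:
        try:
            return train_boost(X[rows], y[rows], n_rounds=n_rounds,
                               rng_seed=rng_seed + stage)
        except ValueError as e:
            raise ValueError(f"stage {stage}: {e}") from e

    def crossfit_maps(X: np.ndarray, full: BoostedClassifier, stage: int, feats_per_case):
        """Per-case probability maps from held-out-fold classifiers."""
        if k_folds < 2:
            return [_stage_map(full, f, stage) for f in feats_per_case]
        maps: list[ProbabilityMap | None] = [None] * n_cases
        for f in range(k_folds):
            rows = np.flatnonzero(fold_of_case[case_of_sample] != f)
            clf = fit(X, stage, rows)
            for k in np.flatnonzero(fold_of_case == f):
                maps[k] = _stage_map(clf, feats_per_case[k], stage)
        return maps

    X0 = np.vstack(app_feats)
    stage0 = fit(X0, 0)
    stages = [stage0]
    pmaps = crossfit_maps(X0, stage0, 0, app_maps)

    for u in range(1, U + 1):
        ctx_feats = []
        for (coords, _), pm in zip(samples, pmaps):
            cmap = context_feature_map(pm, ccfg)
            ctx_feats.append(cmap[coords[:, 0], coords[:, 1]])
        Xu = np.hstack([X0, np.vstack(ctx_feats)])
        stage_u = fit(Xu, u)
        stages.append(stage_u)
        if u < U:
            feats_per_case = [
                np.concatenate([amap, context_feature_map(pm, ccfg)], axis=2)
                for amap, pm in zip(app_maps, pmaps)
            ]
            pmaps = crossfit_maps(Xu, stage_u, u, feats_per_case)
    return ClassifierCascade(stages=tuple(stages), glcm_config=gcfg, context_config=ccfg)


def apply_cascade(
    image: np.ndarray,
    cascade: ClassifierCascade,
    max_extra_iters: int = 5,
    tol: float = 1e-3,
) -> ProbabilityMap:
    """Run the trained cascade over a full image.

    After the last trained stage, that stage is re-applied up to
    ``max_extra_iters`` further times (context read from its own latest
    output), stopping early when the mean absolute map change drops
    below ``tol`` — the test-time convergence loop.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    amap = appearance_feature_map(image, cascade.glcm_config)
    pm = _stage_map(cascade.stages[0], amap, 0)
    ccfg = cascade.context_config
    for u, stage in enumerate(cascade.stages[1:], start=1):
        feats = np.concatenate([amap, context_feature_map(pm, ccfg)], axis=2)
        pm = _stage_map(stage, feats, u)
    if cascade.n_iterations > 0:
        final = cascade.stages[-1]
        for _ in range(max_extra_iters):
            if not tol < np.inf:  # tol=inf: any change counts as converged
                break
            feats = np.concatenate([amap, context_feature_map(pm, ccfg)], axis=2)
            nxt = _stage_map(final, feats, pm.iteration + 1)
            delta = float(np.abs(nxt.probs - pm.probs).mean())
            if delta < tol:  # negligible change: keep the settled map
                break
            pm = nxt
    return pm


# -- serialization ----------------------------------------------------------

def save_cascade(cascade: ClassifierCascade, path) -> None:
    """Write the cascade to a self-describing JSON archive."""
    doc = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "glcm_config": {
            "quant_levels": cascade.glcm_config.quant_levels,
            "offsets": [list(o) for o in cascade.glcm_config.offsets],
            "patch_radius": cascade.glcm_config.patch_radius,
            "symmetric": cascade.glcm_config.symmetric,
            "intensity_range": list(cascade.glcm_config.intensity_range)
            if cascade.glcm_config.intensity_range is not None
            else None,
        },
        "context_config": {
            "radii": list(cascade.context_config.radii),
            "include_center": cascade.context_config.include_center,
        },
        "stages": [
            {
                "n_features": st.n_features,
                "weights": list(st.weights),
                "stumps": [[s.feature, s.threshold, s.polarity] for s in st.stumps],
            }
            for st in cascade.stages
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_cascade(path) -> ClassifierCascade:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != ARCHIVE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported cascade archive version {version!r} "
            f"(expected {ARCHIVE_FORMAT_VERSION})"
        )
    g = doc["glcm_config"]
    gcfg = GLCMConfig(
        quant_levels=g["quant_levels"],
        offsets=tuple(tuple(o) for o in g["offsets"]),
        patch_radius=g["patch_radius"],
        symmetric=g["symmetric"],
        intensity_range=tuple(g["intensity_range"]) if g["intensity_range"] else None,
    )
    c = doc["context_config"]
    ccfg = ContextConfig(radii=tuple(c["radii"]), include_center=c["include_center"])
    stages = tuple(
        BoostedClassifier(
            stumps=tuple(Stump(int(f), float(t), int(p)) for f, t, p in st["stumps"]),
            weights=tuple(float(w) for w in st["weights"]),
            n_features=int(st["n_features"]),
        )
        for st in doc["stages"]
    )
    return ClassifierCascade(stages=stages, glcm_config=gcfg, context_config=ccfg)
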