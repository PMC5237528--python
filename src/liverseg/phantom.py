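"""Synthetic abdominal-slice phantoms with ground-truth liver masks.

Each phantom emulates the statistical structure that makes automatic
liver segmentation hard on real CT slices: one large, irregular, bright
organ placed right of the image center (the liver), adjacent *confuser*
structures (kidney / muscle / vessel stand-ins) whose mean intensity
matches the liver's to within ±0.02 but whose texture correlation
length differs, internal darker lesions (tumors / cysts — part of the
liver in the ground truth, as in the challenge convention), and
additive Gaussian noise.  By construction a plain intensity threshold
cannot separate liver from confusers; texture and spatial context can.

Organ texture is band-limited noise: white noise smoothed to an
organ-specific correlation length and scaled to a fixed amplitude, so
organs share a mean but differ in second-order (GLCM-visible)
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters.

    Intensities are means in [0, 1]; texture scales are Gaussian
    correlation lengths in pixels; ``noise_sigma`` is the standard
    deviation of the additive white noise applied last; ``spacing`` is
    the physical pixel size in mm.
    """

    image_size: tuple[int, int] = (128, 128)
    liver_intensity: float = 0.62
    background_intensity: float = 0.30
    confuser_intensity: float = 0.62
    liver_texture_scale: float = 1.0
    confuser_texture_scale: float = 3.0
    texture_amplitude: float = 0.07
    n_confusers: int = 3
    lesion_count: int = 2
    lesion_intensity: float = 0.45
    noise_sigma: float = 0.03
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if min(self.image_size) < 64:
            raise ValueError("image_size must be at least 64x64")
        for name in ("liver_intensity", "background_intensity",
                     "confuser_intensity", "lesion_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_confusers < 0 or self.lesion_count < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class PhantomCase:
    image: np.ndarray
    truth_mask: np.ndarray
    confuser_masks: tuple[np.ndarray, ...]
    spec: PhantomSpec
    seed: int
    id: str = ""


_MAX_TRIES = 60


def _harmonic_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    rng: np.random.Generator,
    wobble: float = 0.12,
) -> np.ndarray:
    """Star-convex mask: ellipse with low-order harmonic boundary wobble."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = (rr - center[0]) / radii[0]
    dx = (cc - center[1]) / radii[1]
    rho = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    bound = np.ones_like(phi)
    for k in range(2, 6):
        amp = rng.normal(0.0, wobble / k)
        ph = rng.uniform(0, 2 * np.pi)
        bound += amp * np.cos(k * phi + ph)
    return rho <= bound


def _band_limited_texture(
    shape: tuple[int, int], scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean unit-std noise with Gaussian correlation length ``scale``."""
    t = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="wrap")
    return (t - t.mean()) / t.std()


def generate_case(spec: PhantomSpec, seed: int, case_id: str = "") -> PhantomCase:
    """One phantom image + ground truth, fully deterministic given seed."""
    rng = np.random.default_rng(seed)
    H, W = spec.image_size

    # liver: large irregular blob right of the image center, 10-40% area
    liver = None
    for _ in range(_MAX_TRIES):
        center = (H * rng.uniform(0.42, 0.55), W * rng.uniform(0.58, 0.68))
        radii = (H * rng.uniform(0.24, 0.30), W * rng.uniform(0.22, 0.28))
        cand = _harmonic_blob((H, W), center, radii, rng)
        frac = cand.mean()
        lbl, n = ndimage.label(cand)
        if 0.10 <= frac <= 0.40 and n == 1:
            liver = cand
            break
    if liver is None:
        raise RuntimeError("liver mask constraint unsatisfiable: "
                           "connected component with 10-40% area not found")

    near_liver = ndimage.binary_dilation(liver, iterations=3)

    # confusers: adjacent blobs sharing the liver's mean intensity
    confusers: list[np.ndarray] = []
    liver_and_conf = liver.copy()
    boundary = np.argwhere(liver & ~ndimage.binary_erosion(liver))
    for _ in range(spec.n_confusers):
        placed = False
        for _ in range(_MAX_TRIES):
            br, bc = boundary[rng.integers(len(boundary))]
            direction = np.array([br - H / 2.0, bc - W * 0.63])
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 0 else np.array([0.0, -1.0])
            c_radii = (H * rng.uniform(0.11, 0.16), W * rng.uniform(0.11, 0.16))
            gap = rng.uniform(1.0, 2.5)
            ccenter = (
                br + direction[0] * (c_radii[0] + gap),
                bc + direction[1] * (c_radii[1] + gap),
            )
            cand = _harmonic_blob((H, W), ccenter, c_radii, rng, wobble=0.08)
            cand &= ~liver_and_conf  # disjoint from liver and earlier confusers
            lbl, n = ndimage.label(cand)
            if n != 1 or cand.sum() < 0.025 * H * W:
                continue
            if not (cand & near_liver).any():  # must stay within 3 px of the liver
                continue
            confusers.append(cand)
            liver_and_conf |= cand
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "confuser constraint unsatisfiable: could not place a blob "
                "disjoint from, but within 3 px of, the liver"
            )

    # compose intensities
    image = np.full((H, W), spec.background_intensity)
    image[liver] = spec.liver_intensity
    for cm in confusers:
        # per-confuser mean intensity within +-0.02 of the configured value
        image[cm] = np.clip(spec.confuser_intensity + rng.uniform(-0.02, 0.02), 0, 1)

    # lesions: darker blobs strictly inside the liver; still liver in truth
    interior = ndimage.binary_erosion(liver, iterations=6)
    interior_pts = np.argwhere(interior)
    for _ in range(spec.lesion_count if interior_pts.size else 0):
        lr, lc = interior_pts[rng.integers(len(interior_pts))]
        l_rad = rng.uniform(2.5, 5.0)
        lesion = _harmonic_blob((H, W), (float(lr), float(lc)), (l_rad, l_rad), rng,
                                wobble=0.10)
        image[lesion & liver] = spec.lesion_intensity

    # organ-specific band-limited texture
    if spec.texture_amplitude > 0:
        bg_tex = _band_limited_texture((H, W), 2.0, rng)
        liver_tex = _band_limited_texture((H, W), spec.liver_texture_scale, rng)
        conf_tex = _band_limited_texture((H, W), spec.confuser_texture_scale, rng)
        outside = ~liver_and_conf
        image[outside] += 0.3 * spec.texture_amplitude * bg_tex[outside]
        image[liver] += spec.texture_amplitude * liver_tex[liver]
        for cm in confusers:
            image[cm] += spec.texture_amplitude * conf_tex[cm]

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(H, W))

    return PhantomCase(
        image=image,
        truth_mask=liver.astype(np.uint8),
        confuser_masks=tuple(c.astype(np.uint8) for c in confusers),
        spec=spec,
        seed=seed,
        id=case_id,
    )


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """±10% multiplicative jitter on intensities so cases differ."""
    def j(v: float) -> float:
        return float(np.clip(v * rng.uniform(0.9, 1.1), 0.0, 1.0))

    liver = j(spec.liver_intensity)
    return replace(
        spec,
        liver_intensity=liver,
        background_intensity=j(spec.background_intensity),
        confuser_intensity=liver,  # confusers track the liver mean (±0.02 per blob)
        lesion_intensity=j(spec.lesion_intensity),
    )


def generate_dataset(
    n_train: int, n_test: int, spec: PhantomSpec | None = None, seed: int = 0
) -> tuple[list[PhantomCase], list[PhantomCase]]:
    """Reproducible train/test phantom sets with disjoint per-case seeds
    and per-case spec jitter."""
    spec = spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    case_seeds = ss.generate_state(n_train + n_test)
    cases = []
    for k, s in enumerate(case_seeds):
        rng = np.random.default_rng(int(s))
        jspec = _jitter_spec(spec, rng)
        cases.append(generate_case(jspec, int(s) % (2**31), case_id=f"case{k:03d}"))
    return cases[:n_train], cases[n_train:]
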