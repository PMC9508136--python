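"""Synthetic annotated skin-image generator with paired clinical covariates.

The generator emulates the structure of a smartphone dermatology collection:
mostly wide-field images containing one to a few elliptical lesions on a
textured skin background (three skin-tone presets recorded as metadata), and
a small fraction (~9%) of dermoscopy-style images with exactly one large,
centered lesion inside a circular vignette.  Lesion linear size defaults to
about 0.2 of the image side, matching the roughly 554-px lesions in
2834-px images of the reference collection; the default type mix follows
the reference per-type lesion frequencies (57% malignant overall).

Appearance carries the learnable signal: malignant types are rendered
darker (brown/blue-grey shift), with irregular borders and an off-center
pigment core, scaled by ``appearance_separation``; benign types are lighter
and smooth.  The ground-truth box of each lesion is the tight bounding box
of its rendered mask.  Everything is driven by a single seed and is
bit-reproducible.

Clinical covariates are simulated per image either conditionally on the
rendered image label (default) or in "covariate-driven" mode where the
label itself is re-drawn from a logistic model over the covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .taxonomy import (
    DEFAULT_TAXONOMY,
    AnnotatedImage,
    LesionTaxonomy,
    LesionType,
    RoiBox,
    ledger_totals,
    load_reference_ledger,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "CovariateConfig",
    "LesionImageSimulator",
    "generate_dataset",
    "generate_covariates",
    "render_background",
    "reference_type_frequencies",
]

# Skin-tone presets (proportions follow the reference collection's
# light/medium/dark mix) and lesion base colors.  Malignant pigment shifts
# from the benign base toward the dark base as appearance_separation -> 1.
_TONES = {
    "light": np.array([224.0, 188.0, 160.0]),
    "medium": np.array([180.0, 138.0, 108.0]),
    "dark": np.array([110.0, 80.0, 60.0]),
}
_TONE_PROBS = {"light": 0.837, "medium": 0.149, "dark": 0.014}
_BENIGN_BASE = np.array([158.0, 112.0, 78.0])
_MALIGNANT_BASE = np.array([76.0, 52.0, 60.0])
_VIGNETTE = np.array([18.0, 18.0, 24.0])


def reference_type_frequencies(
    taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY,
) -> dict[LesionType, float]:
    """Per-type lesion frequencies of the packaged discovery ledger."""
    ledger = load_reference_ledger("discovery")
    total = ledger_totals(ledger, taxonomy).total
    return {t: ledger.count(t) / total for t in taxonomy.types}


@dataclass
class SimConfig:
    """Study conditions for the synthetic image generator."""

    image_size_range: tuple[int, int] = (96, 160)
    lesions_per_image_range: tuple[int, int] = (1, 4)
    lesion_side_fraction_range: tuple[float, float] = (0.10, 0.30)
    type_frequencies: dict[LesionType, float] | None = None  # None -> reference mix
    appearance_separation: float = 0.8
    dermoscopy_fraction: float = 0.09
    noise_sd: float = 8.0
    max_overlap: float = 0.2
    max_attempts: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesions_per_image_range[0] < 1:
            raise ValueError("lesions_per_image_range minimum must be >= 1")
        if not 0.0 <= self.appearance_separation <= 1.0:
            raise ValueError("appearance_separation must be in [0, 1]")
        if not 0.0 <= self.dermoscopy_fraction <= 1.0:
            raise ValueError("dermoscopy_fraction must be in [0, 1]")
        if self.type_frequencies is not None:
            s = sum(self.type_frequencies.values())
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ValueError(f"type_frequencies sum to {s}, expected 1")

    def frequencies(
        self, taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY
    ) -> dict[LesionType, float]:
        if self.type_frequencies is None:
            return reference_type_frequencies(taxonomy)
        return dict(self.type_frequencies)


def render_background(
    height: int,
    width: int,
    tone: str,
    rng: np.random.Generator,
    noise_sd: float = 8.0,
) -> np.ndarray:
    """Textured skin-tone field (float64 HxWx3, unclipped)."""
    base = _TONES[tone]
    img = np.tile(base, (height, width, 1))
    texture = gaussian_filter(
        rng.normal(0.0, 1.0, (height, width)), sigma=max(3.0, height / 16)
    )
    scale = texture.std() or 1.0
    img += (texture / scale * 6.0)[..., None]
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    return img


def _lesion_mask(
    height: int,
    width: int,
    cx: float,
    cy: float,
    ax: float,
    ay: float,
    irregularity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean mask of a radially perturbed ellipse."""
    yy, xx = np.mgrid[0:height, 0:width]
    dx = (xx - cx) / ax
    dy = (yy - cy) / ay
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    ring = np.ones_like(r)
    if irregularity > 0:
        for k in (2, 3, 5):
            amp = irregularity * rng.uniform(0.3, 1.0) / len((2, 3, 5))
            ring += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return r <= ring


@dataclass
class _RenderedLesion:
    mask: np.ndarray
    box: RoiBox
    lesion_type: LesionType


def _tight_box(mask: np.ndarray) -> RoiBox:
    ys, xs = np.nonzero(mask)
    # half-open pixel extents: a pixel at index i spans [i, i+1)
    return RoiBox.from_corners(
        float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1)
    )


class LesionImageSimulator:
    """Seeded generator of annotated synthetic lesion images."""

    def __init__(
        self,
        config: SimConfig | None = None,
        taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY,
    ):
        self.config = config or SimConfig()
        self.taxonomy = taxonomy

    # -- single-image rendering -----------------------------------------

    def _render_lesion(
        self,
        img: np.ndarray,
        lesion_type: LesionType,
        cx: float,
        cy: float,
        ax: float,
        ay: float,
        rng: np.random.Generator,
    ) -> _RenderedLesion:
        cfg = self.config
        s = cfg.appearance_separation
        malignant = self.taxonomy.is_malignant(lesion_type)
        h, w = img.shape[:2]

        irregularity = 0.08 * s if malignant else 0.02
        mask = _lesion_mask(h, w, cx, cy, ax, ay, irregularity, rng)
        if not mask.any():  # degenerate placement; caller re-samples
            raise RuntimeError("empty lesion mask")

        if malignant:
            color = _BENIGN_BASE + s * (_MALIGNANT_BASE - _BENIGN_BASE)
        else:
            color = _BENIGN_BASE.copy()
        color = color + rng.uniform(-1.0, 1.0, 3) * (5.0 + 15.0 * (1.0 - s))

        alpha = gaussian_filter(mask.astype(float), sigma=0.8)
        img += alpha[..., None] * (color - img)

        if malignant and s > 0:
            # off-center pigment core: asymmetric darker blob
            core = _lesion_mask(
                h,
                w,
                cx + rng.uniform(-0.3, 0.3) * ax,
                cy + rng.uniform(-0.3, 0.3) * ay,
                ax * 0.45,
                ay * 0.45,
                0.1,
                rng,
            )
            core_alpha = gaussian_filter((core & mask).astype(float), 0.8)
            img -= core_alpha[..., None] * 28.0 * s

        return _RenderedLesion(mask, _tight_box(mask), lesion_type)

    def _sample_type(self, rng: np.random.Generator) -> LesionType:
        freqs = self.config.frequencies(self.taxonomy)
        types = list(freqs)
        probs = np.array([freqs[t] for t in types], dtype=float)
        return types[rng.choice(len(types), p=probs / probs.sum())]

    def render_image(
        self,
        image_id: str,
        rng: np.random.Generator,
        patient_id: str = "",
        keep_masks: bool = False,
    ) -> AnnotatedImage:
        cfg = self.config
        dermoscopy = rng.random() < cfg.dermoscopy_fraction
        lo, hi = cfg.image_size_range
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        tone = rng.choice(list(_TONE_PROBS), p=list(_TONE_PROBS.values()))
        img = render_background(h, w, tone, rng, noise_sd=0.0)

        rendered: list[_RenderedLesion] = []
        if dermoscopy:
            side = min(h, w)
            frac = rng.uniform(0.55, 0.75)
            lesion = self._render_lesion(
                img,
                self._sample_type(rng),
                w / 2.0,
                h / 2.0,
                frac * side / 2.0,
                frac * side / 2.0 * rng.uniform(0.8, 1.0),
                rng,
            )
            rendered.append(lesion)
        else:
            n_target = int(
                rng.integers(
                    cfg.lesions_per_image_range[0],
                    cfg.lesions_per_image_range[1] + 1,
                )
            )
            side = min(h, w)
            for _ in range(n_target):
                placed = False
                for _attempt in range(cfg.max_attempts):
                    fx = rng.uniform(*cfg.lesion_side_fraction_range)
                    fy = rng.uniform(*cfg.lesion_side_fraction_range)
                    ax = max(2.0, fx * side / 2.0)
                    ay = max(2.0, fy * side / 2.0)
                    margin_x, margin_y = 1.25 * ax + 1, 1.25 * ay + 1
                    if 2 * margin_x >= w or 2 * margin_y >= h:
                        continue
                    cx = rng.uniform(margin_x, w - margin_x)
                    cy = rng.uniform(margin_y, h - margin_y)
                    cand = RoiBox(cx, cy, 2 * ax, 2 * ay)
                    if any(
                        _box_overlap_fraction(cand, r.box) > cfg.max_overlap
                        for r in rendered
                    ):
                        continue
                    rendered.append(
                        self._render_lesion(
                            img, self._sample_type(rng), cx, cy, ax, ay, rng
                        )
                    )
                    placed = True
                    break
                if not placed:
                    logger.warning(
                        "image %s: could not place lesion %d/%d without "
                        "excessive overlap; emitting fewer lesions",
                        image_id,
                        len(rendered) + 1,
                        n_target,
                    )
            if not rendered:
                # guarantee the non-empty ROI invariant with a small
                # centered lesion
                ax = ay = max(3.0, 0.1 * side / 2.0)
                rendered.append(
                    self._render_lesion(
                        img, self._sample_type(rng), w / 2.0, h / 2.0, ax, ay, rng
                    )
                )

        if dermoscopy:
            yy, xx = np.mgrid[0:h, 0:w]
            radius = 0.48 * min(h, w)
            outside = (
                np.hypot(xx - w / 2.0, yy - h / 2.0) > radius
            )
            img[outside] = _VIGNETTE

        if cfg.noise_sd > 0:
            img += rng.normal(0.0, cfg.noise_sd, img.shape)
        pixels = np.clip(img, 0, 255).astype(np.uint8)

        metadata = {"skin_tone": str(tone)}
        if keep_masks:
            metadata["masks"] = [r.mask for r in rendered]
        return AnnotatedImage(
            image_id=image_id,
            pixels=pixels,
            rois=[(r.box, r.lesion_type) for r in rendered],
            capture_mode="dermoscopy" if dermoscopy else "wide_field",
            patient_id=patient_id or image_id,
            metadata=metadata,
        )

    # -- dataset-level API ----------------------------------------------

    def generate(
        self, n_images: int, keep_masks: bool = False
    ) -> list[AnnotatedImage]:
        if n_images < 1:
            raise ValueError("n_images must be >= 1")
        rng = np.random.default_rng(self.config.seed)
        return [
            self.render_image(f"sim_{i:05d}", rng, keep_masks=keep_masks)
            for i in range(n_images)
        ]


def _box_overlap_fraction(a: RoiBox, b: RoiBox) -> float:
    """Intersection area over the smaller box's area."""
    ax0, ay0, ax1, ay1 = a.corners()
    bx0, by0, bx1, by1 = b.corners()
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    return iw * ih / min(a.area, b.area)


def generate_dataset(
    config: SimConfig, n_images: int, keep_masks: bool = False
) -> list[AnnotatedImage]:
    """Generate ``n_images`` annotated images under the given conditions."""
    return LesionImageSimulator(config).generate(n_images, keep_masks=keep_masks)


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------


@dataclass
class CovariateConfig:
    """Simulated per-image clinical covariates.

    ``effect_on_logit`` values are coefficients on the standardized scale
    (per SD of a numeric covariate; per indicator for categorical levels).
    Defaults emulate an electronic-health-record style table: patient age,
    number of prior dermatology visits, and sex.
    """

    numeric_covariates: tuple[tuple[str, float, float, float], ...] = (
        ("age", 62.0, 14.0, 0.8),
        ("prior_visits", 3.0, 2.0, 0.3),
    )
    categorical_covariates: tuple[tuple[str, tuple[str, ...], tuple[float, ...]], ...] = (
        ("sex", ("F", "M"), (0.0, 0.2)),
    )
    intercept: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, *_ in self.numeric_covariates] + [
            n for n, *_ in self.categorical_covariates
        ]
        if len(set(names)) != len(names):
            raise ValueError(f"covariate name collision in {names}")
        for name, _, sd, _ in self.numeric_covariates:
            if sd <= 0:
                raise ValueError(f"covariate {name!r} must have sd > 0")
        for name, levels, effects in self.categorical_covariates:
            if len(levels) != len(effects):
                raise ValueError(f"covariate {name!r}: levels/effects mismatch")


def generate_covariates(
    images: Sequence[AnnotatedImage],
    config: CovariateConfig | None = None,
    taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY,
    mode: str = "conditional",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a covariate table (one row per image) and image labels.

    ``mode="conditional"`` (default): labels come from the rendered lesion
    types; numeric covariates are drawn as class-conditional Gaussians with
    unit SD on the standardized scale and means ``±effect/2``, so the
    implied logistic coefficient of covariate j is exactly its
    ``effect_on_logit``.  Categorical levels are re-weighted by
    ``exp(effect)`` for positives.

    ``mode="covariate_driven"``: the label is re-drawn as
    ``Bernoulli(sigmoid(intercept + sum of effects))`` given covariates
    sampled from their marginals, ignoring the rendered types.
    """
    config = config or CovariateConfig()
    if mode not in ("conditional", "covariate_driven"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    n = len(images)
    rows: dict[str, np.ndarray | list] = {
        "image_id": [im.image_id for im in images],
        "patient_id": [im.patient_id for im in images],
    }

    if mode == "covariate_driven":
        logit = np.full(n, config.intercept, dtype=float)
        for name, mean, sd, effect in config.numeric_covariates:
            z = rng.normal(0.0, 1.0, n)
            rows[name] = mean + sd * z
            logit += effect * z
        for name, levels, effects in config.categorical_covariates:
            idx = rng.integers(0, len(levels), n)
            rows[name] = [levels[i] for i in idx]
            logit += np.asarray(effects)[idx]
        labels = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    else:
        labels = np.array([im.label(taxonomy) for im in images], dtype=int)
        centered = labels - 0.5
        for name, mean, sd, effect in config.numeric_covariates:
            z = rng.normal(effect * centered, 1.0)
            rows[name] = mean + sd * z
        for name, levels, effects in config.categorical_covariates:
            effects = np.asarray(effects, dtype=float)
            base = np.ones(len(levels))
            out = []
            for y in labels:
                wts = base * np.exp(effects * y)
                out.append(levels[rng.choice(len(levels), p=wts / wts.sum())])
            rows[name] = out

    return pd.DataFrame(rows), labels
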