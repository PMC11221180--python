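"""Synthetic phantom radiographs with ground-truth masks and profusion labels.

The phantom emulates the features the staging pipeline consumes: two
bright lung-shaped ellipses on a darker torso-like background, small
bright discs ("small opacities") whose per-subregion count encodes a
profusion grade 0–3, an optional large coalescent opacity, additive
Gaussian intensity noise, and — for testing mask repair — injectable
mask defects (holes inside the lung fields, stray fragments outside).

Opacity counts per grade scale roughly ×3 per level (grade 1: 3–6,
grade 2: 10–20, grade 3: 30–60 discs per subregion at the default
256-px geometry), so grades are separable by a small CNN while the
class boundaries stay non-trivial.  Opacities are assigned to
subregions using the same bounding-rectangle 2×3 partition the pipeline
itself uses, so emitted labels and downstream crops agree by
construction, and the emitted whole-image stage is exactly the staging
rule applied to the emitted profusion vector.

Everything is driven by a single ``numpy`` generator seeded from the
spec: identical specs give bit-identical phantoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw as skdraw

from .maskops import SUBREGION_KEYS, partition_six
from .staging import StageLabel, stage_from_profusions

__all__ = [
    "PhantomSpec",
    "DefectSpec",
    "PhantomSample",
    "generate_phantom",
    "inject_defects",
    "random_spec",
    "write_dataset",
]

log = logging.getLogger(__name__)

#: intensity lift of a small opacity disc above the lung field, [0,1] scale.
#: Discs saturate rather than stack, mimicking projection: overlapping small
#: opacities stay at the same plateau instead of outshining large ones.
OPACITY_CONTRAST = 0.30
#: intensity lift of a large opacity blob; strictly above the small-opacity
#: plateau so large opacities remain the brightest structure in the image
LARGE_OPACITY_CONTRAST = 0.40

DEFAULT_OPACITIES_PER_LEVEL: dict[int, tuple[int, int]] = {1: (3, 6), 2: (10, 20), 3: (30, 60)}


def _default_lungs(size: int) -> tuple[dict, dict]:
    """Two disjoint rotated ellipses roughly where lungs sit on a radiograph."""
    left = dict(center=(0.48 * size, 0.31 * size), axes=(0.30 * size, 0.15 * size), rotation=-8.0)
    right = dict(center=(0.48 * size, 0.69 * size), axes=(0.30 * size, 0.15 * size), rotation=8.0)
    return left, right


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic radiograph; see module docstring."""

    image_size: int = 256
    lung_ellipse_params: tuple[dict, dict] | None = None
    background_level: float = 0.25
    lung_level: float = 0.55
    noise_sd: float = 0.02
    profusion_per_subregion: tuple[int, ...] = (0, 0, 0, 0, 0, 0)
    large_opacity: bool = False
    opacity_radius_range: tuple[int, int] = (2, 4)
    opacities_per_level: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_OPACITIES_PER_LEVEL))
    seed: int = 0

    def lungs(self) -> tuple[dict, dict]:
        return self.lung_ellipse_params or _default_lungs(self.image_size)

    def validate(self) -> None:
        if self.image_size < 64:
            raise ValueError(f"image_size: must be >= 64, got {self.image_size}")
        if len(self.profusion_per_subregion) != 6:
            raise ValueError("profusion_per_subregion: need exactly 6 values")
        for v in self.profusion_per_subregion:
            if v not in (0, 1, 2, 3):
                raise ValueError(f"profusion_per_subregion: levels must be in {{0..3}}, got {v!r}")
        if not (0.0 <= self.background_level <= 1.0 and 0.0 <= self.lung_level <= 1.0):
            raise ValueError("background_level/lung_level: must lie in [0,1]")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        lo, hi = self.opacity_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"opacity_radius_range: need 0 < lo <= hi, got {self.opacity_radius_range}")
        left = _ellipse_mask(self.image_size, **self.lungs()[0])
        right = _ellipse_mask(self.image_size, **self.lungs()[1])
        if (left & right).any():
            raise ValueError("lung_ellipse_params: lung ellipses must be disjoint")
        for name, m, pars in (("left", left, self.lungs()[0]), ("right", right, self.lungs()[1])):
            if not m.any():
                raise ValueError(f"lung_ellipse_params: {name} lung lies outside the image")
            if _touches_border(m):
                raise ValueError(f"lung_ellipse_params: {name} lung must lie inside the image")


@dataclass(frozen=True)
class DefectSpec:
    """Mask defects to inject: interior holes and exterior fragments."""

    n_holes: int = 0
    hole_radius: int = 2
    n_fragments: int = 0
    fragment_area: float = 13.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_holes", "n_fragments", "hole_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.fragment_area < 0:
            raise ValueError("fragment_area: must be >= 0")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray          # float32 in [0,1]
    mask: np.ndarray           # bool
    profusions: tuple[int, ...]
    large_opacity: bool
    stage: StageLabel


def _ellipse_mask(size: int, center, axes, rotation) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = skdraw.ellipse(center[0], center[1], axes[0], axes[1],
                            shape=(size, size), rotation=np.deg2rad(rotation))
    mask[rr, cc] = True
    return mask


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom radiograph with its mask, labels and stage."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    left, right = spec.lungs()
    mask = _ellipse_mask(size, **left) | _ellipse_mask(size, **right)
    img = np.full((size, size), spec.background_level, dtype=np.float32)
    img[mask] = spec.lung_level

    regions = partition_six(mask)
    for key, level in zip(SUBREGION_KEYS, spec.profusion_per_subregion):
        if level == 0:
            continue
        lo, hi = spec.opacities_per_level[level]
        count = int(rng.integers(lo, hi + 1))
        r0, r1, c0, c1 = regions.rects[key]
        cell = np.zeros_like(mask)
        cell[r0:r1, c0:c1] = True
        candidates = np.flatnonzero(mask & cell)
        if candidates.size == 0:  # degenerate geometry; skip with a note
            log.warning("subregion %s contains no lung pixels; skipping opacities", key)
            continue
        for _ in range(count):
            idx = int(rng.choice(candidates))
            cr, cc_ = divmod(idx, size)
            radius = int(rng.integers(spec.opacity_radius_range[0], spec.opacity_radius_range[1] + 1))
            rr, cc = skdraw.disk((cr, cc_), radius, shape=(size, size))
            keep = mask[rr, cc]
            lvl = np.float32(spec.lung_level + OPACITY_CONTRAST)
            img[rr[keep], cc[keep]] = np.maximum(img[rr[keep], cc[keep]], lvl)

    if spec.large_opacity:
        candidates = np.flatnonzero(mask)
        idx = int(rng.choice(candidates))
        cr, cc_ = divmod(idx, size)
        rr, cc = skdraw.disk((cr, cc_), max(4, int(0.08 * size)), shape=(size, size))
        keep = mask[rr, cc]
        lvl = np.float32(spec.lung_level + LARGE_OPACITY_CONTRAST)
        img[rr[keep], cc[keep]] = np.maximum(img[rr[keep], cc[keep]], lvl)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    stage = stage_from_profusions(spec.profusion_per_subregion, spec.large_opacity)
    return PhantomSample(image=img, mask=mask,
                         profusions=tuple(spec.profusion_per_subregion),
                         large_opacity=spec.large_opacity, stage=stage)


def inject_defects(mask: np.ndarray, d: DefectSpec) -> np.ndarray:
    """Punch holes inside the lung fields and scatter fragments outside.

    An all-zero spec is the identity.  Defect geometry that would leave
    the image is clipped to it (with a log warning).
    """
    d.validate()
    mask = np.asarray(mask).astype(bool)
    out = mask.copy()
    if d.n_holes == 0 and d.n_fragments == 0:
        return out
    rng = np.random.default_rng(d.seed)
    size = mask.shape

    if d.n_holes and d.hole_radius > 0:
        from skimage.morphology import disk, erosion
        interior = erosion(mask, disk(d.hole_radius + 1))
        candidates = np.flatnonzero(interior)
        if candidates.size == 0:
            log.warning("no interior room for holes of radius %d; clipping to mask", d.hole_radius)
            candidates = np.flatnonzero(mask)
        for _ in range(d.n_holes):
            idx = int(rng.choice(candidates))
            cr, cc_ = divmod(idx, size[1])
            rr, cc = skdraw.disk((cr, cc_), d.hole_radius, shape=size)
            out[rr, cc] = False

    if d.n_fragments and d.fragment_area > 0:
        from skimage.morphology import dilation, disk
        radius = max(1, int(round(np.sqrt(d.fragment_area / np.pi))))
        margin = radius + 2
        forbidden = dilation(mask, disk(margin))
        allowed = ~forbidden
        allowed[:margin, :] = allowed[-margin:, :] = False
        allowed[:, :margin] = allowed[:, -margin:] = False
        candidates = np.flatnonzero(allowed)
        for _ in range(d.n_fragments):
            if candidates.size == 0:
                log.warning("no background room for fragments; clipping placement")
                candidates = np.flatnonzero(~mask)
            idx = int(rng.choice(candidates))
            cr, cc_ = divmod(idx, size[1])
            rr, cc = skdraw.disk((cr, cc_), radius, shape=size)
            out[rr, cc] = True

    return out


#: whole-image stage frequencies of the 498-radiograph clinical cohort the
#: phantom emulates (Normal, I, II, III)
COHORT_STAGE_PROBS = (193 / 498, 147 / 498, 108 / 498, 50 / 498)


def _levels_for_stage(stage: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Sample a six-subregion profusion vector whose rule stage is ``stage``."""
    lv = [0] * 6
    if stage == 0:
        if rng.random() < 0.5:
            lv[int(rng.integers(0, 6))] = 1
    elif stage == 1:
        if rng.random() < 0.5:  # grade 1 in >= 2 subregions
            for i in rng.choice(6, size=int(rng.integers(2, 5)), replace=False):
                lv[i] = 1
        else:  # grade 2 in 1-3 subregions
            for i in rng.choice(6, size=int(rng.integers(1, 4)), replace=False):
                lv[i] = 2
    else:  # stage 2 pattern (also the profusion background of stage III)
        if rng.random() < 0.5:  # grade 2 in >= 4 subregions
            for i in rng.choice(6, size=int(rng.integers(4, 7)), replace=False):
                lv[i] = 2
        else:  # grade 3 present
            for i in rng.choice(6, size=int(rng.integers(1, 3)), replace=False):
                lv[i] = 3
            for i in np.flatnonzero(np.array(lv) == 0):
                lv[i] = int(rng.choice((0, 1)))
    return tuple(lv)


def random_spec(seed: int, image_size: int = 256,
                stage_probs: tuple[float, ...] = COHORT_STAGE_PROBS) -> PhantomSpec:
    """Draw a random phantom spec with a cohort-like stage distribution.

    The whole-image stage is sampled first (default frequencies follow
    the clinical cohort the phantom emulates), then a profusion vector
    consistent with that stage; stage III sets the large-opacity flag
    over a stage-0/I/II profusion background.
    """
    rng = np.random.default_rng(seed)
    stage = int(rng.choice(4, p=stage_probs))
    large = stage == 3
    if large:
        sub = int(rng.choice(3, p=np.asarray(stage_probs[:3]) / sum(stage_probs[:3])))
        levels = _levels_for_stage(sub, rng)
    else:
        levels = _levels_for_stage(stage, rng)
    spec = PhantomSpec(image_size=image_size, profusion_per_subregion=levels,
                       large_opacity=large, seed=int(rng.integers(0, 2 ** 31 - 1)))
    assert int(stage_from_profusions(levels, large)) == stage
    return spec


def write_dataset(out_dir: str | Path, n: int, seed: int = 0,
                  image_size: int = 256) -> "pandas.DataFrame":
    """Generate ``n`` phantoms and write PNG pairs plus a CSV manifest.

    Manifest columns: image_path, mask_path, ul, ur, ml, mr, ll, lr,
    large_opacity, stage.
    """
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        spec = random_spec(int(rng.integers(0, 2 ** 31 - 1)), image_size=image_size)
        sample = generate_phantom(spec)
        img_path = out_dir / "images" / f"phantom_{i:04d}.png"
        mask_path = out_dir / "masks" / f"phantom_{i:04d}_mask.png"
        iio.imwrite(img_path, (sample.image * 255).round().astype(np.uint8))
        iio.imwrite(mask_path, (sample.mask.astype(np.uint8) * 255))
        rows.append({"image_path": str(img_path), "mask_path": str(mask_path),
                     **dict(zip(SUBREGION_KEYS, sample.profusions)),
                     "large_opacity": int(sample.large_opacity),
                     "stage": int(sample.stage)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
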