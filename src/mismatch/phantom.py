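"""Synthetic phantoms with known masks, and the data-selection rules.

The generator emulates the two foreground geometries of the segmentation
tasks this package targets: thin elongated tubes (rasterised correlated
random walks with jittered radius, like pulmonary vessels in CT) and
compact ellipsoidal blobs (like whole tumours in MR), in 2-D or 3-D.  An
image is ``contrast * mask + Gaussian noise``, normalised case-wise to zero
mean and unit variance.  Real acquisition physics (partial volume, bias
fields, multi-modal contrast) is deliberately not simulated.

The selection rules mirror the preprocessing of the reference protocol:
keep only slices with strictly more than ``foreground_min`` foreground
pixels (default 100), crop fixed-size patches from the four slice corners,
and draw seeded random subvolumes from 3-D cases.  ``make_benchmark``
assembles disjoint labelled/unlabelled/val/test splits, with the labelled
subset drawn from a single synthetic "case" to emulate the
one-labelled-case regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import disk

from .trainer import DataStream

__all__ = ["PhantomSpec", "SplitSpec", "generate_phantom", "filter_slices",
           "corner_crops", "random_subvolume", "make_benchmark"]


@dataclass(frozen=True)
class PhantomSpec:
    """One phantom image's generative parameters.

    intensity_contrast is the foreground-background mean gap before
    case-wise normalisation, in the same (arbitrary) units as noise_sigma;
    the default contrast 1.0 with noise 0.3 gives a clearly visible but
    non-trivial foreground.
    """

    dims: int = 2
    shape: tuple[int, ...] = (64, 64)
    n_objects: int = 2
    object_kind: str = "tube"
    radius_range: tuple[float, float] = (1.5, 3.0)
    intensity_contrast: float = 1.0
    noise_sigma: float = 0.3
    n_channels: int = 1
    min_foreground: int = 120
    seed: int = 0

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if len(self.shape) != self.dims:
            raise ValueError(f"shape {self.shape} does not match dims {self.dims}")
        if self.object_kind not in ("tube", "blob"):
            raise ValueError("object_kind must be 'tube' or 'blob'")
        if not (0 < self.radius_range[0] <= self.radius_range[1]):
            raise ValueError("radius_range must be positive and ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


@dataclass(frozen=True)
class SplitSpec:
    """Benchmark split sizes and the slice-selection threshold."""

    n_labelled: int = 5
    n_unlabelled: int = 100
    n_val: int = 5
    n_test: int = 20
    foreground_min: int = 100

    def __post_init__(self):
        for name in ("n_labelled", "n_unlabelled", "n_val", "n_test"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _draw_tube_2d(mask: np.ndarray, rng: np.random.Generator,
                  radius_range: tuple[float, float]) -> None:
    h, w = mask.shape
    pos = rng.uniform([h * 0.2, w * 0.2], [h * 0.8, w * 0.8])
    angle = rng.uniform(0, 2 * np.pi)
    base_r = rng.uniform(*radius_range)
    n_steps = int(1.2 * max(h, w))
    for _ in range(n_steps):
        r = np.clip(base_r + rng.normal(0, 0.2), radius_range[0] * 0.5,
                    radius_range[1] * 1.5)
        rr, cc = disk((pos[0], pos[1]), r, shape=mask.shape)
        mask[rr, cc] = True
        angle += rng.normal(0, 0.15)
        pos += np.array([np.sin(angle), np.cos(angle)])
        pos = np.clip(pos, 1.0, [h - 2.0, w - 2.0])


def _draw_tube_3d(mask: np.ndarray, rng: np.random.Generator,
                  radius_range: tuple[float, float]) -> None:
    shape = np.array(mask.shape, dtype=float)
    pos = rng.uniform(shape * 0.2, shape * 0.8)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    base_r = rng.uniform(*radius_range)
    grids = np.indices(mask.shape)
    n_steps = int(1.2 * mask.shape[0])
    for _ in range(n_steps):
        r = max(base_r + rng.normal(0, 0.2), radius_range[0] * 0.5)
        dist2 = sum((g - p) ** 2 for g, p in zip(grids, pos))
        mask |= dist2 <= r * r
        direction += rng.normal(0, 0.15, size=3)
        direction /= np.linalg.norm(direction)
        pos = np.clip(pos + direction, 1.0, shape - 2.0)


def _draw_blob(mask: np.ndarray, rng: np.random.Generator,
               radius_range: tuple[float, float]) -> None:
    shape = np.array(mask.shape, dtype=float)
    center = rng.uniform(shape * 0.25, shape * 0.75)
    # blobs are several times thicker than tubes of the same radius scale
    semi = rng.uniform(radius_range[0], radius_range[1], size=mask.ndim) * 3.0
    grids = np.indices(mask.shape)
    dist = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    mask |= dist <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (image, mask) pair.

    Returns an image of shape ``(n_channels, *shape)`` (channels are
    replicated) and a boolean mask of shape ``spec.shape``.  Regenerates up
    to 25 times until the mask has at least ``spec.min_foreground``
    foreground pixels (skipped when ``n_objects == 0``).
    """
    for attempt in range(25):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(spec.seed, attempt)))
        mask = np.zeros(spec.shape, dtype=bool)
        for _ in range(spec.n_objects):
            if spec.object_kind == "blob":
                _draw_blob(mask, rng, spec.radius_range)
            elif spec.dims == 2:
                _draw_tube_2d(mask, rng, spec.radius_range)
            else:
                _draw_tube_3d(mask, rng, spec.radius_range)
        if spec.n_objects == 0 or mask.sum() >= spec.min_foreground:
            break
    else:
        raise RuntimeError(
            f"could not fit {spec.n_objects} {spec.object_kind}s with "
            f">= {spec.min_foreground} foreground pixels in shape {spec.shape}")

    image = spec.intensity_contrast * mask.astype(float)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    image = case_normalise(image)
    image = np.broadcast_to(image, (spec.n_channels,) + spec.shape).copy()
    return image, mask


def case_normalise(image: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance scaling over the whole case (guarded)."""
    std = image.std()
    if std < 1e-12:
        return np.zeros_like(image, dtype=float)
    return (image - image.mean()) / std


def filter_slices(pairs, foreground_min: int = 100):
    """Keep (image, mask) pairs with strictly more than ``foreground_min``
    foreground pixels."""
    return [(im, m) for im, m in pairs if np.count_nonzero(m) > foreground_min]


def corner_crops(array: np.ndarray, crop: int) -> list[tuple[tuple[int, int], np.ndarray]]:
    """The four ``crop`` x ``crop`` windows anchored at the corners of the
    last two axes, as ``((row0, col0), patch)`` pairs.

    Coordinates are 0-based with half-open windows; applying this to an
    image and its mask with the same ``crop`` yields identically cropped
    pairs.
    """
    h, w = array.shape[-2:]
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} exceeds spatial dims ({h}, {w})")
    anchors = [(0, 0), (0, w - crop), (h - crop, 0), (h - crop, w - crop)]
    return [((r0, c0), array[..., r0:r0 + crop, c0:c0 + crop].copy())
            for r0, c0 in anchors]


def random_subvolume(volume: np.ndarray, size=(96, 96, 96), seed: int = 0,
                     ) -> tuple[tuple[int, int, int], np.ndarray]:
    """Seeded uniform crop of ``size`` from the last three axes of ``volume``;
    returns the ``(z0, y0, x0)`` corner and the patch."""
    dims = volume.shape[-3:]
    size = tuple(size)
    if any(s > d for s, d in zip(size, dims)):
        raise ValueError(f"crop size {size} exceeds volume dims {dims}")
    rng = np.random.default_rng(seed)
    corner = tuple(int(rng.integers(0, d - s + 1)) for s, d in zip(size, dims))
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    return corner, volume[(...,) + sl].copy()


def _case_spec(phantom: PhantomSpec, case_rng: np.random.Generator,
               image_seed: int) -> PhantomSpec:
    """Perturb the phantom parameters once per case so images within a case
    are correlated (same anatomy style) while cases differ."""
    lo, hi = phantom.radius_range
    scale = case_rng.uniform(0.85, 1.15)
    contrast = phantom.intensity_contrast * case_rng.uniform(0.9, 1.1)
    return replace(phantom, radius_range=(lo * scale, hi * scale),
                   intensity_contrast=contrast, seed=image_seed)


def make_benchmark(split: SplitSpec, phantom: PhantomSpec) -> DataStream:
    """Disjoint labelled/unlabelled/val/test splits of generated phantoms.

    The labelled subset comes from a single case; unlabelled images are
    spread over three cases, validation over one and test over five,
    emulating a case-wise protocol.  Fully reproducible from
    ``phantom.seed``.
    """
    layout = [("labelled", split.n_labelled, 1), ("unlabelled", split.n_unlabelled, 3),
              ("val", split.n_val, 1), ("test", split.n_test, 5)]
    out: dict[str, list] = {}
    for part_idx, (name, count, n_cases) in enumerate(layout):
        items = []
        for i in range(count):
            case = i % n_cases
            case_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(phantom.seed, part_idx, case)))
            image_seed = int(np.random.SeedSequence(
                entropy=(phantom.seed, part_idx, case, i)).generate_state(1)[0]
                % (2 ** 31))
            spec = _case_spec(phantom, case_rng, image_seed)
            spec = replace(spec, min_foreground=max(spec.min_foreground,
                                                    split.foreground_min + 1))
            items.append(generate_phantom(spec))
        kept = filter_slices(items, split.foreground_min)
        if len(kept) != count:
            raise RuntimeError(f"{name} split lost items to the foreground filter")
        out[name] = kept
    return DataStream(
        labelled=out["labelled"],
        unlabelled=[im for im, _ in out["unlabelled"]],
        val=out["val"], test=out["test"])
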