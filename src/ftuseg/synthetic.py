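"""Synthetic WSI-like scenes with known ground truth and confusion counts.

The generator emulates the geometry of FTU annotation data rather than
its stain appearance: a rectangular cortex region containing
non-overlapping quasi-elliptical FTU instances whose sizes follow the
published morphometry — glomeruli are roughly spherical with diameters
of 100–350 µm, colonic crypts are elongated tubes with a luminal
diameter of 73.5 ± 3.4 µm and an axis ratio of about 0.17
(≈ 433 µm long).  Shapes are ellipses with axis ratio in [0.8, 1.0]
(glomeruli) plus low-amplitude radial harmonics, so instances are not
trivially circular while their equivalent diameter stays analytically
controlled (zero-mean harmonics perturb the enclosed area only at
second order).

Scenes default to a desk-scale canvas of 2048×2048 px at 4 µm/px — a
downscaled WSI on which a glomerulus spans 25–88 px — so whole test
suites run in seconds; the native 0.5 µm/px resolution is supported by
passing the corresponding pixel size.

:func:`perturb` derives a prediction mask with a *known* object-level
confusion outcome: ``drop_n`` ground-truth instances are omitted
(false negatives), ``add_n`` spurious blobs disjoint from all ground
truth are added (false positives), ``merge_pairs`` adjacent instances
are bridged into single components (exercising watershed separation),
and instance boundaries may be dilated/eroded by ``jitter_px``.  With
no merges and jitter small enough that every kept instance still
overlaps its ground truth at Dice >= 0.5, the expected counts are
exactly (tp = n − drop_n, fn = drop_n, fp = add_n).

All randomness flows from one integer seed through independent
counter-derived streams per sub-task (shape, placement, perturbation),
so adding a perturbation never shifts the placement draws.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import LineString, Point, Polygon, box
from skimage.morphology import disk

from ftuseg.errors import PackingError
from ftuseg.mask_io import (
    Annotation,
    AnnotationSet,
    BinaryMask,
    LabeledMask,
    _paint,
)
from ftuseg.metrics import ConfusionCounts

#: published diameter parameters, µm
GLOMERULUS_DIAMETER_RANGE_UM = (100.0, 350.0)  # uniform (lo, hi)
CRYPT_DIAMETER_MEAN_SD_UM = (73.5, 3.4)  # normal (mean, sd), luminal diameter
CRYPT_AXIS_RATIO = 0.17  # luminal diameter / tube length (~73.5 / 433)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic WSI scene.  ``seed`` is mandatory."""

    seed: int
    image_shape: tuple[int, int] = (2048, 2048)
    pixel_size_um: float = 4.0
    n_ftu: int = 30
    ftu_kind: str = "glomerulus"
    #: glomerulus: (lo, hi) of a uniform equivalent-diameter draw;
    #: crypt: (mean, sd) of a normal luminal-diameter draw.
    diameter_range_um: tuple[float, float] | None = None
    cortex_fraction: float = 0.6
    min_gap_px: int = 4
    wsi_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_ftu < 0:
            raise ValueError("n_ftu must be >= 0")
        if self.ftu_kind not in ("glomerulus", "crypt"):
            raise ValueError("ftu_kind must be 'glomerulus' or 'crypt'")
        if self.diameter_range_um is not None and min(self.diameter_range_um) <= 0:
            raise ValueError("diameter parameters must be positive")
        if not (0 < self.cortex_fraction <= 1):
            raise ValueError("cortex_fraction must be in (0, 1]")
        if self.min_gap_px < 1:
            raise ValueError("min_gap_px must be >= 1")


@dataclass(frozen=True)
class PerturbSpec:
    """Perturbations applied to ground truth to form a prediction mask."""

    seed: int
    drop_n: int = 0
    add_n: int = 0
    merge_pairs: int = 0
    jitter_px: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_n", "add_n", "merge_pairs", "jitter_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Scene:
    """Ground truth (label mask + polygons) and, after perturbation,
    a prediction mask with its expected confusion counts."""

    truth: LabeledMask
    annotations: AnnotationSet
    spec: SceneSpec
    prediction: BinaryMask | None = None
    expected: ConfusionCounts | None = None


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _cortex_rect(shape: tuple[int, int], fraction: float) -> tuple[int, int, int, int]:
    """Centered rectangle (x0, y0, x1, y1) covering ~fraction of the image."""
    rows, cols = shape
    side_r = max(1, int(round(rows * np.sqrt(fraction))))
    side_c = max(1, int(round(cols * np.sqrt(fraction))))
    y0 = (rows - side_r) // 2
    x0 = (cols - side_c) // 2
    return x0, y0, x0 + side_c, y0 + side_r


def _ftu_polygon(spec: SceneSpec, rng: np.random.Generator) -> Polygon:
    """One FTU outline centered at the origin, in pixel units."""
    px = spec.pixel_size_um
    if spec.ftu_kind == "glomerulus":
        lo, hi = spec.diameter_range_um or GLOMERULUS_DIAMETER_RANGE_UM
        d_px = rng.uniform(lo, hi) / px
        q = rng.uniform(0.8, 1.0)  # roughly spherical
        a = (d_px / 2) / np.sqrt(q)  # semi-axes chosen so ab = (d/2)^2,
        b = (d_px / 2) * np.sqrt(q)  # i.e. equivalent diameter == d exactly
    else:
        mean, sd = spec.diameter_range_um or CRYPT_DIAMETER_MEAN_SD_UM
        minor = float(np.clip(rng.normal(mean, sd), mean - 3 * sd, mean + 3 * sd))
        b = (minor / px) / 2
        a = b / CRYPT_AXIS_RATIO  # elongated tube
    phi = rng.uniform(0, np.pi)
    theta = np.linspace(0, 2 * np.pi, 96, endpoint=False)
    r = a * b / np.hypot(b * np.cos(theta - phi), a * np.sin(theta - phi))
    # zero-mean radial harmonics: shape noise with second-order area effect
    for k in (2, 3, 4):
        r = r * (1 + rng.uniform(0, 0.03) * np.cos(k * theta + rng.uniform(0, 2 * np.pi)))
    return Polygon(np.column_stack((r * np.cos(theta), r * np.sin(theta))))


def generate_scene(spec: SceneSpec) -> Scene:
    """Generate the ground-truth portion of a scene.

    Exactly ``n_ftu`` non-overlapping instances are packed inside the
    cortex rectangle with pairwise clearance >= ``min_gap_px``; the
    label mask is the rasterization of the instance polygons (labels in
    placement order), so mask and polygons are mutually consistent by
    construction.  Deterministic under a fixed seed.
    """
    shape_rng = _stream(spec.seed, 0)
    place_rng = _stream(spec.seed, 1)
    x0, y0, x1, y1 = _cortex_rect(spec.image_shape, spec.cortex_fraction)
    gap = float(spec.min_gap_px)

    placed: list[Polygon] = []
    for i in range(spec.n_ftu):
        outline = _ftu_polygon(spec, shape_rng)
        bx0, by0, bx1, by1 = outline.bounds
        lo_x, hi_x = x0 - bx0 + gap, x1 - bx1 - gap
        lo_y, hi_y = y0 - by0 + gap, y1 - by1 - gap
        if lo_x >= hi_x or lo_y >= hi_y:
            raise PackingError(
                f"instance {i} (extent {bx1 - bx0:.0f}x{by1 - by0:.0f} px) does not "
                "fit in the cortex region; reduce diameters or enlarge the image"
            )
        for _ in range(300):
            cx = place_rng.uniform(lo_x, hi_x)
            cy = place_rng.uniform(lo_y, hi_y)
            cand = Polygon(np.asarray(outline.exterior.coords) + (cx, cy))
            if all(
                cand.distance(p) >= gap
                for p in placed
                if _bbox_close(cand.bounds, p.bounds, gap)
            ):
                placed.append(cand)
                break
        else:
            raise PackingError(
                f"could not place instance {i + 1} of {spec.n_ftu} after 300 "
                "attempts; try a smaller n_ftu or a larger cortex_fraction"
            )

    grid = np.zeros(spec.image_shape, dtype=np.int32)
    annotations: list[Annotation] = []
    for k, poly in enumerate(placed, start=1):
        _paint(grid, poly, value=k)
        if not (grid == k).any():
            raise PackingError(f"instance {k} rasterized to zero pixels")
        annotations.append(
            Annotation(
                id=k,
                category=spec.ftu_kind,
                ring=tuple(map(tuple, np.asarray(poly.exterior.coords)[:-1])),
            )
        )
    annotations.append(
        Annotation(
            id="cortex",
            category="cortex",
            ring=((x0, y0), (x1, y0), (x1, y1), (x0, y1)),
        )
    )
    aset = AnnotationSet(
        wsi_id=spec.wsi_id,
        image_shape=spec.image_shape,
        pixel_size_um=spec.pixel_size_um,
        annotations=annotations,
    )
    return Scene(
        truth=LabeledMask(grid, spec.pixel_size_um), annotations=aset, spec=spec
    )


def _bbox_close(a: tuple, b: tuple, gap: float) -> bool:
    return not (
        a[2] + gap < b[0] or b[2] + gap < a[0] or a[3] + gap < b[1] or b[3] + gap < a[1]
    )


def perturb(scene: Scene, pspec: PerturbSpec) -> Scene:
    """Derive a prediction mask with known expected confusion counts."""
    n = scene.truth.n_labels
    if pspec.drop_n > n:
        raise ValueError(f"drop_n = {pspec.drop_n} exceeds the {n} instances")
    if 2 * pspec.merge_pairs > n - pspec.drop_n:
        raise ValueError("not enough kept instances to form the requested merges")
    sel_rng = _stream(pspec.seed, 2)
    add_rng = _stream(pspec.seed, 3)
    jit_rng = _stream(pspec.seed, 4)

    dropped = set(
        (sel_rng.choice(n, size=pspec.drop_n, replace=False) + 1).tolist()
    ) if pspec.drop_n else set()
    kept = [k for k in range(1, n + 1) if k not in dropped]

    grid = scene.truth.grid
    pred = np.zeros(grid.shape, dtype=bool)
    footprint = disk(pspec.jitter_px) if pspec.jitter_px else None
    for k in kept:
        inst = grid == k
        if footprint is not None:
            pad = pspec.jitter_px + 1
            rr, cc = np.nonzero(inst)
            sl = (
                slice(max(0, rr.min() - pad), min(grid.shape[0], rr.max() + 1 + pad)),
                slice(max(0, cc.min() - pad), min(grid.shape[1], cc.max() + 1 + pad)),
            )
            sub = inst[sl]
            if jit_rng.integers(2):
                sub = ndi.binary_dilation(sub, structure=footprint)
            else:
                eroded = ndi.binary_erosion(sub, structure=footprint)
                sub = eroded if eroded.any() else sub
            pred[sl] |= sub
        else:
            pred |= inst

    obstacles = [
        a.polygon for a in scene.annotations.annotations if a.category != "cortex"
    ]

    # bridge nearest kept pairs into single components
    if pspec.merge_pairs:
        cents = {k: ndi.center_of_mass(grid == k) for k in kept}
        pairs = sorted(
            (
                (np.hypot(cents[i][0] - cents[j][0], cents[i][1] - cents[j][1]), i, j)
                for ii, i in enumerate(kept)
                for j in kept[ii + 1 :]
            )
        )
        used: set[int] = set()
        bridged = 0
        for _, i, j in pairs:
            if bridged == pspec.merge_pairs:
                break
            if i in used or j in used:
                continue
            (r0, c0), (r1, c1) = cents[i], cents[j]
            line = LineString([(c0, r0), (c1, r1)]).buffer(1.5)
            _paint(pred, line)
            obstacles.append(line)
            used.update((i, j))
            bridged += 1

    # spurious blobs: disjoint from all ground truth (and its jitter halo)
    clearance = scene.spec.min_gap_px + pspec.jitter_px + 2
    rows, cols = grid.shape
    for _ in range(pspec.add_n):
        for _attempt in range(500):
            radius = add_rng.uniform(8, 16)
            cx = add_rng.uniform(radius + 1, cols - radius - 1)
            cy = add_rng.uniform(radius + 1, rows - radius - 1)
            blob = Point(cx, cy).buffer(radius, quad_segs=16)
            if all(blob.distance(o) >= clearance for o in obstacles):
                _paint(pred, blob)
                obstacles.append(blob)
                break
        else:
            raise PackingError("could not place a spurious blob; image too crowded")

    expected = ConfusionCounts(
        tp=n - pspec.drop_n, fp=pspec.add_n, fn=pspec.drop_n
    )
    return replace(
        scene,
        prediction=BinaryMask(pred, scene.spec.pixel_size_um),
        expected=expected,
    )


def render_intensity(scene: Scene, foreground: int = 70, background: int = 220) -> np.ndarray:
    """Flat-shaded grayscale rendering of the ground truth (uint8).

    Dark objects on a light background, the polarity of stained tissue
    on a bright-field scan; sufficient for the baseline threshold
    segmenter, with no attempt at stain texture.
    """
    img = np.full(scene.truth.shape, background, dtype=np.uint8)
    img[scene.truth.grid > 0] = foreground
    return img


def generate_cohort(
    n_donors: int,
    scenes_per_donor: int = 2,
    density_range: tuple[float, float] = (3.0, 6.0),
    seed: int = 0,
    image_shape: tuple[int, int] = (1024, 1024),
    pixel_size_um: float = 4.0,
    cortex_fraction: float = 0.6,
    ftu_kind: str = "glomerulus",
) -> list[tuple[Scene, dict]]:
    """Generate a donor cohort with per-donor planted FTU densities.

    Each donor gets a density drawn uniformly from ``density_range``
    (FTUs per mm² of cortex, the physiological 3–6 /mm² range by
    default), a sex (alternating F/M), an age, a BMI, and one scene per
    tissue block; the instance count of each scene is the planted
    density times the exact cortex-polygon area, rounded to an integer.
    Scenes carry a ``y_position`` (vertical block ordinate, descending
    with generation order).  Returns (scene, metadata) pairs where the
    metadata dict holds wsi_id, donor fields and the planted density.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    meta_rng = _stream(seed, 5)
    x0, y0, x1, y1 = _cortex_rect(image_shape, cortex_fraction)
    cortex_mm2 = (x1 - x0) * (y1 - y0) * pixel_size_um**2 / 1e6

    out: list[tuple[Scene, dict]] = []
    idx = 0
    for d in range(n_donors):
        sex = "F" if d % 2 == 0 else "M"
        age = int(meta_rng.integers(25, 71))
        bmi = round(float(meta_rng.normal(27.5, 4.0)), 1)
        planted = float(meta_rng.uniform(*density_range))
        for s in range(scenes_per_donor):
            scene_seed = int(
                np.random.SeedSequence([int(seed), 6, d, s]).generate_state(1)[0]
                % 2**31
            )
            wsi_id = f"donor{d:02d}_block{s}"
            spec = SceneSpec(
                seed=scene_seed,
                image_shape=image_shape,
                pixel_size_um=pixel_size_um,
                n_ftu=max(1, int(round(planted * cortex_mm2))),
                ftu_kind=ftu_kind,
                cortex_fraction=cortex_fraction,
                wsi_id=wsi_id,
            )
            scene = generate_scene(spec)
            meta = {
                "wsi_id": wsi_id,
                "donor_id": f"donor{d:02d}",
                "sex": sex,
                "age": age,
                "bmi": bmi,
                "y_position": float(1000 - 10 * idx),
                "planted_density_per_mm2": planted,
            }
            out.append((scene, meta))
            idx += 1
    return out
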