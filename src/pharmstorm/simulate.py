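"""Synthetic ground-truth scenes for the SMLM analysis pipeline.

Real pharmacoprobe STORM data consist of localization points (LPs) from
membrane-bound receptors and drug-binding sites: a molecule blinks one or
more times, each blink is localized with ~10 nm Gaussian error, and blinks
of one molecule appear in nearby frames.  Labeled anatomical structures
(axon varicosities, membrane contours, axon segments) enter the analysis as
binary masks from a second, diffraction-limited channel.

This module fabricates such scenes with known ground truth so every
downstream statistic — density, enrichment ratio, hull distance,
single-LP fraction, localization precision — can be checked against the
generating parameters:

* :func:`generate_structure_masks` — disk ("bouton"), annulus ("membrane
  outline") and curvilinear ("axon segment") binary masks on a 10 nm grid;
* :func:`place_molecules` — Poisson molecule placement with independent
  on-structure and off-structure intensities (their ratio is the scene's
  enrichment; equal intensities give complete spatial randomness, CSR);
* :func:`render_blinks` — turn true molecule positions into an LP table via
  a per-molecule blink-count distribution and Gaussian localization error,
  keeping the ground-truth molecule id on every LP;
* :func:`generate_binding_series` — one-site saturation series with
  Gaussian noise for the curve-fitting stage.

The generator emits already-merged localizations; photophysics kinetics,
PSF rendering, camera noise and drift are out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._rng import as_generator
from .binding import BindingSeries, one_site
from .core import (
    CameraGeometry,
    LocalizationTable,
    PolygonROI,
    StructureMask,
    ValidationError,
    union_masks,
)

#: single-LP probability measured for one-fluorophore pharmacoprobes
PHARMACOPROBE_SINGLE_LP = 0.78
#: single-LP probability measured for multi-fluorophore secondary antibodies
ANTIBODY_SINGLE_LP = 0.36


@dataclass
class BlinkModel:
    """How one molecule turns into localization points.

    ``lp_count_dist`` maps LP count (>= 1) to probability; a one-fluorophore
    pharmacoprobe mostly yields a single LP, a multi-fluorophore antibody a
    cluster.  Each LP is displaced from the true position by independent
    Gaussian error ``sigma_xy`` per axis; blinks of one molecule occupy one
    contiguous burst of frames with gaps of at most ``dark_frame_gap``.
    """

    sigma_xy: float = 9.42
    lp_count_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: PHARMACOPROBE_SINGLE_LP, 2: 0.12, 3: 0.10}
    )
    dark_frame_gap: int = 5
    total_frames: int = 10_000

    def __post_init__(self) -> None:
        if self.sigma_xy < 0:
            raise ValidationError("sigma_xy must be >= 0")
        support = np.array(sorted(self.lp_count_dist), int)
        probs = np.array([self.lp_count_dist[int(k)] for k in support], float)
        if len(support) == 0 or support.min() < 1:
            raise ValidationError("lp_count_dist support must be positive integers")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-9):
            raise ValidationError("lp_count_dist probabilities must be >= 0 and sum to 1")
        if self.dark_frame_gap < 0:
            raise ValidationError("dark_frame_gap must be >= 0")
        self._support, self._probs = support, probs / probs.sum()

    def sample_counts(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self._support, size=n, p=self._probs)


def pharmacoprobe_blink_model(sigma_xy: float = 9.42) -> BlinkModel:
    """One fluorophore per molecule: 78% single LP, short tail."""
    return BlinkModel(sigma_xy=sigma_xy, lp_count_dist={1: 0.78, 2: 0.12, 3: 0.10})


def antibody_blink_model(sigma_xy: float = 9.42) -> BlinkModel:
    """Secondary antibody with unknown fluorophore number: 36% single LP,
    long cluster tail."""
    return BlinkModel(
        sigma_xy=sigma_xy,
        lp_count_dist={1: 0.36, 2: 0.22, 3: 0.15, 4: 0.10, 5: 0.07, 6: 0.05, 7: 0.03, 8: 0.02},
    )


@dataclass
class Scene:
    """Ground truth: true molecule positions with structure assignment.

    ``molecules`` columns: ``x_nm``, ``y_nm``, ``mask_id`` (index into
    ``masks``, −1 for off-structure), ``species`` (mask label or
    "background").  ``enrichment`` is the generating on/off density ratio.
    """

    molecules: pd.DataFrame
    masks: list[StructureMask]
    roi: PolygonROI
    enrichment: float
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.molecules)


def _rasterize_disk(grid_x, grid_y, cx, cy, radius):
    return (grid_x - cx) ** 2 + (grid_y - cy) ** 2 <= radius**2


def generate_structure_masks(
    kind: str,
    n_structures: int,
    size_params: Mapping[str, float],
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 10.0,
    seed: "int | np.random.Generator | None" = None,
    margin_nm: float = 0.0,
) -> list[StructureMask]:
    """Generate ``n_structures`` binary structure masks on a shared raster.

    Kinds
    -----
    ``disks``
        Filled circles (bouton-like); ``size_params['radius_nm']`` is a
        scalar or ``(min, max)`` range.
    ``annulus``
        Rings (membrane-outline-like); needs ``r_inner_nm``/``r_outer_nm``.
    ``curvilinear``
        Persistent-random-walk ribbons (axon-segment-like); needs
        ``length_nm`` and ``width_nm``.

    Structures are placed to fit entirely inside the raster (a structure
    larger than the raster raises); placement avoids overlap on a
    best-effort basis.  Each returned mask holds one structure, labelled
    ``{kind}_{i}``; combine with :func:`pharmstorm.core.union_masks`.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    rng = as_generator(seed)
    h, w = shape
    width_nm, height_nm = w * pixel_size, h * pixel_size
    # pixel-center coordinate grids in nm
    gx, gy = np.meshgrid(
        (np.arange(w) + 0.5) * pixel_size, (np.arange(h) + 0.5) * pixel_size
    )
    masks: list[StructureMask] = []
    centers: list[tuple[float, float, float]] = []  # (cx, cy, extent radius)

    def place_center(extent: float) -> tuple[float, float]:
        lo_x, hi_x = margin_nm + extent, width_nm - margin_nm - extent
        lo_y, hi_y = margin_nm + extent, height_nm - margin_nm - extent
        if lo_x >= hi_x or lo_y >= hi_y:
            raise ValidationError(
                f"structure of extent {extent:.0f} nm does not fit in a "
                f"{width_nm:.0f} x {height_nm:.0f} nm raster"
            )
        for _ in range(200):  # best-effort non-overlap
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            if all((cx - px) ** 2 + (cy - py) ** 2 > (extent + pr) ** 2 for px, py, pr in centers):
                return cx, cy
        return cx, cy

    for i in range(n_structures):
        if kind == "disks":
            r = size_params["radius_nm"]
            radius = float(rng.uniform(*r)) if np.ndim(r) else float(r)
            cx, cy = place_center(radius)
            pix = _rasterize_disk(gx, gy, cx, cy, radius)
            centers.append((cx, cy, radius))
        elif kind == "annulus":
            r_in, r_out = float(size_params["r_inner_nm"]), float(size_params["r_outer_nm"])
            if r_in >= r_out:
                raise ValidationError("annulus needs r_inner_nm < r_outer_nm")
            cx, cy = place_center(r_out)
            pix = _rasterize_disk(gx, gy, cx, cy, r_out) & ~_rasterize_disk(gx, gy, cx, cy, r_in)
            centers.append((cx, cy, r_out))
        elif kind == "curvilinear":
            length_nm = float(size_params["length_nm"])
            width_struct = float(size_params["width_nm"])
            extent = min(length_nm / 2, min(width_nm, height_nm) / 2 - pixel_size)
            if width_struct >= min(width_nm, height_nm) or length_nm <= 0:
                raise ValidationError("curvilinear structure does not fit in raster")
            cx, cy = place_center(min(extent, min(width_nm, height_nm) / 4))
            pix = _random_ribbon(rng, shape, pixel_size, (cx, cy), length_nm, width_struct, margin_nm)
            centers.append((cx, cy, length_nm / 4))
        else:
            raise ValidationError(f"unknown structure kind {kind!r}")
        if not pix.any():
            raise ValidationError("generated structure rasterized to an empty mask")
        masks.append(StructureMask(pix, pixel_size=pixel_size, label=f"{kind}_{i}"))
    return masks


def _random_ribbon(rng, shape, pixel_size, start, length_nm, width_nm, margin_nm):
    """Persistent random walk marked on the raster, thickened to width_nm."""
    h, w = shape
    n_steps = max(2, int(round(length_nm / pixel_size)))
    theta = rng.uniform(0, 2 * np.pi)
    x, y = start
    path = np.zeros(shape, bool)
    lo = margin_nm + width_nm / 2 + pixel_size
    hi_x = w * pixel_size - lo
    hi_y = h * pixel_size - lo
    for _ in range(n_steps):
        theta += rng.normal(0, 0.15)
        x = np.clip(x + pixel_size * np.cos(theta), lo, hi_x)
        y = np.clip(y + pixel_size * np.sin(theta), lo, hi_y)
        path[int(y / pixel_size), int(x / pixel_size)] = True
    dist = ndimage.distance_transform_edt(~path, sampling=pixel_size)
    return dist <= width_nm / 2


def place_molecules(
    masks: Sequence[StructureMask],
    roi: PolygonROI,
    density_on: float,
    density_off: float,
    seed: "int | np.random.Generator | None" = None,
) -> Scene:
    """Place molecules by two independent Poisson processes.

    ``density_on``/``density_off`` are intensities in molecules/µm² on and
    off the structure masks (within ``roi``).  Equal densities produce CSR;
    their ratio is the scene's enrichment (>1 structure-seeking drug, <1
    avoidance, as for a drug excluded from labeled terminals).
    """
    if density_on < 0 or density_off < 0:
        raise ValidationError("densities must be >= 0")
    rng = as_generator(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    mask_ids: list[np.ndarray] = []

    on_area_um2 = 0.0
    pixel_pools = []  # (mask index, rows, cols, pixel_size, origin) restricted to roi
    for mi, mask in enumerate(masks):
        rows, cols = np.nonzero(mask.pixels)
        cx = mask.origin[0] + (cols + 0.5) * mask.pixel_size
        cy = mask.origin[1] + (rows + 0.5) * mask.pixel_size
        keep = roi.contains(cx, cy)
        rows, cols = rows[keep], cols[keep]
        pixel_pools.append((mi, rows, cols, mask.pixel_size, mask.origin))
        on_area_um2 += len(rows) * mask.pixel_size**2 / 1e6
    off_area_um2 = max(roi.area_um2 - on_area_um2, 0.0)

    if density_on > 0:
        for mi, rows, cols, ps, origin in pixel_pools:
            area = len(rows) * ps**2 / 1e6
            n = rng.poisson(density_on * area)
            if n == 0 or len(rows) == 0:
                continue
            pick = rng.integers(0, len(rows), size=n)
            x = origin[0] + (cols[pick] + rng.uniform(0, 1, n)) * ps
            y = origin[1] + (rows[pick] + rng.uniform(0, 1, n)) * ps
            xs.append(x)
            ys.append(y)
            mask_ids.append(np.full(n, mi))

    if density_off > 0 and off_area_um2 > 0:
        n_off = rng.poisson(density_off * off_area_um2)
        x_off, y_off = _uniform_in_region(rng, roi, n_off, exclude_masks=masks)
        xs.append(x_off)
        ys.append(y_off)
        mask_ids.append(np.full(len(x_off), -1))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        mid = np.concatenate(mask_ids).astype(int)
    else:
        x = y = np.empty(0)
        mid = np.empty(0, int)
    species = np.where(mid >= 0, [masks[m].label if m >= 0 else "" for m in mid], "background")
    molecules = pd.DataFrame({"x_nm": x, "y_nm": y, "mask_id": mid, "species": species})
    enrichment = density_on / density_off if density_off > 0 else np.inf
    return Scene(molecules, list(masks), roi, enrichment=float(enrichment), seed=seed_val)


def _uniform_in_region(
    rng: np.random.Generator,
    roi: PolygonROI,
    n: int,
    exclude_masks: Sequence[StructureMask] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample n points uniform over roi (minus excluded masks)."""
    x_min, y_min, x_max, y_max = roi.bounds
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    got = 0
    guard = 0
    while got < n:
        guard += 1
        if guard > 10_000:
            raise ValidationError("rejection sampling failed: region has negligible free area")
        m = max(2 * (n - got), 64)
        x = rng.uniform(x_min, x_max, m)
        y = rng.uniform(y_min, y_max, m)
        ok = roi.contains(x, y)
        for mask in exclude_masks:
            ok &= ~mask.contains(x, y)
        x, y = x[ok], y[ok]
        take = min(len(x), n - got)
        xs.append(x[:take])
        ys.append(y[:take])
        got += take
    if not xs:
        return np.empty(0), np.empty(0)
    return np.concatenate(xs), np.concatenate(ys)


def render_blinks(
    scene: Scene,
    blink_model: BlinkModel,
    background_rate: float = 0.0,
    seed: "int | np.random.Generator | None" = None,
    channel: str = "pharmaco",
    geometry: CameraGeometry | None = None,
) -> LocalizationTable:
    """Render a scene into a localization table.

    Each molecule emits ``k ~ lp_count_dist`` LPs displaced by independent
    Gaussian noise (``sigma_xy`` per axis) and placed in a contiguous frame
    burst with inter-blink gaps of at most ``dark_frame_gap``.  Uniform
    background LPs are added at ``background_rate`` (LPs/µm² over the roi)
    with ``molecule_id = -1``; real molecules keep their row index in
    ``scene.molecules`` as ``molecule_id``.
    """
    if background_rate < 0:
        raise ValidationError("background_rate must be >= 0")
    rng = as_generator(seed)
    mol = scene.molecules
    n_mol = len(mol)
    counts = blink_model.sample_counts(n_mol, rng) if n_mol else np.empty(0, int)
    rep = np.repeat(np.arange(n_mol), counts)
    x = np.repeat(mol["x_nm"].to_numpy(), counts)
    y = np.repeat(mol["y_nm"].to_numpy(), counts)
    if blink_model.sigma_xy > 0 and len(x):
        x = x + rng.normal(0, blink_model.sigma_xy, len(x))
        y = y + rng.normal(0, blink_model.sigma_xy, len(y))

    frames = np.zeros(len(x), int)
    if len(x):
        gap = max(blink_model.dark_frame_gap, 1)
        max_burst = (counts.max() - 1) * gap if len(counts) else 0
        start_hi = max(blink_model.total_frames - max_burst, 1)
        starts = rng.integers(0, start_hi, size=n_mol)
        gaps = rng.integers(1, gap + 1, size=len(x))
        # first blink of each molecule sits at its start frame
        first = np.r_[0, np.cumsum(counts)[:-1]]
        gaps[first[counts > 0]] = 0
        offsets = np.concatenate([np.cumsum(gaps[s : s + k]) for s, k in zip(first, counts) if k]) if n_mol else gaps
        frames = starts[rep] + offsets

    n_bg = rng.poisson(background_rate * scene.roi.area_um2) if background_rate > 0 else 0
    if n_bg:
        bx, by = _uniform_in_region(rng, scene.roi, n_bg)
        bf = rng.integers(0, blink_model.total_frames, n_bg)
        x = np.concatenate([x, bx])
        y = np.concatenate([y, by])
        frames = np.concatenate([frames, bf])
        rep = np.concatenate([rep, np.full(n_bg, -1)])

    order = np.argsort(frames, kind="stable")
    table = LocalizationTable.from_arrays(
        x[order],
        y[order],
        frame=frames[order],
        geometry=geometry,
        channel=np.full(len(x), channel),
        molecule_id=rep[order],
    )
    table.provenance.update(
        {"generator": "pharmstorm.simulate.render_blinks", "sigma_xy_nm": blink_model.sigma_xy}
    )
    return table


def generate_binding_series(
    kd: float,
    bmax: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: "int | np.random.Generator | None" = None,
) -> BindingSeries:
    """One-site saturation series: ``bmax*c/(c+kd)`` plus Gaussian noise."""
    if kd <= 0:
        raise ValidationError("kd must be positive")
    conc = np.asarray(concentrations, float)
    if np.any(conc < 0):
        raise ValidationError("concentrations must be >= 0")
    rng = as_generator(seed)
    all_c = np.tile(conc, replicates)
    rep = np.repeat(np.arange(replicates), len(conc))
    y = one_site(all_c, kd, bmax)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, len(y))
    return BindingSeries(all_c, y, rep)
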