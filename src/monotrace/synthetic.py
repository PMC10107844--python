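"""Synthetic rabies-tracing experiments with known ground truth.

Emulates the statistical structure of a monosynaptic tracing data set from
mouse auditory cortex: per animal, a cloud of starter cells confined to a
~0.5 mm radius around the centre of A1 with a group-specific laminar profile
(mid-layer peak for PV and SST, superficial peak for VIP), local input cells
scattered laterally around the starter centroid with a group-specific spread
(wider for SST), and long-range inputs drawn as one multinomial over the
packaged region vocabulary.  Two-channel fluorescence slices can be rendered
from the cell tables so the detection stage is testable against ground truth.

All sampling takes explicit seeds; identical (config, seed) reproduce
byte-identical tables and images.  Default parameter values follow the group
means of the source data set: starter counts 238/254/154 (PV/SST/VIP),
inputs per starter 31.5/36.4/39.1, starter radius 500 µm, 50 µm slices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (DEFAULT_LAYER_BOUNDARIES, LAYER_LABELS, RegionPolygon,
                       SliceGeometry, assign_region, unflatten_point)
from . import longrange_table

logger = logging.getLogger("monotrace")

CELL_COLUMNS = ["animal_id", "group", "slice_index", "x_um", "y_um", "depth_um",
                "channel_class", "layer", "region", "hemisphere"]

#: flat x (arc length from the rhinal fissure) of the A1 centre in the
#: synthetic geometry, µm
A1_CENTER_X = 2000.0
_DOMAIN_X = 4000.0  # lateral extent of the synthetic slice, µm


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=("int64" if c == "slice_index" else
                                             "float64" if c.endswith("_um") else "object"))
                         for c in CELL_COLUMNS + ["ap_um"]})


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic experiment.

    Per-group dictionaries are keyed by the labels in ``groups``.  Depth
    profiles are weights over the five cortical layers (L1..L6) and must sum
    to one; ``region_probs`` defaults to the per-group mean of the packaged
    long-range proportions.
    """

    groups: tuple[str, ...] = ("PV", "SST", "VIP")
    n_animals_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"PV": 4, "SST": 6, "VIP": 4})
    starter_count_mean: Mapping[str, float] = field(
        default_factory=lambda: {"PV": 238.0, "SST": 254.0, "VIP": 154.0})
    starter_count_sd: Mapping[str, float] = field(
        default_factory=lambda: {"PV": 92.0, "SST": 75.0, "VIP": 30.0})
    starter_radius: float = 500.0  # µm, hard lateral truncation
    starter_depth_profile: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "PV": (0.02, 0.23, 0.30, 0.30, 0.15),
            "SST": (0.02, 0.23, 0.28, 0.30, 0.17),
            "VIP": (0.10, 0.50, 0.15, 0.15, 0.10),
        })
    local_spread_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"PV": 150.0, "SST": 300.0, "VIP": 150.0})  # µm
    inputs_per_starter: Mapping[str, float] = field(
        default_factory=lambda: {"PV": 31.5, "SST": 36.4, "VIP": 39.1})
    longrange_fraction: float = 0.25
    region_probs: Mapping[str, Mapping[str, float]] | None = None
    slice_thickness: float = 50.0  # µm
    n_slices: int = 20
    layer_boundaries: tuple[float, ...] = DEFAULT_LAYER_BOUNDARIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.starter_radius <= 0:
            raise ValueError("starter_radius must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")
        if not 0.0 <= self.longrange_fraction <= 1.0:
            raise ValueError("longrange_fraction must lie in [0, 1]")
        b = np.asarray(self.layer_boundaries, dtype=float)
        if b[0] <= 0 or np.any(np.diff(b) <= 0):
            raise ValueError("layer boundaries must be positive and "
                             "strictly increasing")
        for g in self.groups:
            prof = np.asarray(self.starter_depth_profile[g], dtype=float)
            if len(prof) != len(LAYER_LABELS) or np.any(prof < 0):
                raise ValueError(f"depth profile of {g} must be {len(LAYER_LABELS)} "
                                 "non-negative weights")
            if abs(prof.sum() - 1.0) > 1e-9:
                raise ValueError(f"depth profile of {g} must sum to 1")
            if self.local_spread_sigma[g] <= 0:
                raise ValueError("local_spread_sigma must be positive")
            if self.starter_count_sd[g] <= 0:
                raise ValueError("starter_count_sd must be positive")
        if self.region_probs is not None:
            for g, probs in self.region_probs.items():
                total = float(sum(probs.values()))
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"region_probs[{g}] sum to {total}, not 1")

    def resolve_region_probs(self, group: str) -> pd.Series:
        if self.region_probs is not None:
            return pd.Series(dict(self.region_probs[group]), dtype=float)
        return longrange_table.mean_region_probs(group=group)

    @property
    def ap_extent(self) -> float:
        return self.n_slices * self.slice_thickness

    @property
    def deepest_boundary(self) -> float:
        return float(self.layer_boundaries[-1])


@dataclass
class GroundTruth:
    """Cells with true labels, slice geometries, and per-animal totals."""

    cells: pd.DataFrame
    geometry: list[SliceGeometry]
    longrange_counts: pd.DataFrame  # index (group, animal_id), columns regions
    totals: pd.DataFrame  # animal_id, group, n_starters, n_local, n_longrange


# ---------------------------------------------------------------------------
# geometry


def make_geometry(config: GeneratorConfig, pia_shape: str = "straight",
                  arc_radius: float = 8000.0,
                  vertex_spacing: float = 50.0) -> list[SliceGeometry]:
    """Per-slice geometries: pia polyline, fissure anchor, layers, regions.

    The pia runs 4 mm ventral-to-dorsal with the rhinal-fissure anchor at its
    ventral end; ``pia_shape='arc'`` bends it along a circle of ``arc_radius``
    (µm) while keeping arc-length coordinates.  Region polygons split the
    tissue into AuV / A1 / AuD bands around the A1 centre at flat
    x = 2000 µm; everything deeper than the last layer boundary is white
    matter and lies outside the polygons.
    """
    s = np.arange(0.0, _DOMAIN_X + vertex_spacing / 2, vertex_spacing)
    if pia_shape == "straight":
        pia = np.column_stack([s, np.zeros_like(s)])
    elif pia_shape == "arc":
        # arc-length parametrised circle; tissue is on the inward-normal side
        theta = s / arc_radius
        pia = np.column_stack([arc_radius * np.sin(theta),
                               arc_radius - arc_radius * np.cos(theta)])
    else:
        raise ValueError(f"unknown pia_shape {pia_shape!r}")

    depth = config.deepest_boundary
    bands = {"AuV": (0.0, 1600.0), "A1": (1600.0, 2400.0), "AuD": (2400.0, _DOMAIN_X)}

    def band_polygon(x0: float, x1: float):
        from shapely.geometry import Polygon
        # polygon in slice coordinates, following the (possibly curved) pia
        sel = (s >= x0 - vertex_spacing / 2) & (s <= x1 + vertex_spacing / 2)
        xs = np.clip(s[sel], x0, x1)
        top = np.array([unflatten_point_raw(x, 0.0, pia, s) for x in (x0, *xs, x1)])
        bottom = np.array([unflatten_point_raw(x, depth, pia, s)
                           for x in (x1, *xs[::-1], x0)])
        return Polygon(np.vstack([top, bottom]))

    regions = tuple(RegionPolygon(name, band_polygon(*band))
                    for name, band in bands.items())
    return [SliceGeometry(pia=pia, fissure_index=0,
                          layer_boundaries=config.layer_boundaries,
                          region_polygons=regions,
                          ap_position=i * config.slice_thickness)
            for i in range(config.n_slices)]


def unflatten_point_raw(x: float, y: float, pia: np.ndarray,
                        arc: np.ndarray) -> np.ndarray:
    """unflatten against a raw polyline with known vertex arc lengths."""
    i = min(int(np.searchsorted(arc, x, side="right")) - 1, len(arc) - 2)
    i = max(i, 0)
    d = pia[i + 1] - pia[i]
    t_hat = d / np.linalg.norm(d)
    foot = pia[i] + (x - arc[i]) * t_hat
    return foot + y * np.array([-t_hat[1], t_hat[0]])


# ---------------------------------------------------------------------------
# sampling


def _truncated_normal(rng: np.random.Generator, sigma: float, bound: float,
                      size: int) -> np.ndarray:
    """Zero-mean normal draws hard-truncated (by rejection) at |x| <= bound."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(0.0, sigma, size=2 * (size - filled) + 16)
        draw = draw[np.abs(draw) <= bound][: size - filled]
        out[filled:filled + len(draw)] = draw
        filled += len(draw)
    return out


def _sample_depths(rng: np.random.Generator, profile: Sequence[float],
                   boundaries: Sequence[float], size: int) -> np.ndarray:
    """Depths drawn layer-first (by profile weight), then uniform in the band."""
    edges = np.concatenate([[0.0], np.asarray(boundaries, dtype=float)])
    layer_idx = rng.choice(len(profile), size=size, p=np.asarray(profile, float))
    lo, hi = edges[layer_idx], edges[layer_idx + 1]
    return lo + rng.random(size) * (hi - lo)


def _finalize_cells(x: np.ndarray, depth: np.ndarray, ap: np.ndarray,
                    config: GeneratorConfig, geometry: Sequence[SliceGeometry],
                    animal_id: str, group: str, channel_class: str) -> pd.DataFrame:
    """Assemble a cell table from flat coordinates: clip to the tissue domain,
    map to slice coordinates, and annotate slice, layer and region."""
    x = np.clip(x, 0.0, _DOMAIN_X)
    depth = np.clip(depth, 0.0, np.nextafter(config.deepest_boundary, 0.0))
    slice_index = np.clip((ap // config.slice_thickness).astype(int),
                          0, config.n_slices - 1)
    geom0 = geometry[0]
    pts = np.array([unflatten_point(xi, di, geom0) for xi, di in zip(x, depth)]) \
        if len(x) else np.empty((0, 2))
    regions, hemis, layers = [], [], []
    edges = np.asarray(geom0.layer_boundaries)
    labels = list(LAYER_LABELS)
    for p, d in zip(pts, depth):
        r, h = assign_region(p, geom0)
        regions.append(r)
        hemis.append(h)
        layers.append(labels[int(np.searchsorted(edges, d, side="right"))])
    df = pd.DataFrame({
        "animal_id": animal_id, "group": group, "slice_index": slice_index,
        "x_um": pts[:, 0] if len(pts) else np.array([]),
        "y_um": pts[:, 1] if len(pts) else np.array([]),
        "depth_um": depth, "channel_class": channel_class,
        "layer": layers, "region": regions, "hemisphere": hemis,
    }, columns=CELL_COLUMNS)
    # derived stacking coordinate: slices sit at slice_index * thickness
    df["ap_um"] = df["slice_index"] * config.slice_thickness
    return df


def sample_starters(config: GeneratorConfig, group: str, seed,
                    geometry: Sequence[SliceGeometry] | None = None,
                    n: int | None = None,
                    animal_id: str = "sim") -> pd.DataFrame:
    """Starter cells of one animal.

    Lateral and anterior-posterior offsets from the A1 centre are zero-mean
    normal with SD = starter_radius / 2, hard-truncated at ``starter_radius``
    (the cloud falls to zero within ~0.5 mm of the injection centre); depths
    follow the group's laminar profile.
    """
    if group not in config.groups:
        raise KeyError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = make_geometry(config)
    if n is None:
        n = max(1, int(round(rng.normal(config.starter_count_mean[group],
                                        config.starter_count_sd[group]))))
    if n == 0:
        return _empty_cells()
    sigma = config.starter_radius / 2.0
    x = A1_CENTER_X + _truncated_normal(rng, sigma, config.starter_radius, n)
    ap = config.ap_extent / 2.0 + _truncated_normal(rng, sigma,
                                                    config.starter_radius, n)
    ap = np.clip(ap, 0.0, np.nextafter(config.ap_extent, 0.0))
    depth = _sample_depths(rng, config.starter_depth_profile[group],
                           config.layer_boundaries, n)
    return _finalize_cells(x, depth, ap, config, geometry, animal_id, group,
                           "starter")


def sample_local_inputs(starters: pd.DataFrame, config: GeneratorConfig, seed,
                        geometry: Sequence[SliceGeometry] | None = None,
                        n: int | None = None) -> pd.DataFrame:
    """Local input cells around the starter centroid of one animal.

    Lateral (and anterior-posterior) positions are normal about the starter
    centroid with the group's ``local_spread_sigma``; depths are uniform over
    the cortical depth.  The count is Poisson with mean
    ``inputs_per_starter * (1 - longrange_fraction) * n_starters`` unless
    ``n`` is given.
    """
    if starters.empty:
        raise ValueError("sample_local_inputs requires a non-empty starter table")
    rng = np.random.default_rng(seed)
    if geometry is None:
        geometry = make_geometry(config)
    group = starters["group"].iloc[0]
    animal_id = starters["animal_id"].iloc[0]
    if n is None:
        rate = (config.inputs_per_starter[group]
                * (1.0 - config.longrange_fraction) * len(starters))
        n = int(rng.poisson(rate))
    if n == 0:
        return _empty_cells()
    sigma = config.local_spread_sigma[group]
    cx = float(starters["x_um"].mean())  # straight pia: x_um is the flat x
    cap = float(starters["slice_index"].mean() * config.slice_thickness)
    x = cx + rng.normal(0.0, sigma, n)
    ap = np.clip(cap + rng.normal(0.0, sigma, n), 0.0,
                 np.nextafter(config.ap_extent, 0.0))
    depth = rng.random(n) * config.deepest_boundary
    return _finalize_cells(x, depth, ap, config, geometry, animal_id, group,
                           "input")


def sample_longrange_inputs(config: GeneratorConfig, n_total: int, seed,
                            group: str | None = None) -> pd.Series:
    """One multinomial draw of long-range input counts over the region
    vocabulary; counts sum to ``n_total``."""
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    if group is None and config.region_probs is None:
        raise ValueError("group is required when region_probs is unset")
    probs = config.resolve_region_probs(group)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(n_total), probs.to_numpy())
    return pd.Series(counts, index=probs.index, name="count")


def simulate_animal(config: GeneratorConfig, group: str, animal_id: str, seed,
                    geometry: Sequence[SliceGeometry] | None = None):
    """Ground truth for one animal: (cells, long-range counts, totals row).

    The total input count decomposes into independent Poisson local and
    long-range components with rates ``inputs_per_starter * n_starters``
    split by ``longrange_fraction``, so totals are conserved by construction.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_start, s_local, s_n, s_regions = ss.spawn(4)
    if geometry is None:
        geometry = make_geometry(config)
    starters = sample_starters(config, group, s_start, geometry,
                               animal_id=animal_id)
    locals_ = sample_local_inputs(starters, config, s_local, geometry)
    rate_long = (config.inputs_per_starter[group] * config.longrange_fraction
                 * len(starters))
    n_long = int(np.random.default_rng(s_n).poisson(rate_long))
    longrange = sample_longrange_inputs(config, n_long, s_regions, group=group)
    cells = pd.concat([starters, locals_], ignore_index=True)
    totals = {"animal_id": animal_id, "group": group,
              "n_starters": len(starters), "n_local": len(locals_),
              "n_longrange": int(longrange.sum())}
    return cells, longrange, totals


def simulate_experiment(config: GeneratorConfig,
                        seed: int | None = None) -> GroundTruth:
    """Full multi-animal experiment under ``config`` (seed defaults to
    ``config.seed``); animal ids are ``<group><k>``."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    geometry = make_geometry(config)
    cells, lr_rows, totals = [], {}, []
    children = iter(root.spawn(sum(config.n_animals_per_group[g]
                                   for g in config.groups)))
    for group in config.groups:
        for k in range(config.n_animals_per_group[group]):
            animal_id = f"{group}{k + 1}"
            c, lr, tot = simulate_animal(config, group, animal_id,
                                         next(children), geometry)
            cells.append(c)
            lr_rows[(group, animal_id)] = lr
            totals.append(tot)
    lr_df = pd.DataFrame(lr_rows).T
    lr_df.index.names = ["group", "animal_id"]
    return GroundTruth(cells=pd.concat(cells, ignore_index=True),
                       geometry=geometry, longrange_counts=lr_df,
                       totals=pd.DataFrame(totals))


# ---------------------------------------------------------------------------
# rendering


@dataclass(frozen=True)
class RenderConfig:
    """Blob rendering parameters for two-channel 16-bit slice images."""

    pixel_size_um: float = 2.0
    blob_radius_px: int = 4
    amplitude: float = 2000.0
    background: float = 100.0
    noise_sd: float = 50.0
    width_px: int | None = None
    height_px: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.blob_radius_px < 1:
            raise ValueError("pixel size and blob radius must be positive")
        if self.noise_sd < 0 or self.background < 0:
            raise ValueError("noise SD and background must be non-negative")


@dataclass
class RenderResult:
    images: np.ndarray  # (n_slices, 2, H, W) uint16, channels (green, red)
    truth_masks: np.ndarray  # (n_slices, 2, H, W) bool, noise-free
    cells: pd.DataFrame  # input table + row_px, col_px, clipped
    slice_indices: list[int]


_CLASS_CHANNELS = {"starter": (0, 1), "input": (0,), "red_only": (1,)}


def render_images(cells: pd.DataFrame, geometry: Sequence[SliceGeometry],
                  render_cfg: RenderConfig = RenderConfig(),
                  seed: int | np.random.SeedSequence = 0) -> RenderResult:
    """Render cells as uniform disks into two-channel images per slice.

    Starters appear in both channels, inputs in green only, red-only cells in
    red only.  Gaussian read noise is added on a flat background; the returned
    truth masks are the noise-free disk unions.  Cells whose centres fall
    outside the frame are clipped to the border and flagged (with a warning).
    """
    rng = np.random.default_rng(seed)
    cfg = render_cfg
    w = cfg.width_px or int(np.ceil(_DOMAIN_X / cfg.pixel_size_um))
    h = cfg.height_px or int(np.ceil(
        (geometry[0].layer_boundaries[-1] + 100.0) / cfg.pixel_size_um))
    slice_indices = sorted(int(i) for i in cells["slice_index"].unique()) or [0]
    images = np.zeros((len(slice_indices), 2, h, w), dtype=float)
    masks = np.zeros((len(slice_indices), 2, h, w), dtype=bool)

    r = cfg.blob_radius_px
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = dy ** 2 + dx ** 2 <= r ** 2
    dy, dx = dy[disk], dx[disk]

    out = cells.copy()
    col = np.round(out["x_um"].to_numpy() / cfg.pixel_size_um).astype(int)
    row = np.round(out["y_um"].to_numpy() / cfg.pixel_size_um).astype(int)
    clipped = (row < 0) | (row >= h) | (col < 0) | (col >= w)
    if clipped.any():
        warnings.warn(f"{int(clipped.sum())} cell(s) outside the image frame "
                      "were clipped to the border", stacklevel=2)
        logger.warning("render_images: clipped %d out-of-frame cells",
                       int(clipped.sum()))
    out["row_px"] = np.clip(row, 0, h - 1)
    out["col_px"] = np.clip(col, 0, w - 1)
    out["clipped"] = clipped

    plane_of = {s: k for k, s in enumerate(slice_indices)}
    for _, cell in out.iterrows():
        k = plane_of[int(cell["slice_index"])]
        rr = np.clip(cell["row_px"] + dy, 0, h - 1)
        cc = np.clip(cell["col_px"] + dx, 0, w - 1)
        for ch in _CLASS_CHANNELS[cell["channel_class"]]:
            np.add.at(images[k, ch], (rr, cc), cfg.amplitude)
            masks[k, ch, rr, cc] = True

    images += cfg.background
    if cfg.noise_sd > 0:
        images += rng.normal(0.0, cfg.noise_sd, size=images.shape)
    images = np.clip(images, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return RenderResult(images=images, truth_masks=masks, cells=out,
                        slice_indices=slice_indices)
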