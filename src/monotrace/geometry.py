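"""Flattened cortical coordinates for coronal slices.

Each slice carries a pia polyline (ordered ventral to dorsal), a rhinal-fissure
anchor on that polyline, laminar depth boundaries, and simplified region
polygons.  A cell at 2-D slice position ``p`` is mapped to a flattened
coordinate ``(x, y)`` where ``y`` is the Euclidean distance from ``p`` to its
nearest point on the pia and ``x`` is the signed arc length along the pia from
the fissure anchor to that nearest point (dorsal positive, i.e. toward
increasing vertex index).  Slices are stacked along the anterior-posterior
axis at their ``ap_position``.

Conventions
-----------
* Slice coordinates are in micrometres with y increasing with depth (image
  convention); the tissue lies on the inward-normal side of the pia, which is
  the tangent rotated by +90 degrees for a ventral-to-dorsal vertex order.
* Layer bins are half-open ``[lower, upper)`` on depth; depths at or below the
  deepest boundary get the white-matter label ``"WM"``.
* Ties (equidistant pia feet, points on shared region edges) are broken toward
  the smaller arc length / the first-listed polygon, and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

logger = logging.getLogger("monotrace")

LAYER_LABELS: tuple[str, ...] = ("L1", "L2/3", "L4", "L5", "L6")
WHITE_MATTER = "WM"
#: depth (µm) of the upper edge of L2/3, L4, L5, L6 and the white matter
DEFAULT_LAYER_BOUNDARIES: tuple[float, ...] = (100.0, 300.0, 450.0, 600.0, 900.0)

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class RegionPolygon:
    """A named atlas region, simplified to one polygon per slice."""

    name: str
    polygon: Polygon
    hemisphere: str = "ipsi"  # "ipsi" or "contra"

    def __post_init__(self) -> None:
        if self.hemisphere not in ("ipsi", "contra"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")

    @property
    def reported_name(self) -> str:
        """Region name with the ``_contra`` suffix used in count tables."""
        if self.hemisphere == "contra" and not self.name.endswith("_contra"):
            return self.name + "_contra"
        return self.name


@dataclass(frozen=True)
class SliceGeometry:
    """Per-slice registration geometry."""

    pia: np.ndarray  # (N, 2) polyline vertices, µm, ventral -> dorsal
    fissure_index: int  # vertex index of the rhinal-fissure anchor
    layer_boundaries: tuple[float, ...] = DEFAULT_LAYER_BOUNDARIES
    region_polygons: tuple[RegionPolygon, ...] = ()
    ap_position: float = 0.0

    def __post_init__(self) -> None:
        pia = np.asarray(self.pia, dtype=float)
        if pia.ndim != 2 or pia.shape[1] != 2 or len(pia) < 2:
            raise ValueError("pia must be an (N>=2, 2) array of points")
        object.__setattr__(self, "pia", pia)
        if not LineString(pia).is_simple:
            raise ValueError("pia polyline is self-intersecting")
        if not 0 <= self.fissure_index < len(pia):
            raise ValueError("fissure anchor must be a pia vertex index")
        b = np.asarray(self.layer_boundaries, dtype=float)
        if b.ndim != 1 or len(b) != len(LAYER_LABELS) or np.any(np.diff(b) <= 0) or b[0] <= 0:
            raise ValueError("layer boundaries must be positive and strictly increasing, "
                             f"one per layer in {LAYER_LABELS}")
        object.__setattr__(self, "layer_boundaries", tuple(b))

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each pia vertex (µm)."""
        seg = np.linalg.norm(np.diff(self.pia, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def anchor_arc_length(self) -> float:
        return float(self.arc_lengths[self.fissure_index])

    def to_dict(self) -> dict:
        return {
            "pia": self.pia.tolist(),
            "fissure_index": int(self.fissure_index),
            "layer_boundaries": list(self.layer_boundaries),
            "ap_position": float(self.ap_position),
            "regions": [
                {
                    "name": rp.name,
                    "hemisphere": rp.hemisphere,
                    "polygon": [list(xy) for xy in rp.polygon.exterior.coords],
                }
                for rp in self.region_polygons
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SliceGeometry":
        return cls(
            pia=np.asarray(d["pia"], dtype=float),
            fissure_index=int(d["fissure_index"]),
            layer_boundaries=tuple(d["layer_boundaries"]),
            region_polygons=tuple(
                RegionPolygon(r["name"], Polygon(r["polygon"]), r.get("hemisphere", "ipsi"))
                for r in d.get("regions", [])
            ),
            ap_position=float(d.get("ap_position", 0.0)),
        )


@dataclass(frozen=True)
class FlatCoordinate:
    """Flattened position: arc length from the fissure, depth from pia."""

    x: float  # µm, dorsal positive
    y: float  # µm, >= 0
    layer: str
    ap: float = 0.0


def geometry_to_json(slices: Sequence[SliceGeometry], path) -> None:
    with open(path, "w") as fh:
        json.dump({"slices": [g.to_dict() for g in slices]}, fh)


def geometry_from_json(path) -> list[SliceGeometry]:
    with open(path) as fh:
        d = json.load(fh)
    return [SliceGeometry.from_dict(s) for s in d["slices"]]


# ---------------------------------------------------------------------------
# flattening


def _project_on_polyline(points: np.ndarray, geom: SliceGeometry):
    """Foot point of each query point on the pia polyline.

    Returns (arc length of foot, distance to foot), each shape (M,).
    Equidistant candidate segments are resolved toward the smaller arc length.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = geom.pia[:-1]  # (S, 2) segment starts
    d = np.diff(geom.pia, axis=0)  # (S, 2)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    cum = geom.arc_lengths

    # (M, S) parameter of the orthogonal projection, clamped to the segment
    t = np.einsum("msj,sj->ms", pts[:, None, :] - a[None, :, :], d) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    foot = a[None, :, :] + t[..., None] * d[None, :, :]
    dist = np.linalg.norm(pts[:, None, :] - foot, axis=2)  # (M, S)
    arc = cum[:-1][None, :] + t * np.sqrt(seg_len2)[None, :]

    best = dist.min(axis=1, keepdims=True)
    tie = dist <= best + _TIE_TOL
    n_tied = tie.sum(axis=1)
    if np.any(n_tied > 1):
        logger.debug("flatten: %d point(s) equidistant to several pia segments; "
                     "using the smallest arc length", int((n_tied > 1).sum()))
    arc_tied = np.where(tie, arc, np.inf)
    return arc_tied.min(axis=1), best[:, 0]


def flatten_point(p, geom: SliceGeometry) -> FlatCoordinate:
    """Flatten one slice point ``p`` (µm) to ``(x, y, layer, ap)``."""
    arc, dist = _project_on_polyline(np.asarray(p, dtype=float)[None, :], geom)
    y = float(dist[0])
    x = float(arc[0] - geom.anchor_arc_length)
    return FlatCoordinate(x=x, y=y, layer=assign_layer(y, geom.layer_boundaries),
                          ap=geom.ap_position)


def flatten_points(points, geom: SliceGeometry) -> pd.DataFrame:
    """Vectorised :func:`flatten_point`; returns columns x, y, layer, ap."""
    arc, dist = _project_on_polyline(points, geom)
    x = arc - geom.anchor_arc_length
    layers = assign_layer(dist, geom.layer_boundaries)
    return pd.DataFrame({"x": x, "y": dist, "layer": layers,
                         "ap": geom.ap_position})


def unflatten_point(x: float, y: float, geom: SliceGeometry) -> np.ndarray:
    """Inverse of :func:`flatten_point` for points whose foot is interior.

    Walks ``x`` micrometres of arc from the fissure anchor and steps ``y``
    along the inward normal of the containing segment.
    """
    if y < 0:
        raise ValueError("depth y must be non-negative")
    cum = geom.arc_lengths
    s = geom.anchor_arc_length + x
    if not 0.0 <= s <= cum[-1]:
        raise ValueError("arc-length position lies beyond the pia polyline")
    i = min(int(np.searchsorted(cum, s, side="right")) - 1, len(cum) - 2)
    d = geom.pia[i + 1] - geom.pia[i]
    t_hat = d / np.linalg.norm(d)
    foot = geom.pia[i] + (s - cum[i]) * t_hat
    normal = np.array([-t_hat[1], t_hat[0]])  # +90 deg: inward for v->d order
    return foot + y * normal


# ---------------------------------------------------------------------------
# layers and regions


def assign_layer(y, boundaries: Sequence[float] = DEFAULT_LAYER_BOUNDARIES):
    """Layer label for depth(s) ``y`` using half-open bins ``[lower, upper)``.

    Depths at or beyond the deepest boundary are labelled white matter.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < 0):
        raise ValueError("depth must be non-negative")
    labels = np.array(list(LAYER_LABELS) + [WHITE_MATTER])
    idx = np.searchsorted(np.asarray(boundaries, dtype=float), y_arr, side="right")
    out = labels[idx]
    return str(out) if np.isscalar(y) or y_arr.ndim == 0 else out


def assign_region(p, geom: SliceGeometry) -> tuple[str, str]:
    """(region, hemisphere) of slice point ``p`` by point-in-polygon lookup.

    Points on a shared edge go to the first-listed polygon (logged); points
    covered by no polygon are labelled ``"other"`` (logged).  Contralateral
    regions are reported with the ``_contra`` suffix.
    """
    pt = Point(np.asarray(p, dtype=float))
    hits = [rp for rp in geom.region_polygons if rp.polygon.covers(pt)]
    if not hits:
        logger.debug("assign_region: point %s not covered by any region polygon", p)
        return "other", "ipsi"
    if len(hits) > 1:
        logger.debug("assign_region: point %s on shared boundary of %s; taking %s",
                     p, [h.name for h in hits], hits[0].name)
    return hits[0].reported_name, hits[0].hemisphere


# ---------------------------------------------------------------------------
# population alignment and profiles


def center_population(cells: pd.DataFrame, starters: pd.DataFrame,
                      column: str = "x_um") -> pd.DataFrame:
    """Per animal, subtract the starter-population mean ``column`` from all cells.

    Mirrors aligning animals on their injection site along the dorso-ventral
    axis; depth and layer are untouched.
    """
    if starters.empty:
        raise ValueError("cannot centre a population without starter cells")
    means = starters.groupby("animal_id")[column].mean()
    missing = set(cells["animal_id"].unique()) - set(means.index)
    if missing:
        raise ValueError(f"animals without starter cells: {sorted(missing)}")
    out = cells.copy()
    out[column] = out[column] - out["animal_id"].map(means).to_numpy()
    return out


def binned_profile(cells: pd.DataFrame, axis: str, bin_um: float = 50.0,
                   origin: float = 0.0) -> pd.DataFrame:
    """Fraction of cells per bin along ``axis`` in {'x', 'ap', 'layer'}.

    Numeric axes use left-closed bins of width ``bin_um`` anchored at
    ``origin``; the layer axis counts layer labels (white matter excluded).
    Fractions are normalised to sum to one within each (animal, group).
    """
    if cells.empty:
        raise ValueError("binned_profile requires a non-empty cell table")
    col = {"x": "x_um", "ap": "ap_um", "layer": "layer"}[axis]
    df = cells.copy()
    if axis == "layer":
        df = df[df[col] != WHITE_MATTER]
        df["bin"] = pd.Categorical(df[col], categories=LAYER_LABELS)
    else:
        df["bin"] = np.floor((df[col] - origin) / bin_um) * bin_um + origin
    keys = [k for k in ("animal_id", "group") if k in df.columns]
    grouped = df.groupby(keys + ["bin"], observed=False).size().rename("count").reset_index()
    if keys:
        totals = grouped.groupby(keys, observed=False)["count"].transform("sum")
    else:
        totals = grouped["count"].sum()
    grouped["fraction"] = grouped["count"] / totals
    return grouped
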