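"""Packaged long-range input table: per-animal convergence index and proportion.

The resource ``data/long_range_table.csv`` holds, for 14 animals (4 PV-Cre,
6 SST-Cre, 4 VIP-Cre) and 50 region rows, the convergence index (input cells
per starter cell, from that region) and the proportion of long-range input
cells attributed to that region.  Two region rows are both printed as ECIC in
the source table; the second is kept as ``ECIC_2`` rather than silently
merged.  ``Others`` is an opaque aggregate and is never expanded.

Because CI_r = inputs_r / starters and proportion_r = inputs_r / total
long-range inputs, the ratio ``ci / proportion`` is, for every region of one
animal, an estimate of the same quantity — that animal's total long-range
inputs per starter.  :func:`implied_total_ci` exploits this as an internal
consistency check of the table.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger("monotrace")

#: sha256 of the packaged CSV at transcription time; load_table refuses to
#: return silently corrupted data.
TABLE_SHA256 = "454712844d6831442890f7d99762b635457132a407a19c6de964e7acc74ea9b5"

GROUPS: tuple[str, ...] = ("PV", "SST", "VIP")
GROUP_SIZES: dict[str, int] = {"PV": 4, "SST": 6, "VIP": 4}
LOCAL_REGIONS: tuple[str, ...] = ("A1", "AuD", "AuV")


def _resource_text(name: str) -> str:
    return (resources.files("monotrace") / "data" / name).read_text()


def load_table(check: bool = True) -> pd.DataFrame:
    """Load the packaged long-range table.

    Returns a long-format frame with columns ``row`` (printed row order),
    ``region``, ``group``, ``animal_id``, ``ci``, ``proportion``.  Animal ids
    repeat across groups, so an animal is identified by ``(group, animal_id)``.

    Raises ``RuntimeError`` if ``check`` and the resource checksum does not
    match the frozen transcription checksum.
    """
    text = _resource_text("long_range_table.csv")
    if check:
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != TABLE_SHA256:
            raise RuntimeError("packaged long-range table is corrupted "
                               f"(sha256 {digest} != {TABLE_SHA256})")
    from io import StringIO

    df = pd.read_csv(StringIO(text), dtype={"animal_id": str})
    df["group"] = df["group"].astype("category")
    return df


def load_glossary() -> pd.DataFrame:
    """Abbreviation glossary for the region vocabulary."""
    from io import StringIO

    return pd.read_csv(StringIO(_resource_text("region_glossary.csv")))


def region_vocabulary(table: pd.DataFrame | None = None) -> list[str]:
    """Region names in printed row order."""
    if table is None:
        table = load_table()
    return list(table.drop_duplicates("region").sort_values("row")["region"])


def animals(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per animal: group and animal_id, in printed column order."""
    if table is None:
        table = load_table()
    return table.drop_duplicates(["group", "animal_id"])[["group", "animal_id"]].reset_index(drop=True)


@dataclass(frozen=True)
class ImpliedTotalCI:
    """Per-animal total long-range inputs per starter, implied region-wise."""

    group: str
    animal_id: str
    median: float
    dispersion: float  # max/min - 1 across qualifying regions
    ratios: pd.Series  # region -> ci / proportion


def implied_total_ci(table: pd.DataFrame, group: str, animal_id: str,
                     proportion_floor: float = 0.02) -> ImpliedTotalCI:
    """Implied total long-range CI of one animal, with its relative spread.

    Only regions with printed proportion >= ``proportion_floor`` enter the
    ratio, since 3-decimal rounding dominates below that.
    """
    sub = table[(table["group"] == group) & (table["animal_id"] == str(animal_id))]
    if sub.empty:
        raise KeyError(f"animal ({group}, {animal_id}) not in table")
    q = sub[sub["proportion"] >= proportion_floor]
    if q.empty:
        raise ValueError(f"no region of ({group}, {animal_id}) passes the "
                         f"proportion floor {proportion_floor}")
    ratios = (q["ci"] / q["proportion"]).set_axis(q["region"])
    return ImpliedTotalCI(
        group=group,
        animal_id=str(animal_id),
        median=float(ratios.median()),
        dispersion=float(ratios.max() / ratios.min() - 1.0),
        ratios=ratios,
    )


def group_region_summary(table: pd.DataFrame, region: str,
                         metric: str = "proportion") -> pd.DataFrame:
    """Per-group mean and SEM of ``metric`` in {'ci', 'proportion'} for one region."""
    if metric not in ("ci", "proportion"):
        raise ValueError("metric must be 'ci' or 'proportion'")
    sub = table[table["region"] == region]
    if sub.empty:
        raise KeyError(f"unknown region {region!r}")
    out = (sub.groupby("group", observed=True)[metric]
           .agg(mean="mean", sem=lambda v: v.sem(ddof=1), n="size")
           .reset_index())
    return out


def mean_region_probs(table: pd.DataFrame | None = None,
                      group: str | None = None) -> pd.Series:
    """Mean printed proportion per region (optionally within one group),
    renormalised to sum to one.  Used as the default long-range sampling
    distribution of the synthetic generator."""
    if table is None:
        table = load_table()
    sub = table if group is None else table[table["group"] == group]
    probs = sub.groupby("region", observed=True)["proportion"].mean()
    probs = probs.reindex(region_vocabulary(table))
    return probs / probs.sum()


def display_view(props: pd.DataFrame, min_fraction: float = 0.002) -> pd.DataFrame:
    """Reporting filter: keep regions whose mean proportion exceeds
    ``min_fraction``.  For display only; statistics always use the full table."""
    keep = props.mean(axis=0) > min_fraction
    dropped = [c for c in props.columns if not keep[c]]
    if dropped:
        logger.debug("display_view: hiding %d low-fraction regions", len(dropped))
    return props.loc[:, keep]
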