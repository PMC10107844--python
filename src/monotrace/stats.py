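"""Connectivity measures and group statistics for tracing count data.

Core quantities: the convergence index (CI = input cells per starter cell,
per animal or per region), per-animal proportion tables over the long-range
region vocabulary (local regions A1/AuD/AuV excluded), local and
contralateral input fractions, and distance distributions of input cells
relative to starter cells along the flattened dorso-ventral or the
anterior-posterior axis (``pairwise``: every input-starter pair;
``centerline``: each input against the starter-population centre).

Group comparisons follow the conventions of the source field: two-sample
Kolmogorov-Smirnov on distance distributions, a Kruskal-Wallis omnibus that
gates Tukey HSD pairwise comparisons (Dunn's rank test available as the
statistically conventional alternative), and Pearson correlation for
starter-count dependence checks.  No multiple-testing correction is applied
across regions; results that feed region-by-region scans should be read as
exploratory.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("monotrace")

LOCAL_REGIONS: tuple[str, ...] = ("A1", "AuD", "AuV")
ALPHA_DEFAULT = 0.05

_AXIS_COLUMNS = {"dv": ("x_um",), "ap": ("ap_um",), "2d": ("x_um", "depth_um")}


# ---------------------------------------------------------------------------
# count matrices and ratios


@dataclass
class CountMatrix:
    """Per-animal input counts by region, plus starter counts.

    ``counts`` is indexed by animal_id with one column per region (local
    regions and long-range vocabulary, contralateral regions suffixed
    ``_contra``); ``starters`` and ``groups`` are aligned to the same index.
    """

    counts: pd.DataFrame
    starters: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.starters.index):
            raise ValueError("counts and starters must share the animal index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("input counts must be non-negative")
        if (self.starters < 1).any():
            bad = list(self.starters[self.starters < 1].index)
            raise ValueError(f"animals without starter cells: {bad}")

    @property
    def local_columns(self) -> list[str]:
        return [c for c in self.counts.columns if c in LOCAL_REGIONS]

    @property
    def longrange_columns(self) -> list[str]:
        return [c for c in self.counts.columns if c not in LOCAL_REGIONS]

    @property
    def total_inputs(self) -> pd.Series:
        return self.counts.sum(axis=1)


def build_count_matrix(cells: pd.DataFrame,
                       longrange_counts: pd.DataFrame | None = None) -> CountMatrix:
    """Assemble a CountMatrix from a cell table (starters + local inputs with
    region labels) and an optional per-animal long-range count table indexed
    by (group, animal_id)."""
    starters = cells[cells["channel_class"] == "starter"]
    inputs = cells[cells["channel_class"] == "input"]
    n_starters = starters.groupby("animal_id").size()
    groups = cells.drop_duplicates("animal_id").set_index("animal_id")["group"]
    local = (inputs.groupby(["animal_id", "region"]).size()
             .unstack(fill_value=0))
    local = local.reindex(index=n_starters.index, fill_value=0)
    if longrange_counts is not None:
        lr = longrange_counts.reset_index(level="group", drop=True)
        lr = lr.reindex(index=n_starters.index, fill_value=0)
        counts = pd.concat([local, lr], axis=1).fillna(0).astype(int)
    else:
        counts = local.astype(int)
    return CountMatrix(counts=counts, starters=n_starters.astype(int),
                       groups=groups.loc[n_starters.index])


def convergence_index(n_input: int, n_starter: int) -> float:
    """Input cells per starter cell; requires at least one starter."""
    if n_starter < 1:
        raise ValueError("convergence index undefined without starter cells")
    if n_input < 0:
        raise ValueError("input count must be non-negative")
    return n_input / n_starter


def ci_table(cm: CountMatrix) -> pd.DataFrame:
    """Per-animal total, local and long-range convergence indices."""
    out = pd.DataFrame({
        "group": cm.groups,
        "n_starters": cm.starters,
        "ci_total": cm.total_inputs / cm.starters,
        "ci_local": cm.counts[cm.local_columns].sum(axis=1) / cm.starters,
        "ci_longrange": cm.counts[cm.longrange_columns].sum(axis=1) / cm.starters,
    })
    return out


def proportions_longrange(cm: CountMatrix) -> pd.DataFrame:
    """Per-animal proportions over long-range regions (local A1/AuD/AuV
    excluded); rows sum to one.  Animals without long-range inputs are
    dropped with a log entry."""
    lr = cm.counts[cm.longrange_columns]
    totals = lr.sum(axis=1)
    empty = totals[totals == 0].index
    if len(empty):
        logger.warning("proportions_longrange: excluding animals with no "
                       "long-range inputs: %s", list(empty))
        lr = lr.drop(index=empty)
        totals = totals.drop(index=empty)
    return lr.div(totals, axis=0)


def input_fraction(cm: CountMatrix, selector: str) -> pd.Series:
    """Per-animal fraction of inputs that are local (A1/AuD/AuV) or that come
    from the contralateral hemisphere (columns suffixed ``_contra``)."""
    if selector == "local":
        cols = cm.local_columns
    elif selector == "contralateral":
        cols = [c for c in cm.counts.columns if c.endswith("_contra")]
    else:
        raise ValueError("selector must be 'local' or 'contralateral'")
    totals = cm.total_inputs
    if (totals == 0).any():
        raise ValueError("input_fraction undefined for animals without inputs")
    return cm.counts[cols].sum(axis=1) / totals


def top_k_coverage(props: pd.DataFrame, k: int) -> pd.Series:
    """Per-animal sum of the k largest long-range proportions (k past the
    number of regions saturates at the full sum)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return props.apply(lambda row: row.nlargest(min(k, len(row))).sum(), axis=1)


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceSample:
    """Distances of input cells relative to starter cells of one animal set."""

    distances: np.ndarray
    axis: str  # 'dv', 'ap' or '2d'
    mode: str  # 'pairwise' or 'centerline'
    group: str | None = None
    layer: str | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        self.distances = d


def distance_sample(inputs: pd.DataFrame, starters: pd.DataFrame,
                    axis: str = "dv", mode: str = "pairwise",
                    layer: str | None = None) -> DistanceSample:
    """Distance distribution of inputs relative to starters.

    ``axis``: 'dv' uses the flattened x coordinate, 'ap' the
    anterior-posterior coordinate, '2d' the in-plane (x, depth) pair.
    ``mode='pairwise'`` returns all input-starter distances (sample size
    n_inputs * n_starters); ``mode='centerline'`` returns each input's
    distance to the starter-population centre coordinate.  Distances are
    computed per animal and pooled, so starters of one animal are never
    paired with inputs of another.
    """
    if inputs.empty or starters.empty:
        raise ValueError("distance_sample requires non-empty input and starter tables")
    if layer is not None:
        inputs = inputs[inputs["layer"] == layer]
        if inputs.empty:
            raise ValueError(f"no input cells in layer {layer!r}")
    cols = _AXIS_COLUMNS[axis]
    group = starters["group"].iloc[0] if "group" in starters.columns else None
    out = []
    for animal, inp in inputs.groupby("animal_id"):
        sta = starters[starters["animal_id"] == animal]
        if sta.empty:
            raise ValueError(f"animal {animal!r} has inputs but no starters")
        a = inp[list(cols)].to_numpy(float)
        b = sta[list(cols)].to_numpy(float)
        if mode == "pairwise":
            d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).ravel()
        elif mode == "centerline":
            d = np.linalg.norm(a - b.mean(axis=0), axis=1)
        else:
            raise ValueError("mode must be 'pairwise' or 'centerline'")
        out.append(d)
    return DistanceSample(distances=np.concatenate(out), axis=axis, mode=mode,
                          group=group, layer=layer)


def cumulative_fraction(sample: DistanceSample | np.ndarray,
                        grid: np.ndarray) -> np.ndarray:
    """Empirical CDF of a distance sample evaluated on ``grid`` (µm)."""
    d = sample.distances if isinstance(sample, DistanceSample) else np.asarray(sample, float)
    if len(d) == 0:
        raise ValueError("cumulative_fraction requires a non-empty sample")
    return np.searchsorted(np.sort(d), np.asarray(grid, float),
                           side="right") / len(d)


def ks_compare(a: DistanceSample | np.ndarray,
               b: DistanceSample | np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and two-sided p-value."""
    da = a.distances if isinstance(a, DistanceSample) else np.asarray(a, float)
    db = b.distances if isinstance(b, DistanceSample) else np.asarray(b, float)
    if len(da) < 2 or len(db) < 2:
        raise ValueError("ks_compare requires n >= 2 in both samples")
    if np.ptp(da) == 0 and np.ptp(db) == 0:
        logger.warning("ks_compare: both samples are constant")
    res = sps.ks_2samp(da, db, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    p_value: float
    significant: bool


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus with gated post hoc pairwise comparisons."""

    statistic: float
    p_value: float
    alpha: float
    posthoc: str | None  # 'tukey', 'dunn' or None if the omnibus did not reject
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    degenerate: bool = False


def kw_tukey(groups: dict[str, np.ndarray], alpha: float = ALPHA_DEFAULT,
             posthoc: str = "tukey") -> GroupComparison:
    """Kruskal-Wallis omnibus; if it rejects at ``alpha``, run pairwise
    comparisons (Tukey HSD by default, Dunn's rank test as the conventional
    nonparametric alternative).  Identical-constant groups are degenerate and
    reported with p = 1.  Ties are midranked by the omnibus (logged).
    """
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        logger.warning("kw_tukey: all observations identical; degenerate, p = 1")
        return GroupComparison(statistic=0.0, p_value=1.0, alpha=alpha,
                               posthoc=None, degenerate=True)
    if len(np.unique(pooled)) < len(pooled):
        logger.debug("kw_tukey: ties present; Kruskal-Wallis uses midranks")
    h, p = sps.kruskal(*samples)
    comp = GroupComparison(statistic=float(h), p_value=float(p), alpha=alpha,
                           posthoc=None)
    if p >= alpha:
        return comp  # omnibus not significant: no pairwise tests reported
    comp.posthoc = posthoc
    if posthoc == "tukey":
        res = sps.tukey_hsd(*samples)
        for i, j in itertools.combinations(range(len(names)), 2):
            pv = float(res.pvalue[i, j])
            comp.pairwise.append(PairwiseComparison(names[i], names[j], pv,
                                                    pv < alpha))
    elif posthoc == "dunn":
        for (i, ga), (j, gb), pv in _dunn_pairs(names, samples):
            comp.pairwise.append(PairwiseComparison(ga, gb, pv, pv < alpha))
    else:
        raise ValueError("posthoc must be 'tukey' or 'dunn'")
    return comp


def _dunn_pairs(names, samples):
    """Dunn's z-tests on mean ranks with tie correction, uncorrected p."""
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_tot = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_tot - 1))
    var_unit = n_tot * (n_tot + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start:start + len(s)].mean())
        sizes.append(len(s))
        start += len(s)
    for i, j in itertools.combinations(range(len(names)), 2):
        se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pv = float(2.0 * sps.norm.sf(abs(z)))
        yield (i, names[i]), (j, names[j]), pv


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson requires paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson is undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
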