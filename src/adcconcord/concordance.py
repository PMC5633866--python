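"""Inter-implementation concordance statistics for ROI-mean diffusion metrics.

Given a long-format measurement table (implementation x dataset x ROI x
metric -> mean value), this module computes:

* the pairwise within-subject coefficient of variation (wCV) between every
  implementation pair, using the root-mean-square paired formulation
  (Bland): wCV = 100 * sqrt( mean[ ((x - y)^2 / 2) / ((x + y) / 2)^2 ] );
* threshold grouping: maximal cliques of the graph whose edges are pairs
  with wCV below a threshold (0.1% by convention), selected greedily into
  disjoint groups by descending size;
* consensus reference values per (dataset, ROI): the median across
  implementations (two-b-value data) or the unweighted average of the two
  group means (four-b-value data, each group counted once regardless of
  size);
* percent differences from the reference, intergroup mean difference with
  SD and a paired two-tailed t-test, and an OLS regression of intergroup
  percent difference against the ROI-mean ADC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

REQUIRED_COLUMNS = ("implementation", "dataset", "roi", "metric", "value")

GROUP_WCV_THRESHOLD = 0.1   # %; the conventional intragroup agreement bound


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check measurement-table invariants; returns the (unchanged) table."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns {missing}")
    keys = table[["implementation", "dataset", "roi", "metric"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (implementation, dataset, roi, metric) rows")
    return table


def _paired_values(table: pd.DataFrame, impl_a: str, impl_b: str,
                   metric: str | None = None):
    t = table if metric is None else table[table["metric"] == metric]
    a = t[t["implementation"] == impl_a]
    b = t[t["implementation"] == impl_b]
    m = a.merge(b, on=["dataset", "roi", "metric"], suffixes=("_a", "_b"))
    return m["value_a"].to_numpy(float), m["value_b"].to_numpy(float)


def pairwise_wcv(table: pd.DataFrame, impl_a: str, impl_b: str,
                 metric: str | None = None) -> float:
    """RMS paired within-subject CV (%) over shared (dataset, ROI) entries."""
    x, y = _paired_values(table, impl_a, impl_b, metric)
    if x.size == 0:
        raise ValueError(f"no shared measurements between {impl_a} and {impl_b}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("wCV requires strictly positive measurements")
    within_var = (x - y) ** 2 / 2.0
    mean_sq = ((x + y) / 2.0) ** 2
    return float(100.0 * np.sqrt(np.mean(within_var / mean_sq)))


@dataclass
class WCVMatrix:
    implementations: tuple[str, ...]
    matrix: np.ndarray            # symmetric, % units, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.implementations)
        if m.shape != (n, n):
            raise ValueError("wCV matrix shape must match implementation count")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("wCV matrix must be symmetric with zero diagonal")
        if np.any(m < 0):
            raise ValueError("wCV entries must be non-negative")
        self.matrix = m

    def value(self, a: str, b: str) -> float:
        i = self.implementations.index(a)
        j = self.implementations.index(b)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.implementations,
                            columns=self.implementations)


def wcv_matrix(table: pd.DataFrame, metric: str | None = None) -> WCVMatrix:
    """All-pairs wCV over the implementations present in the table."""
    validate_table(table)
    t = table if metric is None else table[table["metric"] == metric]
    impls = tuple(sorted(t["implementation"].unique()))
    n = len(impls)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = pairwise_wcv(t, impls[i], impls[j], metric)
    return WCVMatrix(implementations=impls, matrix=m)


@dataclass
class GroupAssignment:
    groups: dict[str, tuple[str, ...]]      # label -> implementation set
    ungrouped: tuple[str, ...]
    threshold: float

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def members(self, label: str) -> tuple[str, ...]:
        return self.groups[label]


def find_groups(w: WCVMatrix, threshold: float = GROUP_WCV_THRESHOLD) -> GroupAssignment:
    """Disjoint agreement groups from the sub-threshold wCV graph.

    All maximal cliques of the graph with edges ``wCV < threshold`` are
    enumerated; disjoint groups are selected greedily by descending clique
    size, breaking ties by smaller mean intra-clique wCV, then
    lexicographically for determinism.  Cliques of size 1 (and members left
    over after selection) are reported as ungrouped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    impls = w.implementations
    g = nx.Graph()
    g.add_nodes_from(impls)
    for a, b in itertools.combinations(impls, 2):
        if w.value(a, b) < threshold:
            g.add_edge(a, b)

    def mean_wcv(clique):
        if len(clique) < 2:
            return 0.0
        return float(np.mean([w.value(a, b)
                              for a, b in itertools.combinations(clique, 2)]))

    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), mean_wcv(c), c))
    taken: set[str] = set()
    selected: list[tuple[str, ...]] = []
    for c in cliques:
        if len(c) < 2 or taken.intersection(c):
            continue
        selected.append(c)
        taken.update(c)
    labels = {chr(ord("A") + i): c for i, c in enumerate(selected)}
    ungrouped = tuple(sorted(set(impls) - taken))
    return GroupAssignment(groups=labels, ungrouped=ungrouped, threshold=threshold)


# ---------------------------------------------------------------------------
# consensus references and differences

ReferenceMode = Literal["median_all", "group_average"]


def consensus_reference(table: pd.DataFrame, groups: GroupAssignment | None = None,
                        mode: ReferenceMode = "median_all",
                        metric: str | None = None) -> pd.DataFrame:
    """Per-(dataset, roi) consensus reference values.

    ``median_all``: the median over all implementations.
    ``group_average``: (mean over group-A members + mean over group-B
    members) / 2, each group weighted equally regardless of size; requires
    exactly two groups.
    """
    validate_table(table)
    t = table if metric is None else table[table["metric"] == metric]
    if mode == "median_all":
        ref = (t.groupby(["dataset", "roi", "metric"])["value"]
               .median().rename("reference").reset_index())
        return ref
    if mode == "group_average":
        if groups is None or groups.n_groups != 2:
            raise ValueError("group_average requires exactly 2 groups")
        (la, ga), (lb, gb) = sorted(groups.groups.items())
        ta = t[t["implementation"].isin(ga)]
        tb = t[t["implementation"].isin(gb)]
        ma = ta.groupby(["dataset", "roi", "metric"])["value"].mean()
        mb = tb.groupby(["dataset", "roi", "metric"])["value"].mean()
        ref = ((ma + mb) / 2.0).rename("reference").reset_index()
        if ref["reference"].isna().any():
            raise ValueError("a group has no measurement for some (dataset, roi)")
        return ref
    raise ValueError(f"unknown reference mode {mode!r}")


def percent_difference(value, reference):
    """100 * (value - reference) / reference; reference must be positive."""
    ref = np.asarray(reference, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("percent difference undefined for reference <= 0")
    out = 100.0 * (np.asarray(value, dtype=float) - ref) / ref
    return float(out) if out.ndim == 0 else out


def percent_differences(table: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Join measurements with references; adds a ``pct_diff`` column."""
    merged = validate_table(table).merge(reference, on=["dataset", "roi", "metric"])
    merged["pct_diff"] = percent_difference(merged["value"], merged["reference"])
    return merged


@dataclass
class IntergroupStats:
    mean_pct_diff: float        # group B relative to group A, %
    sd_pct_diff: float
    t_statistic: float
    p_value: float
    n_pairs: int
    group_a: str
    group_b: str


def intergroup_stats(table: pd.DataFrame, groups: GroupAssignment,
                     metric: str | None = None) -> IntergroupStats:
    """Percent difference of group-B vs group-A means per (dataset, ROI).

    Per unit the difference is 100*(mean_B - mean_A)/mean_A; the summary is
    its mean and SD, plus a paired two-tailed t-test of the group means
    across units.  Two identical groups give mean 0 and a degenerate
    (NaN-p) test, reported as no difference.
    """
    if groups.n_groups != 2:
        raise ValueError("intergroup statistics require exactly 2 groups")
    validate_table(table)
    t = table if metric is None else table[table["metric"] == metric]
    (la, ga), (lb, gb) = sorted(groups.groups.items())
    ma = (t[t["implementation"].isin(ga)]
          .groupby(["dataset", "roi"])["value"].mean())
    mb = (t[t["implementation"].isin(gb)]
          .groupby(["dataset", "roi"])["value"].mean())
    joined = pd.concat([ma.rename("a"), mb.rename("b")], axis=1).dropna()
    if len(joined) < 2:
        raise ValueError("need at least 2 paired (dataset, roi) comparisons")
    pct = percent_difference(joined["b"].to_numpy(), joined["a"].to_numpy())
    if np.allclose(joined["a"], joined["b"]):
        tstat, p = 0.0, float("nan")
    else:
        res = sps.ttest_rel(joined["b"], joined["a"])
        tstat, p = float(res.statistic), float(res.pvalue)
    return IntergroupStats(
        mean_pct_diff=float(np.mean(pct)),
        sd_pct_diff=float(np.std(pct, ddof=1)),
        t_statistic=tstat,
        p_value=p,
        n_pairs=int(len(joined)),
        group_a=la,
        group_b=lb,
    )


def bias_vs_adc_regression(percent_diffs, roi_mean_adcs_1e3):
    """OLS of intergroup percent difference on ROI-mean ADC.

    ``roi_mean_adcs_1e3`` is in units of 1e-3 mm^2/s, so the slope is in
    % per 1e-3 mm^2/s.  Returns (slope, r_squared).
    """
    y = np.asarray(percent_diffs, dtype=float)
    x = np.asarray(roi_mean_adcs_1e3, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: no variance in ADC")
    if np.ptp(y) == 0:
        return 0.0, 0.0          # flat response: slope 0, explains nothing
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)


@dataclass
class ConcordanceReport:
    """Everything the concordance engine derives from one measurement table."""

    metric: str
    wcv: WCVMatrix
    groups: GroupAssignment
    reference_mode: str
    references: pd.DataFrame
    percent_diffs: pd.DataFrame
    intergroup: IntergroupStats | None = None
    regression: tuple[float, float] | None = None   # (slope %/1e-3, R^2)

    def summary(self) -> dict:
        out = {
            "metric": self.metric,
            "n_implementations": len(self.wcv.implementations),
            "threshold_pct": self.groups.threshold,
            "groups": {k: list(v) for k, v in self.groups.groups.items()},
            "ungrouped": list(self.groups.ungrouped),
            "reference_mode": self.reference_mode,
            "max_wcv_pct": float(self.wcv.matrix.max()),
        }
        if self.intergroup is not None:
            ig = self.intergroup
            out["intergroup"] = {
                "mean_pct_diff": ig.mean_pct_diff,
                "sd_pct_diff": ig.sd_pct_diff,
                "p_value": ig.p_value,
                "n_pairs": ig.n_pairs,
            }
        if self.regression is not None:
            out["bias_vs_adc"] = {
                "slope_pct_per_1e3": self.regression[0],
                "r_squared": self.regression[1],
            }
        return out


def analyze(table: pd.DataFrame, metric: str,
            threshold: float = GROUP_WCV_THRESHOLD,
            reference_mode: ReferenceMode = "median_all") -> ConcordanceReport:
    """One-call concordance analysis of a measurement table for one metric."""
    validate_table(table)
    t = table[table["metric"] == metric]
    if t.empty:
        raise ValueError(f"no measurements for metric {metric!r}")
    w = wcv_matrix(t, metric)
    groups = find_groups(w, threshold)
    intergroup = None
    regression = None
    mode = reference_mode
    if mode == "group_average" and groups.n_groups != 2:
        mode = "median_all"     # fall back when the two-group structure is absent
    refs = consensus_reference(t, groups, mode, metric)
    pdiffs = percent_differences(t, refs)
    if groups.n_groups == 2:
        try:
            intergroup = intergroup_stats(t, groups, metric)
        except ValueError:
            intergroup = None       # <2 paired units: summary test omitted
        # regress intergroup percent difference on the ROI-mean reference ADC
        (la, ga), (lb, gb) = sorted(groups.groups.items())
        ma = (t[t["implementation"].isin(ga)]
              .groupby(["dataset", "roi"])["value"].mean())
        mb = (t[t["implementation"].isin(gb)]
              .groupby(["dataset", "roi"])["value"].mean())
        joined = pd.concat([ma.rename("a"), mb.rename("b")], axis=1).dropna()
        if len(joined) >= 3 and metric.startswith("ADC"):
            pct = percent_difference(joined["b"].to_numpy(), joined["a"].to_numpy())
            adc_1e3 = (joined[["a", "b"]].mean(axis=1) / 1000.0).to_numpy()
            if np.ptp(adc_1e3) > 0:
                regression = bias_vs_adc_regression(pct, adc_1e3)
    return ConcordanceReport(
        metric=metric,
        wcv=w,
        groups=groups,
        reference_mode=mode,
        references=refs,
        percent_diffs=pdiffs,
        intergroup=intergroup,
        regression=regression,
    )
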