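"""Group-comparison statistics over object tables.

Three designs are supported, mirroring how object-level order metrics are
analyzed across an assembly time course:

* **Timepoint comparison** of object OF or azimuthal disorder: Kruskal–Wallis
  omnibus test followed by Dunn's multiple-comparisons test. Comparisons are
  restricted *before* adjustment to neighboring timepoints plus each timepoint
  against the no-pulse control, and the adjustment (Bonferroni, as in Dunn's
  procedure) runs over exactly that restricted set.
* **Fragment counts** (adhesion assay tables): ordinary one-way ANOVA followed
  by Sidak-adjusted pairwise comparisons over the same restricted set, using
  the pooled within-group variance from the ANOVA.
* **Border pairs** (scratch-wound A/B or confluent A'/B'): paired t-test.

Dunn's test is implemented here directly (rank means on the pooled midranks,
tie-corrected variance) since no post-hoc library is part of the stack; it is
checked against hand-computed oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adj: float


@dataclass
class StatsReport:
    test: str
    statistic: float
    p_value: float
    group_summary: pd.DataFrame
    comparisons: list[ComparisonResult] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "groups": self.group_summary.to_dict(orient="records"),
            "comparisons": [vars(c) for c in self.comparisons],
            "notes": self.notes,
        }


def neighbor_control_pairs(ordered_labels: list[str], control: str) -> list[tuple[str, str]]:
    """Neighboring-timepoint pairs plus each timepoint vs the control, deduplicated."""
    timeline = [g for g in ordered_labels if g != control]
    pairs = [(timeline[i], timeline[i + 1]) for i in range(len(timeline) - 1)]
    pairs += [(g, control) for g in timeline]
    seen, out = set(), []
    for p in pairs:
        key = frozenset(p)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def _check_groups(groups: dict[str, np.ndarray], min_n: int) -> dict[str, np.ndarray]:
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < min_n:
            raise ValueError(f"group {name!r} has {arr.size} finite observations (need >= {min_n})")
        clean[name] = arr
    if len(clean) < 2:
        raise ValueError("need at least 2 groups")
    return clean


def dunn_test(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
) -> list[ComparisonResult]:
    """Dunn's rank-based pairwise z tests with midrank tie correction.

    Adjusted p-values are Bonferroni over the comparisons actually made; they
    are capped at 1 and never smaller than the raw p.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # midranks
    offsets = np.cumsum([0] + [groups[g].size for g in labels])
    rank_mean = {g: float(np.mean(ranks[offsets[i]:offsets[i + 1]])) for i, g in enumerate(labels)}

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    m = len(comparisons)
    out = []
    for a, b in comparisons:
        if a not in groups or b not in groups:
            raise ValueError(f"comparison ({a}, {b}) references an unknown group")
        se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (rank_mean[a] - rank_mean[b]) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        out.append(ComparisonResult(a, b, float(z), p_raw, min(1.0, p_raw * m)))
    return out


def compare_timepoints(
    table: pd.DataFrame,
    metric: str = "mean_of",
    group_col: str = "condition",
    order: list[str] | None = None,
    control: str = "no-pulse",
) -> StatsReport:
    """Kruskal–Wallis omnibus + Dunn post hoc over the neighbor-and-control set."""
    groups = {str(g): sub[metric].to_numpy(dtype=float) for g, sub in table.groupby(group_col, sort=False)}
    groups = _check_groups(groups, min_n=2)
    if order is None:
        order = list(groups)
    arrays = [groups[g] for g in order]
    notes = []
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # every observation identical: no rank variation at all
        h, p = 0.0, 1.0
        notes.append("degenerate: all observations identical; H = 0")
    else:
        h, p = sps.kruskal(*arrays)
    summary = pd.DataFrame({
        "group": order,
        "n": [groups[g].size for g in order],
        "median": [float(np.median(groups[g])) for g in order],
        "iqr_low": [float(np.percentile(groups[g], 25)) for g in order],
        "iqr_high": [float(np.percentile(groups[g], 75)) for g in order],
    })
    comps = (dunn_test(groups, neighbor_control_pairs(order, control))
             if control in groups and np.ptp(pooled) > 0 else [])
    return StatsReport("Kruskal-Wallis + Dunn", float(h), float(p), summary, comps, notes)


def compare_fragment_counts(
    counts: pd.DataFrame,
    value_col: str = "n_fragments",
    group_col: str = "timepoint",
    order: list[str] | None = None,
    control: str = "no-pulse",
) -> StatsReport:
    """One-way ANOVA + Sidak-adjusted pairwise t over the neighbor-and-control set."""
    groups = {str(g): sub[value_col].to_numpy(dtype=float) for g, sub in counts.groupby(group_col, sort=False)}
    groups = _check_groups(groups, min_n=2)
    if order is None:
        order = list(groups)
    arrays = [groups[g] for g in order]
    notes = []
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # all observations identical: zero between- and within-group variance
        notes.append("degenerate: all groups identical constants; F undefined")
        f_stat, p = float("nan"), float("nan")
    else:
        f_stat, p = sps.f_oneway(*arrays)
    summary = pd.DataFrame({
        "group": order,
        "n": [groups[g].size for g in order],
        "mean": [float(np.mean(groups[g])) for g in order],
        "sd": [float(np.std(groups[g], ddof=1)) for g in order],
    })
    comps = []
    if control in groups and np.isfinite(f_stat):
        pairs = neighbor_control_pairs(order, control)
        n_total = sum(a.size for a in arrays)
        k = len(arrays)
        mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / (n_total - k)
        m = len(pairs)
        for a, b in pairs:
            xa, xb = groups[a], groups[b]
            se = np.sqrt(mse * (1.0 / xa.size + 1.0 / xb.size))
            t = (xa.mean() - xb.mean()) / se if se > 0 else 0.0
            p_raw = float(2.0 * sps.t.sf(abs(t), df=n_total - k))
            p_adj = float(1.0 - (1.0 - p_raw) ** m)
            comps.append(ComparisonResult(a, b, float(t), p_raw, p_adj))
    return StatsReport("one-way ANOVA + Sidak", float(f_stat), float(p), summary, comps, notes)


def paired_border_test(pairs: pd.DataFrame, col_a: str = "A", col_b: str = "B") -> StatsReport:
    """Two-sided paired t-test on border-pair values; incomplete pairs are dropped."""
    a = pairs[col_a].to_numpy(dtype=float)
    b = pairs[col_b].to_numpy(dtype=float)
    complete = np.isfinite(a) & np.isfinite(b)
    notes = []
    if (~complete).sum():
        notes.append(f"excluded {int((~complete).sum())} incomplete pairs")
    a, b = a[complete], b[complete]
    if a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    diff = b - a
    summary = pd.DataFrame({
        "group": [col_a, col_b, "difference"],
        "n": [a.size, b.size, a.size],
        "mean": [float(a.mean()), float(b.mean()), float(diff.mean())],
        "sd": [float(np.std(a, ddof=1)), float(np.std(b, ddof=1)), float(np.std(diff, ddof=1))],
    })
    if np.std(diff, ddof=1) == 0:
        notes.append("degenerate: zero variance of paired differences")
        t = 0.0 if diff.mean() == 0 else float("inf") * np.sign(diff.mean())
        p = 1.0 if diff.mean() == 0 else 0.0
    else:
        t, p = sps.ttest_rel(b, a)
    return StatsReport("paired t-test", float(t), float(p), summary, notes=notes)
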