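"""Node-wise two-group comparison with family-wise error control.

At each of the 100 nodes an independent two-sample t-test (equal-variance by
default; Welch via a flag) compares the subject-level node values of the two
groups. Because 100 correlated tests are run per (tract, metric), the raw
p-values are corrected for family-wise error either by the permutation max-T
procedure (default: the null distribution of the maximum |t| over nodes
under group-label permutation) or by Bonferroni.

The :class:`NodewiseGroupComparison` model consumes the long-format profile
table; its :meth:`~NodewiseGroupComparison.fit` returns a results object
with node-level statistics, significance flags at alpha, and a
``summary()`` table of tract-mean values (mean +/- SD across subjects) with
a star on metrics significant in more than ``min_sig_nodes`` nodes.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import DataError
from .profiles import METRICS


def _t_from_sums(s_a, q_a, n_a, s_tot, q_tot, n_tot):
    """Equal-variance two-sample t from group-A sums/sum-squares per node."""
    n_b = n_tot - n_a
    s_b = s_tot - s_a
    q_b = q_tot - q_a
    m_a, m_b = s_a / n_a, s_b / n_b
    ss_a = q_a - n_a * m_a**2
    ss_b = q_b - n_b * m_b**2
    sp2 = (ss_a + ss_b) / (n_tot - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m_a - m_b) / denom
    return np.where(denom > 0, t, 0.0)


def nodewise_ttest(values_a: np.ndarray, values_b: np.ndarray,
                   equal_var: bool = True
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided two-sample t-test per node.

    Parameters are (subjects, nodes) arrays. Returns (t, p, degenerate)
    where degenerate marks nodes with zero pooled variance; those get
    t = 0, p = 1.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("need >= 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise DataError("groups have different node counts")
    with warnings.catch_warnings():
        # zero-variance nodes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return t, p, degenerate


def _maxT_null(data: np.ndarray, n_a: int, n_perm: int | None,
               rng_seed: int) -> np.ndarray:
    """Max-|t| null over nodes under group-label permutation.

    ``n_perm=None`` enumerates all C(n, n_a) label splits (exhaustive);
    otherwise ``n_perm`` random splits are drawn.
    """
    n_tot, _ = data.shape
    s_tot = data.sum(axis=0)
    q_tot = (data**2).sum(axis=0)
    if n_perm is None:
        combos = np.array(list(itertools.combinations(range(n_tot), n_a)))
    else:
        rng = np.random.default_rng(rng_seed)
        order = np.argsort(rng.random((n_perm, n_tot)), axis=1)
        combos = order[:, :n_a]
    member = np.zeros((len(combos), n_tot))
    np.put_along_axis(member, combos, 1.0, axis=1)
    s_a = member @ data
    q_a = member @ data**2
    t_perm = _t_from_sums(s_a, q_a, n_a, s_tot, q_tot, n_tot)
    return np.abs(t_perm).max(axis=1)


@dataclass
class GroupStatsResult:
    """Node-wise statistics of one (tract, hemisphere, metric) comparison."""

    tract: str
    hemisphere: str
    metric: str
    t: np.ndarray
    p_raw: np.ndarray
    p_fwe: np.ndarray
    significant: np.ndarray
    alpha: float
    n_a: int
    n_b: int
    fwe_method: str
    n_perm: int | None = None
    rng_seed: int | None = None
    degenerate: np.ndarray | None = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tract": self.tract, "hemisphere": self.hemisphere,
            "metric": self.metric,
            "node": np.arange(1, len(self.t) + 1),
            "t": self.t, "p_raw": self.p_raw, "p_fwe": self.p_fwe,
            "significant": self.significant,
        })


def fwe_correct(values_a: np.ndarray, values_b: np.ndarray,
                metric: str = "", tract: str = "", hemisphere: str = "",
                method: str = "permutation_maxT",
                n_perm: int | None = 10_000, rng_seed: int = 0,
                alpha: float = 0.05,
                equal_var: bool = True) -> GroupStatsResult:
    """Node-wise t-tests with FWE-adjusted p-values.

    ``method="permutation_maxT"`` (default): adjusted p of a node is the
    fraction of permutations whose max |t| over nodes reaches that node's
    observed |t| (with the add-one correction for sampled permutations;
    ``n_perm=None`` enumerates all splits exactly).
    ``method="bonferroni"``: adjusted p = min(1, n_nodes * p_raw).
    Adjusted p-values are floored at the raw p, so p_fwe >= p_raw always.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise DataError("need >= 2 subjects per group for FWE correction")
    t, p_raw, degenerate = nodewise_ttest(a, b, equal_var=equal_var)

    if method == "bonferroni":
        from statsmodels.stats.multitest import multipletests

        _, p_fwe, _, _ = multipletests(p_raw, alpha=alpha, method="bonferroni")
        used_perm = None
    elif method == "permutation_maxT":
        if n_perm is not None and n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is very low for max-T",
                          stacklevel=2)
        data = np.vstack([a, b])
        null = _maxT_null(data, a.shape[0], n_perm, rng_seed)
        abs_t = np.abs(t)
        hits = (null[:, None] >= abs_t[None, :] - 1e-12).sum(axis=0)
        if n_perm is None:
            p_fwe = hits / len(null)
        else:
            p_fwe = (hits + 1.0) / (len(null) + 1.0)
        used_perm = len(null)
    else:
        raise ValueError(f"unknown FWE method {method!r}")

    p_fwe = np.maximum(p_fwe, p_raw)
    sig = p_fwe < alpha
    return GroupStatsResult(
        tract=tract, hemisphere=hemisphere, metric=metric, t=t,
        p_raw=p_raw, p_fwe=np.minimum(p_fwe, 1.0), significant=sig,
        alpha=alpha, n_a=a.shape[0], n_b=b.shape[0], fwe_method=method,
        n_perm=used_perm, rng_seed=rng_seed, degenerate=degenerate)


def _pivot(profiles: pd.DataFrame, tract, hemisphere, metric, group):
    """(subjects, nodes) matrix of one metric for one tract and group."""
    sub = profiles[(profiles["tract"] == tract)
                   & (profiles["hemisphere"] == hemisphere)
                   & (profiles["group"] == group)]
    wide = sub.pivot(index="subject_id", columns="node", values=metric)
    return wide.sort_index(axis=1).to_numpy()


class NodewiseGroupComparison:
    """Model: node-wise comparison of two groups' tract profiles.

    Parameters
    ----------
    profiles : DataFrame
        Long-format profile table (the shared CSV schema): one row per
        subject x tract x hemisphere x node with fa/md/ad/rd columns.
    group_a, group_b : str
        Labels in the ``group`` column; the t statistic is mean(A) - mean(B).
    alpha : float
        Significance level for the FWE-corrected flags.
    """

    def __init__(self, profiles: pd.DataFrame, group_a: str, group_b: str,
                 alpha: float = 0.05):
        for col in ("subject_id", "group", "tract", "hemisphere", "node"):
            if col not in profiles.columns:
                raise DataError(f"profile table lacks column {col!r}")
        for g in (group_a, group_b):
            if g not in set(profiles["group"]):
                raise DataError(f"group {g!r} absent from profile table")
        self.profiles = profiles
        self.group_a, self.group_b = group_a, group_b
        self.alpha = alpha

    @classmethod
    def from_profiles(cls, profiles_list, group_a: str, group_b: str,
                      alpha: float = 0.05) -> "NodewiseGroupComparison":
        from .profiles import profiles_to_dataframe

        return cls(profiles_to_dataframe(profiles_list), group_a, group_b,
                   alpha=alpha)

    def fit(self, method: str = "permutation_maxT",
            n_perm: int | None = 10_000, rng_seed: int = 0,
            metrics: tuple[str, ...] = METRICS,
            equal_var: bool = True) -> "GroupComparisonResults":
        results = {}
        pairs = self.profiles[["tract", "hemisphere"]].drop_duplicates()
        for _, (tract, hemi) in pairs.iterrows():
            for metric in metrics:
                va = _pivot(self.profiles, tract, hemi, metric, self.group_a)
                vb = _pivot(self.profiles, tract, hemi, metric, self.group_b)
                results[(tract, hemi, metric)] = fwe_correct(
                    va, vb, metric=metric, tract=tract, hemisphere=hemi,
                    method=method, n_perm=n_perm, rng_seed=rng_seed,
                    alpha=self.alpha, equal_var=equal_var)
        return GroupComparisonResults(model=self, results=results)


@dataclass
class GroupComparisonResults:
    """All (tract, hemisphere, metric) node-wise results of one comparison."""

    model: NodewiseGroupComparison
    results: dict[tuple[str, str, str], GroupStatsResult]

    def __getitem__(self, key) -> GroupStatsResult:
        return self.results[key]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.concat([r.to_dataframe() for r in self.results.values()],
                         ignore_index=True)

    def summary(self, min_sig_nodes: int = 10, decimals: int = 2,
                scale: dict[str, float] | None = None) -> pd.DataFrame:
        """Tract-mean table: per (group, tract, metric) the mean +/- SD over
        subjects of the subject's all-node tract mean; a metric is starred
        when FWE-significance holds in more than ``min_sig_nodes`` nodes.

        ``scale`` optionally multiplies a metric before formatting (e.g.
        1e3 to print diffusivities in 10^-3 mm^2/s units).
        """
        return summarize_table(self.model.profiles, self.results,
                               min_sig_nodes=min_sig_nodes,
                               decimals=decimals, scale=scale,
                               groups=(self.model.group_a, self.model.group_b))


def summarize_table(profiles: pd.DataFrame,
                    stats_results: dict[tuple[str, str, str], GroupStatsResult],
                    min_sig_nodes: int = 10, decimals: int = 2,
                    scale: dict[str, float] | None = None,
                    groups: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Group-mean summary with significance stars (long layout).

    One row per (group, tract, hemisphere, metric): the mean and SD across
    subjects of each subject's tract mean (averaged over all nodes), a
    ``cell`` string ``"mean ± sd"`` (starred when the comparison is
    significant in more than ``min_sig_nodes`` nodes), and the significant
    node count.
    """
    scale = scale or {}
    if groups is None:
        groups = tuple(pd.unique(profiles["group"]))
    rows = []
    pairs = profiles[["tract", "hemisphere"]].drop_duplicates()
    for _, (tract, hemi) in pairs.iterrows():
        for metric in METRICS:
            res = stats_results.get((tract, hemi, metric))
            n_sig = res.n_significant if res is not None else 0
            starred = n_sig > min_sig_nodes
            for group in groups:
                sub = profiles[(profiles["tract"] == tract)
                               & (profiles["hemisphere"] == hemi)
                               & (profiles["group"] == group)]
                if sub.empty:
                    continue
                per_subject = sub.groupby("subject_id")[metric].mean()
                k = scale.get(metric, 1.0)
                mu = per_subject.mean() * k
                sd = per_subject.std(ddof=1) * k
                if not np.isfinite(sd):  # single subject
                    sd = 0.0
                cell = f"{mu:.{decimals}f} ± {sd:.{decimals}f}"
                if starred:
                    cell += "*"
                rows.append({"group": group, "tract": tract,
                             "hemisphere": hemi, "metric": metric,
                             "mean": mu, "sd": sd, "n_sig_nodes": n_sig,
                             "significant": starred, "cell": cell})
    return pd.DataFrame(rows)
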