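"""Nonparametric group statistics for histology and cohort comparisons.

Implements the small-sample tests used throughout the quantification
figures of a multimodal epilepsy-tissue study design: Fisher's exact test
on marker-by-cell-class contingency tables, the two-sided Mann-Whitney
U test with exact small-sample enumeration, the Kruskal-Wallis H test with
Dunn's post hoc comparisons, and the Mantel-Cox log-rank test with
Kaplan-Meier curves.

All tests are written from first principles (only distribution tails and
ranking utilities come from :mod:`scipy`) so that each one can be checked
against exhaustive enumeration oracles in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FisherResult",
    "MannWhitneyResult",
    "KruskalDunnResult",
    "LogrankResult",
    "fisher_exact_2x2",
    "mann_whitney",
    "kruskal_dunn",
    "logrank",
    "kaplan_meier",
    "marker_fraction_report",
]

# Total-sample-size bound below which the Mann-Whitney p-value is computed by
# exhaustive permutation of group assignments rather than normal approximation.
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    #: True when a zero cell forced the Haldane-Anscombe 0.5 correction on the OR
    haldane_corrected: bool


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    #: "exact" (full enumeration) or "normal" (tie-corrected approximation)
    method: str


@dataclass(frozen=True)
class KruskalDunnResult:
    h_statistic: float
    p_value: float
    #: one row per group pair: group_a, group_b, z, p_raw, p_adjusted
    pairwise: pd.DataFrame
    adjust: str


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]
    #: Kaplan-Meier step curves, one DataFrame per arm (time, survival, at_risk)
    km_curves: tuple[pd.DataFrame, pd.DataFrame] = field(repr=False)


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    return np.round(t).astype(np.int64)


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 contingency table.

    The two-sided p-value follows the probability-mass rule: with all margins
    fixed, sum the hypergeometric probabilities of every table whose
    probability does not exceed that of the observed table. The odds ratio is
    the sample OR ``ad/bc``; if any cell is zero the Haldane-Anscombe
    correction (add 0.5 to each cell) is applied and flagged.
    """
    t = _as_2x2(table)
    a = t[0, 0]
    r1, r2 = t.sum(axis=1)
    c1, _ = t.sum(axis=0)
    n = t.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("all margins must be positive for Fisher's exact test")

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    # tolerance guards against float jitter when summing "<= observed" mass
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    p = min(p, 1.0)

    corrected = bool(np.any(t == 0))
    tf = t.astype(float) + (0.5 if corrected else 0.0)
    odds = (tf[0, 0] * tf[1, 1]) / (tf[0, 1] * tf[1, 0])
    return FisherResult(odds_ratio=float(odds), p_value=p, haldane_corrected=corrected)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y via midranks (tie-aware)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y, exact_max_n: int = EXACT_MW_MAX_N) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    For ``len(x)+len(y) <= exact_max_n`` the p-value is computed exactly by
    enumerating every assignment of the pooled observations to the two groups
    (a permutation test on U, which remains exact under ties). Larger samples
    use the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    nx, ny = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = nx * ny / 2.0

    if nx + ny <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = np.arange(nx + ny)
        count = 0
        total = 0
        d_obs = abs(u_obs - mu)
        for comb in itertools.combinations(idx, nx):
            sel = np.array(comb)
            mask = np.zeros(nx + ny, dtype=bool)
            mask[sel] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                count += 1
        return MannWhitneyResult(u_statistic=u_obs, p_value=count / total, method="exact")

    pooled = np.concatenate([x, y])
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all values identical
        return MannWhitneyResult(u_statistic=u_obs, p_value=1.0, method="normal")
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = float(2 * sps.norm.sf(z))
    return MannWhitneyResult(u_statistic=u_obs, p_value=min(p, 1.0), method="normal")


def _adjust_pairwise(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "none":
        adj = p.copy()
    elif method == "bonferroni":
        adj = np.minimum(p * m, 1.0)
    elif method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
    elif method == "sidak":
        adj = 1.0 - (1.0 - p) ** m
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return np.maximum(adj, p)  # an adjusted p may never fall below the raw p


def kruskal_dunn(groups, labels=None, adjust: str = "bonferroni") -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis H test with Dunn's all-pairs post hoc z tests.

    Parameters
    ----------
    groups : sequence of 1-D arrays
        One array of observations per group (k >= 2, each non-empty).
    labels : sequence of str, optional
        Group names for the pairwise table; defaults to ``group0..group{k-1}``.
    adjust : {"bonferroni", "holm", "sidak", "none"}
        Family-wise adjustment applied to Dunn's pairwise p-values.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]

    sizes = np.array([a.size for a in arrays])
    n = int(sizes.sum())
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rank_sums = np.array([ranks[bounds[i]: bounds[i + 1]].sum() for i in range(k)])
    rank_means = rank_sums / sizes

    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes) - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_sum / (n**3 - n) if n > 1 else 1.0
    if correction <= 0:  # every observation identical
        h_corr, p = 0.0, 1.0
    else:
        h_corr = h / correction
        p = float(sps.chi2.sf(h_corr, df=k - 1))

    rows = []
    # Dunn's pooled-rank variance with tie correction
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)) if n > 1 else 0.0
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (rank_means[i] - rank_means[j]) / se if se > 0 else 0.0
        p_raw = float(2 * sps.norm.sf(abs(z)))
        rows.append((labels[i], labels[j], float(z), p_raw))
    pair = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    pair["p_adjusted"] = _adjust_pairwise(pair["p_raw"].to_numpy(), adjust)
    return KruskalDunnResult(h_statistic=float(h_corr), p_value=p, pairwise=pair, adjust=adjust)


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with right censoring.

    Returns a step function sampled at each distinct event time, including the
    origin row (time 0, survival 1).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = [(0.0, 1.0, len(t))]
    surv = 1.0
    for ti in np.unique(t[e]):
        at_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & e))
        surv *= 1.0 - d / at_risk
        rows.append((float(ti), surv, at_risk))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk"])


def logrank(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Mantel-Cox log-rank test comparing two survival arms.

    At every distinct event time the observed arm-A deaths are compared with
    the expectation under the pooled hazard; the chi-square statistic is
    ``(O - E)^2 / V`` with the hypergeometric variance summed over event times
    (1 degree of freedom).
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both arms must be non-empty")

    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size, bool), np.ones(tb.size, bool)])

    o_a = e_a = var = 0.0
    d_total = 0.0
    for ti in np.unique(all_t[all_e]):
        at_risk = all_t >= ti
        n_i = float(at_risk.sum())
        n_ai = float((at_risk & ~group).sum())
        died = (all_t == ti) & all_e
        d_i = float(died.sum())
        d_ai = float((died & ~group).sum())
        o_a += d_ai
        e_a += d_i * n_ai / n_i
        if n_i > 1:
            var += d_i * (n_ai / n_i) * (1 - n_ai / n_i) * (n_i - d_i) / (n_i - 1)
        d_total += d_i

    if var <= 0:  # no informative event times (e.g. censoring-only arms)
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o_a - e_a) ** 2 / var
        p = float(sps.chi2.sf(chi2, df=1))
    return LogrankResult(
        chi_square=float(chi2),
        p_value=p,
        observed=(o_a, d_total - o_a),
        expected=(e_a, d_total - e_a),
        km_curves=(kaplan_meier(ta, ea), kaplan_meier(tb, eb)),
    )


def marker_fraction_report(cells: pd.DataFrame, *, sample_col: str = "sample",
                           marker_col: str = "marker_pos",
                           denom_col: str = "neun_pos") -> pd.DataFrame:
    """Per-sample marker-positive percentages among reference-positive cells.

    Each row of ``cells`` is one cell with boolean marker and reference
    (e.g. NeuN) status. Per sample, percent = marker+ref+ / ref+ x 100;
    samples with no reference-positive cells are flagged and excluded from
    the mean +/- SEM summary row (sample id "__summary__").
    """
    for col in (sample_col, marker_col, denom_col):
        if col not in cells.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    for sid, sub in cells.groupby(sample_col, sort=True):
        denom = int(sub[denom_col].astype(bool).sum())
        num = int((sub[marker_col].astype(bool) & sub[denom_col].astype(bool)).sum())
        pct = 100.0 * num / denom if denom > 0 else np.nan
        rows.append((sid, num, denom, pct, denom == 0))
    rep = pd.DataFrame(rows, columns=["sample", "n_marker_pos", "n_denom", "percent", "excluded"])
    valid = rep.loc[~rep["excluded"], "percent"]
    mean = float(valid.mean()) if len(valid) else np.nan
    sem = float(valid.std(ddof=1) / np.sqrt(len(valid))) if len(valid) > 1 else np.nan
    summary = pd.DataFrame(
        [("__summary__", np.nan, np.nan, mean, False)], columns=rep.columns
    )
    out = pd.concat([rep, summary], ignore_index=True)
    out.attrs["mean"] = mean
    out.attrs["sem"] = sem
    out.attrs["n_samples"] = int((~rep["excluded"]).sum())
    return out
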