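"""Patch-seq expression analysis.

QC gating on wet-lab covariates (cDNA yield strictly above 1 ng, main cDNA
peak within 1000-5000 bp) plus expression-level filters; counts-per-10k
log-normalization with spike-ins excluded from the size factor; PCA+k-means
clustering (k = 4 by default, mirroring the four-cluster cortical-neuron
structure, with an optional graph-community path); one-vs-rest Wilcoxon
rank-sum marker detection under the rule "BH-adjusted p < 0.05 and fold
change > 1.5"; panel-based cluster annotation; and a weighted
Kolmogorov-Smirnov permutation enrichment score for senescence/SASP gene
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import EXACT_MW_MAX_N, mann_whitney

__all__ = [
    "QCThresholds",
    "qc_filter",
    "normalize_log",
    "cluster_cells",
    "find_markers",
    "annotate_clusters",
    "enrichment_score",
    "composition_report",
    "SENESCENCE_PANEL",
    "SENESCENCE_NEGATIVE",
    "SASP_PANEL",
    "INTERNEURON_PANEL",
    "PYRAMIDAL_PANEL",
]

# Reference gene panels used for cluster annotation and enrichment fixtures.
INTERNEURON_PANEL = ("GAD1", "GAD2", "ERBB4", "DLX1", "LHX6")
PYRAMIDAL_PANEL = ("SATB2", "CUX2", "SLC17A6", "SLC17A7")
SENESCENCE_PANEL = ("CDKN1A", "TP53", "NFKBIA", "GLB1", "PTGS2", "H2AX")
#: senescence genes whose *loss* marks the phenotype (excluded from the up-panel)
SENESCENCE_NEGATIVE = ("LMNB1",)
SASP_PANEL = ("IL1A", "IL1B", "CCL4", "CCL2", "CXCL8", "CXCL12", "MMP2",
              "CTSB", "ICAM1", "TNFRSF1B", "TNFRSF12A")

MARKER_PADJ_MAX = 0.05
MARKER_FC_MIN = 1.5


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC gates; set a field to None to disable that gate."""

    min_yield_ng: float | None = 1.0          # strict: yield must exceed this
    peak_range_bp: tuple | None = (1000.0, 5000.0)  # inclusive window
    min_genes: int | None = 200
    max_ercc_fraction: float | None = 0.5


def qc_filter(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()):
    """Drop cells failing the QC gates; returns (kept AnnData, report).

    The report DataFrame lists, per rule, how many cells it removed (cells
    can fail several rules); ``report.attrs`` carries totals including the
    overall failure fraction. Raises if no cell survives.
    """
    n = adata.n_obs
    fail = pd.DataFrame(index=adata.obs_names)
    th = thresholds
    if th.min_yield_ng is not None:
        fail["yield"] = ~(adata.obs["cdna_yield_ng"] > th.min_yield_ng)
    if th.peak_range_bp is not None:
        lo, hi = th.peak_range_bp
        fail["peak"] = ~adata.obs["cdna_peak_bp"].between(lo, hi)
    x = np.asarray(adata.X)
    is_ercc = adata.var["is_ercc"].to_numpy() if "is_ercc" in adata.var else np.zeros(adata.n_vars, bool)
    if th.min_genes is not None:
        fail["min_genes"] = (x[:, ~is_ercc] > 0).sum(axis=1) < th.min_genes
    if th.max_ercc_fraction is not None and is_ercc.any():
        total = x.sum(axis=1)
        frac = np.divide(x[:, is_ercc].sum(axis=1), total,
                         out=np.zeros(n), where=total > 0)
        fail["ercc_fraction"] = frac > th.max_ercc_fraction

    any_fail = fail.any(axis=1) if len(fail.columns) else pd.Series(False, index=fail.index)
    kept = adata[~any_fail.to_numpy()].copy()
    report = pd.DataFrame({
        "rule": fail.columns,
        "n_failed": [int(fail[c].sum()) for c in fail.columns],
    })
    report.attrs.update({
        "n_input": int(n),
        "n_failed": int(any_fail.sum()),
        "n_kept": int(kept.n_obs),
        "failure_percent": 100.0 * float(any_fail.sum()) / n if n else np.nan,
        "failed_cells": list(fail.index[any_fail]),
    })
    if kept.n_obs == 0:
        raise ValueError(f"QC removed every cell: {report.to_dict('records')}")
    return kept, report


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Counts-per-10k scaling then log1p, spike-ins excluded from the size factor.

    The raw counts are preserved in ``layers["counts"]``. Cells with zero
    biological counts normalize to all-zero rows. Not idempotent by design:
    the input must be raw counts.
    """
    out = adata.copy()
    x = np.asarray(out.X, dtype=float)
    is_ercc = out.var["is_ercc"].to_numpy() if "is_ercc" in out.var else np.zeros(out.n_vars, bool)
    bio_sum = x[:, ~is_ercc].sum(axis=1)
    factor = np.divide(target_sum, bio_sum, out=np.zeros_like(bio_sum),
                       where=bio_sum > 0)
    out.layers["counts"] = x.copy()
    out.X = np.log1p(x * factor[:, None])
    return out


def _normalized_matrix(data) -> tuple[np.ndarray, np.ndarray]:
    """(cells x genes float matrix, biological-gene mask) from AnnData or array."""
    if isinstance(data, ad.AnnData):
        x = np.asarray(data.X, dtype=float)
        is_ercc = (data.var["is_ercc"].to_numpy() if "is_ercc" in data.var
                   else np.zeros(data.n_vars, bool))
        return x, ~is_ercc
    x = np.asarray(data, dtype=float)
    return x, np.ones(x.shape[1], bool)


def _highly_variable(x: np.ndarray, n_top: int, n_bins: int = 20) -> np.ndarray:
    """Indices of the top genes by mean-binned normalized dispersion.

    Dispersion (variance/mean of the normalized values) is z-scored within
    bins of comparable mean expression, so selection favours genes whose
    variability exceeds the technical expectation at their depth rather than
    genes that are merely highly expressed.
    """
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    disp = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    pos = mean > 0
    if pos.sum() <= n_top:
        return np.argsort(disp)[::-1][:n_top]
    edges = np.quantile(mean[pos], np.linspace(0, 1, n_bins + 1)[1:-1])
    bins = np.digitize(mean, edges)
    norm_disp = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        sd = disp[m].std()
        norm_disp[m] = (disp[m] - disp[m].mean()) / (sd if sd > 0 else 1.0)
    norm_disp[~pos] = -np.inf
    return np.argsort(norm_disp)[::-1][:n_top]


def cluster_cells(data, n_clusters: int = 4, seed: int = 0, n_pcs: int = 20,
                  n_hvg: int = 500, method: str = "kmeans",
                  resolution: float = 1.0) -> np.ndarray:
    """Cluster cells on the normalized matrix; deterministic under a fixed seed.

    Default path: top-variance genes -> PCA (``n_pcs`` components) -> k-means.
    ``method="leiden"`` substitutes a shared-nearest-neighbour Leiden
    community search at the given resolution (``n_clusters`` ignored).
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x, bio = _normalized_matrix(data)
    x = x[:, bio]
    n_cells = x.shape[0]
    if method == "kmeans" and n_clusters > n_cells:
        raise ValueError("more clusters requested than cells")

    hv = _highly_variable(x, min(n_hvg, x.shape[1]))
    xh = x[:, hv]
    # centred but not variance-scaled: scaling would weight every retained
    # gene equally and dilute the informative minority among noise genes
    xh = xh - xh.mean(axis=0)
    n_comp = min(n_pcs, n_cells - 1, xh.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(xh)

    if method == "kmeans":
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        return km.fit_predict(pcs)
    if method == "leiden":
        import igraph
        import leidenalg
        from sklearn.neighbors import kneighbors_graph

        k = min(15, n_cells - 1)
        adj = kneighbors_graph(pcs, n_neighbors=k, mode="connectivity")
        sources, targets = adj.nonzero()
        g = igraph.Graph(n=n_cells, edges=list(zip(sources.tolist(), targets.tolist())))
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution, seed=seed)
        return np.asarray(part.membership)
    raise ValueError(f"unknown clustering method {method!r}")


def _ranksum_z_vectorized(x: np.ndarray, in_group: np.ndarray):
    """Tie-corrected rank-sum z and U for every gene column, one cluster vs rest."""
    n, n1 = x.shape[0], int(in_group.sum())
    n2 = n - n1
    ranks = sps.rankdata(x, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # per-gene tie correction
    tie_term = np.empty(x.shape[1])
    for g in range(x.shape[1]):
        _, cnt = np.unique(x[:, g], return_counts=True)
        tie_term[g] = np.sum(cnt.astype(float) ** 3 - cnt) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = np.where(sigma2 > 0, np.maximum(z, 0.0), 0.0)
    p = np.where(sigma2 > 0, 2 * sps.norm.sf(z), 1.0)
    z_signed = np.where(sigma2 > 0, np.sign(u - mu) * z, 0.0)
    return u, z_signed, np.minimum(p, 1.0)


def find_markers(data, labels, pseudocount: float = 1e-9) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table per cluster.

    For every gene and cluster: tie-corrected rank-sum p (exact enumeration
    when the cohort is small enough, normal approximation otherwise),
    fold-change of expm1-scale means with a pseudocount, BH adjustment across
    genes within each cluster, and the marker flag
    ``padj < 0.05 and fc > 1.5``. Constant genes get p = 1 by convention.
    """
    if isinstance(data, ad.AnnData):
        x, bio = _normalized_matrix(data)
        gene_names = np.asarray(data.var_names)[bio]
        x = x[:, bio]
    else:
        x = np.asarray(data, dtype=float)
        gene_names = np.array([f"g{i}" for i in range(x.shape[1])])
    labels = np.asarray(labels)
    if x.shape[0] != labels.size:
        raise ValueError("labels must align with cells")

    frames = []
    expm = np.expm1(x)
    for cl in pd.unique(labels):
        in_g = labels == cl
        if in_g.sum() < 3 or (~in_g).sum() < 3:
            raise ValueError(f"cluster {cl!r} needs >= 3 cells on each side")
        if x.shape[0] <= EXACT_MW_MAX_N:
            stats_p = [mann_whitney(x[in_g, g], x[~in_g, g]) for g in range(x.shape[1])]
            u = np.array([s.u_statistic for s in stats_p])
            p = np.array([s.p_value for s in stats_p])
            mu = in_g.sum() * (~in_g).sum() / 2.0
            z = np.sign(u - mu)
        else:
            u, z, p = _ranksum_z_vectorized(x, in_g)
        mean_in = expm[in_g].mean(axis=0)
        mean_out = expm[~in_g].mean(axis=0)
        fc = (mean_in + pseudocount) / (mean_out + pseudocount)
        padj = multipletests(p, method="fdr_bh")[1]
        frames.append(pd.DataFrame({
            "gene": gene_names,
            "cluster": cl,
            "u_statistic": u,
            "z": z,
            "log2_fc": np.log2(fc),
            "fold_change": fc,
            "p_value": p,
            "p_adjusted": padj,
            "is_marker": (padj < MARKER_PADJ_MAX) & (fc > MARKER_FC_MIN),
        }))
    return pd.concat(frames, ignore_index=True)


def annotate_clusters(markers: pd.DataFrame, panels: dict | None = None) -> dict:
    """Name each cluster by the majority reference panel among its enriched genes.

    Each panel is scored per cluster as (+1) for every panel gene
    significantly enriched there (positive rank-sum z, adjusted p < 0.05) and
    (-1) for every panel gene significantly depleted: an identity program
    shared by several clusters may not clear the one-vs-rest fold-change bar
    of the strict marker rule, but depletion of the *other* class's panel is
    equally diagnostic. The unique highest-scoring panel names the cluster;
    ties (including the all-zero no-overlap case) give "ambiguous". When the
    table lacks z/p columns the plain ``is_marker`` overlap count is used.
    """
    if panels is None:
        panels = {"INT": INTERNEURON_PANEL, "PY": PYRAMIDAL_PANEL}
    out = {}
    for cl, sub in markers.groupby("cluster", sort=False):
        if "z" in sub.columns:
            sig = sub["p_adjusted"] < MARKER_PADJ_MAX
            up = set(sub.loc[sig & (sub["z"] > 0), "gene"])
            down = set(sub.loc[sig & (sub["z"] < 0), "gene"])
            scores = {name: len(up & set(g)) - len(down & set(g))
                      for name, g in panels.items()}
        else:
            mset = set(sub.loc[sub["is_marker"], "gene"])
            scores = {name: len(mset & set(g)) for name, g in panels.items()}
        best = max(scores.values())
        winners = [k for k, v in scores.items() if v == best]
        out[cl] = winners[0] if len(winners) == 1 else "ambiguous"
    return out


def enrichment_score(ranking: pd.Series, gene_set, n_perm: int = 1000,
                     seed: int = 0, weight: float = 1.0) -> dict:
    """Weighted Kolmogorov-Smirnov running-sum enrichment with a permutation null.

    ``ranking`` maps every tested gene to its signed ranking statistic (e.g.
    the rank-sum z from :func:`find_markers`). The enrichment score is the
    extremum of the running sum over the |statistic|^weight-weighted hit steps;
    the null is built by drawing random same-size gene sets from the ranking
    (gene-label permutation); NES divides by the mean |null| of the same sign.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    ranking = ranking.sort_values(ascending=False)
    genes = ranking.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")

    stat = np.abs(ranking.to_numpy()) ** weight

    def es(mask: np.ndarray) -> float:
        hits = stat * mask
        denom = hits.sum()
        if denom == 0:
            return 0.0
        step = hits / denom - (~mask) / max(len(mask) - mask.sum(), 1)
        run = np.cumsum(step)
        lo, hi = run.min(), run.max()
        return float(hi if abs(hi) >= abs(lo) else lo)

    es_obs = es(in_set)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.zeros(genes.size, dtype=bool)
        perm[rng.choice(genes.size, size=n_hit, replace=False)] = True
        null[i] = es(perm)

    same_sign = null[np.sign(null) == np.sign(es_obs)] if es_obs != 0 else null
    denom = np.abs(same_sign).mean() if same_sign.size else np.nan
    nes = es_obs / denom if denom and np.isfinite(denom) else np.nan
    n_extreme = int(np.sum(np.abs(same_sign) >= abs(es_obs)))
    p = (1.0 + n_extreme) / (1.0 + max(same_sign.size, 1))
    return {"es": es_obs, "nes": float(nes), "p_value": float(p),
            "n_hits": n_hit, "n_perm": n_perm}


def composition_report(labels, annotations: dict | None = None,
                       pyramidal_prefix: str = "PY") -> pd.DataFrame:
    """Cluster size bookkeeping: counts, percent of all cells, percent of pyramidal.

    ``annotations`` maps cluster label -> class name (INT / PY...); when
    omitted, clusters whose label starts with ``pyramidal_prefix`` count as
    pyramidal.
    """
    labels = pd.Series(labels)
    n_total = len(labels)
    counts = labels.value_counts()
    if annotations is None:
        is_py = {cl: str(cl).startswith(pyramidal_prefix) for cl in counts.index}
    else:
        is_py = {cl: str(annotations.get(cl, "")).startswith(pyramidal_prefix)
                 for cl in counts.index}
    n_py = int(sum(c for cl, c in counts.items() if is_py[cl]))
    rows = []
    for cl, c in counts.items():
        rows.append({
            "cluster": cl,
            "n_cells": int(c),
            "percent_of_total": 100.0 * c / n_total,
            "percent_of_pyramidal": 100.0 * c / n_py if is_py[cl] and n_py else np.nan,
        })
    rep = pd.DataFrame(rows)
    rep.attrs["n_total"] = n_total
    rep.attrs["n_pyramidal"] = n_py
    return rep
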