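"""Expression pipeline: QC gates, normalization, clustering, markers, enrichment."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from senpatch import scrna
from senpatch.sim import gen_expression, gen_qc_covariates
from senpatch.specs import ExprSimSpec


def _adata_from_cov(cov: pd.DataFrame, n_genes: int = 5) -> ad.AnnData:
    a = ad.AnnData(X=np.ones((len(cov), n_genes)), obs=cov.copy())
    a.var["is_ercc"] = False
    return a


# ---------------------------------------------------------------------- QC


def test_qc_reports_the_constructed_failure_fraction():
    cov = gen_qc_covariates(324, 127, seed=9)
    kept, report = scrna.qc_filter(
        _adata_from_cov(cov),
        scrna.QCThresholds(min_genes=None, max_ercc_fraction=None))
    assert report.attrs["n_kept"] == 197
    assert report.attrs["failure_percent"] == pytest.approx(100 * 127 / 324)


def test_qc_disabled_gates_keep_everything(expr_cohort):
    adata, _, _ = expr_cohort
    kept, report = scrna.qc_filter(
        adata, scrna.QCThresholds(None, None, None, None))
    assert kept.n_obs == adata.n_obs
    assert report.attrs["n_failed"] == 0


def test_qc_yield_boundary_is_strict():
    cov = pd.DataFrame({"cdna_yield_ng": [1.0, 1.0001],
                        "cdna_peak_bp": [2000.0, 2000.0]})
    kept, report = scrna.qc_filter(
        _adata_from_cov(cov), scrna.QCThresholds(min_genes=None,
                                                 max_ercc_fraction=None))
    assert kept.n_obs == 1  # exactly 1 ng fails the strict > 1 ng gate
    assert report.attrs["failed_cells"] == ["0"]


def test_qc_raises_when_all_cells_fail():
    cov = pd.DataFrame({"cdna_yield_ng": [0.1, 0.2],
                        "cdna_peak_bp": [2000.0, 2000.0]})
    with pytest.raises(ValueError):
        scrna.qc_filter(_adata_from_cov(cov),
                        scrna.QCThresholds(min_genes=None, max_ercc_fraction=None))


# ------------------------------------------------------------ normalization


def test_normalize_zero_cell_stays_zero(expr_cohort):
    adata, _, _ = expr_cohort
    a = adata[:3].copy()
    a.X = np.asarray(a.X).copy()
    a.X[0, :] = 0
    norm = scrna.normalize_log(a)
    assert np.all(np.asarray(norm.X)[0] == 0)


def test_normalize_is_scale_invariant_per_cell(expr_cohort):
    adata, _, _ = expr_cohort
    a = adata[:5].copy()
    doubled = a.copy()
    doubled.X = np.asarray(doubled.X) * 2
    n1 = scrna.normalize_log(a)
    n2 = scrna.normalize_log(doubled)
    np.testing.assert_allclose(np.asarray(n1.X), np.asarray(n2.X), atol=1e-12)


def test_normalize_excludes_ercc_from_size_factor():
    x = np.array([[100, 100, 800]], dtype=float)  # third column is a spike-in
    a = ad.AnnData(X=x)
    a.var["is_ercc"] = [False, False, True]
    norm = scrna.normalize_log(a)
    # size factor uses the 200 biological counts only
    assert np.asarray(norm.X)[0, 0] == pytest.approx(np.log1p(100 / 200 * 1e4))


# --------------------------------------------------------------- clustering


def test_clustering_two_separated_blobs_is_exact():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.3, size=(40, 30))
    b = rng.normal(4, 0.3, size=(40, 30))
    x = np.vstack([a, b])
    labels = scrna.cluster_cells(x, n_clusters=2, seed=0, n_hvg=30, n_pcs=5)
    truth = np.array([0] * 40 + [1] * 40)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_clustering_seeded_determinism(expr_pipeline):
    norm, labels, _, _, _ = expr_pipeline
    again = scrna.cluster_cells(norm, n_clusters=4, seed=0)
    assert np.array_equal(labels, again)


def test_clustering_cell_order_permutation_only_permutes_labels(expr_cohort):
    adata, _, _ = expr_cohort
    norm = scrna.normalize_log(adata)
    labels = scrna.cluster_cells(norm, n_clusters=4, seed=0)
    rng = np.random.default_rng(1)
    perm = rng.permutation(adata.n_obs)
    labels_p = scrna.cluster_cells(norm[perm].copy(), n_clusters=4, seed=0)
    assert adjusted_rand_score(labels[perm], labels_p) == 1.0


def test_clustering_rejects_k_above_n():
    with pytest.raises(ValueError):
        scrna.cluster_cells(np.zeros((3, 5)), n_clusters=10)


def test_leiden_path_recovers_the_same_partition(expr_cohort):
    adata, truth, _ = expr_cohort
    norm = scrna.normalize_log(adata)
    labels = scrna.cluster_cells(norm, seed=0, method="leiden", resolution=0.5)
    assert adjusted_rand_score(truth["labels"].to_numpy(), labels) > 0.8


def test_cluster_recovery_and_marker_recall_across_replicates():
    """At study-like proportions (13.7% PY2) the pipeline recovers clusters
    (ARI >= 0.9) and every planted 4-fold-or-stronger PY2 marker."""
    n_rep = 20
    for seed in range(n_rep):
        spec = ExprSimSpec(seed=100 + seed)
        adata, truth = gen_expression(spec)
        norm = scrna.normalize_log(adata)
        labels = scrna.cluster_cells(norm, n_clusters=4, seed=0)
        ari = adjusted_rand_score(truth["labels"].to_numpy(), labels)
        assert ari >= 0.9, f"seed {seed}: ARI {ari}"
        markers = scrna.find_markers(norm, labels)
        py2_cluster = pd.Series(labels, index=norm.obs_names)[
            truth["labels"] == "PY2"].mode()[0]
        planted = [g for g, lfc in spec.markers["PY2"].items() if lfc >= 2.0]
        calls = markers[(markers.cluster == py2_cluster)
                        & markers.gene.isin(planted)]
        assert calls["is_marker"].all(), f"seed {seed} missed planted markers"


# ------------------------------------------------------------------ markers


def test_marker_rule_and_bh_monotonicity(expr_pipeline):
    _, _, markers, _, _ = expr_pipeline
    assert (markers["p_adjusted"] >= markers["p_value"] - 1e-15).all()
    rule = (markers["p_adjusted"] < 0.05) & (markers["fold_change"] > 1.5)
    assert (markers["is_marker"] == rule).all()


def test_find_markers_small_instance_matches_exact_enumeration():
    # 6 cells: the rank-sum p must equal enumeration over all C(6,3) splits
    x = np.array([[0.1], [0.9], [0.4], [2.0], [2.5], [1.8]])
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    mk = scrna.find_markers(x, labels)
    vals = x[:, 0]

    def u_of(idx):
        ranks = pd.Series(vals).rank().to_numpy()
        return ranks[list(idx)].sum() - 6.0

    d_obs = abs(u_of([0, 1, 2]) - 4.5)
    hits = sum(abs(u_of(c) - 4.5) >= d_obs - 1e-12
               for c in itertools.combinations(range(6), 3))
    p_enum = hits / 20
    assert mk.loc[mk.cluster == "a", "p_value"].iloc[0] == pytest.approx(p_enum)


def test_constant_gene_gets_p_one(expr_pipeline):
    x = np.column_stack([np.ones(30), np.r_[np.zeros(15), np.ones(15)]])
    labels = np.array(["a"] * 15 + ["b"] * 15)
    mk = scrna.find_markers(x, labels)
    assert (mk.loc[mk.gene == "g0", "p_value"] == 1.0).all()


def test_marker_table_reproducible(expr_pipeline):
    norm, labels, markers, _, _ = expr_pipeline
    again = scrna.find_markers(norm, labels)
    pd.testing.assert_frame_equal(markers, again)


def test_null_marker_rate_is_nominal():
    """With no planted structure, BH keeps false marker calls near zero."""
    n_marker_calls = []
    for seed in range(5):
        spec = ExprSimSpec(seed=400 + seed, cluster_cells={"A": 60, "B": 60},
                           n_genes=400, n_ercc=0, markers={}, class_markers={},
                           donor_sd=0.0)
        adata, _ = gen_expression(spec)
        norm = scrna.normalize_log(adata)
        labels = np.array(["A"] * 60 + ["B"] * 60)  # true (null) grouping
        mk = scrna.find_markers(norm, labels)
        n_marker_calls.append(int(mk["is_marker"].sum()))
    assert np.mean(n_marker_calls) <= 2.0


def test_bh_matches_brute_force_step_up():
    rng = np.random.default_rng(7)
    for _ in range(50):
        p = rng.random(rng.integers(2, 10))
        ref = multipletests(p, method="fdr_bh")[1]
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            brute[i] = running
        np.testing.assert_allclose(ref, brute, atol=1e-12)


# --------------------------------------------------------------- annotation


def test_annotation_gad_markers_name_interneurons(expr_pipeline):
    norm, labels, markers, truth, _ = expr_pipeline
    ann = scrna.annotate_clusters(markers)
    int_cluster = pd.Series(labels, index=norm.obs_names)[
        truth["labels"] == "INT"].mode()[0]
    assert ann[int_cluster] == "INT"
    py_clusters = [c for c in ann if c != int_cluster]
    assert all(ann[c] in ("PY", "ambiguous") for c in py_clusters)
    assert sum(ann[c] == "PY" for c in py_clusters) >= 2


def test_annotation_without_panel_overlap_is_ambiguous():
    mk = pd.DataFrame({"gene": ["FOO", "BAR"], "cluster": ["c0", "c0"],
                       "is_marker": [True, True]})
    assert scrna.annotate_clusters(mk) == {"c0": "ambiguous"}


def test_annotation_ignores_panel_order():
    mk = pd.DataFrame({"gene": ["GAD1", "GAD2"], "cluster": ["c0", "c0"],
                       "is_marker": [True, True]})
    p1 = {"INT": ("GAD1", "GAD2"), "PY": ("SATB2",)}
    p2 = {"PY": ("SATB2",), "INT": ("GAD2", "GAD1")}
    assert (scrna.annotate_clusters(mk, p1) == scrna.annotate_clusters(mk, p2)
            == {"c0": "INT"})


# --------------------------------------------------------------- enrichment


def test_enrichment_top_of_ranking_maximal():
    ranking = pd.Series(np.linspace(5, -5, 100),
                        index=[f"g{i}" for i in range(100)])
    res = scrna.enrichment_score(ranking, [f"g{i}" for i in range(5)],
                                 n_perm=200, seed=0)
    assert res["es"] > 0.9
    assert res["p_value"] < 0.05


def test_enrichment_random_set_is_null():
    rng = np.random.default_rng(0)
    ranking = pd.Series(rng.normal(size=200),
                        index=[f"g{i}" for i in range(200)])
    ps = []
    for seed in range(30):
        gs = rng.choice(ranking.index, size=15, replace=False)
        ps.append(scrna.enrichment_score(ranking, gs, n_perm=200,
                                         seed=seed)["p_value"])
    assert np.mean(np.array(ps) < 0.05) < 0.2
    assert np.mean(ps) > 0.3


def test_enrichment_of_planted_senescence_panel(expr_pipeline):
    norm, labels, markers, truth, _ = expr_pipeline
    py2_cluster = pd.Series(labels, index=norm.obs_names)[
        truth["labels"] == "PY2"].mode()[0]
    ranking = markers[markers.cluster == py2_cluster].set_index("gene")["z"]
    panel = set(scrna.SENESCENCE_PANEL) | set(scrna.SASP_PANEL)
    res = scrna.enrichment_score(ranking, panel, n_perm=500, seed=0)
    assert res["nes"] > 0
    assert res["p_value"] < 0.05


def test_enrichment_empty_intersection_is_an_error():
    ranking = pd.Series([1.0, -1.0], index=["a", "b"])
    with pytest.raises(ValueError):
        scrna.enrichment_score(ranking, ["zzz"], n_perm=100)


# -------------------------------------------------------------- composition


def test_composition_percentages_match_cohort_arithmetic():
    labels = ["INT"] * 53 + ["PY1"] * 90 + ["PY2"] * 27 + ["PY3"] * 27
    rep = scrna.composition_report(labels).set_index("cluster")
    assert rep.loc["PY2", "percent_of_total"] == pytest.approx(100 * 27 / 197)
    assert rep.loc["PY2", "percent_of_pyramidal"] == pytest.approx(100 * 27 / 144)
    assert np.isnan(rep.loc["INT", "percent_of_pyramidal"])
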