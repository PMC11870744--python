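"""Patch-seq count-matrix simulator.

Generates an integer gene-by-cell count matrix with four planted neuron
clusters (one interneuron, three pyramidal, one of which is a minority
senescence-marker-high cluster), ERCC spike-in rows independent of cluster
identity, per-donor random effects, log-normal library sizes, Poisson
counts and Bernoulli dropout. The planted cluster labels and marker
fold-changes are returned as ground truth.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

from ..specs import ExprSimSpec

__all__ = ["gen_expression", "gen_qc_covariates", "cluster_counts_from_proportions"]

_REGIONS = ("FL", "TL", "PL", "IL")
_PATHOLOGIES = ("FCD", "TLE", "PT")
_LAYERS = ("L2/3", "L4", "L5", "L6")


def cluster_counts_from_proportions(n_total: int, proportions: dict) -> dict:
    """Integer cluster sizes from proportions by largest-remainder rounding."""
    if n_total < len(proportions):
        raise ValueError("fewer cells than clusters")
    p = np.array(list(proportions.values()), dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("cluster proportions must sum to 1")
    raw = p * n_total
    base = np.floor(raw).astype(int)
    rem = n_total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return dict(zip(proportions.keys(), (int(x) for x in base)))


def _gene_names(spec: ExprSimSpec) -> list[str]:
    named: list[str] = []
    for d in spec.markers.values():
        named += [g for g in d if g not in named]
    for d in spec.class_markers.values():
        named += [g for g in d if g not in named]
    fillers = [f"GENE{i:04d}" for i in range(spec.n_genes - len(named))]
    return named + fillers


def gen_expression(spec: ExprSimSpec) -> tuple[ad.AnnData, dict]:
    """Simulate the patch-seq cohort described by ``spec``.

    Returns an :class:`anndata.AnnData` (cells x genes, integer counts, ERCC
    rows flagged in ``var["is_ercc"]``, covariates in ``obs``) and a truth
    record with the planted labels and marker tables.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec)
    n_bio = len(genes)
    n_cells = spec.n_cells

    labels = np.concatenate([
        np.full(n, name) for name, n in spec.cluster_cells.items()
    ])

    # per-gene baseline relative expression; planted markers sit at the
    # population median so their fold-changes are measurable at patch-seq depth
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_bio)
    marked = {g for d in spec.markers.values() for g in d}
    marked |= {g for d in spec.class_markers.values() for g in d}
    for gi, g in enumerate(genes):
        if g in marked:
            base[gi] = 1.0

    gene_index = {g: i for i, g in enumerate(genes)}
    lfc = np.zeros((n_bio, len(spec.cluster_cells)))
    cluster_names = list(spec.cluster_cells.keys())
    for ci, cname in enumerate(cluster_names):
        for g, v in spec.markers.get(cname, {}).items():
            lfc[gene_index[g], ci] += v
    for members, d in spec.class_markers.items():
        for cname in members:
            if cname in cluster_names:
                ci = cluster_names.index(cname)
                for g, v in d.items():
                    lfc[gene_index[g], ci] += v

    donor_ids = np.array([f"D{i:02d}" for i in range(spec.n_donors)])
    donors = rng.choice(donor_ids, size=n_cells)
    donor_effect = rng.lognormal(mean=0.0, sigma=spec.donor_sd,
                                 size=(spec.n_donors, n_bio))
    donor_row = {d: i for i, d in enumerate(donor_ids)}

    cluster_of = np.array([cluster_names.index(c) for c in labels])
    expected = base[None, :] * (2.0 ** lfc.T)[cluster_of, :]
    expected *= donor_effect[[donor_row[d] for d in donors], :]
    props = expected / expected.sum(axis=1, keepdims=True)

    sigma = spec.library_size_sigma
    lib = rng.lognormal(np.log(spec.library_size_mean) - sigma**2 / 2.0, sigma,
                        size=n_cells)
    lam = props * lib[:, None]
    counts = rng.poisson(lam).astype(np.int64)
    if spec.dropout_rate >= 1.0:
        counts[:] = 0
    elif spec.dropout_rate > 0:
        # expression-dependent Bernoulli dropout: the keep probability rises
        # from (1 - dropout_rate) at zero expression toward 1 for well-covered
        # genes, mirroring how full-length scRNA-seq loses lowly expressed
        # transcripts; dropout_rate = 1 zeroes everything regardless
        keep_p = (1.0 - spec.dropout_rate) ** np.exp(-lam / spec.dropout_decay)
        counts = counts * (rng.random(counts.shape) < keep_p)

    # ERCC spike-ins: fixed expected count per spike, independent of the cell
    ercc_names = [f"ERCC-{i + 1:05d}" for i in range(spec.n_ercc)]
    ercc_conc = rng.lognormal(mean=2.0, sigma=1.0, size=spec.n_ercc)
    ercc = rng.poisson(np.broadcast_to(ercc_conc, (n_cells, spec.n_ercc))).astype(np.int64)

    x = np.concatenate([counts, ercc], axis=1)
    var = pd.DataFrame(index=pd.Index(genes + ercc_names, name="gene"))
    var["is_ercc"] = [False] * n_bio + [True] * spec.n_ercc

    obs = pd.DataFrame(index=pd.Index([f"cell{i:04d}" for i in range(n_cells)],
                                      name="cell"))
    obs["true_cluster"] = labels
    obs["donor"] = donors
    obs["sex"] = rng.choice(["F", "M"], size=n_cells)
    obs["age"] = rng.integers(4, 60, size=n_cells)
    obs["region"] = rng.choice(_REGIONS, size=n_cells)
    obs["layer"] = rng.choice(_LAYERS, size=n_cells)
    obs["pathology"] = rng.choice(_PATHOLOGIES, size=n_cells)
    # QC covariates of cells that passed the wet-lab gates
    obs["cdna_yield_ng"] = rng.uniform(1.2, 5.0, size=n_cells)
    obs["cdna_peak_bp"] = rng.uniform(1500, 4500, size=n_cells)

    adata = ad.AnnData(X=x, obs=obs, var=var)
    truth = {
        "labels": pd.Series(labels, index=obs.index, name="true_cluster"),
        "markers": {c: dict(d) for c, d in spec.markers.items()},
        "class_markers": {tuple(k): dict(v) for k, v in spec.class_markers.items()},
        "baseline": pd.Series(base, index=genes),
        "ercc_expected": pd.Series(ercc_conc, index=ercc_names),
        "seed": spec.seed,
    }
    return adata, truth


def gen_qc_covariates(n_total: int = 324, n_fail: int = 127,
                      seed: int = 0) -> pd.DataFrame:
    """Construct a cohort covariate table with a known number of QC failures.

    Exactly ``n_fail`` cells violate the wet-lab gates (cDNA yield strictly
    greater than 1 ng; main cDNA peak within 1000-5000 bp); failure modes are
    split between low yield, out-of-range peak, and both.
    """
    if not 0 <= n_fail <= n_total:
        raise ValueError("n_fail must lie in [0, n_total]")
    rng = np.random.default_rng(seed)
    yield_ng = rng.uniform(1.2, 5.0, size=n_total)
    peak_bp = rng.uniform(1500, 4500, size=n_total)
    fail_idx = rng.choice(n_total, size=n_fail, replace=False)
    modes = rng.integers(0, 3, size=n_fail)  # 0 yield, 1 peak, 2 both
    for i, m in zip(fail_idx, modes):
        if m in (0, 2):
            yield_ng[i] = rng.uniform(0.05, 1.0)  # includes the ==1 ng boundary
        if m in (1, 2):
            peak_bp[i] = rng.uniform(400, 950) if rng.random() < 0.5 else rng.uniform(5200, 8000)
    df = pd.DataFrame({
        "cdna_yield_ng": yield_ng,
        "cdna_peak_bp": peak_bp,
        "true_fail": np.isin(np.arange(n_total), fail_idx),
    }, index=pd.Index([f"cell{i:04d}" for i in range(n_total)], name="cell"))
    return df
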