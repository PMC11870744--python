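"""Plain-text and standard-format readers/writers.

Sweeps travel as wide TSV (time column + one voltage column per sweep) with
a stimulus sidecar table; count matrices as MatrixMarket MTX plus
genes/metadata TSVs; gene sets as GMT; FISH spots, soma tables and survival
records as tidy TSVs; image stacks as multi-page TIFF via :mod:`tifffile`.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .ephys import SweepSet

__all__ = [
    "write_sweeps", "read_sweeps",
    "write_counts_mtx", "read_counts_mtx",
    "write_gmt", "read_gmt",
    "write_table", "read_table",
    "write_stack", "read_stack",
]


def write_sweeps(sweeps: SweepSet, prefix: str) -> None:
    """Write ``<prefix>.tsv`` (time + sweep columns, mV) and ``<prefix>_stim.tsv``."""
    wide = pd.DataFrame({"time_s": sweeps.time})
    for j in range(sweeps.n_sweeps):
        wide[f"sweep{j:03d}_mV"] = sweeps.voltages[:, j]
    wide.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    stim = pd.DataFrame({
        "sweep": [f"sweep{j:03d}" for j in range(sweeps.n_sweeps)],
        "current_pA": sweeps.currents,
        "step_on_s": sweeps.step_on,
        "step_off_s": sweeps.step_off,
    })
    stim.to_csv(f"{prefix}_stim.tsv", sep="\t", index=False)


def read_sweeps(prefix: str, cell_id: str | None = None) -> SweepSet:
    wide = pd.read_csv(f"{prefix}.tsv", sep="\t")
    stim = pd.read_csv(f"{prefix}_stim.tsv", sep="\t")
    return SweepSet(
        time=wide["time_s"].to_numpy(),
        voltages=wide.drop(columns="time_s").to_numpy(),
        currents=stim["current_pA"].to_numpy(),
        step_on=float(stim["step_on_s"].iloc[0]),
        step_off=float(stim["step_off_s"].iloc[0]),
        cell_id=cell_id or os.path.basename(prefix),
    )


def write_counts_mtx(adata: ad.AnnData, outdir: str) -> None:
    """MTX (genes x cells) + genes.tsv (gene, is_ercc) + metadata.tsv per cell."""
    os.makedirs(outdir, exist_ok=True)
    x = sparse.csr_matrix(np.asarray(adata.X).T)
    spio.mmwrite(os.path.join(outdir, "matrix.mtx"), x)
    genes = pd.DataFrame({"gene": adata.var_names,
                          "is_ercc": adata.var.get("is_ercc", False)})
    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    adata.obs.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t")


def read_counts_mtx(outdir: str) -> ad.AnnData:
    x = spio.mmread(os.path.join(outdir, "matrix.mtx")).tocsr().T
    genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t")
    obs = pd.read_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index_col=0)
    var = pd.DataFrame({"is_ercc": genes["is_ercc"].to_numpy()},
                       index=pd.Index(genes["gene"], name="gene"))
    return ad.AnnData(X=np.asarray(x.todense()), obs=obs, var=var)


def write_gmt(gene_sets: dict, path: str) -> None:
    """``{name: [genes...]}`` to GMT (name, description, genes, tab-separated)."""
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gmt(path: str) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_stack(volume: np.ndarray, path: str) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(volume), photometric="minisblack")


def read_stack(path: str) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
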