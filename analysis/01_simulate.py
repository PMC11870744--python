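#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes raw datasets (sweeps, counts, spot tables, histology counts,
survival records) under scratch/analysis_data/ and a summary of what was
generated to results/01_simulation_summary.json. Ground-truth records are
stored alongside each dataset so later steps can score themselves.
"""

import argparse
import json
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from senpatch import io
from senpatch.sim import (gen_ephys, gen_expression, gen_fish, gen_histo,
                          gen_qc_covariates, gen_survival)
from senpatch.specs import (EphysSimSpec, ExprSimSpec, FishSimSpec,
                            HistoSimSpec, SurvivalSimSpec)

ROOT = os.path.join(os.path.dirname(__file__), "..")
DATA = os.path.join(ROOT, "scratch", "analysis_data")
RESULTS = os.path.join(ROOT, "results")
STEPS = np.arange(-100.0, 301.0, 25.0)

N_EPHYS_PER_CLASS = 10
N_FISH_SLICES = 7
N_FISH_CELLS_PER_SLICE = 1098  # 7 slices of ~1100 neurons ~ the 7,688 total


def main(seed: int) -> None:
    os.makedirs(DATA, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)
    summary = {"seed": seed}

    # current-clamp cohort: interleaved fast-spiking / regular-spiking cells
    sweep_dir = os.path.join(DATA, "sweeps")
    os.makedirs(sweep_dir, exist_ok=True)
    truth_rows = {}
    rng = np.random.default_rng(seed)
    for i in range(2 * N_EPHYS_PER_CLASS):
        ctor = (EphysSimSpec.fast_spiking if i % 2 == 0
                else EphysSimSpec.regular_spiking)
        base = ctor()
        # biological scatter: per-cell parameters vary around the class means
        jitter = {name: getattr(base, name) * float(rng.lognormal(0, 0.10))
                  for name in ("rin_MOhm", "cm_pF", "rheobase_pA", "ahp_mV",
                               "ap_amp_mV", "fi_gain_hz_per_pa")}
        spec = ctor(seed=seed * 1000 + i, **jitter)
        sweeps, truth = gen_ephys(spec, STEPS)
        cell = f"cell{i:03d}"
        io.write_sweeps(sweeps, os.path.join(sweep_dir, cell))
        truth_rows[cell] = {k: v for k, v in truth.items() if k != "spike_times"}
    with open(os.path.join(sweep_dir, "truth.json"), "w") as fh:
        json.dump(truth_rows, fh, indent=1)
    summary["ephys_cells"] = len(truth_rows)

    # 324-cell QC covariates (127 constructed gate failures) and the
    # 197-cell four-cluster expression cohort
    cov = gen_qc_covariates(324, 127, seed=seed)
    io.write_table(cov.reset_index(), os.path.join(DATA, "qc_cohort.tsv"))
    adata, truth = gen_expression(ExprSimSpec(seed=seed))
    io.write_counts_mtx(adata, os.path.join(DATA, "counts"))
    summary["expression"] = {"cells": adata.n_obs, "genes": adata.n_vars,
                             "py2_cells": int((truth["labels"] == "PY2").sum())}

    # EASI-FISH: seven slices at the study's PY2 fraction
    fish_dir = os.path.join(DATA, "fish")
    os.makedirs(fish_dir, exist_ok=True)
    n_total = 0
    for s in range(N_FISH_SLICES):
        spec = FishSimSpec(n_cells=N_FISH_CELLS_PER_SLICE, seed=seed * 100 + s)
        sample, _ = gen_fish(spec)
        io.write_table(sample.cells, os.path.join(fish_dir, f"slice{s}_somas.tsv"))
        io.write_table(sample.spots, os.path.join(fish_dir, f"slice{s}_spots.tsv"))
        n_total += len(sample.cells)
    summary["fish"] = {"slices": N_FISH_SLICES, "neurons": n_total}

    # histology contingency tables and the two-arm survival experiment
    tables, _ = gen_histo(HistoSimSpec(seed=seed))
    histo_dir = os.path.join(DATA, "histo")
    os.makedirs(histo_dir, exist_ok=True)
    for t in tables:
        t.to_csv(os.path.join(histo_dir, f"{t.attrs['sample_id']}.tsv"), sep="\t")
    records, _ = gen_survival(SurvivalSimSpec(seed=seed))
    io.write_table(records, os.path.join(DATA, "survival.tsv"))
    summary["histo_samples"] = len(tables)
    summary["survival_subjects"] = len(records)

    with open(os.path.join(RESULTS, "01_simulation_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
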