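#!/usr/bin/env python
"""Extract the 13-parameter electrophysiological profile of every simulated
cell and compare fast-spiking vs regular-spiking phenotypes.

Reads the sweep sets written by 01_simulate.py, writes the per-cell feature
table, the recovery-vs-truth table, and the Welch ANOVA / Tukey comparison
to results/. The expectation under the planted phenotypes: fast-spiking
cells show higher input resistance, smaller capacitance, deeper AHP and
higher steady-state firing rates.
"""

import argparse
import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from senpatch import io
from senpatch.ephys import compare_feature_groups, extract_features

ROOT = os.path.join(os.path.dirname(__file__), "..")
DATA = os.path.join(ROOT, "scratch", "analysis_data", "sweeps")
RESULTS = os.path.join(ROOT, "results")


def main(seed: int) -> None:
    with open(os.path.join(DATA, "truth.json")) as fh:
        truth = json.load(fh)

    rows, labels = [], []
    for cell, tr in truth.items():
        feats = extract_features(io.read_sweeps(os.path.join(DATA, cell)))
        s = feats.to_series()
        s.name = cell
        rows.append(s)
        labels.append(tr["cell_class"])
    features = pd.DataFrame(rows)
    features.insert(0, "cell_class", labels)
    io.write_table(features.rename_axis("cell").reset_index(),
                   os.path.join(RESULTS, "02_ephys_features.tsv"))

    recovery = pd.DataFrame({
        "cell": list(truth.keys()),
        "rin_true": [truth[c]["rin_MOhm"] for c in truth],
        "rin_hat": features["rin_MOhm"].to_numpy(),
        "cm_true": [truth[c]["cm_pF"] for c in truth],
        "cm_hat": features["cm_pF"].to_numpy(),
    })
    recovery["rin_error_pct"] = (recovery.rin_hat / recovery.rin_true - 1) * 100
    recovery["cm_error_pct"] = (recovery.cm_hat / recovery.cm_true - 1) * 100
    io.write_table(recovery, os.path.join(RESULTS, "02_ephys_recovery.tsv"))

    table, _ = compare_feature_groups(features.drop(columns="cell_class"), labels)
    io.write_table(table, os.path.join(RESULTS, "02_ephys_comparison.tsv"))

    print(f"extracted features for {len(features)} cells")
    print("max |Rin error| %.2f%%, max |Cm error| %.2f%%" % (
        recovery.rin_error_pct.abs().max(), recovery.cm_error_pct.abs().max()))
    sig = table[table["p_value"] < 0.05]
    print(f"{len(sig)}/{len(table)} features differ between phenotypes "
          f"(Welch ANOVA p < 0.05): {', '.join(sig['feature'])}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
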