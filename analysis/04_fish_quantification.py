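#!/usr/bin/env python
"""EASI-FISH quantification across the seven simulated brain slices.

Per slice: assign spots to somas, convert soma volumes to the pre-expansion
scale (2x linear expansion), recluster neurons into two molecular classes
anchored on CDKN1A/NFKBIA density, and compute per-class density slopes.
Across slices: the normality-gated paired comparison of PY1 vs PY2 soma
volume and per-gene density slopes, mirroring a per-sample paired design.
"""

import argparse
import json
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from senpatch import fish, io
from senpatch.specs import FISH_GENES

ROOT = os.path.join(os.path.dirname(__file__), "..")
DATA = os.path.join(ROOT, "scratch", "analysis_data", "fish")
RESULTS = os.path.join(ROOT, "results")
EXPANSION = 2.0


def main(seed: int) -> None:
    slices = sorted({f.split("_")[0] for f in os.listdir(DATA)})
    per_slice = []
    all_cells = []
    for s in slices:
        somas = io.read_table(os.path.join(DATA, f"{s}_somas.tsv"))
        spots = io.read_table(os.path.join(DATA, f"{s}_spots.tsv"))
        assigned = fish.assign_spots(spots, somas)
        vols = pd.Series(somas["volume_post_um3"].to_numpy(),
                         index=np.arange(1, len(somas) + 1))
        cells = fish.quantify_cells(assigned, vols, EXPANSION,
                                    genes=list(FISH_GENES))
        labels, diag = fish.classify_cells(cells, seed=seed)
        cells = cells.assign(mol_class=labels.to_numpy(), slice=s)
        all_cells.append(cells)

        row = {"slice": s, "n_py1": diag["n_py1"], "n_py2": diag["n_py2"],
               "silhouette": diag["silhouette"]}
        for klass in ("PY1", "PY2"):
            m = cells["mol_class"] == klass
            row[f"volume_median_{klass}"] = cells.loc[m, "volume_pre_um3"].median()
            for g in FISH_GENES:
                row[f"slope_{g}_{klass}"] = fish.density_slope(
                    cells.loc[m, f"count_{g}"], cells.loc[m, "volume_pre_um3"])
        per_slice.append(row)

    per_slice = pd.DataFrame(per_slice)
    io.write_table(per_slice, os.path.join(RESULTS, "04_fish_per_slice.tsv"))
    combined = pd.concat(all_cells)
    n1, n2 = (combined.mol_class == "PY1").sum(), (combined.mol_class == "PY2").sum()
    print(f"{len(combined)} neurons across {len(slices)} slices: "
          f"{n1} PY1 + {n2} PY2 ({100 * n2 / len(combined):.1f}% PY2)")

    # paired per-slice comparisons, PY2 vs PY1
    comparisons = {}
    res = fish.per_sample_paired_compare(per_slice["volume_median_PY2"],
                                         per_slice["volume_median_PY1"])
    comparisons["soma_volume"] = res
    print(f"soma volume (PY2 vs PY1 per slice): {res['test']}, p = {res['p_value']:.4f}")
    for g in FISH_GENES:
        res = fish.per_sample_paired_compare(per_slice[f"slope_{g}_PY2"],
                                             per_slice[f"slope_{g}_PY1"])
        comparisons[f"density_slope_{g}"] = res
        print(f"density slope {g}: {res['test']}, p = {res['p_value']:.4f}")

    with open(os.path.join(RESULTS, "04_fish_comparisons.json"), "w") as fh:
        json.dump({
            "n_neurons": int(len(combined)),
            "n_py1": int(n1), "n_py2": int(n2),
            "comparisons": comparisons,
        }, fh, indent=1)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
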