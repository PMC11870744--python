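"""Histology count-table simulator.

Emits per-sample contingency tables of marker-positivity by neuron class
(e.g. SMI+ dysmorphic vs SMI- neurons) from independent binomial draws with
known class-specific marker probabilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..specs import HistoSimSpec

__all__ = ["gen_histo"]


def gen_histo(spec: HistoSimSpec) -> tuple[list[pd.DataFrame], dict]:
    """Simulate ``spec.n_samples`` k x 2 marker-by-class count tables.

    Each table has one row per cell class and columns ``marker_pos`` /
    ``marker_neg``; rows are binomial draws with the class probability in
    ``spec.p_marker``. Returns the tables and the truth probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.n_per_class.keys())
    tables = []
    for s in range(spec.n_samples):
        pos = [rng.binomial(spec.n_per_class[c], spec.p_marker[c]) for c in classes]
        df = pd.DataFrame({
            "marker_pos": pos,
            "marker_neg": [spec.n_per_class[c] - p for c, p in zip(classes, pos)],
        }, index=pd.Index(classes, name="cell_class"))
        df.attrs["sample_id"] = f"S{s:02d}"
        tables.append(df)
    truth = {"p_marker": dict(spec.p_marker),
             "n_per_class": dict(spec.n_per_class), "seed": spec.seed}
    return tables, truth
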