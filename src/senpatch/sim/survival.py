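"""Two-arm survival-record simulator.

Event times are exponential with arm-specific hazards; administrative
censoring truncates follow-up at a fixed time, as in a treated-vs-vehicle
lifespan experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..specs import SurvivalSimSpec

__all__ = ["gen_survival"]


def gen_survival(spec: SurvivalSimSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate the two arms described by ``spec``.

    Returns a tidy records table (arm, time, event) where ``event`` is False
    for subjects alive at the censoring time, plus the truth hazards.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for arm, n, hz in (("A", spec.n_a, spec.hazard_a), ("B", spec.n_b, spec.hazard_b)):
        t = rng.exponential(1.0 / hz, size=n)
        event = t <= spec.censor_time
        t = np.minimum(t, spec.censor_time)
        rows.append(pd.DataFrame({"arm": arm, "time": t, "event": event}))
    records = pd.concat(rows, ignore_index=True)
    truth = {"hazard_a": spec.hazard_a, "hazard_b": spec.hazard_b,
             "censor_time": spec.censor_time, "seed": spec.seed}
    return records, truth
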