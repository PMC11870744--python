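"""Current-clamp feature extraction and across-cluster comparison.

Extracts a 13-parameter electrophysiological profile per cell from a set of
current-step sweeps: passive membrane properties (resting potential, input
resistance, time constant, capacitance), rheobase and rheobase-AP waveform
features (threshold, amplitude, half-width, afterhyperpolarization,
latency), and firing-pattern features from the largest suprathreshold step
(instantaneous and steady-state frequency, adaptation index).

The feature set covers every quantity named in the study design's
intrinsic-property panels (Rin, Cm, Amp, Ahp, ISI-derived frequencies,
rheobase); the exact membership is configurable because different labs cut
this list differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "SweepSet",
    "APEvent",
    "EphysFeatures",
    "FEATURE_NAMES",
    "detect_aps",
    "passive_properties",
    "find_rheobase",
    "extract_features",
    "compare_feature_groups",
]

#: default spike-detection slope threshold, mV/ms (standard patch-clamp convention)
DEFAULT_DVDT_THRESHOLD = 20.0
#: afterhyperpolarization search window after the AP peak, ms
AHP_WINDOW_MS = 50.0
#: minimum inter-event interval, ms
REFRACTORY_MS = 2.0


@dataclass(frozen=True)
class SweepSet:
    """One cell's current-clamp sweeps on a common uniform time grid.

    ``voltages`` has shape (n_samples, n_sweeps) in mV; ``currents`` holds the
    step amplitude of each sweep in pA; the step occupies
    [``step_on``, ``step_off``] seconds of every sweep.
    """

    time: np.ndarray
    voltages: np.ndarray
    currents: np.ndarray
    step_on: float
    step_off: float
    cell_id: str = "cell"

    def __post_init__(self):
        t = np.asarray(self.time, float)
        v = np.asarray(self.voltages, float)
        c = np.asarray(self.currents, float)
        if t.ndim != 1 or v.ndim != 2 or v.shape[0] != t.size:
            raise ValueError("voltages must be (n_samples, n_sweeps) on the time grid")
        if c.size != v.shape[1]:
            raise ValueError("one step current per sweep required")
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if not (t[0] <= self.step_on < self.step_off <= t[-1]):
            raise ValueError("step window must lie within the recording")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", c)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_sweeps(self) -> int:
        return self.voltages.shape[1]

    def sweep(self, i: int) -> np.ndarray:
        return self.voltages[:, i]


@dataclass(frozen=True)
class APEvent:
    peak_time_s: float
    threshold_mV: float
    peak_mV: float
    amplitude_mV: float
    halfwidth_ms: float
    ahp_mV: float


#: the 13 extracted parameters, in reporting order
FEATURE_NAMES = (
    "rmp_mV",
    "rin_MOhm",
    "cm_pF",
    "tau_ms",
    "rheobase_pA",
    "ap_threshold_mV",
    "ap_amplitude_mV",
    "ap_halfwidth_ms",
    "ahp_mV",
    "rheobase_latency_ms",
    "f_inst_Hz",
    "f_steady_Hz",
    "adaptation_index",
)


@dataclass
class EphysFeatures:
    """The 13-parameter per-cell record; missing values are NaN and listed in ``flags``."""

    cell_id: str = "cell"
    rmp_mV: float = np.nan
    rin_MOhm: float = np.nan
    cm_pF: float = np.nan
    tau_ms: float = np.nan
    rheobase_pA: float = np.nan
    ap_threshold_mV: float = np.nan
    ap_amplitude_mV: float = np.nan
    ap_halfwidth_ms: float = np.nan
    ahp_mV: float = np.nan
    rheobase_latency_ms: float = np.nan
    f_inst_Hz: float = np.nan
    f_steady_Hz: float = np.nan
    adaptation_index: float = np.nan
    flags: list = field(default_factory=list)

    def to_series(self) -> pd.Series:
        vals = {f.name: getattr(self, f.name) for f in dc_fields(self)
                if f.name in FEATURE_NAMES}
        s = pd.Series(vals, name=self.cell_id)
        return s


def _dvdt_mv_per_ms(v: np.ndarray, dt_s: float) -> np.ndarray:
    return np.gradient(v, dt_s) / 1000.0


def detect_aps(voltage, time, dvdt_threshold: float = DEFAULT_DVDT_THRESHOLD,
               refractory_ms: float = REFRACTORY_MS,
               ahp_window_ms: float = AHP_WINDOW_MS) -> list[APEvent]:
    """Detect action potentials in one sweep.

    A peak qualifies as an AP if the membrane slope exceeded ``dvdt_threshold``
    (mV/ms) within the preceding 5 ms. The AP threshold is the voltage at the
    last sub-threshold-slope sample before the peak, the AHP is the drop from
    threshold to the voltage minimum within ``ahp_window_ms`` after the peak,
    and the half-width is measured at threshold + amplitude/2 with linear
    interpolation. Events closer than ``refractory_ms`` collapse to the first.
    """
    v = np.asarray(voltage, float)
    t = np.asarray(time, float)
    if v.ndim != 1 or v.size != t.size:
        raise ValueError("voltage and time must be 1-D and equal length")
    dts = np.diff(t)
    if t.size < 2 or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time grid must be uniform")
    dt = float(dts[0])
    dvdt = _dvdt_mv_per_ms(v, dt)

    min_dist = max(1, int(round(refractory_ms / 1000.0 / dt)))
    peaks, _ = find_peaks(v, prominence=20.0, distance=min_dist)
    lookback = max(1, int(round(5e-3 / dt)))
    ahp_n = max(1, int(round(ahp_window_ms / 1000.0 / dt)))

    events: list[APEvent] = []
    for p in peaks:
        pre = slice(max(0, p - lookback), p + 1)
        if np.max(dvdt[pre]) < dvdt_threshold:
            continue  # slow depolarizing bump, not a spike
        # walk back from the peak to the first sample at which dV/dt crossed
        # the criterion: that sample's voltage is the AP threshold
        i = p
        while i > 0 and dvdt[i - 1] >= dvdt_threshold:
            i -= 1
        thr_idx = i
        thr = float(v[thr_idx])
        peak_v = float(v[p])
        amp = peak_v - thr
        if amp <= 0:
            continue

        half = thr + amp / 2.0
        # left crossing
        li = p
        while li > thr_idx and v[li - 1] > half:
            li -= 1
        t_left = _interp_crossing(t, v, li - 1, half) if li > 0 else t[li]
        # right crossing
        ri = p
        stop = min(v.size - 1, p + ahp_n)
        while ri < stop and v[ri + 1] > half:
            ri += 1
        t_right = _interp_crossing(t, v, ri, half) if ri < v.size - 1 else t[ri]
        hw_ms = max(t_right - t_left, dt) * 1000.0

        trough = float(np.min(v[p: min(v.size, p + ahp_n)]))
        events.append(APEvent(
            peak_time_s=float(t[p]), threshold_mV=thr, peak_mV=peak_v,
            amplitude_mV=amp, halfwidth_ms=hw_ms, ahp_mV=thr - trough,
        ))
    return events


def _interp_crossing(t, v, i, level) -> float:
    """Linear interpolation of the time where v crosses `level` in [i, i+1]."""
    v0, v1 = v[i], v[i + 1]
    if v1 == v0:
        return float(t[i])
    f = (level - v0) / (v1 - v0)
    f = min(max(f, 0.0), 1.0)
    return float(t[i] + f * (t[i + 1] - t[i]))


def passive_properties(sweeps: SweepSet, detect_kwargs: dict | None = None):
    """Resting potential, input resistance, membrane time constant and capacitance.

    Uses hyperpolarizing, spike-free sweeps only. RMP is the median pre-step
    voltage; Rin is the slope of steady-state voltage deflection against step
    current; tau comes from a single-exponential fit to the onset transient of
    the most hyperpolarizing sweep; Cm = tau / Rin.

    Returns (rmp_mV, rin_MOhm, tau_ms, cm_pF, flags) with NaN + flag entries
    when no hyperpolarizing sweep exists.
    """
    detect_kwargs = detect_kwargs or {}
    t = sweeps.time
    pre = t < sweeps.step_on
    flags: list[str] = []

    rmp = float(np.median(sweeps.voltages[pre, :]))

    hyper = [i for i in range(sweeps.n_sweeps) if sweeps.currents[i] < 0
             and not detect_aps(sweeps.sweep(i), t, **detect_kwargs)]
    if not hyper:
        return rmp, np.nan, np.nan, np.nan, ["no_hyperpolarizing_sweeps"]

    # steady state: last 20% of the step window
    ss_lo = sweeps.step_off - 0.2 * (sweeps.step_off - sweeps.step_on)
    ss = (t >= ss_lo) & (t <= sweeps.step_off)
    d_v = np.array([np.mean(sweeps.sweep(i)[ss]) - np.mean(sweeps.sweep(i)[pre])
                    for i in hyper])
    cur = sweeps.currents[hyper]
    if len(hyper) >= 2:
        slope = np.polyfit(cur, d_v, 1)[0]  # mV per pA
    else:
        slope = d_v[0] / cur[0]
    rin = float(slope * 1000.0)  # mV/pA -> MOhm

    # tau from the onset transient of the largest hyperpolarizing step
    i_big = hyper[int(np.argmin(cur))]
    on = (t >= sweeps.step_on) & (t <= min(sweeps.step_off, sweeps.step_on + 0.15))
    tt = t[on] - sweeps.step_on
    vv = sweeps.sweep(i_big)[on]
    v0 = float(np.mean(sweeps.sweep(i_big)[pre]))
    dv_ss = float(np.mean(vv[-max(3, len(vv) // 10):]) - v0)

    def rc(x, dv, tau):
        return v0 + dv * (1.0 - np.exp(-x / tau))

    try:
        popt, _ = curve_fit(rc, tt, vv, p0=(dv_ss, 0.02),
                            bounds=([-np.inf, 1e-5], [np.inf, 1.0]))
        tau_ms = float(popt[1] * 1000.0)
    except RuntimeError:
        flags.append("tau_fit_failed")
        tau_ms = np.nan

    cm = tau_ms / rin * 1000.0 if rin > 0 and np.isfinite(tau_ms) else np.nan
    if not (rin > 0):
        flags.append("nonpositive_rin")
    return rmp, rin, tau_ms, float(cm), flags


def find_rheobase(sweeps: SweepSet, detect_kwargs: dict | None = None):
    """Smallest step current eliciting at least one AP.

    Returns (rheobase_pA, events_on_that_sweep, flags). If the lowest tested
    current already spikes the estimate is left-censored; if nothing spikes
    the rheobase is missing.
    """
    detect_kwargs = detect_kwargs or {}
    order = np.argsort(sweeps.currents, kind="stable")
    for rank, i in enumerate(order):
        ev = detect_aps(sweeps.sweep(i), sweeps.time, **detect_kwargs)
        ev = [e for e in ev if sweeps.step_on <= e.peak_time_s <= sweeps.step_off]
        if ev:
            flags = ["left_censored"] if rank == 0 else []
            return float(sweeps.currents[i]), ev, flags
    return np.nan, [], ["no_spiking_sweep"]


def extract_features(sweeps: SweepSet, dvdt_threshold: float = DEFAULT_DVDT_THRESHOLD) -> EphysFeatures:
    """Compose the full 13-parameter profile for one cell.

    AP waveform features come from the first AP of the rheobase sweep;
    firing-frequency features come from the largest suprathreshold step
    (instantaneous = 1/first ISI, steady-state = 1/mean of the last three
    ISIs, adaptation index = last/first ISI).
    """
    dk = {"dvdt_threshold": dvdt_threshold}
    feats = EphysFeatures(cell_id=sweeps.cell_id)

    rmp, rin, tau, cm, pflags = passive_properties(sweeps, dk)
    feats.rmp_mV, feats.rin_MOhm, feats.tau_ms, feats.cm_pF = rmp, rin, tau, cm
    feats.flags += pflags

    rheo, rheo_events, rflags = find_rheobase(sweeps, dk)
    feats.rheobase_pA = rheo
    feats.flags += rflags
    if rheo_events:
        ap = rheo_events[0]
        feats.ap_threshold_mV = ap.threshold_mV
        feats.ap_amplitude_mV = ap.amplitude_mV
        feats.ap_halfwidth_ms = ap.halfwidth_ms
        feats.ahp_mV = ap.ahp_mV
        feats.rheobase_latency_ms = (ap.peak_time_s - sweeps.step_on) * 1000.0

    # firing pattern at the largest suprathreshold step
    i_max = int(np.argmax(sweeps.currents))
    if sweeps.currents[i_max] > 0:
        ev = detect_aps(sweeps.sweep(i_max), sweeps.time, **dk)
        ev = [e for e in ev if sweeps.step_on <= e.peak_time_s <= sweeps.step_off]
        if len(ev) >= 2:
            isis = np.diff([e.peak_time_s for e in ev])
            feats.f_inst_Hz = 1.0 / isis[0]
            feats.f_steady_Hz = 1.0 / float(np.mean(isis[-3:]))
            if len(isis) >= 2:
                feats.adaptation_index = float(isis[-1] / isis[0])
            else:
                feats.flags.append("single_isi_no_adaptation")
        else:
            feats.flags.append("too_few_spikes_for_frequency")
    else:
        feats.flags.append("no_suprathreshold_step")
    return feats


def compare_feature_groups(features: pd.DataFrame, labels,
                           feature_names=FEATURE_NAMES):
    """Welch's (unequal-variance) one-way ANOVA plus all-pairs Tukey HSD per feature.

    ``features`` has one row per cell; ``labels`` aligns with its index.
    Missing values are dropped per feature. A feature is flagged (NaN p) when
    fewer than two groups retain >= 2 non-missing cells.

    Returns (anova_table, {feature: pairwise Tukey DataFrame}).
    """
    import pingouin as pg
    from scipy.stats import tukey_hsd

    labels = pd.Series(np.asarray(labels), index=features.index, name="group")
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    rows = []
    pairwise: dict[str, pd.DataFrame] = {}
    for feat in feature_names:
        if feat not in features.columns:
            continue
        df = pd.DataFrame({"value": features[feat], "group": labels}).dropna()
        sizes = df.groupby("group")["value"].count()
        usable = sizes[sizes >= 2].index
        if len(usable) < 2:
            rows.append((feat, np.nan, np.nan, "insufficient_data"))
            continue
        df = df[df["group"].isin(usable)]
        if (df.groupby("group")["value"].var(ddof=1) <= 0).any():
            rows.append((feat, np.nan, np.nan, "zero_variance_group"))
            continue
        aov = pg.welch_anova(data=df, dv="value", between="group")
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        rows.append((feat, float(aov["F"].iloc[0]), float(aov[p_col].iloc[0]), ""))

        samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in usable]
        if all(len(s) >= 3 for s in samples):
            res = tukey_hsd(*samples)
            prow = []
            for i in range(len(usable)):
                for j in range(i + 1, len(usable)):
                    prow.append((usable[i], usable[j],
                                 float(res.statistic[i, j]), float(res.pvalue[i, j])))
            pairwise[feat] = pd.DataFrame(
                prow, columns=["group_a", "group_b", "mean_diff", "p_tukey"])
    table = pd.DataFrame(rows, columns=["feature", "welch_F", "p_value", "flag"])
    return table, pairwise
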