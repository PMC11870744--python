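"""Current-clamp sweep simulator.

Subthreshold sweeps follow the single-exponential RC response of a passive
membrane (tau = Rin * Cm); suprathreshold sweeps carry stereotyped AP
templates injected at spike times from an adapting renewal model whose
first-ISI rate grows linearly with drive above rheobase. The goal is a
waveform whose every extracted feature has a closed-form or recorded ground
truth — the simulator tests feature *extraction*, not biophysics.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from ..ephys import SweepSet
from ..specs import EphysSimSpec

__all__ = ["gen_ephys"]

# template timing constants (s / fractions); see _render_sweep
_RAMP_S = 5e-4          # pre-upstroke approach to threshold
_UP_FRACTION = 0.6      # upstroke duration as a fraction of the half-width
_AHP_TAU_S = 0.015      # post-AHP recovery time constant
_NOISE_TAU_S = 0.002    # Ornstein-Uhlenbeck membrane-noise correlation time
_BASE_RATE_HZ = 5.0     # first-ISI rate at rheobase
_ADAPT_K = 2.0          # ISI-lengthening rate constant (spikes)


def _spike_times(spec: EphysSimSpec, current_pa: float, step_on: float,
                 step_off: float) -> np.ndarray:
    """Deterministic spike (upstroke-onset) times for one suprathreshold step."""
    if current_pa < spec.rheobase_pA:
        return np.array([])
    tau_s = spec.tau_ms / 1000.0
    # RC charge time to the effective spike-initiation level; at exactly
    # rheobase this saturates at ~6.9 tau instead of diverging
    latency = tau_s * np.log(current_pa / max(current_pa - 0.999 * spec.rheobase_pA,
                                              1e-3 * spec.rheobase_pA))
    f1 = _BASE_RATE_HZ + spec.fi_gain_hz_per_pa * (current_pa - spec.rheobase_pA)
    isi1 = 1.0 / f1
    a = spec.adaptation_ratio
    times = [step_on + latency]
    k = 1
    while True:
        isi_k = isi1 * (1.0 + (a - 1.0) * (1.0 - np.exp(-(k - 1) / _ADAPT_K)))
        isi_k = max(isi_k, 0.002)  # absolute refractory floor
        t_next = times[-1] + isi_k
        if t_next >= step_off - 0.002:
            break
        times.append(t_next)
        k += 1
    return np.array(times)


def _render_sweep(spec: EphysSimSpec, t: np.ndarray, current_pa: float,
                  step_on: float, step_off: float) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless voltage trace and its AP peak times for one step current."""
    dt = t[1] - t[0]
    tau_s = spec.tau_ms / 1000.0
    drive_mv = current_pa * spec.rin_MOhm / 1000.0  # pA * MOhm -> mV
    # membrane cannot sit above its spike-initiation level between spikes
    v_cap = min(spec.rmp_mV + spec.rheobase_pA * spec.rin_MOhm / 1000.0,
                spec.ap_threshold_mV - 1.0)

    v = np.full_like(t, spec.rmp_mV)
    on = (t >= step_on) & (t < step_off)
    on_idx = np.flatnonzero(on)
    v[on] = spec.rmp_mV + drive_mv * (1.0 - np.exp(-(t[on] - step_on) / tau_s))

    spikes = _spike_times(spec, current_pa, step_on, step_off)
    peak_times: list[float] = []
    if spikes.size:
        v[on] = np.minimum(v[on], v_cap)
        thr, amp, ahp = spec.ap_threshold_mV, spec.ap_amp_mV, spec.ahp_mV
        hw_s = spec.ap_halfwidth_ms / 1000.0
        t_up = _UP_FRACTION * hw_s
        # triangle waveform solved so the width at threshold+amp/2 equals hw_s
        t_down = (hw_s - t_up / 2.0) * (amp + ahp) / (amp / 2.0)
        for k, ts in enumerate(spikes):
            i0 = int(round((ts - t[0]) / dt))
            if i0 >= t.size:
                break
            n_ramp = max(1, int(round(_RAMP_S / dt)))
            n_up = max(1, int(round(t_up / dt)))
            n_down = max(1, int(round(t_down / dt)))
            i_thr = min(i0 + n_ramp, t.size - 1)
            i_pk = min(i_thr + n_up, t.size - 1)
            i_end = min(i_pk + n_down, t.size - 1)
            v[i0:i_thr + 1] = np.linspace(v[i0], thr, i_thr - i0 + 1)
            v[i_thr:i_pk + 1] = np.linspace(thr, thr + amp, i_pk - i_thr + 1)
            v[i_pk:i_end + 1] = np.linspace(thr + amp, thr - ahp, i_end - i_pk + 1)
            peak_times.append(float(t[i_pk]))
            # AHP recovery toward the capped baseline until the next spike
            next_i = (int(round((spikes[k + 1] - t[0]) / dt))
                      if k + 1 < spikes.size else t.size)
            seg = slice(i_end + 1, min(next_i, t.size))
            if seg.start < seg.stop:
                base = np.minimum(v[seg], v_cap)
                v[seg] = base + (thr - ahp - v_cap) * np.exp(
                    -(t[seg] - t[i_end]) / _AHP_TAU_S)

    # post-step relaxation continues from the actual end-of-step voltage
    after = t >= step_off
    if on_idx.size and np.any(after):
        v_off = v[on_idx[-1]]
        v[after] = spec.rmp_mV + (v_off - spec.rmp_mV) * np.exp(
            -(t[after] - step_off) / tau_s)
    return v, np.array(peak_times)


def _ou_noise(rng: np.random.Generator, n: int, sd: float, dt: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise as an AR(1) filter of white noise."""
    rho = np.exp(-dt / _NOISE_TAU_S)
    white = rng.standard_normal(n) * sd * np.sqrt(1.0 - rho**2)
    x0 = rng.standard_normal() * sd
    noise = lfilter([1.0], [1.0, -rho], white, zi=np.array([rho * x0]))[0]
    return noise


def gen_ephys(spec: EphysSimSpec, step_currents, duration_s: float = 1.0,
              dt_s: float = 5e-5, step_on: float = 0.1,
              step_off: float = 0.7) -> tuple[SweepSet, dict]:
    """Simulate one cell's sweep set over the given step currents (pA).

    Returns the :class:`~senpatch.ephys.SweepSet` plus a truth record holding
    every spec parameter and the realized per-sweep AP peak times. Membrane
    noise is Ornstein-Uhlenbeck with a 2 ms correlation time and stationary
    standard deviation ``spec.noise_sd_mV``, so the stated noise amplitude
    does not alias into the dV/dt band used for spike detection.
    """
    currents = np.asarray(list(step_currents), dtype=float)
    if currents.size == 0:
        raise ValueError("step_currents must be non-empty")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, duration_s, dt_s)

    voltages = np.empty((t.size, currents.size))
    spike_times = {}
    for j, cur in enumerate(currents):
        v, peaks = _render_sweep(spec, t, cur, step_on, step_off)
        if spec.noise_sd_mV > 0:
            v = v + _ou_noise(rng, t.size, spec.noise_sd_mV, dt_s)
        voltages[:, j] = v
        spike_times[float(cur)] = peaks

    sweeps = SweepSet(time=t, voltages=voltages, currents=currents,
                      step_on=step_on, step_off=step_off,
                      cell_id=f"{spec.cell_class}_{spec.seed}")
    truth = {
        "cell_class": spec.cell_class,
        "rmp_mV": spec.rmp_mV,
        "rin_MOhm": spec.rin_MOhm,
        "cm_pF": spec.cm_pF,
        "tau_ms": spec.tau_ms,
        "ap_threshold_mV": spec.ap_threshold_mV,
        "ap_amp_mV": spec.ap_amp_mV,
        "ahp_mV": spec.ahp_mV,
        "ap_halfwidth_ms": spec.ap_halfwidth_ms,
        "rheobase_pA": spec.rheobase_pA,
        "adaptation_ratio": spec.adaptation_ratio,
        "noise_sd_mV": spec.noise_sd_mV,
        "seed": spec.seed,
        "spike_times": spike_times,
    }
    return sweeps, truth
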