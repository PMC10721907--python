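"""Extracellular stimulation of the multi-compartment RGC cable model.

The neuron is a chain of compartments (dendrite → soma → hillock →
sodium band → axon).  Extracellular stimulation enters through the axial
terms of the cable equation: the intracellular potential is Vm + Ve, so
spatial differences of the extracellular potential along the cable drive
transmembrane current (the classical activating-function mechanism).
Because the volume conductor is linear, Ve per compartment is the
unit-current field solution scaled by the stimulus amplitude and waveform
— one field solve per electrode serves every amplitude.

Integration is semi-implicit: gate variables advance by exponential Euler
at the current potential, then the membrane potential is solved implicitly
along the chain (tridiagonal system), which keeps the scheme stable at
the default 10 µs step.  A spike is an upward crossing of 0 mV in any
compartment.  Thresholds are located by bisection on the amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .membrane import MembraneParams, FARADAY, gate_rates, gate_steady_states
from .population import NeuronGeometry, SECTION_CODES

__all__ = ["StimulusWaveform", "make_pulse_train", "CableModel", "SimResult",
           "simulate", "find_threshold", "INEXCITABLE"]

INEXCITABLE = np.nan   # sentinel threshold for neurons that never spike


@dataclass
class StimulusWaveform:
    """Sampled biphasic pulse train.

    ``samples`` holds dimensionless scale factors in {−1, 0, +1} on a
    uniform grid of step ``dt_ms``; the physical stimulus is
    ``amplitude_uA · samples``.  Cathodic (negative) phase first,
    charge-balanced by construction.
    """

    amplitude_uA: float
    pulse_width_ms: float
    frequency_hz: float
    n_pulses: int
    interphase_gap_ms: float
    dt_ms: float
    samples: np.ndarray

    @property
    def duration_ms(self) -> float:
        return len(self.samples) * self.dt_ms

    def with_amplitude(self, amplitude_uA: float) -> "StimulusWaveform":
        return StimulusWaveform(amplitude_uA, self.pulse_width_ms,
                                self.frequency_hz, self.n_pulses,
                                self.interphase_gap_ms, self.dt_ms, self.samples)


def make_pulse_train(amplitude_uA: float, pulse_width_ms: float = 0.45,
                     frequency_hz: float = 20.0, n_pulses: int = 5,
                     interphase_gap_ms: float = 0.0,
                     dt_ms: float = 0.01) -> StimulusWaveform:
    """Cathode-first biphasic pulse train (default 0.45 ms/phase at 20 Hz).

    Total duration is ``n_pulses / frequency`` (five pulses at 20 Hz span
    250 ms).  Raises ``ValueError`` if the two phases plus gap overlap the
    next pulse period.
    """
    period_ms = 1000.0 / frequency_hz
    if 2 * pulse_width_ms + interphase_gap_ms > period_ms:
        raise ValueError("pulse phases overlap the next pulse period")
    n_phase = int(round(pulse_width_ms / dt_ms))
    n_gap = int(round(interphase_gap_ms / dt_ms))
    n_period = int(round(period_ms / dt_ms))
    one = np.zeros(n_period)
    one[:n_phase] = -1.0
    one[n_phase + n_gap:2 * n_phase + n_gap] = 1.0
    samples = np.tile(one, n_pulses)
    return StimulusWaveform(amplitude_uA, pulse_width_ms, frequency_hz,
                            n_pulses, interphase_gap_ms, dt_ms, samples)


@dataclass
class SimResult:
    spiked: bool
    spike_time_ms: float
    spike_compartment: int
    vm: np.ndarray | None      # (n_steps+1, n_comp) mV when recorded
    dt_ms: float
    n_steps: int


class CableModel:
    """Per-neuron arrays of the cable equation, ready for integration.

    Precomputes absolute conductances (mS), capacitances (µF) and axial
    coupling (mS) from the morphology and membrane parameters, and solves
    the per-compartment leak reversal so the configured resting potential
    is an exact equilibrium.
    """

    def __init__(self, neuron: NeuronGeometry, params: MembraneParams | None = None):
        self.params = p = params or MembraneParams()
        self.neuron = neuron
        n = neuron.n_compartments
        d_cm = neuron.diameter_um * 1e-4
        l_cm = neuron.length_um * 1e-4
        area = np.pi * d_cm * l_cm
        soma = neuron.mask("soma")
        area[soma] = np.pi * d_cm[soma] ** 2          # sphere
        self.area_cm2 = area
        self.cm_abs = p.cm * area                     # µF

        code_names = {v: k for k, v in SECTION_CODES.items()}
        dens = np.array([p.densities[code_names[int(c)]] for c in neuron.section])
        self.g_na = dens[:, 0] * area                 # mS
        self.g_ca = dens[:, 1] * area
        self.g_k = dens[:, 2] * area
        self.g_a = dens[:, 3] * area
        self.g_kca = dens[:, 4] * area
        self.g_l = p.g_leak * area

        # axial conductance between consecutive compartments (mS)
        r_half = p.axial_resistivity * (l_cm / 2.0) / (np.pi * (d_cm / 2.0) ** 2)
        self.axial = 1000.0 / (r_half[:-1] + r_half[1:])

        # leak reversal balancing the standing currents at rest
        v0 = p.v_rest
        g = gate_steady_states(v0)
        m, h, c, nn, a, ha = g
        e_ca0 = p.nernst_factor * np.log(p.ca_out / p.ca_rest)
        i_other = (self.g_na * m ** 3 * h * (v0 - p.e_na)
                   + self.g_ca * c ** 3 * (v0 - e_ca0)
                   + self.g_k * nn ** 4 * (v0 - p.e_k)
                   + self.g_a * a ** 3 * ha * (v0 - p.e_k)
                   + self.g_kca * (p.ca_rest ** 2 /
                                   (p.ca_rest ** 2 + p.ca_dissociation ** 2))
                   * (v0 - p.e_k))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.e_l = np.where(self.g_l > 0, v0 + i_other / self.g_l, v0)
        self.gates0 = np.tile(g[:, None], (1, n))
        # calcium influx coefficient: mM per ms per (µA/cm²) of Ca current
        sv = 4.0 / d_cm
        sv[soma] = 6.0 / d_cm[soma]
        self.ca_coef = sv / (2.0 * FARADAY * 1000.0)

    @property
    def n_compartments(self) -> int:
        return self.neuron.n_compartments


@njit(cache=True)
def _integrate(dt, n_steps, cm, g_na, g_ca, g_k, g_a, g_kca, g_l, e_l,
               axial, area, ca_coef, ve_amp, wave, gates0, v_rest,
               e_na, e_k, nernst, ca_out, ca_rest, ca_kd, ca_tau,
               rate_scale, record):
    n = cm.shape[0]
    v = np.full(n, v_rest)
    m = gates0[0].copy(); h = gates0[1].copy(); c = gates0[2].copy()
    nn = gates0[3].copy(); a = gates0[4].copy(); ha = gates0[5].copy()
    ca = np.full(n, ca_rest)
    trace = np.empty((n_steps + 1, n)) if record else np.empty((1, n))
    trace[0] = v
    lower = np.empty(n); diag = np.empty(n); upper = np.empty(n); rhs = np.empty(n)
    spiked = False
    spike_step = -1
    spike_comp = -1
    ok = True
    for step in range(n_steps):
        w_now = wave[step] if step < wave.shape[0] else 0.0
        w_next = wave[step + 1] if step + 1 < wave.shape[0] else 0.0
        # gates: exponential Euler at current v
        for i in range(n):
            am, bm, ahh, bhh, acc, bcc, an, bn, aa, ba, aha, bha = gate_rates(v[i])
            m[i] += (am / (am + bm) - m[i]) * (1.0 - np.exp(-dt * rate_scale * (am + bm)))
            h[i] += (ahh / (ahh + bhh) - h[i]) * (1.0 - np.exp(-dt * rate_scale * (ahh + bhh)))
            c[i] += (acc / (acc + bcc) - c[i]) * (1.0 - np.exp(-dt * rate_scale * (acc + bcc)))
            nn[i] += (an / (an + bn) - nn[i]) * (1.0 - np.exp(-dt * rate_scale * (an + bn)))
            a[i] += (aa / (aa + ba) - a[i]) * (1.0 - np.exp(-dt * rate_scale * (aa + ba)))
            ha[i] += (aha / (aha + bha) - ha[i]) * (1.0 - np.exp(-dt * rate_scale * (aha + bha)))
        # calcium and reversals, then the implicit membrane solve
        for i in range(n):
            e_ca = nernst * np.log(ca_out / ca[i])
            i_ca_abs = g_ca[i] * c[i] ** 3 * (v[i] - e_ca)        # µA
            dca = -ca_coef[i] * (i_ca_abs / area[i]) - (ca[i] - ca_rest) / ca_tau
            ca[i] = max(ca[i] + dt * dca, 1e-8)
            kca_open = ca[i] ** 2 / (ca[i] ** 2 + ca_kd ** 2)
            g_tot = (g_na[i] * m[i] ** 3 * h[i] + g_ca[i] * c[i] ** 3
                     + g_k[i] * nn[i] ** 4 + g_a[i] * a[i] ** 3 * ha[i]
                     + g_kca[i] * kca_open + g_l[i])
            g_e = (g_na[i] * m[i] ** 3 * h[i] * e_na
                   + g_ca[i] * c[i] ** 3 * e_ca
                   + (g_k[i] * nn[i] ** 4 + g_a[i] * a[i] ** 3 * ha[i]
                      + g_kca[i] * kca_open) * e_k
                   + g_l[i] * e_l[i])
            diag[i] = cm[i] / dt + g_tot
            rhs[i] = cm[i] / dt * v[i] + g_e
            lower[i] = 0.0
            upper[i] = 0.0
        for i in range(n - 1):
            ax = axial[i]
            diag[i] += ax
            diag[i + 1] += ax
            upper[i] = -ax
            lower[i + 1] = -ax
            # extracellular drive (activating function), semi-implicit in time
            dve = (ve_amp[i + 1] - ve_amp[i]) * 0.5 * (w_now + w_next)
            rhs[i] += ax * dve
            rhs[i + 1] -= ax * dve
        # Thomas solve
        for i in range(1, n):
            f = lower[i] / diag[i - 1]
            diag[i] -= f * upper[i - 1]
            rhs[i] -= f * rhs[i - 1]
        v_new = np.empty(n)
        v_new[n - 1] = rhs[n - 1] / diag[n - 1]
        for i in range(n - 2, -1, -1):
            v_new[i] = (rhs[i] - upper[i] * v_new[i + 1]) / diag[i]
        for i in range(n):
            if v[i] < 0.0 and v_new[i] >= 0.0 and not spiked:
                spiked = True
                spike_step = step + 1
                spike_comp = i
            # forced polarization under a strong pulse is large but finite;
            # divergence or non-finite values mean the step size failed
            if not np.isfinite(v_new[i]) or abs(v_new[i]) > 2.0e4:
                ok = False
            v[i] = v_new[i]
        if record:
            trace[step + 1] = v
        if not ok or (spiked and not record):
            break
    return spiked, spike_step, spike_comp, trace, ok


def simulate(cable: CableModel, unit_potentials_V: np.ndarray,
             waveform: StimulusWaveform, dt_ms: float = 0.01,
             duration_ms: float | None = None,
             record: bool = False) -> SimResult:
    """Integrate the membrane response to one stimulus.

    ``unit_potentials_V`` is the extracellular potential per compartment
    for a 1 A injection (from the field solution); the applied Ve is
    ``amplitude_uA · 1e-6 · unit · waveform(t)``.  ``duration_ms`` may be
    shorter than the nominal waveform to truncate the simulated window.

    Raises ``RuntimeError`` on numerical instability (|Vm| > 200 mV),
    which a smaller ``dt_ms`` resolves.
    """
    if dt_ms > 0.025:
        raise ValueError("dt_ms must be <= 0.025 (25 µs)")
    unit = np.asarray(unit_potentials_V, dtype=float)
    if unit.shape[0] != cable.n_compartments:
        raise ValueError("one extracellular potential per compartment required")
    duration = duration_ms if duration_ms is not None else waveform.duration_ms
    n_steps = int(round(duration / dt_ms))
    # resample the waveform onto the integration grid
    t = np.arange(n_steps + 1) * dt_ms
    src_idx = np.minimum((t / waveform.dt_ms).astype(np.int64),
                         len(waveform.samples) - 1)
    wave = waveform.samples[src_idx].astype(float)
    wave[t >= waveform.duration_ms] = 0.0
    ve_amp = waveform.amplitude_uA * 1e-6 * unit * 1000.0   # mV per waveform unit
    p = cable.params
    spiked, step, comp, trace, ok = _integrate(
        dt_ms, n_steps, cable.cm_abs, cable.g_na, cable.g_ca, cable.g_k,
        cable.g_a, cable.g_kca, cable.g_l, cable.e_l, cable.axial,
        cable.area_cm2, cable.ca_coef, ve_amp, wave, cable.gates0, p.v_rest,
        p.e_na, p.e_k, p.nernst_factor, p.ca_out, p.ca_rest,
        p.ca_dissociation, p.ca_tau_ms, p.rate_scale, record)
    if not ok:
        raise RuntimeError("numerical instability (|Vm| > 200 mV); "
                           "reduce dt_ms")
    return SimResult(spiked=bool(spiked), spike_time_ms=step * dt_ms,
                     spike_compartment=int(comp),
                     vm=trace if record else None, dt_ms=dt_ms,
                     n_steps=n_steps)


def find_threshold(cable: CableModel, unit_potentials_V: np.ndarray,
                   waveform_template: StimulusWaveform,
                   lo_uA: float = 0.0, hi_uA: float = 1000.0,
                   tol_uA: float = 0.1, cap_factor: float = 4.0,
                   dt_ms: float = 0.01,
                   duration_ms: float | None = None) -> float:
    """Bisection search for the activation threshold (µA).

    The bracket is expanded geometrically up to ``cap_factor · hi_uA`` if
    the initial upper bound does not elicit a spike; a neuron silent at
    the cap is reported as inexcitable (NaN).  Bisection stops when the
    bracket is narrower than ``tol_uA`` and returns its midpoint, within
    ``tol_uA`` of the true boundary for monotone activation.
    """
    def spikes(amp: float) -> bool:
        if amp <= 0:
            return False
        return simulate(cable, unit_potentials_V,
                        waveform_template.with_amplitude(amp),
                        dt_ms=dt_ms, duration_ms=duration_ms).spiked

    return bisect_threshold(spikes, lo_uA=lo_uA, hi_uA=hi_uA, tol_uA=tol_uA,
                            cap_factor=cap_factor)


def bisect_threshold(spikes, lo_uA: float = 0.0, hi_uA: float = 1000.0,
                     tol_uA: float = 0.1, cap_factor: float = 4.0) -> float:
    """Bisection on a boolean ``spikes(amplitude)`` predicate.

    Assumes monotone activation; see :func:`find_threshold` for the
    bracket-expansion and inexcitable-sentinel behaviour.
    """
    if lo_uA > 0 and spikes(lo_uA):
        raise ValueError("lower bracket already spikes; decrease lo_uA")
    hi = hi_uA
    cap = cap_factor * hi_uA
    while not spikes(hi):
        hi *= 2.0
        if hi > cap:
            return INEXCITABLE
    lo = lo_uA
    while hi - lo > tol_uA:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
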