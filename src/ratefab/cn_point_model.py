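"""Reduced conductance-based cerebellar-nucleus (CN) neuron and scan harness.

The full-morphology CN neuron is replaced by a spiking point model with a
minimal conductance set — transient Na, delayed-rectifier K, leak, a tonic
depolarizing drive, and a spike-triggered Ca pool activating an SK
current — tuned to the macroscopic properties the transmission questions
depend on: tonic spontaneous firing, a near-linear f-I curve, and
SK-dependent afterhyperpolarization and gain control.  It receives 50
depressing inhibitory (Purkinje-cell) inputs and 48 excitatory
(mossy-fiber) inputs as spike trains; each synapse class is a unit-peak
dual-exponential conductance, with AMPA+NMDA (voltage-dependent Mg block)
excitation.

Because a point neuron lacks the dendritic attenuation of the distributed
morphology, each synapse class has a somatic efficacy factor (``w_in``,
``w_ex``) that maps a unitary dendritic conductance onto its effective
somatic value; the factors are part of the reduction and are calibrated so
the standard operating points (G_in = 16 nS with low/high excitation)
yield CN rates in the recorded 10–70 Hz range.

Numerics: exponential-Euler integration at dt = 0.025 ms; synaptic
conductance waveforms are computed by exact single-pole IIR filtering of
the weighted spike impulse sequences.  Identical seed and inputs give
identical output spike times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import lfilter

from .depressing_synapse import (
    DepressionParams,
    SynapseKinetics,
    default_depression_params,
    depression_weights,
)
from .io_fixtures import EventSeries, SpikeTrain
from .population_builder import (
    ModulationWaveform,
    PopulationSpec,
    build_population,
)
from .rate_template import RateTemplate, rescale_to_rate
from .spike_stats import compute_cv, compute_lv

__all__ = [
    "NeuronParams",
    "SynapseLayout",
    "ScanSpec",
    "SimResult",
    "simulate",
    "f_i_curve",
    "run_scan",
    "sk_scan",
    "GABA_KINETICS",
    "AMPA_KINETICS",
    "NMDA_KINETICS",
]

DT_MS_DEFAULT = 0.025

GABA_KINETICS = SynapseKinetics(tau_rise=0.5e-3, tau_decay=14e-3, e_rev=-70.0)
AMPA_KINETICS = SynapseKinetics(tau_rise=0.3e-3, tau_decay=3e-3, e_rev=0.0)
NMDA_KINETICS = SynapseKinetics(tau_rise=5e-3, tau_decay=70e-3, e_rev=0.0)


@dataclass(frozen=True)
class NeuronParams:
    """Point-neuron parameters (conductances in nS, capacitance in pF).

    The Na/K kinetics are standard fast-spiking interneuron rate functions;
    the SK current is driven by a per-spike Ca increment with exponential
    decay (``tau_ca``) and Hill-4 activation at ``sk_half``.  ``tonic_drive``
    is the constant depolarizing current (pA) producing spontaneous firing
    at zero synaptic input.
    """

    capacitance: float = 100.0      # pF
    g_leak: float = 10.0            # nS
    e_leak: float = -65.0           # mV
    g_na: float = 3500.0            # nS
    e_na: float = 55.0              # mV
    g_kdr: float = 900.0            # nS
    e_k: float = -90.0              # mV
    g_sk_max: float = 12.0          # nS
    ca_increment: float = 0.75      # concentration units per spike
    tau_ca: float = 0.08            # s
    sk_half: float = 3.5            # Ca units, Hill-4 half activation
    tonic_drive: float = 30.0       # pA

    def __post_init__(self):
        for name in ("g_leak", "g_na", "g_kdr", "g_sk_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SynapseLayout:
    """Synaptic configuration of the CN model.

    ``g_in``/``g_ex`` are unitary dendritic conductances (nS) per PC/MF
    input; ``w_in``/``w_ex`` are the point-reduction somatic efficacy
    factors.  ``nmda_fraction`` is the NMDA share of excitatory charge
    (before Mg block).  When using 500 PC inputs, divide ``g_in`` by 10 to
    keep the mean inhibitory conductance matched to the 50-input setting.
    """

    n_pc: int = 50
    n_mf: int = 48
    g_in: float = 16.0
    g_ex: float = 3.5
    w_in: float = 0.055
    w_ex: float = 0.35
    nmda_fraction: float = 0.5
    e_gaba: float = -70.0
    e_exc: float = 0.0
    std_enabled: bool = True

    def __post_init__(self):
        if not (0 <= self.nmda_fraction <= 1):
            raise ValueError("nmda_fraction must be in [0, 1]")
        if self.g_in < 0 or self.g_ex < 0:
            raise ValueError("conductances must be >= 0")


@dataclass(frozen=True)
class SimResult:
    """Output of one CN simulation."""

    train: SpikeTrain
    vm: np.ndarray | None = None
    t: np.ndarray | None = None
    mean_i_inh: float = 0.0
    mean_i_exc: float = 0.0
    mean_i_net: float = 0.0


# ---------------------------------------------------------------------------
# Synaptic conductance waveforms
# ---------------------------------------------------------------------------


def _impulse_array(trains, weights_list, n, dt):
    """Bin weighted spike impulses from many trains onto one grid."""
    x = np.zeros(n)
    for tr, w in zip(trains, weights_list):
        idx = np.minimum((tr.times / dt).astype(np.int64), n - 1)
        np.add.at(x, idx, w)
    return x


def _dual_exp_filter(x, kin: SynapseKinetics, dt):
    """Exact unit-peak dual-exponential shot noise via two IIR filters."""
    ad = np.exp(-dt / kin.tau_decay)
    ar = np.exp(-dt / kin.tau_rise)
    yd = lfilter([1.0], [1.0, -ad], x)
    yr = lfilter([1.0], [1.0, -ar], x)
    return (yd - yr) / kin.peak_norm


def total_conductances(
    pc_trains,
    mf_trains,
    layout: SynapseLayout,
    depression: DepressionParams | None,
    duration: float,
    dt: float,
):
    """Summed somatic GABA, AMPA and NMDA conductance waveforms (nS)."""
    n = int(round(duration / dt))
    if depression is None:
        depression = default_depression_params()
    if layout.std_enabled:
        pc_weights = [depression_weights(tr.times, depression) for tr in pc_trains]
    else:
        pc_weights = [np.ones(tr.n_spikes) for tr in pc_trains]
    x_in = _impulse_array(pc_trains, pc_weights, n, dt)
    g_gaba = layout.g_in * layout.w_in * _dual_exp_filter(x_in, GABA_KINETICS, dt)

    mf_weights = [np.ones(tr.n_spikes) for tr in mf_trains]
    x_ex = _impulse_array(mf_trains, mf_weights, n, dt)
    f = layout.nmda_fraction
    g_ampa_unit = layout.g_ex * layout.w_ex * (1.0 - f) / 0.5
    # NMDA peak set so its charge share (pre Mg block) equals nmda_fraction
    charge_ratio = AMPA_KINETICS.unit_integral / NMDA_KINETICS.unit_integral
    g_nmda_unit = layout.g_ex * layout.w_ex * (f / 0.5) * charge_ratio
    g_ampa = g_ampa_unit * _dual_exp_filter(x_ex, AMPA_KINETICS, dt)
    g_nmda = g_nmda_unit * _dual_exp_filter(x_ex, NMDA_KINETICS, dt)
    return g_gaba, g_ampa, g_nmda


# ---------------------------------------------------------------------------
# Membrane integration (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _integrate(
    g_gaba, g_ampa, g_nmda, dt_ms,
    cap, g_leak, e_leak, g_na, e_na, g_kdr, e_k,
    g_sk_max, ca_inc, tau_ca_ms, sk_half, i_tonic,
    e_gaba, e_exc, i_inject, v0, record_vm,
):
    n = g_gaba.size
    v = v0
    # gating state at rest
    h = 0.78
    nk = 0.09
    ca = 0.0
    spikes = np.empty(n // 20 + 16, dtype=np.float64)
    n_sp = 0
    vm = np.zeros(n if record_vm else 1, dtype=np.float64)
    vm[0] = v
    last_v = v
    sum_ii = 0.0
    sum_ie = 0.0
    phi = 5.0
    sk4 = sk_half ** 4
    for i in range(n):
        # rate functions (V mV, rates 1/ms)
        vv = v
        dm = vv + 35.0
        if abs(dm) < 1e-6:
            am = 1.0
        else:
            am = 0.1 * dm / (1.0 - np.exp(-dm / 10.0))
        bm = 4.0 * np.exp(-(vv + 60.0) / 18.0)
        m_inf = am / (am + bm)

        ah = 0.07 * np.exp(-(vv + 58.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(vv + 28.0) / 10.0))
        dn = vv + 34.0
        if abs(dn) < 1e-6:
            an = 0.1
        else:
            an = 0.01 * dn / (1.0 - np.exp(-dn / 10.0))
        bn = 0.125 * np.exp(-(vv + 44.0) / 80.0)

        # exponential-Euler gating updates
        th = 1.0 / (phi * (ah + bh))
        h_inf = ah / (ah + bh)
        h = h_inf + (h - h_inf) * np.exp(-dt_ms / th)
        tn = 1.0 / (phi * (an + bn))
        n_inf = an / (an + bn)
        nk = n_inf + (nk - n_inf) * np.exp(-dt_ms / tn)
        ca = ca * np.exp(-dt_ms / tau_ca_ms)

        ca4 = ca ** 4
        s_sk = ca4 / (ca4 + sk4)

        gna = g_na * m_inf * m_inf * m_inf * h
        gk = g_kdr * nk ** 4
        gsk = g_sk_max * s_sk
        # Mg block (Jahr-Stevens, 1 mM)
        b_mg = 1.0 / (1.0 + np.exp(-0.062 * vv) / 3.57)
        g_e = g_ampa[i] + g_nmda[i] * b_mg
        g_i = g_gaba[i]

        g_tot = g_leak + gna + gk + gsk + g_i + g_e
        num = (
            g_leak * e_leak + gna * e_na + (gk + gsk) * e_k
            + g_i * e_gaba + g_e * e_exc + i_tonic + i_inject
        )
        v_inf = num / g_tot
        # exponential Euler on V: tau_m in ms = cap(pF)/g_tot(nS)
        tau_m = cap / g_tot
        v = v_inf + (v - v_inf) * np.exp(-dt_ms / tau_m)

        sum_ii += g_i * (v - e_gaba)
        sum_ie += g_e * (v - e_exc)

        if last_v < 0.0 <= v:
            if n_sp >= spikes.size:
                tmp = np.empty(spikes.size * 2, dtype=np.float64)
                tmp[: spikes.size] = spikes
                spikes = tmp
            spikes[n_sp] = (i + 1) * dt_ms * 1e-3
            n_sp += 1
            ca += ca_inc
        last_v = v
        if record_vm:
            vm[i] = v
    if not record_vm:
        vm[0] = v  # final state, used by the divergence check
    return spikes[:n_sp], vm, sum_ii / n, sum_ie / n


def simulate(
    pc_trains: list[SpikeTrain],
    mf_trains: list[SpikeTrain],
    layout: SynapseLayout | None = None,
    params: NeuronParams | None = None,
    duration: float | None = None,
    dt_ms: float = DT_MS_DEFAULT,
    depression: DepressionParams | None = None,
    i_inject: float = 0.0,
    record_vm: bool = False,
) -> SimResult:
    """Integrate the CN point model driven by PC and MF spike trains.

    *duration* defaults to the common duration of the input trains.
    ``i_inject`` is an additional constant current (pA).  With
    ``record_vm=True`` the full Vm trace is returned.  Mean inhibitory and
    excitatory synaptic currents (pA) are always reported.
    """
    if dt_ms > 0.05:
        raise ValueError("dt_ms must be <= 0.05 ms")
    layout = layout or SynapseLayout()
    params = params or NeuronParams()
    if duration is None:
        durs = [tr.duration for tr in pc_trains + mf_trains]
        duration = min(durs) if durs else 1.0
    dt = dt_ms * 1e-3
    g_gaba, g_ampa, g_nmda = total_conductances(
        pc_trains, mf_trains, layout, depression, duration, dt
    )
    spikes, vm, mii, mie = _integrate(
        g_gaba, g_ampa, g_nmda, dt_ms,
        params.capacitance, params.g_leak, params.e_leak,
        params.g_na, params.e_na, params.g_kdr, params.e_k,
        params.g_sk_max, params.ca_increment, params.tau_ca * 1e3,
        params.sk_half, params.tonic_drive,
        layout.e_gaba, layout.e_exc, i_inject, -60.0, record_vm,
    )
    if not np.isfinite(vm[-1]) or (spikes.size and not np.all(np.isfinite(spikes))):
        raise FloatingPointError("CN integration diverged; reduce dt or check inputs")
    train = SpikeTrain(times=spikes[spikes < duration], duration=duration, label="cn_model")
    t = np.arange(g_gaba.size) * dt if record_vm else None
    return SimResult(
        train=train,
        vm=vm if record_vm else None,
        t=t,
        mean_i_inh=float(mii),
        mean_i_exc=float(mie),
        # outward-positive convention: net = inhibitory + excitatory
        mean_i_net=float(mii + mie),
    )


def f_i_curve(
    params: NeuronParams | None = None,
    currents: np.ndarray | None = None,
    equilibration: float = 1.0,
    measure: float = 1.0,
    dt_ms: float = DT_MS_DEFAULT,
) -> pd.DataFrame:
    """Firing rate vs injected current with zero synaptic input.

    Rate is the inverse mean ISI over *measure* seconds following
    *equilibration* seconds at the same current.
    """
    params = params or NeuronParams()
    if currents is None:
        currents = np.arange(0.0, 201.0, 20.0)
    duration = equilibration + measure
    rows = []
    for i_amp in currents:
        res = simulate(
            [], [], layout=SynapseLayout(), params=params,
            duration=duration, dt_ms=dt_ms, i_inject=float(i_amp),
        )
        t = res.train.times
        t = t[t >= equilibration]
        rate = (t.size - 1) / (t[-1] - t[0]) if t.size >= 2 else 0.0
        rows.append({"current_pa": float(i_amp), "rate_hz": float(rate)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scan harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanSpec:
    """Grid specification for CN input-parameter scans.

    Each combination of the listed values is one scan cell; every cell
    records its manifest (parameters and seed).  ``duration`` applies to
    every cell.
    """

    g_in: tuple = (16.0,)
    g_ex: tuple = (3.5,)
    sf: tuple = (0.5,)
    bms: tuple = (0.0,)
    bmf: tuple = (0.0,)
    n_pc: tuple = (50,)
    sk_scale: tuple = (1.0,)
    duration: float = 20.0
    pc_rate: float = 64.9
    pc_lv: float = 0.31
    mf_rate: float = 20.4
    mf_lv: float = 0.7
    n_mf: int = 48
    seed: int = 0


def _mf_population(master_mf: RateTemplate, spec: ScanSpec, seed: int):
    pop_spec = PopulationSpec(
        n_trains=spec.n_mf, sf=1.0, bmf=0.0, bms=0.0,
        uniform_rate=spec.mf_rate, lv=spec.mf_lv, seed=seed,
    )
    return build_population(master_mf, pop_spec)


def run_scan(
    spec: ScanSpec,
    master_pc: RateTemplate,
    master_mf: RateTemplate | None = None,
    events: EventSeries | None = None,
    waveform: ModulationWaveform | None = None,
    params: NeuronParams | None = None,
    psth_smoothing: float = 0.03,
) -> pd.DataFrame:
    """Run the CN model over the scan grid and summarize each cell.

    For every grid cell an AST population is built from the master
    templates, the CN model is simulated, and the output spike train is
    summarized (rate, CV, LV, and — when events are supplied — the PSTH
    modulation score against shift controls).  Per-cell failures are
    recorded in the ``error`` column and the scan continues.
    """
    from .event_psth import compute_psth, score_modulation, shifted_controls

    params = params or NeuronParams()
    master_mf = master_mf or rescale_to_rate(master_pc, spec.mf_rate)
    rows = []
    cell = 0
    for n_pc in spec.n_pc:
        for g_in in spec.g_in:
            for g_ex in spec.g_ex:
                for sf in spec.sf:
                    for bms in spec.bms:
                        for bmf in spec.bmf:
                            for sk in spec.sk_scale:
                                cell += 1
                                seed = spec.seed * 100003 + cell
                                row = {
                                    "n_pc": n_pc, "g_in": g_in, "g_ex": g_ex,
                                    "sf": sf, "bms": bms, "bmf": bmf,
                                    "sk_scale": sk, "seed": seed,
                                    "duration": spec.duration,
                                }
                                try:
                                    row.update(_run_cell(
                                        spec, master_pc, master_mf, events,
                                        waveform, params, n_pc, g_in, g_ex,
                                        sf, bms, bmf, sk, seed, psth_smoothing,
                                    ))
                                    row["error"] = ""
                                except Exception as exc:  # noqa: BLE001 — scan must continue
                                    row["error"] = f"{type(exc).__name__}: {exc}"
                                rows.append(row)
    return pd.DataFrame(rows)


def _run_cell(
    spec, master_pc, master_mf, events, waveform, params,
    n_pc, g_in, g_ex, sf, bms, bmf, sk, seed, psth_smoothing,
):
    from .event_psth import compute_psth, score_modulation, shifted_controls

    pc_spec = PopulationSpec(
        n_trains=n_pc, sf=sf, bmf=bmf, bms=bms,
        uniform_rate=spec.pc_rate, lv=spec.pc_lv, seed=seed,
    )
    pc_trains = build_population(master_pc, pc_spec, waveform=waveform, events=events)
    mf_trains = _mf_population(master_mf, spec, seed + 1)
    # 500 inputs use g_in / 10 to keep the mean conductance matched
    eff_g_in = g_in / 10.0 if n_pc == 500 else g_in
    layout = SynapseLayout(n_pc=n_pc, n_mf=spec.n_mf, g_in=eff_g_in, g_ex=g_ex)
    cell_params = replace(params, g_sk_max=params.g_sk_max * sk)
    res = simulate(pc_trains, mf_trains, layout, cell_params,
                   duration=spec.duration)
    out = res.train
    row = {
        "rate_hz": out.mean_rate,
        "mean_i_inh": res.mean_i_inh,
        "mean_i_exc": res.mean_i_exc,
    }
    if out.n_spikes >= 3:
        row["cv"] = compute_cv(out)
        row["lv"] = compute_lv(out)
    else:
        row["cv"] = np.nan
        row["lv"] = np.nan
    if events is not None and out.n_spikes >= 10 and events.n_events >= 10:
        psth = compute_psth(out, events, smoothing=psth_smoothing)
        controls = shifted_controls(
            out, events, n_controls=100, smoothing=psth_smoothing, seed=seed,
        )
        score = score_modulation(psth, controls)
        row["psth_peak_hz"] = score.peak_rate_increase
        row["psth_peak_pct"] = score.peak_percent
        row["psth_spikes_per_event"] = score.spikes_per_event
        row["psth_significant"] = score.found
    return row


def sk_scan(
    sk_scales,
    master_pc: RateTemplate,
    master_mf: RateTemplate | None = None,
    events: EventSeries | None = None,
    waveform: ModulationWaveform | None = None,
    base_spec: ScanSpec | None = None,
    params: NeuronParams | None = None,
) -> pd.DataFrame:
    """Scan SK conductance with *identical* AST inputs across levels.

    Unlike :func:`run_scan`, the input populations are generated once and
    reused for every SK level, isolating the intrinsic effect.
    """
    from .event_psth import compute_psth, score_modulation, shifted_controls

    spec = base_spec or ScanSpec()
    params = params or NeuronParams()
    master_mf = master_mf or rescale_to_rate(master_pc, spec.mf_rate)
    seed = spec.seed * 100003 + 1
    pc_spec = PopulationSpec(
        n_trains=spec.n_pc[0], sf=spec.sf[0], bmf=spec.bmf[0], bms=spec.bms[0],
        uniform_rate=spec.pc_rate, lv=spec.pc_lv, seed=seed,
    )
    pc_trains = build_population(master_pc, pc_spec, waveform=waveform, events=events)
    mf_trains = _mf_population(master_mf, spec, seed + 1)
    layout = SynapseLayout(g_in=spec.g_in[0], g_ex=spec.g_ex[0], n_mf=spec.n_mf)
    rows = []
    for sk in sk_scales:
        cell_params = replace(params, g_sk_max=params.g_sk_max * float(sk))
        res = simulate(pc_trains, mf_trains, layout, cell_params, duration=spec.duration)
        out = res.train
        row = {"sk_scale": float(sk), "rate_hz": out.mean_rate, "seed": seed}
        row["cv"] = compute_cv(out) if out.n_spikes >= 3 else np.nan
        row["lv"] = compute_lv(out) if out.n_spikes >= 3 else np.nan
        if events is not None and out.n_spikes >= 10:
            psth = compute_psth(out, events, smoothing=0.03)
            controls = shifted_controls(out, events, n_controls=100,
                                        smoothing=0.03, seed=seed)
            score = score_modulation(psth, controls)
            row["psth_peak_hz"] = score.peak_rate_increase
            row["psth_peak_pct"] = score.peak_percent
        rows.append(row)
    return pd.DataFrame(rows)
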