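"""Populations of ASTs with controlled rate covariance and event modulation.

All trains in a population derive from one *master* rate template.  Three
manipulations control the population code:

* **SF (shift fraction)** — each train's template is a normalized mixture
  ``(1−SF)·master + SF·circshift(master, random)``.  SF = 0 gives full rate
  covariance across the population; SF = 1 gives none.  The expected
  pairwise template correlation follows the mixture formula
  ``(1−SF)² / ((1−SF)² + SF²)``.
* **BMF / BMS (behavioral modulation fraction / strength)** — a unit-mean
  event-locked modulation waveform (the normalized PSTH shape of the
  behavior) is injected multiplicatively at each event time into the first
  ``round(BMF·n)`` trains of a seeded shuffle, with gain BMS.
* **Rate assignment** — all trains at one uniform rate, or each at a rate
  drawn from a supplied 'natural' distribution of recorded rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ast_sampler import SamplerConfig, kappa_from_lv, sample_ast
from .io_fixtures import EventSeries, SpikeTrain
from .rate_template import RateTemplate, rescale_to_rate

__all__ = [
    "PopulationSpec",
    "ModulationWaveform",
    "cosine_modulation_waveform",
    "respiratory_modulation_waveform",
    "mix_shifted_template",
    "inject_event_modulation",
    "build_population",
    "modulated_flags",
]


@dataclass(frozen=True)
class ModulationWaveform:
    """Unit-mean event-locked rate-modulation factor m(τ) over a lag window.

    ``factor`` must be non-negative with mean 1 (±1e-6); ``lags`` spans
    ``[-W, +W]`` seconds on a uniform grid.
    """

    lags: np.ndarray
    factor: np.ndarray

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float).ravel()
        factor = np.asarray(self.factor, dtype=float).ravel()
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "factor", factor)
        if lags.size != factor.size:
            raise ValueError("lags and factor must have equal length")
        if np.any(factor < 0):
            raise ValueError("modulation factor must be non-negative")
        if abs(factor.mean() - 1.0) > 1e-6:
            raise ValueError("modulation factor must have unit mean")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


def cosine_modulation_waveform(
    depth: float = 0.114,
    half_width: float = 0.121,
    window: float = 0.5,
    dt: float = 1e-3,
    phase: str = "trough",
) -> ModulationWaveform:
    """Raised-cosine event-locked modulation with a given fractional depth.

    The default emulates a typical respiratory modulation: an 11.4% rate
    trough centered on the event, one half respiratory cycle wide (121 ms),
    inside a ±500 ms window.  ``phase='peak'`` flips the sign.  The waveform
    is shifted to unit mean after construction so the depth refers to the
    trough (or peak) relative to the waveform mean.
    """
    n = int(round(window / dt))
    lags = np.arange(-n, n + 1) * dt
    bump = np.zeros_like(lags)
    inside = np.abs(lags) <= half_width
    bump[inside] = 0.5 * (1.0 + np.cos(np.pi * lags[inside] / half_width))
    sign = -1.0 if phase == "trough" else 1.0
    # raw amplitude chosen so that after unit-mean normalization the
    # extremum sits exactly at (1 + sign·depth) × mean
    m_bar = bump.mean()
    d_eff = depth / (1.0 - (1.0 + sign * depth) * m_bar)
    factor = 1.0 + sign * d_eff * bump
    factor = np.clip(factor, 0.0, None)
    factor /= factor.mean()
    return ModulationWaveform(lags=lags, factor=factor)


def respiratory_modulation_waveform(
    depth: float = 0.114,
    period: float = 0.2564,
    window: float = 0.5,
    decay: float = 0.25,
    dt: float = 1e-3,
    phase: str = "trough",
) -> ModulationWaveform:
    """Rhythmic event-locked modulation shaped like a measured respiratory
    PSTH: a cosinusoid at the respiratory period whose side cycles decay
    away from the event (interval jitter dephases the rhythm at longer
    lags).

    ``depth`` is the fractional rate decrease (``phase='trough'``) or
    increase (``'peak'``) at lag zero, relative to the waveform mean; the
    default 11.4% trough at a 256 ms period emulates a typical modulated
    Purkinje cell.
    """
    n = int(round(window / dt))
    lags = np.arange(-n, n + 1) * dt
    bump = np.cos(2.0 * np.pi * lags / period) * np.exp(-np.abs(lags) / decay)
    sign = -1.0 if phase == "trough" else 1.0
    m_bar = bump.mean()
    d_eff = depth / (1.0 - (1.0 + sign * depth) * m_bar)
    factor = np.clip(1.0 + sign * d_eff * bump, 0.0, None)
    factor /= factor.mean()
    return ModulationWaveform(lags=lags, factor=factor)


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of an AST population derived from one master template.

    ``rate_mode='uniform'`` assigns ``uniform_rate`` to every train;
    ``'natural'`` draws each train's rate from ``natural_rates``.
    """

    n_trains: int = 50
    sf: float = 0.5
    bmf: float = 0.0
    bms: float = 0.0
    rate_mode: str = "uniform"
    uniform_rate: float = 64.9
    natural_rates: tuple | None = None
    lv: float = 0.31
    t_ref: float = 1e-3
    refractory_correction: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.sf <= 1):
            raise ValueError("sf must be in [0, 1]")
        if not (0 <= self.bmf <= 1):
            raise ValueError("bmf must be in [0, 1]")
        if not (0 <= self.bms <= 2):
            raise ValueError("bms must be in [0, 2]")
        if self.rate_mode not in ("uniform", "natural"):
            raise ValueError("rate_mode must be 'uniform' or 'natural'")
        if self.rate_mode == "natural" and not self.natural_rates:
            raise ValueError("natural rate mode requires a natural_rates list")
        if self.n_trains < 1:
            raise ValueError("n_trains must be >= 1")

    @property
    def n_modulated(self) -> int:
        return int(round(self.bmf * self.n_trains))


def mix_shifted_template(
    master: RateTemplate, sf: float, shift: float
) -> RateTemplate:
    """Mix the master template with a circularly shifted copy of itself.

    On unit-mean normalized rates,
    ``out_norm = (1−sf)·master_norm + sf·circshift(master_norm, shift)``,
    rescaled back to the master's mean rate.  ``sf = 0`` returns the master
    unchanged; ``sf = 1`` yields a template uncorrelated with the master
    for shifts well beyond the template's correlation time.  The circular
    shift preserves the template's marginal statistics exactly.
    """
    if not (0 <= sf <= 1):
        raise ValueError("sf must be in [0, 1]")
    if sf == 0:
        return master
    norm = master.normalized()
    k = int(round(shift / master.dt)) % norm.size
    mixed = (1.0 - sf) * norm + sf * np.roll(norm, k)
    out = master.with_values(np.clip(mixed, 0.0, None))
    return rescale_to_rate(out, master.mean_rate)


def inject_event_modulation(
    template: RateTemplate,
    waveform: ModulationWaveform,
    events: EventSeries,
    bms: float = 1.0,
) -> RateTemplate:
    """Inject event-locked rate modulation into a template.

    A multiplicative factor ``M(t) = Π_j [1 + bms·(m(t − e_j) − 1)]`` is
    applied to the template (product composition handles overlapping event
    windows), and the result is rescaled to the original mean rate.
    ``bms = 0`` is the identity.
    """
    if bms < 0:
        raise ValueError("bms must be >= 0")
    if np.any(waveform.factor < 0):
        raise ValueError("waveform must be non-negative")
    if bms == 0 or events.n_events == 0:
        return template
    dt = template.dt
    n = template.n
    log_m = np.zeros(n)
    per_event = np.clip(1.0 + bms * (waveform.factor - 1.0), 1e-6, None)
    log_pe = np.log(per_event)
    w = waveform.lags.size
    lag0 = waveform.lags[0]
    for e in events.times:
        start = int(round((e + lag0) / dt))
        lo = max(0, start)
        hi = min(n, start + w)
        if hi <= lo:
            continue
        log_m[lo:hi] += log_pe[lo - start : hi - start]
    modulated = template.values * np.exp(log_m)
    out = template.with_values(modulated)
    return rescale_to_rate(out, template.mean_rate)


def modulated_flags(spec: PopulationSpec) -> np.ndarray:
    """Boolean mask of the trains carrying the event-locked modulation.

    Exactly ``round(bmf × n_trains)`` trains are flagged: the first
    ``n_modulated`` indices of a seeded shuffle, so sweeps over BMF with a
    fixed seed are nested.
    """
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(spec.n_trains)
    flags = np.zeros(spec.n_trains, dtype=bool)
    flags[order[: spec.n_modulated]] = True
    return flags


def build_population(
    master: RateTemplate,
    spec: PopulationSpec,
    waveform: ModulationWaveform | None = None,
    events: EventSeries | None = None,
) -> list[SpikeTrain]:
    """Build a population of ASTs from a master template.

    Per train: mix with an independently shifted copy (SF), optionally
    inject the event-locked modulation (for the flagged BMF subset, at gain
    BMS), rescale to the assigned rate, and sample as a gamma AST at
    ``κ = kappa_from_lv(spec.lv)``.  Deterministic under ``spec.seed``.
    """
    if spec.bmf > 0 and spec.bms > 0 and (waveform is None or events is None):
        raise ValueError("bmf > 0 requires both a waveform and events")
    rng = np.random.default_rng(spec.seed)
    flags = modulated_flags(spec)
    kappa = kappa_from_lv(spec.lv)
    if spec.rate_mode == "natural":
        rates = rng.choice(np.asarray(spec.natural_rates, dtype=float),
                           size=spec.n_trains, replace=True)
    else:
        rates = np.full(spec.n_trains, spec.uniform_rate)
    trains = []
    for i in range(spec.n_trains):
        shift = rng.uniform(0.0, master.duration)
        tpl = mix_shifted_template(master, spec.sf, shift)
        if flags[i] and spec.bms > 0:
            tpl = inject_event_modulation(tpl, waveform, events, spec.bms)
        tpl = rescale_to_rate(tpl, rates[i])
        cfg = SamplerConfig(
            kappa=kappa,
            t_ref=spec.t_ref,
            refractory_correction=spec.refractory_correction,
            seed=int(rng.integers(2**31 - 1)),
        )
        tr = sample_ast(tpl, cfg)
        trains.append(tr.with_label(f"ast_{i:03d}" + ("_mod" if flags[i] else "")))
    return trains
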