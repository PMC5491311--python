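"""Population builder: SF mixing, event modulation, rate assignment."""

import numpy as np
import pytest

from ratefab.io_fixtures import EventSeries, SpikeTrain
from ratefab.population_builder import (
    ModulationWaveform,
    PopulationSpec,
    build_population,
    cosine_modulation_waveform,
    inject_event_modulation,
    mix_shifted_template,
    modulated_flags,
    respiratory_modulation_waveform,
)
from ratefab.rate_template import RateTemplate


def _pairwise_template_corr(tpls):
    vals = [t.values - t.values.mean() for t in tpls]
    cors = []
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            a, b = vals[i], vals[j]
            cors.append((a @ b) / np.sqrt((a @ a) * (b @ b)))
    return float(np.mean(cors))


class TestWaveforms:
    @pytest.mark.parametrize("maker", [cosine_modulation_waveform,
                                       respiratory_modulation_waveform])
    def test_unit_mean_and_exact_depth(self, maker):
        w = maker(depth=0.114)
        assert w.factor.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w.factor >= 0)
        assert 1 - w.factor.min() / w.factor.mean() == pytest.approx(0.114, abs=1e-6)

    def test_peak_phase(self):
        w = respiratory_modulation_waveform(depth=0.2, phase="peak")
        assert w.factor.max() / w.factor.mean() - 1 == pytest.approx(0.2, abs=1e-6)

    def test_invalid_waveform_rejected(self):
        with pytest.raises(ValueError, match="unit mean"):
            ModulationWaveform(lags=np.arange(3) * 1e-3, factor=np.array([2.0, 2, 2]))
        with pytest.raises(ValueError, match="non-negative"):
            ModulationWaveform(lags=np.arange(3) * 1e-3,
                               factor=np.array([-0.5, 1.5, 2.0]))


class TestMixShiftedTemplate:
    def test_sf_zero_identity(self, master_115s):
        out = mix_shifted_template(master_115s, 0.0, 17.3)
        np.testing.assert_array_equal(out.values, master_115s.values)

    def test_sf_one_decorrelates(self, master_115s):
        shifted = mix_shifted_template(master_115s, 1.0, 50.0)
        a = master_115s.values - master_115s.mean_rate
        b = shifted.values - shifted.mean_rate
        r = (a @ b) / np.sqrt((a @ a) * (b @ b))
        assert abs(r) < 0.1

    def test_marginal_statistics_preserved(self, master_115s):
        shifted = mix_shifted_template(master_115s, 1.0, 50.0)
        assert shifted.mean_rate == pytest.approx(master_115s.mean_rate, rel=1e-9)
        assert shifted.values.std() == pytest.approx(master_115s.values.std(),
                                                     rel=1e-6)

    @pytest.mark.parametrize("sf", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_mixture_correlation_formula(self, master_115s, sf):
        """Pairwise template correlation follows
        (1−SF)² / ((1−SF)² + SF²) for independent shifts."""
        rng = np.random.default_rng(0)
        tpls = [mix_shifted_template(master_115s, sf,
                                     rng.uniform(0, master_115s.duration))
                for _ in range(8)]
        pred = (1 - sf) ** 2 / ((1 - sf) ** 2 + sf**2)
        assert _pairwise_template_corr(tpls) == pytest.approx(pred, abs=0.05)


class TestInjectEventModulation:
    def test_bms_zero_identity(self, master_115s, events_115s):
        w = respiratory_modulation_waveform()
        out = inject_event_modulation(master_115s, w, events_115s, bms=0.0)
        np.testing.assert_array_equal(out.values, master_115s.values)

    def test_single_event_rectangular_factor(self):
        """A rectangular 1.2× factor over 100 ms elevates the local rate by
        20% before the mean-rate rescale."""
        n_w = 501
        factor = np.ones(n_w)
        factor[200:300] = 1.2
        factor /= factor.mean()
        w = ModulationWaveform(lags=(np.arange(n_w) - 250) * 1e-3, factor=factor)
        tpl = RateTemplate(dt=1e-3, values=np.full(10_000, 50.0), duration=10.0)
        ev = EventSeries([5.0], 10.0)
        out = inject_event_modulation(tpl, w, ev, bms=1.0)
        inside = out.values[4955:5045].mean()
        # compare against the unelevated part of the event window (the
        # unit-mean normalization scales the whole window uniformly)
        baseline = out.values[4800:4900].mean()
        assert inside / baseline == pytest.approx(1.2, rel=1e-3)

    def test_mean_rate_preserved(self, master_115s, events_115s):
        w = respiratory_modulation_waveform()
        out = inject_event_modulation(master_115s, w, events_115s, bms=1.0)
        assert out.mean_rate == pytest.approx(master_115s.mean_rate, rel=1e-9)

    def test_trough_depth_recovered_in_psth(self):
        """A population sampled from templates carrying an 11.4% trough
        reproduces that depth in its own event-aligned PSTH (±2 pp),
        measured with non-overlapping event windows."""
        from ratefab.event_psth import compute_psth, shifted_controls

        dur = 115.0
        ev = EventSeries(np.arange(1.0, dur - 1, 0.6), dur)
        wave = cosine_modulation_waveform(depth=0.114, half_width=0.121,
                                          window=0.25)
        master = RateTemplate(dt=1e-3, values=np.full(115_000, 64.9),
                              duration=dur)
        spec = PopulationSpec(n_trains=30, sf=0.0, bmf=1.0, bms=1.0, seed=3)
        pop = build_population(master, spec, waveform=wave, events=ev)
        pooled = SpikeTrain(np.sort(np.concatenate([t.times for t in pop])), dur)
        psth = compute_psth(pooled, ev, smoothing=0.03)
        ctl = shifted_controls(pooled, ev, smoothing=0.03, seed=5)
        c = np.abs(psth.lags) < 0.03
        depth = 1 - psth.rate[c].min() / ctl.mean[c].mean()
        assert depth == pytest.approx(0.114, abs=0.02)


class TestBuildPopulation:
    def test_modulated_count_exact(self):
        spec = PopulationSpec(n_trains=50, bmf=0.2, seed=0)
        assert spec.n_modulated == 10
        assert modulated_flags(spec).sum() == 10

    def test_bmf_sweeps_nested(self):
        low = modulated_flags(PopulationSpec(n_trains=50, bmf=0.2, seed=4))
        high = modulated_flags(PopulationSpec(n_trains=50, bmf=0.5, seed=4))
        assert np.all(high[low])  # the 20% subset is inside the 50% subset

    def test_rates_within_tolerance(self, master_115s):
        pop = build_population(master_115s,
                               PopulationSpec(n_trains=10, sf=0.5,
                                              uniform_rate=64.9, seed=2))
        rates = [tr.mean_rate for tr in pop]
        assert np.mean(rates) == pytest.approx(64.9, rel=0.05)

    def test_natural_rate_mode(self, master_115s):
        rates = (30.0, 50.0, 80.0)
        pop = build_population(
            master_115s,
            PopulationSpec(n_trains=6, sf=0.5, rate_mode="natural",
                           natural_rates=rates, seed=1),
        )
        for tr in pop:
            assert min(abs(tr.mean_rate - r) / r for r in rates) < 0.1

    def test_natural_mode_requires_rates(self):
        with pytest.raises(ValueError, match="natural_rates"):
            PopulationSpec(n_trains=5, rate_mode="natural")

    def test_determinism(self, master_20s):
        spec = PopulationSpec(n_trains=4, sf=0.5, seed=9)
        a = build_population(master_20s, spec)
        b = build_population(master_20s, spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.times, y.times)

    def test_count_correlations_shared_vs_shifted(self, master_115s):
        """sf=0 siblings share all rate fluctuations (positive 100-ms count
        correlations); sf=1 siblings are uncorrelated."""
        def mean_corr(sf, seed):
            pop = build_population(master_115s,
                                   PopulationSpec(n_trains=6, sf=sf, seed=seed))
            edges = np.arange(0, 115.0 + 0.1, 0.1)
            counts = [np.histogram(tr.times, bins=edges)[0] for tr in pop]
            cors = []
            for i in range(len(counts)):
                for j in range(i + 1, len(counts)):
                    cors.append(np.corrcoef(counts[i], counts[j])[0, 1])
            return float(np.mean(cors))

        assert mean_corr(0.0, 0) > 0.15
        assert abs(mean_corr(1.0, 1)) < 0.05

    def test_psth_shows_injected_waveform(self, master_115s, events_115s):
        """With bms>0 the population PSTH matches the injected waveform
        shape (cosine similarity > 0.9 after smoothing)."""
        from ratefab.event_psth import compute_psth, shifted_controls

        wave = respiratory_modulation_waveform()
        pop = build_population(
            master_115s,
            PopulationSpec(n_trains=30, sf=0.0, bmf=1.0, bms=1.0, seed=5),
            waveform=wave, events=events_115s,
        )
        pooled = SpikeTrain(
            np.sort(np.concatenate([t.times for t in pop])), 115.0
        )
        psth = compute_psth(pooled, events_115s, smoothing=0.03)
        ctl = shifted_controls(pooled, events_115s, smoothing=0.03, seed=1)
        resp = psth.rate / ctl.mean - 1.0
        target = np.interp(psth.lags, wave.lags, wave.factor) - 1.0
        cos = (resp @ target) / np.sqrt((resp @ resp) * (target @ target))
        assert cos > 0.9

    def test_requires_waveform_when_modulating(self, master_20s):
        with pytest.raises(ValueError, match="waveform"):
            build_population(master_20s,
                             PopulationSpec(n_trains=5, bmf=0.5, bms=1.0, seed=0))
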