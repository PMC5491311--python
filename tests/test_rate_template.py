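"""Rate-template construction and algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ratefab.io_fixtures import SpikeTrain
from ratefab.rate_template import (
    KernelRule,
    RateTemplate,
    build_template,
    fast_component,
    fluctuation_gain,
    rescale_to_rate,
    slow_component,
)


@pytest.fixture()
def surrogate_template(master_115s):
    return master_115s


class TestBuildTemplate:
    def test_needs_two_spikes(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_template(SpikeTrain(times=[0.5], duration=1.0))

    def test_periodic_train_constant_rate(self):
        tr = SpikeTrain(times=np.arange(0.02, 10.0, 0.02), duration=10.0)
        tpl = build_template(tr)
        interior = tpl.values[1000:9000]
        np.testing.assert_allclose(interior, 50.0, rtol=0.02)

    def test_mass_conservation(self, pc_train_115s, master_115s):
        assert master_115s.integral() == pytest.approx(
            pc_train_115s.n_spikes, rel=0.02
        )

    def test_poisson_mean_rate(self):
        rng = np.random.default_rng(0)
        tr = SpikeTrain(np.sort(rng.uniform(0, 60.0, 60 * 65)), 60.0)
        tpl = build_template(tr, KernelRule(adaptive_scale=1.0))
        assert tpl.mean_rate == pytest.approx(65.0, rel=0.03)

    def test_fixed_kernel_mode(self):
        tr = SpikeTrain(times=np.arange(0.02, 10.0, 0.02), duration=10.0)
        tpl = build_template(tr, KernelRule(mode="fixed", fixed_sigma=0.05))
        assert tpl.integral() == pytest.approx(tr.n_spikes, rel=0.02)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mass_conservation_random_trains(self, seed):
        """Kernel truncation at the record edges is renormalized per spike,
        so the template integral equals the spike count for any train."""
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 200)
        times = np.sort(rng.uniform(0, 5.0, n))
        times = times[np.concatenate([[True], np.diff(times) > 1e-6])]
        if times.size < 2:
            return
        tpl = build_template(SpikeTrain(times, 5.0))
        assert np.all(tpl.values >= 0)
        assert tpl.integral() == pytest.approx(times.size, rel=0.02)


class TestSlowFast:
    def test_constant_invariance(self):
        tpl = RateTemplate(dt=1e-3, values=np.full(5000, 40.0), duration=5.0)
        out = slow_component(tpl, 0.1)
        np.testing.assert_allclose(out.values, 40.0, rtol=1e-6)

    def test_mean_preserved(self, surrogate_template):
        out = slow_component(surrogate_template, 0.1)
        assert out.mean_rate == pytest.approx(surrogate_template.mean_rate, rel=0.01)

    @pytest.mark.parametrize("f0,sigma", [(10.0, 0.02), (5.0, 0.05)])
    def test_sinusoid_gaussian_transfer_gain(self, f0, sigma):
        t = np.arange(100_000) * 1e-3
        tpl = RateTemplate(dt=1e-3, values=50 + 10 * np.sin(2 * np.pi * f0 * t),
                           duration=100.0)
        out = slow_component(tpl, sigma)
        interior = out.values[20_000:80_000]
        measured_gain = (interior.max() - interior.min()) / 20.0
        analytic = np.exp(-2 * np.pi**2 * f0**2 * sigma**2)
        assert measured_gain == pytest.approx(analytic, rel=0.03)

    def test_bad_sigma_rejected(self, surrogate_template):
        with pytest.raises(ValueError):
            slow_component(surrogate_template, -0.1)
        with pytest.raises(ValueError):
            slow_component(surrogate_template, 1e-4)

    def test_fast_of_slow_is_unity(self, surrogate_template):
        slow = slow_component(surrogate_template, 0.1)
        fast = fast_component(slow, slow)
        np.testing.assert_allclose(fast.values, 1.0, atol=1e-9)

    def test_decomposition_identity(self, surrogate_template):
        slow = slow_component(surrogate_template, 0.1)
        fast = fast_component(surrogate_template, slow)
        s_norm = np.maximum(slow.normalized(), 1e-3)
        np.testing.assert_allclose(
            s_norm * fast.values, surrogate_template.normalized(), atol=1e-12
        )

    def test_fast_mean_near_unity(self, surrogate_template):
        slow = slow_component(surrogate_template, 0.1)
        fast = fast_component(surrogate_template, slow)
        assert fast.values.mean() == pytest.approx(1.0, abs=0.02)

    def test_grid_mismatch_rejected(self, surrogate_template):
        short = RateTemplate(dt=1e-3, values=np.full(1000, 50.0), duration=1.0)
        with pytest.raises(ValueError, match="grid"):
            fast_component(surrogate_template, short)


class TestFluctuationGain:
    def test_unit_gains_identity(self, surrogate_template):
        out = fluctuation_gain(surrogate_template, gain_slow=1.0, gain_fast=1.0)
        np.testing.assert_allclose(out.values, surrogate_template.values,
                                   rtol=1e-5, atol=1e-3)

    def test_zero_gains_constant(self, surrogate_template):
        out = fluctuation_gain(surrogate_template, gain_slow=0.0, gain_fast=0.0)
        np.testing.assert_allclose(out.values, surrogate_template.mean_rate,
                                   rtol=0.01)

    def test_double_slow_gain_doubles_slow_sd(self):
        """With well-separated slow (0.5 Hz) and fast (40 Hz) components,
        doubling the slow gain doubles the slow-component SD."""
        t = np.arange(200_000) * 1e-3
        vals = 60 * (1 + 0.15 * np.sin(2 * np.pi * 0.5 * t)) \
            * (1 + 0.3 * np.sin(2 * np.pi * 40.0 * t))
        tpl = RateTemplate(dt=1e-3, values=vals, duration=200.0)
        out = fluctuation_gain(tpl, gain_slow=2.0, gain_fast=1.0)
        sd_in = slow_component(tpl, 0.1).values.std()
        sd_out = slow_component(out, 0.1).values.std()
        assert sd_out == pytest.approx(2 * sd_in, rel=0.05)
        assert out.mean_rate == pytest.approx(tpl.mean_rate, rel=1e-6)

    def test_surrogate_slow_gain_direction(self, surrogate_template):
        """On realistic templates the doubling is approximate (the slow and
        fast bands are not perfectly separated) but clearly expressed."""
        out = fluctuation_gain(surrogate_template, gain_slow=2.0, gain_fast=1.0)
        sd_in = slow_component(surrogate_template, 0.1).values.std()
        sd_out = slow_component(out, 0.1).values.std()
        assert sd_out == pytest.approx(2 * sd_in, rel=0.15)
        assert out.mean_rate == pytest.approx(surrogate_template.mean_rate,
                                              rel=1e-6)

    def test_output_non_negative(self, surrogate_template):
        out = fluctuation_gain(surrogate_template, gain_slow=2.0, gain_fast=2.0)
        assert np.all(out.values >= 0)


class TestRescale:
    def test_identity_and_inverse(self, surrogate_template):
        m = surrogate_template.mean_rate
        same = rescale_to_rate(surrogate_template, m)
        np.testing.assert_allclose(same.values, surrogate_template.values)
        half = rescale_to_rate(surrogate_template, m / 2)
        np.testing.assert_allclose(half.values, surrogate_template.values / 2)
        back = rescale_to_rate(half, m)
        np.testing.assert_allclose(back.values, surrogate_template.values)

    def test_halving_pc_rate(self):
        tpl = RateTemplate(dt=1e-3, values=np.full(1000, 64.86), duration=1.0)
        out = rescale_to_rate(tpl, 32.43)
        np.testing.assert_allclose(out.values, tpl.values / 2)

    def test_zero_mean_rejected(self):
        tpl = RateTemplate(dt=1e-3, values=np.zeros(1000), duration=1.0)
        with pytest.raises(ValueError):
            rescale_to_rate(tpl, 10.0)
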