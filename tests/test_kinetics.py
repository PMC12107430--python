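"""One-phase association fitting, filters, and fold changes."""
import math

import numpy as np
import pandas as pd
import pytest

from smarti import kinetics
from smarti.kinetics import (
    FilterConfig,
    KineticFit,
    fallback_amplitude,
    filter_amplitude,
    filter_rate,
    fit_one_phase,
    fold_change,
    one_phase,
)
from smarti.reference import WILD_TYPE
from smarti.simulate import KineticTruth, simulate_gel_timecourse

TIMES = [0.0, 2.0, 5.0, 10.0, 20.0, 30.0, 60.0]


def _tc(times, values, n_total=10_000):
    return pd.DataFrame(
        {"time_min": times, "pct_cleaved": values, "n_total": n_total}
    )


def _fit(variant="V", replicate="r1", **kw):
    defaults = dict(
        Y0=0.0, amplitude=20.0, k=0.2, sd_Y0=1.0, sd_amplitude=1.0, sd_k=0.05,
        converged=True, n_points=7,
    )
    defaults.update(kw)
    return KineticFit(variant, replicate, **defaults)


class TestFit:
    def test_noiseless_recovery_to_machine_tolerance(self):
        y = one_phase(TIMES, 2.0, 30.0, 0.1)
        fit = fit_one_phase(_tc(TIMES, y))
        assert fit.converged
        assert fit.Y0 == pytest.approx(2.0, rel=1e-6, abs=1e-6)
        assert fit.amplitude == pytest.approx(30.0, rel=1e-6)
        assert fit.k == pytest.approx(0.1, rel=1e-6)
        assert fit.fallback_amplitude is None

    def test_constant_course_has_zero_amplitude_unreliable_k(self):
        fit = fit_one_phase(_tc(TIMES, [7.5] * len(TIMES)))
        assert fit.converged
        assert fit.Y0 == pytest.approx(7.5)
        assert fit.amplitude == 0.0
        assert not fit.k_reliable

    def test_binomial_noise_recovery(self):
        truth = KineticTruth(WILD_TYPE, Y0=0.0, amplitude=55.0, k=0.15)
        rng = np.random.default_rng(100)
        tc = simulate_gel_timecourse(truth, TIMES, 10_000, rng)
        fit = fit_one_phase(tc)
        assert fit.amplitude == pytest.approx(55.0, abs=2.0)

    def test_too_few_points_goes_to_fallback(self):
        fit = fit_one_phase(_tc([0.0, 60.0], [3.0, 12.0]))
        assert not fit.converged
        assert fit.fallback_amplitude == pytest.approx(9.0)

    def test_missing_time_zero_goes_to_fallback(self):
        y = one_phase(TIMES[1:], 0.0, 20.0, 0.1)
        fit = fit_one_phase(_tc(TIMES[1:], y))
        assert not fit.converged

    def test_exact_invariance_to_point_ordering(self):
        rng = np.random.default_rng(7)
        y = one_phase(TIMES, 1.0, 25.0, 0.12) + rng.normal(0, 0.5, len(TIMES))
        base = fit_one_phase(_tc(TIMES, y))
        perm = rng.permutation(len(TIMES))
        shuffled = fit_one_phase(
            _tc(np.asarray(TIMES)[perm], np.asarray(y)[perm])
        )
        assert (base.Y0, base.amplitude, base.k) == (shuffled.Y0, shuffled.amplitude, shuffled.k)

    def test_bootstrap_sds_are_seeded_and_finite(self):
        rng = np.random.default_rng(8)
        y = np.clip(one_phase(TIMES, 1.0, 25.0, 0.12) + rng.normal(0, 0.8, len(TIMES)), 0, 100)
        a = fit_one_phase(_tc(TIMES, y), bootstrap=50, seed=5)
        b = fit_one_phase(_tc(TIMES, y), bootstrap=50, seed=5)
        assert a.sd_amplitude == b.sd_amplitude > 0

    def test_parameter_recovery_across_variant_panel(self):
        """Over 200 synthetic variants with binomial read noise at 2e4
        reads/timepoint: median |amplitude error| < 1 point and median
        relative k error < 10%."""
        rng = np.random.default_rng(314)
        amp_errs, k_errs = [], []
        for _ in range(200):
            y0 = rng.uniform(0, 5)
            amp = rng.uniform(5, 70)
            k = rng.uniform(0.05, 0.5)
            truth = KineticTruth(WILD_TYPE, Y0=y0, amplitude=amp, k=k)
            tc = simulate_gel_timecourse(truth, TIMES, 20_000, rng)
            fit = fit_one_phase(tc)
            assert fit.converged
            amp_errs.append(abs(fit.amplitude - amp))
            k_errs.append(abs(fit.k - k) / k)
        assert np.median(amp_errs) < 1.0
        assert np.median(k_errs) < 0.10


class TestFallback:
    def test_last_minus_first(self):
        assert fallback_amplitude([0, 60], [3.0, 12.0]) == pytest.approx(9.0)

    def test_negative_allowed(self):
        assert fallback_amplitude([0, 60], [10.0, 4.0]) == pytest.approx(-6.0)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            fallback_amplitude([0], [3.0])


class TestFilters:
    def test_amplitude_sd_boundary_is_strict(self):
        cfg = FilterConfig()
        kept = filter_amplitude([_fit(sd_amplitude=9.9), _fit(sd_amplitude=10.0)], cfg)
        assert [f.sd_amplitude for f in kept] == [9.9]

    def test_fallback_fits_kept_in_amplitude_table(self):
        cfg = FilterConfig()
        fb = KineticFit(
            "V", "r1", float("nan"), float("nan"), float("nan"),
            float("nan"), float("nan"), float("nan"),
            converged=False, fallback_amplitude=4.0,
        )
        assert fb in filter_amplitude([fb], cfg)
        assert fb not in filter_amplitude([fb], cfg, include_fallback=False)

    @pytest.mark.parametrize(
        "amplitude,k,sd_k,kept",
        [
            (4.0, 0.2, 0.05, False),   # amplitude too small
            (20.0, 0.8, 0.1, False),   # k too large
            (20.0, 0.3, 0.1, True),
            (5.0, 0.3, 0.1, False),    # strict >5
            (20.0, 0.7, 0.1, False),   # strict <0.7
            (20.0, 0.3, 0.3, False),   # sd_k < k strict
        ],
    )
    def test_rate_filter_boundaries(self, amplitude, k, sd_k, kept):
        cfg = FilterConfig()
        fits = [_fit(amplitude=amplitude, k=k, sd_k=sd_k)]
        assert (len(filter_rate(fits, cfg)) == 1) is kept

    def test_filters_are_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        fits = [
            _fit(
                amplitude=rng.uniform(0, 40),
                k=rng.uniform(0.01, 1.0),
                sd_k=rng.uniform(0.0, 0.5),
                sd_amplitude=rng.uniform(0, 20),
            )
            for _ in range(100)
        ]
        loose = FilterConfig(max_amplitude_sd=10, max_k=0.7)
        tight = FilterConfig(max_amplitude_sd=5, max_k=0.3)
        assert set(map(id, filter_amplitude(fits, tight))) <= set(
            map(id, filter_amplitude(fits, loose))
        )
        assert set(map(id, filter_rate(fits, tight))) <= set(map(id, filter_rate(fits, loose)))


class TestNonfunctional:
    def test_low_in_both_replicates(self):
        cfg = FilterConfig()
        fits = {"r1": _fit(amplitude=3.0), "r2": _fit(amplitude=4.0)}
        assert kinetics.call_nonfunctional(fits, cfg) is True

    def test_high_in_one_replicate(self):
        cfg = FilterConfig()
        fits = {"r1": _fit(amplitude=3.0), "r2": _fit(amplitude=8.0)}
        assert kinetics.call_nonfunctional(fits, cfg) is False

    def test_zero_amplitudes_are_nonfunctional(self):
        cfg = FilterConfig()
        fits = {"r1": _fit(amplitude=0.0), "r2": _fit(amplitude=0.0)}
        assert kinetics.call_nonfunctional(fits, cfg) is True

    def test_single_replicate_indeterminate(self):
        cfg = FilterConfig()
        assert kinetics.call_nonfunctional({"r1": _fit(amplitude=3.0)}, cfg) is None


class TestFoldChange:
    def test_wt_against_itself_is_exactly_one(self):
        wt = [_fit("WT", "r1"), _fit("WT", "r2", amplitude=25.0, k=0.3)]
        rec = fold_change(wt, wt)
        assert rec.mean_fold_amplitude == 1.0
        assert rec.mean_fold_k == 1.0
        assert rec.sd_fold_amplitude == 0.0

    def test_replicate_folds_averaged(self):
        wt = [_fit("WT", "r1", amplitude=10.0), _fit("WT", "r2", amplitude=10.0)]
        mut = [_fit("M", "r1", amplitude=20.0), _fit("M", "r2", amplitude=10.0)]
        rec = fold_change(mut, wt)
        assert rec.mean_fold_amplitude == pytest.approx(1.5)
        assert rec.n_amplitude == 2

    def test_no_passing_replicate_is_not_detectable(self):
        wt = [_fit("WT", "r1"), _fit("WT", "r2")]
        mut = [
            _fit("M", "r1", sd_amplitude=50.0, amplitude=2.0, k=0.9),
            _fit("M", "r2", sd_amplitude=50.0, amplitude=2.0, k=0.9),
        ]
        rec = fold_change(mut, wt)
        assert not rec.amplitude_detectable and not rec.rate_detectable
        assert math.isnan(rec.mean_fold_amplitude)

    def test_zero_wild_type_value_excluded(self):
        wt = [_fit("WT", "r1", amplitude=0.0, sd_amplitude=0.5)]
        mut = [_fit("M", "r1", amplitude=10.0)]
        rec = fold_change(mut, wt)
        assert rec.n_amplitude == 0

    def test_unpaired_replicates_ignored(self):
        wt = [_fit("WT", "r1", amplitude=10.0)]
        mut = [_fit("M", "r1", amplitude=20.0), _fit("M", "r3", amplitude=99.0)]
        rec = fold_change(mut, wt)
        assert rec.mean_fold_amplitude == pytest.approx(2.0)
        assert rec.n_replicates == 1


class TestFitInvariants:
    def test_converged_fit_bounds_enforced(self):
        with pytest.raises(ValueError):
            KineticFit("V", "r", 0.0, -1.0, 0.1, 0, 0, 0, converged=True)
        with pytest.raises(ValueError):
            KineticFit(
                "V", "r", 0.0, 1.0, 0.1, 0, 0, 0, converged=True, fallback_amplitude=1.0
            )
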