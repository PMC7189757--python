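import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

import otem
from otem.analysis import (
    amplitude_spectrum,
    border_pairs,
    circular_mean,
    detrended_series,
    fisher_exact_2x2,
    jump_tests,
    mean_rt_series,
    permutation_thresholds,
    phase_difference_3_5,
    preprocess,
    priming_effects,
    rayleigh_test,
    sequential_regression,
    slow_trend_exponential,
    watson_williams,
)
from otem.design import TRIAL_COLUMNS


def _toy_trials(rts, soas=None, participant="p01", congruency="C", rt_limit_ok=True):
    n = len(rts)
    soas = soas if soas is not None else [20 * (i % 10) for i in range(n)]
    return pd.DataFrame(
        {
            "participant": participant,
            "condition": "huang_masked",
            "block_index": 0,
            "trial_index": range(n),
            "soa_ms": soas,
            "congruency": congruency,
            "prime_dir": "L",
            "target_dir": "L" if congruency == "C" else "R",
            "response": "L" if congruency == "C" else "R",
            "rt_ms": rts,
            "correct": True,
            "excluded": False,
        }
    )[TRIAL_COLUMNS]


class TestPreprocess:
    def test_truncation_keeps_41_soa_levels(self, masked_design, demo_params):
        ds = otem.simulate_dataset(masked_design, demo_params, "otem_additive", seed=1)
        out = preprocess(ds, masked_design, truncate_above=800)
        assert out["soa_ms"].nunique() == 41
        assert out["soa_ms"].max() == 800

    def test_identical_rts_no_sd_exclusions(self, masked_design):
        ds = _toy_trials([400.0] * 100)
        out = preprocess(ds, masked_design)
        assert not out["excluded"].any()

    def test_single_outlier_flagged(self, masked_design, rng):
        rts = 400.0 + rng.normal(0, 10, 100)
        rts[17] = 400.0 + 5 * rts.std()
        out = preprocess(_toy_trials(rts), masked_design)
        flagged = np.flatnonzero(out["excluded"])
        assert list(flagged) == [17]

    def test_timeout_and_premature_flags(self, masked_design):
        ds = _toy_trials([400.0, 50.0, 1600.0, 420.0])
        out = preprocess(ds, masked_design)
        assert list(out["excluded"]) == [False, True, True, False]


class TestSlowTrend:
    def test_recovers_exact_exponential(self):
        soas = np.arange(0, 820, 20.0)
        y = 350.0 + 80.0 * np.exp(-soas / 250.0)
        res = slow_trend_exponential(soas, y)
        assert res.method == "exponential"
        assert np.max(np.abs(res.detrended)) < 1e-6 * 400

    def test_constant_series(self):
        soas = np.arange(0, 400, 20.0)
        res = slow_trend_exponential(soas, np.full(soas.size, 400.0))
        assert np.allclose(res.detrended, 0.0, atol=1e-6)

    def test_residual_recovers_injected_sinusoid(self):
        # several cycles across the SOA range so trend/oscillation separate
        soas = np.arange(0, 820, 20.0)
        osc = 6.0 * np.sin(2 * np.pi * 7.5 * soas / 1000.0)
        y = 350.0 + 80.0 * np.exp(-soas / 250.0) + osc
        res = slow_trend_exponential(soas, y)
        r = np.corrcoef(res.detrended, osc)[0, 1]
        assert r > 0.99

    def test_decomposition_identity(self):
        soas = np.arange(0, 600, 20.0)
        y = 400 + 50 * np.exp(-soas / 150.0) + np.sin(soas / 30.0)
        res = slow_trend_exponential(soas, y)
        assert np.allclose(res.trend + res.detrended, y, atol=1e-9)


class TestSpectrum:
    def test_exact_bin_sinusoid(self):
        n, dt = 40, 0.02
        t = np.arange(n) * dt
        f_bin = 5 / (n * dt)  # an exact DFT bin (6.25 Hz)
        x = 3.5 * np.sin(2 * np.pi * f_bin * t)
        freqs, amp, _ = amplitude_spectrum(x, dt)
        k = np.argmin(np.abs(freqs - f_bin))
        assert amp[k] == pytest.approx(3.5, abs=1e-10)
        others = np.delete(amp, k)
        assert np.all(others < 1e-10)

    def test_zero_series(self):
        freqs, amp, _ = amplitude_spectrum(np.zeros(41))
        assert np.all(amp == 0.0)
        assert freqs.max() <= 25.0  # Nyquist at 20 ms sampling

    def test_parseval_identity(self, rng):
        x = rng.normal(size=41)
        _, amp, _ = amplitude_spectrum(x)
        n = x.size
        total = (amp**2).sum() * n / 2 + x.sum() ** 2 / n
        assert total == pytest.approx((x**2).sum(), abs=1e-8)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            amplitude_spectrum(np.ones(5))


class TestPermutationThresholds:
    def test_corrected_dominates_and_reproducible(self, rng):
        data = rng.normal(size=(10, 41))
        a = permutation_thresholds(data, n_perm=200, seed=3)
        b = permutation_thresholds(data, n_perm=200, seed=3)
        assert np.all(a.corrected >= a.uncorrected - 1e-12)
        assert np.allclose(a.uncorrected, b.uncorrected)

    def test_white_noise_calibration(self, rng):
        # ~5% of (replicate, frequency) cells exceed their uncorrected threshold
        hits, cells = 0, 0
        for _ in range(30):
            data = rng.normal(size=(12, 41))
            thr = permutation_thresholds(data, n_perm=150, seed=int(rng.integers(1e6)))
            amps = np.vstack([amplitude_spectrum(row)[1] for row in data])
            group = amps.mean(axis=0)
            hits += (group > thr.uncorrected).sum()
            cells += group.size
        assert 0.02 < hits / cells < 0.09

    def test_n_perm_floor(self, rng):
        with pytest.raises(ValueError):
            permutation_thresholds(rng.normal(size=(5, 41)), n_perm=10)


class TestPhaseDifference:
    def test_identical_series_zero(self, rng):
        x = rng.normal(size=41)
        assert phase_difference_3_5(x, x) == pytest.approx(0.0)

    def test_sign_flip_gives_pi(self, rng):
        x = rng.normal(size=41)
        d = phase_difference_3_5(x, -x)
        assert abs(abs(d) - math.pi) < 1e-9

    def test_antiphased_sinusoids_near_pi(self, rng):
        t = np.arange(41) * 0.02
        base = np.sin(2 * np.pi * 3.3 * t)
        x = base + 0.1 * rng.normal(size=41)
        y = -base + 0.1 * rng.normal(size=41)
        d = phase_difference_3_5(x, y)
        assert abs(abs(d) - math.pi) < 0.2


class TestCircularStats:
    def test_rayleigh_perfect_coherence(self):
        mean, r, z, p = rayleigh_test([0.7] * 16)
        assert mean == pytest.approx(0.7)
        assert r == pytest.approx(1.0)
        assert z == pytest.approx(16.0)
        assert p < 1e-4

    def test_rayleigh_uniform_angles(self):
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        _, r, z, p = rayleigh_test(angles)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_rayleigh_p_matches_monte_carlo(self, rng):
        n, r_obs = 18, 0.5
        _, _, _, p = rayleigh_test(
            rng.vonmises(0.0, 1.2, n)  # angles only set n; recompute p at r=0.5
        )
        z = n * r_obs**2
        # Monte-Carlo null distribution of R_bar for n=18
        draws = 10**6
        angles = rng.uniform(0, 2 * np.pi, size=(draws, 1)) * 0  # placeholder
        sums = np.abs(np.exp(1j * rng.uniform(0, 2 * np.pi, size=(draws, n))).sum(axis=1)) / n
        p_mc = (sums >= r_obs).mean()
        p_formula = math.exp(-z) * (
            1 + (2 * z - z**2) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
        )
        assert p_formula == pytest.approx(p_mc, rel=0.1)

    def test_rayleigh_needs_three_angles(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 1.0])

    def test_watson_williams_identical_groups(self, rng):
        g = rng.vonmises(0.5, 8.0, 20)
        f, p = watson_williams([g, g.copy()])
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_watson_williams_offset_groups(self, rng):
        g1 = rng.vonmises(0.0, 12.0, 20)
        g2 = rng.vonmises(np.pi / 2, 12.0, 20)
        f, p = watson_williams([g1, g2])
        assert p < 0.01

    def test_watson_williams_cross_implementation(self, rng):
        # independent textbook formulation computed from scratch
        groups = [rng.vonmises(0.3, 5.0, 15), rng.vonmises(0.6, 5.0, 12),
                  rng.vonmises(0.1, 5.0, 18)]
        f_got, p_got = watson_williams(groups)

        def resultant(a):
            return abs(np.exp(1j * np.asarray(a)).sum())

        n = sum(len(g) for g in groups)
        k = len(groups)
        sum_r = sum(resultant(g) for g in groups)
        r_all = resultant(np.concatenate(groups))
        rw = sum_r / n
        kappa = (lambda r: 2 * r + r**3 + 5 * r**5 / 6 if r < 0.53
                 else (-0.4 + 1.39 * r + 0.43 / (1 - r) if r < 0.85
                       else 1 / (r**3 - 4 * r**2 + 3 * r)))(rw)
        f_ref = (1 + 3 / (8 * kappa)) * ((n - k) * (sum_r - r_all)) / ((k - 1) * (n - sum_r))
        p_ref = 1 - stats.f.cdf(f_ref, k - 1, n - k)
        assert f_got == pytest.approx(f_ref, abs=1e-6)
        assert p_got == pytest.approx(p_ref, abs=1e-9)


class TestFisherExact:
    def test_jump_proportion_table(self):
        assert round(fisher_exact_2x2(8, 18, 1, 21), 3) == 0.028

    def test_degenerate_and_symmetric(self):
        assert fisher_exact_2x2(0, 10, 0, 10) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_row_column_swap_invariance(self, rng):
        for _ in range(5):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact_2x2(a, c, b, d), abs=1e-12
            )

    def test_matches_hypergeometric_enumeration(self, rng):
        # brute force: sum P(table) over all tables with the same margins
        # whose probability does not exceed the observed table's
        for _ in range(6):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            n = a + b + c + d
            if n == 0 or (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            r1, c1 = a + b, a + c

            def p_table(x):
                return (comb(r1, x, exact=True)
                        * comb(n - r1, c1 - x, exact=True)) / comb(n, c1, exact=True)

            p_obs = p_table(a)
            total = sum(
                p_table(x)
                for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
                if p_table(x) <= p_obs * (1 + 1e-12)
            )
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(total, abs=1e-9)


class TestPrimingEffects:
    def test_identical_conditions_zero_effect(self):
        c = _toy_trials([400.0] * 200, soas=[20 * (i % 41) for i in range(200)])
        ic = _toy_trials([400.0] * 200, soas=[20 * (i % 41) for i in range(200)],
                         congruency="IC")
        ds = pd.concat([c, ic], ignore_index=True)
        eff = priming_effects(ds)
        assert np.allclose(eff["effect_ms"], 0.0)

    def test_uniform_shift_recovered(self):
        soas = [20 * (i % 41) for i in range(410)]
        c = _toy_trials([400.0] * 410, soas=soas)
        ic = _toy_trials([420.0] * 410, soas=soas, congruency="IC")
        eff = priming_effects(pd.concat([c, ic], ignore_index=True))
        assert np.allclose(eff["effect_ms"], 20.0)


class TestJumpAndSequential:
    def test_border_pair_counts(self):
        pairs = set()
        n_comparisons = 0
        for preset in ("tc_20soa", "tc_10soa", "tc_4soa"):
            bp = border_pairs(otem.make_design(preset))
            n_comparisons += 2 * len(bp)  # congruent + incongruent
            pairs |= set(bp)
        assert n_comparisons == 26
        assert 2 * len(pairs) == 22  # base-rate comparisons on the 40-SOA design

    def test_flat_rts_produce_no_jumps(self, rng):
        design = otem.make_design("tc_20soa")
        frames = []
        for i in range(8):
            t = otem.generate_trial_sequence(design, seed=i, participant=f"p{i}")
            t["rt_ms"] = 400.0 + rng.normal(0, 5, len(t))
            t["correct"] = True
            frames.append(t)
        res = jump_tests(pd.concat(frames, ignore_index=True), design)
        assert res["significant"].sum() <= 1  # ~5% false positives on 2 tests

    def test_sequential_regression_null_and_signal(self, rng):
        design = otem.make_design("tc_40soa")
        frames = []
        for i in range(6):
            t = otem.generate_trial_sequence(design, seed=i, participant=f"p{i}")
            soa = t["soa_ms"].to_numpy(dtype=float)
            lag1 = np.roll(soa, 1)
            t["rt_ms"] = 400.0 + 0.1 * lag1 + rng.normal(0, 5, len(t))
            t["correct"] = True
            frames.append(t)
        res = sequential_regression(pd.concat(frames, ignore_index=True))
        group = res.attrs["group"]
        assert group["soa_lag1"]["mean_beta"] == pytest.approx(0.1, abs=0.01)
        assert group["soa_lag1"]["p"] < 1e-6
        assert abs(group["soa_lag2"]["mean_beta"]) < 0.01


class TestModelPredictionCurves:
    def test_noise_free_prediction_equals_deterministic_curve(self, demo_params):
        from otem.analysis import simulate_and_analyze
        from otem._engine import PreparedCondition

        design = otem.make_design("int0")
        p = demo_params.replace(sigma_noise=0.0)
        res = otem.FitResult(
            participant="p01", model="otem_additive",
            params={k: getattr(p, k) for k in (
                "alpha", "gamma", "mu", "kappa", "theta_prime", "theta_mask",
                "zeta", "nu", "b", "sigma_noise")},
            neg_log_lik=0.0, n_trials=1280, k_params=10, aicc=0.0,
            n_restarts=1, best_restart_seed=0, success=True,
        )
        curves = simulate_and_analyze([res], design, n_sims=1, seed=3)
        assert set(curves["soa_ms"]) == set(design.all_soas)
        # deterministic: the curve equals the engine's expected RT per cell
        sim = otem.simulate_dataset(design, p, "otem_additive", seed=99)
        prep = PreparedCondition(sim, design)
        rt = prep.expected_rt_otem(p) * 1000
        sim = sim.assign(rt_exp=rt)
        cells = sim.groupby(["congruency", "soa_ms"])["rt_exp"].mean()
        merged = curves.set_index(["congruency", "soa_ms"])["rt_ms"]
        # same model, same design; trial-order differences only move cells by
        # the belief path, which is identical in distribution — compare coarsely
        assert np.abs(merged.mean() - cells.mean()) < 5.0


class TestPipelineOnSimulatedData:
    def test_detrend_reconstruction_and_grids(self, small_masked_dataset, masked_design):
        clean = preprocess(small_masked_dataset, masked_design, truncate_above=800)
        trends = detrended_series(clean)
        series = mean_rt_series(clean)
        for (pid, cong), tr in trends.items():
            assert np.allclose(tr.trend + tr.detrended, tr.mean_rt, atol=1e-9)
            assert tr.soas.size == 41
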