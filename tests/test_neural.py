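"""Running-window rates, truncation rules, and the two window-wise
spike-count regressions."""

import numpy as np
import pandas as pd
import pytest

from stndecide.neural import (
    CHANCE_LEVEL,
    compute_running_rates,
    fraction_significant,
    regress_coherence,
    regress_rt,
    zscore_rates,
)

MAGS = [0.032, 0.064, 0.128, 0.256, 0.512]


def make_trials(n=200, seed=0, rt=0.8):
    rng = np.random.default_rng(seed)
    coh = rng.choice(np.r_[MAGS, [-m for m in MAGS]], n)
    return pd.DataFrame(
        {
            "session_id": "s",
            "trial_id": np.arange(n),
            "signed_coh": coh,
            "estim": False,
            "choice": rng.choice(["contra", "ipsi"], n),
            "rt_s": rt + 0.2 * rng.random(n),
            "correct": True,
        }
    )


def make_spikes(trials, counts_fn, starts=(-300, 0, 300), window_ms=300,
                alignment="motion", neuron_id="n0"):
    """Spike table with counts from counts_fn(trials_row_df, start)."""
    rows = []
    for start in starts:
        rows.append(
            pd.DataFrame(
                {
                    "neuron_id": neuron_id,
                    "trial_id": trials["trial_id"],
                    "alignment": alignment,
                    "window_start_ms": start,
                    "window_ms": window_ms,
                    "count": counts_fn(trials, start),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestRunningRates:
    def test_rate_is_count_over_duration(self):
        trials = make_trials(20)
        spikes = make_spikes(trials, lambda t, s: np.full(len(t), 6))
        rates = compute_running_rates(spikes, trials, "motion", 300)
        assert np.allclose(rates.rates, 20.0)  # 6 / 0.3 s

    def test_motion_truncation_before_saccade(self):
        """A motion-aligned window that ends within 100 ms of saccade
        onset is masked."""
        trials = make_trials(10, rt=0.45)  # rt in [0.45, 0.65]
        spikes = make_spikes(trials, lambda t, s: np.zeros(len(t), dtype=int))
        rates = compute_running_rates(spikes, trials, "motion", 300)
        w300 = np.where(rates.window_centers_ms == 450.0)[0][0]
        # window [300, 600] needs rt >= 700 ms: none qualify
        assert not rates.valid[:, :, w300].any()
        w_base = np.where(rates.window_centers_ms == -150.0)[0][0]
        assert rates.valid[:, :, w_base].all()

    def test_saccade_truncation_after_motion(self):
        trials = make_trials(10, rt=0.4)
        spikes = make_spikes(
            trials, lambda t, s: np.zeros(len(t), dtype=int),
            starts=(-400, -200), alignment="saccade",
        )
        rates = compute_running_rates(spikes, trials, "saccade", 300)
        # start -400 ms relative to saccade = motion + rt - 400 < 200 ms
        w = np.where(rates.window_centers_ms == -250.0)[0][0]
        assert not rates.valid[:, :, w].any()

    def test_unknown_alignment(self):
        trials = make_trials(5)
        spikes = make_spikes(trials, lambda t, s: np.zeros(len(t), dtype=int))
        with pytest.raises(ValueError):
            compute_running_rates(spikes, trials, "fixation", 300)


class TestZScore:
    def test_arithmetic(self):
        trials = make_trials(40, rt=2.0)
        rng = np.random.default_rng(1)
        base_counts = rng.normal(3.0, 0.6, len(trials)).round().clip(0)
        spikes = pd.concat(
            [
                make_spikes(trials, lambda t, s: base_counts, starts=(-300,)),
                make_spikes(trials, lambda t, s: np.full(len(t), 5), starts=(100,)),
            ],
            ignore_index=True,
        )
        rates = compute_running_rates(spikes, trials, "motion", 300)
        base_idx = np.where(rates.window_centers_ms == -150.0)[0][0]
        mu = rates.rates[0, :, base_idx].mean()
        sd = rates.rates[0, :, base_idx].std(ddof=1)
        z = zscore_rates(rates, rates, baseline_start_ms=-300)
        w = np.where(z.window_centers_ms == 250.0)[0][0]
        assert np.allclose(z.rates[0, :, w], (5 / 0.3 - mu) / sd)

    def test_zero_variance_neuron_excluded(self):
        trials = make_trials(10, rt=2.0)
        spikes = make_spikes(trials, lambda t, s: np.full(len(t), 4))
        rates = compute_running_rates(spikes, trials, "motion", 300)
        z = zscore_rates(rates, rates, baseline_start_ms=-300)
        assert z.excluded_neurons == ["n0"]
        assert len(z.neuron_ids) == 0


class TestRegressions:
    def test_noiseless_coherence_recovery(self):
        trials = make_trials(300, seed=2, rt=2.0)
        contra = (trials["choice"] == "contra").to_numpy()
        i_choice = np.where(contra, 1.0, -1.0)
        coh_c = np.where(contra, np.abs(trials["signed_coh"]), 0.0)

        def counts(t, s):
            return 2.0 + 1.0 * i_choice + 3.0 * coh_c

        spikes = make_spikes(trials, counts, starts=(100,))
        rates = compute_running_rates(spikes, trials, "motion", 300)
        res = regress_coherence(rates, trials)
        b = dict(zip(res.coef_names, res.coefs[0, 0]))
        assert b["b0"] == pytest.approx(2.0, abs=1e-9)
        assert b["bChoice"] == pytest.approx(1.0, abs=1e-9)
        assert b["bCohContra"] == pytest.approx(3.0, abs=1e-9)
        assert b["bCohIpsi"] == pytest.approx(0.0, abs=1e-9)

    def test_choice_swap_symmetry(self):
        trials = make_trials(250, seed=3, rt=2.0)
        rng = np.random.default_rng(4)
        noise = rng.poisson(4.0, len(trials)).astype(float)
        spikes = make_spikes(trials, lambda t, s: noise, starts=(100,))
        rates = compute_running_rates(spikes, trials, "motion", 300)
        res = regress_coherence(rates, trials)
        swapped = trials.assign(
            choice=np.where(trials["choice"] == "contra", "ipsi", "contra")
        )
        res2 = regress_coherence(rates, swapped)
        b, b2 = res.coefs[0, 0], res2.coefs[0, 0]
        names = res.coef_names
        assert b2[names.index("bChoice")] == pytest.approx(
            -b[names.index("bChoice")], abs=1e-9
        )
        assert b2[names.index("bCohContra")] == pytest.approx(
            b[names.index("bCohIpsi")], abs=1e-9
        )

    def test_rt_regressor_exact_and_unit_scaling(self):
        trials = make_trials(300, seed=5, rt=1.5)
        contra = (trials["choice"] == "contra").to_numpy()
        rt_c = np.where(contra, trials["rt_s"], 0.0)

        def counts(t, s):
            return 5.0 + 0.01 * rt_c

        spikes = make_spikes(trials, counts, starts=(100,))
        rates = compute_running_rates(spikes, trials, "motion", 300)
        res = regress_rt(rates, trials)
        b = dict(zip(res.coef_names, res.coefs[0, 0]))
        assert b["bRTContra"] == pytest.approx(0.01, abs=1e-9)
        assert b["bRTIpsi"] == pytest.approx(0.0, abs=1e-9)
        # seconds -> milliseconds rescales the coefficient by 1e-3
        ms = trials.assign(rt_s=trials["rt_s"] * 1000.0)
        spikes_ms = make_spikes(ms, lambda t, s: counts(None, None), starts=(100,))
        # identical counts, identical window validity at long rt
        rates_ms = compute_running_rates(spikes_ms, ms, "motion", 300)
        res_ms = regress_rt(rates_ms, ms)
        assert res_ms.coefs[0, 0][2] == pytest.approx(0.01 * 1e-3, rel=1e-9)

    def test_intercepts_agree_with_centered_regressors(self):
        """With all non-intercept regressors centered, both regressions
        share the intercept (the mean count)."""
        trials = make_trials(400, seed=6, rt=2.0)
        rng = np.random.default_rng(7)
        noise = rng.poisson(5.0, len(trials)).astype(float)
        spikes = make_spikes(trials, lambda t, s: noise, starts=(100,))
        rates = compute_running_rates(spikes, trials, "motion", 300)

        def centered(res_builder, kind):
            from stndecide.neural import _design

            X, _ = _design(kind, trials, rates.trial_ids)
            Xc = X.copy()
            Xc[:, 1:] -= Xc[:, 1:].mean(axis=0)
            beta = np.linalg.lstsq(Xc, noise, rcond=None)[0]
            return beta[0]

        b0_coh = centered(regress_coherence, "coherence")
        b0_rt = centered(regress_rt, "rt")
        assert b0_coh == pytest.approx(b0_rt, abs=1e-9)
        assert b0_coh == pytest.approx(noise.mean(), abs=1e-9)


class TestFractionSignificant:
    def test_single_always_significant_neuron(self):
        trials = make_trials(300, seed=8, rt=2.0)
        contra = (trials["choice"] == "contra").to_numpy()
        rng = np.random.default_rng(9)

        def counts(t, s):
            return 10.0 * contra + rng.poisson(1.0, len(contra))

        spikes = make_spikes(trials, counts, starts=(0, 100))
        rates = compute_running_rates(spikes, trials, "motion", 300)
        res = regress_coherence(rates, trials)
        frac = fraction_significant(res, "bChoice")
        assert (frac["fraction"] == 1.0).all()
        assert (frac["chance_level"] == CHANCE_LEVEL).all()

    def test_masked_windows_do_not_leak(self):
        """Windows masked by truncation contribute to no fraction."""
        trials = make_trials(50, seed=10, rt=0.4)  # short RTs
        spikes = make_spikes(trials, lambda t, s: np.full(len(t), 3), starts=(300,))
        rates = compute_running_rates(spikes, trials, "motion", 300)
        res = regress_coherence(rates, trials)
        assert not res.fitted.any()
        frac = fraction_significant(res, "bChoice")
        assert frac["n_neurons"].eq(0).all()
        assert frac["fraction"].isna().all()
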