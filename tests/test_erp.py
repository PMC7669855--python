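"""Evoked averaging, sliding-window repeated-measures ANOVA, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from caneeg.epochs import EpochsSet
from caneeg.erp import (
    EmptyConditionError,
    EvokedResponse,
    average_evoked,
    contiguity_filter,
    enumerate_windows,
    grand_average,
    planned_contrast,
    rm_anova_2way,
    sliding_contrast,
    sliding_window_anova,
)
from caneeg.labels import FACE_CATEGORIES

SFREQ = 512.0


def _epochs_from(data, labels):
    n_trials, n_ch, n_samp = data.shape
    times = -150.0 + np.arange(n_samp) * (1000.0 / SFREQ)
    return EpochsSet(data, times, SFREQ, [f"ch{i}" for i in range(n_ch)],
                     np.asarray(labels, dtype=object), subject="dog01")


def _evoked(data, subject="dog01", condition="HH", t0=-150.0):
    data = np.asarray(data, dtype=np.float64)
    times = t0 + np.arange(data.shape[1]) * (1000.0 / SFREQ)
    return EvokedResponse(data, times, [f"ch{i}" for i in range(data.shape[0])],
                          condition, subject, 10)


class TestAveraging:
    def test_identical_trials_average_to_any_trial(self):
        trial = np.random.default_rng(0).standard_normal((2, 64))
        ep = _epochs_from(np.stack([trial] * 3), ["S"] * 3)
        ev = average_evoked(ep, "S")
        np.testing.assert_allclose(ev.data, trial, atol=1e-14)
        assert ev.n_trials == 3

    def test_constant_trials_average(self):
        data = np.stack([np.zeros((1, 32)), np.full((1, 32), 2.0)])
        ev = average_evoked(_epochs_from(data, ["S", "S"]), "S")
        np.testing.assert_allclose(ev.data, 1.0)

    def test_rejected_trials_excluded(self):
        data = np.stack([np.zeros((1, 32)), np.full((1, 32), 2.0)])
        ep = _epochs_from(data, ["S", "S"])
        ep.kept[1] = False
        assert average_evoked(ep, "S").data.max() == 0.0

    def test_empty_condition_error(self):
        ep = _epochs_from(np.zeros((2, 1, 32)), ["S", "S"])
        with pytest.raises(EmptyConditionError, match="OB"):
            average_evoked(ep, "OB")

    def test_grand_average_equals_pooled_mean_for_equal_trials(self):
        """Algebraic identity: with equal trial counts per subject the
        unweighted grand average equals the pooled-trial mean."""
        rng = np.random.default_rng(1)
        all_trials, evokeds = [], []
        for s in range(4):
            trials = rng.standard_normal((5, 2, 32))
            all_trials.append(trials)
            evokeds.append(_evoked(trials.mean(axis=0), subject=f"s{s}"))
        ga = grand_average(evokeds)
        pooled = np.concatenate(all_trials).mean(axis=0)
        np.testing.assert_allclose(ga.data, pooled, atol=1e-12)
        assert ga.subject == "grand"


class TestSlidingAnova:
    def test_59_windows_enumerated(self):
        starts = enumerate_windows((0.0, 250.0), 16.0, 4.0)
        assert starts.size == 59
        assert starts[0] == 0.0 and starts[-1] == 232.0

    def _face_evokeds(self, rng, n_sub=8, effect_uV=0.0, channel=1,
                      window=(60.0, 90.0), noise_sd=0.5, n_samp=256):
        """Subject-level face-condition evokeds with an optional planted
        species effect (dog conditions shifted on one channel)."""
        out = []
        times = -150.0 + np.arange(n_samp) * (1000.0 / SFREQ)
        for s in range(n_sub):
            per = {}
            for cat in FACE_CATEGORIES:
                data = rng.standard_normal((7, n_samp)) * noise_sd
                if effect_uV and cat.species == "dog":
                    mask = (times >= window[0]) & (times < window[1])
                    data[channel, mask] += effect_uV
                per[cat] = EvokedResponse(
                    data, times, [f"ch{i}" for i in range(7)],
                    cat.value, f"s{s}", 100,
                )
            out.append(per)
        return out

    def test_matches_statsmodels_anova_rm(self):
        """Dual route: the vectorized closed-form sums of squares agree
        with statsmodels' general repeated-measures ANOVA."""
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(2)
        Y = rng.standard_normal((8, 2, 3))
        res = rm_anova_2way(Y[None, ...])
        rows = []
        for s in range(8):
            for a in range(2):
                for b in range(3):
                    rows.append({"subject": s, "sp": a, "ex": b, "y": Y[s, a, b]})
        table = AnovaRM(pd.DataFrame(rows), "y", "subject",
                        within=["sp", "ex"]).fit().anova_table
        for effect, key in [("sp", "species"), ("ex", "expression"),
                            ("sp:ex", "interaction")]:
            np.testing.assert_allclose(
                res[key]["F"][0], table.loc[effect, "F Value"], rtol=1e-8
            )
            np.testing.assert_allclose(
                res[key]["p"][0], table.loc[effect, "Pr > F"], rtol=1e-8
            )

    def test_species_f_equals_t_squared_when_expression_collapsed(self):
        """With one expression level per species cell, the species main
        effect F equals the paired t statistic squared."""
        rng = np.random.default_rng(3)
        dog = rng.standard_normal(8)
        human = rng.standard_normal(8)
        Y = np.stack([np.tile(dog[:, None], 3), np.tile(human[:, None], 3)],
                     axis=1)  # (8, 2, 3), expression constant
        res = rm_anova_2way(Y[None, ...])
        t, p = planned_contrast(dog, human)
        np.testing.assert_allclose(res["species"]["F"][0], t**2, rtol=1e-8)
        np.testing.assert_allclose(res["species"]["p"][0], p, rtol=1e-8)

    def test_planted_species_effect_detected_contiguously(self):
        rng = np.random.default_rng(4)
        evokeds = self._face_evokeds(rng, effect_uV=3.0, channel=1)
        stats = sliding_window_anova(evokeds)
        runs = contiguity_filter(stats, alpha=0.05, min_run=2)
        hits = runs[(runs["effect"] == "species") & (runs["channel"] == "ch1")]
        assert len(hits) >= 1
        covered = any(
            row["start_ms"] <= 60.0 and row["end_ms"] >= 90.0
            for _, row in hits.iterrows()
        )
        assert covered

    def test_null_type_one_rate_near_alpha(self):
        """On null data the per-window rejection rate stays near 0.05."""
        rng = np.random.default_rng(5)
        rates = []
        for _ in range(60):
            evokeds = self._face_evokeds(rng, effect_uV=0.0, n_samp=224)
            stats = sliding_window_anova(evokeds)
            p = stats[["p_species", "p_expression", "p_interaction"]].to_numpy()
            rates.append((p < 0.05).mean())
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(mean - 0.05) <= 3.0 * se + 0.005

    def test_missing_condition_named(self):
        rng = np.random.default_rng(6)
        evokeds = self._face_evokeds(rng, n_sub=3)
        del evokeds[1][FACE_CATEGORIES[0]]
        with pytest.raises(ValueError, match="AD"):
            sliding_window_anova(evokeds)

    def test_gg_correction_only_deflates(self):
        rng = np.random.default_rng(7)
        evokeds = self._face_evokeds(rng, n_sub=6, n_samp=224)
        plain = sliding_window_anova(evokeds)
        gg = sliding_window_anova(evokeds, gg_correction=True)
        # F statistics are untouched; near-significant p only grows
        np.testing.assert_allclose(gg["F_expression"], plain["F_expression"])
        small = plain["p_expression"].to_numpy() < 0.05
        assert (gg["p_expression"].to_numpy()[small]
                >= plain["p_expression"].to_numpy()[small] - 1e-12).all()


class TestContiguity:
    def _stats(self, sig_starts, step=4.0):
        starts = np.arange(0.0, 236.0, step)
        df = pd.DataFrame(
            {
                "channel": "P4",
                "win_start_ms": starts,
                "win_end_ms": starts + 16.0,
                "p_species": 0.5,
                "F_species": 1.0,
            }
        )
        df.loc[df["win_start_ms"].isin(sig_starts), "p_species"] = 0.01
        return df

    def test_isolated_window_not_reported(self):
        out = contiguity_filter(self._stats([28.0]), effects=("species",))
        assert out.empty

    def test_run_merged_to_interval(self):
        out = contiguity_filter(self._stats([28.0, 32.0, 36.0]),
                                effects=("species",))
        assert len(out) == 1
        assert out.loc[0, "start_ms"] == 28.0
        assert out.loc[0, "end_ms"] == 52.0

    def test_gap_splits_runs(self):
        out = contiguity_filter(self._stats([28.0, 32.0, 44.0, 48.0]),
                                effects=("species",))
        assert len(out) == 2

    def test_order_independence(self):
        df = self._stats([28.0, 32.0, 36.0, 100.0, 104.0])
        shuffled = df.sample(frac=1.0, random_state=0)
        a = contiguity_filter(df, effects=("species",))
        b = contiguity_filter(shuffled, effects=("species",))
        pd.testing.assert_frame_equal(a, b)


class TestPlannedContrast:
    def test_identical_samples(self):
        t, p = planned_contrast(np.ones(8), np.ones(8))
        assert (t, p) == (0.0, 1.0)

    def test_hand_computed_value(self):
        """Differences {1,2,1,2,...}: mean 1.5, sd 0.5345 -> t ~ 7.94."""
        a = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        t, p = planned_contrast(a, np.zeros(8))
        assert t == pytest.approx(7.937, abs=0.01)
        assert p < 1e-4

    @given(st.integers(0, 2**31 - 1))
    def test_sign_flip_negates_t_keeps_p(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal((2, 8))
        t1, p1 = planned_contrast(a, b)
        t2, p2 = planned_contrast(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            planned_contrast(np.array([1.0]), np.array([2.0]))

    def test_sliding_contrast_detects_pooled_difference(self):
        rng = np.random.default_rng(8)
        times = np.arange(256)
        a_ev, b_ev = [], []
        for s in range(8):
            base = rng.standard_normal((7, 256)) * 0.3
            shifted = base.copy()
            shifted[3] += 2.0  # faces differ from objects on one channel
            a_ev.append(_evoked(shifted, subject=f"s{s}"))
            b_ev.append(_evoked(base, subject=f"s{s}"))
        df = sliding_contrast(a_ev, b_ev)
        ch3 = df[df["channel"] == "ch3"]
        assert (ch3["p"] < 0.05).mean() > 0.9
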