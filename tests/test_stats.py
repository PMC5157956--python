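"""Closed-form statistics vs independent oracles, coverage, recovery."""

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from hyphatrack.config import SimulationConfig
from hyphatrack.detection import Focus
from hyphatrack.simulate import ground_truth_tracks, simulate_dataset
from hyphatrack.stats import (
    anova_games_howell,
    chi_squared_counts,
    colocalization_fraction,
    compute_velocity_pairs,
    correlation_by_index,
    duplication_fraction_timecourse,
    mixed_vs_pooled,
    pearson_with_ci,
    tip_distance_summary,
    tukey_hsd,
    variance_ratio_test,
)
from hyphatrack.tracking import DuplicationEvent, FocusTrack


class TestPearson:
    def test_exact_linear(self):
        res = pearson_with_ci([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_hand_computed_value(self):
        # direct evaluation of the Pearson formula on (1,2),(2,4),(3,5)
        res = pearson_with_ci([1, 2, 3], [2, 4, 5])
        assert round(res.estimate, 4) == 0.9820

    def test_matches_brute_force_formula(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = pearson_with_ci(x, y)
            r_direct = float(
                np.sum((x - x.mean()) * (y - y.mean()))
                / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            )
            assert abs(res.estimate - r_direct) < 1e-10
            r_scipy, p_scipy = sps.pearsonr(x, y)
            assert abs(res.estimate - r_scipy) < 1e-10
            assert abs(res.p_value - p_scipy) < 1e-8

    def test_degenerate_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_with_ci([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_with_ci([1, 2], [1, 2])

    def test_fisher_ci_coverage(self, rng):
        # empirical coverage of the 95% interval at n=50, rho=0.5
        rho, n, hits, trials = 0.5, 50, 0, 2000
        cov = np.array([[1, rho], [rho, 1]])
        chol = np.linalg.cholesky(cov)
        for _ in range(trials):
            xy = rng.standard_normal((n, 2)) @ chol.T
            res = pearson_with_ci(xy[:, 0], xy[:, 1])
            hits += res.ci_low <= rho <= res.ci_high
        assert 0.93 <= hits / trials <= 0.97


class TestVarianceRatio:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = variance_ratio_test(a, list(a))
        assert res.estimate == pytest.approx(1.0)

    def test_sd_two_vs_one(self):
        a = np.array([0, 2, 4, 6], dtype=float)  # sd 2x that of b
        b = a / 2.0
        res = variance_ratio_test(a, b)
        assert res.estimate == pytest.approx(4.0)

    def test_matches_f_distribution_oracle(self, rng):
        for _ in range(50):
            a = rng.normal(0, 2, size=int(rng.integers(5, 40)))
            b = rng.normal(0, 1, size=int(rng.integers(5, 40)))
            res = variance_ratio_test(a, b)
            F = np.var(a, ddof=1) / np.var(b, ddof=1)
            d1, d2 = len(a) - 1, len(b) - 1
            p = 2 * min(sps.f.cdf(F, d1, d2), sps.f.sf(F, d1, d2))
            assert abs(res.statistic - F) < 1e-10
            assert abs(res.p_value - min(p, 1.0)) < 1e-10

    def test_scale_invariance(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(size=25)
        r1 = variance_ratio_test(a, b)
        r2 = variance_ratio_test(7.3 * a, 7.3 * b)
        assert r1.estimate == pytest.approx(r2.estimate)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_mutant_contrast_recovery(self, rng):
        # true sd ratio sqrt(11.9) at n=170/group: the mean estimated
        # variance ratio lands within 20% of 11.9 and essentially every
        # trial rejects equality decisively
        estimates, hits = [], 0
        for _ in range(100):
            wt = rng.normal(1.4, 0.4, size=170)
            mut = rng.normal(2.5, 0.4 * np.sqrt(11.9), size=170)
            res = variance_ratio_test(mut, wt)
            estimates.append(res.estimate)
            hits += res.p_value < 1e-6
        assert abs(np.mean(estimates) - 11.9) / 11.9 < 0.2
        assert hits >= 95


class TestGamesHowellAndTukey:
    def test_games_howell_k2_equals_welch(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, size=int(rng.integers(5, 30)))
            b = rng.normal(0.5, 2, size=int(rng.integers(5, 30)))
            gh = anova_games_howell([a, b])["pairwise"][(0, 1)]
            t, p = sps.ttest_ind(a, b, equal_var=False)
            assert abs(gh.p_value - p) < 1e-6

    def test_games_howell_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        groups = [rng.normal(m, s, size=n)
                  for m, s, n in [(1.4, 0.4, 40), (2.3, 1.0, 35), (2.5, 1.4, 30)]]
        res = anova_games_howell(groups)["pairwise"]
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat([0, 1, 2], [len(g) for g in groups]),
            }
        )
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        for _, row in ref.iterrows():
            mine = res[(int(row["A"]), int(row["B"]))]
            assert abs(mine.p_value - row["pval"]) < 1e-6
            assert abs(abs(mine.statistic) - abs(row["T"])) < 1e-8

    def test_tukey_k2_equals_pooled_t(self, rng):
        a = rng.normal(0, 1, size=12)
        b = rng.normal(1, 1, size=15)
        tk = tukey_hsd([a, b])[(0, 1)]
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert abs(tk.p_value - p) < 1e-6

    def test_tukey_matches_scipy(self, rng):
        groups = [rng.normal(m, 1.0, size=20) for m in (0.0, 0.4, 1.0)]
        mine = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for (i, j), res in mine.items():
            assert abs(res.p_value - ref.pvalue[i, j]) < 1e-9

    def test_three_group_mutant_simulation(self, rng):
        # tip-distance contrasts (1.4/2.3/2.5 um means) all significant
        hits = 0
        for _ in range(30):
            groups = [
                rng.normal(1.4, 0.4, size=170),
                rng.normal(2.3, 1.0, size=170),
                rng.normal(2.5, 1.4, size=170),
            ]
            res = anova_games_howell(groups)
            # both mutant-vs-wild-type contrasts decisively significant
            # (the two mutant groups differ by only 0.2 um and need not be)
            ok = res["omnibus"].p_value < 0.001 and all(
                res["pairwise"][pair].p_value < 0.001 for pair in [(0, 1), (0, 2)]
            )
            hits += ok
        assert hits >= 28

    def test_degenerate_groups_error(self):
        with pytest.raises(ValueError):
            anova_games_howell([[1.0, 1.0], [1.0, 1.0]])


class TestChiSquared:
    def test_no_association(self):
        res = chi_squared_counts([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed(self):
        # sum over cells of (O-E)^2/E for [[8,2],[1,9]] is 9.8990
        res = chi_squared_counts([[8, 2], [1, 9]])
        assert round(res.statistic, 4) == 9.8990

    def test_matches_scipy_uncorrected(self, rng):
        for _ in range(30):
            table = rng.integers(1, 40, size=(2, int(rng.integers(2, 5))))
            res = chi_squared_counts(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert abs(res.statistic - ref.statistic) < 1e-10
            assert abs(res.p_value - ref.pvalue) < 1e-10

    def test_stall_proportions_significant(self, rng):
        # 8% vs 33% stalled at n~100/group
        hits = 0
        for _ in range(100):
            a = rng.binomial(100, 0.08)
            b = rng.binomial(100, 0.33)
            res = chi_squared_counts([[a, 100 - a], [b, 100 - b]])
            hits += res.p_value < 0.001
        assert hits >= 95

    def test_empty_margin(self):
        with pytest.raises(ValueError):
            chi_squared_counts([[0, 0], [1, 2]])


class TestKDEAndSummary:
    def make_tracks(self, values):
        tracks = []
        for i, v in enumerate(values):
            t = FocusTrack(track_id=i, channel="fros", frames=[0],
                           positions=[float(v)], amplitudes=[1.0])
            t.tip_index[0] = 1
            tracks.append(t)
        return tracks

    def test_constant_distances(self):
        s = tip_distance_summary(self.make_tracks([1.4] * 10))
        assert s["mean"] == pytest.approx(1.4)
        assert s["sd"] == 0.0

    def test_kde_normalization(self, rng):
        s = tip_distance_summary(self.make_tracks(rng.normal(1.4, 0.4, 200)))
        integral = integrate.trapezoid(s["density"], s["grid"])
        assert abs(integral - 1.0) < 1e-6

    def test_parameter_recovery(self):
        cfg = SimulationConfig(n_hyphae=40, n_frames=30, anchor_offset=1.4,
                               anchor_sd=0.4, seed=77)
        tracks, _ = ground_truth_tracks(simulate_dataset(cfg))
        s = tip_distance_summary(tracks, tip_index=1)
        assert abs(s["mean"] - 1.4) < 0.1
        assert abs(s["sd"] - 0.4) < 0.1

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            tip_distance_summary(self.make_tracks([1.0]))


class TestVelocityPairs:
    def make_track(self, positions, hypha_id=0):
        t = FocusTrack(track_id=0, channel="fros",
                       frames=list(range(len(positions))),
                       positions=list(map(float, positions)),
                       amplitudes=[1.0] * len(positions), hypha_id=hypha_id)
        for f in t.frames:
            t.tip_index[f] = 1
        return t

    def test_anchored_focus_co_moves(self):
        track = self.make_track([1.4, 1.4])
        lengths = {0: {0: 5.0, 1: 5.5}}
        (pair,) = compute_velocity_pairs([track], lengths)
        assert pair.extension == pytest.approx(0.5)
        assert pair.movement == pytest.approx(0.5)

    def test_material_frame_focus_is_static(self):
        track = self.make_track([1.4, 1.9])  # dd == dL
        lengths = {0: {0: 5.0, 1: 5.5}}
        (pair,) = compute_velocity_pairs([track], lengths)
        assert pair.movement == pytest.approx(0.0)

    def test_alternative_sign_convention(self):
        track = self.make_track([1.4, 1.9])
        lengths = {0: {0: 5.0, 1: 5.5}}
        (pair,) = compute_velocity_pairs([track], lengths,
                                         movement_definition="tip_distance")
        assert pair.movement == pytest.approx(-0.5)

    def test_noiseless_slope_equals_coupling(self):
        cfg = SimulationConfig(
            n_hyphae=6, n_frames=15, n_chromosomes_initial=4,
            coupling_base=0.7, anchor_sd=0.0, trailing_noise_sd=0.0,
            extension_rate_sd=0.3, extension_noise_sd=0.2, seed=11,
        )
        tracks, lengths = ground_truth_tracks(simulate_dataset(cfg))
        pairs = compute_velocity_pairs(tracks, lengths)
        corr = correlation_by_index(pairs)
        for j in (2, 3, 4):
            slope = corr["lines"][j][0]
            assert slope == pytest.approx(0.7 ** j, abs=1e-9)

    def test_correlation_decays_with_index(self):
        rho_negative = 0
        for rep in range(10):
            cfg = SimulationConfig(n_hyphae=10, n_frames=20,
                                   n_chromosomes_initial=5,
                                   coupling_base=0.7, seed=500 + rep)
            tracks, lengths = ground_truth_tracks(simulate_dataset(cfg))
            pairs = compute_velocity_pairs(tracks, lengths)
            corr = correlation_by_index(pairs, max_index=5)
            idxs = sorted(corr["per_index"])
            rs = [corr["per_index"][i].estimate for i in idxs]
            rho = sps.spearmanr(idxs, rs).statistic
            rho_negative += rho < 0
        assert rho_negative >= 9


class TestMixedVsPooled:
    def simulate(self, rng, between_sd, n_groups=8, n_per=10, resid_sd=0.3):
        x, y, g = [], [], []
        for i in range(n_groups):
            offset = rng.normal(0, between_sd)
            xi = rng.uniform(0, 1, n_per)
            yi = 1.0 + 2.0 * xi + offset + rng.normal(0, resid_sd, n_per)
            x.extend(xi), y.extend(yi), g.extend([i] * n_per)
        return x, y, g

    def test_no_group_effect_boundary(self, rng):
        x, y, g = self.simulate(rng, between_sd=0.0)
        res = mixed_vs_pooled(x, y, g)
        assert res["lrt"].p_value >= 0.5

    def test_strong_group_effect_detected(self, rng):
        hits = 0
        for _ in range(30):
            x, y, g = self.simulate(rng, between_sd=0.9)
            res = mixed_vs_pooled(x, y, g)
            hits += res["lrt"].p_value < 0.01
            assert res["loglik_mixed"] >= res["loglik_pooled"] - 1e-6
        assert hits >= 28

    def test_under_identified(self):
        with pytest.raises(ValueError):
            mixed_vs_pooled([1, 2, 3], [1, 2, 3], [0, 1, 2])


class TestColocalization:
    def foci(self, positions, channel, hypha=0, frame=0):
        return [Focus(hypha, frame, channel, p, 1.0) for p in positions]

    def test_identical_positions(self):
        a = self.foci([1.0, 3.0], "fros")
        b = self.foci([1.0, 3.0], "parb")
        assert colocalization_fraction(a, b)["fraction"] == 1.0

    def test_distant_pairs(self):
        a = self.foci([1.0], "fros")
        b = self.foci([3.0], "parb")
        assert colocalization_fraction(a, b, cutoff=1.0)["fraction"] == 0.0

    def test_cutoff_is_strict(self):
        a = self.foci([0.0], "fros")
        assert colocalization_fraction(a, self.foci([0.9], "parb"))["fraction"] == 1.0
        assert colocalization_fraction(a, self.foci([1.0], "parb"))["fraction"] == 0.0

    def test_empty_channel_a(self):
        with pytest.raises(ValueError):
            colocalization_fraction([], self.foci([1.0], "parb"))


class TestDuplicationTimecourse:
    def event(self, hypha, lag, appear=3, interval=10.0):
        e = DuplicationEvent(0, 1, 2, split_frame=appear + int(lag // interval),
                             hypha_id=hypha)
        e.replisome_appear_frame = appear
        e.lag_minutes = lag
        e.separation = {
            f: 0.4 * (f - e.split_frame) + 0.8
            for f in range(e.split_frame, e.split_frame + 5)
        }
        return e

    def test_all_duplicated(self):
        events = [self.event(h, 20.0) for h in range(5)]
        out = duplication_fraction_timecourse(events, 5, [10, 20, 30])
        fractions = [b["fraction"] for b in out]
        assert fractions == [0.0, 1.0, 1.0]
        for b in out:
            assert 0.0 <= b["ci_low"] <= b["fraction"] <= b["ci_high"] <= 1.0

    def test_zero_events(self):
        out = duplication_fraction_timecourse([], 10, [10, 20])
        assert all(b["fraction"] == 0.0 for b in out)
        assert all(b["ci_high"] > 0 for b in out)

    def test_seventy_percent_within_wilson_ci(self, rng):
        # 70% of 32 hyphae duplicate within 3 frames of replisome appearance
        n = 32
        events = [self.event(h, 30.0) for h in range(n) if rng.uniform() < 0.7]
        out = duplication_fraction_timecourse(events, n, [30.0])
        b = out[0]
        assert b["ci_low"] <= 0.70 <= b["ci_high"]

    def test_empty_denominator(self):
        with pytest.raises(ValueError):
            duplication_fraction_timecourse([], 0, [10])
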