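"""Motor-component identification: dipole fits, ranks, the motor index f,
and the worked-example scoring table."""

import numpy as np
import pytest

from rest2task.datasets import (
    SAMPLE_EXPECTED,
    SAMPLE_REJECTED,
    SAMPLE_SELECTED,
    sample_ic_parameters,
)
from rest2task.forward import forward_gain
from rest2task.motor_ic import (
    Template,
    fit_dipole,
    loo_templates,
    motor_index,
    power_ratio,
    rank_indices,
    rv_gate,
    score_components,
    select_motor_ics,
)
from rest2task.simulate import _narrowband_noise


@pytest.fixture(scope="module")
def report():
    df = sample_ic_parameters()
    return score_components(
        df["rv"].to_numpy(), df["power_ratio"].to_numpy(),
        df["dist_left"].to_numpy(), df["corr_left"].to_numpy(),
        df["dist_right"].to_numpy(), df["corr_right"].to_numpy(),
        component_ids=df.index.to_numpy(),
    )


class TestWorkedExample:
    """The fully desk-reproducible scoring table of one subject."""

    def test_rv_gate_rejects_components_11_12_13_15(self, report):
        rejected = report.table.index[report.table["rejected"]].tolist()
        assert rejected == list(SAMPLE_REJECTED)

    @pytest.mark.parametrize("column", sorted(SAMPLE_EXPECTED))
    def test_all_printed_ranks_and_f_values_reproduced(self, report, column):
        got = report.table[column].to_numpy()
        expected = np.array(SAMPLE_EXPECTED[column], dtype=float)
        assert np.array_equal(np.isnan(got), np.isnan(expected))
        m = ~np.isnan(expected)
        assert np.array_equal(got[m], expected[m])

    def test_final_selection(self, report):
        assert report.selected_left == SAMPLE_SELECTED["left"]
        assert report.selected_right == SAMPLE_SELECTED["right"]
        assert report.table.loc[report.selected_left, "f_left"] == 6
        assert report.table.loc[report.selected_right, "f_right"] == 8

    def test_f_is_invariant_to_component_permutation(self, rng):
        df = sample_ic_parameters().dropna()
        perm = rng.permutation(len(df))
        base = score_components(
            df["rv"].to_numpy(), df["power_ratio"].to_numpy(),
            df["dist_left"].to_numpy(), df["corr_left"].to_numpy(),
            df["dist_right"].to_numpy(), df["corr_right"].to_numpy(),
            component_ids=df.index.to_numpy(),
        )
        shuf = score_components(
            df["rv"].to_numpy()[perm], df["power_ratio"].to_numpy()[perm],
            df["dist_left"].to_numpy()[perm], df["corr_left"].to_numpy()[perm],
            df["dist_right"].to_numpy()[perm], df["corr_right"].to_numpy()[perm],
            component_ids=df.index.to_numpy()[perm],
        )
        # the left-hemisphere columns are tie-free, so each component's
        # f_left must be unchanged by reordering (right has a 0.07/0.07 tie,
        # whose ordinal break is by design order-dependent)
        merged = base.table[["f_left"]].join(shuf.table[["f_left"]], rsuffix="_shuf")
        assert np.array_equal(merged["f_left"], merged["f_left_shuf"])


class TestRankingPrimitives:
    def test_printed_left_distance_ranks(self):
        dist = np.array([88, 100, 90, 82, 21, 48, 71, 78, 131, 60, 80])
        assert rank_indices(dist, "asc").tolist() == [8, 10, 9, 7, 1, 2, 4, 5, 11, 3, 6]

    def test_tied_correlations_rank_in_component_order(self):
        corr = np.array([0.07, 0.81, 0.44, 0.14, 0.53, 0.30, 0.94, 0.08, 0.27, 0.03, 0.07])
        ranks = rank_indices(corr, "desc")
        assert ranks[0] == 9 and ranks[10] == 10  # the two 0.07 ties
        assert sorted(ranks) == list(range(1, 12))

    def test_single_value(self):
        assert rank_indices(np.array([3.5]), "asc").tolist() == [1]

    @pytest.mark.parametrize(
        "ranks,f", [((1, 1, 1), 6), ((1, 1, 2), 8), ((4, 5, 2), 21), ((11, 6, 9), 57)]
    )
    def test_motor_index_weighted_sum(self, ranks, f):
        i_dist, i_corr, i_ratio = ranks
        assert motor_index(i_dist, i_corr, i_ratio) == f

    def test_minimum_f_requires_rank_one_on_all_criteria(self):
        assert motor_index(1, 1, 1) == 6
        for ranks in [(2, 1, 1), (1, 2, 1), (1, 1, 2)]:
            assert motor_index(*ranks) > 6

    def test_rv_gate_cases(self):
        rvs = np.array([0.022, 0.007, 0.546, 0.102])
        assert rv_gate(rvs).tolist() == [True, True, False, True]
        assert rv_gate(rvs, threshold=1.0).all()
        with pytest.raises(ValueError, match="no candidate"):
            rv_gate(np.full(5, 0.5))


class TestDipoleFit:
    def test_recovers_forward_model_pattern(self, montage, rng):
        _, pos = montage
        for _ in range(3):
            loc = rng.uniform(-0.5, 0.5, 3)
            loc *= 0.6 / max(0.6, np.linalg.norm(loc))
            ori = rng.standard_normal(3)
            fit = fit_dipole(forward_gain(loc, ori, pos), pos)
            assert np.linalg.norm(fit.location - loc) < 0.05
            assert fit.rv < 0.01

    def test_rv_tracks_injected_noise_fraction(self, montage, rng):
        _, pos = montage
        rvs = []
        for _ in range(15):
            p = forward_gain([-0.5, 0.1, 0.45], [1, 0, 1], pos)
            p = p / np.linalg.norm(p)
            noise = rng.standard_normal(len(p))
            p_noisy = p + noise / np.linalg.norm(noise)  # 50% noise energy
            rvs.append(fit_dipole(p_noisy, pos).rv)
        assert abs(np.mean(rvs) - 0.5) < 0.15

    def test_random_patterns_fail_the_gate(self, montage, rng):
        _, pos = montage
        rvs = np.array([fit_dipole(rng.standard_normal(32), pos).rv for _ in range(100)])
        assert (rvs > 0.2).mean() >= 0.95

    def test_zero_pattern_rejected(self, montage):
        _, pos = montage
        with pytest.raises(ValueError, match="zero"):
            fit_dipole(np.zeros(32), pos)


class TestPowerRatio:
    def test_narrowband_sources(self, rng):
        fs = 256.0
        mu = _narrowband_noise(rng, 30_000, fs, [(11, 13)], burst=0)
        beta = _narrowband_noise(rng, 30_000, fs, [(17, 19)], burst=0)
        assert power_ratio(mu, fs)[0] >= 5.0
        assert power_ratio(beta, fs)[0] < 1.0

    def test_white_noise_ratio_near_one(self, rng):
        x = rng.standard_normal(480 * 256)
        assert power_ratio(x, 256.0)[0] == pytest.approx(1.0, abs=0.2)

    def test_requires_two_seconds(self, rng):
        with pytest.raises(ValueError, match="2 s"):
            power_ratio(rng.standard_normal(100), 256.0)


class TestSelection:
    def test_simulated_selection_matches_ground_truth(
        self, sim_subject, rest_decomposition, rest_selection
    ):
        from rest2task.decomposition import best_match_correlations

        _, _, truth = sim_subject
        dec, _ = rest_decomposition
        idx, r = best_match_correlations(
            dec.patterns,
            np.c_[truth.column("motor_left"), truth.column("motor_right")],
        )
        assert rest_selection.selected_left == idx[0]
        assert rest_selection.selected_right == idx[1]
        assert np.all(r >= 0.95)

    def test_report_exposes_quality_in_motorless_scene(self, montage):
        """Without motor sources selection still returns an argmin, and the
        report's correlation columns reveal that the winners are poor."""
        from rest2task.decomposition import apply_filters, decompose_state
        from rest2task.io import state_segments
        from rest2task.motor_ic import canonical_motor_template
        from rest2task.simulate import SimConfig, default_scene, simulate_session

        labels, pos = montage
        scene = [s for s in default_scene() if not s.name.startswith("motor")]
        cfg = SimConfig(scene, n_trials_per_class=25, seed=55)
        ts, _ = simulate_session(cfg)
        X = state_segments(ts, "rest")
        dec = decompose_state(X, seed=55)
        tc = apply_filters(dec, X)
        tc.fs = ts.fs
        rep = select_motor_ics(dec, tc, canonical_motor_template(labels, pos), pos)
        win_corr = [
            rep.table.loc[rep.selected_left, "corr_left"],
            rep.table.loc[rep.selected_right, "corr_right"],
        ]
        assert max(win_corr) < 0.8  # caller can see these are not motor-like

    def test_mm_scale_distances_reported(self, rest_selection):
        t = rest_selection.table
        m = ~t["dist_left"].isna()
        assert np.allclose(t.loc[m, "dist_left_mm"], t.loc[m, "dist_left"] * 87.5)


class TestTemplates:
    def test_identical_subjects_yield_common_template(self, montage):
        labels, pos = montage
        d = {"left": np.array([-0.5, 0, 0.5]), "right": np.array([0.5, 0, 0.5])}
        p = {"left": forward_gain(d["left"], [0, 0, 1], pos),
             "right": forward_gain(d["right"], [0, 0, 1], pos)}
        tpls = loo_templates([d] * 3, [p] * 3)
        for t in tpls:
            assert np.allclose(t.dipole_left, d["left"])
            assert np.allclose(t.pattern_right, p["right"] / np.sign(
                p["right"][np.abs(p["right"]).argmax()]))

    def test_two_subjects_swap(self, montage):
        _, pos = montage
        d1 = {"left": np.array([-0.5, 0, 0.5]), "right": np.array([0.5, 0, 0.5])}
        d2 = {"left": np.array([-0.4, 0.1, 0.5]), "right": np.array([0.4, 0.1, 0.5])}
        p1 = {s: forward_gain(d1[s], [0, 0, 1], pos) for s in d1}
        p2 = {s: forward_gain(d2[s], [0, 0, 1], pos) for s in d2}
        tpls = loo_templates([d1, d2], [p1, p2])
        assert np.allclose(tpls[0].dipole_left, d2["left"])
        assert np.allclose(tpls[1].dipole_left, d1["left"])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="leave-one-out"):
            loo_templates([{}], [{}])

    def test_jittered_cohort_template_near_true_mean(self, montage, rng):
        labels, pos = montage
        from rest2task.simulate import motor_dipole_location

        true = {s: motor_dipole_location(labels, pos, s) for s in ("left", "right")}
        dips, pats = [], []
        for _ in range(9):
            d = {s: true[s] + rng.normal(scale=0.05, size=3) for s in true}
            p = {s: forward_gain(d[s], d[s], pos) for s in d}
            dips.append(d)
            pats.append(p)
        for t in loo_templates(dips, pats):
            assert np.linalg.norm(t.dipole_left - true["left"]) < 0.05
            assert np.linalg.norm(t.dipole_right - true["right"]) < 0.05
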