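"""The four stability statistics against brute-force oracles and limits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from refstab.stability import (
    StabilityError,
    bestkeeper,
    bestkeeper_index,
    delta_ct_stability,
    genorm_m,
    genorm_v,
    normfinder,
    recommend_n_references,
    to_relative_quantities,
)

import oracles
from conftest import make_condition_frame, random_condition_frame


def _rows(frame: pd.DataFrame) -> dict[str, list[float]]:
    return {g: list(frame.loc[g]) for g in frame.index}


class TestRelativeQuantities:
    def test_powers_of_two(self):
        frame = make_condition_frame(["gA"], 3, [[20.0, 21.0, 22.0]])
        q = to_relative_quantities(frame)
        assert np.allclose(q.loc["gA"], [1.0, 0.5, 0.25])

    def test_constant_row_all_ones(self):
        frame = make_condition_frame(["gA"], 4, [[19.5] * 4])
        assert (to_relative_quantities(frame) == 1.0).all(axis=None)

    def test_custom_efficiency_base(self):
        frame = make_condition_frame(["gA"], 2, [[20.0, 21.0]])
        q = to_relative_quantities(frame, efficiency=0.9)
        assert np.allclose(q.loc["gA"], [1.0, 1 / 1.9])

    def test_missing_cells_rejected(self):
        frame = make_condition_frame(["gA", "gB"], 2, [[20, np.nan], [18, 18]])
        with pytest.raises(StabilityError, match="missing"):
            to_relative_quantities(frame)


class TestGenormM:
    def test_constant_offset_pair_survives(self):
        # genes 1,2 differ by a constant Ct offset -> zero pairwise SD
        frame = make_condition_frame(
            ["g1", "g2", "g3"], 4,
            [[20, 21, 22, 23], [18, 19, 20, 21], [20, 23, 19, 25]],
        )
        res = genorm_m(to_relative_quantities(frame))
        assert res.exclusion_order == ["g3"]
        assert res.scores["g1"] == pytest.approx(0.0, abs=1e-12)
        assert res.ranks["g1"] == res.ranks["g2"] == 1.5
        assert res.ranks["g3"] == 3.0

    def test_matches_bruteforce_every_round(self, rng):
        frame = random_condition_frame(rng, 6, 12)
        q = to_relative_quantities(frame)
        res = genorm_m(q)
        rounds, excluded = oracles.genorm_exclusion_rounds(_rows(q))
        assert res.exclusion_order == excluded
        assert len(res.rounds) == len(rounds)
        for got, want in zip(res.rounds, rounds):
            for g, v in want.items():
                assert abs(got[g] - v) < 1e-9

    def test_proportional_profiles_degenerate(self):
        base = np.array([20.0, 21.0, 22.5, 19.0])
        frame = make_condition_frame(["g1", "g2", "g3"], 4, [base, base + 1, base - 2])
        with pytest.warns(UserWarning, match="degenerate"):
            res = genorm_m(to_relative_quantities(frame))
        assert res.degenerate
        assert np.allclose(res.scores, 0.0)

    def test_two_genes_share_single_pairwise_sd(self):
        frame = make_condition_frame(["g1", "g2"], 4, [[20, 21, 22, 23], [20, 22, 21, 23]])
        res = genorm_m(to_relative_quantities(frame))
        assert res.scores["g1"] == pytest.approx(res.scores["g2"])


class TestGenormV:
    def test_matches_bruteforce(self, rng):
        frame = random_condition_frame(rng, 6, 12)
        q = to_relative_quantities(frame)
        res = genorm_m(q)
        curve = genorm_v(q, res.extras["stability_order"])
        want = oracles.genorm_v_curve(_rows(q), res.extras["stability_order"])
        for (n_got, v_got), (n_want, v_want) in zip(curve.values, want):
            assert n_got == n_want and abs(v_got - v_want) < 1e-9

    def test_proportional_profiles_recommend_two(self):
        base = np.array([20.0, 21.0, 22.5, 19.0])
        frame = make_condition_frame(["g1", "g2", "g3"], 4, [base, base + 1, base - 2])
        q = to_relative_quantities(frame)
        with pytest.warns(UserWarning):
            res = genorm_m(q)
        curve = genorm_v(q, res.extras["stability_order"])
        assert all(v == pytest.approx(0.0, abs=1e-12) for _, v in curve.values)
        assert curve.recommended_n == 2

    def test_recommendation_rule_boundaries(self):
        assert recommend_n_references([(2, 0.149), (3, 0.2)]) == (2, True)
        assert recommend_n_references([(2, 0.151), (3, 0.149)]) == (3, True)
        assert recommend_n_references([(2, 0.16), (3, 0.17)]) == (4, False)
        # strict inequality: exactly 0.15 does not fire
        assert recommend_n_references([(2, 0.15), (3, 0.14)]) == (3, True)

    def test_no_curve_below_three_genes(self):
        frame = make_condition_frame(["g1", "g2"], 4, [[20, 21, 22, 23], [20, 22, 21, 23]])
        q = to_relative_quantities(frame)
        with pytest.raises(StabilityError):
            genorm_v(q, ["g1", "g2"])


class TestNormfinder:
    def test_constant_centered_profile_scores_zero(self):
        # perturbations of gA..gC sum to zero per sample, so the cross-gene
        # column mean is baseline + loading and gD's centered profile is
        # exactly constant -> stability 0, rank 1
        load = np.array([0.0, 0.5, -0.5, 1.0, 0.2, -0.2])
        p = np.array([0.0, 0.3, -0.1, 0.2, -0.3, 0.1])
        q = np.array([0.0, -0.2, 0.4, -0.1, 0.3, -0.2])
        rows = [20 + load + p, 18 + load + q, 22 + load - p - q, 19 + load]
        frame = make_condition_frame(["gA", "gB", "gC", "gD"], 6, rows)
        res = normfinder(frame)
        assert res.scores["gD"] == pytest.approx(0.0, abs=1e-12)
        assert res.ranks["gD"] == 1.0

    def test_group_shift_penalized(self, rng):
        # one gene takes a 2-cycle between-group shift; another is pure noise
        n = 6
        cols = [("A", float(i)) for i in range(n)] + [("B", float(i)) for i in range(n)]
        shifted = np.r_[np.full(n, 20.0), np.full(n, 22.0)] + 0.05 * rng.standard_normal(2 * n)
        quiet = 19.0 + 0.1 * rng.standard_normal(2 * n)
        others = 21.0 + 0.3 * rng.standard_normal((2, 2 * n))
        frame = pd.DataFrame(
            np.vstack([shifted, quiet, others]),
            index=pd.Index(["shifted", "quiet", "o1", "o2"], name="gene"),
            columns=pd.MultiIndex.from_tuples(cols, names=("treatment", "timepoint")),
        )
        groups = {c: c[0] for c in frame.columns}
        res = normfinder(frame, groups=groups)
        assert res.scores["shifted"] > res.scores["quiet"]
        assert res.extras["n_groups"] == 2

    def test_single_sample_group_rejected(self):
        cols = [("A", 0.0), ("A", 1.0), ("B", 0.0)]
        frame = pd.DataFrame(
            20 + np.arange(9.0).reshape(3, 3),
            index=pd.Index(["g1", "g2", "g3"], name="gene"),
            columns=pd.MultiIndex.from_tuples(cols, names=("treatment", "timepoint")),
        )
        with pytest.raises(StabilityError, match="B"):
            normfinder(frame, groups={c: c[0] for c in frame.columns})

    def test_needs_three_genes(self):
        frame = make_condition_frame(["g1", "g2"], 4, np.full((2, 4), 20.0))
        with pytest.raises(StabilityError):
            normfinder(frame)


class TestBestkeeper:
    def test_hand_arithmetic(self):
        frame = make_condition_frame(["gA", "gB"], 3, [[20, 21, 22], [18, 18, 18]])
        res = bestkeeper(frame)
        assert res.scores["gA"] == pytest.approx(1.0)
        assert res.extras["cv_pct"]["gA"] == pytest.approx(100 / 21, abs=1e-9)
        assert not res.extras["sd_flag"]["gA"]  # SD == 1 is not > 1
        assert res.scores["gB"] == 0.0 and res.ranks["gB"] == 1.0

    def test_sd_boundary_flags(self):
        # deviations scaled by 1.0001 -> SD exactly 1.0001
        frame = make_condition_frame(
            ["on", "over"], 3, [[20.0, 21.0, 22.0], [19.9999, 21.0, 22.0001]]
        )
        res = bestkeeper(frame)
        assert res.scores["over"] == pytest.approx(1.0001, abs=1e-9)
        assert not res.extras["sd_flag"]["on"]
        assert bool(res.extras["sd_flag"]["over"])

    def test_matches_bruteforce(self, rng):
        frame = random_condition_frame(rng, 6, 12)
        res = bestkeeper(frame)
        want = oracles.bestkeeper_stats(_rows(frame))
        for g, (sd, cv) in want.items():
            assert abs(res.scores[g] - sd) < 1e-9
            assert abs(res.extras["cv_pct"][g] - cv) < 1e-9

    def test_mad_variant(self):
        frame = make_condition_frame(["gA", "gB"], 3, [[20, 21, 22], [18, 18, 18]])
        res = bestkeeper(frame, use_mad=True)
        assert res.scores["gA"] == pytest.approx(2 / 3)


class TestBestkeeperIndex:
    def test_gene_identical_to_index(self):
        base = np.array([20.0, 21.0, 19.5, 20.5])
        frame = make_condition_frame(["g1", "g2", "g3"], 4, [base, base, base])
        out = bestkeeper_index(frame)
        assert np.allclose(out["pearson_r"], 1.0)

    def test_noise_decorrelates(self, rng):
        frame = random_condition_frame(rng, 5, 12)
        out = bestkeeper_index(frame)
        assert (out["pearson_r"] < 1.0).all()

    def test_matches_direct_correlation(self, rng):
        # dispersion kept under the SD cutoff so every gene joins the index
        frame = random_condition_frame(rng, 5, 12, scale=0.3)
        out = bestkeeper_index(frame)
        logs = np.log(frame.to_numpy())
        index = np.exp(logs.mean(axis=0))
        for g in frame.index:
            want = oracles.pearson_r(list(frame.loc[g]), list(index))
            assert abs(out.loc[g, "pearson_r"] - want) < 1e-9

    def test_too_few_survivors_skipped(self):
        frame = make_condition_frame(
            ["g1", "g2", "g3"], 3,
            [[10, 20, 30], [10, 21, 32], [20, 20, 20]],
        )
        with pytest.warns(UserWarning, match="skipped"):
            assert bestkeeper_index(frame) is None


class TestDeltaCt:
    def test_constant_offset_pair_zero_sd(self):
        frame = make_condition_frame(
            ["g1", "g2", "g3"], 4,
            [[20, 21, 22, 23], [18, 19, 20, 21], [20, 23, 19, 25]],
        )
        res = delta_ct_stability(frame)
        pair_sd = np.std(frame.loc["g1"] - frame.loc["g3"], ddof=1)
        assert res.scores["g1"] == pytest.approx(pair_sd / 2)

    def test_matches_bruteforce(self, rng):
        frame = random_condition_frame(rng, 6, 12)
        res = delta_ct_stability(frame)
        want = oracles.delta_ct_scores(_rows(frame))
        for g, v in want.items():
            assert abs(res.scores[g] - v) < 1e-9

    def test_exact_ties_share_average_rank(self):
        # two genes mirror-symmetric around a third -> identical mean SD
        frame = make_condition_frame(
            ["up", "down", "mid"], 4,
            [[20, 21, 22, 23], [26, 25, 24, 23], [23, 23, 23, 23]],
        )
        res = delta_ct_stability(frame)
        assert res.scores["up"] == pytest.approx(res.scores["down"])
        assert res.ranks["up"] == res.ranks["down"]
        assert res.ranks["up"] in (1.5, 2.5)


class TestMethodLevelInvariants:
    def test_common_sample_shift_cancels_in_genorm_and_delta_ct(self, rng):
        frame = random_condition_frame(rng, 5, 10)
        shift = rng.normal(0, 1, size=10)
        shifted = frame + shift
        a, b = genorm_m(to_relative_quantities(frame)), genorm_m(to_relative_quantities(shifted))
        assert np.allclose(a.scores, b.scores, atol=1e-9)
        da, db = delta_ct_stability(frame), delta_ct_stability(shifted)
        assert np.allclose(da.scores, db.scores, atol=1e-9)

    def test_delta_ct_equals_genorm_on_ct_scale(self, rng):
        # with E=1, log2 Q differences equal negated Ct differences
        frame = random_condition_frame(rng, 6, 12)
        dc = delta_ct_stability(frame)
        gm_first_round = genorm_m(to_relative_quantities(frame)).rounds[0]
        for g in frame.index:
            assert abs(dc.scores[g] - gm_first_round[g]) < 1e-9

    def test_permutation_equivariance(self, rng):
        frame = random_condition_frame(rng, 6, 12)
        perm_genes = frame.sample(frac=1, random_state=7)
        perm_samples = frame.sample(frac=1, axis=1, random_state=9)
        for fn in (
            lambda f: delta_ct_stability(f).scores,
            lambda f: bestkeeper(f).scores,
            lambda f: normfinder(f).scores,
            lambda f: genorm_m(to_relative_quantities(f)).scores,
        ):
            base = fn(frame).sort_index()
            assert np.allclose(fn(perm_genes).sort_index(), base, atol=1e-12)
            assert np.allclose(fn(perm_samples).sort_index(), base, atol=1e-12)
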