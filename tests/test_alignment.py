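"""IC-weighted PCC column scores, local PWM alignment, empirical p-values."""

import numpy as np
import pytest

import zfpwm as z
from zfpwm.alignment import NullModel, column_score

from conftest import brute_force_align, random_pwm


def sharp_pwm(consensus):
    """A PWM with IC-2 columns spelling the consensus."""
    m = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        m[i, "ACGT".index(b)] = 1.0
    return z.PWM(m)


class TestColumnScore:
    def test_affine_match_with_ic2_column_scores_one(self):
        assert column_score([0.7, 0.1, 0.1, 0.1], [1, 0, 0, 0]) == \
            pytest.approx(1.0, abs=1e-12)

    def test_uniform_experimental_column_scores_zero(self, rng):
        for _ in range(5):
            pred = rng.dirichlet([0.5] * 4)
            assert column_score(pred, [0.25] * 4) == 0.0

    def test_bounded_and_maximized_by_affine_transform(self, rng):
        for _ in range(50):
            e = rng.dirichlet([0.7] * 4)
            p = rng.dirichlet([0.7] * 4)
            s = column_score(p, e)
            assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12
            # the max over predictions is IC(e)/2, attained at pred = e
            assert s <= column_score(e, e) + 1e-12
            assert column_score(e, e) == pytest.approx(
                z.information_content(e) / 2, abs=1e-9)

    def test_invariant_under_joint_nucleotide_permutation(self, rng):
        p = rng.dirichlet([1] * 4)
        e = rng.dirichlet([1] * 4)
        ref = column_score(p, e)
        for _ in range(5):
            perm = rng.permutation(4)
            assert column_score(p[perm], e[perm]) == pytest.approx(ref, abs=1e-12)


class TestAlignPWMs:
    def test_identity_alignment_scores_column_count(self):
        pred = sharp_pwm("GCGTACG")
        res = z.align_pwms(pred, z.PWM(pred.matrix.copy()))
        assert res.orientation == "forward"
        assert res.pred_span == (0, 7) and res.exp_span == (0, 7)
        assert res.total_score == pytest.approx(7.0)  # sum IC/2 = 1 per column

    def test_reverse_complement_scores_identically(self):
        pred = sharp_pwm("GCGTACG")
        res = z.align_pwms(pred, z.reverse_complement(pred))
        assert res.orientation == "revcomp"
        assert res.total_score == pytest.approx(7.0)

    def test_uniform_flanks_are_excluded_from_the_window(self):
        pred = sharp_pwm("GCGTACG")
        flank = np.full((3, 4), 0.25)
        exp = z.PWM(np.vstack([flank, pred.matrix[1:6], flank]))
        res = z.align_pwms(pred, exp)
        assert res.pred_span == (1, 6)
        assert res.exp_span == (3, 8)
        assert res.total_score == pytest.approx(5.0)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            pred = random_pwm(rng, int(rng.integers(3, 11)))
            exp = random_pwm(rng, int(rng.integers(3, 11)))
            res = z.align_pwms(pred, exp)
            oracle = brute_force_align(pred, exp)
            assert res.total_score == pytest.approx(oracle["total"], abs=1e-12)
            assert res.orientation == oracle["orientation"]
            assert res.pred_span == oracle["pred_span"]
            assert res.offset == oracle["offset"]
            np.testing.assert_allclose(res.column_scores, oracle["scores"],
                                       atol=1e-12)

    def test_result_bookkeeping(self, rng):
        pred = random_pwm(rng, 6)
        exp = random_pwm(rng, 9)
        res = z.align_pwms(pred, exp)
        assert res.total_score == pytest.approx(sum(res.column_scores))
        assert res.span_length == res.exp_span[1] - res.exp_span[0]
        assert res.span_length >= 3
        assert res.offset == res.exp_span[0] - res.pred_span[0]

    def test_empty_or_too_short_inputs_rejected(self, rng):
        empty = z.PWM(np.zeros((0, 4)))
        two = random_pwm(rng, 2)
        with pytest.raises(ValueError):
            z.align_pwms(empty, random_pwm(rng, 5))
        with pytest.raises(ValueError):
            z.align_pwms(two, random_pwm(rng, 5), min_overlap=3)


class TestEmpiricalPValue:
    def test_untouchable_observed_score_gives_minimum_p(self, rng):
        pred = sharp_pwm("GCGTA")
        exp = z.PWM(pred.matrix.copy())
        pool = np.full((50, 4), 0.25)  # uniform nulls can never score > 0
        null = NullModel(pool, n_random=99, seed=1)
        assert z.empirical_pvalue(pred, exp, null) == pytest.approx(1 / 100)

    def test_zero_n_random_rejected(self, rng):
        with pytest.raises(ValueError):
            NullModel(np.full((5, 4), 0.25), n_random=0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            NullModel(np.zeros((0, 4)))

    def test_monotone_in_observed_score(self, rng):
        pred = random_pwm(rng, 6)
        exp = random_pwm(rng, 8)
        pool = rng.dirichlet([1] * 4, size=100)
        null = NullModel(pool, n_random=499, seed=3)
        ps = [z.empirical_pvalue(pred, exp, null, observed=o)
              for o in (0.5, 1.5, 3.0, 6.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_null_is_calibrated(self, rng):
        """Experimental matrices drawn from the pool give ~uniform p-values."""
        from zfpwm.synth import generate_background_columns

        pred = random_pwm(rng, 7, alpha=0.2)
        pool = generate_background_columns(300, 1.0, seed=8)
        ps = []
        for rep in range(60):
            exp = z.PWM(pool[rng.integers(0, len(pool), size=8)])
            null = NullModel(pool, n_random=199, seed=int(rng.integers(2**31)))
            ps.append(z.empirical_pvalue(pred, exp, null))
        frac = np.mean(np.array(ps) <= 0.2)
        assert 0.08 <= frac <= 0.35  # coarse check; fine-grained in acceptance


class TestDownstreamMeasures:
    def test_identity_alignment_is_fully_correct(self):
        pred = sharp_pwm("GCGTACG")
        res = z.align_pwms(pred, z.PWM(pred.matrix.copy()))
        assert z.fraction_correct_columns(res) == 1.0

    def test_near_uniform_experiment_scores_nothing_correct(self, rng):
        pred = sharp_pwm("GCGTA")
        exp = z.PWM(np.full((5, 4), 0.25) + 0.0)
        # uniform exp columns have IC 0 -> all scores 0 < 0.25
        res = z.align_pwms(pred, exp)
        assert z.fraction_correct_columns(res) == 0.0

    def test_six_of_seven_columns(self):
        pred = sharp_pwm("GCGTACG")
        exp_m = pred.matrix.copy()
        exp_m[6] = [0.25, 0.26, 0.25, 0.24]  # ruin one column, keep IC > 0
        res = z.align_pwms(pred, z.PWM(exp_m))
        assert z.fraction_correct_columns(res) == pytest.approx(6 / 7)

    @pytest.mark.parametrize("col,expected", [
        ((0, 0.5, 0.4, 0.1), "CG_rich"),
        ((0.5, 0, 0, 0.5), "AT_rich"),
        ((0.25, 0.25, 0.25, 0.25), "mixed"),
    ])
    def test_column_composition(self, col, expected):
        assert z.classify_column_composition(col) == expected


class TestProteinCorrect:
    def test_definition_on_crafted_pvalues(self, rng):
        pred = sharp_pwm("GCGTACG")
        matching = z.PWM(pred.matrix.copy())
        pool = rng.dirichlet([1] * 4, size=100)
        null = NullModel(pool, n_random=999, seed=5)
        # decoys drawn from the null pool itself cannot beat the exact match
        decoys = [z.PWM(pool[rng.integers(0, 100, size=8)]) for _ in range(2)]
        ok, (arr, exp, p) = z.protein_correct([pred], decoys + [matching], null)
        assert ok and p == pytest.approx(1 / 1000)
        assert exp is not None and len(exp) == 7

    def test_no_match_returns_false(self, rng):
        pred = sharp_pwm("GGGGGGG")
        pool = rng.dirichlet([0.3] * 4, size=200)
        null = NullModel(pool, n_random=199, seed=6)
        # experimental matrices drawn from the null pool itself: generically
        # insignificant, but guard with the returned p rather than chance
        exps = [z.PWM(pool[rng.integers(0, 200, size=8)]) for _ in range(2)]
        ok, (_, _, p) = z.protein_correct([pred], exps, null)
        assert ok == (p <= 0.05)

    def test_all_empty_after_trim_is_an_error(self, rng):
        pred = sharp_pwm("GCGTACG")
        uniform = z.PWM(np.full((6, 4), 0.25))
        null = NullModel(rng.dirichlet([1] * 4, size=50), n_random=9, seed=0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                z.protein_correct([pred], [uniform], null)

    def test_planted_scenario_is_recovered(self, planted, trained_planted):
        pred = z.array_pwm(trained_planted, planted.array)
        exp = planted.experimental_pwm()
        pool = np.random.default_rng(99).dirichlet([1] * 4, size=300)
        null = NullModel(pool, n_random=499, seed=11)
        ok, (_, _, p) = z.protein_correct([pred], [exp], null)
        assert ok and p <= 0.05
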