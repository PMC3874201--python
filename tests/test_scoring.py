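"""Training and applying contact-energy scorers."""

import numpy as np
import pytest

import zfpwm as z
from zfpwm import encoding, scoring
from zfpwm.scoring import ScoringModel, TrainingExample

from conftest import random_residues


def single_weight_model(aa="R", base="G", contact=(-1, 3), value=1.0):
    cm = z.CANONICAL
    w = np.zeros(cm.dims)
    c = cm.contacts.index(contact)
    w[encoding.feature_index(aa, base, c, cm)] = value
    return ScoringModel(kind="linear_canonical", contact_model=cm, w=w)


def separable_examples(rng, n=20):
    """Labels from a random planted direction, guaranteed separable."""
    from zfpwm.synth import generate_training_set, planted_weights

    w = planted_weights(z.CANONICAL, seed=5)
    return generate_training_set(w, n // 2, n - n // 2, margin=0.3,
                                 seed=int(rng.integers(2**31)))


class TestTrainLinear:
    def test_separable_labels_recovered(self, rng):
        examples = separable_examples(rng)
        model = scoring.train_linear(examples, model=z.CANONICAL,
                                     regularization=100.0)
        for ex in examples:
            assert np.sign(model.score(ex.residues, ex.site)) == ex.label

    def test_origin_constraint_zero_vector_scores_zero(self, rng):
        model = scoring.train_linear(separable_examples(rng), model=z.CANONICAL)
        # an all-X helix encodes to the zero vector
        assert model.score(("X", "X", "X", "X"), "ACGT") == 0.0

    def test_auto_regularization_is_inverse_mean_squared_norm(self, rng):
        model = scoring.train_linear(separable_examples(rng), model=z.CANONICAL,
                                     regularization="auto")
        assert model.metadata["C"] == pytest.approx(0.25)  # ||x||^2 = 4 always

    def test_single_class_or_empty_input_rejected(self):
        ex = TrainingExample(("R", "D", "E", "R"), "GCGT", 1)
        with pytest.raises(ValueError):
            scoring.train_linear([ex, ex], model=z.CANONICAL)
        with pytest.raises(ValueError):
            scoring.train_linear([], model=z.CANONICAL)

    def test_planted_weights_sign_agreement_on_held_out(self, planted,
                                                        trained_planted):
        """>= 95% held-out sign agreement after training on 2000+2000 pairs."""
        from zfpwm.synth import generate_training_set

        held_out = generate_training_set(planted.w_true, 1000, 1000,
                                         margin=0.1, seed=777)
        agree = np.mean([
            np.sign(trained_planted.score(ex.residues, ex.site)) == ex.label
            for ex in held_out])
        assert agree >= 0.95

    def test_retraining_is_deterministic(self, rng):
        examples = separable_examples(rng, n=40)
        a = scoring.train_linear(examples, model=z.CANONICAL)
        b = scoring.train_linear(examples, model=z.CANONICAL)
        np.testing.assert_array_equal(a.w, b.w)


class TestTrainPolynomial:
    def xor_examples(self):
        out = []
        for r1 in "RK":
            for r3 in "RK":
                label = 1 if r1 == r3 else -1
                out.extend(TrainingExample((r1, "A", r3, "A"), "AAAA", label)
                           for _ in range(10))
        return out

    def test_interaction_labels_need_the_kernel(self):
        """Parity of two helix-residue identities: quadratic yes, linear no."""
        examples = self.xor_examples()

        def accuracy(model):
            return np.mean([(1 if model.score(e.residues, e.site) > 0 else -1)
                            == e.label for e in examples])

        linear = scoring.train_linear(examples, model=z.CANONICAL,
                                      regularization=1.0)
        poly = scoring.train_polynomial(examples, regularization=1.0)
        assert accuracy(poly) >= 0.95
        assert accuracy(linear) <= 0.65

    def test_separable_labels_recovered(self, rng):
        examples = separable_examples(rng)
        model = scoring.train_polynomial(examples, regularization=100.0)
        for ex in examples:
            assert np.sign(model.score(ex.residues, ex.site)) == ex.label

    def test_deterministic_and_origin_constrained(self):
        examples = self.xor_examples()
        a = scoring.train_polynomial(examples)
        b = scoring.train_polynomial(examples)
        np.testing.assert_array_equal(a.w, b.w)
        assert a.score(("X", "X", "X", "X"), "AAAA") == 0.0

    def test_only_degree_two_supported(self):
        with pytest.raises(ValueError):
            scoring.train_polynomial(self.xor_examples(), degree=3)


class TestScore:
    def test_zero_weights_score_zero_everywhere(self):
        model = ScoringModel(kind="linear_canonical", contact_model=z.CANONICAL,
                             w=np.zeros(320))
        assert all(model.score(("R", "D", "E", "R"), s) == 0.0
                   for s in ["AAAA", "GCGT", "TTTT"])

    def test_single_weight_fires_only_on_matching_contact(self):
        model = single_weight_model()
        finger = ("R", "A", "A", "A")
        for site in z.enumerate_sites():
            expected = 1.0 if site[2] == "G" else 0.0
            assert model.score(finger, site) == expected

    def test_linear_score_is_sum_over_contacts(self, rng):
        from conftest import random_linear_model

        model = random_linear_model(rng)
        res = random_residues(rng)
        site = "".join(rng.choice(list("ACGT"), size=4))
        vec = encoding.encode_interface(res, site, z.CANONICAL)
        assert model.score(res, site) == pytest.approx(
            sum(model.w[i] for i in vec.nonzero_indices), abs=1e-12)

    def test_linear_score_additive_over_positions(self, rng):
        from conftest import random_linear_model

        model = random_linear_model(rng, z.EXPANDED)
        res = random_residues(rng)
        e = model.position_energies(res)
        for site in ["AAAA", "GCGT", "TCAG"]:
            total = sum(e[pos, "ACGT".index(b)] for pos, b in enumerate(site))
            assert model.score(res, site) == pytest.approx(total, abs=1e-12)


class TestPersistence:
    @pytest.mark.parametrize("kind", ["linear_canonical", "linear_expanded",
                                      "polynomial"])
    def test_round_trip_preserves_scores(self, kind, rng, tmp_path):
        examples = separable_examples(rng, n=30)
        if kind == "polynomial":
            model = scoring.train_polynomial(examples)
        else:
            cm = z.CANONICAL if kind.endswith("canonical") else z.EXPANDED
            model = scoring.train_linear(examples, model=cm)
        path = tmp_path / "model.txt"
        scoring.save_model(model, path)
        back = scoring.load_model(path)
        assert back.kind == model.kind
        for _ in range(10):
            res = random_residues(rng)
            site = "".join(rng.choice(list("ACGT"), size=4))
            assert back.score(res, site) == pytest.approx(
                model.score(res, site), abs=1e-12)

    def test_version_mismatch_rejected(self, rng, tmp_path):
        model = scoring.train_linear(separable_examples(rng), model=z.CANONICAL)
        path = tmp_path / "model.txt"
        scoring.save_model(model, path)
        text = path.read_text().replace("format_version: 1", "format_version: 99")
        path.write_text(text)
        with pytest.raises(ValueError, match="version"):
            scoring.load_model(path)


def test_standardize_scores_sets_unit_sd(rng):
    from conftest import random_linear_model

    model = random_linear_model(rng, scale=7.3)
    fingers = [random_residues(rng) for _ in range(20)]
    std = scoring.standardize_scores(model, fingers)
    scores = np.concatenate([std.site_scores(f) for f in fingers])
    assert scores.std() == pytest.approx(1.0, rel=1e-9)


def test_training_tsv_round_trip(tmp_path, rng):
    examples = separable_examples(rng, n=10)
    path = tmp_path / "train.tsv"
    scoring.write_training_tsv(examples, path)
    back = scoring.read_training_tsv(path)
    assert back == examples
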