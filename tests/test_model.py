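"""One-hot encoding, network architecture contracts, training determinism,
grid search and the linear baseline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from emotifre.model import (
    ConvNet,
    EncodingError,
    Hyperparams,
    baseline_linear,
    encode_batch,
    grid_search,
    one_hot_decode,
    one_hot_encode,
    train,
)
from emotifre.simulate import random_background

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestOneHot:
    def test_acgt_rows(self):
        mat = one_hot_encode("ACGT")
        assert np.array_equal(mat, np.eye(4))

    def test_column_sums(self):
        mat = one_hot_encode("AAAA")
        assert mat[:, 0].sum() == 4 and mat[:, 1:].sum() == 0

    def test_non_acgt_rejected(self):
        with pytest.raises(EncodingError):
            one_hot_encode("ACGN")

    @given(dna)
    def test_round_trip(self, seq):
        assert one_hot_decode(one_hot_encode(seq)) == seq

    def test_mixed_lengths_rejected(self):
        with pytest.raises(EncodingError):
            encode_batch(["ACGT", "ACG"])


class TestArchitecture:
    def test_flatten_width_is_filter_count(self):
        hp = Hyperparams(n_filters=32, kernel_size=12, seed=0)
        model = ConvNet(hp, input_length=500)
        x = encode_batch(random_background(3, 500, 0.5, seed=0))
        _, cache = model.forward(x, cache=True)
        assert cache["m"].shape == (3, 32)

    def test_zeroed_output_head_predicts_half(self):
        model = ConvNet(Hyperparams(seed=0), input_length=100)
        model.params["w2"][:] = 0.0
        model.params["b2"][:] = 0.0
        x = encode_batch(random_background(5, 100, 0.5, seed=1))
        assert np.allclose(model.predict_proba(x), 0.5)

    def test_probabilities_in_open_interval(self):
        model = ConvNet(Hyperparams(seed=3), input_length=80)
        x = encode_batch(random_background(16, 80, 0.5, seed=2))
        p = model.predict_proba(x)
        assert p.shape == (16,) and np.all((p > 0) & (p < 1))

    def test_batch_order_invariance(self):
        model = ConvNet(Hyperparams(seed=4), input_length=60)
        x = encode_batch(random_background(10, 60, 0.5, seed=5))
        p = model.predict_proba(x)
        perm = np.random.default_rng(0).permutation(10)
        assert np.allclose(model.predict_proba(x[perm]), p[perm])

    def test_kernel_wider_than_input_rejected(self):
        with pytest.raises(ValueError):
            ConvNet(Hyperparams(kernel_size=200), input_length=100)


class TestTraining:
    def test_same_seed_reproduces_report(self, small_dataset):
        pos, neg, _ = small_dataset
        hp = Hyperparams(n_filters=8, kernel_size=8, dense_units=8, max_epochs=4,
                         patience=2, seed=5)
        _, r1 = train(pos[:80], neg[:80], hp)
        _, r2 = train(pos[:80], neg[:80], hp)
        assert r1 == r2

    def test_learns_synthetic_signal(self, small_model):
        _, report = small_model
        assert report.auroc > 0.85

    def test_too_few_examples_rejected(self):
        seqs = random_background(5, 50, 0.5, seed=0)
        with pytest.raises(ValueError, match="at least 10"):
            train(seqs, seqs, Hyperparams())

    def test_checkpoint_round_trip(self, tmp_path, small_model):
        model, _ = small_model
        path = str(tmp_path / "model.ckpt")
        model.save(path)
        back = ConvNet.load(path + ".npz")
        x = encode_batch(random_background(4, model.input_length, 0.5, seed=9))
        assert np.allclose(back.predict_proba(x), model.predict_proba(x))

    def test_translation_tolerance(self, small_model):
        """Global max pooling keeps the prediction stable when the implanted
        motif shifts within the sequence."""
        model, _ = small_model
        rng = np.random.default_rng(21)
        base = random_background(50, 100, 0.55, seed=21)
        center, shifted = [], []
        for seq in base:
            pos0 = 46
            shift = int(rng.integers(-20, 21))
            center.append(seq[:pos0] + "CAGCTGC" + seq[pos0 + 7:])
            p1 = pos0 + shift
            shifted.append(seq[:p1] + "CAGCTGC" + seq[p1 + 7:])
        p_center = model.predict_proba(encode_batch(center))
        p_shift = model.predict_proba(encode_batch(shifted))
        assert np.mean(np.abs(p_center - p_shift)) < 0.2


class TestGridSearch:
    def test_singleton_grid_returns_it(self, small_dataset):
        pos, neg, _ = small_dataset
        hp = Hyperparams(n_filters=8, kernel_size=8, dense_units=8, max_epochs=3,
                         patience=2, seed=7)
        best, table = grid_search([hp], pos[:60], neg[:60])
        assert best is hp and len(table) == 1

    def test_invalid_cell_contained_and_best_is_argmax(self, small_dataset):
        pos, neg, _ = small_dataset
        grid = [
            Hyperparams(n_filters=8, kernel_size=8, dense_units=8, max_epochs=3,
                        patience=2, seed=7),
            Hyperparams(n_filters=8, kernel_size=500, dense_units=8, max_epochs=3,
                        patience=2, seed=7),
            Hyperparams(n_filters=4, kernel_size=12, dense_units=8, max_epochs=3,
                        patience=2, seed=7),
        ]
        best, table = grid_search(grid, pos[:60], neg[:60])
        assert not table.loc[1, "valid"]
        valid = table[table["valid"]]
        assert best.kernel_size != 500
        assert valid["val_auroc"].max() == pytest.approx(
            valid.loc[valid["val_auroc"].idxmax(), "val_auroc"]
        )
        assert (best.n_filters, best.kernel_size) in [
            (g.n_filters, g.kernel_size) for g in grid
        ]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], ["ACGT"] * 20, ["ACGT"] * 20)


def test_linear_baseline_learns_marginal_signal(small_dataset):
    pos, neg, _ = small_dataset
    report = baseline_linear(pos, neg, seed=0)
    assert report.auroc > 0.5
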