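"""Splits, early stopping, LISI, adversarial alternation, grid search."""

import numpy as np
import pandas as pd
import pytest

from crosscell import (CVAE, ModelConfig, TrainConfig, compute_lisi, fit,
                       grid_search, simulate_multispecies, split_train_val)
from crosscell.training import EarlyStopper


def _levels(m):
    return {"species": sorted(m.cells["species"].unique()),
            "batch": sorted(m.cells["batch"].unique()),
            "tissue": sorted(m.cells["tissue"].unique())}


class TestSplit:
    def _cells(self, n, species="mouse"):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                             "species": [species] * n,
                             "cell_type": ["t0"] * n})

    def test_ten_percent_validation(self):
        tr, va, te = split_train_val(self._cells(1000), None, seed=0)
        assert len(va) == 100 and len(te) == 0 and len(tr) == 900

    def test_cap_binds(self):
        tr, va, te = split_train_val(self._cells(500_000), None,
                                     val_cap=20000, seed=0)
        assert len(va) == 20000

    def test_same_seed_identical_split(self):
        s1 = split_train_val(self._cells(300), None, seed=5)
        s2 = split_train_val(self._cells(300), None, seed=5)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a, b)

    def test_disjoint_cover(self):
        cells = self._cells(200)
        cells.loc[:49, "cell_type"] = "held"
        tr, va, te = split_train_val(cells, {"cell_type": "held"}, seed=1)
        assert len(te) == 50
        allidx = np.sort(np.concatenate([tr, va, te]))
        np.testing.assert_array_equal(allidx, np.arange(200))

    def test_selector_matching_everything_raises(self):
        with pytest.raises(ValueError):
            split_train_val(self._cells(10), {"species": "mouse"})


class TestEarlyStopping:
    def test_patience_trace(self):
        # losses [5, 4, 4.1, 4.2, 4.3] with patience 2: stop after the 4th
        # epoch, best model is the one from epoch index 1
        stopper = EarlyStopper(patience=2)
        stops = [stopper.update(i, v) for i, v in enumerate([5, 4, 4.1, 4.2, 4.3])]
        assert stops == [False, False, False, True, True]
        assert stopper.best_epoch == 1 and stopper.best == 4

    def test_monotone_decrease_never_stops(self):
        stopper = EarlyStopper(patience=2)
        assert not any(stopper.update(i, 10 - i) for i in range(10))
        assert stopper.best_epoch == 9


@pytest.fixture(scope="module")
def fitted():
    m, truth = simulate_multispecies(n_cells_per_species=150, n_genes=60,
                                     n_cell_types=2, seed=21)
    cfg = TrainConfig(patience=5, max_epochs=15, seed=21)
    tr_idx, va_idx, _ = split_train_val(m.cells, None, seed=21)
    model = CVAE(60, _levels(m), ModelConfig(n_latent=8, hidden_width=32, seed=21))
    tm = fit(model, m, cfg, tr_idx, va_idx)
    return m, truth, tm


class TestFit:
    def test_loss_decreases_on_synthetic_data(self, fitted):
        _, _, tm = fitted
        h = tm.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]
        assert tm.best_val_loss <= h["val_loss"].min() + 1e-12

    def test_returned_epoch_is_validation_argmin(self, fitted):
        _, _, tm = fitted
        assert tm.best_epoch == int(tm.history["val_loss"].idxmin())

    def test_restored_parameters_reproduce_best_val_loss(self, fitted):
        m, _, tm = fitted
        x = np.asarray(m.values.todense(), float).T
        f = tm.model.factor_matrix(m.cells)
        tr_idx, va_idx, _ = split_train_val(m.cells, None, seed=21)
        _, _, total = tm.model.cvae_loss(x[va_idx], f[va_idx])
        assert total == pytest.approx(tm.best_val_loss, rel=1e-9)


class TestAdversarialAlternation:
    def test_parameter_updates_are_compartmentalised(self):
        m, _ = simulate_multispecies(n_cells_per_species=40, n_genes=30, seed=2)
        model = CVAE(30, _levels(m),
                     ModelConfig(n_latent=4, hidden_width=16,
                                 use_discriminator=True, seed=2))
        cfg = TrainConfig(patience=2, max_epochs=1, batch_size=32, seed=2)
        gen_before = [p.data.copy() for p in model.generator_params()]
        dis_before = [p.data.copy() for p in model.discriminator_params()]
        tr_idx, va_idx, _ = split_train_val(m.cells, None, seed=2)
        fit(model, m, cfg, tr_idx, va_idx)
        # both groups were updated by their own steps
        assert any(not np.array_equal(a, p.data)
                   for a, p in zip(gen_before, model.generator_params()))
        assert any(not np.array_equal(a, p.data)
                   for a, p in zip(dis_before, model.discriminator_params()))

    def test_generator_step_leaves_discriminator_untouched(self):
        from crosscell.autodiff import Adam
        m, _ = simulate_multispecies(n_cells_per_species=20, n_genes=30, seed=3)
        model = CVAE(30, _levels(m),
                     ModelConfig(n_latent=4, hidden_width=16,
                                 use_discriminator=True, seed=3))
        x = np.asarray(m.values.todense(), float).T
        f = model.factor_matrix(m.cells)
        sidx = np.array([model.levels["species"].index(s)
                         for s in m.cells["species"]])
        dis_hash = [p.data.copy() for p in model.discriminator_params()]
        opt = Adam(model.generator_params())
        recon, kl, z = model._forward(x, f, np.random.default_rng(0))
        dis = model.discriminator_loss_tensor(z, sidx, frozen=True)
        total = recon + kl - dis
        opt.zero_grad()
        total.backward()
        opt.step()
        for before, p in zip(dis_hash, model.discriminator_params()):
            np.testing.assert_array_equal(before, p.data)
            assert p.grad is None  # frozen: no gradient reaches it


class TestLisi:
    def test_single_label_gives_one(self):
        emb = np.random.default_rng(0).normal(size=(50, 3))
        np.testing.assert_allclose(compute_lisi(emb, ["a"] * 50, perplexity=5), 1.0)

    def test_interleaved_lattice_approaches_two(self):
        x = np.arange(600, dtype=float)[:, None]
        labels = np.array(["a", "b"] * 300)
        lisi = compute_lisi(x, labels, perplexity=30)
        assert lisi.mean() > 1.9

    def test_separated_clusters_stay_near_one(self):
        rng = np.random.default_rng(4)
        emb = np.vstack([rng.normal(0, 0.1, size=(100, 2)),
                         rng.normal(50, 0.1, size=(100, 2))])
        labels = ["a"] * 100 + ["b"] * 100
        assert compute_lisi(emb, labels, perplexity=10).mean() < 1.1

    def test_matches_direct_definition_on_small_instance(self):
        rng = np.random.default_rng(7)
        emb = rng.normal(size=(40, 2))
        labels = rng.choice(["a", "b"], size=40)
        perp, k = 5.0, 15
        got = compute_lisi(emb, labels, perplexity=perp, k=k)
        # independent brute-force: full distance matrix, bisection on beta
        want = np.empty(40)
        for i in range(40):
            d2 = ((emb - emb[i]) ** 2).sum(axis=1)
            order = np.argsort(d2, kind="stable")
            nb = order[order != i][:k]
            dd = d2[nb] - d2[nb].min()
            lo, hi = 1e-12, 1e12
            for _ in range(200):
                beta = np.sqrt(lo * hi)
                w = np.exp(-beta * dd)
                p = w / w.sum()
                h = -(p * np.log(p + 1e-300)).sum()
                if h > np.log(perp):
                    lo = beta
                else:
                    hi = beta
            w = np.exp(-beta * dd)
            p = w / w.sum()
            probs = np.array([p[labels[nb] == l].sum() for l in ("a", "b")])
            want[i] = 1.0 / (probs ** 2).sum()
        np.testing.assert_allclose(got, want, rtol=1e-3)

    def test_too_few_cells_reduces_k_with_warning(self, caplog):
        emb = np.random.default_rng(1).normal(size=(10, 2))
        lisi = compute_lisi(emb, ["a", "b"] * 5, perplexity=2, k=20)
        assert len(lisi) == 10
        assert "reducing k" in caplog.text


class TestGridSearch:
    def test_grid_runs_all_points_and_selects_argmax(self):
        m, _ = simulate_multispecies(n_cells_per_species=60, n_genes=30, seed=6)
        cfg = TrainConfig(patience=2, max_epochs=2, batch_size=64, seed=6,
                          grid_n_latent=(4, 6),
                          grid_discriminator=(False, True),
                          model=ModelConfig(n_latent=4, hidden_width=16))
        tr_idx, va_idx, _ = split_train_val(m.cells, None, seed=6)
        best, metrics = grid_search(m, cfg, tr_idx, va_idx)
        assert len(metrics) == 4  # 2 x 2 grid, all attempted
        assert best.lisi_score == pytest.approx(metrics["lisi"].max())

    def test_fixed_seed_same_selection(self):
        m, _ = simulate_multispecies(n_cells_per_species=40, n_genes=20, seed=8)
        cfg = TrainConfig(patience=1, max_epochs=1, batch_size=64, seed=8,
                          grid_n_latent=(4,), grid_discriminator=(False, True),
                          model=ModelConfig(n_latent=4, hidden_width=8))
        tr_idx, va_idx, _ = split_train_val(m.cells, None, seed=8)
        b1, m1 = grid_search(m, cfg, tr_idx, va_idx)
        b2, m2 = grid_search(m, cfg, tr_idx, va_idx)
        pd.testing.assert_frame_equal(m1, m2)
        assert b1.model.config == b2.model.config
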