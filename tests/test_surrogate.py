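"""Surrogate regressor: splits, gradients, training, invariances, persistence."""

import numpy as np
import pytest
from rdkit import Chem

import gapdesign as gd
from gapdesign.db import PropertyRecord
from gapdesign.errors import EmptySetError, TooFewRecords
from gapdesign.featurize import featurize
from gapdesign.surrogate import (
    SurrogateConfig,
    TrainedSurrogate,
    build_batch,
    backward,
    evaluate,
    forward,
    init_params,
    split_dataset,
    train,
)


def _records(smiles_list, gaps=None):
    oracle = gd.ToyGapOracle()
    out = []
    for i, s in enumerate(smiles_list):
        gap = gaps[i] if gaps is not None else oracle(gd.parse_smiles(s))
        out.append(PropertyRecord(smiles=s, gap=gap, generation=0, split="train"))
    return out


class TestSplitDataset:
    def test_default_fractions_on_1000(self):
        records = _records(["C" * (i % 19 + 1) for i in range(1000)], gaps=[1.0] * 1000)
        tr, va, te = split_dataset(records, seed=0)
        assert (len(tr), len(va), len(te)) == (900, 50, 50)

    def test_remainder_goes_to_train(self):
        records = _records(["C" * (i + 1) for i in range(20)], gaps=[1.0] * 20)
        tr, va, te = split_dataset(records, seed=0)
        assert (len(tr), len(va), len(te)) == (18, 1, 1)

    def test_partitions_disjoint_and_exhaustive(self):
        records = _records(["C" * (i % 15 + 1) for i in range(137)], gaps=[1.0] * 137)
        tr, va, te = split_dataset(records, seed=3)
        ids = [id(r) for part in (tr, va, te) for r in part]
        assert len(ids) == len(set(ids)) == 137

    def test_reproducible_given_seed(self):
        records = _records(["C" * (i % 9 + 1) for i in range(50)], gaps=[1.0] * 50)
        a = split_dataset(records, seed=11)
        b = split_dataset(records, seed=11)
        assert all([x is y for pa, pb in zip(a, b) for x, y in zip(pa, pb)])

    def test_too_few_records(self):
        with pytest.raises(TooFewRecords):
            split_dataset(_records(["C"], gaps=[1.0]))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full PNA stack agree with central differences."""
        mols = ["CCO", "c1ccccc1", "C", "CC(=O)N", "FC(F)C#N"]
        graphs = [featurize(gd.parse_smiles(s)) for s in mols]
        batch = build_batch(graphs, np.array([1.0, -0.5, 2.0, 0.3, -1.2]))
        rng = np.random.default_rng(3)
        params = init_params(rng, 11, 4, 7, 2, [5])
        delta = 1.1

        def loss_of(params):
            preds, _ = forward(params, batch, 2, delta)
            return float(np.mean((preds - batch.targets) ** 2))

        preds, cache = forward(params, batch, 2, delta)
        residual = preds - batch.targets
        grads = backward(params, batch, cache, 2 * residual / residual.size, 2)

        eps = 1e-6
        rng_idx = np.random.default_rng(0)
        for key, p in params.items():
            flat = p.reshape(-1)
            for idx in rng_idx.choice(flat.size, size=min(8, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_of(params)
                flat[idx] = orig - eps
                lm = loss_of(params)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[key].reshape(-1)[idx]
                assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-8), key


@pytest.fixture(scope="module")
def overfit_model():
    pop = gd.make_seed_population(gd.FixtureConfig(n_molecules=56, seed=3))
    records = _records(pop)
    cfg = SurrogateConfig(
        n_mp_layers=3, hidden_dim=16, fc_dims=[32, 16],
        epochs=500, batch_size=8, weight_decay=0.0, seed=0,
    )
    return train(records, cfg), records


@pytest.fixture(scope="module")
def desk_model(labeled_records):
    return train(labeled_records, SurrogateConfig.desk(epochs=30, seed=6))


class TestTraining:
    def test_small_set_overfits(self, overfit_model):
        model, _ = overfit_model
        assert model.report.mae_train < 0.1

    def test_training_molecules_predicted_closely(self, overfit_model):
        model, records = overfit_model
        tr, _, _ = split_dataset(records, seed=0)
        _, max_err, _ = evaluate(model, tr)
        assert max_err < 0.3

    def test_constant_target_is_learnable(self, seed_population):
        records = _records(seed_population[:60], gaps=[5.0] * 60)
        model = train(records, SurrogateConfig.desk(epochs=60, seed=1))
        assert model.report.mae_test < 0.05

    def test_same_seed_gives_bitwise_identical_loss_curve(self, labeled_records):
        cfg = SurrogateConfig.desk(epochs=8, seed=4)
        a = train(labeled_records, cfg)
        b = train(labeled_records, cfg)
        assert a.report.loss_curve == b.report.loss_curve
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_loss_curve_length_and_report_invariants(self, labeled_records):
        cfg = SurrogateConfig.desk(epochs=12, seed=5)
        model = train(labeled_records, cfg)
        report = model.report
        assert len(report.loss_curve) == 12
        assert report.max_abs_error_all >= max(
            report.mae_train, report.mae_val, report.mae_test
        )
        assert sum(report.n_records.values()) == len(labeled_records)

    def test_unfeaturizable_records_skipped_and_counted(self, labeled_records):
        bad = PropertyRecord(smiles="N[SH](C)C", gap=5.0, generation=0, split="train")
        model = train(labeled_records + [bad], SurrogateConfig.desk(epochs=5, seed=0))
        assert model.report.n_skipped == 1


class TestPredict:
    def test_prediction_is_finite_and_deterministic(self, desk_model):
        model = desk_model
        a = model.predict("CC(=O)c1ccccc1")
        assert np.isfinite(a)
        assert model.predict("CC(=O)c1ccccc1") == a

    def test_invariant_under_atom_relabeling(self, desk_model, seed_population):
        model = desk_model
        for smiles in seed_population[:20]:
            ref = model.predict(smiles)
            variant = Chem.MolToSmiles(
                Chem.MolFromSmiles(smiles), canonical=False, doRandom=True
            )
            assert model.predict(variant) == pytest.approx(ref, abs=1e-9)

    def test_parameter_count_reported(self, desk_model):
        model = desk_model
        assert model.n_parameters == sum(p.size for p in model.params.values())

    def test_save_load_reproduces_predictions_bitwise(self, desk_model, tmp_path):
        model = desk_model
        path = tmp_path / "ckpt.npz"
        model.save(path)
        clone = TrainedSurrogate.load(path)
        for smiles in ("CCO", "c1ccccc1F", "CC#N"):
            assert clone.predict(smiles) == model.predict(smiles)

    def test_load_refuses_foreign_feature_layout(self, desk_model, tmp_path):
        model = desk_model
        path = tmp_path / "ckpt.npz"
        model.save(path)
        clone = TrainedSurrogate.load(path)
        clone.feature_version = "node99-edge9-v0"
        clone.save(path)
        with pytest.raises(ValueError, match="feature layout"):
            TrainedSurrogate.load(path)


class TestEvaluate:
    def test_perfect_model_scores_zero(self, labeled_records):
        # a model is exact on records labeled with its own predictions
        model = train(labeled_records, SurrogateConfig.desk(epochs=10, seed=0))
        self_records = [
            PropertyRecord(smiles=r.smiles, gap=model.predict(r.smiles),
                           generation=0, split="train")
            for r in labeled_records[:20]
        ]
        mae, max_err, errors = evaluate(model, self_records)
        assert mae == pytest.approx(0.0, abs=1e-12)
        assert max_err == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_loop(self, labeled_records):
        model = train(labeled_records, SurrogateConfig.desk(epochs=10, seed=0))
        mae, max_err, errors = evaluate(model, labeled_records)
        brute = [abs(model.predict(r.smiles) - r.gap) for r in labeled_records]
        assert mae == pytest.approx(np.mean(brute), abs=1e-9)
        assert max_err == pytest.approx(np.max(brute), abs=1e-9)
        assert errors == pytest.approx(np.array(brute), abs=1e-9)

    def test_empty_set_raises(self, labeled_records):
        model = train(labeled_records, SurrogateConfig.desk(epochs=5, seed=0))
        with pytest.raises(EmptySetError):
            evaluate(model, [])
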