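import numpy as np
import pytest

from conftest import make_rapide_event
from sporoclass import nn
from sporoclass.events import EventDataset
from sporoclass.models import (
    Model,
    ModelConfig,
    TrainConfig,
    build_model,
    dataset_hash,
    predict,
    split_dataset,
    train,
)
from sporoclass.synth import SimulationConfig, generate_dataset, separable_profiles


def _label_dataset(class_sizes: dict[str, int]) -> EventDataset:
    """Cheap labelled rapid_e dataset for split-protocol tests."""
    events = [
        make_rapide_event(label=lab, t=4)
        for lab, n in class_sizes.items()
        for _ in range(n)
    ]
    return EventDataset(events, "rapid_e")


class TestSplit:
    def test_exact_801010_partition(self):
        ds = _label_dataset({"Botrytis cinerea": 500, "Epicoccum nigrum": 500})
        tr, va, te = split_dataset(ds, TrainConfig(seed=1))
        assert (len(tr), len(va), len(te)) == (800, 100, 100)

    def test_disjoint_and_exhaustive(self):
        ds = _label_dataset({"Botrytis cinerea": 37, "Epicoccum nigrum": 23})
        tr, va, te = split_dataset(ds, TrainConfig(seed=2))
        ids = [id(e) for part in (tr, va, te) for e in part.events]
        assert len(ids) == len(set(ids)) == 60

    def test_per_class_counts_within_one_of_fractions(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sizes = {
                "Botrytis cinerea": int(rng.integers(10, 80)),
                "Epicoccum nigrum": int(rng.integers(10, 80)),
                "Curvularia caricae-papayae": int(rng.integers(10, 80)),
            }
            tr, va, te = split_dataset(_label_dataset(sizes), TrainConfig(seed=4))
            for lab, n in sizes.items():
                n_tr = sum(1 for e in tr.events if e.label == lab)
                assert abs(n_tr - 0.8 * n) <= 1

    def test_partition_keyed_on_data_and_seed_only(self):
        ds = _label_dataset({"Botrytis cinerea": 20, "Epicoccum nigrum": 20})
        a = split_dataset(ds, TrainConfig(seed=5))
        b = split_dataset(ds, TrainConfig(seed=5))
        for pa, pb in zip(a, b):
            assert [id(e) for e in pa.events] == [id(e) for e in pb.events]
        c = split_dataset(ds, TrainConfig(seed=6))
        assert any(
            [id(e) for e in pa.events] != [id(e) for e in pc.events]
            for pa, pc in zip(a, c)
        )

    def test_small_class_rejected(self):
        ds = _label_dataset({"Botrytis cinerea": 9, "Epicoccum nigrum": 20})
        with pytest.raises(ValueError, match="at least 10"):
            split_dataset(ds, TrainConfig(seed=7))


class TestArchitectures:
    def _batch(self, model: Model, n=3, size=24):
        rng = np.random.default_rng(0)
        inputs = {
            "image_a": rng.random((n, 1, size, size)),
            "image_b": rng.random((n, 1, size, size)),
            "fluorescence": rng.random((n, 15)),
        }
        return inputs

    def test_forward_shape_contract(self):
        for family in ("poleno_holo", "poleno_holo_fluor"):
            model = build_model(ModelConfig(family=family, n_classes=4), seed=0)
            logits = model.net.forward(self._batch(model))
            assert logits.shape == (3, 4)

    def test_fluorescence_branch_adds_parameters(self):
        count = lambda m: sum(p.value.size for p in m.net.params())
        holo = build_model(ModelConfig(family="poleno_holo", n_classes=4), seed=0)
        fused = build_model(ModelConfig(family="poleno_holo_fluor", n_classes=4), seed=0)
        assert count(fused) > count(holo)

    def test_shared_encoder_halves_image_parameters(self):
        count = lambda m: sum(p.value.size for p in m.net.params())
        shared = build_model(ModelConfig(family="poleno_holo", n_classes=4), seed=0)
        unshared = build_model(
            ModelConfig(family="poleno_holo", n_classes=4, share_image_encoder=False),
            seed=0,
        )
        assert count(unshared) > count(shared)

    def test_rapide_branch_block_counts_match_config(self):
        config = ModelConfig(family="rapide_multibranch", n_classes=3)
        model = build_model(config, seed=0)
        for name, blocks in config.branch_blocks.items():
            residuals = [
                l for l in model.net.branches[name].layers if isinstance(l, nn.Residual)
            ]
            assert len(residuals) == blocks
            # 3 convolutions per block-layer, 4 in the first
            n_convs = [
                sum(isinstance(x, nn.Conv2d) for x in r.inner.layers)
                for r in residuals
            ]
            assert n_convs == [4] + [3] * (blocks - 1)

    def test_rapide_first_conv_is_5x5_pad2_stride1(self):
        model = build_model(ModelConfig(family="rapide_multibranch", n_classes=3), seed=0)
        first = model.net.branches["spectrum"].layers[0]
        assert (first.kernel, first.pad, first.stride) == (5, 2, 1)

    def test_gradient_flows_into_every_branch(self):
        model = build_model(ModelConfig(family="rapide_multibranch", n_classes=3), seed=1)
        rng = np.random.default_rng(2)
        inputs = {
            "spectrum": rng.random((2, 1, 30, 30)),
            "lifetime": rng.random((2, 1, 30, 30)),
            "scattering": rng.random((2, 2, 14, 64)),
            "infrared": rng.random((2, 1, 16, 16)),
        }
        logits = model.net.forward(inputs)
        _, dlogits = nn.softmax_cross_entropy(logits, np.array([0, 1]))
        nn.zero_grad(model.net.params())
        model.net.backward(dlogits)
        for name, branch in model.net.branches.items():
            grads = [np.abs(p.grad).max() for p in branch.params()]
            assert max(grads) > 0, f"no gradient reached branch {name}"

    def test_paper_scale_builds_and_runs(self):
        model = build_model(
            ModelConfig(family="poleno_holo", n_classes=3, backbone_scale="paper",
                        image_input_size=64),
            seed=0,
        )
        rng = np.random.default_rng(1)
        inputs = {
            "image_a": rng.random((1, 1, 64, 64)),
            "image_b": rng.random((1, 1, 64, 64)),
        }
        assert model.net.forward(inputs).shape == (1, 3)


@pytest.fixture(scope="module")
def splits(tiny_poleno_dataset):
    tc = TrainConfig(seed=11, epochs=5, batch_size=16)
    tr, va, te = split_dataset(tiny_poleno_dataset, tc)
    return tc, tr, va, te


class TestTraining:
    def test_loss_decreases_on_separable_classes(self, splits):
        tc, tr, va, te = splits
        model = build_model(ModelConfig(family="poleno_holo", n_classes=3), seed=11)
        model, hist = train(model, tr, va, tc)
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_same_seed_identical_history(self, splits):
        tc, tr, va, _ = splits
        tc_short = TrainConfig(seed=12, epochs=2, batch_size=16)
        hists = []
        for _ in range(2):
            model = build_model(ModelConfig(family="poleno_holo", n_classes=3), seed=12)
            _, hist = train(model, tr, va, tc_short)
            hists.append(hist)
        assert hists[0].equals(hists[1])

    def test_predictions_are_probabilities_and_order_invariant(self, splits):
        tc, tr, va, te = splits
        model = build_model(ModelConfig(family="poleno_holo", n_classes=3), seed=13)
        model, _ = train(model, tr, va, TrainConfig(seed=13, epochs=3, batch_size=16))
        frame = predict(model, te)
        assert len(frame) == len(te)
        probs = frame.drop(columns="pred").to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        perm = np.random.default_rng(0).permutation(len(te))
        frame2 = predict(model, te.subset(perm.tolist()))
        np.testing.assert_allclose(probs[perm], frame2.drop(columns="pred").to_numpy(),
                                   atol=1e-9)

    def test_shuffled_labels_give_chance_level_accuracy(self):
        config = SimulationConfig(
            separable_profiles(5, corruption=0.0), 30, seed=21, image_size=32
        )
        ds = generate_dataset(config)
        rng = np.random.default_rng(22)
        labels = [e.label for e in ds.events]
        shuffled = rng.permutation(labels)
        for ev, lab in zip(ds.events, shuffled):
            ev.label = str(lab)
        tc = TrainConfig(seed=22, epochs=3, batch_size=16)
        tr, va, te = split_dataset(ds, tc)
        model = build_model(ModelConfig(family="poleno_holo", n_classes=5), seed=22)
        model, _ = train(model, tr, va, tc)
        frame = predict(model, te)
        acc = np.mean(frame["pred"].to_numpy() == np.array([e.label for e in te.events]))
        p = 1 / 5
        se = np.sqrt(p * (1 - p) / len(te))
        assert acc <= p + 4 * se  # no better than chance under the null

    def test_mismatched_class_count_rejected(self, splits):
        tc, tr, va, _ = splits
        model = build_model(ModelConfig(family="poleno_holo", n_classes=7), seed=14)
        with pytest.raises(ValueError, match="classes"):
            train(model, tr, va, tc)

    def test_save_load_roundtrip(self, splits, tmp_path):
        tc, tr, va, te = splits
        model = build_model(ModelConfig(family="poleno_holo", n_classes=3), seed=15)
        model, _ = train(model, tr, va, TrainConfig(seed=15, epochs=2, batch_size=16))
        model.save(str(tmp_path / "m"))
        loaded = Model.load(str(tmp_path / "m"))
        f1 = predict(model, te)
        f2 = predict(loaded, te)
        np.testing.assert_allclose(
            f1.drop(columns="pred").to_numpy(), f2.drop(columns="pred").to_numpy()
        )


def test_dataset_hash_sensitive_to_content(tiny_poleno_dataset):
    h1 = dataset_hash(tiny_poleno_dataset)
    other = generate_dataset(
        SimulationConfig(separable_profiles(3), 30, seed=999, image_size=48)
    )
    assert h1 == dataset_hash(tiny_poleno_dataset)
    assert h1 != dataset_hash(other)
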