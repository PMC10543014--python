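"""Generator tests: long-tailed marginals, co-occurrence control, grouping."""

import numpy as np
import pytest

from pruneaudit.synth import (
    CorrelationRepairError,
    LabeledDataset,
    generate_dataset,
    generate_prediction_fixture,
    sample_class_structure,
    split_dataset,
)


class TestClassStructure:
    def test_two_equal_classes_give_identity_correlation(self):
        s = sample_class_structure(2, 0.5, 0.5, seed=0)
        np.testing.assert_allclose(s.prevalence, [0.5, 0.5])
        np.testing.assert_allclose(s.latent_corr, np.eye(2))

    def test_log_linear_prevalence_spans_orders_of_magnitude(self):
        s = sample_class_structure(20, 0.3, 0.001, seed=0)
        assert s.prevalence[0] / s.prevalence[19] == pytest.approx(300.0)
        # log-linear: ratios of consecutive prevalences are constant
        ratios = s.prevalence[:-1] / s.prevalence[1:]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_requested_pair_strength_installed(self):
        s = sample_class_structure(5, 0.3, 0.05, cooccur_pairs=[(0, 1, 0.8)], seed=0)
        assert s.latent_corr[0, 1] == pytest.approx(0.8)
        assert s.latent_corr[1, 0] == pytest.approx(0.8)

    def test_unrepairable_correlation_names_offending_pairs(self):
        # three mutually near-perfect correlations with a conflicting negative
        # structure cannot form a PSD matrix without large distortion
        pairs = [(0, 1, 0.95), (1, 2, 0.95), (0, 2, 0.0), (2, 3, 0.95), (0, 3, 0.95), (1, 3, 0.0)]
        with pytest.raises(CorrelationRepairError) as err:
            sample_class_structure(4, 0.3, 0.1, cooccur_pairs=pairs, seed=0)
        assert err.value.pairs  # names which requests could not be honoured

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_class_structure(1, 0.3, 0.1)
        with pytest.raises(ValueError):
            sample_class_structure(5, 0.1, 0.3)  # tail > head
        with pytest.raises(ValueError):
            sample_class_structure(5, 0.3, 0.1, cooccur_pairs=[(0, 1, 1.0)])


class TestGenerateDataset:
    def test_marginals_match_prevalence_within_binomial_noise(self):
        s = sample_class_structure(5, 0.4, 0.05, seed=3)
        reps = 5
        counts = np.zeros(5)
        for seed in range(reps):
            ds = generate_dataset(s, N=5000, D=8, noise_sd=1.0, seed=seed)
            counts += ds.labels.sum(axis=0)
        counts /= reps
        expected = s.prevalence * 5000
        # class 0 absorbs the "no finding" backfill, inflating its count,
        # so only classes 1.. are checked against the binomial band
        sd = np.sqrt(5000 * s.prevalence * (1 - s.prevalence) / reps)
        for c in range(1, 5):
            assert abs(counts[c] - expected[c]) < 3 * sd[c]

    def test_every_row_has_a_positive_label(self):
        s = sample_class_structure(6, 0.1, 0.01, seed=1)
        ds = generate_dataset(s, N=2000, D=8, noise_sd=1.0, seed=1)
        assert (ds.labels.sum(axis=1) >= 1).all()

    def test_cooccurrence_strength_is_monotone_in_realized_iou(self):
        # stronger latent correlation must yield larger empirical IoU
        ious = {}
        for strength in (0.0, 0.5, 0.9):
            vals = []
            for seed in range(10):
                s = sample_class_structure(
                    4, 0.3, 0.3, cooccur_pairs=[(0, 1, strength)] if strength else None, seed=seed
                )
                ds = generate_dataset(s, N=2000, D=8, noise_sd=1.0, seed=seed)
                a, b = ds.labels[:, 0].astype(bool), ds.labels[:, 1].astype(bool)
                vals.append((a & b).sum() / (a | b).sum())
            ious[strength] = np.mean(vals)
        assert ious[0.0] < ious[0.5] < ious[0.9]

    def test_requested_pair_exceeds_unrequested_pair_iou(self):
        hits = 0
        for seed in range(10):
            s = sample_class_structure(4, 0.3, 0.1, cooccur_pairs=[(0, 1, 0.9)], seed=seed)
            ds = generate_dataset(s, N=2000, D=8, noise_sd=1.0, seed=seed)
            lab = ds.labels.astype(bool)
            iou01 = (lab[:, 0] & lab[:, 1]).sum() / (lab[:, 0] | lab[:, 1]).sum()
            iou02 = (lab[:, 0] & lab[:, 2]).sum() / (lab[:, 0] | lab[:, 2]).sum()
            hits += iou01 > iou02
        assert hits >= 9

    def test_noiseless_separable_labels_admit_perfect_linear_probe(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import average_precision_score

        s = sample_class_structure(2, 0.5, 0.3, seed=5)
        ds = generate_dataset(s, N=400, D=8, noise_sd=0.0, seed=5)
        for c in range(2):
            probe = LogisticRegression(max_iter=2000).fit(ds.features, ds.labels[:, c])
            scores = probe.decision_function(ds.features)
            assert average_precision_score(ds.labels[:, c], scores) == pytest.approx(1.0)

    def test_determinism_byte_identical(self):
        s = sample_class_structure(5, 0.3, 0.05, seed=2)
        a = generate_dataset(s, N=500, D=8, noise_sd=1.0, seed=9)
        b = generate_dataset(s, N=500, D=8, noise_sd=1.0, seed=9)
        assert a.labels.tobytes() == b.labels.tobytes()
        assert a.features.tobytes() == b.features.tobytes()
        assert (a.split == b.split).all()

    def test_thin_class_warns(self):
        s = sample_class_structure(5, 0.3, 0.0005, seed=0)
        with pytest.warns(UserWarning, match="zero positives"):
            generate_dataset(s, N=1000, D=8, noise_sd=1.0, seed=0)

    def test_dimension_preconditions(self):
        s = sample_class_structure(5, 0.3, 0.05, seed=0)
        with pytest.raises(ValueError):
            generate_dataset(s, N=10, D=8, noise_sd=1.0, seed=0)  # N < 10C
        with pytest.raises(ValueError):
            generate_dataset(s, N=500, D=3, noise_sd=1.0, seed=0)  # D < C

    def test_prototype_overlap_sets_requested_cosine(self):
        s = sample_class_structure(4, 0.3, 0.1, seed=11)
        ds0 = generate_dataset(s, N=400, D=16, noise_sd=0.0, seed=11)
        ds1 = generate_dataset(
            s, N=400, D=16, noise_sd=0.0, seed=11, prototype_overlap=[(3, 0, 0.9)]
        )
        # recover prototypes from single-label rows and compare alignment
        def proto(ds, c):
            only = (ds.labels[:, c] == 1) & (ds.labels.sum(axis=1) == 1)
            return ds.features[only][0] / s.signal_strength[c]

        def cos(u, v):
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        assert abs(cos(proto(ds1, 3), proto(ds1, 0))) > abs(cos(proto(ds0, 3), proto(ds0, 0)))
        assert cos(proto(ds1, 3), proto(ds1, 0)) == pytest.approx(0.9, abs=1e-9)


class TestSplitDataset:
    def _singleton_dataset(self, n):
        labels = np.ones((n, 1), dtype=int)
        return LabeledDataset(
            features=np.zeros((n, 2)),
            labels=labels,
            group_id=np.arange(n),
            split=np.full(n, "train", dtype=object),
            class_names=["c0"],
        )

    def test_ten_singleton_groups_split_exactly_7_1_2(self):
        ds = split_dataset(self._singleton_dataset(10), (0.7, 0.1, 0.2), seed=0)
        counts = {s: int((ds.split == s).sum()) for s in ("train", "val", "test")}
        assert counts == {"train": 7, "val": 1, "test": 2}

    def test_same_seed_gives_identical_assignment(self):
        ds = self._singleton_dataset(50)
        a = split_dataset(ds, seed=4)
        b = split_dataset(ds, seed=4)
        assert (a.split == b.split).all()

    def test_groups_never_straddle_splits(self):
        s = sample_class_structure(4, 0.3, 0.1, seed=0)
        ds = generate_dataset(s, N=1000, D=8, noise_sd=1.0, seed=0)
        for g in np.unique(ds.group_id):
            assert len(set(ds.split[ds.group_id == g])) == 1
        # and split-wise group sets are disjoint
        by_split = {s_: set(ds.group_id[ds.split == s_]) for s_ in ("train", "val", "test")}
        assert not (by_split["train"] & by_split["val"])
        assert not (by_split["train"] & by_split["test"])
        assert not (by_split["val"] & by_split["test"])

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._singleton_dataset(2))


class TestSerialization:
    def test_dataset_npz_roundtrip(self, tmp_path):
        s = sample_class_structure(4, 0.3, 0.1, seed=0)
        ds = generate_dataset(s, N=200, D=8, noise_sd=1.0, seed=0)
        from pruneaudit.synth import load_dataset, save_dataset

        save_dataset(ds, tmp_path / "d.npz", tmp_path / "d.json")
        back = load_dataset(tmp_path / "d.npz", tmp_path / "d.json")
        np.testing.assert_array_equal(back.labels, ds.labels)
        np.testing.assert_array_equal(back.features, ds.features)
        assert (back.split == ds.split).all()
        assert back.class_names == ds.class_names

    def test_weights_npz_roundtrip(self, tmp_path):
        from pruneaudit.classifier import load_weights, save_weights, train_classifier

        s = sample_class_structure(4, 0.3, 0.1, seed=0)
        ds = generate_dataset(s, N=200, D=8, noise_sd=1.0, seed=0)
        w = train_classifier(ds, hidden_units=8, epochs=1, seed=0)
        save_weights(w, tmp_path / "w.npz", tmp_path / "w.json")
        back = load_weights(tmp_path / "w.npz", tmp_path / "w.json")
        assert back.prunable == w.prunable
        for name in w.tensors:
            np.testing.assert_array_equal(back.tensors[name], w.tensors[name])


class TestPredictionFixture:
    def test_full_agreement_gives_unit_rank_correlation(self):
        from pruneaudit.pies import image_agreement

        p0, p1 = generate_prediction_fixture(50, 5, agreement=1.0, seed=0)
        np.testing.assert_allclose(image_agreement(p0, p1), 1.0)

    def test_zero_agreement_has_near_zero_mean_correlation(self):
        from pruneaudit.pies import image_agreement

        p0, p1 = generate_prediction_fixture(2000, 20, agreement=0.0, seed=1)
        assert abs(np.nanmean(image_agreement(p0, p1))) < 0.05

    def test_redrawn_rows_have_the_lowest_correlations(self):
        from pruneaudit.pies import image_agreement

        for seed in range(5):
            p0, p1, redrawn = generate_prediction_fixture(
                400, 20, agreement=0.95, seed=seed, return_mask=True
            )
            corr = image_agreement(p0, p1)
            worst = np.argsort(corr)[: redrawn.sum()]
            overlap = np.intersect1d(worst, np.flatnonzero(redrawn)).size
            assert overlap / redrawn.sum() >= 0.9

    def test_needs_three_classes(self):
        with pytest.raises(ValueError):
            generate_prediction_fixture(10, 2, agreement=0.5, seed=0)
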