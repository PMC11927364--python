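import itertools

import numpy as np
import pandas as pd
import pytest

from meioloop import (CTCF_ONLY_FEATURES, LoopSet, RegionSet, ValidationError,
                      compute_loop_features, evaluate_against_truth,
                      generate_candidate_pairs, label_candidates,
                      pet_support_sweep, predict_loops,
                      train_ctcf_only_classifier, train_loop_classifier)
from meioloop.core_data import validate_ctcf_sites


def make_sites(rows):
    """rows: (chrom, mid, strand)."""
    df = pd.DataFrame(rows, columns=["chrom", "mid0", "strand"])
    df["start"] = df["mid0"] - 9
    df["end"] = df["mid0"] + 10
    df["motif_score"] = 10.0
    df["conservation"] = 0.5
    df["peak_strength"] = 0.5
    return validate_ctcf_sites(df.drop(columns="mid0"))


class TestCandidatePairs:
    def test_single_site_empty(self):
        cand = generate_candidate_pairs(make_sites([("chr1", 50_000, "+")]))
        assert len(cand) == 0

    def test_three_site_enumeration(self):
        sites = make_sites([("chr1", 10_000, "+"), ("chr1", 500_000, "-"),
                            ("chr1", 2_400_000, "-")])
        cand = generate_candidate_pairs(sites)
        got = {(r.mid1, r.mid2, r.orientation)
               for r in cand.itertuples()}
        # (10 kb, 2.4 Mb) is excluded by the 2 Mb length cap
        assert got == {(10_000, 500_000, "convergent"),
                       (500_000, 2_400_000, "tandem")}

    def test_distance_bound_is_inclusive(self):
        sites = make_sites([("chr1", 0 + 10, "+"),
                            ("chr1", 2_000_010, "-"),
                            ("chr1", 2_000_011, "-")])
        cand = generate_candidate_pairs(sites)
        lengths = set(cand["length"])
        assert 2_000_000 in lengths and 2_000_001 not in lengths

    def test_unsorted_input_errors(self):
        sites = make_sites([("chr1", 50_000, "+"), ("chr1", 20_000, "-")])
        shuffled = sites.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValidationError):
            generate_candidate_pairs(shuffled)

    def test_require_convergent_filter(self):
        sites = make_sites([("chr1", 10_000, "+"), ("chr1", 500_000, "-"),
                            ("chr1", 900_000, "+")])
        cand = generate_candidate_pairs(sites, require_convergent=True)
        assert set(cand["orientation"]) == {"convergent"}

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        mids = np.sort(rng.choice(np.arange(0, 3_000_000, 1000), 150,
                                  replace=False))
        strands = rng.choice(["+", "-"], 150)
        sites = make_sites([("chr1", int(m), s)
                            for m, s in zip(mids, strands)])
        cand = generate_candidate_pairs(sites)
        brute = {(a, b) for a, b in itertools.combinations(mids, 2)
                 if 10_000 <= abs(b - a) <= 2_000_000}
        assert {(r.mid1, r.mid2) for r in cand.itertuples()} == brute


class TestLabelling:
    def _cand(self, n=400, seed=1):
        rng = np.random.default_rng(seed)
        mids = np.sort(rng.choice(np.arange(10_000, 3_900_000, 500), n,
                                  replace=False))
        sites = make_sites([("chr1", int(m), s) for m, s in
                            zip(mids, rng.choice(["+", "-"], n))])
        return generate_candidate_pairs(sites)

    def test_no_truth_gives_no_positives(self):
        cand = self._cand()
        train, y = label_candidates(cand, LoopSet(), seed=0)
        assert len(train) == 0 and len(y) == 0

    def test_tolerance_arithmetic(self):
        cand = pd.DataFrame({"chrom": ["chr1"], "site1": [0], "site2": [1],
                             "mid1": [100_200], "mid2": [399_900],
                             "strand1": ["+"], "strand2": ["-"],
                             "length": [299_700],
                             "orientation": ["convergent"]})
        truth = LoopSet(pd.DataFrame({"chrom": ["chr1"], "mid1": [100_000],
                                      "mid2": [400_000]}))
        train, y = label_candidates(cand, truth, anchor_tolerance=1000, seed=0)
        assert y.tolist() == [1]

    def test_negative_length_decile_matching(self):
        cand = self._cand(n=400)
        k = 40
        truth = LoopSet(pd.DataFrame({
            "chrom": "chr1",
            "mid1": cand["mid1"].iloc[:k].to_numpy(),
            "mid2": cand["mid2"].iloc[:k].to_numpy()}))
        train, y = label_candidates(cand, truth, seed=5)
        pos_len = train.loc[y == 1, "length"]
        neg_len = train.loc[y == 0, "length"]
        assert abs(len(pos_len) - len(neg_len)) <= 10
        edges = np.quantile(pos_len, np.linspace(0, 1, 11))
        edges[0] -= 1
        pc, _ = np.histogram(pos_len, bins=edges)
        nc, _ = np.histogram(neg_len, bins=edges)
        assert (np.abs(pc - nc) <= 1).all()


class TestFeatures:
    def _one_candidate(self):
        return pd.DataFrame({"chrom": ["chr1"], "site1": [0], "site2": [1],
                             "mid1": [100_000], "mid2": [400_000],
                             "strand1": ["+"], "strand2": ["-"],
                             "length": [300_000],
                             "orientation": ["convergent"]})

    def test_all_zero_tracks(self):
        cand = self._one_candidate()
        frags = RegionSet()
        X = compute_loop_features(cand, fragments=frags)
        assert X["length"].iloc[0] == 300_000
        assert (X.filter(like="frag_").iloc[0] == 0).all()

    def test_hand_counted_anchor_fragments(self):
        # four 136-bp fragments with midpoints inside anchor 1 only:
        # each counts once, so anchor_avg = (4+0)/2 = 2, anchor_std = 2
        cand = self._one_candidate()
        starts = np.array([99_000, 99_200, 99_400, 100_500]) - 68
        frags = RegionSet.from_arrays(["chr1"] * 4, starts, starts + 136)
        X = compute_loop_features(cand, fragments=frags)
        assert X["frag_anchor_avg"].iloc[0] == pytest.approx(2.0)
        assert X["frag_anchor_std"].iloc[0] == pytest.approx(2.0)
        assert X["frag_left"].iloc[0] == 0
        assert X["frag_right"].iloc[0] == 0
        assert X["frag_in_between"].iloc[0] == 0

    def test_mirror_symmetric_signal(self):
        cand = self._one_candidate()
        center = 250_000
        offs = np.array([-150_500, -149_000, 149_000, 150_500])
        pos = center + offs - 68
        frags = RegionSet.from_arrays(["chr1"] * 4, pos, pos + 136)
        X = compute_loop_features(cand, fragments=frags)
        assert X["frag_anchor_std"].iloc[0] == 0
        assert X["frag_left"].iloc[0] == X["frag_right"].iloc[0]

    def test_translation_invariance(self):
        cand = self._one_candidate()
        starts = np.array([95_000, 200_000, 398_000])
        frags = RegionSet.from_arrays(["chr1"] * 3, starts, starts + 136)
        X1 = compute_loop_features(cand, fragments=frags)
        shift = 1_000_000
        cand2 = cand.assign(mid1=cand["mid1"] + shift,
                            mid2=cand["mid2"] + shift)
        frags2 = RegionSet.from_arrays(["chr1"] * 3, starts + shift,
                                       starts + shift + 136)
        X2 = compute_loop_features(cand2, fragments=frags2)
        pd.testing.assert_frame_equal(X1, X2)


@pytest.fixture(scope="module")
def separable_training():
    """Synthetic feature matrix where one feature separates the classes."""
    rng = np.random.default_rng(3)
    n = 300
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({
        "length": rng.integers(10_000, 2_000_000, n),
        "frag_anchor_avg": np.where(y, rng.normal(10, 1, n),
                                    rng.normal(0, 1, n)),
        "peak_strength_avg": rng.random(n),
        "conservation_avg": rng.random(n),
        "orientation_convergent": rng.integers(0, 2, n),
        "orientation_tandem": 0,
        "orientation_divergent": 0,
    })
    chroms = rng.choice([f"chr{i}" for i in range(1, 7)], n)
    return X, y, chroms


class TestTraining:
    def test_separable_features_reach_high_auc(self, separable_training):
        X, y, _ = separable_training
        model = train_loop_classifier(X, y, n_estimators=50, seed=0)
        assert model.mean_roc_auc >= 0.99
        assert model.importances.sum() == pytest.approx(1.0)
        assert (model.importances >= 0).all()

    def test_permuted_labels_are_chance_level(self, separable_training):
        X, y, _ = separable_training
        rng = np.random.default_rng(1)
        model = train_loop_classifier(X, rng.permutation(y), n_estimators=50,
                                      seed=0)
        assert 0.45 <= model.mean_roc_auc <= 0.55

    def test_grouped_scheme_separates_chromosomes(self, separable_training):
        X, y, chroms = separable_training
        model = train_loop_classifier(X, y, scheme="chrom_grouped5",
                                      chroms=chroms, n_estimators=50, seed=0)
        for row in model.cv_metrics.itertuples():
            assert not set(row.test_chroms.split(",")) & \
                set(row.train_chroms.split(","))

    def test_single_class_errors(self, separable_training):
        X, y, _ = separable_training
        with pytest.raises(ValidationError):
            train_loop_classifier(X, np.zeros_like(y))

    def test_grouped_needs_five_chromosomes(self, separable_training):
        X, y, _ = separable_training
        few = np.repeat(["chr1", "chr2"], len(y) // 2)
        with pytest.raises(ValidationError):
            train_loop_classifier(X, y, scheme="chrom_grouped5", chroms=few)

    def test_ctcf_only_feature_set(self, separable_training):
        X, y, _ = separable_training
        model = train_ctcf_only_classifier(X, y, n_estimators=50, seed=0)
        assert set(model.feature_names) == \
            {"length"} | set(CTCF_ONLY_FEATURES)
        assert not any(n.startswith(("frag_", "expr_"))
                       for n in model.importances.index)
        slim = train_ctcf_only_classifier(X, y, include_length=False,
                                          n_estimators=50, seed=0)
        assert "length" not in slim.feature_names


class TestPrediction:
    def test_threshold_extremes_and_monotonicity(self, separable_training):
        X, y, chroms = separable_training
        model = train_loop_classifier(X, y, n_estimators=50, seed=0)
        cand = pd.DataFrame({"chrom": chroms,
                             "mid1": np.arange(len(y)) * 10_000,
                             "mid2": np.arange(len(y)) * 10_000 + 50_000})
        assert len(predict_loops(model, cand, X, threshold=1.5)) == 0
        assert len(predict_loops(model, cand, X, threshold=0.0)) == len(cand)
        counts = [len(predict_loops(model, cand, X, threshold=t))
                  for t in (0.2, 0.5, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_schema_mismatch_errors(self, separable_training):
        X, y, chroms = separable_training
        model = train_loop_classifier(X, y, n_estimators=50, seed=0)
        cand = pd.DataFrame({"chrom": chroms, "mid1": 0, "mid2": 1})
        with pytest.raises(ValidationError):
            predict_loops(model, cand, X[X.columns[::-1]])

    def test_model_persistence_roundtrip(self, separable_training, tmp_path):
        import json

        import joblib
        X, y, _ = separable_training
        model = train_loop_classifier(X, y, n_estimators=50, seed=0)
        model.save(tmp_path / "model.joblib")
        manifest = json.loads((tmp_path / "model.joblib.json").read_text())
        assert manifest["feature_names"] == list(X.columns)
        clf = joblib.load(tmp_path / "model.joblib")
        np.testing.assert_allclose(
            clf.predict_proba(X.to_numpy(float)),
            model.model.predict_proba(X.to_numpy(float)))


class TestTruthComparison:
    def test_identical_sets_fully_supported(self):
        loops = LoopSet(pd.DataFrame({"chrom": ["chr1", "chr2"],
                                      "mid1": [100_000, 50_000],
                                      "mid2": [400_000, 500_000]}))
        res = evaluate_against_truth(loops, loops)
        assert res["truth_recovered_frac"] == 1.0
        assert res["predicted_supported_frac"] == 1.0

    def test_hand_reciprocal_example(self):
        truth = LoopSet(pd.DataFrame({"chrom": ["chr1"], "mid1": [100_000],
                                      "mid2": [400_000], "pet_count": [2]}))
        pred = LoopSet(pd.DataFrame({"chrom": ["chr1"], "mid1": [101_000],
                                     "mid2": [401_000]}))
        # overlap 299k over 300k spans -> 0.9967 >= 0.99
        res = evaluate_against_truth(pred, truth, min_pet=1)
        assert res["predicted_supported_frac"] == 1.0
        res2 = evaluate_against_truth(pred, truth, reciprocal=0.999)
        assert res2["predicted_supported_frac"] == 0.0

    def test_support_monotone_in_pet_threshold(self):
        rng = np.random.default_rng(2)
        mid1 = rng.integers(0, 1_000_000, 50) * 10
        truth = LoopSet(pd.DataFrame({
            "chrom": "chr1", "mid1": mid1, "mid2": mid1 + 200_000,
            "pet_count": rng.integers(1, 6, 50)}))
        pred = LoopSet(truth.df.iloc[:30][["chrom", "mid1", "mid2"]])
        sweep = pet_support_sweep(pred, truth, min_pets=[5, 4, 3, 2, 1])
        fr = sweep["predicted_supported_frac"].to_numpy()
        assert (np.diff(fr) >= 0).all()  # support grows as min_pet decreases

    def test_empty_truth_signalled_absent(self):
        pred = LoopSet(pd.DataFrame({"chrom": ["chr1"], "mid1": [100_000],
                                     "mid2": [400_000]}))
        res = evaluate_against_truth(pred, LoopSet())
        assert res["truth_recovered_frac"] is None
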