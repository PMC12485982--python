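"""Clustering, PC-space similarity, and origin prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from procap_atlas import (
    TissueDesign,
    evaluate_origin_study,
    hier_cluster,
    pc_correlations,
    predict_topk,
    simulate_origin_study,
    train_origin_model,
)
from procap_atlas.origin import build_feature_set


def toy_training(n_tissues=3, per_tissue=4, n_feat=5, sep=10.0, seed=0):
    """Linearly separable toy: disjoint active features per tissue."""
    rng = np.random.default_rng(seed)
    tissues = [f"tis{i}" for i in range(n_tissues)]
    eids = [f"{t}_f{j}" for t in tissues for j in range(n_feat)]
    cols, assign = {}, {}
    for t in tissues:
        for r in range(per_tissue):
            sid = f"{t}_s{r}"
            assign[sid] = t
            v = rng.normal(0, 0.1, len(eids))
            for j, eid in enumerate(eids):
                if eid.startswith(t):
                    v[j] += sep
            cols[sid] = v
    m = pd.DataFrame(cols, index=eids)
    sets = {t: [e for e in eids if e.startswith(t)] for t in tissues}
    return m, TissueDesign(assign), sets, tissues


class TestHierCluster:
    def test_identical_samples_merge_at_zero(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 1], "b": [1.0, 2, 3, 1], "c": [3.0, 1, 0, 5]})
        Z, order = hier_cluster(m)
        assert order == ["a", "b", "c"]
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_identical_pair_merges_before_anticorrelated(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [3.0, 2, 1]})
        Z, _ = hier_cluster(m)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_constant_sample_raises_with_name(self):
        m = pd.DataFrame({"flat": [2.0, 2, 2], "x": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="flat"):
            hier_cluster(m)

    def test_two_planted_tissues_recovered_at_two_clusters(self):
        st = simulate_origin_study(seed=4, n_tissues=2, n_train=6, n_queries=2,
                                   n_specific_per_tissue=20, n_shared=40)
        log = np.log2(st.train_counts + 1)
        Z, order = hier_cluster(log)
        labels = fcluster(Z, t=2, criterion="maxclust")
        truth = st.train_design.set_index("sample_id")["tissue"]
        parts = {}
        for sid, lab in zip(order, labels):
            parts.setdefault(lab, set()).add(truth[sid])
        assert all(len(v) == 1 for v in parts.values())


class TestPcCorrelations:
    def test_single_dominant_direction_keeps_one_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        cols = {f"s{i}": (i - 2.0) * base for i in range(5)}
        m = pd.DataFrame(cols)
        design = TissueDesign({f"s{i}": "norm" for i in range(4)})
        tumors = pd.DataFrame(
            [{"sample_id": "s4", "primary_site": "norm", "metastatic_site": "none"}]
        )
        rep = pc_correlations(m, tumors, design)
        assert rep.n_components == 1
        assert rep.explained_variance > 0.95

    def test_tumor_identical_to_normal_has_r_one(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(30, 4)), columns=["n1", "n2", "n3", "tum"])
        m["tum"] = m["n1"]
        design = TissueDesign({"n1": "liver", "n2": "brain", "n3": "lung"})
        tumors = pd.DataFrame(
            [{"sample_id": "tum", "primary_site": "liver", "metastatic_site": "brain"}]
        )
        rep = pc_correlations(m, tumors, design)
        r = rep.pairwise.set_index("normal").loc["n1", "r"]
        assert r == pytest.approx(1.0)

    def test_invariant_to_constant_shift_of_one_element(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(25, 6)),
                         columns=[f"n{i}" for i in range(5)] + ["tum"])
        design = TissueDesign({f"n{i}": f"t{i}" for i in range(5)})
        tumors = pd.DataFrame(
            [{"sample_id": "tum", "primary_site": "t0", "metastatic_site": "t1"}]
        )
        a = pc_correlations(m, tumors, design)
        shifted = m.copy()
        shifted.iloc[3] += 100.0  # add a constant to all samples of one element
        b = pc_correlations(shifted, tumors, design)
        np.testing.assert_allclose(a.pairwise["r"], b.pairwise["r"], atol=1e-8)

    def test_metastatic_mixtures_rank_primary_over_destination(self):
        """Tumors built as 0.7 primary + 0.3 destination signature order the
        mean correlations primary > metastatic site > other in >= 18/20
        seeded replicates."""
        wins = 0
        for seed in range(20):
            st = simulate_origin_study(seed=seed, n_tissues=6, n_train=24,
                                       n_queries=6, n_specific_per_tissue=20,
                                       n_shared=60)
            log = np.log2(pd.concat([st.train_counts, st.query_counts], axis=1) + 1)
            design = TissueDesign.from_frame(st.train_design)
            rep = pc_correlations(log, st.queries, design)
            s = rep.summary.mean()
            if s["mean_r_primary"] > s["mean_r_metastatic"] > s["mean_r_other"]:
                wins += 1
        assert wins >= 18


class TestOriginModel:
    def test_separable_toy_training_accuracy_one(self):
        m, design, sets, tissues = toy_training()
        model = train_origin_model(m, design, sets)
        pred = predict_topk(model, m, k=1)
        top1 = pred.top1()
        assert all(top1[s] == design.assignment[s] for s in design.assignment.index)

    def test_shared_feature_excluded(self):
        m, design, sets, tissues = toy_training()
        sets = {t: list(v) for t, v in sets.items()}
        sets[tissues[0]].append("shared_x")
        sets[tissues[1]].append("shared_x")
        mapping = build_feature_set(sets)
        assert "shared_x" not in mapping

    def test_tissue_losing_all_features_raises(self):
        sets = {"a": ["f1"], "b": ["f1"]}
        with pytest.raises(ValueError, match="a, b"):
            build_feature_set(sets)

    def test_topk_exceeding_classes_rejected(self):
        m, design, sets, _ = toy_training()
        model = train_origin_model(m, design, sets)
        with pytest.raises(ValueError, match="exceeds"):
            predict_topk(model, m, k=4)

    def test_topk_equal_classes_always_contains_truth(self):
        m, design, sets, _ = toy_training()
        model = train_origin_model(m, design, sets)
        pred = predict_topk(model, m, k=3)
        topk = pred.topk_sets()
        assert all(design.assignment[s] in topk[s] for s in design.assignment.index)

    def test_missing_features_imputed_with_warning(self):
        m, design, sets, _ = toy_training()
        model = train_origin_model(m, design, sets)
        query = m.drop(index=m.index[:2])
        with pytest.warns(UserWarning, match="imputed"):
            pred = predict_topk(model, query, k=1)
        assert pred.n_missing_features == 2

    def test_ranking_invariant_to_class_relabeling(self):
        m, design, sets, _ = toy_training()
        model = train_origin_model(m, design, sets)
        # retrain with samples presented in reversed order (class order flips)
        rev_assign = dict(reversed(list(design.assignment.items())))
        model2 = train_origin_model(m[list(rev_assign)], TissueDesign(rev_assign), sets)
        p1 = predict_topk(model, m, k=1).top1()
        p2 = predict_topk(model2, m, k=1).top1()
        assert (p1 == p2[p1.index]).all()

    def test_json_round_trip(self, tmp_path):
        from procap_atlas import OriginModel

        m, design, sets, _ = toy_training()
        model = train_origin_model(m, design, sets)
        model.to_json(tmp_path / "model.json")
        back = OriginModel.from_json(tmp_path / "model.json")
        assert back.features == model.features
        np.testing.assert_allclose(back.coef, model.coef)
        p1 = predict_topk(model, m, k=2).ranking
        p2 = predict_topk(back, m, k=2).ranking
        pd.testing.assert_frame_equal(p1, p2)

    def test_perfect_information_oracle_15_tissues(self):
        """93 noise-free training samples over 15 disjoint signatures: every
        training sample's top-1 is its own tissue."""
        st = simulate_origin_study(seed=0, nb_dispersion=1e9, off_level=0.0)
        log = np.log2(st.train_counts + 1)
        design = TissueDesign.from_frame(st.train_design)
        model = train_origin_model(log, design, st.specific_elements)
        top1 = predict_topk(model, log, k=1).top1()
        truth = st.train_design.set_index("sample_id")["tissue"]
        assert (top1[truth.index] == truth).all()

    def test_full_recovery_at_default_noise(self):
        out = evaluate_origin_study(simulate_origin_study(seed=11))
        assert out["top1_accuracy"] >= 0.9
        assert out["top3_accuracy"] >= 0.95
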