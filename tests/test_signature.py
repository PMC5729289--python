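import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppisig.gsva import GsvaProfile
from ppisig.prep import ClinicalTable
from ppisig.signature import (
    apply_one_se_rule,
    cluster_patients,
    evaluate_benefit,
    predict_cohort,
    rf_backward_select,
    roc_auc,
    train_predictor,
)


def profile_from(arr, modules=None, samples=None) -> GsvaProfile:
    arr = np.asarray(arr, dtype=float)
    modules = modules or [f"M{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return GsvaProfile(pd.DataFrame(arr, index=modules, columns=samples))


def two_block_profile(n_samples=40, n_modules=10, noise=0.1, seed=0):
    """Anti-correlated patient blocks: planted labels in {1, 2}."""
    rng = np.random.RandomState(seed)
    labels = np.array([1] * (n_samples // 2) + [2] * (n_samples - n_samples // 2))
    base = np.ones((n_modules, n_samples)) * 0.0
    half = n_modules // 2
    base[:half, labels == 2] += 0.8
    base[half:, labels == 2] -= 0.8
    base[:half, labels == 1] -= 0.8
    base[half:, labels == 1] += 0.8
    arr = np.clip(base + rng.normal(scale=noise, size=base.shape), -1, 1)
    return profile_from(arr), labels


class TestClustering:
    def test_identical_patients_cluster_together(self):
        arr = np.array([[0.5, 0.5, -0.5], [0.2, 0.2, -0.2], [-0.1, -0.1, 0.3]])
        cl = cluster_patients(profile_from(arr))
        assert cl.labels.iloc[0] == cl.labels.iloc[1]

    def test_anticorrelated_vectors_split(self):
        v = np.array([0.6, -0.2, 0.4])
        arr = np.column_stack([v, v, -v, -v])
        cl = cluster_patients(profile_from(arr))
        assert cl.labels.iloc[0] == cl.labels.iloc[1]
        assert cl.labels.iloc[2] == cl.labels.iloc[3]
        assert cl.labels.iloc[0] != cl.labels.iloc[2]

    def test_planted_partition_recovered(self):
        prof, labels = two_block_profile(noise=0.3, seed=4)
        cl = cluster_patients(prof)
        got = cl.labels.to_numpy()
        agree = max((got == labels).mean(), (got == 3 - labels).mean())
        assert agree == 1.0

    def test_label_one_is_larger_cluster(self):
        prof, _ = two_block_profile(n_samples=30, seed=1)
        # drop some of block 2 so sizes differ
        sub = GsvaProfile(prof.values.iloc[:, :25])
        cl = cluster_patients(sub)
        sizes = cl.sizes
        assert sizes[1] >= sizes[2]

    def test_sample_order_permutation_invariance(self):
        prof, _ = two_block_profile(seed=2)
        rng = np.random.RandomState(0)
        perm = rng.permutation(prof.values.shape[1])
        shuffled = GsvaProfile(prof.values.iloc[:, perm])
        a = cluster_patients(prof).labels
        b = cluster_patients(shuffled).labels.loc[a.index]
        same = (b == a).all()
        swapped = (b == 3 - a).all()
        assert same or swapped  # partition identical up to label convention

    def test_constant_sample_rejected(self):
        arr = np.array([[0.1, 0.3], [0.1, 0.5]])
        with pytest.raises(ValueError, match="constant"):
            cluster_patients(profile_from(arr))


class TestBackwardSelection:
    def test_one_se_rule_hand_trace(self):
        idx = apply_one_se_rule([10, 5, 2], [0.10, 0.09, 0.12], [0.02, 0.02, 0.03])
        assert idx == 1  # threshold 0.11 -> smallest qualifying subset has 5

    def test_single_feature_trace(self):
        prof, labels = two_block_profile(n_modules=2, seed=3)
        single = prof.values.iloc[[0]]
        trace = rf_backward_select(single, labels, ntree_first=200, ntree_iter=100)
        assert len(trace.steps) == 1
        assert trace.chosen_features == [single.index[0]]

    def test_subset_sizes_strictly_decrease(self):
        prof, labels = two_block_profile(n_modules=12, seed=5)
        trace = rf_backward_select(
            prof.values, labels, ntree_first=300, ntree_iter=200, seed=1
        )
        sizes = trace.steps["n_features"].tolist()
        assert sizes[0] == 12 and sizes[-1] == 1
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_informative_features_survive_elimination(self):
        rng = np.random.RandomState(0)
        hits = 0
        for seed in range(6):
            n, p, informative = 150, 30, 5
            labels = rng.randint(1, 3, size=n)
            x = rng.normal(size=(p, n))
            x[:informative, labels == 2] += 2.0
            feats = pd.DataFrame(
                x, index=[f"M{i}" for i in range(p)], columns=[f"s{j}" for j in range(n)]
            )
            trace = rf_backward_select(
                feats, labels, ntree_first=400, ntree_iter=250, seed=seed
            )
            chosen = set(trace.chosen_features)
            hits += len(chosen & {f"M{i}" for i in range(informative)}) >= 4
        assert hits >= 4

    def test_single_class_rejected(self):
        prof, _ = two_block_profile(seed=6)
        with pytest.raises(ValueError, match="classes"):
            rf_backward_select(prof.values, np.ones(prof.values.shape[1]))


class TestPredictor:
    def test_separable_blobs_high_oob_accuracy(self):
        prof, labels = two_block_profile(n_samples=80, noise=0.2, seed=7)
        pred = train_predictor(prof.values, labels, ntree=400, seed=0)
        oob_label = np.where(pred.oob_probabilities > 0.5, 1, 2)
        assert (oob_label == labels).mean() >= 0.95

    def test_same_seed_identical_probabilities(self):
        prof, labels = two_block_profile(seed=8)
        a = train_predictor(prof.values, labels, ntree=200, seed=3)
        b = train_predictor(prof.values, labels, ntree=200, seed=3)
        assert np.allclose(a.oob_probabilities, b.oob_probabilities)

    def test_permuted_labels_near_chance(self):
        prof, labels = two_block_profile(n_samples=100, seed=9)
        rng = np.random.RandomState(1)
        permuted = rng.permutation(labels)
        pred = train_predictor(prof.values, permuted, ntree=400, seed=1)
        oob_label = np.where(pred.oob_probabilities > 0.5, 1, 2)
        acc = (oob_label == permuted).mean()
        assert 0.35 <= acc <= 0.65

    def test_probability_cutoff_strict(self):
        prof, labels = two_block_profile(seed=10)
        pred = train_predictor(prof.values, labels, ntree=100, seed=0)
        pred.model.predict_proba = lambda x: np.column_stack(
            [np.full(x.shape[0], 0.5), np.full(x.shape[0], 0.5)]
        )
        out = predict_cohort(pred, prof)
        assert (out["cluster"] == 2).all()  # 0.50 is not > 0.5

    def test_missing_module_named_in_error(self):
        prof, labels = two_block_profile(seed=11)
        pred = train_predictor(prof.values, labels, ntree=100, seed=0)
        partial = GsvaProfile(prof.values.iloc[1:])
        with pytest.raises(ValueError, match="M0"):
            predict_cohort(pred, partial)

    def test_single_class_training_rejected(self):
        prof, _ = two_block_profile(seed=12)
        with pytest.raises(ValueError, match="single class"):
            train_predictor(prof.values, np.ones(prof.values.shape[1]))


class TestRoc:
    def test_perfect_ranking(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(1.0)

    def test_hand_example_three_quarters(self):
        res = roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)
        assert res.ci_lower <= res.auc <= res.ci_upper

    def test_all_ties_give_half(self):
        res = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert res.auc == pytest.approx(0.5)

    def test_matches_concordant_pair_count(self):
        rng = np.random.RandomState(0)
        for _ in range(10):
            n = rng.randint(6, 20)
            y = rng.randint(0, 2, size=n)
            if len(set(y)) < 2:
                continue
            p = rng.uniform(size=n)
            pos, neg = p[y == 1], p[y == 0]
            conc = sum(
                1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
            )
            want = conc / (len(pos) * len(neg))
            assert roc_auc(p, y).auc == pytest.approx(want)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


def survival_table(seed, n=150, benefit_by_cluster=False, labels=None):
    rng = np.random.RandomState(seed)
    if labels is None:
        labels = rng.randint(1, 3, size=n)
    trt = rng.binomial(1, 0.5, size=n)
    lin = np.zeros(n)
    if benefit_by_cluster:
        lin = np.where(labels == 1, -0.7, 0.7) * trt
    t_event = rng.exponential(1.0 / (0.2 * np.exp(lin)))
    t_cens = rng.uniform(0, 12, size=n)
    ids = [f"s{i}" for i in range(n)]
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "rfs_time": np.minimum(t_event, t_cens),
                "rfs_event": (t_event <= t_cens).astype(int),
                "treatment": trt,
            },
            index=ids,
        )
    )
    return clin, pd.Series(labels, index=ids)


class TestBenefit:
    def test_opposite_effects_detected(self):
        hits = 0
        for seed in range(8):
            clin, labels = survival_table(seed, n=300, benefit_by_cluster=True)
            rep = evaluate_benefit(clin, labels)
            if rep.interaction["rfs"]["p"] < 0.05:
                hits += 1
        assert hits >= 7

    def test_null_interaction_p_uniform(self):
        pvals = []
        for seed in range(20):
            clin, labels = survival_table(100 + seed, n=120)
            rep = evaluate_benefit(clin, labels)
            pvals.append(rep.interaction["rfs"]["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_identical_arm_outcomes_logrank_one(self):
        n = 40
        ids = [f"s{i}" for i in range(n)]
        times = np.repeat([1.0, 2.0, 3.0, 4.0], n // 4)
        events = np.repeat([1, 0, 1, 1], n // 4)
        trt = np.array([0, 1] * (n // 2))  # arms identical within each time block
        clin = ClinicalTable(
            pd.DataFrame(
                {"rfs_time": times, "rfs_event": events, "treatment": trt},
                index=ids,
            )
        )
        labels = pd.Series(np.ones(n, dtype=int), index=ids)
        rep = evaluate_benefit(clin, labels)
        assert rep.strata[("all", "rfs")]["logrank_p"] == pytest.approx(1.0, abs=1e-6)

    def test_stratum_without_events_skips_tests(self):
        clin, labels = survival_table(7, n=60)
        df = clin.data.copy()
        df.loc[labels == 2, "rfs_event"] = 0
        clin2 = ClinicalTable(df)
        with pytest.warns(UserWarning):
            rep = evaluate_benefit(clin2, labels)
        assert "logrank_p" not in rep.strata[("Cluster2", "rfs")]
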