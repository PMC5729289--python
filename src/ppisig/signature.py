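"""Patient sub-grouping and predictive-signature construction.

Patients are clustered on the screened module scores (1 - Pearson
correlation, complete linkage, k = 2); a minimal module panel predicting
the two clusters is then selected by backward-elimination random forests
with the out-of-bag (OOB) 1-SE rule, and the final random-forest predictor
is evaluated by ROC/AUC (DeLong confidence interval) and by the treatment
benefit observed within each predicted sub-group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .gsva import GsvaProfile
from .prep import ClinicalTable
from .survival import fit_cox, km_curve, logrank_test

__all__ = [
    "PatientClustering",
    "SelectionTrace",
    "Predictor",
    "RocResult",
    "BenefitReport",
    "apply_one_se_rule",
    "cluster_patients",
    "rf_backward_select",
    "train_predictor",
    "predict_cohort",
    "roc_auc",
    "evaluate_benefit",
]


@dataclass(frozen=True)
class PatientClustering:
    """Two-group patient partition; label 1 is the larger cluster."""

    labels: pd.Series  # sample id -> 1 or 2

    @property
    def sizes(self) -> dict[int, int]:
        return self.labels.value_counts().to_dict()


@dataclass(frozen=True)
class SelectionTrace:
    """Backward-elimination record: one row per fitted feature subset.

    ``steps`` columns: n_features, oob_error, oob_se, members (tuple);
    ``chosen`` indexes the smallest subset whose OOB error is within one
    standard error of the minimum.
    """

    steps: pd.DataFrame
    chosen: int

    @property
    def chosen_features(self) -> list[str]:
        return list(self.steps.loc[self.chosen, "members"])


@dataclass
class Predictor:
    """Selected module panel + trained ensemble + probability cut-off."""

    modules: list[str]
    model: RandomForestClassifier = field(repr=False)
    cutoff: float = 0.5
    class_names: tuple[str, str] = ("Cluster1", "Cluster2")
    oob_probabilities: pd.Series | None = field(default=None, repr=False)


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    points: pd.DataFrame  # columns fpr, tpr


def cluster_patients(profile: GsvaProfile, k: int = 2) -> PatientClustering:
    """Cluster patients on module scores: 1 - Pearson r, complete linkage.

    Labels are relabeled by decreasing cluster size (ties: the cluster
    containing the first sample becomes 1) so that "Cluster 1" is always
    the major sub-group.
    """
    x = profile.values.to_numpy(dtype=float).T  # samples x modules
    n = x.shape[0]
    if n < k:
        raise ValueError("need at least k samples to form k clusters")
    if x.shape[1] >= 2:
        sds = x.std(axis=1)
        if (sds == 0).any():
            bad = [profile.samples[i] for i in np.flatnonzero(sds == 0)][:5]
            raise ValueError(f"constant score vector for sample(s): {bad}")
        dist = ssd.pdist(x, metric="correlation")  # 1 - Pearson r
    else:
        # correlation between length-1 vectors is undefined; fall back to
        # absolute score difference for a single-module profile
        dist = ssd.pdist(x, metric="euclidean")
    z = sch.linkage(dist, method="complete")
    raw = sch.fcluster(z, t=k, criterion="maxclust")
    order = sorted(
        np.unique(raw), key=lambda c: (-(raw == c).sum(), np.flatnonzero(raw == c)[0])
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series(
        [remap[c] for c in raw], index=profile.values.columns, name="cluster"
    )
    return PatientClustering(labels=labels)


def _oob_error(rf: RandomForestClassifier, y: np.ndarray) -> tuple[float, float]:
    """OOB misclassification rate and its binomial standard error."""
    proba = rf.oob_decision_function_
    pred = rf.classes_[np.nanargmax(proba, axis=1)]
    err = float(np.mean(pred != y))
    se = math.sqrt(err * (1.0 - err) / len(y))
    return err, se


def rf_backward_select(
    features: pd.DataFrame,
    labels,
    ntree_first: int = 5000,
    ntree_iter: int = 3000,
    drop_fraction: float = 0.2,
    seed: int = 0,
    importance_repeats: int = 5,
) -> SelectionTrace:
    """Backward-elimination random forest with the OOB 1-SE rule.

    ``features`` is a module x sample score matrix.  A first forest
    (``ntree_first`` trees) ranks modules by permutation importance —
    computed once and not re-ranked later, which avoids selection bias from
    re-estimated importances.  The bottom ``drop_fraction`` of modules
    (at least one) is then dropped repeatedly, refitting a forest
    (``ntree_iter`` trees) and recording OOB error with its binomial
    standard error at each subset, down to a single module.  The chosen
    panel is the smallest subset whose OOB error does not exceed the
    minimum error plus the standard error observed at that minimum.
    """
    x = features.to_numpy(dtype=float).T  # samples x modules
    names = [str(i) for i in features.index]
    y = np.asarray(labels)
    if len(set(y)) < 2:
        raise ValueError("both classes must be present for selection")
    rng = np.random.RandomState(seed)

    def fit(cols: list[int], ntree: int) -> RandomForestClassifier:
        rf = RandomForestClassifier(
            n_estimators=ntree,
            oob_score=True,
            random_state=rng.randint(0, 2**31 - 1),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(x[:, cols], y)
        return rf

    cols = list(range(len(names)))
    first = fit(cols, ntree_first)
    if len(cols) > 1:
        imp = permutation_importance(
            first,
            x,
            y,
            n_repeats=importance_repeats,
            random_state=rng.randint(0, 2**31 - 1),
            n_jobs=1,
        ).importances_mean
    else:
        imp = np.ones(1)
    ranking = list(np.argsort(-imp, kind="stable"))  # best first

    rows = []
    err, se = _oob_error(first, y)
    rows.append((len(cols), err, se, tuple(names[i] for i in ranking)))

    size = len(cols)
    while size > 1:
        size -= max(1, int(math.floor(drop_fraction * size)))
        keep = ranking[:size]
        rf = fit(keep, ntree_iter)
        err, se = _oob_error(rf, y)
        rows.append((size, err, se, tuple(names[i] for i in keep)))

    steps = pd.DataFrame(
        rows, columns=["n_features", "oob_error", "oob_se", "members"]
    )
    chosen = apply_one_se_rule(steps["n_features"], steps["oob_error"], steps["oob_se"])
    return SelectionTrace(steps=steps, chosen=chosen)


def apply_one_se_rule(sizes, errors, ses) -> int:
    """Index of the smallest subset with error <= min error + SE(min).

    The minimum is the first occurrence of the smallest error; the
    threshold adds that subset's own standard error.
    """
    sizes = np.asarray(sizes)
    errors = np.asarray(errors, dtype=float)
    ses = np.asarray(ses, dtype=float)
    imin = int(np.argmin(errors))
    threshold = errors[imin] + ses[imin]
    ok = np.flatnonzero(errors <= threshold)
    return int(ok[np.argmin(sizes[ok])])


def train_predictor(
    features: pd.DataFrame,
    labels,
    ntree: int = 5000,
    seed: int = 0,
    cutoff: float = 0.5,
) -> Predictor:
    """Train the final random-forest predictor on the selected modules.

    Training-cohort class probabilities are taken from out-of-bag votes
    (the fraction of OOB trees voting Cluster 1), which — unlike in-bag
    votes — are not nearly degenerate for a random forest.
    """
    x = features.to_numpy(dtype=float).T
    y = np.asarray(labels)
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")
    rf = RandomForestClassifier(
        n_estimators=ntree, oob_score=True, random_state=seed, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(x, y)
    cls1 = int(np.flatnonzero(rf.classes_ == 1)[0])
    oob = pd.Series(
        rf.oob_decision_function_[:, cls1],
        index=features.columns,
        name="prob_cluster1",
    )
    return Predictor(
        modules=[str(i) for i in features.index],
        model=rf,
        cutoff=cutoff,
        oob_probabilities=oob,
    )


def predict_cohort(predictor: Predictor, profile: GsvaProfile) -> pd.DataFrame:
    """Apply a trained predictor to a cohort's module profile.

    Returns a frame indexed by sample with columns ``probability``
    (of Cluster 1) and ``cluster`` (1 iff probability > cut-off, else 2).
    """
    missing = [m for m in predictor.modules if m not in profile.modules]
    if missing:
        raise ValueError(f"profile lacks selected module(s): {missing}")
    x = profile.values.loc[predictor.modules].to_numpy(dtype=float).T
    cls1 = int(np.flatnonzero(predictor.model.classes_ == 1)[0])
    prob = predictor.model.predict_proba(x)[:, cls1]
    label = np.where(prob > predictor.cutoff, 1, 2)
    return pd.DataFrame(
        {"probability": prob, "cluster": label},
        index=profile.values.columns,
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong confidence interval


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative-class scores."""
    m, n = len(pos), len(neg)
    # placement values via mid-ranks
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    pos_ranks, neg_ranks = ranks[:m], ranks[m:]
    auc = (pos_ranks.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (pos_ranks - stats.rankdata(pos)) / n  # P(score_neg < pos_i)
    v01 = 1.0 - (neg_ranks - stats.rankdata(neg)) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_auc(probabilities, labels, alpha: float = 0.05) -> RocResult:
    """ROC curve and AUC with a DeLong 95% confidence interval.

    ``labels`` are binary with 1 the positive class; AUC equals the
    Mann–Whitney concordance probability of the scores.
    """
    prob = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    classes = set(np.unique(y))
    if len(classes) != 2:
        raise ValueError("ROC requires exactly two classes in labels")
    positive = y == 1 if 1 in classes else y == max(classes)
    pos, neg = prob[positive], prob[~positive]
    auc, var = _delong_variance(pos, neg)
    zq = stats.norm.ppf(1 - alpha / 2)
    half = zq * math.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)

    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(positive.astype(int), prob)
    return RocResult(
        auc=auc,
        ci_lower=lo,
        ci_upper=hi,
        points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
    )


# ---------------------------------------------------------------------------
# treatment-benefit evaluation


@dataclass(frozen=True)
class BenefitReport:
    """Treatment-vs-control survival comparison per predicted sub-group.

    ``strata`` maps (stratum, endpoint) -> dict with the log-rank p, arm
    sizes, the per-stratum treatment log hazard ratio, and the two KM
    curves; ``interaction`` maps endpoint -> Wald p of treatment x cluster
    in a Cox model on the whole cohort.
    """

    strata: dict
    interaction: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (stratum, endpoint), rec in self.strata.items():
            rows.append(
                {
                    "stratum": stratum,
                    "endpoint": endpoint,
                    "logrank_p": rec.get("logrank_p", np.nan),
                    "treatment_log_hr": rec.get("treatment_log_hr", np.nan),
                    "n_treated": rec["n_treated"],
                    "n_untreated": rec["n_untreated"],
                }
            )
        return pd.DataFrame(rows)


def evaluate_benefit(clinical: ClinicalTable, labels: pd.Series) -> BenefitReport:
    """Quantify how the treatment effect differs between predicted clusters.

    For each stratum (whole cohort, Cluster 1, Cluster 2) and each
    available endpoint, treated and untreated patients are compared by
    Kaplan–Meier curves, a log-rank test, and a univariate Cox treatment
    coefficient; on the whole cohort a Cox model
    ``endpoint ~ treatment + cluster + treatment*cluster`` supplies the
    interaction Wald p.  Strata without events keep their curves but skip
    the tests (with a warning).
    """
    labels = labels.reindex(clinical.data.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all clinical samples")
    strata: dict = {}
    interaction: dict = {}
    trt = clinical.data["treatment"]

    for endpoint in clinical.endpoints_available():
        time, event = clinical.endpoint(endpoint)
        for stratum, mask in (
            ("all", np.ones(len(labels), dtype=bool)),
            ("Cluster1", (labels == 1).to_numpy()),
            ("Cluster2", (labels == 2).to_numpy()),
        ):
            tmask = mask & (trt == 1).to_numpy()
            umask = mask & (trt == 0).to_numpy()
            rec: dict = {
                "n_treated": int(tmask.sum()),
                "n_untreated": int(umask.sum()),
                "km_treated": km_curve(time[tmask], event[tmask])
                if tmask.any()
                else None,
                "km_untreated": km_curve(time[umask], event[umask])
                if umask.any()
                else None,
            }
            if (
                tmask.any()
                and umask.any()
                and event[mask].sum() > 0
            ):
                lr = logrank_test(
                    time[tmask], event[tmask], time[umask], event[umask]
                )
                rec["logrank_p"] = lr.p_value
                try:
                    sub = clinical.subset(clinical.data.index[mask])
                    fit = fit_cox(sub, ["treatment"], endpoint=endpoint)
                    rec["treatment_log_hr"] = float(
                        fit.coefficients["treatment"]
                    )
                except ValueError:
                    pass
            else:
                warnings.warn(
                    f"stratum {stratum}/{endpoint}: no events or empty arm; "
                    "tests skipped",
                    stacklevel=2,
                )
            strata[(stratum, endpoint)] = rec

        design = pd.DataFrame(
            {
                "treatment": trt.astype(float),
                "cluster2": (labels == 2).astype(float),
                "trt_cluster2": trt.astype(float) * (labels == 2).astype(float),
            },
            index=clinical.data.index,
        )
        try:
            fit = fit_cox(clinical, design, endpoint=endpoint)
            interaction[endpoint] = {
                "p": float(fit.p_values["trt_cluster2"]),
                "beta": float(fit.coefficients["trt_cluster2"]),
            }
        except ValueError as exc:
            warnings.warn(
                f"interaction Cox fit skipped for {endpoint}: {exc}", stacklevel=2
            )
    return BenefitReport(strata=strata, interaction=interaction)
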