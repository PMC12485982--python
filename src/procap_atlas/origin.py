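"""Tissue-of-origin analysis: clustering, PC-space similarity, and a
linear-SVM primary-site classifier.

Metastatic tumors retain the regulatory-element usage of their tissue of
origin.  Three analyses exploit this:

* :func:`hier_cluster` — average-linkage agglomerative clustering of
  samples under correlation distance (1 − Pearson r), the standard
  dendrogram for expression profiles.
* :func:`pc_correlations` — project samples onto the principal components
  explaining 90% of variance and compare each tumor to normal samples
  from its primary site, its metastatic site, and other sites by Pearson
  correlation of PC score vectors.
* :func:`train_origin_model` / :func:`predict_topk` — a one-vs-rest
  linear support vector classifier (C = 1) over tissue-specific element
  features (the union of per-tissue specific sets, excluding elements
  claimed by more than one tissue), ranking candidate origins per query
  with top-k output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from .specificity import TissueDesign

__all__ = [
    "SimilarityReport",
    "OriginModel",
    "PredictionResult",
    "hier_cluster",
    "pc_correlations",
    "train_origin_model",
    "predict_topk",
    "evaluate_origin_study",
]


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def hier_cluster(
    log_matrix: pd.DataFrame, element_subset: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of sample columns, distance = 1 − Pearson r.

    Returns the scipy linkage table and the sample order it indexes.
    Constant (zero-variance) columns make the correlation undefined and
    raise, naming the offending sample.
    """
    X = log_matrix if element_subset is None else log_matrix.loc[list(element_subset)]
    if X.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    arr = X.to_numpy(dtype=float).T  # samples x elements
    stds = arr.std(axis=1)
    for sid, sd in zip(X.columns, stds):
        if sd == 0:
            raise ValueError(f"sample {sid!r} has constant expression; correlation undefined")
    dist = pdist(arr, metric="correlation")
    return linkage(dist, method="average"), list(X.columns)


# ---------------------------------------------------------------------------
# PC-space similarity
# ---------------------------------------------------------------------------


@dataclass
class SimilarityReport:
    """Pairwise tumor-vs-normal correlations in PC space, plus means by group."""

    pairwise: pd.DataFrame  # tumor, normal, tissue, group, r
    summary: pd.DataFrame  # per tumor: mean_r_primary, mean_r_metastatic, mean_r_other
    n_components: int
    explained_variance: float


def _pc_scores(matrix: pd.DataFrame, variance_target: float) -> tuple[pd.DataFrame, float]:
    """PCA on samples (columns as observations); keep the smallest m PCs
    whose cumulative explained variance reaches the target."""
    X = matrix.to_numpy(dtype=float).T  # samples x elements
    pca = PCA()
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    m = min(m, scores.shape[1])
    return (
        pd.DataFrame(scores[:, :m], index=matrix.columns),
        float(cum[m - 1]),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) == 1:
        # a single retained component has no variance across itself; fall back
        # to sign agreement of the scalar scores
        p = x[0] * y[0]
        return float(np.sign(p)) if p != 0 else 0.0
    return float(np.corrcoef(x, y)[0, 1])


def pc_correlations(
    log_matrix: pd.DataFrame,
    tumors: pd.DataFrame,
    design: TissueDesign,
    variance_target: float = 0.90,
) -> SimilarityReport:
    """Tumor-to-normal Pearson correlations over the top principal components.

    ``log_matrix`` holds tumors and normals as columns; ``tumors`` has
    columns sample_id, primary_site, metastatic_site; ``design`` labels
    the normal samples with their tissue.  PCA is fit on all included
    samples jointly, and each tumor-normal pair is correlated over the
    retained PC scores.  Normals are grouped per tumor as primary-site,
    metastatic-site, or other.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    normals = list(design.assignment.index)
    tumor_ids = list(tumors["sample_id"])
    cols = [c for c in log_matrix.columns if c in set(normals) | set(tumor_ids)]
    scores, reached = _pc_scores(log_matrix[cols], variance_target)
    rows = []
    for _, trow in tumors.iterrows():
        tid = trow["sample_id"]
        tvec = scores.loc[tid].to_numpy()
        for nid in normals:
            tissue = design.assignment[nid]
            if tissue == trow["primary_site"]:
                group = "primary"
            elif tissue == trow["metastatic_site"]:
                group = "metastatic"
            else:
                group = "other"
            rows.append(
                {
                    "tumor": tid,
                    "normal": nid,
                    "tissue": tissue,
                    "group": group,
                    "r": _pearson(tvec, scores.loc[nid].to_numpy()),
                }
            )
    pairwise = pd.DataFrame(rows)
    summary = (
        pairwise.pivot_table(index="tumor", columns="group", values="r", aggfunc="mean")
        .rename(columns=lambda g: f"mean_r_{g}")
        .reindex(tumor_ids)
    )
    return SimilarityReport(
        pairwise=pairwise,
        summary=summary,
        n_components=scores.shape[1],
        explained_variance=reached,
    )


# ---------------------------------------------------------------------------
# origin classifier
# ---------------------------------------------------------------------------


@dataclass
class OriginModel:
    """Linear one-vs-rest decision weights over tissue-specific features."""

    features: list[str]
    classes: list[str]
    coef: np.ndarray  # n_classes x n_features (1 x f for 2 classes)
    intercept: np.ndarray
    feature_tissue: dict[str, str]  # feature -> the single tissue claiming it

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class decision values, samples x classes."""
        raw = X @ self.coef.T + self.intercept
        if len(self.classes) == 2 and raw.shape[1] == 1:
            return np.column_stack([-raw[:, 0], raw[:, 0]])
        return raw

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": self.features,
            "classes": self.classes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "feature_tissue": self.feature_tissue,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "OriginModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=d["features"],
            classes=d["classes"],
            coef=np.asarray(d["coef"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float),
            feature_tissue=d["feature_tissue"],
        )


@dataclass
class PredictionResult:
    """Ranked origin calls for query samples."""

    ranking: pd.DataFrame  # sample_id, rank, tissue, score, top_k
    k: int
    n_missing_features: int

    def top1(self) -> pd.Series:
        top = self.ranking[self.ranking["rank"] == 1]
        return pd.Series(top["tissue"].values, index=top["sample_id"].values)

    def topk_sets(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, sub in self.ranking[self.ranking["top_k"]].groupby("sample_id"):
            out[sid] = list(sub.sort_values("rank")["tissue"])
        return out


def build_feature_set(tissue_specific_sets: Mapping[str, Sequence[str]]) -> dict[str, str]:
    """Union of per-tissue specific elements, excluding multi-tissue ones.

    Returns feature -> owning tissue; raises if any tissue loses all its
    features to the shared-element exclusion.
    """
    claim_count: dict[str, int] = {}
    for ids in tissue_specific_sets.values():
        for eid in ids:
            claim_count[eid] = claim_count.get(eid, 0) + 1
    mapping: dict[str, str] = {}
    empty: list[str] = []
    for tissue in sorted(tissue_specific_sets):
        kept = [eid for eid in tissue_specific_sets[tissue] if claim_count[eid] == 1]
        if not kept:
            empty.append(tissue)
        for eid in kept:
            mapping[eid] = tissue
    if empty:
        raise ValueError(
            "tissues lost all features to the multi-tissue exclusion: " + ", ".join(empty)
        )
    return mapping


def train_origin_model(
    log_matrix: pd.DataFrame,
    design: TissueDesign,
    tissue_specific_sets: Mapping[str, Sequence[str]],
    C: float = 1.0,
    class_weight: str | None = None,
) -> OriginModel:
    """Train the one-vs-rest linear SVC on normal samples.

    Features are the tissue-specific union set minus multi-tissue
    elements; the input matrix is the log-normalized expression of the
    training (normal) samples.
    """
    if design.n_tissues < 2:
        raise ValueError("training requires at least 2 tissues")
    feature_tissue = build_feature_set(tissue_specific_sets)
    features = sorted(feature_tissue)
    missing = [f for f in features if f not in log_matrix.index]
    if missing:
        raise ValueError(f"features missing from matrix: {missing[:5]}...")
    samples = list(design.assignment.index)
    X = log_matrix.loc[features, samples].to_numpy(dtype=float).T
    y = design.assignment[samples].to_numpy()
    clf = LinearSVC(C=C, class_weight=class_weight)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # liblinear convergence chatter on toy data
        clf.fit(X, y)
    return OriginModel(
        features=features,
        classes=[str(c) for c in clf.classes_],
        coef=np.asarray(clf.coef_, dtype=float),
        intercept=np.asarray(clf.intercept_, dtype=float),
        feature_tissue=feature_tissue,
    )


def predict_topk(model: OriginModel, query: pd.DataFrame, k: int = 3) -> PredictionResult:
    """Rank candidate origin tissues for each query sample (column).

    Query rows are aligned to model features; missing features are imputed
    as 0 with a warning.  Ties in decision score break by tissue name, so
    the ranking is strictly ordered.
    """
    if k > len(model.classes):
        raise ValueError(f"k={k} exceeds the {len(model.classes)} trained classes")
    if k < 1:
        raise ValueError("k must be >= 1")
    aligned = query.reindex(model.features)
    n_missing = int(aligned.isna().all(axis=1).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} model features absent from query matrix; imputed as 0",
            stacklevel=2,
        )
    X = aligned.fillna(0.0).to_numpy(dtype=float).T
    scores = model.decision_scores(X)
    rows = []
    for si, sid in enumerate(query.columns):
        order = sorted(
            range(len(model.classes)), key=lambda c: (-scores[si, c], model.classes[c])
        )
        for rank, c in enumerate(order, start=1):
            rows.append(
                {
                    "sample_id": sid,
                    "rank": rank,
                    "tissue": model.classes[c],
                    "score": float(scores[si, c]),
                    "top_k": rank <= k,
                }
            )
    return PredictionResult(ranking=pd.DataFrame(rows), k=k, n_missing_features=n_missing)


def evaluate_origin_study(study, k: int = 3, top_frac: float = 0.05) -> dict[str, float]:
    """Run the full origin workflow on a simulated study; report accuracies.

    From raw counts: joint median-of-ratios normalization of training and
    query samples, per-tissue t-statistic feature selection (top
    ``top_frac`` of the union set), linear-SVC training on the normals,
    and top-k prediction for the queries.  Returns top-1 and top-k
    accuracy against the planted primary sites.
    """
    from .quantify import normalize, size_factors
    from .specificity import select_sets, specificity_scores, tissue_t_statistics

    combined = pd.concat([study.train_counts, study.query_counts], axis=1)
    s = size_factors(combined)
    norm = normalize(combined, s)
    train_ids = list(study.train_design["sample_id"])
    design = TissueDesign.from_frame(study.train_design)
    scaled_train = norm.scaled[train_ids]
    log_train = norm.log2[train_ids]
    res = specificity_scores(scaled_train, design)
    t_by_tissue = {
        t: tissue_t_statistics(log_train, design, t) for t in design.eligible_tissues()
    }
    proximity = pd.Series("distal", index=res.score.index)
    sets = select_sets(t_by_tissue, res, proximity, top_frac=top_frac)
    model = train_origin_model(log_train, design, sets.specific)
    pred = predict_topk(model, norm.log2[list(study.queries["sample_id"])], k=k)
    truth = dict(zip(study.queries["sample_id"], study.queries["primary_site"]))
    top1 = pred.top1()
    topk = pred.topk_sets()
    n = len(truth)
    return {
        "top1_accuracy": sum(top1[q] == truth[q] for q in truth) / n,
        f"top{k}_accuracy": sum(truth[q] in topk[q] for q in truth) / n,
        "n_features": float(len(model.features)),
    }
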