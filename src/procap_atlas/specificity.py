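"""Entropy-based tissue specificity and selection of tissue-specific sets.

For each element e, the mean normalized expression q_{e,t} per tissue t is
converted to a probability vector p_{t|e} = q_{e,t} / Σ_t q_{e,t}; the
Shannon entropy H_e = −Σ_t p log2 p (bits) then yields the specificity
score

    S_e = 1 − H_e / log2 N,   N = number of tissue types,

which is 0 for perfectly ubiquitous activity and 1 for activity confined
to a single tissue.

Tissue-specific sets are chosen by a per-tissue ±1-coded OLS t-statistic:
regress each element's log-normalized expression on an intercept and a
membership indicator (+1 in-tissue, −1 out), and rank elements by the
membership t.  The top 5% of the element union set per tissue forms that
tissue's specific set.  The non-tissue-specific background set collects
distal elements with S < 0.1 and proximal elements with S < 0.02,
excluding anything that entered a tissue-specific set.

The probability construction uses the nonnegative ``scaled`` matrix
(count / size factor); the t-statistics use the log-transformed matrix,
whose variances are comparable across expression levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TissueDesign",
    "SpecificityResult",
    "TissueSpecificSets",
    "specificity_scores",
    "tissue_t_statistics",
    "select_sets",
]


class TissueDesign:
    """Sample → tissue assignment with eligibility rules for t-statistics."""

    def __init__(self, assignment: Mapping[str, str] | pd.Series):
        s = pd.Series(dict(assignment)) if not isinstance(assignment, pd.Series) else assignment
        if s.empty:
            raise ValueError("design is empty")
        self.assignment = s.astype(str)
        self.tissues = sorted(self.assignment.unique())

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.assignment.index[self.assignment == tissue])

    def eligible_tissues(self, min_samples: int = 3) -> list[str]:
        """Tissues with enough samples for a per-tissue t-statistic."""
        counts = self.assignment.value_counts()
        return sorted(t for t in self.tissues if counts[t] >= min_samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TissueDesign":
        return cls(pd.Series(df["tissue"].values, index=df["sample_id"].values))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TissueDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class SpecificityResult:
    """Per-element tissue means, probabilities, entropy and score.

    ``defined`` flags elements with Σ_t q > 0; for the rest, p, H and S
    are NaN and the element is excluded from downstream selection.
    """

    q: pd.DataFrame  # elements x tissues, mean normalized expression
    p: pd.DataFrame  # elements x tissues, probabilities
    entropy: pd.Series  # bits
    score: pd.Series  # S in [0, 1]
    defined: pd.Series  # bool


@dataclass
class TissueSpecificSets:
    specific: dict[str, list[str]]  # tissue -> element ids (top 5% by t)
    t_statistics: pd.DataFrame  # elements x tissues
    non_specific: list[str]
    n_top: int


def specificity_scores(scaled: pd.DataFrame, design: TissueDesign) -> SpecificityResult:
    """Specificity scores from the nonnegative normalized matrix.

    ``scaled`` is elements x samples (count / size factor).  Requires at
    least two tissues; negative values indicate the wrong input matrix
    (log values can be negative) and raise.
    """
    if design.n_tissues < 2:
        raise ValueError("specificity scores require at least 2 tissue types")
    missing = set(design.assignment.index) - set(scaled.columns)
    if missing:
        raise ValueError(f"samples missing from matrix: {sorted(missing)}")
    if (scaled.to_numpy() < 0).any():
        raise ValueError("negative values in expression matrix; pass the scaled "
                         "(count/size-factor) matrix, not log values")
    q = pd.DataFrame(
        {t: scaled[design.samples_of(t)].mean(axis=1) for t in design.tissues},
        index=scaled.index,
    )
    totals = q.sum(axis=1)
    defined = totals > 0
    p = q.div(totals, axis=0)
    p[~defined] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = p * np.log2(p)
    entropy = -plogp.fillna(0.0).sum(axis=1)
    entropy[~defined] = np.nan
    score = 1.0 - entropy / math.log2(design.n_tissues)
    return SpecificityResult(q=q, p=p, entropy=entropy, score=score, defined=defined)


def tissue_t_statistics(
    log_matrix: pd.DataFrame, design: TissueDesign, tissue: str, min_samples: int = 3
) -> pd.Series:
    """Per-element OLS t-statistic for ±1-coded membership in one tissue.

    Fits y = b0 + b1·m per element, with m = +1 for samples of the tissue
    and −1 otherwise, and returns t = b1 / SE(b1) with n − 2 residual
    degrees of freedom.  Zero residual variance yields ±inf with the sign
    of the coefficient (a documented sentinel).  For a balanced design
    this equals the classical equal-variance two-sample t.
    """
    samples = list(log_matrix.columns)
    n = len(samples)
    if n <= 2:
        raise ValueError("t-statistics require more than 2 samples")
    membership = design.assignment.reindex(samples)
    if membership.isna().any():
        raise ValueError("samples missing from design")
    n_in = int((membership == tissue).sum())
    if n_in < min_samples:
        raise ValueError(
            f"tissue {tissue!r} has {n_in} samples; needs >= {min_samples}"
        )
    if n_in == n:
        raise ValueError("all samples belong to the tissue; no out-group")
    m = np.where(membership == tissue, 1.0, -1.0)
    Y = log_matrix.to_numpy(dtype=float)  # elements x samples
    X = np.column_stack([np.ones(n), m])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # elements x 2
    resid = Y - beta @ X.T
    rss = np.sum(resid**2, axis=1)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    b1 = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            se > 0,
            np.divide(b1, se, out=np.zeros_like(b1), where=se > 0),
            np.where(b1 > 0, np.inf, np.where(b1 < 0, -np.inf, 0.0)),
        )
    return pd.Series(t, index=log_matrix.index, name=tissue)


def select_sets(
    t_by_tissue: Mapping[str, pd.Series],
    scores: SpecificityResult,
    proximity: pd.Series,
    top_frac: float = 0.05,
    distal_cut: float = 0.1,
    proximal_cut: float = 0.02,
) -> TissueSpecificSets:
    """Per-tissue top-5% sets by t-statistic plus the non-specific set.

    The union set is the set of elements with defined specificity (nonzero
    total expression); each tissue's specific set is the top
    ``ceil(top_frac * |union|)`` elements by t, ties broken by element id.
    The non-specific set is {distal with S < distal_cut} ∪ {proximal with
    S < proximal_cut} minus every tissue-specific set.
    """
    if not t_by_tissue:
        raise ValueError("no tissue t-statistics supplied")
    union = [eid for eid in scores.score.index if scores.defined[eid]]
    n_top = math.ceil(top_frac * len(union))
    union_set = set(union)
    specific: dict[str, list[str]] = {}
    t_frame = pd.DataFrame({t: s for t, s in t_by_tissue.items()})
    for tissue in sorted(t_by_tissue):
        t = t_by_tissue[tissue]
        t = t[t.index.isin(union_set)]
        ranked = sorted(t.items(), key=lambda kv: (-kv[1], kv[0]))
        specific[tissue] = [eid for eid, _ in ranked[:n_top]]
    in_any_specific = set().union(*specific.values()) if specific else set()
    prox = proximity.reindex(scores.score.index)
    non_specific = [
        eid
        for eid in union
        if eid not in in_any_specific
        and (
            (prox[eid] == "distal" and scores.score[eid] < distal_cut)
            or (prox[eid] == "proximal" and scores.score[eid] < proximal_cut)
        )
    ]
    return TissueSpecificSets(
        specific=specific, t_statistics=t_frame, non_specific=non_specific, n_top=n_top
    )
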