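"""Quantification: element count matrix and median-of-ratios normalization.

Initiation activity per element is the number of read 5' ends falling
within the element span (both strands).  Across samples this yields an
elements x samples count matrix, normalized with the median-of-ratios
size-factor method: the reference for each element is its geometric mean
across samples (over elements with all counts positive), and a sample's
size factor is the median of its count/reference ratios, rescaled so the
factors have geometric mean 1.  Values are then stabilized as
``log2(count / size_factor + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import SignalTrack, count_in_interval
from .elements import Element

__all__ = ["NormalizedMatrix", "build_count_matrix", "size_factors", "normalize"]


@dataclass
class NormalizedMatrix:
    """Size factors plus the two normalized views used downstream.

    ``scaled`` (count / size factor) feeds nonnegative quantities such as
    the tissue-specificity probabilities; ``log2`` (log2(scaled + 1)) feeds
    variance-sensitive analyses (t-statistics, PCA, clustering, SVM).
    """

    size_factors: pd.Series
    scaled: pd.DataFrame
    log2: pd.DataFrame


def build_count_matrix(
    tracks: Mapping[str, SignalTrack], elements: Sequence[Element]
) -> pd.DataFrame:
    """Count 5' ends within each element span (both strands) per sample.

    Rows are element_ids, columns sample_ids.  Overlapping elements each
    count shared reads (reads are not partitioned between elements).
    """
    sample_ids = list(tracks)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    eids = [e.element_id for e in elements]
    if len(set(eids)) != len(eids):
        raise ValueError("duplicate element ids")
    data = {
        sid: [count_in_interval(track, e.span, "both") for e in elements]
        for sid, track in tracks.items()
    }
    return pd.DataFrame(data, index=pd.Index(eids, name="element_id"), dtype=np.int64)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The per-element reference is the geometric mean of counts across
    samples, computed over elements with strictly positive counts in every
    sample; each sample's factor is the median ratio of its counts to the
    references.
    """
    if counts.shape[1] == 0:
        raise ValueError("count matrix has no samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("cannot compute size factors: no element has positive counts in all samples")
    sub = counts.loc[positive].to_numpy(dtype=float)
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, s: pd.Series) -> NormalizedMatrix:
    """Apply size factors: ``scaled = count/s``, ``log2 = log2(scaled + 1)``."""
    s = s.reindex(counts.columns)
    if s.isna().any():
        raise ValueError("size factors missing for some samples")
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    scaled = counts.astype(float).div(s, axis=1)
    return NormalizedMatrix(size_factors=s, scaled=scaled, log2=np.log2(scaled + 1.0))
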