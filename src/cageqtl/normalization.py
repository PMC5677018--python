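"""Depth and between-sample normalization of tag-count matrices.

The quantification chain is the FANTOM-style one: raw tag counts are scaled
within each sample to tags per million mapped reads (TPM), then normalized
between samples with relative log expression (RLE, the median-of-ratios
estimator). Lowly expressed features are removed on mean RLE-TPM, and
principal components of the normalized matrix (and of the genotypes) serve
as regression covariates downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def tpm_normalize(raw_counts: pd.DataFrame, library_sizes) -> pd.DataFrame:
    """Scale counts to tags per million mapped reads, per sample.

    ``library_sizes`` maps sample id -> total mapped tags (a Series or dict);
    feature-level counts need not sum to the library size.
    """
    lib = pd.Series(library_sizes).reindex(raw_counts.columns)
    if lib.isna().any():
        missing = list(raw_counts.columns[lib.isna()])
        raise ValueError(f"library sizes missing for samples: {missing}")
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return raw_counts * (1e6 / lib)


def rle_size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean across samples, computed
    over features with a nonzero value in every sample.
    """
    vals = matrix.to_numpy(dtype=float)
    all_nonzero = (vals > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("RLE undefined: no feature is nonzero in every sample")
    v = vals[all_nonzero]
    log_geo = np.mean(np.log(v), axis=1, keepdims=True)
    log_ratios = np.log(v) - log_geo
    log_factors = np.median(log_ratios, axis=0)
    log_factors = log_factors - np.mean(log_factors)  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=matrix.columns, name="size_factor")


def rle_normalize(matrix: pd.DataFrame):
    """Apply RLE: returns (normalized matrix, size factors)."""
    factors = rle_size_factors(matrix)
    return matrix / factors, factors


def filter_by_mean(matrix: pd.DataFrame, threshold: float = 0.5):
    """Keep features whose mean over samples is >= threshold (RLE-TPM units).

    Returns (filtered matrix, n_kept, n_dropped).
    """
    keep = matrix.mean(axis=1) >= threshold
    return matrix.loc[keep], int(keep.sum()), int((~keep).sum())


def pca_covariates(data, k: int, scale: bool = True) -> pd.DataFrame:
    """Top-k principal-component scores per sample.

    ``data`` is features-by-samples (DataFrame) or an (n_samples, n_features)
    array (genotype dosages). Features are centered; unit-scaled when ``scale``
    (expression convention; genotype PCs conventionally use centered dosages
    only). Component signs are fixed so each loading's largest-magnitude entry
    is positive, making scores deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float).T  # samples x features
        sample_ids = list(data.columns)
    else:
        X = np.asarray(data, dtype=float)
        sample_ids = list(range(X.shape[0]))
    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest |loading| entry positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :k] * S[:k]
    return pd.DataFrame(
        scores, index=sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )


def rank_inverse_normal(matrix: pd.DataFrame, offset: float = 0.5) -> pd.DataFrame:
    """Per-feature rank-based inverse normal transform (Blom offset 0.5).

    Guards the linear QTL model against residual count skew; ties get average
    ranks.
    """
    vals = matrix.to_numpy(dtype=float)
    n = vals.shape[1]
    ranks = stats.rankdata(vals, axis=1)
    transformed = stats.norm.ppf((ranks - offset) / n)
    return pd.DataFrame(transformed, index=matrix.index, columns=matrix.columns)


def normalize_counts(raw_counts: pd.DataFrame, library_sizes, mean_threshold: float = 0.5):
    """Full promoter-expression chain: TPM -> RLE -> mean filter.

    Returns (normalized filtered matrix, size factors, n_kept, n_dropped).
    """
    tpm = tpm_normalize(raw_counts, library_sizes)
    norm, factors = rle_normalize(tpm)
    filtered, kept, dropped = filter_by_mean(norm, mean_threshold)
    return filtered, factors, kept, dropped
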