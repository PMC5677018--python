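"""Transcribed-enhancer detection and activity quantification from CTSS data.

Active enhancers produce short divergent (bidirectional) capped transcripts.
The detector pools CTSS records across the cohort, builds density-based tag
clusters per strand (the recursive maximal-density-segment formulation of
Paraclu), keeps enhancers whose center is flanked by clusters on both strands
within 400 nt, and scores directionality D = (F - R) / (F + R) from the
normalized expression of the two 200-nt flanking windows. Balanced elements
(|D| < 0.8) are quantified per sample as the sum of the twice-normalized
(TPM then RLE) window expressions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomicInterval, aggregate_tags_to_features
from .normalization import rle_normalize, tpm_normalize

logger = logging.getLogger(__name__)


@dataclass
class TagCluster:
    """A maximal-density CTSS segment on one strand.

    ``min_density`` is the density at which the segment detaches from its
    parent in the density hierarchy; ``max_density`` the density at which it
    breaks apart (infinite for single positions).
    """

    chrom: str
    strand: str
    start: int
    end: int  # half-open; last position + 1
    tag_count: int
    min_density: float
    max_density: float

    def __len__(self) -> int:
        return self.end - self.start


def _weakest_prefix(pos, val, i, j):
    """(min prefix density, break index, total value) for sites [i, j)."""
    origin = pos[i]
    tot = val[i]
    min_d, brk = math.inf, i
    for k in range(i + 1, j):
        d = tot / (pos[k] - origin)
        if d < min_d:
            min_d, brk = d, k
        tot += val[k]
    return min_d, brk, tot


def _weakest_suffix(pos, val, i, j):
    last = pos[j - 1]
    tot = val[j - 1]
    min_d, brk = math.inf, j - 1
    for k in range(j - 2, i - 1, -1):
        d = tot / (last - pos[k])
        if d < min_d:
            min_d, brk = d, k
        tot += val[k]
    return min_d, brk


def paraclu_cluster(
    positions,
    counts,
    min_tags: int = 5,
    min_density_fold: float = 2.0,
    max_length: int = 200,
    chrom: str = ".",
    strand: str = ".",
) -> list:
    """Density clustering of CTSS positions on a single chromosome strand.

    Candidate clusters are all segments maximal for some density d under the
    score sum(counts) - d * span: the input is split recursively at the
    weakest prefix or suffix (the boundary of minimal density), recording for
    each segment the density interval [min_density, max_density) over which it
    is maximal. Emitted clusters must hold at least ``min_tags`` tags, satisfy
    max_density / min_density >= ``min_density_fold`` (single-position
    clusters have infinite max density and always pass), and span at most
    ``max_length`` nt.
    """
    pos = np.asarray(positions)
    val = np.asarray(counts, dtype=float)
    if len(pos) == 0:
        return []
    if np.any(np.diff(pos) <= 0):
        raise ValueError("CTSS positions must be sorted and unique")
    if np.any(val < 1):
        raise ValueError("tag counts must be >= 1")
    pos = pos.tolist()
    val = val.tolist()

    candidates = []
    stack = [(0, len(pos), 0.0)]
    while stack:
        i, j, min_density = stack.pop()
        if j - i == 1:
            candidates.append((i, j, min_density, math.inf, val[i]))
            continue
        d_pre, k_pre, tot = _weakest_prefix(pos, val, i, j)
        d_suf, k_suf = _weakest_suffix(pos, val, i, j)
        break_density = min(d_pre, d_suf)
        if break_density > min_density:
            candidates.append((i, j, min_density, break_density, tot))
        if d_pre <= d_suf:
            parts = ((i, k_pre), (k_pre, j))
        else:
            parts = ((i, k_suf + 1), (k_suf + 1, j))
        # a child is maximal only above the strongest break on its ancestor
        # chain, so the detachment density accumulates as a running maximum
        child_min = max(min_density, break_density)
        for a, b in parts:
            stack.append((a, b, child_min))

    out = []
    for i, j, dmin, dmax, tot in candidates:
        if tot < min_tags:
            continue
        length = pos[j - 1] - pos[i] + 1
        if length > max_length:
            continue
        ratio = math.inf if (dmin == 0 or math.isinf(dmax)) else dmax / dmin
        if ratio < min_density_fold:
            continue
        out.append(TagCluster(chrom, strand, pos[i], pos[j - 1] + 1,
                              int(round(tot)), dmin, dmax))
    out.sort(key=lambda c: (c.start, c.end))
    return out


def pool_ctss(tag_streams) -> pd.DataFrame:
    """Sum CTSS counts across samples per (chrom, strand, pos)."""
    all_tags = pd.concat([ts.data for ts in tag_streams], ignore_index=True)
    return (
        all_tags.groupby(["chrom", "strand", "pos"], sort=True)["count"]
        .sum()
        .reset_index()
    )


def cluster_pooled_ctss(tag_streams, min_tags: int = 5,
                        min_density_fold: float = 2.0,
                        max_length: int = 200) -> list:
    """Paraclu clusters on the cohort-pooled CTSS, per chromosome strand."""
    pooled = pool_ctss(tag_streams)
    clusters = []
    for (chrom, strand), grp in pooled.groupby(["chrom", "strand"], sort=True):
        g = grp.sort_values("pos")
        clusters.extend(
            paraclu_cluster(
                g["pos"].to_numpy(), g["count"].to_numpy(),
                min_tags=min_tags, min_density_fold=min_density_fold,
                max_length=max_length, chrom=chrom, strand=strand,
            )
        )
    return clusters


def enhancer_midpoint(iv: GenomicInterval) -> int:
    return (iv.start + iv.end) // 2


def select_bidirectional(enhancers, clusters, window: int = 400) -> list:
    """Enhancers flanked by tag clusters on both strands near their center.

    Keeps an enhancer iff at least one plus-strand and one minus-strand
    cluster each overlap [mid - window, mid + window).
    """
    kept = []
    by_strand = {"+": [], "-": []}
    for c in clusters:
        if c.strand in by_strand:
            by_strand[c.strand].append(c)
    for iv in enhancers:
        mid = enhancer_midpoint(iv)
        lo, hi = mid - window, mid + window
        ok = all(
            any(c.chrom == iv.chrom and c.start < hi and c.end > lo
                for c in by_strand[s])
            for s in ("+", "-")
        )
        if ok:
            kept.append(iv)
    return kept


def directionality_and_quantify(tag_streams, enhancers, flank: int = 200):
    """Window counts -> TPM -> RLE, directionality and per-sample activity.

    F is the plus-strand window [mid, mid + flank), R the minus-strand window
    [mid - flank, mid). Both windows of all enhancers are normalized jointly
    (TPM then RLE). The cohort directionality score uses the across-sample
    sums of normalized window expression, D = (F - R) / (F + R); per-sample
    activity is F_s + R_s. Enhancers with F + R = 0 have undefined D and are
    dropped (logged).

    Returns (quant table with enhancer_id/midpoint/F/R/D, activity matrix).
    """
    f_windows, r_windows = [], []
    mids = {}
    for iv in enhancers:
        mid = enhancer_midpoint(iv)
        mids[iv.feature_id] = mid
        f_windows.append(GenomicInterval(iv.chrom, mid, mid + flank, "+",
                                         iv.feature_id + "::F"))
        r_windows.append(GenomicInterval(iv.chrom, mid - flank, mid, "-",
                                         iv.feature_id + "::R"))
    raw = aggregate_tags_to_features(tag_streams, f_windows + r_windows,
                                     strand_rule="same-strand")
    lib = pd.Series({ts.sample_id: ts.library_size for ts in tag_streams})
    tpm = tpm_normalize(raw, lib)
    norm, _ = rle_normalize(tpm)
    ids = [iv.feature_id for iv in enhancers]
    f_norm = norm.loc[[i + "::F" for i in ids]].to_numpy()
    r_norm = norm.loc[[i + "::R" for i in ids]].to_numpy()
    f_tot = f_norm.sum(axis=1)
    r_tot = r_norm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (f_tot - r_tot) / (f_tot + r_tot)
    quant = pd.DataFrame({
        "enhancer_id": ids,
        "midpoint": [mids[i] for i in ids],
        "F": f_tot,
        "R": r_tot,
        "D": d,
    })
    n_undef = int(quant["D"].isna().sum())
    if n_undef:
        logger.info("directionality: dropped %d enhancers with F + R = 0", n_undef)
    quant = quant.dropna(subset=["D"]).reset_index(drop=True)
    activity = pd.DataFrame(
        f_norm + r_norm, index=pd.Index(ids, name="feature_id"),
        columns=norm.columns,
    ).loc[quant["enhancer_id"]]
    return quant, activity


def build_enhancer_matrix(quant: pd.DataFrame, activity: pd.DataFrame,
                          d_max: float = 0.8,
                          max_null_fraction: float = 50 / 154):
    """Filter on |D| and on the fraction of zero-activity samples.

    The default null-expression cutoff mirrors an absolute cutoff of 50
    individuals in a cohort of 154. Returns (kept quant, activity matrix).
    """
    n_samples = activity.shape[1]
    max_null = max_null_fraction * n_samples
    keep_d = quant["D"].abs() < d_max
    null_counts = (activity.loc[quant["enhancer_id"]] == 0).sum(axis=1).to_numpy()
    keep_null = null_counts <= max_null
    keep = keep_d.to_numpy() & keep_null
    logger.info(
        "enhancer matrix: %d kept, %d failed |D| < %g, %d failed null-expression cutoff",
        int(keep.sum()), int((~keep_d).sum()), d_max,
        int((keep_d.to_numpy() & ~keep_null).sum()),
    )
    kept_quant = quant.loc[keep].reset_index(drop=True)
    if len(kept_quant) == 0:
        raise ValueError("no enhancer passed the directionality/expression filters")
    return kept_quant, activity.loc[kept_quant["enhancer_id"]]
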