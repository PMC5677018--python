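"""Cross-phenotype statistics: replication, colocalization and causality.

Connects the promoter-usage and enhancer-activity QTL maps with each other,
with a total-mRNA eQTL pass, with GWAS hits, and with functional annotations:

* pi1 (1 - Storey's pi0): the fraction of one QTL set replicating in another
  phenotype's nominal p-values;
* LD statistics (dosage r^2 and Spearman rho) between lead variants;
* RTC: rank-based concordance between a QTL and a GWAS hit sharing an
  interval (residualize the phenotype on each interval variant in turn and
  rank how strongly the GWAS variant's correction extinguishes the QTL
  association; RTC = (N - rank)/N, > 0.9 is high confidence);
* matched-permutation GWAS overlap enrichment (MAF and TSS-distance matched
  null variants);
* causal inference testing for (variant, enhancer, promoter) triplets with
  four component tests per direction and omnibus p = max component p;
* the four-step hierarchical TSS annotation;
* permutation overlap enrichment of QTLs within functional annotations,
  against the landscape of all tested phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cis_qtl import qvalue, residualize, storey_pi0
from .io import GenotypeMatrix, IntervalIndex

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pi1 replication


def pi1(pvalues, lambda_grid=None, n_bootstrap: int = 100, seed: int = 0) -> dict:
    """Proportion of truly alternative tests, pi1 = 1 - pi0.

    Returns pi0, pi1, a bootstrap standard error over ``n_bootstrap``
    resamples, and the number of tests. Warns below 100 tests (unstable).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 100:
        logger.warning("pi1 on %d tests; estimate is unstable", p.size)
    pi0 = storey_pi0(p, lambda_grid)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        res = rng.choice(p, size=p.size, replace=True)
        boots.append(1.0 - storey_pi0(res, lambda_grid))
    return {
        "m": int(p.size),
        "pi0": float(pi0),
        "pi1": float(1.0 - pi0),
        "pi1_se": float(np.std(boots, ddof=1)) if n_bootstrap > 1 else np.nan,
    }


# ---------------------------------------------------------------------------
# LD


def ld_stats(genotypes: GenotypeMatrix, v1: str, v2: str) -> tuple:
    """(r^2, Spearman rho) between two variants' dosages on shared samples."""
    g1 = genotypes.dosage_of(v1)
    g2 = genotypes.dosage_of(v2)
    if np.std(g1) == 0 or np.std(g2) == 0:
        raise ValueError("LD undefined for a monomorphic variant")
    r = np.corrcoef(g1, g2)[0, 1]
    rho = stats.spearmanr(g1, g2).statistic
    return float(r * r), float(rho)


# ---------------------------------------------------------------------------
# RTC


@dataclass
class RtcResult:
    gwas_variant: str
    qtl_variant: str
    interval_id: str
    n_variants: int
    rank: int
    rtc: float

    @property
    def high_confidence(self) -> bool:
        return self.rtc > 0.9


def rtc(phenotype, genotypes: GenotypeMatrix, gwas_variant: str,
        qtl_variant: str, interval) -> RtcResult:
    """Regulatory trait concordance of a QTL and a GWAS hit in one interval.

    ``phenotype`` must already be covariate-residualized. For each of the N
    interval variants the phenotype is residualized on that variant's dosage
    and the QTL variant is re-tested against the residuals; the corrected
    p-values are ranked descending (rank 0 = the correction that most destroys
    the QTL signal, ties broken by genomic position) and
    RTC = (N - rank_of_gwas_variant) / N. Concordant (shared-signal) pairs
    give RTC near 1.
    """
    y = np.asarray(phenotype, dtype=float)
    v = genotypes.variants
    mask = (
        (v["chrom"] == interval.chrom)
        & (v["pos"] >= interval.start)
        & (v["pos"] < interval.end)
    ).to_numpy()
    idx = np.flatnonzero(mask)
    n_var = len(idx)
    if n_var < 2:
        raise ValueError("RTC needs at least 2 variants in the interval")
    ids = v["id"].to_numpy()[idx]
    pos = v["pos"].to_numpy()[idx]
    if gwas_variant not in ids or qtl_variant not in ids:
        raise ValueError("both variants must lie inside the interval")
    gq = genotypes.dosage_of(qtl_variant)
    gq = gq - gq.mean()
    gq_norm = np.linalg.norm(gq)
    n = len(y)
    corrected_p = np.empty(n_var)
    for k, j in enumerate(idx):
        resid = residualize(y, genotypes.dosages[:, j])
        rs = resid - resid.mean()
        denom = np.linalg.norm(rs) * gq_norm
        r = float(rs @ gq / denom) if denom > 0 else 0.0
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t2 = (n - 3) * r * r / (1 - r * r)
        corrected_p[k] = stats.f.sf(t2, 1, n - 3)
    # rank 0 = largest corrected p (association most destroyed)
    order = np.lexsort((pos, -corrected_p))
    rank = int(np.flatnonzero(ids[order] == gwas_variant)[0])
    return RtcResult(gwas_variant, qtl_variant, interval.feature_id, n_var,
                     rank, (n_var - rank) / n_var)


# ---------------------------------------------------------------------------
# enrichment helpers


@dataclass
class EnrichmentResult:
    observed: int
    n_qtls: int
    perm_mean: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n_perm: int


def _odds(count, total):
    count = np.clip(count, 0.5, total - 0.5)  # Haldane correction at the edges
    return count / (total - count)


def _enrichment_from_counts(observed: int, perm_counts, total: int) -> EnrichmentResult:
    perm_counts = np.asarray(perm_counts, dtype=float)
    n_perm = len(perm_counts)
    or_point = _odds(observed, total) / _odds(perm_counts.mean(), total)
    or_per_perm = _odds(observed, total) / _odds(perm_counts, total)
    ci_low, ci_high = np.percentile(or_per_perm, [2.5, 97.5])
    p = (1 + int((perm_counts >= observed).sum())) / (1 + n_perm)
    return EnrichmentResult(int(observed), int(total), float(perm_counts.mean()),
                            float(or_point), float(ci_low), float(ci_high),
                            float(p), n_perm)


def _bin_indices(values, n_bins, log_spaced=False):
    v = np.asarray(values, dtype=float)
    if log_spaced:
        v = np.log10(np.abs(v) + 1.0)
    edges = np.quantile(v, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    return np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(edges) - 2)


def gwas_overlap_enrichment(
    qtl_variant_ids,
    gwas_catalog: pd.DataFrame,
    genotypes: GenotypeMatrix,
    tss_positions,
    flank: int = 500_000,
    r2_min: float = 0.5,
    n_perm: int = 1000,
    n_maf_bins: int = 10,
    n_dist_bins: int = 10,
    seed: int = 0,
) -> EnrichmentResult:
    """Overlap of QTL variants with GWAS hits versus a matched null.

    A QTL variant overlaps if it is itself in the catalog or lies within
    +/- ``flank`` of a catalog variant with dosage r^2 > ``r2_min``. The null
    redraws, for each QTL variant, a random non-QTL variant from the same MAF
    decile and TSS-distance bin (log-spaced); empty matched bins are widened
    to the MAF bin alone, then to all non-QTL variants (logged).
    """
    rng = np.random.default_rng(seed)
    v = genotypes.variants
    var_ids = v["id"].to_numpy()
    var_pos = v["pos"].to_numpy()
    var_chrom = v["chrom"].to_numpy()
    tss = np.sort(np.asarray(tss_positions))
    j = np.clip(np.searchsorted(tss, var_pos), 1, len(tss) - 1)
    dist_tss = np.minimum(np.abs(var_pos - tss[j - 1]), np.abs(var_pos - tss[j]))
    maf_bin = _bin_indices(v["maf"].to_numpy(), n_maf_bins)
    dist_bin = _bin_indices(dist_tss, n_dist_bins, log_spaced=True)

    gwas_ids = set(gwas_catalog["variant_id"])
    gwas_pos = gwas_catalog["pos"].to_numpy()
    gwas_chrom = gwas_catalog["chrom"].to_numpy()
    gwas_order = np.argsort(gwas_pos)
    dos = genotypes.dosages
    dos_c = dos - dos.mean(axis=0)
    dos_n = np.linalg.norm(dos_c, axis=0)
    id_to_col = {vid: k for k, vid in enumerate(var_ids)}
    gwas_cols = np.array([id_to_col[g] for g in gwas_catalog["variant_id"]
                          if g in id_to_col])

    def overlaps(col: int) -> bool:
        if var_ids[col] in gwas_ids:
            return True
        p0, c0 = var_pos[col], var_chrom[col]
        lo = np.searchsorted(gwas_pos[gwas_order], p0 - flank)
        hi = np.searchsorted(gwas_pos[gwas_order], p0 + flank, side="right")
        for g_idx in gwas_order[lo:hi]:
            if gwas_chrom[g_idx] != c0:
                continue
            gcol = id_to_col.get(gwas_catalog.iloc[g_idx]["variant_id"])
            if gcol is None or dos_n[gcol] == 0 or dos_n[col] == 0:
                continue
            r = dos_c[:, col] @ dos_c[:, gcol] / (dos_n[col] * dos_n[gcol])
            if r * r > r2_min:
                return True
        return False

    qtl_cols = np.array([id_to_col[q] for q in qtl_variant_ids if q in id_to_col])
    observed = sum(overlaps(c) for c in qtl_cols)

    qtl_set = set(qtl_cols.tolist())
    pool = {}
    for c in range(len(var_ids)):
        if c in qtl_set:
            continue
        pool.setdefault((maf_bin[c], dist_bin[c]), []).append(c)
    pool_maf = {}
    for c in range(len(var_ids)):
        if c in qtl_set:
            continue
        pool_maf.setdefault(maf_bin[c], []).append(c)
    all_non_qtl = np.array([c for c in range(len(var_ids)) if c not in qtl_set])
    overlap_cache = {}

    def cached_overlap(c):
        if c not in overlap_cache:
            overlap_cache[c] = overlaps(c)
        return overlap_cache[c]

    n_widened = 0
    perm_counts = np.zeros(n_perm, dtype=int)
    draws = {}
    for c in qtl_cols:
        key = (maf_bin[c], dist_bin[c])
        cand = pool.get(key)
        if not cand:
            n_widened += 1
            cand = pool_maf.get(maf_bin[c]) or all_non_qtl.tolist()
        draws[c] = rng.choice(cand, size=n_perm, replace=True)
    if n_widened:
        logger.info("gwas_overlap_enrichment: widened matched bins for %d variants",
                    n_widened)
    for k in range(n_perm):
        perm_counts[k] = sum(cached_overlap(int(draws[c][k])) for c in qtl_cols)
    return _enrichment_from_counts(observed, perm_counts, len(qtl_cols))


def feature_enrichment(
    qtls: pd.DataFrame,
    annotation_intervals,
    landscape: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Do QTLs fall inside functional annotations more often than chance?

    ``qtls`` needs columns chrom, pos, anchor_pos (the tested phenotype's
    anchor); ``landscape`` (columns chrom, pos) holds the anchors of all
    tested phenotypes. Each permutation keeps every QTL's signed offset to its
    anchor but re-draws the anchor uniformly from the landscape.
    """
    rng = np.random.default_rng(seed)
    index = IntervalIndex(annotation_intervals)
    offsets = (qtls["pos"] - qtls["anchor_pos"]).to_numpy()
    observed = sum(
        bool(index.query_point(c, int(p)))
        for c, p in zip(qtls["chrom"], qtls["pos"])
    )
    land_chrom = landscape["chrom"].to_numpy()
    land_pos = landscape["pos"].to_numpy()
    n_q = len(qtls)
    perm_counts = np.zeros(n_perm, dtype=int)
    for k in range(n_perm):
        picks = rng.integers(0, len(land_pos), size=n_q)
        perm_counts[k] = sum(
            bool(index.query_point(land_chrom[i], int(land_pos[i] + off)))
            for i, off in zip(picks, offsets)
        )
    return _enrichment_from_counts(observed, perm_counts, n_q)


# ---------------------------------------------------------------------------
# causal inference test


def _f_added(y, base, added, n_cov_extra: int = 0):
    """F statistic and p for adding one regressor to an OLS model."""
    n = len(y)
    X0 = np.column_stack([np.ones(n)] + ([base] if base is not None else []))
    X1 = np.column_stack([X0, added])
    b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ b0) ** 2))
    rss1 = float(np.sum((y - X1 @ b1) ** 2))
    df2 = n - X1.shape[1] - n_cov_extra
    if df2 < 1 or rss1 <= 0:
        return np.inf, 0.0, 1, df2
    f = (rss0 - rss1) / (rss1 / df2)
    return f, float(stats.f.sf(f, 1, df2)), 1, df2


def _cit_one_direction(L, M, T, n_perm: int, rng, covariates=None) -> dict:
    """Component tests for 'M mediates the effect of L on T'."""
    n_cov = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        n_cov = C.shape[1]
        L, M, T = (residualize(x, C) for x in (L, M, T))
    _, p1, _, _ = _f_added(T, None, L, 0)
    _, p2, _, _ = _f_added(M, T, L, 0)
    _, p3, _, _ = _f_added(T, L, M, 0)

    # component 4: equivalence test of conditional independence L _||_ T | M.
    # The no-mediation reference distribution preserves the L-M association but
    # severs any M-T link beyond L: M* = fitted(M ~ L) + permuted residuals.
    f_obs, _, df1, df2 = _f_added(T, M, L, 0)
    n = len(L)
    XL = np.column_stack([np.ones(n), L])
    bM, *_ = np.linalg.lstsq(XL, M, rcond=None)
    fitted = XL @ bM
    resid_M = M - fitted
    f_perm = np.empty(n_perm)
    for k in range(n_perm):
        m_star = fitted + rng.permutation(resid_M)
        f_perm[k], _, _, _ = _f_added(T, m_star, L, 0)
    # method-of-moments noncentrality from the permuted F's
    mean_f = float(np.mean(f_perm))
    ncp = max(0.0, mean_f * df1 * (df2 - 2) / df2 - df1)
    if ncp > 0:
        p4 = float(stats.ncf.cdf(f_obs, df1, df2, ncp))
    else:
        p4 = float(stats.f.cdf(f_obs, df1, df2))
    ps = {"p1": p1, "p2": p2, "p3": p3, "p4": p4}
    ps["omnibus"] = max(ps.values())
    ps["n_cov"] = n_cov
    return ps


def cit_test(L, M, T, covariates=None, n_perm: int = 500, seed: int = 0) -> dict:
    """Causal inference test for a (variant, mediator, outcome) triplet.

    Four component tests for 'M mediates L -> T': (1) T associated with L;
    (2) M associated with L given T; (3) T associated with M given L;
    (4) equivalence test that L is independent of T given M, with a
    permutation-derived noncentral-F reference under no mediation. The
    omnibus p is the maximum component p; the test is run in both causal
    directions (mediator and outcome swapped).
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    T = np.asarray(T, dtype=float)
    for name, x in (("L", L), ("M", M), ("T", T)):
        if np.std(x) == 0:
            raise ValueError(f"{name} has zero variance")
    mask = np.isfinite(L) & np.isfinite(M) & np.isfinite(T)
    L, M, T = L[mask], M[mask], T[mask]
    # both directions draw the same permutation stream, so relabeling
    # (M, T) -> (T, M) swaps the two directional results exactly
    rng_f = np.random.default_rng(np.random.SeedSequence([seed % 2**31]))
    rng_r = np.random.default_rng(np.random.SeedSequence([seed % 2**31]))
    forward = _cit_one_direction(L, M, T, n_perm, rng_f, covariates)
    reverse = _cit_one_direction(L, T, M, n_perm, rng_r, covariates)
    return {"forward": forward, "reverse": reverse, "n": int(mask.sum())}


# ---------------------------------------------------------------------------
# triplets


def build_triplets(
    eaqtls: pd.DataFrame,
    pairing: pd.DataFrame,
    puqtls: pd.DataFrame,
    genotypes: GenotypeMatrix,
    rho_min: float = 0.8,
) -> pd.DataFrame:
    """(variant, enhancer, promoter) triplets from eaQTLs and pairings.

    One triplet per eaQTL enhancer and each of its paired promoter peaks.
    A triplet is flagged 'shared' when the eaQTL variant is itself a puQTL
    variant or in LD (|Spearman rho| > ``rho_min``) with one.
    """
    puqtl_variants = list(dict.fromkeys(puqtls["variant_id"])) if len(puqtls) else []
    rows = []
    pairs_by_enh = pairing.groupby("enhancer_id")["peak_id"].agg(list).to_dict()
    for qtl in eaqtls.itertuples(index=False):
        peaks = pairs_by_enh.get(qtl.phenotype_id, [])
        for peak_id in peaks:
            shared, best_rho, partner = False, 0.0, ""
            if qtl.variant_id in set(puqtl_variants):
                shared, best_rho, partner = True, 1.0, qtl.variant_id
            else:
                for pv in puqtl_variants:
                    try:
                        _, rho = ld_stats(genotypes, qtl.variant_id, pv)
                    except (KeyError, ValueError):
                        continue
                    if abs(rho) > abs(best_rho):
                        best_rho, partner = rho, pv
                shared = abs(best_rho) > rho_min
            rows.append({
                "variant_id": qtl.variant_id,
                "enhancer_id": qtl.phenotype_id,
                "promoter_id": peak_id,
                "shared_with_puqtl": bool(shared),
                "spearman_rho": float(best_rho),
                "puqtl_partner": partner,
            })
    return pd.DataFrame(rows, columns=["variant_id", "enhancer_id", "promoter_id",
                                       "shared_with_puqtl", "spearman_rho",
                                       "puqtl_partner"])


def test_triplets(
    triplets: pd.DataFrame,
    enhancer_activity: pd.DataFrame,
    promoter_expression: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates=None,
    n_perm: int = 500,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """CIT on every triplet; FDR-adjusted causal calls per direction.

    'forward' tests enhancer activity as the mediator of promoter expression;
    'reverse' the converse. Calls use Storey q-values over the omnibus p's.
    """
    rows = []
    for i, t in enumerate(triplets.itertuples(index=False)):
        L = genotypes.dosage_of(t.variant_id)
        M = enhancer_activity.loc[t.enhancer_id].to_numpy(dtype=float)
        T = promoter_expression.loc[t.promoter_id].to_numpy(dtype=float)
        res = cit_test(L, M, T, covariates=covariates, n_perm=n_perm,
                       seed=seed + i)
        row = {"variant_id": t.variant_id, "enhancer_id": t.enhancer_id,
               "promoter_id": t.promoter_id}
        for d in ("forward", "reverse"):
            for k in ("p1", "p2", "p3", "p4", "omnibus"):
                row[f"{d}_{k}"] = res[d][k]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        for d in ("forward", "reverse"):
            _, q = qvalue(out[f"{d}_omnibus"].to_numpy(),
                          lambda_grid=np.array([0.5]))
            out[f"{d}_q"] = q
            out[f"{d}_causal"] = out[f"{d}_q"] < fdr
    return out


# ---------------------------------------------------------------------------
# TSS annotation


def annotate_tss(cage_peaks, transcripts, segments) -> pd.DataFrame:
    """Hierarchical annotation of CAGE peaks.

    1. 'Annotated gene': the peak's stranded 5' end lies within 500 nt
       upstream of an annotated TSS on the same strand, or inside a 5'-UTR
       first exon or first intron of a same-strand transcript.
    2. Otherwise, by chromatin segment at the peak: 'eRNA/enhancer' for
       enhancer states; promoter states go to step 3; anything else 'other'.
    3. Promoter-state peaks overlapping a gene body on the opposite strand
       are 'Antisense promoter'; the rest are 'Putative promoter', recorded
       as intragenic or intergenic.
    """
    tss_list = [t for t in transcripts if t.attributes.get("kind") == "tss"]
    utr = [t for t in transcripts
           if t.attributes.get("kind") in ("utr5_exon", "utr5_intron")]
    bodies = [t for t in transcripts if t.attributes.get("kind") == "gene_body"]
    utr_index = IntervalIndex(utr)
    body_index = IntervalIndex(bodies)
    seg_index = IntervalIndex(segments)

    upstream = []
    for t in tss_list:
        pos = t.start if t.strand == "+" else t.end - 1
        if t.strand == "+":
            iv = (t.chrom, pos - 500, pos + 1, "+")
        else:
            iv = (t.chrom, pos, pos + 501, "-")
        upstream.append(iv)

    rows = []
    for p in cage_peaks:
        pos5 = p.start if p.strand == "+" else p.end - 1
        label, localization = None, "."
        for chrom, lo, hi, strand in upstream:
            if chrom == p.chrom and lo <= pos5 < hi and strand == p.strand:
                label = "Annotated gene"
                break
        if label is None:
            for k in utr_index.query_point(p.chrom, pos5):
                if utr[k].strand == p.strand:
                    label = "Annotated gene"
                    break
        if label is None:
            states = {segments[k].attributes.get("state")
                      for k in seg_index.query_point(p.chrom, pos5)}
            if "enhancer" in states:
                label = "eRNA/enhancer"
            elif "promoter" in states:
                hits = body_index.query_point(p.chrom, pos5)
                antisense = any(bodies[k].strand not in (p.strand, ".")
                                for k in hits)
                if antisense:
                    label = "Antisense promoter"
                else:
                    label = "Putative promoter"
                    localization = "intragenic" if hits else "intergenic"
            else:
                label = "other"
        rows.append({"peak_id": p.feature_id, "label": label,
                     "localization": localization})
    return pd.DataFrame(rows)
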