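"""Calibration experiments: operating characteristics on planted truth.

Each function runs a self-contained simulation-plus-analysis experiment and
returns summary statistics (realized false discovery proportion, power, slope
error, pi1 recovery, RTC separation, causal-test error rates, enhancer filter
sensitivity/specificity). They are the package's own validation instruments;
the problem sizes default to the study's sample size (n = 150) with feature
counts chosen to keep each experiment in the minutes range on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cis_qtl, enhancers, integration, promoter_groups
from .io import GenomicInterval
from .synthetic import (
    SimulationConfig,
    simulate_cage_tags,
    simulate_dataset,
    simulate_genotypes,
    simulate_mediation_triplet,
    simulate_qtl_phenotypes,
)


def _tads_for(config: SimulationConfig):
    return [
        GenomicInterval("chr1", t * config.tad_span, (t + 1) * config.tad_span,
                        ".", f"tad{t:04d}")
        for t in range(config.n_tads)
    ]


def fdp_power_experiment(
    n_samples: int = 150,
    n_phenotypes: int = 200,
    frac_alt: float = 0.1,
    slope_range: tuple = (0.5, 1.0),
    n_perm: int = 1000,
    n_replicates: int = 10,
    fdr: float = 0.05,
    seed: int = 0,
    n_variants: int = 2000,
) -> dict:
    """Realized FDP and power of the cis mapping pass at 5% FDR.

    Phenotypes are Gaussian with planted standardized per-allele slopes for a
    ``frac_alt`` fraction; windows hold ~50 variants each. Power is reported
    overall and for planted slopes >= 0.7.
    """
    cfg = SimulationConfig(
        n_samples=n_samples, n_variants=n_variants, ld_block_span=2_000,
        n_genes=80, n_enhancers=20, tad_span=200_000, seed=seed,
    )
    genotypes = simulate_genotypes(cfg)
    tads = _tads_for(cfg)
    fdps, powers, powers_strong = [], [], []
    for rep in range(n_replicates):
        phen, anchors, truth = simulate_qtl_phenotypes(
            genotypes, n_phenotypes, frac_alt, slope_range,
            seed=seed * 1000 + rep + 1,
        )
        res = cis_qtl.map_cis(phen, anchors, genotypes, tads,
                              n_perm=n_perm, mode="beta",
                              seed=seed * 1000 + rep + 1, fdr=fdr)
        sig = cis_qtl.call_significant(res, fdr)
        merged = sig.merge(truth, on="phenotype_id")
        n_disc = len(merged)
        n_false = int((~merged["is_alt"]).sum())
        fdps.append(n_false / n_disc if n_disc else 0.0)
        alts = truth[truth["is_alt"]]
        found = set(sig["phenotype_id"])
        powers.append(np.mean([pid in found for pid in alts["phenotype_id"]]))
        strong = alts[alts["true_slope"].abs() >= 0.7]
        if len(strong):
            powers_strong.append(
                np.mean([pid in found for pid in strong["phenotype_id"]]))
    return {
        "mean_fdp": float(np.mean(fdps)),
        "power": float(np.mean(powers)),
        "power_slope_ge_0.7": float(np.mean(powers_strong)),
        "n_replicates": n_replicates,
    }


def slope_recovery_experiment(
    n_samples: int = 150,
    slope: float = 0.5,
    n_phenotypes: int = 10,
    n_replicates: int = 50,
    seed: int = 0,
) -> dict:
    """Mean absolute error of the mapper's slope estimate at the causal variant.

    Variants are unlinked (single-variant LD blocks) with MAF >= 0.3 so the
    error reflects estimation noise, not LD attenuation.
    """
    cfg = SimulationConfig(
        n_samples=n_samples, n_variants=500, ld_block_span=1,
        n_genes=40, n_enhancers=10, tad_span=200_000,
        maf_range=(0.3, 0.5), seed=seed,
    )
    genotypes = simulate_genotypes(cfg)
    errors = []
    for rep in range(n_replicates):
        phen, anchors, truth = simulate_qtl_phenotypes(
            genotypes, n_phenotypes, 1.0, (slope, slope),
            seed=seed * 1000 + rep + 1, min_maf=0.3,
        )
        for row in truth.itertuples(index=False):
            y = phen.loc[row.phenotype_id].to_numpy()
            resid = cis_qtl.residualize(y, None)
            scan, _ = cis_qtl.nominal_scan(
                resid, genotypes.dosage_of(row.variant_id))
            errors.append(abs(float(scan["beta"][0]) - row.true_slope))
    return {
        "mae": float(np.mean(errors)),
        "n_estimates": len(errors),
        "planted_slope": slope,
    }


def pi1_recovery_experiment(
    true_pi1_grid=(0.0, 0.2, 0.5, 0.8),
    m: int = 5000,
    n_samples: int = 150,
    slope_range: tuple = (0.5, 1.0),
    n_replicates: int = 10,
    seed: int = 0,
) -> dict:
    """pi1 estimates across a grid of true alternative fractions.

    Null p-values come from regressions of pure-noise phenotypes on dosage;
    alternative p-values from phenotypes with planted slopes, so the
    alternative distribution matches the planted-QTL one. The estimate per
    grid point averages ``n_replicates`` independent cohorts of m tests.
    """
    from scipy import stats

    out = {}
    for true_pi1 in true_pi1_grid:
        estimates = []
        for rep in range(n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed % 2**31, int(true_pi1 * 10), rep]))
            maf = rng.uniform(0.2, 0.5, size=m)
            g = rng.binomial(2, maf[None, :].repeat(n_samples, 0))
            n_alt = int(round(true_pi1 * m))
            slopes = np.zeros(m)
            slopes[:n_alt] = rng.uniform(*slope_range, size=n_alt)
            y = slopes[None, :] * g + rng.normal(size=(n_samples, m))
            gc = g - g.mean(axis=0)
            yc = y - y.mean(axis=0)
            num = (gc * yc).sum(axis=0)
            denom = np.linalg.norm(gc, axis=0) * np.linalg.norm(yc, axis=0)
            r = num / denom
            dof = n_samples - 2
            t2 = dof * r * r / (1 - r * r)
            pvals = stats.f.sf(t2, 1, dof)
            est = integration.pi1(pvals, n_bootstrap=0, seed=seed)
            estimates.append(est["pi1"])
        pi1_hat = float(np.mean(estimates))
        out[float(true_pi1)] = {
            "pi1_hat": pi1_hat,
            "abs_error": abs(pi1_hat - true_pi1),
        }
    out["max_abs_error"] = max(v["abs_error"] for k, v in out.items()
                               if isinstance(k, float))
    return out


def rtc_separation_experiment(
    n_sims: int = 50,
    n_samples: int = 150,
    n_variants: int = 60,
    slope: float = 0.8,
    seed: int = 0,
) -> dict:
    """Median RTC for shared versus independent QTL/GWAS signals.

    The interval holds two LD blocks with realistic within-block LD decay.
    The causal QTL variant sits in block A; the 'shared' GWAS variant is a
    nearby block-A variant (tagging the same signal), the 'independent' one a
    block-B variant. With LD around the causal variant, correcting for any
    of its LD partners erodes the QTL signal, so an unlinked GWAS variant
    ranks low and an LD partner ranks near the top.
    """
    shared_scores, indep_scores = [], []
    for sim in range(n_sims):
        cfg = SimulationConfig(
            n_samples=n_samples, n_variants=n_variants,
            ld_block_span=250_000, tad_span=250_000, features_per_tad=5,
            n_genes=8, n_enhancers=2, maf_range=(0.2, 0.5),
            ld_switch_prob=0.02, seed=seed + 17 * sim + 1,
        )
        genotypes = simulate_genotypes(cfg)
        v = genotypes.variants
        blocks = (v["pos"] // cfg.ld_block_span).to_numpy()
        rng = np.random.default_rng(seed + sim)
        block_a = blocks == blocks[0]
        in_a = np.flatnonzero(block_a)
        in_b = np.flatnonzero(~block_a)
        if len(in_a) < 8 or len(in_b) < 3:
            continue
        qtl_col = int(in_a[len(in_a) // 2])
        shared_col = int(in_a[len(in_a) // 2 + 2])
        far_col = int(rng.choice(in_b))
        y = slope * genotypes.dosages[:, qtl_col] + rng.normal(size=n_samples)
        interval = GenomicInterval("chr1", 0, int(v["pos"].max()) + 1, ".", "iv")
        qtl_id = v.iloc[qtl_col]["id"]
        res_s = integration.rtc(y, genotypes, v.iloc[shared_col]["id"], qtl_id,
                                interval)
        res_i = integration.rtc(y, genotypes, v.iloc[far_col]["id"], qtl_id,
                                interval)
        shared_scores.append(res_s.rtc)
        indep_scores.append(res_i.rtc)
    return {
        "median_rtc_shared": float(np.median(shared_scores)),
        "median_rtc_independent": float(np.median(indep_scores)),
        "n_sims": len(shared_scores),
    }


def cit_operating_characteristics(
    n_replicates: int = 100,
    n_samples: int = 150,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power and false-positive rates of the causal inference test.

    Strong mediation chains L -> M -> T (unit effects) should be called in the
    causal direction; the reverse direction and the independent topology
    (L -> M, L -> T separately) should stay non-significant at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    chain_fwd, chain_rev, indep_any = [], [], []
    for rep in range(n_replicates):
        g = rng.binomial(2, 0.3, size=n_samples)
        while np.std(g) == 0:
            g = rng.binomial(2, 0.3, size=n_samples)
        L, M, T = simulate_mediation_triplet(g, "chain", rng=rng)
        res = integration.cit_test(L, M, T, n_perm=n_perm, seed=seed + rep)
        chain_fwd.append(res["forward"]["omnibus"] < alpha)
        chain_rev.append(res["reverse"]["omnibus"] < alpha)
        L2, M2, T2 = simulate_mediation_triplet(g, "independent", rng=rng)
        res2 = integration.cit_test(L2, M2, T2, n_perm=n_perm,
                                    seed=seed + 10_000 + rep)
        indep_any.append(res2["forward"]["omnibus"] < alpha
                         or res2["reverse"]["omnibus"] < alpha)
    return {
        "power_causal_direction": float(np.mean(chain_fwd)),
        "fpr_reverse_direction": float(np.mean(chain_rev)),
        "fpr_independent_topology": float(np.mean(indep_any)),
        "n_replicates": n_replicates,
    }


def enhancer_filter_experiment(n_replicates: int = 5, seed: int = 0,
                               n_samples: int = 60) -> dict:
    """Sensitivity/specificity of the bidirectionality and |D| filters.

    Fraction of planted bidirectional enhancers surviving selection and of
    planted unidirectional (promoter-like) elements rejected, per replicate.
    """
    passed_bidir, rejected_unidir = [], []
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_samples=n_samples, n_variants=400, n_genes=10, n_enhancers=40,
            tad_span=300_000, depth_mean=4e6, depth_sd=5e5,
            seed=seed + 101 * rep,
        )
        genotypes = simulate_genotypes(cfg)
        from .synthetic import generate_effect_table, simulate_annotation

        annotation = simulate_annotation(cfg)
        effects, pairing = generate_effect_table(cfg, genotypes, annotation)
        annotation.pairing = pairing
        streams, _ = simulate_cage_tags(genotypes, annotation, cfg, effects)
        stream_list = list(streams.values())
        clusters = enhancers.cluster_pooled_ctss(stream_list)
        selected = enhancers.select_bidirectional(annotation.enhancers, clusters)
        quant, activity = enhancers.directionality_and_quantify(
            stream_list, annotation.enhancers)
        kept, _ = enhancers.build_enhancer_matrix(quant, activity)
        kept_ids = set(kept["enhancer_id"]) & {
            iv.feature_id for iv in selected}
        classes = {iv.feature_id: iv.attributes["class"]
                   for iv in annotation.enhancers}
        bidir = [fid for fid, c in classes.items() if c == "bidirectional"]
        unidir = [fid for fid, c in classes.items() if c == "unidirectional"]
        passed_bidir.append(np.mean([fid in kept_ids for fid in bidir]))
        rejected_unidir.append(np.mean([fid not in kept_ids for fid in unidir]))
    return {
        "frac_bidirectional_kept": float(np.mean(passed_bidir)),
        "frac_unidirectional_rejected": float(np.mean(rejected_unidir)),
        "n_replicates": n_replicates,
    }


def classifier_recovery_experiment(seed: int = 0, n_samples: int = 150,
                                   n_perm: int = 300) -> dict:
    """Fraction of genes with well-separated planted effects whose five-group
    label is recovered by the full map-then-classify pass."""
    cfg = SimulationConfig(
        n_samples=n_samples, n_variants=4000, n_genes=120, n_enhancers=10,
        tad_span=300_000, depth_mean=8e6, depth_sd=1e6, seed=seed,
        frac_gene_qtl=0.6,
    )
    ds = simulate_dataset(cfg)
    from .io import aggregate_tags_to_features
    from .normalization import normalize_counts, rank_inverse_normal

    streams = list(ds.tag_streams.values())
    raw = aggregate_tags_to_features(streams, ds.annotation.peaks, "same-strand")
    lib = pd.Series({ts.sample_id: ts.library_size for ts in streams})
    expr, _, _, _ = normalize_counts(raw, lib)
    phen = rank_inverse_normal(expr)
    anchors = pd.DataFrame([
        {"phenotype_id": p.feature_id, "chrom": p.chrom,
         "pos": p.start if p.strand == "+" else p.end - 1}
        for p in ds.annotation.peaks if p.feature_id in set(expr.index)
    ])
    res = cis_qtl.map_cis(phen, anchors, ds.genotypes, ds.annotation.tads,
                          n_perm=n_perm, mode="beta", seed=seed)
    sig = cis_qtl.call_significant(res)
    peak_table = pd.DataFrame([
        {"peak_id": p.feature_id, "gene_id": p.attributes["gene_id"],
         "position": p.start if p.strand == "+" else p.end - 1}
        for p in ds.annotation.peaks
    ])
    # per-peak slopes on the log scale so effect-size ratios are comparable
    groups = promoter_groups.classify_all(sig, peak_table, np.log(expr + 1.0),
                                          ds.genotypes)
    gene_of = {p.feature_id: p.attributes["gene_id"]
               for p in ds.annotation.peaks}
    truth_genes = (
        ds.truth[ds.truth["feature_id"].isin(gene_of)]
        .assign(gene_id=lambda d: d["feature_id"].map(gene_of))
        .groupby("gene_id")
        .agg(true_group=("true_group_label", "first"),
             min_abs_slope=("true_slope", lambda s: s.abs().min()))
    )
    merged = groups.merge(truth_genes, on="gene_id")
    well_sep = merged[merged["min_abs_slope"] >= 0.5]
    if len(well_sep) == 0:
        return {"recovery": float("nan"), "n_genes": 0}
    return {
        "recovery": float((well_sep["group"] == well_sep["true_group"]).mean()),
        "n_genes": int(len(well_sep)),
        "n_classified": int(len(groups)),
    }
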