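"""Synthetic cohort generator with planted regulatory effects.

Emulates the study design end to end so every pipeline stage can be tested
against known truth: LD-structured diploid genotypes for ~150 unrelated
samples, a TAD-partitioned genome carrying multi-promoter genes and
enhancers, negative-binomially dispersed CAGE tag counts with planted
allelic effects on promoter usage (including opposite-sign and
unequal-magnitude multi-promoter patterns) and on enhancer activity
(divergent two-strand tag production), plus a GWAS catalog containing
variants in LD with planted QTLs.

Counts follow a log-linear negative-binomial model: the expected tag count of
a feature is baseline_TPM * 1e-6 * depth_s * exp(slope * dosage), so planted
slopes are per-allele effects on log expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomicInterval, GenotypeMatrix, TagStream

DEFAULT_PROMOTER_DIST = {1: 0.40, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05, 6: 0.03, 7: 0.02}
MEDIATION_TOPOLOGIES = (
    "none",
    "variant->enhancer->promoter",
    "variant->promoter->enhancer",
    "independent",
)


@dataclass
class PlantedEffect:
    """One planted cis effect: a variant acting on one or more features."""

    variant_id: str
    targets: dict  # feature_id -> slope on the log-expression scale
    mediation: str = "none"

    def __post_init__(self):
        if self.mediation not in MEDIATION_TOPOLOGIES:
            raise ValueError(f"unknown mediation topology {self.mediation!r}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real design: 150 unrelated samples, sequencing depth
    16.2e6 +/- 4.3e6 mapped tags, TAD cis-windows, multi-promoter genes with
    peaks both closer and farther than 200 nt, planted per-allele log-scale
    slopes of 0.5-1.0.
    """

    n_samples: int = 150
    n_variants: int = 20_000
    ld_block_span: int = 20_000
    maf_range: tuple = (0.05, 0.5)
    n_genes: int = 400
    promoters_per_gene: dict = field(default_factory=lambda: dict(DEFAULT_PROMOTER_DIST))
    n_enhancers: int = 100
    tad_span: int = 500_000
    features_per_tad: int = 8
    depth_mean: float = 16.2e6
    depth_sd: float = 4.3e6
    dispersion: float = 0.05  # NB overdispersion (1/size); 0 -> Poisson
    ld_switch_prob: float = 0.15  # haplotype copy-with-mutation rate within a block
    frac_gene_qtl: float = 0.5
    frac_enhancer_qtl: float = 0.5
    frac_mediated: float = 0.3  # enhancer QTLs extended into mediation chains
    slope_range: tuple = (0.5, 1.0)
    effect_table: list | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("ld_block_span", "tad_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not math.isclose(sum(self.promoters_per_gene.values()), 1.0, rel_tol=1e-6):
            raise ValueError("promoters_per_gene probabilities must sum to 1")
        if any(k < 1 or k > 7 for k in self.promoters_per_gene):
            raise ValueError("promoters_per_gene supports 1..7 promoters")

    @property
    def n_tads(self) -> int:
        n_feat = self.n_genes + self.n_enhancers
        return max(1, math.ceil(n_feat / self.features_per_tad))

    @property
    def genome_length(self) -> int:
        return self.n_tads * self.tad_span

    def rng(self, stage: str) -> np.random.Generator:
        import zlib

        h = zlib.crc32(stage.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([int(self.seed) % (2**31), h]))


@dataclass
class AnnotationSet:
    """All simulated interval annotations plus the GWAS catalog and pairing."""

    tads: list
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end, tad_index
    peaks: list  # GenomicInterval, attrs gene_id / rank
    enhancers: list  # GenomicInterval, attrs class in {bidirectional, unidirectional, silent}
    transcripts: list  # GenomicInterval, attrs kind / gene_id
    segments: list  # GenomicInterval, attrs state
    gwas: pd.DataFrame  # variant_id, chrom, pos, trait
    pairing: pd.DataFrame  # enhancer_id, peak_id

    def peaks_of(self, gene_id: str) -> list:
        return [p for p in self.peaks if p.attributes["gene_id"] == gene_id]


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """LD-structured diploid dosages with the rare-variant filter applied.

    Variant positions are uniform over the genome; within each LD block of
    ``ld_block_span`` bases, haplotypes follow a copy-with-mutation chain
    (allele copied from the previous variant, redrawn from the block allele
    frequency with probability ``ld_switch_prob``), giving immediate-neighbor
    r^2 of about (1 - switch)^2. Variants with alternative-allele count < 10
    are excluded, as in the real genotype preprocessing.
    """
    rng = config.rng("genotypes")
    pos = np.sort(rng.choice(config.genome_length, size=config.n_variants, replace=False))
    block = pos // config.ld_block_span
    n_hap = 2 * config.n_samples
    lo, hi = config.maf_range
    hap = np.empty((n_hap, config.n_variants), dtype=np.int8)
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        p = rng.uniform(lo, hi)
        h = rng.random((n_hap, len(idx)))
        col = (h[:, 0] < p).astype(np.int8)
        hap[:, idx[0]] = col
        for k in range(1, len(idx)):
            redraw = rng.random(n_hap) < config.ld_switch_prob
            fresh = (h[:, k] < p).astype(np.int8)
            col = np.where(redraw, fresh, col)
            hap[:, idx[k]] = col
    dosage = hap[0::2] + hap[1::2]  # unphased dosages
    alt_count = dosage.sum(axis=0)
    keep = alt_count >= 10
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    freq = alt_count / (2 * config.n_samples)
    variants = pd.DataFrame({
        "id": [f"v{j:06d}" for j in range(config.n_variants)],
        "chrom": "chr1",
        "pos": pos,
        "ref": "A",
        "alt": "G",
        "maf": np.minimum(freq, 1 - freq),
        "alt_count": alt_count,
    })
    return GenotypeMatrix(
        sample_ids,
        variants.loc[keep].reset_index(drop=True),
        dosage[:, keep].astype(float),
    )


# ---------------------------------------------------------------------------
# annotations


def _promoter_units_from_positions(positions, max_gap: int = 200):
    """Single-linkage unit membership (list of index lists), sorted order."""
    units = [[0]]
    for i in range(1, len(positions)):
        if positions[i] - positions[i - 1] < max_gap:
            units[-1].append(i)
        else:
            units.append([i])
    return units


def simulate_annotation(config: SimulationConfig) -> AnnotationSet:
    """Genome layout: TADs, genes with CAGE peaks, enhancers, transcripts,
    chromatin segments, and a placeholder GWAS catalog (populated once effects
    are planted; see :func:`build_gwas_catalog`).

    Every feature falls inside exactly one TAD; multi-promoter genes draw
    inter-peak gaps from a mixture with both < 200 nt and >= 200 nt values
    (at least one >= 200 nt gap whenever a gene has several peaks, so multiple
    promoter units exist); enhancer midpoints sit >= 1 kb from any promoter.
    """
    rng = config.rng("annotation")
    margin = 10_000
    peak_width = 20
    ks = np.array(sorted(config.promoters_per_gene))
    probs = np.array([config.promoters_per_gene[k] for k in ks], dtype=float)
    max_gene_span = 7 * 800 + peak_width + 6_000  # peaks + transcript structures
    if config.tad_span <= max_gene_span + 2 * margin:
        raise ValueError("tad_span too small for the simulated gene span")

    tads = [
        GenomicInterval("chr1", t * config.tad_span, (t + 1) * config.tad_span,
                        ".", f"tad{t:04d}")
        for t in range(config.n_tads)
    ]

    n_feat = config.n_genes + config.n_enhancers
    feat_kind = np.array(["gene"] * config.n_genes + ["enh"] * config.n_enhancers)
    rng.shuffle(feat_kind)
    per_tad = math.ceil(n_feat / config.n_tads)
    slot_span = (config.tad_span - 2 * margin) // per_tad

    genes_rows, peaks, enhancers, transcripts, segments = [], [], [], [], []
    g_i = e_i = 0
    enh_classes = rng.choice(
        ["bidirectional", "unidirectional", "silent"],
        size=config.n_enhancers, p=[0.7, 0.15, 0.15],
    )
    for f_idx, kind in enumerate(feat_kind):
        tad = f_idx // per_tad
        slot = f_idx % per_tad
        base = tad * config.tad_span + margin + slot * slot_span
        anchor = base + int(rng.integers(2_000, max(2_001, slot_span - max_gene_span - 2_000)))
        if kind == "gene":
            gene_id = f"g{g_i:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_peaks = int(rng.choice(ks, p=probs))
            gaps = []
            for _ in range(n_peaks - 1):
                if rng.random() < 0.5:
                    gaps.append(int(rng.integers(60, 180)))
                else:
                    gaps.append(int(rng.integers(250, 700)))
            if n_peaks > 1 and all(g < 200 for g in gaps):
                gaps[int(rng.integers(0, len(gaps)))] = int(rng.integers(250, 700))
            positions = [anchor]
            for g in gaps:
                positions.append(positions[-1] + g + peak_width)
            for r, p0 in enumerate(positions, start=1):
                peaks.append(GenomicInterval(
                    "chr1", p0, p0 + peak_width, strand, f"{gene_id}_p{r}",
                    {"gene_id": gene_id, "rank": r},
                ))
            first, last = positions[0], positions[-1] + peak_width
            tss = first if strand == "+" else last - 1
            body_len = 5_000
            if strand == "+":
                body = (first, last + body_len)
                utr_exon = (tss, tss + 150)
                utr_intron = (tss + 150, tss + 1_000)
            else:
                body = (first - body_len, last)
                utr_exon = (tss - 149, tss + 1)
                utr_intron = (tss - 999, tss - 149)
            transcripts.append(GenomicInterval("chr1", max(0, tss - 1), tss + 1, strand,
                                               f"{gene_id}_tss", {"kind": "tss", "gene_id": gene_id}))
            transcripts.append(GenomicInterval("chr1", *utr_exon, strand,
                                               f"{gene_id}_utr5exon",
                                               {"kind": "utr5_exon", "gene_id": gene_id}))
            transcripts.append(GenomicInterval("chr1", *utr_intron, strand,
                                               f"{gene_id}_utr5intron",
                                               {"kind": "utr5_intron", "gene_id": gene_id}))
            transcripts.append(GenomicInterval("chr1", *body, strand,
                                               f"{gene_id}_body",
                                               {"kind": "gene_body", "gene_id": gene_id}))
            segments.append(GenomicInterval("chr1", first - 500, last + 500, ".",
                                            f"{gene_id}_seg", {"state": "promoter"}))
            genes_rows.append({
                "gene_id": gene_id, "chrom": "chr1", "strand": strand,
                "start": first, "end": last, "tad_index": tad, "n_peaks": n_peaks,
            })
            g_i += 1
        else:
            enh_id = f"e{e_i:04d}"
            mid = anchor
            enhancers.append(GenomicInterval(
                "chr1", mid - 200, mid + 200, ".", enh_id,
                {"class": enh_classes[e_i], "midpoint": mid},
            ))
            segments.append(GenomicInterval("chr1", mid - 500, mid + 500, ".",
                                            f"{enh_id}_seg", {"state": "enhancer"}))
            e_i += 1
    genes = pd.DataFrame(genes_rows)
    gwas = pd.DataFrame(columns=["variant_id", "chrom", "pos", "trait"])
    pairing = pd.DataFrame(columns=["enhancer_id", "peak_id"])
    return AnnotationSet(tads, genes, peaks, enhancers, transcripts, segments,
                         gwas, pairing)


# ---------------------------------------------------------------------------
# planted effects


def _variant_near(genotypes: GenotypeMatrix, chrom, lo, hi, rng, min_maf=0.15):
    v = genotypes.variants
    mask = (v["chrom"] == chrom) & (v["pos"] >= lo) & (v["pos"] < hi)
    cand = np.flatnonzero(mask & (v["maf"] >= min_maf))
    if len(cand) == 0:
        cand = np.flatnonzero(mask)
    if len(cand) == 0:
        return None
    return v.iloc[int(rng.choice(cand))]["id"]


def generate_effect_table(config: SimulationConfig, genotypes: GenotypeMatrix,
                          annotation: AnnotationSet):
    """Plant allelic effects: puQTLs covering all five gene groups, eaQTLs on
    bidirectional enhancers, and mediation chains for a subset of eaQTLs.

    Returns (effects, pairing) where pairing links mediated enhancers to their
    target promoter peaks.
    """
    if config.effect_table is not None:
        return list(config.effect_table), annotation.pairing
    rng = config.rng("effects")
    effects, pairing_rows = [], []
    slo, shi = config.slope_range

    def slope():
        return float(rng.uniform(slo, shi))

    tad_bounds = {i: (t.start, t.end) for i, t in enumerate(annotation.tads)}
    for row in annotation.genes.itertuples(index=False):
        if rng.random() >= config.frac_gene_qtl:
            continue
        lo, hi = tad_bounds[row.tad_index]
        vid = _variant_near(genotypes, row.chrom, lo, hi, rng)
        if vid is None:
            continue
        gene_peaks = annotation.peaks_of(row.gene_id)
        positions = [p.start for p in gene_peaks]
        units = _promoter_units_from_positions(positions)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if len(units) == 1:
            targets = {gene_peaks[units[0][0]].feature_id: sign * slope()}
        else:
            pattern = rng.choice(["single", "opposite", "similar", "different"])
            u_pick = rng.choice(len(units), size=min(2, len(units)), replace=False)
            first_peak = gene_peaks[units[u_pick[0]][0]].feature_id
            b1 = sign * slope()
            if pattern == "single":
                targets = {first_peak: b1}
            else:
                second_peak = gene_peaks[units[u_pick[1]][0]].feature_id
                if pattern == "opposite":
                    targets = {first_peak: b1, second_peak: -sign * slope()}
                elif pattern == "similar":
                    targets = {first_peak: b1, second_peak: b1 * float(rng.uniform(1.0, 1.8))}
                else:  # different magnitudes, ER > 2
                    targets = {first_peak: b1, second_peak: b1 * float(rng.uniform(2.5, 3.5))}
        effects.append(PlantedEffect(vid, targets, "none"))

    tad_of_enh = {
        iv.feature_id: int(enhancer_tad(iv, annotation.tads))
        for iv in annotation.enhancers
    }
    gene_by_tad = annotation.genes.groupby("tad_index")["gene_id"].agg(list).to_dict()
    for iv in annotation.enhancers:
        if iv.attributes["class"] != "bidirectional":
            continue
        if rng.random() >= config.frac_enhancer_qtl:
            continue
        t = tad_of_enh[iv.feature_id]
        lo, hi = tad_bounds[t]
        vid = _variant_near(genotypes, iv.chrom, lo, hi, rng)
        if vid is None:
            continue
        b = (1.0 if rng.random() < 0.5 else -1.0) * slope()
        mediation = "none"
        targets = {iv.feature_id: b}
        if rng.random() < config.frac_mediated and gene_by_tad.get(t):
            gene_id = str(rng.choice(gene_by_tad[t]))
            gene_peaks = annotation.peaks_of(gene_id)
            peak = gene_peaks[int(rng.integers(0, len(gene_peaks)))]
            mediation = "variant->enhancer->promoter"
            targets[peak.feature_id] = b  # transmitted through the chain
            pairing_rows.append({"enhancer_id": iv.feature_id,
                                 "peak_id": peak.feature_id})
        effects.append(PlantedEffect(vid, targets, mediation))
    pairing = pd.DataFrame(pairing_rows, columns=["enhancer_id", "peak_id"])
    return effects, pairing


def enhancer_tad(iv: GenomicInterval, tads) -> int:
    mid = (iv.start + iv.end) // 2
    for i, t in enumerate(tads):
        if t.chrom == iv.chrom and t.start <= mid < t.end:
            return i
    raise ValueError(f"enhancer {iv.feature_id} outside every TAD")


def build_gwas_catalog(genotypes: GenotypeMatrix, effects, config: SimulationConfig,
                       n_null: int = 50) -> pd.DataFrame:
    """GWAS variant list: LD partners of planted QTLs plus random null hits."""
    rng = config.rng("gwas")
    v = genotypes.variants
    pos_of = dict(zip(v["id"], v["pos"]))
    rows = []
    for k, eff in enumerate(effects):
        if rng.random() < 0.5 or eff.variant_id not in pos_of:
            continue
        p = pos_of[eff.variant_id]
        block = p // config.ld_block_span
        in_block = v.loc[(v["pos"] // config.ld_block_span) == block]
        partner = in_block.iloc[int(rng.integers(0, len(in_block)))]
        rows.append({"variant_id": partner["id"], "chrom": partner["chrom"],
                     "pos": int(partner["pos"]), "trait": f"trait{k:03d}"})
    null_ids = rng.choice(len(v), size=min(n_null, len(v)), replace=False)
    for j in null_ids:
        rows.append({"variant_id": v.iloc[int(j)]["id"], "chrom": v.iloc[int(j)]["chrom"],
                     "pos": int(v.iloc[int(j)]["pos"]), "trait": "null_trait"})
    return pd.DataFrame(rows).drop_duplicates("variant_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# tag counts


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def true_group_label(gene_peaks, targets: dict, max_gap: int = 200) -> int:
    """Group label implied by planted slopes, by the classifier's own rules."""
    from .promoter_groups import PeakEffect, classify_gene, collapse_proximal_peaks

    effects = []
    for p in gene_peaks:
        b = targets.get(p.feature_id, 0.0)
        effects.append(PeakEffect("", p.feature_id, p.start, b,
                                  0.0 if b != 0 else 1.0))
    units = collapse_proximal_peaks(effects, max_gap=max_gap)
    return classify_gene("", units).group


def simulate_cage_tags(genotypes: GenotypeMatrix, annotation: AnnotationSet,
                       config: SimulationConfig, effects=None):
    """NB tag counts per sample with planted effects; returns (streams, truth).

    Promoter tags sit at each peak's stranded 5' end; enhancer tags are placed
    divergently over three positions per 200-nt flank (minus strand left of
    the midpoint, plus strand right), with a per-enhancer F/R balance drawn
    within the |D| < 0.8 acceptance region for 'bidirectional' elements and
    fully one-sided for 'unidirectional' ones. Mediated effects flow through a
    latent per-sample activity so the enhancer drives the paired promoter.
    """
    if effects is None:
        effects, pairing = generate_effect_table(config, genotypes, annotation)
        annotation.pairing = pairing
    rng = config.rng("tags")
    n = config.n_samples
    depth = np.clip(
        rng.normal(config.depth_mean, config.depth_sd, size=n),
        0.2 * config.depth_mean, None,
    )

    # per-feature planted slope terms (n_samples,) on the log scale
    targeted = {}
    mediation_label = {}
    truth_rows = []
    for eff in effects:
        g = genotypes.dosage_of(eff.variant_id)
        if eff.mediation == "variant->enhancer->promoter":
            # shared latent activity: slope * dosage + biological noise
            b = list(eff.targets.values())[0]
            a = b * g + rng.normal(0.0, 0.3, size=n)
            for fid in eff.targets:
                targeted[fid] = targeted.get(fid, 0.0) + a
        else:
            for fid, b in eff.targets.items():
                targeted[fid] = targeted.get(fid, 0.0) + b * g
        for fid, b in eff.targets.items():
            mediation_label[fid] = eff.mediation

    gene_of = {p.feature_id: p.attributes["gene_id"] for p in annotation.peaks}
    gene_targets = {}
    for eff in effects:
        for fid, b in eff.targets.items():
            if fid in gene_of:
                gene_targets.setdefault(gene_of[fid], {})[fid] = b
    group_of = {
        gid: true_group_label(annotation.peaks_of(gid), tg)
        for gid, tg in gene_targets.items()
    }
    for eff in effects:
        for fid, b in eff.targets.items():
            truth_rows.append({
                "feature_id": fid,
                "variant_id": eff.variant_id,
                "true_slope": b,
                "true_group_label": group_of.get(gene_of.get(fid, ""), 0),
                "mediation_topology": eff.mediation,
            })
    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_id", "variant_id", "true_slope", "true_group_label",
                 "mediation_topology"],
    )

    # baseline expression (configured TPM at the mean depth)
    base_tpm = {}
    for p in annotation.peaks:
        if p.feature_id in targeted or rng.random() > 0.15:
            base_tpm[p.feature_id] = float(rng.lognormal(np.log(60.0), 1.0))
        else:
            base_tpm[p.feature_id] = float(rng.lognormal(np.log(0.03), 0.5))
    enh_tpm, enh_balance = {}, {}
    for iv in annotation.enhancers:
        cls = iv.attributes["class"]
        if cls == "silent":
            enh_tpm[iv.feature_id] = 0.02
        else:
            enh_tpm[iv.feature_id] = float(rng.lognormal(np.log(30.0), 0.8))
        enh_balance[iv.feature_id] = (
            1.0 if cls == "unidirectional" else float(rng.uniform(0.35, 0.65))
        )

    records = {s: [] for s in range(n)}  # (chrom, pos, strand, count)
    for p in annotation.peaks:
        fid = p.feature_id
        mu = base_tpm[fid] * 1e-6 * depth * np.exp(targeted.get(fid, 0.0))
        counts = _nb_draw(rng, mu, config.dispersion)
        pos5 = p.start if p.strand == "+" else p.end - 1
        for s in np.flatnonzero(counts > 0):
            records[s].append((p.chrom, pos5, p.strand, int(counts[s])))

    for iv in annotation.enhancers:
        fid = iv.feature_id
        mid = iv.attributes["midpoint"]
        q = enh_balance[fid]
        mu = enh_tpm[fid] * 1e-6 * depth * np.exp(targeted.get(fid, 0.0))
        f_counts = _nb_draw(rng, mu * q, config.dispersion)
        r_counts = _nb_draw(rng, mu * (1 - q), config.dispersion)
        f_pos = [mid + 20, mid + 60, mid + 100]
        r_pos = [mid - 21, mid - 61, mid - 101]
        for s in range(n):
            for total, positions, strand in ((f_counts[s], f_pos, "+"),
                                             (r_counts[s], r_pos, "-")):
                if total <= 0:
                    continue
                split = rng.multinomial(int(total), [0.5, 0.3, 0.2])
                for pos, c in zip(positions, split):
                    if c > 0:
                        records[s].append((iv.chrom, pos, strand, int(c)))

    streams = {}
    for s in range(n):
        sid = genotypes.sample_ids[s]
        df = pd.DataFrame(records[s], columns=["chrom", "pos", "strand", "count"])
        df = (df.groupby(["chrom", "pos", "strand"], sort=True)["count"].sum()
                .reset_index())
        streams[sid] = TagStream(sid, df)
    return streams, truth


# ---------------------------------------------------------------------------
# direct phenotype-level generators for calibration experiments


def simulate_qtl_phenotypes(genotypes: GenotypeMatrix, n_phenotypes: int,
                            frac_alt: float, slope_range: tuple, seed: int,
                            min_maf: float = 0.2):
    """Gaussian phenotypes y = beta * dosage + N(0, 1) with planted truth.

    ``beta`` is the per-allele effect in residual-SD units (the 'standardized
    slope'). Each phenotype is anchored at its planted variant (alternatives)
    or at a random variant (nulls). Returns (phenotypes, anchors, truth).
    """
    rng = np.random.default_rng(seed)
    v = genotypes.variants
    eligible = np.flatnonzero(v["maf"].to_numpy() >= min_maf)
    if len(eligible) == 0:
        raise ValueError("no variant passes the MAF floor")
    n_alt = int(round(frac_alt * n_phenotypes))
    rows, anchor_rows, truth_rows = [], [], []
    for k in range(n_phenotypes):
        pid = f"ph{k:04d}"
        j = int(rng.choice(eligible))
        is_alt = k < n_alt
        beta = float(rng.uniform(*slope_range)) if is_alt else 0.0
        if is_alt and rng.random() < 0.5:
            beta = -beta
        y = beta * genotypes.dosages[:, j] + rng.normal(size=genotypes.n_samples)
        rows.append(y)
        anchor_rows.append({"phenotype_id": pid,
                            "chrom": v.iloc[j]["chrom"],
                            "pos": int(v.iloc[j]["pos"])})
        truth_rows.append({"phenotype_id": pid, "variant_id": v.iloc[j]["id"],
                           "true_slope": beta, "is_alt": is_alt})
    phen = pd.DataFrame(np.asarray(rows),
                        index=[r["phenotype_id"] for r in anchor_rows],
                        columns=genotypes.sample_ids)
    return phen, pd.DataFrame(anchor_rows), pd.DataFrame(truth_rows)


def simulate_mediation_triplet(dosage, topology: str, n: int | None = None,
                               beta1: float = 1.0, beta2: float = 1.0,
                               rng=None):
    """Gaussian (L, M, T) triplet for causal-inference calibration.

    'chain': L -> M -> T (M = beta1 L + e, T = beta2 M + e');
    'independent': L -> M and L -> T with independent noise;
    'null': M, T pure noise.
    """
    if rng is None:
        rng = np.random.default_rng()
    L = np.asarray(dosage, dtype=float)
    n = len(L)
    if topology == "chain":
        M = beta1 * L + rng.normal(size=n)
        T = beta2 * M + rng.normal(size=n)
    elif topology == "independent":
        M = beta1 * L + rng.normal(size=n)
        T = beta2 * L + rng.normal(size=n)
    elif topology == "null":
        M = rng.normal(size=n)
        T = rng.normal(size=n)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return L, M, T


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    annotation: AnnotationSet
    tag_streams: dict
    truth: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic cohort: genotypes, annotation, effects, tags, truth."""
    genotypes = simulate_genotypes(config)
    annotation = simulate_annotation(config)
    effects, pairing = generate_effect_table(config, genotypes, annotation)
    annotation.pairing = pairing
    annotation.gwas = build_gwas_catalog(genotypes, effects, config)
    streams, truth = simulate_cage_tags(genotypes, annotation, config, effects)
    return SyntheticDataset(config, genotypes, annotation, streams, truth)
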