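"""End-to-end orchestration: simulate or ingest, normalize, map, integrate.

Stages communicate only through declared files inside the run directory, all
randomness flows from one root seed, and every output file is hashed into a
manifest so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cis_qtl, enhancers, integration, io, normalization, promoter_groups
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "normalize", "map-puqtl", "classify", "enhancers",
              "map-eaqtl", "integrate", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative run configuration; every CLI flag overrides a key here."""

    out_dir: str = "run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    # synthetic cohort
    n_samples: int = 150
    n_variants: int = 20_000
    n_genes: int = 400
    n_enhancers: int = 100
    tad_span: int = 500_000
    ld_block_span: int = 20_000
    depth_mean: float = 16.2e6
    depth_sd: float = 4.3e6
    dispersion: float = 0.05
    # normalization / covariates
    mean_threshold: float = 0.5
    genotype_pcs: int = 3
    promoter_pcs: int = 20
    enhancer_pcs: int = 12
    rank_transform: bool = True
    # QTL mapping
    n_perm: int = 1000
    adjust_mode: str = "beta"
    fdr: float = 0.05
    # classification
    p_threshold: float = 0.05
    er_threshold: float = 2.0
    max_gap: int = 200
    # enhancers
    min_tags: int = 5
    density_fold: float = 2.0
    max_cluster_len: int = 200
    bidir_window: int = 400
    d_max: float = 0.8
    max_null_fraction: float = 50 / 154
    # integration
    rho_min: float = 0.8
    rtc_max_pairs: int = 50
    cit_perm: int = 500
    enrich_perm: int = 1000

    @classmethod
    def from_yaml(cls, path=None, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        # coerce scalars to the declared field types (YAML 1.1 reads numbers
        # like 2.0e6 as strings)
        types = {f.name: f.type for f in __import__("dataclasses").fields(cls)}
        for key, value in list(data.items()):
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            if types[key] == "int":
                data[key] = int(float(value))
            elif types[key] == "float":
                data[key] = float(value)
        return cls(**data)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_samples=self.n_samples, n_variants=self.n_variants,
            n_genes=self.n_genes, n_enhancers=self.n_enhancers,
            tad_span=self.tad_span, ld_block_span=self.ld_block_span,
            depth_mean=self.depth_mean, depth_sd=self.depth_sd,
            dispersion=self.dispersion, seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_bed_with_attrs(path, names):
    ivs = io.read_intervals(path)
    for iv in ivs:
        for k, name in enumerate(names, start=1):
            if f"attr{k}" in iv.attributes:
                iv.attributes[name] = iv.attributes.pop(f"attr{k}")
    return ivs


class PipelineRun:
    """Executes stages in dependency order inside one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.dir = Path(config.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        (self.dir / "ctss").mkdir(exist_ok=True)
        with open(self.dir / "config.yaml", "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=True)

    # -- helpers ----------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.dir / name

    def _genotypes(self):
        return io.read_genotypes(str(self.path("genotypes.vcf")))

    def _tag_streams(self):
        streams = []
        for p in sorted((self.dir / "ctss").glob("*.bed")):
            streams.append(io.read_ctss(p, p.name[: -len(".ctss.bed")]))
        return streams

    def _covariates(self, expr: pd.DataFrame, n_expr_pcs: int) -> pd.DataFrame:
        cfg = self.config
        genotypes = self._genotypes()
        n_samples = expr.shape[1]
        if n_expr_pcs >= n_samples:
            # default PC counts are sized for the full cohort design (150
            # samples); clamp for small runs instead of failing
            n_expr_pcs = max(1, n_samples // 4)
            logger.warning("expression PCs clamped to %d for %d samples",
                           n_expr_pcs, n_samples)
        cov = []
        if cfg.genotype_pcs > 0:
            g = normalization.pca_covariates(genotypes.dosages, cfg.genotype_pcs,
                                             scale=False)
            g.columns = [f"geno_{c}" for c in g.columns]
            g.index = genotypes.sample_ids
            cov.append(g)
        if n_expr_pcs > 0:
            e = normalization.pca_covariates(expr, n_expr_pcs, scale=True)
            e.columns = [f"expr_{c}" for c in e.columns]
            cov.append(e)
        return pd.concat(cov, axis=1)

    # -- stages -----------------------------------------------------------
    def stage_simulate(self):
        ds = simulate_dataset(self.config.sim_config())
        io.write_vcf(ds.genotypes, self.path("genotypes.vcf"))
        for sid, stream in ds.tag_streams.items():
            io.write_ctss(stream, self.dir / "ctss" / f"{sid}.ctss.bed")
        ann = ds.annotation
        io.write_intervals(ann.tads, self.path("tads.bed"))
        io.write_intervals(ann.peaks, self.path("peaks.bed"),
                           extra_attrs=("gene_id", "rank"))
        io.write_intervals(ann.enhancers, self.path("enhancers.bed"),
                           extra_attrs=("class", "midpoint"))
        io.write_intervals(ann.segments, self.path("segments.bed"),
                           extra_attrs=("state",))
        io.write_intervals(ann.transcripts, self.path("transcripts.bed"),
                           extra_attrs=("kind", "gene_id"))
        ann.gwas.to_csv(self.path("gwas.tsv"), sep="\t", index=False)
        ann.pairing.to_csv(self.path("pairing.tsv"), sep="\t", index=False)
        ds.truth.to_csv(self.path("truth.tsv"), sep="\t", index=False)

    def stage_normalize(self):
        cfg = self.config
        peaks = _read_bed_with_attrs(self.path("peaks.bed"), ("gene_id", "rank"))
        streams = self._tag_streams()
        raw = io.aggregate_tags_to_features(streams, peaks, "same-strand")
        lib = pd.Series({ts.sample_id: ts.library_size for ts in streams})
        expr, factors, kept, dropped = normalization.normalize_counts(
            raw, lib, cfg.mean_threshold
        )
        logger.info("normalize: kept %d peaks, dropped %d", kept, dropped)
        io.write_matrix(raw, self.path("promoter_counts.tsv"))
        lib.rename("library_size").to_csv(self.path("library_sizes.tsv"), sep="\t")
        factors.to_csv(self.path("size_factors.tsv"), sep="\t")
        io.write_matrix(expr, self.path("promoter_expr.tsv"))
        cov = self._covariates(expr, cfg.promoter_pcs)
        cov.to_csv(self.path("covariates_promoter.tsv"), sep="\t",
                   index_label="sample_id")

    def _peak_anchors(self, peaks) -> pd.DataFrame:
        rows = []
        for p in peaks:
            pos = p.start if p.strand == "+" else p.end - 1
            rows.append({"phenotype_id": p.feature_id, "chrom": p.chrom,
                         "pos": pos, "strand": p.strand})
        return pd.DataFrame(rows)

    def _mapping_phenotypes(self, expr: pd.DataFrame) -> pd.DataFrame:
        if self.config.rank_transform:
            return normalization.rank_inverse_normal(expr)
        return expr

    def stage_map_puqtl(self):
        cfg = self.config
        expr = io.read_matrix(self.path("promoter_expr.tsv"))
        peaks = _read_bed_with_attrs(self.path("peaks.bed"), ("gene_id", "rank"))
        anchors = self._peak_anchors([p for p in peaks
                                      if p.feature_id in set(expr.index)])
        tads = io.read_intervals(self.path("tads.bed"))
        genotypes = self._genotypes()
        cov = pd.read_csv(self.path("covariates_promoter.tsv"), sep="\t",
                          index_col="sample_id")
        phen = self._mapping_phenotypes(expr)
        res = cis_qtl.map_cis(phen, anchors, genotypes, tads,
                              covariates=cov.to_numpy(), n_perm=cfg.n_perm,
                              mode=cfg.adjust_mode, seed=cfg.seed, fdr=cfg.fdr)
        res.to_csv(self.path("puqtl.tsv"), sep="\t", index=False)
        sig = cis_qtl.call_significant(res, cfg.fdr)
        sig.to_csv(self.path("puqtl_significant.tsv"), sep="\t", index=False)
        logger.info("map-puqtl: %d/%d significant at FDR %g", len(sig), len(res),
                    cfg.fdr)

    def stage_classify(self):
        cfg = self.config
        sig = pd.read_csv(self.path("puqtl_significant.tsv"), sep="\t")
        peaks = _read_bed_with_attrs(self.path("peaks.bed"), ("gene_id", "rank"))
        peak_table = pd.DataFrame([
            {"peak_id": p.feature_id, "gene_id": p.attributes["gene_id"],
             "position": p.start if p.strand == "+" else p.end - 1}
            for p in peaks
        ])
        expr = io.read_matrix(self.path("promoter_expr.tsv"))
        # effect-size ratios need slopes on a common scale: per-peak effects
        # are estimated on log expression, not the rank-transformed values
        phen = np.log(expr + 1.0)
        cov = pd.read_csv(self.path("covariates_promoter.tsv"), sep="\t",
                          index_col="sample_id")
        if len(sig) == 0:
            pd.DataFrame(columns=["gene_id", "group", "er", "n_units",
                                  "lead_variant", "significant_peaks"]).to_csv(
                self.path("gene_groups.tsv"), sep="\t", index=False)
            return
        groups = promoter_groups.classify_all(
            sig, peak_table, phen, self._genotypes(), covariates=cov.to_numpy(),
            p_threshold=cfg.p_threshold, er_threshold=cfg.er_threshold,
            max_gap=cfg.max_gap,
        )
        groups.to_csv(self.path("gene_groups.tsv"), sep="\t", index=False)

    def stage_enhancers(self):
        cfg = self.config
        streams = self._tag_streams()
        enh = _read_bed_with_attrs(self.path("enhancers.bed"), ("class", "midpoint"))
        clusters = enhancers.cluster_pooled_ctss(
            streams, min_tags=cfg.min_tags, min_density_fold=cfg.density_fold,
            max_length=cfg.max_cluster_len,
        )
        selected = enhancers.select_bidirectional(enh, clusters, cfg.bidir_window)
        if not selected:
            raise PipelineError("enhancers", "no enhancer passed bidirectional selection")
        quant, activity = enhancers.directionality_and_quantify(streams, selected)
        kept, matrix = enhancers.build_enhancer_matrix(
            quant, activity, d_max=cfg.d_max,
            max_null_fraction=cfg.max_null_fraction,
        )
        kept.to_csv(self.path("enhancer_quant.tsv"), sep="\t", index=False)
        io.write_matrix(matrix, self.path("enhancer_activity.tsv"))
        kept_ids = set(kept["enhancer_id"])
        io.write_intervals([iv for iv in selected if iv.feature_id in kept_ids],
                           self.path("enhancers_selected.bed"),
                           extra_attrs=("class", "midpoint"))
        cov = self._covariates(matrix, cfg.enhancer_pcs)
        cov.to_csv(self.path("covariates_enhancer.tsv"), sep="\t",
                   index_label="sample_id")

    def stage_map_eaqtl(self):
        cfg = self.config
        activity = io.read_matrix(self.path("enhancer_activity.tsv"))
        quant = pd.read_csv(self.path("enhancer_quant.tsv"), sep="\t")
        anchors = pd.DataFrame({
            "phenotype_id": quant["enhancer_id"],
            "chrom": "chr1",
            "pos": quant["midpoint"],
        })
        enh = _read_bed_with_attrs(self.path("enhancers_selected.bed"),
                                   ("class", "midpoint"))
        chrom_of = {iv.feature_id: iv.chrom for iv in enh}
        anchors["chrom"] = anchors["phenotype_id"].map(chrom_of)
        tads = io.read_intervals(self.path("tads.bed"))
        genotypes = self._genotypes()
        cov = pd.read_csv(self.path("covariates_enhancer.tsv"), sep="\t",
                          index_col="sample_id")
        phen = self._mapping_phenotypes(activity)
        res = cis_qtl.map_cis(phen, anchors, genotypes, tads,
                              covariates=cov.to_numpy(), n_perm=cfg.n_perm,
                              mode=cfg.adjust_mode, seed=cfg.seed + 1, fdr=cfg.fdr)
        res.to_csv(self.path("eaqtl.tsv"), sep="\t", index=False)
        sig = cis_qtl.call_significant(res, cfg.fdr)
        sig.to_csv(self.path("eaqtl_significant.tsv"), sep="\t", index=False)
        logger.info("map-eaqtl: %d/%d significant at FDR %g", len(sig), len(res),
                    cfg.fdr)

    def stage_integrate(self):
        cfg = self.config
        genotypes = self._genotypes()
        peaks = _read_bed_with_attrs(self.path("peaks.bed"), ("gene_id", "rank"))
        tads = io.read_intervals(self.path("tads.bed"))
        segments = _read_bed_with_attrs(self.path("segments.bed"), ("state",))
        transcripts = _read_bed_with_attrs(self.path("transcripts.bed"),
                                           ("kind", "gene_id"))
        puqtl_sig = pd.read_csv(self.path("puqtl_significant.tsv"), sep="\t")
        expr = io.read_matrix(self.path("promoter_expr.tsv"))
        phen = self._mapping_phenotypes(expr)
        cov = pd.read_csv(self.path("covariates_promoter.tsv"), sep="\t",
                          index_col="sample_id").to_numpy()
        summary = {}

        # stand-in eQTL pass on mRNA totals (per-gene sums of peak counts),
        # then pi1 replication of puQTLs in the mRNA nominal p-values
        raw = io.read_matrix(self.path("promoter_counts.tsv"))
        gene_of = {p.feature_id: p.attributes["gene_id"] for p in peaks}
        gene_counts = raw.groupby(raw.index.map(gene_of)).sum()
        lib = pd.read_csv(self.path("library_sizes.tsv"), sep="\t", index_col=0)[
            "library_size"]
        gene_tpm = normalization.tpm_normalize(gene_counts, lib)
        gene_expr, _ = normalization.rle_normalize(gene_tpm)
        gene_phen = normalization.rank_inverse_normal(gene_expr)
        mrna_ps = []
        for row in puqtl_sig.itertuples(index=False):
            gid = gene_of.get(row.phenotype_id)
            if gid is None or gid not in gene_phen.index:
                continue
            y = gene_phen.loc[gid].to_numpy()
            resid = cis_qtl.residualize(y, cov)
            scan, _ = cis_qtl.nominal_scan(
                resid, genotypes.dosage_of(row.variant_id),
                n_covariates=cov.shape[1],
            )
            mrna_ps.append(float(scan["p"][0]))
        if len(mrna_ps) >= 10:
            rep = integration.pi1(mrna_ps, seed=cfg.seed)
            summary["pi1_mrna_replication"] = rep
            pd.DataFrame({"p": mrna_ps}).to_csv(self.path("eqtl_nominal_p.tsv"),
                                                sep="\t", index=False)

        gwas = pd.read_csv(self.path("gwas.tsv"), sep="\t")
        anchors = self._peak_anchors(peaks)
        if len(puqtl_sig) and len(gwas):
            enr = integration.gwas_overlap_enrichment(
                puqtl_sig["variant_id"].unique(), gwas, genotypes,
                anchors["pos"].to_numpy(), n_perm=cfg.enrich_perm, seed=cfg.seed,
            )
            summary["gwas_enrichment"] = asdict(enr)

            # RTC for QTL-GWAS pairs sharing a TAD
            gwas_by_tad = {}
            tad_idx = io.assign_points_to_intervals(
                gwas["chrom"].tolist(), gwas["pos"].tolist(), tads)
            for k, t in enumerate(tad_idx):
                if t >= 0:
                    gwas_by_tad.setdefault(t, []).append(gwas.iloc[k]["variant_id"])
            qtl_tads = io.assign_points_to_intervals(
                puqtl_sig["chrom"].tolist(), puqtl_sig["variant_pos"].tolist(), tads)
            known = set(genotypes.variants["id"])
            rtc_rows = []
            for k, row in enumerate(puqtl_sig.itertuples(index=False)):
                if len(rtc_rows) >= cfg.rtc_max_pairs or qtl_tads[k] < 0:
                    continue
                for gv in gwas_by_tad.get(qtl_tads[k], []):
                    if gv not in known or gv == row.variant_id:
                        continue
                    y = phen.loc[row.phenotype_id].to_numpy()
                    resid = cis_qtl.residualize(y, cov)
                    try:
                        r = integration.rtc(resid, genotypes, gv, row.variant_id,
                                            tads[qtl_tads[k]])
                    except ValueError:
                        continue
                    rtc_rows.append({
                        "phenotype_id": row.phenotype_id,
                        "qtl_variant": row.variant_id, "gwas_variant": gv,
                        "interval": r.interval_id, "n_variants": r.n_variants,
                        "rank": r.rank, "rtc": r.rtc,
                    })
                    break
            pd.DataFrame(rtc_rows).to_csv(self.path("rtc.tsv"), sep="\t",
                                          index=False)
            summary["n_rtc_high_confidence"] = int(
                sum(r["rtc"] > 0.9 for r in rtc_rows))

        # QTL enrichment within promoter-state chromatin against the landscape
        if len(puqtl_sig):
            anchor_pos = dict(zip(anchors["phenotype_id"], anchors["pos"]))
            qtl_df = pd.DataFrame({
                "chrom": puqtl_sig["chrom"],
                "pos": puqtl_sig["variant_pos"],
                "anchor_pos": puqtl_sig["phenotype_id"].map(anchor_pos),
            })
            landscape = anchors[anchors["phenotype_id"].isin(set(expr.index))][
                ["chrom", "pos"]]
            prom_segments = [s for s in segments
                             if s.attributes.get("state") == "promoter"]
            if prom_segments:
                fe = integration.feature_enrichment(
                    qtl_df, prom_segments, landscape, n_perm=cfg.enrich_perm,
                    seed=cfg.seed,
                )
                summary["promoter_segment_enrichment"] = asdict(fe)

        # TSS annotation of all peaks
        labels = integration.annotate_tss(peaks, transcripts, segments)
        labels.to_csv(self.path("tss_annotation.tsv"), sep="\t", index=False)

        # triplets + causal inference, when the enhancer stages ran
        ea_path = self.path("eaqtl_significant.tsv")
        pairing = pd.read_csv(self.path("pairing.tsv"), sep="\t")
        if ea_path.exists() and len(pairing):
            ea_sig = pd.read_csv(ea_path, sep="\t")
            triplets = integration.build_triplets(ea_sig, pairing, puqtl_sig,
                                                  genotypes, rho_min=cfg.rho_min)
            if len(triplets):
                activity = io.read_matrix(self.path("enhancer_activity.tsv"))
                act_phen = self._mapping_phenotypes(activity)
                tested = integration.test_triplets(
                    triplets, act_phen, phen, genotypes,
                    n_perm=cfg.cit_perm, fdr=cfg.fdr, seed=cfg.seed,
                )
                tested = triplets.merge(tested, on=["variant_id", "enhancer_id",
                                                    "promoter_id"])
                tested.to_csv(self.path("triplets.tsv"), sep="\t", index=False)
                summary["n_triplets"] = int(len(tested))
                summary["n_causal_forward"] = int(tested["forward_causal"].sum())
            else:
                triplets.to_csv(self.path("triplets.tsv"), sep="\t", index=False)
        with open(self.path("integration_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    # -- manifest & report -------------------------------------------------
    def write_manifest(self):
        entries = {}
        for p in sorted(self.dir.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                entries[str(p.relative_to(self.dir))] = _sha256(p)
        manifest = {"seed": self.config.seed,
                    "stages": list(self.config.stages), "files": entries}
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    def run(self):
        stage_fns = {
            "simulate": self.stage_simulate,
            "normalize": self.stage_normalize,
            "map-puqtl": self.stage_map_puqtl,
            "classify": self.stage_classify,
            "enhancers": self.stage_enhancers,
            "map-eaqtl": self.stage_map_eaqtl,
            "integrate": self.stage_integrate,
        }
        for stage in ALL_STAGES:
            if stage == "report" or stage not in self.config.stages:
                continue
            logger.info("== stage %s ==", stage)
            try:
                stage_fns[stage]()
            except PipelineError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(stage, str(exc)) from exc
        manifest = self.write_manifest()
        if "report" in self.config.stages:
            write_report(self.dir)
        return manifest


def run_pipeline(config: RunConfig):
    """Run all enabled stages; returns the manifest dict."""
    return PipelineRun(config).run()


def write_report(run_dir) -> dict:
    """Human-readable per-stage counts, recomputed from the stage TSVs."""
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError("manifest.json not found; run the pipeline first")
    rep = {}

    def _count(name):
        p = run_dir / name
        if not p.exists():
            return None
        return int(len(pd.read_csv(p, sep="\t")))

    expr = run_dir / "promoter_expr.tsv"
    rep["peaks_kept"] = (int(len(io.read_matrix(expr))) if expr.exists() else None)
    rep["puqtls"] = _count("puqtl_significant.tsv")
    groups_path = run_dir / "gene_groups.tsv"
    if groups_path.exists():
        groups = pd.read_csv(groups_path, sep="\t")
        rep["classified_genes"] = int(len(groups))
        rep["group_sizes"] = {
            int(g): int(c) for g, c in groups["group"].value_counts().items()
        }
    enh = run_dir / "enhancer_activity.tsv"
    rep["enhancers_kept"] = (int(len(io.read_matrix(enh))) if enh.exists() else None)
    rep["eaqtls"] = _count("eaqtl_significant.tsv")
    rep["triplets"] = _count("triplets.tsv")
    summ = run_dir / "integration_summary.json"
    if summ.exists():
        with open(summ) as fh:
            rep["integration"] = json.load(fh)
    lines = ["pipeline run report", "===================", ""]
    for key in ("peaks_kept", "puqtls", "classified_genes", "enhancers_kept",
                "eaqtls", "triplets"):
        val = rep.get(key)
        lines.append(f"{key:>18}: {'absent' if val is None else val}")
    if "group_sizes" in rep:
        sizes = rep["group_sizes"]
        lines.append(f"{'group sizes':>18}: " + ", ".join(
            f"{g}:{sizes.get(g, 0)}" for g in (1, 2, 3, 4, 5)))
    if "integration" in rep:
        integ = rep["integration"]
        if "pi1_mrna_replication" in integ:
            lines.append(f"{'pi1 (mRNA)':>18}: "
                         f"{integ['pi1_mrna_replication']['pi1']:.3f}")
        if "gwas_enrichment" in integ:
            e = integ["gwas_enrichment"]
            lines.append(f"{'GWAS overlap OR':>18}: {e['odds_ratio']:.3f} "
                         f"(CI {e['ci_low']:.2f}-{e['ci_high']:.2f}, p={e['p']:.4g})")
    text = "\n".join(lines) + "\n"
    with open(run_dir / "report.txt", "w") as fh:
        fh.write(text)
    with open(run_dir / "summary.json", "w") as fh:
        json.dump(rep, fh, indent=2, sort_keys=True)
    return rep
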