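"""Readers, writers and interval utilities shared by every pipeline stage.

All genomic coordinates are 0-based half-open internally. VCF positions are
converted from 1-based on read and back on write; BED files are native.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
STRAND_RULES = ("same-strand", "plus-only", "minus-only", "both")


@dataclass
class GenomicInterval:
    """A stranded half-open interval with a feature id and free-form attributes."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_id: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"interval {self.feature_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass
class GenotypeMatrix:
    """Sample-by-variant allelic dosages plus per-variant metadata.

    ``dosages`` is float (n_samples, n_variants); missing calls are mean-imputed
    per variant, with the original missingness kept in ``missing``. ``variants``
    has columns id, chrom, pos, ref, alt, maf, alt_count.
    """

    sample_ids: list
    variants: pd.DataFrame
    dosages: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape mismatch")
        if self.missing is None:
            self.missing = np.zeros(self.dosages.shape, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return int(idx[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.loc[mask].reset_index(drop=True),
            self.dosages[:, mask],
            self.missing[:, mask],
        )


@dataclass
class TagStream:
    """Per-sample stranded single-nucleotide 5'-tag counts (CTSS records)."""

    sample_id: str
    data: pd.DataFrame  # columns: chrom, pos, strand, count

    def __post_init__(self):
        d = self.data
        if (d["count"] < 1).any():
            raise ValueError("tag counts must be >= 1")
        if d.duplicated(subset=["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate CTSS positions per (chrom, strand)")

    @property
    def library_size(self) -> int:
        return int(self.data["count"].sum())


# ---------------------------------------------------------------------------
# genotypes


def _finalize_genotypes(sample_ids, records, dosage_rows, min_alt_count):
    variants = pd.DataFrame(
        records, columns=["id", "chrom", "pos", "ref", "alt"]
    )
    dos = (
        np.asarray(dosage_rows, dtype=float).reshape(len(records), len(sample_ids)).T
        if records
        else np.zeros((len(sample_ids), 0))
    )
    missing = np.isnan(dos)
    alt_count = np.nansum(dos, axis=0)
    n_called = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt_count / (2.0 * n_called)
    maf = np.minimum(freq, 1.0 - freq)
    keep = alt_count >= min_alt_count
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "read_genotypes: removed %d variants with alt-allele count < %d",
            n_removed,
            min_alt_count,
        )
    variants["maf"] = maf
    variants["alt_count"] = alt_count.astype(int)
    variants = variants.loc[keep].reset_index(drop=True)
    dos = dos[:, keep]
    missing = missing[:, keep]
    # mean-impute missing calls per variant, keeping the flag
    if missing.any():
        col_mean = np.nanmean(dos, axis=0)
        idx = np.where(missing)
        dos[idx] = col_mean[idx[1]]
    return GenotypeMatrix(list(sample_ids), variants, dos, missing)


def read_genotypes(path, min_alt_count: int = 10) -> GenotypeMatrix:
    """Read a VCF (GT fields) or a dosage TSV, dropping rare variants.

    Variants with a total alternative-allele count below ``min_alt_count``
    (default 10) are removed; the number removed is logged.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path, min_alt_count)
    return _read_dosage_tsv(path, min_alt_count)


def _read_vcf(path, min_alt_count):
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    records, rows = [], []
    for v in vcf:
        vid = v.ID or f"{v.CHROM}:{v.POS}"
        records.append((vid, v.CHROM, v.POS - 1, v.REF, v.ALT[0] if v.ALT else "."))
        gts = v.genotype.array()
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        rows.append(alleles.sum(axis=1))
    vcf.close()
    return _finalize_genotypes(sample_ids, records, rows, min_alt_count)


def _read_dosage_tsv(path, min_alt_count):
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    records = list(df[meta_cols].itertuples(index=False, name=None))
    rows = df[sample_ids].to_numpy(dtype=float)
    return _finalize_genotypes(sample_ids, records, rows, min_alt_count)


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (CHROM POS ID REF ALT, GT per sample)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = genotypes.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + list(map(str, genotypes.sample_ids))) + "\n")
        dos = genotypes.dosages
        miss = genotypes.missing
        for j, row in genotypes.variants.iterrows():
            gts = []
            for i in range(genotypes.n_samples):
                if miss[i, j]:
                    gts.append("./.")
                else:
                    d = int(round(dos[i, j]))
                    gts.append(("0/0", "0/1", "1/1")[d])
            fh.write(
                f"{row['chrom']}\t{row['pos'] + 1}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.variants[["id", "chrom", "pos", "ref", "alt"]].copy()
    dos = genotypes.dosages.T.copy()
    dos[genotypes.missing.T] = np.nan
    for i, s in enumerate(genotypes.sample_ids):
        df[s] = dos[:, i]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals (BED)


def read_intervals(path, kind: str | None = None) -> list:
    """Read BED4/6/8+ records as :class:`GenomicInterval`, input order kept.

    Columns beyond the sixth are stored in ``attributes`` as attr1, attr2, ...;
    column 5 (score) is stored under ``attributes['score']`` when present.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            strand = f[5] if len(f) > 5 else "."
            attrs = {}
            if len(f) > 4:
                attrs["score"] = f[4]
            for k, extra in enumerate(f[6:], start=1):
                attrs[f"attr{k}"] = extra
            if kind is not None:
                attrs["kind"] = kind
            out.append(GenomicInterval(chrom, start, end, strand, name, attrs))
    return out


def write_intervals(intervals, path, extra_attrs: tuple = ()) -> None:
    """Write BED6 (+ optional attribute columns, in the given order)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = iv.attributes.get("score", "0")
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.feature_id, str(score), iv.strand]
            cols += [str(iv.attributes.get(a, ".")) for a in extra_attrs]
            fh.write("\t".join(cols) + "\n")


def read_ctss(path, sample_id: str) -> TagStream:
    """Read a CTSS BED6 file (chrom, pos, pos+1, label, count, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "end", "label", "count", "strand"],
        dtype={"chrom": str},
    )
    if len(df) and (df["end"] != df["pos"] + 1).any():
        raise ValueError(f"{path}: CTSS records must be single-base")
    return TagStream(sample_id, df[["chrom", "pos", "strand", "count"]].copy())


def write_ctss(stream: TagStream, path) -> None:
    d = stream.data.sort_values(["chrom", "strand", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        for t in d.itertuples(index=False):
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.pos + 1}\t{t.chrom}:{t.pos}:{t.strand}\t"
                f"{t.count}\t{t.strand}\n"
            )


# ---------------------------------------------------------------------------
# matrices


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a features-by-samples TSV with the feature id as first column."""
    df.to_csv(path, sep="\t", index=True, index_label="feature_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


# ---------------------------------------------------------------------------
# interval indexing and tag aggregation


class IntervalIndex:
    """Overlap queries against a fixed interval set, grouped by chromosome."""

    def __init__(self, intervals):
        self.intervals = list(intervals)
        self._by_chrom = {}
        for i, iv in enumerate(self.intervals):
            self._by_chrom.setdefault(iv.chrom, []).append(i)
        self._arrays = {}
        for chrom, idx in self._by_chrom.items():
            starts = np.array([self.intervals[i].start for i in idx])
            ends = np.array([self.intervals[i].end for i in idx])
            self._arrays[chrom] = (np.asarray(idx), starts, ends)

    def query(self, chrom: str, start: int, end: int) -> list:
        """Indices of intervals overlapping [start, end) on chrom."""
        if chrom not in self._arrays:
            return []
        idx, starts, ends = self._arrays[chrom]
        hit = (starts < end) & (ends > start)
        return list(idx[hit])

    def query_point(self, chrom: str, pos: int) -> list:
        return self.query(chrom, pos, pos + 1)


def assign_points_to_intervals(chroms, positions, intervals) -> np.ndarray:
    """Index of the first interval containing each point, or -1.

    Intended for disjoint interval sets (TADs); with overlapping intervals the
    lowest input index wins.
    """
    index = IntervalIndex(intervals)
    out = np.full(len(positions), -1, dtype=int)
    for k, (c, p) in enumerate(zip(chroms, positions)):
        hits = index.query_point(c, int(p))
        if hits:
            out[k] = min(hits)
    return out


def aggregate_tags_to_features(tag_streams, intervals, strand_rule: str = "same-strand") -> pd.DataFrame:
    """Sum tag counts per interval per sample into a features-by-samples matrix.

    ``strand_rule``: 'same-strand' counts tags matching the interval strand
    ('.' matches both); 'plus-only'/'minus-only' restrict to one tag strand;
    'both' counts all tags. Tags outside every interval are ignored.
    """
    if strand_rule not in STRAND_RULES:
        raise ValueError(f"unknown strand_rule {strand_rule!r}")
    ids = [iv.feature_id for iv in intervals]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature_id in interval set")
    mat = np.zeros((len(intervals), len(tag_streams)), dtype=np.int64)
    for s_idx, stream in enumerate(tag_streams):
        # sorted positions + cumulative counts per (chrom, strand)
        lookup = {}
        for (chrom, strand), grp in stream.data.groupby(["chrom", "strand"], sort=False):
            g = grp.sort_values("pos")
            pos = g["pos"].to_numpy()
            cum = np.concatenate([[0], np.cumsum(g["count"].to_numpy())])
            lookup[(chrom, strand)] = (pos, cum)

        def window_sum(chrom, strand, start, end):
            if (chrom, strand) not in lookup:
                return 0
            pos, cum = lookup[(chrom, strand)]
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            return int(cum[hi] - cum[lo])

        for f_idx, iv in enumerate(intervals):
            if strand_rule == "plus-only":
                strands = ["+"]
            elif strand_rule == "minus-only":
                strands = ["-"]
            elif strand_rule == "both" or iv.strand == ".":
                strands = ["+", "-"]
            else:
                strands = [iv.strand]
            mat[f_idx, s_idx] = sum(
                window_sum(iv.chrom, st, iv.start, iv.end) for st in strands
            )
    return pd.DataFrame(mat, index=pd.Index(ids, name="feature_id"),
                        columns=[ts.sample_id for ts in tag_streams])
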