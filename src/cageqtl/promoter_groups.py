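"""Five-group classification of genes associated with promoter-usage QTLs.

Per gene, every CAGE peak is tested against the gene's single lead puQTL
variant; peaks closer than 200 nt collapse into one promoter unit. Groups:

1. one promoter unit (single-promoter gene, or all peaks within 200 nt);
2. multi-promoter gene where exactly one unit responds (p < 0.05);
3. >= 2 responding units with opposite slope signs (promoter shift);
4. >= 2 responding units, same sign, similar magnitude (ER <= 2);
5. >= 2 responding units, same sign, different magnitude (ER > 2),

with ER = |max(beta)| / |min(beta)| over the responding units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis_qtl import nominal_scan, residualize

logger = logging.getLogger(__name__)


@dataclass
class PeakEffect:
    """Slope and nominal p of one CAGE peak against the gene's lead variant."""

    gene_id: str
    peak_id: str
    position: int
    beta: float
    p: float


@dataclass
class PromoterUnit:
    """A collapsed group of proximal peaks; carries its best peak's effect."""

    peak_ids: list
    start: int
    end: int
    beta: float
    p: float


def collapse_proximal_peaks(peaks, max_gap: int = 200) -> list:
    """Single-linkage collapse of peaks less than ``max_gap`` nt apart.

    Consecutive peaks (by position) merge whenever their distance is below the
    gap; a chain 0,150,300 therefore forms a single unit. Each unit takes the
    slope/p of its most significant member.
    """
    peaks = sorted(peaks, key=lambda pk: pk.position)
    units = []
    current = [peaks[0]]
    for pk in peaks[1:]:
        if pk.position - current[-1].position < max_gap:
            current.append(pk)
        else:
            units.append(current)
            current = [pk]
    units.append(current)
    out = []
    for members in units:
        best = min(members, key=lambda pk: (pk.p, pk.position))
        out.append(PromoterUnit(
            [pk.peak_id for pk in members],
            members[0].position,
            members[-1].position + 1,
            best.beta,
            best.p,
        ))
    return out


@dataclass
class GeneClassification:
    gene_id: str
    group: int
    er: float  # effect-size ratio; NaN unless >= 2 same-sign responding units
    n_units: int
    significant_peaks: list


def classify_gene(gene_id: str, units, p_threshold: float = 0.05,
                  er_threshold: float = 2.0) -> GeneClassification:
    """Assign the five-group label from per-unit slopes and p-values.

    ``units`` are :class:`PromoterUnit` (or any objects with beta/p/peak_ids).
    ER exactly at the threshold stays in group 4 (the split is strict).
    """
    if len(units) == 1:
        return GeneClassification(gene_id, 1, np.nan, 1,
                                  list(units[0].peak_ids))
    sig = [u for u in units if u.p < p_threshold]
    if len(sig) == 0:
        # the gene reached genome-wide significance, so at least its lead peak
        # should respond; treat the best unit as the single responding one
        logger.warning("gene %s: no unit passes p < %g against its lead variant; "
                       "assigning group 2 to the best unit", gene_id, p_threshold)
        best = min(units, key=lambda u: u.p)
        return GeneClassification(gene_id, 2, np.nan, len(units),
                                  list(best.peak_ids))
    sig_peaks = [pid for u in sig for pid in u.peak_ids]
    if len(sig) == 1:
        return GeneClassification(gene_id, 2, np.nan, len(units), sig_peaks)
    betas = np.array([u.beta for u in sig])
    if (betas > 0).any() and (betas < 0).any():
        return GeneClassification(gene_id, 3, np.nan, len(units), sig_peaks)
    er = float(np.abs(betas).max() / np.abs(betas).min())
    group = 5 if er > er_threshold else 4
    return GeneClassification(gene_id, group, er, len(units), sig_peaks)


def peak_effects_for_gene(gene_id, peak_rows, lead_variant_dosage, phenotypes,
                          covariates=None) -> list:
    """Re-test each of a gene's peaks against the gene's lead puQTL variant.

    ``peak_rows`` is an iterable of (peak_id, position); expression comes from
    the normalized ``phenotypes`` matrix (features x samples).
    """
    n_cov = 0 if covariates is None else np.asarray(covariates).shape[1]
    out = []
    for peak_id, position in peak_rows:
        y = phenotypes.loc[peak_id].to_numpy(dtype=float)
        resid = residualize(y, covariates)
        scan, _ = nominal_scan(resid, lead_variant_dosage, n_covariates=n_cov)
        out.append(PeakEffect(gene_id, peak_id, int(position),
                              float(scan["beta"][0]), float(scan["p"][0])))
    return out


def classify_all(
    significant_qtls: pd.DataFrame,
    peak_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    genotypes,
    covariates=None,
    p_threshold: float = 0.05,
    er_threshold: float = 2.0,
    max_gap: int = 200,
) -> pd.DataFrame:
    """Classify every gene with at least one genome-wide significant puQTL.

    ``significant_qtls`` is the 5% FDR set from :func:`cageqtl.cis_qtl.map_cis`
    (phenotype_id = peak id); ``peak_table`` maps peak_id -> gene_id, position.
    The gene's lead variant is the one attached to its most significant peak
    (smallest adjusted p, ties by nominal p then variant position).
    """
    peak_info = peak_table.set_index("peak_id")
    qtls = significant_qtls.copy()
    qtls["gene_id"] = qtls["phenotype_id"].map(peak_info["gene_id"])
    rows = []
    for gene_id, grp in qtls.groupby("gene_id"):
        grp = grp.sort_values(["adjusted_p", "nominal_p", "variant_pos"])
        lead_variant = grp.iloc[0]["variant_id"]
        gene_peaks = peak_info[peak_info["gene_id"] == gene_id]
        tested = [(pid, r["position"]) for pid, r in gene_peaks.iterrows()
                  if pid in phenotypes.index]
        dosage = genotypes.dosage_of(lead_variant)
        effects = peak_effects_for_gene(gene_id, tested, dosage, phenotypes,
                                        covariates)
        units = collapse_proximal_peaks(effects, max_gap=max_gap)
        cls = classify_gene(gene_id, units, p_threshold, er_threshold)
        rows.append({
            "gene_id": gene_id,
            "group": cls.group,
            "er": cls.er,
            "n_units": cls.n_units,
            "lead_variant": lead_variant,
            "significant_peaks": ",".join(cls.significant_peaks),
        })
    return pd.DataFrame(rows)
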