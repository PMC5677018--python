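"""Permutation-based cis-QTL mapping within TAD windows.

Each molecular phenotype (CAGE-peak expression, enhancer activity, or total
mRNA level) is tested against every variant inside its topologically
associating domain. Covariates are regressed out once, the best in-window
nominal p-value is adjusted for the number of correlated tests with 1000
phenotype permutations (empirically or through a fitted Beta null), and the
adjusted p-values are converted to genome-wide q-values with the Storey
estimator; q < 0.05 defines the 5% FDR QTL set.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, assign_points_to_intervals

logger = logging.getLogger(__name__)

ADJUST_MODES = ("empirical", "beta", "exhaustive")


@dataclass
class CisWindow:
    """Candidate variants for one phenotype (all variants in its TAD)."""

    phenotype_id: str
    chrom: str
    start: int
    end: int
    variant_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_variants(self) -> int:
        return len(self.variant_indices)


def residualize(phenotype: np.ndarray, covariates) -> np.ndarray:
    """OLS residuals of a phenotype on an intercept plus covariates."""
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    if n <= X.shape[1] + 2:
        raise ValueError("too few samples for the covariate model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _standardize_columns(G: np.ndarray):
    """Zero-mean unit-norm columns; zero-variance columns flagged."""
    Gc = G - G.mean(axis=0)
    norms = np.linalg.norm(Gc, axis=0)
    ok = norms > 0
    Gs = np.zeros_like(Gc)
    Gs[:, ok] = Gc[:, ok] / norms[ok]
    return Gs, ok, norms


def _r_to_p(r: np.ndarray, dof: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = dof * r * r / np.maximum(1.0 - r * r, 1e-300)
    return stats.f.sf(t2, 1, dof)


def nominal_scan(residual_phenotype, dosages, positions=None, n_covariates: int = 0):
    """Per-variant simple regression of a residualized phenotype on dosage.

    Returns a dict of arrays (beta, r, p, tested) and the lead variant index
    (smallest p; ties broken by genomic position, then column order).
    Monomorphic variants are skipped and flagged tested=False.
    """
    y = np.asarray(residual_phenotype, dtype=float)
    G = np.asarray(dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    if m == 0:
        raise ValueError("empty cis window")
    dof = n - 2 - n_covariates
    if dof < 1:
        raise ValueError("nonpositive degrees of freedom")
    ys = y - y.mean()
    y_norm = np.linalg.norm(ys)
    if y_norm == 0:
        raise ValueError("constant phenotype")
    Gs, tested, g_norms = _standardize_columns(G)
    n_skip = int((~tested).sum())
    if n_skip:
        logger.debug("nominal_scan: skipped %d monomorphic variants", n_skip)
    r = Gs.T @ (ys / y_norm)
    r[~tested] = 0.0
    p = _r_to_p(r, dof)
    p[~tested] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(tested, r * y_norm / np.where(g_norms > 0, g_norms, 1.0), np.nan)
    if not tested.any():
        lead = -1
    else:
        pos = np.asarray(positions) if positions is not None else np.arange(m)
        key = np.where(tested, p, np.inf)
        best_p = key.min()
        cand = np.flatnonzero(key == best_p)
        lead = int(cand[np.argmin(pos[cand])])
    return {"beta": beta, "r": r, "p": p, "tested": tested}, lead


def _best_perm_pvalues(ys_unit, Gs, tested, dof, n_perm, rng):
    """Best in-window p-value for each of n_perm phenotype permutations."""
    n = len(ys_unit)
    perm_idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    Y = ys_unit[perm_idx]  # rows stay zero-mean unit-norm
    R = Y @ Gs[:, tested]
    best_r2 = (R * R).max(axis=1)
    return _r_to_p(np.sqrt(best_r2), dof)


def permutation_adjust(
    residual_phenotype,
    dosages,
    n_perm: int = 1000,
    mode: str = "beta",
    n_covariates: int = 0,
    rng=None,
):
    """Adjust the best in-window nominal p for the number of correlated tests.

    Modes: 'empirical' -> (1 + #{perm best p <= observed}) / (1 + n_perm);
    'beta' -> maximum-likelihood Beta(a, b) fit to the permutation best
    p-values, adjusted p = Beta CDF at the observed best p; 'exhaustive' ->
    enumerate every sample permutation (small n only) and report the exact
    fraction with best p <= observed (the identity permutation included).

    Returns dict with observed best p, adjusted p, mode used, and the fitted
    (a, b) for beta mode.
    """
    if mode not in ADJUST_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(residual_phenotype, dtype=float)
    G = np.asarray(dosages, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n = len(y)
    dof = n - 2 - n_covariates
    ys = y - y.mean()
    ys_unit = ys / np.linalg.norm(ys)
    Gs, tested, _ = _standardize_columns(G)
    if not tested.any():
        raise ValueError("no polymorphic variant in window")
    r_obs = Gs[:, tested].T @ ys_unit
    obs_best_p = float(_r_to_p(np.abs(r_obs), dof).min())

    if mode == "exhaustive":
        if n > 9:
            raise ValueError("exhaustive enumeration limited to n <= 9 samples")
        count = 0
        total = 0
        Gt = Gs[:, tested]
        for perm in iter_permutations(range(n)):
            rp = Gt.T @ ys_unit[list(perm)]
            bp = _r_to_p(np.abs(rp), dof).min()
            count += bp <= obs_best_p + 1e-12
            total += 1
        return {
            "nominal_best_p": obs_best_p,
            "adjusted_p": count / total,
            "mode": "exhaustive",
            "n_perm": total,
            "beta_shape": (np.nan, np.nan),
        }

    if rng is None:
        rng = np.random.default_rng()
    if mode == "beta" and n_perm < 100:
        logger.warning("beta adjustment with < 100 permutations; using empirical")
        mode = "empirical"
    perm_best = _best_perm_pvalues(ys_unit, Gs, tested, dof, n_perm, rng)
    emp = (1 + int((perm_best <= obs_best_p).sum())) / (1 + n_perm)
    if mode == "empirical":
        return {
            "nominal_best_p": obs_best_p,
            "adjusted_p": emp,
            "mode": "empirical",
            "n_perm": n_perm,
            "beta_shape": (np.nan, np.nan),
        }
    clipped = np.clip(perm_best, 1e-12, 1 - 1e-12)
    try:
        a, b, _, _ = stats.beta.fit(clipped, floc=0, fscale=1)
        adj = float(stats.beta.cdf(obs_best_p, a, b))
    except Exception:  # degenerate fits fall back to the empirical estimate
        logger.warning("beta fit failed; using empirical adjustment")
        return {
            "nominal_best_p": obs_best_p,
            "adjusted_p": emp,
            "mode": "empirical",
            "n_perm": n_perm,
            "beta_shape": (np.nan, np.nan),
        }
    return {
        "nominal_best_p": obs_best_p,
        "adjusted_p": adj,
        "mode": "beta",
        "n_perm": n_perm,
        "beta_shape": (a, b),
    }


# ---------------------------------------------------------------------------
# Storey q-values


def storey_pi0(pvalues, lambda_grid=None) -> float:
    """Storey's pi0: fraction of truly null tests, smoothed over lambda.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the grid, smoothed with
    a cubic polynomial and evaluated at the largest lambda, clipped to (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    if lambda_grid is None:
        # the cubic smoother needs many tests to be stable; with few tests the
        # single mid-grid point is the conservative standard choice
        lambda_grid = np.arange(0.05, 0.951, 0.05) if m >= 100 else np.array([0.5])
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 1:
        pi0 = (p > lam[0]).sum() / (m * (1 - lam[0]))
        return float(min(max(pi0, 1.0 / m), 1.0))
    pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
    # var(pi0(lambda)) ~ pi0 / (m (1 - lambda)): weight by precision so the
    # noisy high-lambda end does not dominate the fit it is evaluated at
    weights = np.sqrt(1.0 - lam)
    coeffs = np.polyfit(lam, pi0_lam, deg=3, w=weights)
    pi0 = float(np.polyval(coeffs, lam.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalue(pvalues, lambda_grid=None):
    """Storey q-values: returns (pi0, q) with q aligned to the input order."""
    p = np.asarray(pvalues, dtype=float)
    pi0 = storey_pi0(p, lambda_grid)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return pi0, q


def call_significant(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """QTLs passing the genome-wide q-value threshold (default 5% FDR)."""
    return results.loc[results["q"] < fdr].copy()


# ---------------------------------------------------------------------------
# window construction and the full mapping pass


def build_cis_windows(anchors: pd.DataFrame, genotypes: GenotypeMatrix, tads,
                      fallback_flank: int = 1_000_000) -> list:
    """One :class:`CisWindow` per phenotype: all variants in the anchor's TAD.

    ``anchors`` needs columns phenotype_id, chrom, pos (the stranded 5' end of
    a CAGE peak, or an enhancer midpoint). Anchors outside every TAD fall back
    to a fixed +/- ``fallback_flank`` window (logged).
    """
    tad_idx = assign_points_to_intervals(
        anchors["chrom"].tolist(), anchors["pos"].tolist(), tads
    )
    var_chrom = genotypes.variants["chrom"].to_numpy()
    var_pos = genotypes.variants["pos"].to_numpy()
    windows = []
    n_orphan = 0
    for k, row in enumerate(anchors.itertuples(index=False)):
        if tad_idx[k] >= 0:
            tad = tads[tad_idx[k]]
            chrom, start, end = tad.chrom, tad.start, tad.end
        else:
            n_orphan += 1
            chrom = row.chrom
            start, end = max(0, row.pos - fallback_flank), row.pos + fallback_flank
        vmask = (var_chrom == chrom) & (var_pos >= start) & (var_pos < end)
        windows.append(
            CisWindow(row.phenotype_id, chrom, start, end, np.flatnonzero(vmask))
        )
    if n_orphan:
        logger.info("build_cis_windows: %d anchors outside every TAD; used +/-%d bp",
                    n_orphan, fallback_flank)
    return windows


def _phenotype_rng(seed: int, phenotype_id: str) -> np.random.Generator:
    """Per-phenotype generator so results are independent of scan order."""
    h = zlib.crc32(phenotype_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), h]))


def map_cis(
    phenotypes: pd.DataFrame,
    anchors: pd.DataFrame,
    genotypes: GenotypeMatrix,
    tads,
    covariates=None,
    n_perm: int = 1000,
    mode: str = "beta",
    seed: int = 0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full cis pass: residualize, scan, permute, q-values.

    ``phenotypes`` is features-by-samples (columns must match the genotype
    sample order); ``anchors`` as in :func:`build_cis_windows`. Returns one row
    per phenotype with the lead variant, slope, nominal/adjusted p and q.
    """
    if list(phenotypes.columns) != list(genotypes.sample_ids):
        raise ValueError("phenotype samples do not match genotype samples")
    n_cov = 0 if covariates is None else np.asarray(covariates).shape[1]
    windows = build_cis_windows(anchors, genotypes, tads)
    anchor_pos = dict(zip(anchors["phenotype_id"], anchors["pos"]))
    rows = []
    var_ids = genotypes.variants["id"].to_numpy()
    var_pos_all = genotypes.variants["pos"].to_numpy()
    for win in windows:
        if win.n_variants == 0:
            logger.info("phenotype %s: no variants in window; skipped", win.phenotype_id)
            continue
        y = phenotypes.loc[win.phenotype_id].to_numpy(dtype=float)
        if np.std(y) == 0:
            logger.info("phenotype %s: constant values; skipped", win.phenotype_id)
            continue
        resid = residualize(y, covariates)
        G = genotypes.dosages[:, win.variant_indices]
        pos = var_pos_all[win.variant_indices]
        scan, lead = nominal_scan(resid, G, pos, n_covariates=n_cov)
        if lead < 0:
            continue
        rng = _phenotype_rng(seed, win.phenotype_id)
        adj = permutation_adjust(resid, G, n_perm=n_perm, mode=mode,
                                 n_covariates=n_cov, rng=rng)
        vi = win.variant_indices[lead]
        rows.append({
            "phenotype_id": win.phenotype_id,
            "chrom": win.chrom,
            "window_start": win.start,
            "window_end": win.end,
            "variant_id": var_ids[vi],
            "variant_pos": int(var_pos_all[vi]),
            "distance": int(var_pos_all[vi] - anchor_pos[win.phenotype_id]),
            "beta": float(scan["beta"][lead]),
            "nominal_p": float(scan["p"][lead]),
            "adjusted_p": float(adj["adjusted_p"]),
            "n_variants": win.n_variants,
            "n_perm": adj["n_perm"],
            "beta_shape_a": adj["beta_shape"][0],
            "beta_shape_b": adj["beta_shape"][1],
        })
    results = pd.DataFrame(rows)
    if len(results):
        _, q = qvalue(results["adjusted_p"].to_numpy())
        results["q"] = q
    else:
        results["q"] = []
    return results
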