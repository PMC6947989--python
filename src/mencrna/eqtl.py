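"""mencRNA eQTL scan: normalization, per-pair OLS, FDR, signal overlap.

Expression is log2-transformed and quantile normalized across samples; each
(gene, variant) pair within the gene's capture region is tested by ordinary
least squares of expression on additive dosage plus covariates (always
including the gene's copy-number estimate in tumor data); discoveries are
reported at Benjamini-Hochberg FDR < 5%. An eQTL gene overlaps a risk
signal when some CCV's eQTL p-value is within two orders of magnitude of
the top eQTL variant's p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ccv import CCVSet

__all__ = [
    "EqtlResult",
    "normalize_expression",
    "fit_eqtl",
    "bh_fdr",
    "eqtl_signal_overlap",
    "FDR_THRESHOLD",
]

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05
OVERLAP_FACTOR = 100.0  # top-eQTL p within two orders of magnitude of a CCV's


@dataclass(frozen=True)
class EqtlResult:
    gene_id: str
    variant_id: str
    beta: float
    se: float
    p: float
    q: float = np.nan


def normalize_expression(
    m: pd.DataFrame, pseudocount: float = 1.0, log: bool = True
) -> pd.DataFrame:
    """log2(x + pseudocount) then quantile normalization across samples.

    Every sample's sorted values are replaced by the cross-sample mean of
    order statistics; tied values within a sample receive the mean of the
    reference values at their tied ranks. After normalization every sample
    has identical sorted values (asserted).
    """
    if log:
        if (m.values < 0).any():
            raise ValueError("expression matrix has negative entries")
        x = np.log2(m.to_numpy(dtype=float) + pseudocount)
    else:
        x = m.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples == 1:
        logger.warning("single-sample matrix: quantile normalization is the identity")
        return pd.DataFrame(x, index=m.index, columns=m.columns)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n_genes + 1, dtype=float)
    tie_free = []
    for j in range(n_samples):
        ranks = sps.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
        tie_free.append(np.unique(x[:, j]).size == n_genes)
    # defining property: every tie-free sample carries exactly the reference
    # distribution (tied entries get the mean of their tied ranks' reference
    # values, which perturbs the sorted vector by construction)
    for j in range(n_samples):
        if tie_free[j]:
            assert np.allclose(np.sort(out[:, j]), reference), (
                "quantile normalization failed to equalize sample distributions"
            )
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def _ols_t(
    y: np.ndarray, dosage: np.ndarray, covs: np.ndarray | None
) -> tuple[float, float, float] | None:
    """Closed-form OLS of y on [1, dosage, covs]; returns (beta, se, p)."""
    n = y.shape[0]
    cols = [np.ones(n), dosage]
    if covs is not None:
        cols.extend(covs.T)
    X = np.column_stack(cols)
    p_params = X.shape[1]
    if n <= p_params:
        return None
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return None
    # guard against rank deficiency that inv() silently tolerates
    if np.linalg.matrix_rank(xtx) < p_params:
        return None
    beta_hat = xtx_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    df = n - p_params
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(beta_hat[1])
    if se == 0.0:
        return beta, 0.0, 0.0
    tstat = beta / se
    p = float(2.0 * sps.t.sf(abs(tstat), df))
    return beta, se, max(p, np.nextafter(0, 1))


def fit_eqtl(
    genotypes: pd.DataFrame,
    expression: pd.DataFrame,
    tests: Mapping[str, Sequence[str]],
    copy_number: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    fdr: bool = True,
) -> list[EqtlResult]:
    """OLS eQTL scan over the requested (gene, variant) pairs.

    Parameters
    ----------
    genotypes
        variants x samples additive dosages in [0, 2].
    expression
        genes x samples (already normalized).
    tests
        gene_id -> variant ids to test (the cis set, e.g. variants sharing
        the gene's capture region).
    copy_number
        genes x samples per-gene copy-number estimates, added as a covariate
        for its gene (mandatory for tumor data; optional here so normal-
        tissue runs can omit it).
    covariates
        covariate x samples global covariates.
    fdr
        attach global BH q-values across all tests in the run.
    """
    samples = expression.columns
    if not genotypes.columns.equals(samples):
        genotypes = genotypes.reindex(columns=samples)
        if genotypes.isna().any().any():
            raise ValueError("genotype and expression sample ids do not align")
    glob_cov = None
    if covariates is not None:
        glob_cov = covariates.reindex(columns=samples).to_numpy(dtype=float).T

    results: list[EqtlResult] = []
    for gene_id in tests:
        if gene_id not in expression.index:
            logger.warning("gene %s missing from expression; skipped", gene_id)
            continue
        y = expression.loc[gene_id].to_numpy(dtype=float)
        cov_cols = []
        if glob_cov is not None:
            cov_cols.append(glob_cov)
        if copy_number is not None:
            if gene_id not in copy_number.index:
                logger.warning("gene %s missing copy number; skipped", gene_id)
                continue
            cov_cols.append(
                copy_number.loc[gene_id].reindex(samples).to_numpy(dtype=float)[:, None]
            )
        covs = np.column_stack([c for c in cov_cols]) if cov_cols else None
        for vid in tests[gene_id]:
            if vid not in genotypes.index:
                continue
            dosage = genotypes.loc[vid].to_numpy(dtype=float)
            if np.all(dosage == dosage[0]):
                logger.info("variant %s monomorphic; skipped", vid)
                continue
            fit = _ols_t(y, dosage, covs)
            if fit is None:
                logger.warning(
                    "rank-deficient design for gene %s / variant %s; skipped",
                    gene_id,
                    vid,
                )
                continue
            beta, se, p = fit
            results.append(EqtlResult(gene_id, vid, beta, se, p))
    if fdr and results:
        qs = bh_fdr([r.p for r in results])
        results = [
            EqtlResult(r.gene_id, r.variant_id, r.beta, r.se, r.p, q)
            for r, q in zip(results, qs)
        ]
    return results


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def eqtl_signal_overlap(
    gene_results: Sequence[EqtlResult], ccv_set: CCVSet
) -> tuple[bool, str | None, str | None]:
    """Does this gene's eQTL association overlap a risk signal?

    ``True`` iff some CCV of the signal was tested and its eQTL p-value is
    within two orders of magnitude of the top (minimal-p) eQTL variant's:
    ``p_ccv <= 100 * p_top``. Returns ``(overlaps, top_variant, best_ccv)``;
    ``best_ccv`` is None when no CCV was among the tested variants.
    """
    if not gene_results:
        raise ValueError("no eQTL results for gene")
    top = min(gene_results, key=lambda r: (r.p, r.variant_id))
    ccv_ids = set(ccv_set.variant_ids)
    ccv_hits = [r for r in gene_results if r.variant_id in ccv_ids]
    if not ccv_hits:
        return False, top.variant_id, None
    best = min(ccv_hits, key=lambda r: (r.p, r.variant_id))
    return bool(best.p <= OVERLAP_FACTOR * top.p), top.variant_id, best.variant_id
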