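"""ERCC spike-in based capture performance metrics.

A dose-response line (log2 FPKM vs log2 known concentration) is fitted per
library over detected spike-ins; the lower limit of detection is the
smallest concentration reaching the detection threshold (FPKM 0.5); capture
fold enrichment compares the captured and non-captured regression lines;
and targeted vs non-targeted gene fold changes are compared with a paired
t-test as the specificity measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpikeInTable",
    "DoseResponseFit",
    "DETECTION_FPKM",
    "fit_dose_response",
    "lld",
    "uld",
    "capture_fold_enrichment",
    "specificity_test",
]

DETECTION_FPKM = 0.5


@dataclass
class SpikeInTable:
    """Known concentrations and observed FPKM for one library's spike-ins."""

    table: pd.DataFrame  # columns: transcript, concentration, fpkm
    library_id: str = ""
    captured: bool = True

    def __post_init__(self) -> None:
        required = {"transcript", "concentration", "fpkm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"spike-in table missing columns {sorted(missing)}")
        if (self.table["concentration"] <= 0).any():
            raise ValueError("spike-in concentrations must be positive")
        if (self.table["fpkm"] < 0).any():
            raise ValueError("spike-in FPKM must be non-negative")

    def detected(self, threshold_fpkm: float = DETECTION_FPKM) -> pd.DataFrame:
        return self.table[self.table["fpkm"] >= threshold_fpkm]


@dataclass
class DoseResponseFit:
    slope: float
    intercept: float
    r2: float
    library_id: str = ""
    n_detected: int = 0

    def predict_log2_fpkm(self, concentration: float) -> float:
        return self.intercept + self.slope * np.log2(concentration)


def fit_dose_response(
    t: SpikeInTable, threshold_fpkm: float = DETECTION_FPKM
) -> DoseResponseFit:
    """OLS of log2(FPKM) on log2(concentration) over detected spike-ins."""
    det = t.detected(threshold_fpkm)
    if len(det) < 3:
        raise ValueError(
            f"library {t.library_id!r}: only {len(det)} detected spike-ins (need >= 3)"
        )
    x = np.log2(det["concentration"].to_numpy(dtype=float))
    y = np.log2(det["fpkm"].to_numpy(dtype=float))
    if np.allclose(x, x[0]):
        raise ValueError("all detected spike-ins share one concentration")
    res = sps.linregress(x, y)
    return DoseResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        library_id=t.library_id,
        n_detected=len(det),
    )


def lld(t: SpikeInTable, threshold_fpkm: float = DETECTION_FPKM) -> float:
    """Lower limit of detection: smallest concentration with FPKM >= threshold.

    NaN when nothing is detected.
    """
    det = t.detected(threshold_fpkm)
    if det.empty:
        return float("nan")
    return float(det["concentration"].min())


def uld(t: SpikeInTable, threshold_fpkm: float = DETECTION_FPKM) -> float:
    """Upper limit of detection (probe-saturation heuristic).

    The highest concentration before the dose-response residual drops more
    than 2 residual-SDs below the fitted line; the full maximum when no
    saturation is seen.
    """
    fit = fit_dose_response(t, threshold_fpkm)
    det = t.detected(threshold_fpkm).sort_values("concentration")
    x = np.log2(det["concentration"].to_numpy(dtype=float))
    y = np.log2(det["fpkm"].to_numpy(dtype=float))
    resid = y - (fit.intercept + fit.slope * x)
    sd = resid.std(ddof=1) if len(resid) > 1 else 0.0
    conc = det["concentration"].to_numpy(dtype=float)
    saturated = resid < -2.0 * sd if sd > 0 else np.zeros(len(resid), dtype=bool)
    if not saturated.any():
        return float(conc.max())
    first_sat = int(np.argmax(saturated))
    if first_sat == 0:
        return float("nan")
    return float(conc[first_sat - 1])


def capture_fold_enrichment(
    captured_fit: DoseResponseFit,
    noncaptured_fit: DoseResponseFit,
    at_conc: float,
) -> float:
    """Linear-scale enrichment of the captured over the non-captured line.

    ``2 ** (predicted log2 FPKM captured - predicted log2 FPKM non-captured)``
    at a stated concentration; with unequal slopes the ratio depends on the
    concentration, so callers should also report the shared-range endpoints.
    """
    if at_conc <= 0:
        raise ValueError("evaluation concentration must be positive")
    diff = captured_fit.predict_log2_fpkm(at_conc) - noncaptured_fit.predict_log2_fpkm(
        at_conc
    )
    return float(2.0**diff)


def specificity_test(
    fold_changes_targeted: Sequence[float],
    fold_changes_nontargeted: Sequence[float],
    paired: bool = True,
) -> float:
    """Two-sided t-test on log fold changes, targeted vs non-targeted genes.

    Paired by design (each targeted gene vs its nearest non-targeted
    neighbor). Degenerate zero-variance differences are reported as p -> 0
    with a warning (the observed enrichment is then deterministic).
    """
    a = np.log(np.asarray(fold_changes_targeted, dtype=float))
    b = np.log(np.asarray(fold_changes_nontargeted, dtype=float))
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test needs equal-length fold-change vectors")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1) if diffs.size > 1 else 0.0, 0.0):
            if np.allclose(diffs, 0.0):
                return 1.0
            warnings.warn(
                "zero variance in paired differences; p reported as 0"
            )
            return 0.0
        return float(sps.ttest_rel(a, b).pvalue)
    return float(sps.ttest_ind(a, b).pvalue)
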