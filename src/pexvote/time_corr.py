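"""Tumor immune-microenvironment (TIME) statistics for the paired
plasma/tumor cohort.

Links plasma exosome marker levels to the matched tumor: Pearson
correlation of plasma -dCt against tumor expression, Fisher's exact test
for concordance with the IHC protein call, median-split group comparisons
of deconvolved immune-cell fractions by Mann-Whitney U, and mean-z
interferon-gamma signature scores on the tumor TPM matrix.

Deconvolved fractions, CPS and IHC status are consumed as data; their
upstream estimation is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

HIGH = "high"
LOW = "low"

#: exact Mann-Whitney enumeration below this combined sample size (tie-free)
_MW_EXACT_MAX_N = 12


@dataclass(frozen=True)
class TumorProfile:
    """One paired part-2 patient."""

    patient_id: str
    tumor_tpm: dict[str, float] | None  # None when RNA-seq failed
    ihc_hla_e: str | None               # "high" / "low"
    cps: float | None
    immune_fractions: dict[str, float] | None
    plasma_expr: dict[str, float] | None  # -dCt per marker gene


@dataclass(frozen=True)
class SignatureScore:
    patient_id: str
    signature_name: str
    score: float


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p on n-2 df."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if len(xa) < 3:
        raise ValidationError("Pearson test requires n >= 3")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValidationError("values must be finite")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("zero variance in an input vector")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (sum of
    hypergeometric probabilities no larger than the observed table's)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError("table must hold non-negative integers")
    if arr.sum() == 0:
        raise ValidationError("all-zero table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def median_split(values: pd.Series) -> pd.Series:
    """Label each patient high/low by the median; values at or above the
    median are high, so odd n yields ceil(n/2) high."""
    v = values.dropna()
    if len(v) < 2:
        raise ValidationError("median split requires n >= 2")
    med = float(np.median(v.to_numpy()))
    return pd.Series(np.where(v.to_numpy() >= med, HIGH, LOW), index=v.index, name="split")


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U statistic of the first sample).

    Uses the exact null enumeration for small tie-free inputs
    (n_a + n_b <= 12), otherwise the tie-corrected normal approximation.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if len(aa) == 0 or len(bb) == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([aa, bb])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= _MW_EXACT_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(aa, bb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ifng_signature_score(
    tpm: pd.DataFrame, gene_list, signature_name: str = "ifng"
) -> pd.Series:
    """Mean over listed genes of patient-z-scored log2(TPM + 1).

    ``tpm`` is genes-by-patients. Listed genes missing from the matrix are
    dropped with a logged warning; genes constant across patients
    contribute 0.
    """
    present = [g for g in gene_list if g in tpm.index]
    absent = [g for g in gene_list if g not in tpm.index]
    if absent:
        logger.warning("signature %s: dropping %d absent genes: %s",
                       signature_name, len(absent), absent)
    if not present:
        raise ValidationError(f"signature {signature_name!r}: no listed genes present")
    x = np.log2(tpm.loc[present].to_numpy(dtype=float) + 1.0)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=0), index=tpm.columns, name=signature_name)


def ihc_concordance(
    ihc_status: pd.Series, plasma_values: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate plasma high/low (median split) against the IHC
    protein call and test association by Fisher's exact test.

    Patients missing either measurement are excluded with a log entry.
    Returns the 2x2 table (rows plasma high/low, columns IHC high/low)
    and the two-sided p.
    """
    joined = pd.DataFrame({"ihc": ihc_status, "plasma": plasma_values}).dropna()
    dropped = len(ihc_status.index.union(plasma_values.index)) - len(joined)
    if dropped:
        logger.info("ihc_concordance: excluded %d patients with missing data", dropped)
    if len(joined) < 2:
        raise ValidationError("concordance requires >=2 complete patients")
    split = median_split(joined["plasma"])
    table = np.zeros((2, 2), dtype=int)
    for plasma_lab, ihc_lab in zip(split, joined["ihc"]):
        table[0 if plasma_lab == HIGH else 1, 0 if ihc_lab == HIGH else 1] += 1
    frame = pd.DataFrame(table,
                         index=[f"plasma_{HIGH}", f"plasma_{LOW}"],
                         columns=[f"ihc_{HIGH}", f"ihc_{LOW}"])
    return frame, fisher_exact_2x2(table)
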