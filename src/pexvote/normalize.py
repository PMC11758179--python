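"""Expression normalization and group statistics.

qPCR panels are normalized by the delta-Ct method against a reference
gene; the working scale everywhere downstream is ``-dCt =
Ct_ref - Ct_gene``, which increases monotonically with transcript
abundance. ROC/threshold-vote classification is invariant under monotone
transforms, so the choice between ``-dCt`` and ``2^-dCt`` does not affect
any classification output; thresholds stay in cycle units.

For discovery-stage RNA-seq counts the package works on log2 counts per
million; differential expression uses Welch's t-test per grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RESPONDER_CATEGORIES
from .errors import ValidationError
from .io import ClinicalTable

#: BOR groupings used in discovery; each maps to (group1, group2) label sets.
GROUPINGS: dict[str, tuple[frozenset, frozenset]] = {
    "PR_vs_PD": (frozenset({"PR"}), frozenset({"PD"})),
    "PR_vs_SDPD": (frozenset({"PR"}), frozenset({"SD", "PD"})),
    "PRSD_vs_PD": (frozenset({"PR", "SD"}), frozenset({"PD"})),
}


@dataclass(frozen=True)
class GroupStat:
    gene: str
    grouping: str
    log2_fc: float
    p_value: float
    test: str = "welch"


def delta_ct(table: ClinicalTable, reference_gene: str) -> pd.DataFrame:
    """Per-patient ``-dCt = Ct_ref - Ct_gene`` for every non-reference gene.

    Returns a patients-by-genes frame indexed by patient id. Missing
    marker Ct values propagate as NaN; a missing *reference* Ct is an
    error naming the patient.
    """
    if reference_gene not in table.genes:
        raise ValidationError(f"reference gene {reference_gene!r} not assayed")
    ref = table.ct(reference_gene)
    if ref.isna().any():
        missing = list(ref.index[ref.isna()])
        raise ValidationError(f"missing reference Ct for patients {missing}")
    out = {}
    for gene in table.genes:
        if gene == reference_gene:
            continue
        out[gene] = ref - table.ct(gene)
    return pd.DataFrame(out, index=ref.index)


def compare_raw_ct(table: ClinicalTable, gene: str, responder_def=RESPONDER_CATEGORIES) -> GroupStat:
    """Welch's t on *raw* Ct between responders and non-responders.

    Used to probe reference-gene behavior itself (raw Ct is lower when
    more template is present, so a raw-Ct shift flags differential total
    exosome load rather than a normalized expression change).
    """
    ct = table.ct(gene).to_numpy()
    resp = table.frame["bor"].isin(responder_def).to_numpy()
    a = ct[resp & ~np.isnan(ct)]
    b = ct[~resp & ~np.isnan(ct)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(f"gene {gene!r}: need >=2 measured patients per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupStat(gene=gene, grouping="responder_vs_nonresponder",
                     log2_fc=float(a.mean() - b.mean()), p_value=float(res.pvalue))


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """``log2(1e6 * count / library_size + 1)`` per column (sample)."""
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValidationError("counts must be non-negative")
    libsize = mat.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(counts.columns[libsize <= 0])
        raise ValidationError(f"zero library size in samples {bad}")
    cpm = 1e6 * mat / libsize
    return pd.DataFrame(np.log2(cpm + 1.0), index=counts.index, columns=counts.columns)


def _welch_by_gene(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sided p for genes-by-samples blocks; degenerate
    rows (no variance anywhere, equal means) yield p = 1."""
    res = stats.ttest_ind(g1, g2, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def group_logfc(expr: pd.DataFrame, labels: pd.Series, grouping: str) -> pd.DataFrame:
    """Per-gene log2 fold change (mean difference on the log2 scale) and
    Welch p for one BOR grouping of a genes-by-samples expression matrix."""
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}; expected one of {list(GROUPINGS)}")
    set1, set2 = GROUPINGS[grouping]
    lab = labels.reindex(expr.columns)
    m1 = lab.isin(set1).to_numpy()
    m2 = lab.isin(set2).to_numpy()
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValidationError(f"grouping {grouping!r} has an empty side")
    g1 = expr.to_numpy(dtype=float)[:, m1]
    g2 = expr.to_numpy(dtype=float)[:, m2]
    lfc = g1.mean(axis=1) - g2.mean(axis=1)
    if m1.sum() >= 2 and m2.sum() >= 2:
        p = _welch_by_gene(g1, g2)
    else:
        raise ValidationError(f"grouping {grouping!r}: need >=2 samples per side")
    return pd.DataFrame({"log2_fc": lfc, "p_value": p}, index=expr.index)
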