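"""Candidate-marker discovery filter.

A gene qualifies as a candidate BOR-predicting marker if it meets at least
one of four criteria on the discovery count matrix:

* C1 — differentially expressed (Welch p below ``de_alpha``) in any of the
  BOR groupings PR vs PD, PR vs SD/PD, PR/SD vs PD;
* C2 — absolute log2 fold change above ``lfc_cutoff`` in any grouping;
* C3 — per-gene ROC AUC above ``auc_cutoff``, where AUC1 is the larger of
  the PR-vs-PD and PR/SD-vs-PD AUCs and AUC2 the PR-vs-SD/PD AUC;
* C4 — membership of a literature allowlist of previously reported
  immune-checkpoint response markers.

Qualifiers are ranked by (number of criteria met, best AUC, smallest p,
gene symbol) and the top *k* are returned. The ranking rule is a declared
convention of this package: the union filter alone does not determine a
unique top-20 and no published rule exists to reconstruct.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import ValidationError
from .normalize import GROUPINGS, group_logfc

CRITERIA = ("C1", "C2", "C3", "C4")


def _auc_by_gene(expr: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise orientation-free AUC (max of AUC and 1-AUC) between two
    sample masks of a genes-by-samples matrix."""
    sub = expr[:, pos | neg]
    is_pos = pos[pos | neg]
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())
    ranks = stats.rankdata(sub, axis=1)
    auc = (ranks[:, is_pos].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return np.maximum(auc, 1.0 - auc)


def score_discovery_genes(
    expr: pd.DataFrame, bor_labels: pd.Series, config: AnalysisConfig
) -> pd.DataFrame:
    """Evaluate all four selection criteria per gene.

    Parameters
    ----------
    expr
        log2-CPM matrix, genes by samples.
    bor_labels
        BOR category per sample (must cover PR, SD and PD with >=2 each).
    config
        Supplies ``de_alpha``, ``lfc_cutoff``, ``auc_cutoff`` and the
        literature allowlist.

    Returns a frame indexed by gene with per-grouping ``p_*``/``lfc_*``
    columns, ``auc1``, ``auc2``, boolean ``c1``..``c4``, ``n_criteria``
    and a comma-joined ``criteria_met`` summary.
    """
    lab = bor_labels.reindex(expr.columns)
    for cat in ("PR", "SD", "PD"):
        if int((lab == cat).sum()) < 2:
            raise ValidationError(f"discovery requires >=2 samples in group {cat!r}")

    out = pd.DataFrame(index=expr.index)
    for name in GROUPINGS:
        res = group_logfc(expr, lab, name)
        out[f"p_{name}"] = res["p_value"]
        out[f"lfc_{name}"] = res["log2_fc"]

    mat = expr.to_numpy(dtype=float)
    pr = (lab == "PR").to_numpy()
    sd = (lab == "SD").to_numpy()
    pd_ = (lab == "PD").to_numpy()
    auc_pr_pd = _auc_by_gene(mat, pd_, pr)
    auc_prsd_pd = _auc_by_gene(mat, pd_, pr | sd)
    auc_pr_sdpd = _auc_by_gene(mat, sd | pd_, pr)
    out["auc1"] = np.maximum(auc_pr_pd, auc_prsd_pd)
    out["auc2"] = auc_pr_sdpd

    p_cols = [f"p_{g}" for g in GROUPINGS]
    lfc_cols = [f"lfc_{g}" for g in GROUPINGS]
    out["c1"] = (out[p_cols] < config.de_alpha).any(axis=1)
    out["c2"] = (out[lfc_cols].abs() > config.lfc_cutoff).any(axis=1)
    out["c3"] = (out["auc1"] > config.auc_cutoff) | (out["auc2"] > config.auc_cutoff)
    out["c4"] = out.index.isin(config.literature_allowlist)
    crit = out[["c1", "c2", "c3", "c4"]].to_numpy()
    out["n_criteria"] = crit.sum(axis=1)
    out["criteria_met"] = [
        ",".join(c for c, hit in zip(CRITERIA, row) if hit) for row in crit
    ]
    out["min_p"] = out[p_cols].min(axis=1)
    return out


def select_candidates(stats_frame: pd.DataFrame, k: int = 20) -> list[str]:
    """Rank qualifying genes and return the top ``k`` (all, if fewer).

    Deterministic ranking: criteria count desc, max(AUC1, AUC2) desc,
    smallest grouping p asc, gene symbol asc.
    """
    qual = stats_frame[stats_frame["n_criteria"] > 0].copy()
    if qual.empty:
        return []
    qual["best_auc"] = qual[["auc1", "auc2"]].max(axis=1)
    qual["gene"] = qual.index.astype(str)
    ranked = qual.sort_values(
        by=["n_criteria", "best_auc", "min_p", "gene"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return list(ranked.index[:k])
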