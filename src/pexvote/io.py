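"""Tabular input/output.

All exchange formats are plain text: comma-separated CSV (UTF-8, ``.``
decimal, mandatory header) for clinical/IHC/fraction/output tables and
tab-separated TSV for gene-by-sample count and TPM matrices. Raw qPCR
threshold-cycle columns are named ``<GENE>_ct``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

import numpy as np
import pandas as pd

from .config import AnalysisConfig, BOR_CATEGORIES, NON_RESPONDER_CATEGORIES
from .errors import ParseError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .combinations import CombinationResult

CT_SUFFIX = "_ct"
REQUIRED_CLINICAL_COLUMNS = ("patient_id", "bor", "nlr", "os_months", "os_event")


@dataclass
class ClinicalTable:
    """Validated part-1 clinical table.

    ``frame`` holds one row per patient with columns ``patient_id``, ``bor``,
    ``nlr``, ``os_months``, ``os_event`` and one ``<GENE>_ct`` column per
    assayed gene (reference gene included). Missing Ct values for
    non-reference genes are permitted and stored as NaN; downstream
    operations decide per-operation how to treat them.
    """

    frame: pd.DataFrame
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patient_ids(self) -> pd.Series:
        return self.frame["patient_id"]

    def ct(self, gene: str) -> pd.Series:
        """Raw Ct values for ``gene``, indexed by patient id."""
        col = gene + CT_SUFFIX
        if col not in self.frame.columns:
            raise SchemaError(f"no Ct column for gene {gene!r}")
        return pd.Series(
            self.frame[col].to_numpy(), index=self.frame["patient_id"].to_numpy(), name=gene
        )

    def nonresponder_labels(self) -> np.ndarray:
        """Boolean vector: True for SD/PD/NE (the ROC positive class)."""
        return self.frame["bor"].isin(NON_RESPONDER_CATEGORIES).to_numpy()


def _validate_clinical_frame(frame: pd.DataFrame, config: AnalysisConfig | None) -> ClinicalTable:
    for col in REQUIRED_CLINICAL_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"clinical table is missing required column {col!r}")
    ct_cols = [c for c in frame.columns if c.endswith(CT_SUFFIX)]
    if not ct_cols:
        raise SchemaError(f"clinical table has no {CT_SUFFIX!r}-suffixed Ct column")

    dup = frame["patient_id"][frame["patient_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate patient_id values: {sorted(set(dup))}")
    bad_bor = set(frame["bor"]) - set(BOR_CATEGORIES)
    if bad_bor:
        raise ValidationError(
            f"unknown BOR categories {sorted(bad_bor)}; expected one of {BOR_CATEGORIES}"
        )
    if (frame["os_months"] < 0).any():
        raise ValidationError("os_months must be non-negative")
    if not frame["os_event"].isin((0, 1)).all():
        raise ValidationError("os_event must be 0 or 1")
    if (frame["nlr"] < 0).any():
        raise ValidationError("nlr must be non-negative")

    for col in ct_cols:
        raw = frame[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric Ct in column {col!r} at row {row}")
        frame[col] = parsed.astype(float)

    if config is not None:
        ref_col = config.reference_gene + CT_SUFFIX
        if ref_col not in frame.columns:
            raise SchemaError(
                f"reference gene column {ref_col!r} required for delta-Ct normalization"
            )
    genes = tuple(c[: -len(CT_SUFFIX)] for c in ct_cols)
    return ClinicalTable(frame=frame.reset_index(drop=True), genes=genes)


def read_clinical_table(path: str | Path, config: AnalysisConfig | None = None) -> ClinicalTable:
    """Read and validate a part-1 clinical CSV.

    Raises :class:`SchemaError` for missing columns, :class:`ValidationError`
    for duplicate ids / unknown BOR strings, :class:`ParseError` for
    non-numeric Ct cells.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str, "bor": str})
    return _validate_clinical_frame(frame, config)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, index=False)
    return path


COMBINATION_COLUMNS = (
    "rank", "markers", "auc", "auc_ci_low", "auc_ci_high", "threshold",
    "sensitivity", "specificity", "ppv", "npv", "ppv_full", "npv_full",
)


def format_markers(markers: Iterable[str]) -> str:
    """Space-joined marker list, genes alphabetical with NLR last."""
    names = list(markers)
    genes = sorted(m for m in names if m != "NLR")
    return " ".join(genes + (["NLR"] if "NLR" in names else []))


def write_combination_table(results: "list[CombinationResult]", path: str | Path) -> Path:
    """Write ranked combination results in the published-table schema.

    One row per combination: rank, markers, AUC with its 95% CI, the
    selected score threshold, and confusion metrics at that threshold.
    Values are rounded to 3 decimals; ppv/npv additionally carry
    full-precision columns.
    """
    if not results:
        raise ValidationError("no combination results to write")
    rows = []
    for res in results:
        m = res.metrics
        rows.append({
            "rank": res.rank,
            "markers": format_markers(res.combination.markers),
            "auc": round(res.auc, 3),
            "auc_ci_low": round(res.auc_ci[0], 3),
            "auc_ci_high": round(res.auc_ci[1], 3),
            "threshold": round(m.threshold, 3),
            "sensitivity": round(m.sensitivity, 3),
            "specificity": round(m.specificity, 3),
            "ppv": round(m.ppv, 3) if m.ppv is not None else np.nan,
            "npv": round(m.npv, 3) if m.npv is not None else np.nan,
            "ppv_full": m.ppv if m.ppv is not None else np.nan,
            "npv_full": m.npv if m.npv is not None else np.nan,
        })
    frame = pd.DataFrame(rows, columns=COMBINATION_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_combination_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(COMBINATION_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"combination table missing columns {sorted(missing)}")
    return frame


# -- count / TPM matrices (genes x samples, TSV) --------------------------

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise SchemaError("count matrix is empty")
    return frame


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t")
    return path


read_tpm_tsv = read_counts_tsv
write_tpm_tsv = write_counts_tsv


def read_labels_csv(path: str | Path) -> pd.Series:
    """Sample -> BOR label table with columns ``sample_id,bor``."""
    frame = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "bor"):
        if col not in frame.columns:
            raise SchemaError(f"label table missing column {col!r}")
    bad = set(frame["bor"]) - set(BOR_CATEGORIES)
    if bad:
        raise ValidationError(f"unknown BOR categories {sorted(bad)}")
    return pd.Series(frame["bor"].to_numpy(), index=frame["sample_id"].to_numpy(), name="bor")


def write_labels_csv(labels: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": labels.index, "bor": labels.to_numpy()}).to_csv(path, index=False)
    return path


# -- part-2 side tables ----------------------------------------------------

def read_ihc_table(path: str | Path) -> pd.DataFrame:
    """IHC/CPS table: ``patient_id, ihc_hla_e (high|low), cps``."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("patient_id", "ihc_hla_e", "cps"):
        if col not in frame.columns:
            raise SchemaError(f"IHC table missing column {col!r}")
    bad = set(frame["ihc_hla_e"].dropna()) - {"high", "low"}
    if bad:
        raise ValidationError(f"ihc_hla_e must be 'high' or 'low', got {sorted(bad)}")
    return frame


def read_fraction_table(path: str | Path) -> pd.DataFrame:
    """Immune-fraction table: ``patient_id`` plus one column per cell type."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in frame.columns:
        raise SchemaError("fraction table missing column 'patient_id'")
    value_cols = [c for c in frame.columns if c != "patient_id"]
    vals = frame[value_cols].to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValidationError("immune fractions must lie in [0, 1]")
    return frame


def read_plasma_table(path: str | Path) -> pd.DataFrame:
    """Part-2 plasma table: ``patient_id, nlr`` plus ``<GENE>_ct`` columns."""
    frame = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("patient_id", "nlr"):
        if col not in frame.columns:
            raise SchemaError(f"plasma table missing column {col!r}")
    if not any(c.endswith(CT_SUFFIX) for c in frame.columns):
        raise SchemaError(f"plasma table has no {CT_SUFFIX!r}-suffixed column")
    return frame
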