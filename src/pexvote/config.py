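"""Run configuration: marker panel, directions, and analysis thresholds.

The pipeline classifies patients by best overall response (BOR) into
responders (CR/PR) and non-responders (SD/PD/NE) and builds directional
threshold-vote combinations of plasma-exosome mRNA markers plus the
neutrophil-to-lymphocyte ratio (NLR). ``AnalysisConfig`` carries every
tunable constant; defaults mirror the study design the package emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ValidationError

UNFAVORABLE = "unfavorable"  # elevated in non-responders; vote 1 when value > threshold
FAVORABLE = "favorable"      # elevated in responders; vote 1 when value < threshold
NLR_MARKER = "NLR"

BOR_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})
NON_RESPONDER_CATEGORIES = frozenset({"SD", "PD", "NE"})

#: Default validated marker panel with the direction of each marker's
#: association with non-response.
DEFAULT_MARKER_DIRECTIONS: dict[str, str] = {
    "HLA-E": UNFAVORABLE,
    "ACTB": UNFAVORABLE,
    "MPIG6B": UNFAVORABLE,
    "TNFRSF13C": UNFAVORABLE,
    "RABL2B": FAVORABLE,
    "ZNF480": FAVORABLE,
}

# Interferon-gamma response signatures used to score the tumor immune
# microenvironment. These are editable defaults drawn from the ICI
# biomarker literature, not a frozen claim about any particular cohort.
IFNG_SIGNATURE_6 = ("IDO1", "CXCL10", "CXCL9", "HLA-DRA", "STAT1", "IFNG")
IFNG_SIGNATURE_18 = (
    "CCL5", "CD27", "CD274", "CD276", "CD8A", "CMKLR1", "CXCL9", "CXCR6",
    "HLA-DQA1", "HLA-DRB1", "HLA-E", "IDO1", "LAG3", "NKG7", "PDCD1LG2",
    "PSMB10", "STAT1", "TIGIT",
)

#: Genes flagged as immune-checkpoint biomarker candidates in prior studies;
#: they pass the discovery filter regardless of cohort-level statistics.
DEFAULT_LITERATURE_ALLOWLIST = ("CD3D", "TCF7", "CTSW", "HLA-DRA", "HLA-DQA1", "HLA-E")


@dataclass
class AnalysisConfig:
    """All analysis constants in one validated record.

    Parameters
    ----------
    reference_gene
        qPCR reference gene for delta-Ct normalization.
    marker_directions
        Map of validated marker gene -> {"unfavorable", "favorable"}.
    nlr_included
        Whether the NLR joins the combination search as an extra
        unfavorable marker.
    combination_size_min, combination_size_max
        Subset sizes enumerated in the combination search. ``None`` for the
        maximum means "all available markers".
    top_k_combinations
        How many AUC-ranked combinations are reported.
    de_alpha, lfc_cutoff, auc_cutoff
        Discovery-filter constants: per-grouping Welch p-value cutoff,
        absolute log2 fold-change cutoff, and per-gene AUC cutoff.
    literature_allowlist
        Genes that qualify as discovery candidates on prior evidence alone.
    signature_gene_lists
        Named gene lists for tumor signature scoring (6- and 18-gene
        IFN-gamma signatures by default).
    rng_seed
        Seed governing every stochastic stage of a run.
    censor_horizon_months
        Administrative right-censoring horizon used by the simulator.
    """

    reference_gene: str = "GAPDH"
    marker_directions: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_DIRECTIONS)
    )
    nlr_included: bool = True
    combination_size_min: int = 2
    combination_size_max: int | None = None
    top_k_combinations: int = 10
    de_alpha: float = 0.05
    lfc_cutoff: float = 1.5
    auc_cutoff: float = 0.7
    literature_allowlist: tuple[str, ...] = DEFAULT_LITERATURE_ALLOWLIST
    signature_gene_lists: dict[str, list[str]] = field(
        default_factory=lambda: {
            "ifng_6": list(IFNG_SIGNATURE_6),
            "ifng_18": list(IFNG_SIGNATURE_18),
        }
    )
    rng_seed: int = 0
    censor_horizon_months: float = 36.0

    def __post_init__(self) -> None:
        for gene, direction in self.marker_directions.items():
            if direction not in (UNFAVORABLE, FAVORABLE):
                raise ValidationError(
                    f"marker {gene!r}: direction must be "
                    f"{UNFAVORABLE!r} or {FAVORABLE!r}, got {direction!r}"
                )
        n_rules = self.n_rules
        if self.combination_size_min < 1:
            raise ValidationError("combination_size_min must be >= 1")
        if self.combination_size_max is not None:
            if not (self.combination_size_min <= self.combination_size_max <= n_rules):
                raise ValidationError(
                    f"combination sizes must satisfy "
                    f"{self.combination_size_min} <= max <= {n_rules}"
                )
        if not 0.0 < self.de_alpha < 1.0:
            raise ValidationError("de_alpha must be in (0, 1)")
        if self.lfc_cutoff < 0:
            raise ValidationError("lfc_cutoff must be non-negative")
        if not 0.5 < self.auc_cutoff < 1.0:
            raise ValidationError("auc_cutoff must be in (0.5, 1)")
        if self.censor_horizon_months < 0:
            raise ValidationError("censor_horizon_months must be >= 0")

    @property
    def marker_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.marker_directions))

    @property
    def n_rules(self) -> int:
        """Number of candidate marker rules (genes plus NLR if included)."""
        return len(self.marker_directions) + (1 if self.nlr_included else 0)

    @property
    def resolved_size_max(self) -> int:
        return self.combination_size_max if self.combination_size_max is not None else self.n_rules

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["literature_allowlist"] = list(self.literature_allowlist)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "literature_allowlist" in raw:
            raw["literature_allowlist"] = tuple(raw["literature_allowlist"])
        return cls(**raw)
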