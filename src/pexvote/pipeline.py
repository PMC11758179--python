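"""End-to-end orchestration of the part-1 and part-2 analyses.

Part 1: delta-Ct normalization -> per-marker ROC thresholds -> exhaustive
combination search -> survival stratification of every reported
combination (Kaplan-Meier, log-rank, Cox). The combination with the
highest hazard ratio is frozen (per-marker thresholds plus the score cut)
for later application.

Part 2: the frozen combination labels the treatment-naive paired cohort,
then plasma-vs-tumor Pearson correlations, IHC concordance, median-split
Mann-Whitney comparisons of immune fractions, and IFN-gamma signature
comparisons are computed.

Every run emits a manifest with the config snapshot, seed, per-stage row
counts and explicit exclusion reasons; row arithmetic balances per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combinations import (
    Combination,
    CombinationResult,
    MarkerRule,
    SCORE_HIGH,
    apply_frozen_combination,
    fit_marker_rules,
    marker_matrix,
    rank_combinations,
)
from .config import NLR_MARKER, AnalysisConfig
from .errors import ValidationError
from .io import (
    CT_SUFFIX,
    ClinicalTable,
    format_markers,
    write_combination_table,
)
from .simulate import Part2Tables
from .survival import cox_binary, km_estimator, logrank_test, survival_at
from .time_corr import (
    HIGH,
    ifng_signature_score,
    ihc_concordance,
    mann_whitney_u,
    median_split,
    pearson_test,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    stage: str
    seed: int
    package_version: str
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)
    output_paths: dict[str, str] = field(default_factory=dict)

    def check_balance(self) -> None:
        """input = analyzed + excluded, whenever all three are recorded."""
        rc = self.row_counts
        if {"input", "analyzed", "excluded"} <= set(rc):
            if rc["input"] != rc["analyzed"] + rc["excluded"]:
                raise ValidationError(
                    f"manifest imbalance: {rc['input']} != "
                    f"{rc['analyzed']} + {rc['excluded']}"
                )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class FrozenCombination:
    """A combination with frozen per-marker thresholds and score cut."""

    combination: Combination
    score_threshold: float

    def to_dict(self) -> dict:
        return {
            "score_threshold": self.score_threshold,
            "rules": [
                {"marker": r.marker, "direction": r.direction, "threshold": r.threshold}
                for r in self.combination.rules
            ],
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "FrozenCombination":
        rules = tuple(MarkerRule(**r) for r in d["rules"])
        return cls(combination=Combination(rules=rules),
                   score_threshold=float(d["score_threshold"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "FrozenCombination":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SurvivalSummary:
    markers: str
    threshold: float
    n_high: int
    n_low: int
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    wald_p: float
    os24_high: float | None
    os24_low: float | None


@dataclass
class Part1Result:
    rules: list[MarkerRule]
    combinations: list[CombinationResult]
    survival: list[SurvivalSummary]
    frozen: FrozenCombination
    manifest: RunManifest


def _survival_for_combination(
    res: CombinationResult, values: pd.DataFrame, table: ClinicalTable
) -> SurvivalSummary | None:
    labels = apply_frozen_combination(res.combination, res.metrics.threshold, values)
    frame = table.frame.set_index("patient_id").loc[labels.index]
    high = (labels == SCORE_HIGH).to_numpy()
    if high.all() or (~high).all():
        return None
    t = frame["os_months"].to_numpy()
    e = frame["os_event"].to_numpy()
    lr = logrank_test(t, e, high)
    cox = cox_binary(t, e, high)
    km_high = km_estimator(t[high], e[high])
    km_low = km_estimator(t[~high], e[~high])
    return SurvivalSummary(
        markers=format_markers(res.combination.markers),
        threshold=res.metrics.threshold,
        n_high=int(high.sum()), n_low=int((~high).sum()),
        logrank_chi2=lr.chi2, logrank_p=lr.p,
        hr=cox.hr, hr_ci=cox.ci95, wald_p=cox.wald_p,
        os24_high=survival_at(km_high, 24.0),
        os24_low=survival_at(km_low, 24.0),
    )


def run_part1(
    table: ClinicalTable, config: AnalysisConfig, outdir: str | Path | None = None
) -> Part1Result:
    """Run the full part-1 pipeline on a clinical table."""
    values = marker_matrix(table, config)
    complete = values.notna().all(axis=1)
    exclusions = [
        {"patient_id": pid, "reason": "missing_marker_measurement"}
        for pid in values.index[~complete]
    ]

    rules = fit_marker_rules(table, config)
    combos = rank_combinations(table, rules, config)
    if not combos:
        raise ValidationError("combination search returned no rankable combination")

    survival_rows = []
    for res in combos:
        summary = _survival_for_combination(res, values, table)
        if summary is None:
            logger.warning("combination %s: single survival stratum, skipped",
                           format_markers(res.combination.markers))
            continue
        survival_rows.append(summary)
    if not survival_rows:
        raise ValidationError("no combination produced two survival strata")

    # adopt the combination with the highest hazard ratio (ties: lower p)
    best = max(survival_rows, key=lambda s: (s.hr, -s.wald_p))
    best_res = next(
        r for r in combos if format_markers(r.combination.markers) == best.markers
    )
    frozen = FrozenCombination(
        combination=best_res.combination, score_threshold=best_res.metrics.threshold
    )

    manifest = RunManifest(
        stage="part1", seed=config.rng_seed, package_version=__version__,
        config=config.to_dict(),
        row_counts={
            "input": len(table),
            "analyzed": int(complete.sum()),
            "excluded": int((~complete).sum()),
            "combinations_enumerated": sum(
                1 for _ in _enumerate_count(config)
            ),
            "combinations_reported": len(combos),
        },
        exclusions=exclusions,
    )
    manifest.check_balance()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "combinations": outdir / "combinations.csv",
            "km": outdir / "km.csv",
            "tests": outdir / "tests.json",
            "frozen": outdir / "frozen_combination.json",
            "manifest": outdir / "manifest_part1.json",
        }
        write_combination_table(combos, paths["combinations"])
        _write_km_csv(best_res, values, table, paths["km"])
        paths["tests"].write_text(json.dumps(
            [asdict(s) for s in survival_rows], indent=2))
        frozen.to_json(paths["frozen"])
        manifest.output_paths = {k: str(v) for k, v in paths.items()}
        manifest.to_json(paths["manifest"])

    return Part1Result(rules=rules, combinations=combos,
                       survival=survival_rows, frozen=frozen, manifest=manifest)


def _enumerate_count(config: AnalysisConfig):
    from math import comb as _comb
    n = config.n_rules
    for size in range(config.combination_size_min, config.resolved_size_max + 1):
        for _ in range(_comb(n, size)):
            yield size


def _write_km_csv(
    res: CombinationResult, values: pd.DataFrame, table: ClinicalTable, path: Path
) -> None:
    labels = apply_frozen_combination(res.combination, res.metrics.threshold, values)
    frame = table.frame.set_index("patient_id").loc[labels.index]
    rows = []
    for stratum in (SCORE_HIGH, "score_low"):
        mask = (labels == stratum).to_numpy()
        if not mask.any():
            continue
        curve = km_estimator(frame["os_months"].to_numpy()[mask],
                             frame["os_event"].to_numpy()[mask])
        for t, s, se, nr, ne in zip(curve.event_times, curve.survival,
                                    curve.greenwood_se, curve.n_at_risk, curve.n_events):
            rows.append({"stratum": stratum, "time_months": t, "survival": s,
                         "greenwood_se": se, "n_at_risk": nr, "n_events": ne})
    pd.DataFrame(rows).to_csv(path, index=False)


# -- part 2 ---------------------------------------------------------------

def part2_marker_matrix(plasma: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Patients-by-markers matrix (-dCt plus NLR) from a part-2 plasma table."""
    ref_col = config.reference_gene + CT_SUFFIX
    if ref_col not in plasma.columns:
        raise ValidationError(f"plasma table lacks reference column {ref_col!r}")
    idx = plasma["patient_id"].to_numpy()
    out = {}
    for gene in config.marker_genes:
        col = gene + CT_SUFFIX
        if col not in plasma.columns:
            raise ValidationError(f"plasma table lacks column {col!r}")
        out[gene] = plasma[ref_col].to_numpy() - plasma[col].to_numpy()
    mat = pd.DataFrame(out, index=idx)
    if config.nlr_included:
        mat[NLR_MARKER] = plasma["nlr"].to_numpy()
    return mat


def run_part2(
    tables: Part2Tables,
    frozen: FrozenCombination,
    config: AnalysisConfig,
    outdir: str | Path | None = None,
) -> dict:
    """Apply the frozen part-1 combination and compute TIME statistics."""
    if frozen is None:
        raise ValidationError("run_part2 requires a frozen part-1 combination")
    values = part2_marker_matrix(tables.plasma, config)
    labels = apply_frozen_combination(frozen.combination, frozen.score_threshold, values)
    report: dict = {
        "n_patients": int(len(tables.plasma)),
        "signature_counts": labels.value_counts().to_dict(),
        "frozen": frozen.to_dict(),
    }

    tumor_log2 = np.log2(tables.tumor_tpm + 1.0)
    paired = [p for p in tumor_log2.columns if p in values.index]
    report["n_with_tumor_expression"] = len(paired)
    corr = {}
    for gene in config.marker_genes:
        if gene not in tumor_log2.index:
            continue
        x = values.loc[paired, gene].to_numpy()
        y = tumor_log2.loc[gene, paired].to_numpy()
        r, p = pearson_test(x, y)
        corr[gene] = {"r": r, "p": p, "n": len(paired)}
    report["plasma_tumor_pearson"] = corr

    ihc_series = pd.Series(tables.ihc["ihc_hla_e"].to_numpy(),
                           index=tables.ihc["patient_id"].to_numpy())
    ihc_table, ihc_p = ihc_concordance(ihc_series, values["HLA-E"])
    report["ihc_concordance"] = {
        "table": ihc_table.to_dict(), "fisher_p": ihc_p,
        "n": int(ihc_table.to_numpy().sum()),
    }

    if tables.fractions.empty:
        logger.warning("empty immune-fraction table; fraction stage skipped")
        report["fractions"] = None
    else:
        frac = tables.fractions.set_index("patient_id")
        split = median_split(values.loc[frac.index, "HLA-E"])
        comparisons = {}
        for cell_type in frac.columns:
            a = frac.loc[split.index[split == HIGH], cell_type].to_numpy()
            b = frac.loc[split.index[split != HIGH], cell_type].to_numpy()
            u, p = mann_whitney_u(a, b)
            comparisons[cell_type] = {
                "U": u, "p": p,
                "mean_high": float(a.mean()), "mean_low": float(b.mean()),
            }
        report["fractions"] = {
            "split_counts": split.value_counts().to_dict(),
            "mann_whitney": comparisons,
        }

    signatures = {}
    for name, gene_list in config.signature_gene_lists.items():
        scores = ifng_signature_score(tables.tumor_tpm, gene_list, name)
        split = median_split(values.loc[scores.index, "HLA-E"])
        a = scores[split.index[split == HIGH]].to_numpy()
        b = scores[split.index[split != HIGH]].to_numpy()
        u, p = mann_whitney_u(a, b)
        signatures[name] = {"U": u, "p": p,
                            "mean_high": float(a.mean()), "mean_low": float(b.mean())}
    report["ifng_signatures"] = signatures

    manifest = RunManifest(
        stage="part2", seed=config.rng_seed, package_version=__version__,
        config=config.to_dict(),
        row_counts={
            "input": int(len(tables.plasma)),
            "analyzed": int(len(labels)),
            "excluded": int(len(tables.plasma) - len(labels)),
        },
    )
    manifest.check_balance()
    report["manifest"] = asdict(manifest)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out = outdir / "part2_report.json"
        out.write_text(json.dumps(report, indent=2, default=float))
        manifest.output_paths["report"] = str(out)
        manifest.to_json(outdir / "manifest_part2.json")
    return report
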