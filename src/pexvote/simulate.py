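"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a 104-patient immunotherapy cohort: best overall
response (BOR) drawn with mix CR/PR/SD/PD/NE = 7/12/25/55/5, marker
-dCt values shifted between responders and non-responders, NLR lognormal
by response class, and exponential survival per BOR class with a frailty
term coupling marker burden to hazard, censored administratively. A
discovery-stage count matrix (lognormal-Poisson) and a 20-patient paired
treatment-naive tumor/plasma cohort round out the inputs every pipeline
stage needs.

Defaults are a stated world, chosen once: marker shifts give per-marker
AUCs around 0.59-0.73 and the NLR about 0.59, matching the published
per-marker discrimination range; hazards reproduce the published survival
ordering by BOR (responders near 90% 2-year OS, SD about 49% at 20
months, PD about 21% at 2 years, NE rapidly fatal). See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    BOR_CATEGORIES,
    IFNG_SIGNATURE_18,
    IFNG_SIGNATURE_6,
    NON_RESPONDER_CATEGORIES,
)
from .errors import ValidationError
from .io import CT_SUFFIX, ClinicalTable

#: Shift of the -dCt mean from responders to non-responders, in cycles;
#: positive = unfavorable marker (higher in non-responders).
DEFAULT_MARKER_EFFECTS: dict[str, float] = {
    "HLA-E": 1.2,
    "ACTB": 0.9,
    "MPIG6B": 0.8,
    "TNFRSF13C": 0.8,
    "RABL2B": -0.9,
    "ZNF480": -0.8,
}

#: Responder-class mean -dCt per marker (markers are less abundant than
#: the reference transcript, hence negative).
DEFAULT_MARKER_BASELINES: dict[str, float] = {
    "HLA-E": -6.0,
    "ACTB": -1.5,
    "MPIG6B": -7.0,
    "TNFRSF13C": -6.5,
    "RABL2B": -5.5,
    "ZNF480": -8.0,
}

#: Exponential hazard per BOR class (month^-1). Anchors: SD ~49% OS at 20
#: months, PD ~21% at 24 months, NE rapidly fatal, responders >85% at 2 y.
DEFAULT_SURVIVAL_HAZARDS: dict[str, float] = {
    "CR": 0.002, "PR": 0.004, "SD": 0.035, "PD": 0.066, "NE": 0.5,
}

DEFAULT_BOR_PROBS = (7 / 104, 12 / 104, 25 / 104, 55 / 104, 5 / 104)

#: (mean, sd) of log NLR per response class; shift tuned for AUC ~0.59.
DEFAULT_NLR_LOGNORMAL = {"responder": (1.10, 0.5), "non_responder": (1.28, 0.5)}

PART2_CELL_TYPES = (
    "NK_activated", "NK_resting", "CD8_T", "CD4_T_memory",
    "Macrophage_M1", "Macrophage_M2", "B_naive", "Treg",
)


@dataclass
class SimulationSpec:
    """Full description of the simulated world."""

    n_patients: int = 104
    bor_probs: tuple[float, ...] = DEFAULT_BOR_PROBS
    marker_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_EFFECTS))
    marker_baselines: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_BASELINES))
    marker_sd: float = 1.5
    nlr_lognormal_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NLR_LOGNORMAL))
    survival_hazards: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL_HAZARDS))
    score_frailty: float = 0.6
    censor_horizon_months: float = 36.0
    reference_gene: str = "GAPDH"
    reference_ct_mean: float = 25.0
    reference_ct_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if len(self.bor_probs) != len(BOR_CATEGORIES):
            raise ValidationError(f"bor_probs must have {len(BOR_CATEGORIES)} entries")
        if abs(sum(self.bor_probs) - 1.0) > 1e-12:
            raise ValidationError("bor_probs must sum to 1 within 1e-12")
        if min(self.bor_probs) < 0:
            raise ValidationError("bor_probs must be non-negative")
        if self.marker_sd <= 0:
            raise ValidationError("marker_sd must be positive")
        for cat in BOR_CATEGORIES:
            if self.survival_hazards.get(cat, 0) <= 0:
                raise ValidationError(f"hazard for {cat!r} must be positive")
        if self.censor_horizon_months < 0:
            raise ValidationError("censor_horizon_months must be >= 0")
        for gene in self.marker_effects:
            self.marker_baselines.setdefault(gene, -6.0)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.marker_effects))

    @property
    def p_nonresponder(self) -> float:
        probs = dict(zip(BOR_CATEGORIES, self.bor_probs))
        return sum(probs[c] for c in NON_RESPONDER_CATEGORIES)


def simulate_part1_cohort(spec: SimulationSpec) -> ClinicalTable:
    """Generate the part-1 clinical table.

    -dCt per marker is normal with a class-dependent mean; raw Ct is
    reconstructed as ``Ct_gene = Ct_ref - (-dCt)`` with a per-patient
    reference Ct. Survival is exponential per BOR class, scaled by
    ``exp(score_frailty * standardized marker burden)`` so that patients
    with a high true marker burden die earlier, then censored
    administratively at the horizon. Bit-identical given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    bor = rng.choice(BOR_CATEGORIES, size=n, p=np.asarray(spec.bor_probs))
    nonresp = np.isin(bor, list(NON_RESPONDER_CATEGORIES))

    neg_dct = {}
    burden_parts = []
    for gene in spec.genes:
        eff = spec.marker_effects[gene]
        base = spec.marker_baselines[gene]
        mean = base + eff * nonresp
        vals = rng.normal(mean, spec.marker_sd)
        neg_dct[gene] = vals
        # direction-aligned standardized deviation from the mixture mean
        mix_mean = base + eff * spec.p_nonresponder
        burden_parts.append(np.sign(eff) * (vals - mix_mean) / spec.marker_sd)
    burden = np.mean(burden_parts, axis=0) if burden_parts else np.zeros(n)

    mu_r, sd_r = spec.nlr_lognormal_params["responder"]
    mu_n, sd_n = spec.nlr_lognormal_params["non_responder"]
    nlr = np.where(nonresp, rng.lognormal(mu_n, sd_n, n), rng.lognormal(mu_r, sd_r, n))

    rates = np.array([spec.survival_hazards[b] for b in bor])
    rates = rates * np.exp(spec.score_frailty * burden)
    t_death = rng.exponential(1.0 / rates)
    horizon = spec.censor_horizon_months
    os_event = (t_death <= horizon).astype(int)
    os_months = np.minimum(t_death, horizon)

    ct_ref = rng.normal(spec.reference_ct_mean, spec.reference_ct_sd, n)
    frame = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "bor": bor,
        "nlr": nlr,
        "os_months": os_months,
        "os_event": os_event,
        spec.reference_gene + CT_SUFFIX: ct_ref,
    })
    for gene in spec.genes:
        frame[gene + CT_SUFFIX] = ct_ref - neg_dct[gene]
    genes = (spec.reference_gene,) + spec.genes
    return ClinicalTable(frame=frame, genes=genes)


def simulate_discovery_counts(
    spec: SimulationSpec,
    n_genes: int = 500,
    n_samples: int = 17,
    planted_log2fc: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Lognormal-Poisson count matrix with PR/SD/PD labels.

    Samples split PR/SD/PD in the proportions 6/5/6. Planted genes get the
    stated log2 fold change applied to the PR group (so PR-vs-PD and
    PR-vs-SD/PD groupings carry signal). Library sizes vary by more than
    two-fold across samples.
    """
    if n_samples < 3:
        raise ValidationError("need at least one sample per BOR group")
    rng = np.random.default_rng(spec.seed)
    base = np.array([6, 5, 6]) / 17
    sizes = np.maximum(1, np.round(base * n_samples).astype(int))
    while sizes.sum() > n_samples:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_samples:
        sizes[np.argmin(sizes)] += 1
    labels = np.repeat(["PR", "SD", "PD"], sizes)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    planted = planted_log2fc or {}
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValidationError(f"planted genes outside the universe: {sorted(unknown)}")

    log_mu = rng.normal(np.log(100.0), 1.0, size=n_genes)
    # library-size factors spanning a 3-fold range (log-uniform)
    lib = np.exp(rng.uniform(np.log(0.6), np.log(1.8), size=n_samples))
    shift = np.zeros((n_genes, n_samples))
    pr_mask = labels == "PR"
    for gene, lfc in planted.items():
        shift[genes.index(gene), pr_mask] = lfc * np.log(2.0)
    noise = rng.normal(0.0, 0.4, size=(n_genes, n_samples))
    lam = np.exp(log_mu[:, None] + shift + noise) * lib[None, :]
    counts = rng.poisson(lam)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    return (
        pd.DataFrame(counts, index=genes, columns=sample_ids),
        pd.Series(labels, index=sample_ids, name="bor"),
    )


@dataclass
class Part2Tables:
    """Paired treatment-naive cohort: plasma qPCR + NLR, tumor TPM
    (subset of patients), IHC/CPS calls, and immune fractions."""

    plasma: pd.DataFrame      # patient_id, nlr, <GENE>_ct columns
    tumor_tpm: pd.DataFrame   # genes x patients with tumor expression
    ihc: pd.DataFrame         # patient_id, ihc_hla_e, cps
    fractions: pd.DataFrame   # patient_id + one column per cell type

    @property
    def patients_with_tumor_expression(self) -> list[str]:
        return list(self.tumor_tpm.columns)


def simulate_part2_cohort(
    spec: SimulationSpec,
    n: int = 20,
    rho_hla_e: float = 0.7,
    n_missing_tumor: int = 3,
    naive_shift: float = 4.0,
) -> Part2Tables:
    """Generate the paired part-2 cohort.

    Plasma HLA-E -dCt and tumor HLA-E expression share a latent bivariate
    normal with population correlation ``rho_hla_e``. The IHC protein
    call thresholds a noisy tumor latent. The activated-NK fraction mean
    is elevated in the high-tumor-HLA-E half. All marker means carry a
    favorable treatment-naive shift of ``naive_shift`` cycles relative to
    part-1 responders, so frozen part-1 combinations score these patients
    low. ``n_missing_tumor`` patients lack tumor expression.
    """
    if not -1.0 <= rho_hla_e <= 1.0:
        raise ValidationError("rho_hla_e must lie in [-1, 1]")
    if n < 4:
        raise ValidationError("part-2 cohort needs n >= 4")
    if not 0 <= n_missing_tumor < n:
        raise ValidationError("n_missing_tumor must be in [0, n)")
    rng = np.random.default_rng(spec.seed)
    patients = [f"Q{i + 1:03d}" for i in range(n)]

    z_plasma = rng.standard_normal(n)
    z_indep = rng.standard_normal(n)
    z_tumor = rho_hla_e * z_plasma + np.sqrt(1.0 - rho_hla_e ** 2) * z_indep

    neg_dct = {}
    for gene in spec.genes:
        eff = spec.marker_effects[gene]
        base = spec.marker_baselines[gene]
        fav_mean = base - np.sign(eff) * naive_shift
        if gene == "HLA-E":
            neg_dct[gene] = fav_mean + spec.marker_sd * z_plasma
        else:
            neg_dct[gene] = rng.normal(fav_mean, spec.marker_sd, n)

    # treatment-naive inflammation well below even the responder class
    mu_r, sd_r = spec.nlr_lognormal_params["responder"]
    nlr = rng.lognormal(mu_r - 0.8, sd_r, n)
    ct_ref = rng.normal(spec.reference_ct_mean, spec.reference_ct_sd, n)
    plasma = pd.DataFrame({"patient_id": patients, "nlr": nlr,
                           spec.reference_gene + CT_SUFFIX: ct_ref})
    for gene in spec.genes:
        plasma[gene + CT_SUFFIX] = ct_ref - neg_dct[gene]

    # tumor TPM: marker genes + signature genes + filler
    signature_genes = sorted(set(IFNG_SIGNATURE_6) | set(IFNG_SIGNATURE_18))
    filler = [f"T{i:04d}" for i in range(40)]
    tumor_genes = sorted(set(spec.genes) | set(signature_genes)) + filler
    log2_tpm = rng.normal(4.0, 1.5, size=(len(tumor_genes), n))
    hla_idx = tumor_genes.index("HLA-E")
    log2_tpm[hla_idx] = 5.0 + 1.5 * z_tumor
    tpm = np.power(2.0, log2_tpm)
    missing = list(rng.choice(patients, size=n_missing_tumor, replace=False))
    kept = [p for p in patients if p not in missing]
    tumor_tpm = pd.DataFrame(tpm, index=tumor_genes, columns=patients)[kept]

    ihc_latent = z_tumor + rng.normal(0.0, 0.5, n)
    ihc = pd.DataFrame({
        "patient_id": patients,
        "ihc_hla_e": np.where(ihc_latent > 0, "high", "low"),
        "cps": np.round(rng.gamma(2.0, 10.0, n), 1),
    })

    # immune fractions only for patients with tumor RNA (deconvolution input)
    z_kept = z_tumor[[patients.index(p) for p in kept]]
    high_half = z_kept >= np.median(z_kept)
    raw = rng.gamma(2.0, 1.0, size=(len(kept), len(PART2_CELL_TYPES)))
    nk_col = PART2_CELL_TYPES.index("NK_activated")
    raw[:, nk_col] = rng.gamma(2.0, 1.0, len(kept)) + 3.0 * high_half
    raw = raw / raw.sum(axis=1, keepdims=True) * 0.6  # immune compartment share
    fractions = pd.DataFrame(raw, columns=PART2_CELL_TYPES)
    fractions.insert(0, "patient_id", kept)
    return Part2Tables(plasma=plasma, tumor_tpm=tumor_tpm, ihc=ihc, fractions=fractions)


def write_part2_tables(tables: Part2Tables, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plasma": outdir / "part2_plasma.csv",
        "tumor_tpm": outdir / "part2_tumor_tpm.tsv",
        "ihc": outdir / "part2_ihc.csv",
        "fractions": outdir / "part2_fractions.csv",
    }
    tables.plasma.to_csv(paths["plasma"], index=False)
    tables.tumor_tpm.to_csv(paths["tumor_tpm"], sep="\t")
    tables.ihc.to_csv(paths["ihc"], index=False)
    tables.fractions.to_csv(paths["fractions"], index=False)
    return paths
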