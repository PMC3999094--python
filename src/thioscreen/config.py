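"""Configuration objects for simulation and pipeline runs.

All randomness in the package flows through seeds held in these configs;
identical configs reproduce identical outputs byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

GENIC_REGIONS = ("3UTR", "5UTR", "CDS", "exon", "intron")
REGION_CLASSES = GENIC_REGIONS + ("intergenic",)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic cohort generators.

    Defaults mirror the in-vitro panel (30 lymphoblastoid cell lines) and
    the clinical cohort (38 patients) the analysis is designed around.

    Parameters
    ----------
    seed : int
        Base seed; every generator stream is derived from it.
    n_lines : int
        Number of lymphoblastoid cell lines in the exposure panel.
    n_patients : int
        Number of patients in the clinical cohort.
    n_snps : int
        Size of the simulated SNP panel.
    maf : float
        Minor-allele frequency, in (0, 0.5]; genotypes are drawn under
        Hardy-Weinberg equilibrium.
    n_eai_snps : int
        Number of SNPs with a planted cis-acting drug-induced expression
        allelic imbalance.
    eai_effect : float
        Fold-change (>= 1) applied to one allele's premature-RNA signal
        under drug exposure at planted EAI SNPs in heterozygous lines.
    n_clinical_snps : int
        Number of SNPs with a planted additive effect on the patient
        6-TGN/AZA risk ratio.
    n_shared_planted : int
        Number of SNP ids forced to be in both planted sets (EAI and
        clinical), to exercise the intersection stage.
    beta_risk : float
        Additive risk-ratio increment per genotype code unit (AA=0, AB=1,
        BB=2) at planted clinical SNPs.
    risk_baseline : float
        Baseline latent risk ratio (6-TGN pmol/8x10^8 RBCs per mg/day AZA).
    risk_noise_sd : float
        SD of additive Gaussian noise on the latent risk ratio.
    signal_mu, signal_sigma : float
        Log-scale location/scale of the lognormal baseline allele signal.
    noise_sigma : float
        Log-scale SD of the multiplicative lognormal measurement noise on
        every allele signal.
    background : float
        Mean background signal reported for the allele absent from a
        homozygous genotype (array probes report nonzero background).
    dropout_rate : float
        Probability a (line, SNP, condition) probe is flagged Absent.
    nocall_rate : float
        Probability a genotype call is NoCall.
    mcv_rho, wbc_rho : float
        Target correlations of MCV (positive) and WBC (negative) with the
        6-TGN concentration in simulated patients.
    """

    seed: int
    n_lines: int = 30
    n_patients: int = 38
    n_snps: int = 200
    maf: float = 0.3
    n_eai_snps: int = 20
    eai_effect: float = 4.0
    n_clinical_snps: int = 5
    n_shared_planted: int = 0
    beta_risk: float = 2.6
    risk_baseline: float = 4.0
    risk_noise_sd: float = 1.5
    signal_mu: float = 6.0
    signal_sigma: float = 0.8
    noise_sigma: float = 0.3
    background: float = 5.0
    dropout_rate: float = 0.02
    nocall_rate: float = 0.01
    mcv_rho: float = 0.7
    wbc_rho: float = -0.5

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_patients", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("n_eai_snps", "n_clinical_snps", "n_shared_planted"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a nonnegative count")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.eai_effect < 1.0:
            raise ValueError("eai_effect must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not (0.0 <= self.nocall_rate < 1.0):
            raise ValueError("nocall_rate must lie in [0, 1)")
        if self.n_eai_snps > self.n_snps or self.n_clinical_snps > self.n_snps:
            raise ValueError("planted SNP counts cannot exceed n_snps")
        if self.n_shared_planted > min(self.n_eai_snps, self.n_clinical_snps):
            raise ValueError("n_shared_planted cannot exceed either planted set")
        if self.signal_sigma < 0 or self.noise_sigma < 0 or self.risk_noise_sd < 0:
            raise ValueError("scale parameters must be nonnegative")
        if self.background <= 0:
            raise ValueError("background must be positive")
        if not isinstance(self.seed, int):
            raise TypeError("seed must be an integer")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and mode flags for a full simulate -> analyse run.

    Defaults are the published decision rules: clinical r^2 >= 0.4 with
    p < 0.01, per-line EAI ratio >= 2, cohort test at p < 0.01 with >= 3
    heterozygous lines and >= 2-fold imbalance, 5-ASA exclusion below
    2000 mg/day, and each genotype class observed in >= 2 samples.
    """

    seed: int
    sim: SimConfig | None = None
    r2_min: float = 0.4
    alpha_clinical: float = 0.01
    threshold_on: str = "r2"
    min_dose: float = 2000.0
    min_per_class: int = 2
    eai_threshold: float = 2.0
    alpha_eai: float = 0.01
    min_het: int = 3
    fold_min: float = 2.0
    fold_rule: str = "drug_abs"
    up_min: float = 2.0
    down_max: float = 0.5
    norm_target: float = 100.0
    integrate_mode: str = "either"

    def __post_init__(self) -> None:
        for name in ("r2_min", "eai_threshold", "fold_min", "up_min", "down_max",
                     "norm_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_clinical", "alpha_eai"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_dose < 0:
            raise ValueError("min_dose must be nonnegative")
        if self.min_per_class < 0 or self.min_het < 0:
            raise ValueError("count thresholds must be nonnegative")
        if self.threshold_on not in ("r2", "abs_r"):
            raise ValueError("threshold_on must be 'r2' or 'abs_r'")
        if self.fold_rule not in ("drug_abs", "ratio_of_ratios"):
            raise ValueError("fold_rule must be 'drug_abs' or 'ratio_of_ratios'")
        if self.integrate_mode not in ("any_line", "cohort_responsive", "either"):
            raise ValueError("integrate_mode must be any_line|cohort_responsive|either")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        """Build from a parsed config mapping; unknown keys are rejected."""
        data = dict(mapping)
        sim_data = data.pop("sim", None)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = None
        if sim_data is not None:
            sim_known = {f.name for f in fields(SimConfig)}
            sim_unknown = set(sim_data) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            sim = SimConfig(**sim_data)
        return cls(sim=sim, **data)
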