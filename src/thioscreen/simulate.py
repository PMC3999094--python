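"""Synthetic cohort generators.

Emulates the four data sources the biomarker screen consumes: genotype-call
tables for a cell-line panel and a patient cohort, allele-resolved
premature-RNA signals under vehicle and drug exposure, probe-level total
mRNA signals, and a clinical table (drug doses, 6-TGN metabolite level,
optional haematology).  Planted effects — cis-acting drug-induced expression
allelic imbalance in heterozygous lines, and additive genotype effects on
the patient 6-TGN/AZA risk ratio — provide a truth set for testing every
downstream stage.

Noise on array intensities is multiplicative lognormal: intensities are
positive and right-skewed, and the imbalance statistics are ratios, so
log-scale noise is the natural model.  Genotypes are drawn under
Hardy-Weinberg equilibrium at a single configured minor-allele frequency;
no linkage disequilibrium is simulated.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GENIC_REGIONS, REGION_CLASSES, SimConfig

CONDITIONS = ("vehicle", "drug")

# fixed stream offsets so each generator draws from an independent stream
_PANEL, _GENO, _SIGNAL, _PATIENT, _PROBE = 5, 11, 13, 17, 23


def _rng(config: SimConfig, stream: int, tag: str = "") -> np.random.Generator:
    key = [config.seed, stream]
    if tag:
        key.append(zlib.crc32(tag.encode()) & 0x7FFFFFFF)
    return np.random.default_rng(key)


@dataclass(frozen=True)
class TruthSet:
    """Planted-effect SNP ids; consumed only by tests and reports."""

    eai_snp_ids: frozenset[str]
    clinical_snp_ids: frozenset[str]


def snp_panel(config: SimConfig) -> pd.DataFrame:
    """Deterministic SNP annotation shared by every generator.

    Returns one row per SNP: gene id, region class, lognormal baseline
    expression level, which allele is boosted under drug at planted EAI
    SNPs, and the planted-effect flags.
    """
    rng = _rng(config, _PANEL)
    n = config.n_snps
    snp_ids = np.array([f"rs{1000001 + i}" for i in range(n)])
    genes = np.array([f"G{i // 2:04d}" for i in range(n)])
    # genic classes dominate a typed SNP panel; intergenic is a minority
    probs = [0.1, 0.05, 0.1, 0.15, 0.45, 0.15]
    regions = rng.choice(REGION_CLASSES, size=n, p=probs)
    base_level = rng.lognormal(config.signal_mu, config.signal_sigma, size=n)
    eai_allele = rng.choice(["A", "B"], size=n)

    order = rng.permutation(n)
    shared = order[: config.n_shared_planted]
    k_eai = config.n_eai_snps - config.n_shared_planted
    k_cli = config.n_clinical_snps - config.n_shared_planted
    rest = order[config.n_shared_planted:]
    eai_idx = np.concatenate([shared, rest[:k_eai]]).astype(int)
    cli_idx = np.concatenate([shared, rest[k_eai: k_eai + k_cli]]).astype(int)

    is_eai = np.zeros(n, bool)
    is_eai[eai_idx] = True
    is_cli = np.zeros(n, bool)
    is_cli[cli_idx] = True
    # planted EAI SNPs must survive the genic-region filter downstream
    needs_fix = is_eai & ~np.isin(regions, GENIC_REGIONS)
    regions[needs_fix] = rng.choice(GENIC_REGIONS, size=needs_fix.sum())

    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene": genes,
            "region": regions,
            "base_level": base_level,
            "eai_allele": eai_allele,
            "is_eai": is_eai,
            "is_clinical": is_cli,
        }
    ).set_index("snp_id", drop=False)


def truth_set(config: SimConfig) -> TruthSet:
    panel = snp_panel(config)
    return TruthSet(
        eai_snp_ids=frozenset(panel.index[panel["is_eai"]]),
        clinical_snp_ids=frozenset(panel.index[panel["is_clinical"]]),
    )


def simulate_genotypes(
    config: SimConfig,
    n_samples: int | None = None,
    sample_prefix: str = "line",
) -> pd.DataFrame:
    """Draw a sample x SNP genotype-call table under Hardy-Weinberg.

    The B allele is the minor allele at frequency ``config.maf``.  Returns
    a DataFrame indexed by snp_id with ``gene`` and ``region`` annotation
    columns followed by one call column (AA/AB/BB/NoCall) per sample.
    """
    panel = snp_panel(config)
    if n_samples is None:
        n_samples = config.n_lines
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = _rng(config, _GENO, sample_prefix)
    m = config.maf
    probs = [(1 - m) ** 2, 2 * m * (1 - m), m * m]
    calls = rng.choice(["AA", "AB", "BB"], size=(config.n_snps, n_samples), p=probs)
    if config.nocall_rate > 0:
        nocall = rng.random((config.n_snps, n_samples)) < config.nocall_rate
        calls = np.where(nocall, "NoCall", calls)
    samples = [f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)]
    table = pd.DataFrame(calls, index=panel.index, columns=samples)
    return pd.concat([panel[["gene", "region"]], table], axis=1)


def sample_columns(genotypes: pd.DataFrame) -> list[str]:
    """Call columns of a genotype table (everything past the annotation)."""
    return [c for c in genotypes.columns if c not in ("gene", "region")]


def simulate_allele_signals(genotypes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Allele-resolved premature-RNA signals under vehicle and drug.

    For each (line, SNP, condition) both allele signals are positive: the
    expressed allele(s) draw from the SNP's lognormal baseline and the
    allele absent from a homozygous call reports background.  At planted
    EAI SNPs the drug condition multiplies exactly one allele's mean (the
    panel's fixed choice per SNP) by ``eai_effect`` in heterozygous lines.
    Multiplicative lognormal noise applies everywhere; probes are flagged
    Absent with probability ``dropout_rate``.
    """
    panel = snp_panel(config)
    unknown = set(genotypes.index) - set(panel.index)
    if unknown:
        raise ValueError(f"genotype table contains unknown SNPs: {sorted(unknown)[:5]}")
    samples = sample_columns(genotypes)
    if not samples:
        raise ValueError("genotype table has no sample columns")

    prefix = samples[0].rstrip("0123456789")
    rng = _rng(config, _SIGNAL, prefix)

    sub = panel.loc[genotypes.index]
    n_snps, n_samples = len(sub), len(samples)
    calls = genotypes[samples].to_numpy(str)
    base = sub["base_level"].to_numpy()[:, None]
    bg = config.background

    mean_a = np.select(
        [calls == "AA", calls == "AB", calls == "BB"],
        [np.broadcast_to(base, calls.shape)] * 2 + [np.full(calls.shape, bg)],
        default=0.0,
    )
    mean_b = np.select(
        [calls == "AA", calls == "AB", calls == "BB"],
        [np.full(calls.shape, bg)] + [np.broadcast_to(base, calls.shape)] * 2,
        default=0.0,
    )
    nocall = calls == "NoCall"
    mean_a[nocall] = base.repeat(n_samples, axis=1)[nocall] / 2
    mean_b[nocall] = base.repeat(n_samples, axis=1)[nocall] / 2

    frames = []
    boost_a = (sub["is_eai"] & (sub["eai_allele"] == "A")).to_numpy()[:, None]
    boost_b = (sub["is_eai"] & (sub["eai_allele"] == "B")).to_numpy()[:, None]
    het = calls == "AB"
    for condition in CONDITIONS:
        ma, mb = mean_a.copy(), mean_b.copy()
        if condition == "drug":
            ma = np.where(het & boost_a, ma * config.eai_effect, ma)
            mb = np.where(het & boost_b, mb * config.eai_effect, mb)
        noise_a = rng.lognormal(0.0, config.noise_sigma, size=calls.shape)
        noise_b = rng.lognormal(0.0, config.noise_sigma, size=calls.shape)
        sig_a = ma * noise_a
        sig_b = mb * noise_b
        detect = np.where(
            rng.random(calls.shape) < config.dropout_rate, "Absent", "Present"
        )
        frames.append(
            pd.DataFrame(
                {
                    "line_id": np.tile(samples, n_snps),
                    "snp_id": np.repeat(genotypes.index.to_numpy(), n_samples),
                    "condition": condition,
                    "signal_a": sig_a.ravel(),
                    "signal_b": sig_b.ravel(),
                    "detect": detect.ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["snp_id", "line_id", "condition"], ignore_index=True)


_AZA_DOSES = np.array([25.0, 50.0, 75.0, 100.0])
_ASA_DOSES = np.array([0.0, 1500.0, 2000.0, 2250.0, 2400.0, 3000.0, 3600.0, 4000.0])
_ASA_PROBS = np.array([0.06, 0.06, 0.08, 0.20, 0.06, 0.30, 0.14, 0.10])


def simulate_patients(config: SimConfig, genotypes: pd.DataFrame) -> pd.DataFrame:
    """Clinical records for a patient cohort with genotype-driven exposure.

    The latent risk ratio (6-TGN per mg/day AZA) is the baseline plus
    ``beta_risk`` per genotype code unit summed over planted clinical SNPs,
    plus Gaussian noise, truncated positive; the 6-TGN concentration is
    that ratio times the sampled AZA dose, so recomputing 6-TGN/dose
    recovers the latent ratio exactly.  MCV and WBC are generated with the
    configured correlation (positive and negative respectively) to 6-TGN.
    """
    panel = snp_panel(config)
    samples = sample_columns(genotypes)
    rng = _rng(config, _PATIENT)
    n = len(samples)

    cli_snps = panel.index[panel["is_clinical"]]
    missing = set(cli_snps) - set(genotypes.index)
    if missing:
        raise ValueError(f"patient genotypes missing clinical SNPs: {sorted(missing)[:5]}")
    code_map = {"AA": 0.0, "AB": 1.0, "BB": 2.0, "NoCall": 0.0}
    codes = (
        genotypes.loc[cli_snps, samples].map(code_map.get).to_numpy(float)
        if len(cli_snps)
        else np.zeros((0, n))
    )
    burden = codes.sum(axis=0)

    risk = (
        config.risk_baseline
        + config.beta_risk * burden
        + rng.normal(0.0, config.risk_noise_sd, size=n)
    )
    risk = np.clip(risk, 0.05, None)
    aza = rng.choice(_AZA_DOSES, size=n)
    asa = rng.choice(_ASA_DOSES, size=n, p=_ASA_PROBS)
    tgn = risk * aza

    z = (tgn - tgn.mean()) / (tgn.std() if tgn.std() > 0 else 1.0)
    mcv = 90.0 + 6.0 * (
        config.mcv_rho * z
        + np.sqrt(max(0.0, 1 - config.mcv_rho**2)) * rng.normal(size=n)
    )
    wbc = 6000.0 + 1500.0 * (
        config.wbc_rho * z
        + np.sqrt(max(0.0, 1 - config.wbc_rho**2)) * rng.normal(size=n)
    )
    wbc = np.clip(wbc, 500.0, None)

    return pd.DataFrame(
        {
            "sample_number": samples,
            "catalog_id": [f"SIM{i + 1:07d}" for i in range(n)],
            "aza_dose": aza,
            "asa_dose": asa,
            "tgn": tgn,
            "wbc": wbc,
            "mcv": mcv,
        }
    )


def simulate_probe_signals(
    config: SimConfig,
    n_probes: int = 500,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    effect: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Probe-level total mRNA signals with planted up/down regulation.

    A fraction of probes has its drug-condition mean multiplied (divided)
    by ``effect``; the rest are null.  Returns the long signal table and a
    truth dict with the planted probe id sets.
    """
    if effect < 1:
        raise ValueError("effect must be >= 1")
    rng = _rng(config, _PROBE)
    probe_ids = np.array([f"P{i + 1:05d}_at" for i in range(n_probes)])
    genes = np.array([f"G{i // 2:04d}" for i in range(n_probes)])
    base = rng.lognormal(config.signal_mu, config.signal_sigma, size=n_probes)
    n_up = int(round(frac_up * n_probes))
    n_down = int(round(frac_down * n_probes))
    order = rng.permutation(n_probes)
    up_idx, down_idx = order[:n_up], order[n_up: n_up + n_down]

    mult = np.ones(n_probes)
    mult[up_idx] = effect
    mult[down_idx] = 1.0 / effect
    frames = []
    for condition in CONDITIONS:
        mean = base * mult if condition == "drug" else base
        sig = mean * rng.lognormal(0.0, config.noise_sigma, size=n_probes)
        detect = np.where(
            rng.random(n_probes) < config.dropout_rate, "Absent", "Present"
        )
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "gene": genes,
                    "condition": condition,
                    "signal": sig,
                    "detect": detect,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    truth = {
        "up_probe_ids": set(probe_ids[up_idx]),
        "down_probe_ids": set(probe_ids[down_idx]),
    }
    return table, truth
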