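"""Drug-induced expression allelic imbalance (EAI) statistics.

At a heterozygous SNP the two alleles of a gene can respond differently to
a drug.  The per-line statistic is the folded allelic expression ratio
EAI(max) = max(A/B, B/A) of premature-RNA signal, computed separately for
the vehicle and drug conditions; their quotient, the EAI ratio
drug EAI(max) / vehicle EAI(max), flags a drug-specific imbalance when it
reaches 2.  The cohort-level analysis runs over lines carrying the AB call
(at least 3 required) and combines two arms at p < 0.01:

* ANCOVA arm — ordinary least squares of the log drug-condition allele
  signal on allele identity with the same allele's log vehicle-condition
  signal as covariate; the allele-factor p-value measures drug-condition
  allelic difference adjusted for baseline imbalance.
* t-test arm — one-sample two-sided t-test of the per-line paired
  differences log2(drug EAI max) - log2(vehicle EAI max) against zero.

A responsive SNP additionally needs a >= 2-fold inter-allelic ratio (by
default the drug-condition EAI(max) in at least one heterozygous line).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import GENIC_REGIONS

_GENIC = frozenset(GENIC_REGIONS)


def eai_max(signal_a, signal_b):
    """Folded allelic ratio max(A/B, B/A); >= 1, equal to 1 iff A == B.

    Accepts scalars or arrays; both signals must be strictly positive
    (callers floor at background first).
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("allele signals must be strictly positive")
    out = np.maximum(a / b, b / a)
    return float(out) if out.ndim == 0 else out


def eai_ratio(drug_max, vehicle_max, threshold: float = 2.0):
    """EAI ratio drug EAI(max)/vehicle EAI(max) and its detection flag.

    The detection boundary is inclusive: a ratio of exactly ``threshold``
    counts as drug-induced imbalance.
    """
    d = np.asarray(drug_max, dtype=float)
    v = np.asarray(vehicle_max, dtype=float)
    if np.any(d < 1) or np.any(v < 1):
        raise ValueError("EAI(max) values must be >= 1 by construction")
    ratio = d / v
    detected = ratio >= threshold
    if ratio.ndim == 0:
        return float(ratio), bool(detected)
    return ratio, detected


def _het_wide(
    signals: pd.DataFrame,
    genotypes: pd.DataFrame,
    regions: frozenset[str] | set[str] = _GENIC,
    background_floor: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vehicle/drug signal pairs for heterozygous (line, SNP) in genic regions.

    Returns a wide table (one row per eligible pair with Present calls in
    both conditions) and a log of how many pairs were dropped and why.
    """
    required = {"line_id", "snp_id", "condition", "signal_a", "signal_b", "detect"}
    missing = required - set(signals.columns)
    if missing:
        raise ValueError(f"allele signal table missing columns: {sorted(missing)}")
    sample_cols = [c for c in genotypes.columns if c not in ("gene", "region")]
    unknown_lines = set(signals["line_id"]) - set(sample_cols)
    if unknown_lines:
        raise ValueError(
            f"signal lines absent from genotype table: {sorted(unknown_lines)[:5]}"
        )
    unknown_snps = set(signals["snp_id"]) - set(genotypes.index)
    if unknown_snps:
        raise ValueError(
            f"signal SNPs absent from genotype table: {sorted(unknown_snps)[:5]}"
        )

    calls = (
        genotypes[sample_cols]
        .stack()
        .rename("call")
        .rename_axis(["snp_id", "line_id"])
        .reset_index()
    )
    df = signals.merge(calls, on=["snp_id", "line_id"], how="left")
    if "region" in genotypes.columns:
        df = df.merge(
            genotypes["region"].rename_axis("snp_id").reset_index(),
            on="snp_id", how="left",
        )
    else:
        df["region"] = "exon"

    log = {"non_het": 0, "non_genic": 0, "absent_call": 0, "unpaired": 0}
    het = df["call"] == "AB"
    log["non_het"] = int((~het).sum()) // 2  # two conditions per pair
    df = df[het]
    genic = df["region"].isin(regions)
    log["non_genic"] = int((~genic).sum()) // 2
    df = df[genic]
    present = df["detect"] == "Present"
    log["absent_call"] = int((~present).sum())
    df = df[present]

    if background_floor is not None:
        df = df.copy()
        df["signal_a"] = np.maximum(df["signal_a"], background_floor)
        df["signal_b"] = np.maximum(df["signal_b"], background_floor)

    wide = df.pivot_table(
        index=["snp_id", "line_id"],
        columns="condition",
        values=["signal_a", "signal_b"],
        aggfunc="first",
    )
    needed = [("signal_a", "vehicle"), ("signal_a", "drug"),
              ("signal_b", "vehicle"), ("signal_b", "drug")]
    for col in needed:
        if col not in wide.columns:
            wide[col] = np.nan
    complete = wide[needed].notna().all(axis=1)
    log["unpaired"] = int((~complete).sum())
    wide = wide.loc[complete, needed]
    wide.columns = ["va", "da", "vb", "db"]
    return wide.reset_index(), log


def detect_line_eai(
    signals: pd.DataFrame,
    genotypes: pd.DataFrame,
    regions: frozenset[str] | set[str] = _GENIC,
    threshold: float = 2.0,
    background_floor: float | None = None,
) -> pd.DataFrame:
    """Per-(line, SNP) EAI records over heterozygous calls in genic regions.

    Emits one record per eligible pair: vehicle EAI(max), drug EAI(max),
    their quotient, and the ``detected`` flag at the inclusive threshold.
    Pairs with a homozygous or NoCall genotype, an intergenic SNP, an
    Absent detection call or a missing condition are skipped.
    """
    wide, _ = _het_wide(signals, genotypes, regions, background_floor)
    v_max = eai_max(wide["va"], wide["vb"])
    d_max = eai_max(wide["da"], wide["db"])
    ratio, detected = eai_ratio(d_max, v_max, threshold)
    return pd.DataFrame(
        {
            "line_id": wide["line_id"],
            "snp_id": wide["snp_id"],
            "vehicle_eai_max": v_max,
            "drug_eai_max": d_max,
            "eai_ratio": ratio,
            "detected": detected,
        }
    ).sort_values(["snp_id", "line_id"], ignore_index=True)


def _ancova_allele_pvalue(
    log_drug: np.ndarray, allele: np.ndarray, log_vehicle: np.ndarray
) -> float:
    """p-value of the allele factor in OLS: log_drug ~ allele + log_vehicle.

    Closed-form least squares on the 3-column design [1, allele, covariate];
    equivalent to the statsmodels OLS fit (checked in the test suite) but
    cheap enough to run over thousands of SNPs.
    """
    n = len(log_drug)
    X = np.column_stack([np.ones(n), allele, log_vehicle])
    df_resid = n - X.shape[1]
    if df_resid < 1:
        return np.nan
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return np.nan
    beta = XtX_inv @ (X.T @ log_drug)
    resid = log_drug - X @ beta
    sigma2 = float(resid @ resid) / df_resid
    if sigma2 <= 0:
        return np.nan
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    if se == 0:
        return np.nan
    t = beta[1] / se
    return float(2 * stats.t.sf(abs(t), df_resid))


def het_cohort_test(
    snp_id: str,
    wide: pd.DataFrame,
    alpha: float = 0.01,
    min_het: int = 3,
    fold_min: float = 2.0,
    fold_rule: str = "drug_abs",
) -> dict:
    """AB-heterozygote cohort test for one SNP.

    ``wide`` holds one row per heterozygous line with columns va/vb (vehicle
    allele signals) and da/db (drug).  Returns the per-SNP result row with
    both arm p-values, the maximum fold statistic and the responsive call:
    n_het >= min_het AND (p_ancova < alpha OR p_ttest < alpha) AND
    max_fold >= fold_min.
    """
    n_het = len(wide)
    base = {
        "snp_id": snp_id,
        "n_het": n_het,
        "p_ancova": np.nan,
        "p_ttest": np.nan,
        "max_fold": np.nan,
        "responsive": False,
        "reason": "",
    }
    if n_het < min_het:
        base["reason"] = "insufficient_het"
        return base

    va, vb = wide["va"].to_numpy(float), wide["vb"].to_numpy(float)
    da, db = wide["da"].to_numpy(float), wide["db"].to_numpy(float)

    # ANCOVA arm: two rows per line, one per allele
    log_drug = np.log2(np.concatenate([da, db]))
    log_veh = np.log2(np.concatenate([va, vb]))
    allele = np.concatenate([np.zeros(n_het), np.ones(n_het)])
    p_ancova = _ancova_allele_pvalue(log_drug, allele, log_veh)

    # paired t-test arm on folded log-ratios
    d = np.log2(eai_max(da, db)) - np.log2(eai_max(va, vb))
    if np.ptp(d) == 0:
        p_ttest = np.nan
    else:
        p_ttest = float(stats.ttest_1samp(d, 0.0).pvalue)

    drug_max = eai_max(da, db)
    if fold_rule == "drug_abs":
        max_fold = float(np.max(drug_max))
    elif fold_rule == "ratio_of_ratios":
        max_fold = float(np.max(drug_max / eai_max(va, vb)))
    else:
        raise ValueError("fold_rule must be 'drug_abs' or 'ratio_of_ratios'")

    p_ok = (not np.isnan(p_ancova) and p_ancova < alpha) or (
        not np.isnan(p_ttest) and p_ttest < alpha
    )
    base.update(
        p_ancova=p_ancova,
        p_ttest=p_ttest,
        max_fold=max_fold,
        responsive=bool(p_ok and max_fold >= fold_min),
        reason="" if p_ok and max_fold >= fold_min else "below_threshold",
    )
    return base


def cohort_summary(cohort: pd.DataFrame, per_line: pd.DataFrame) -> dict:
    """Counts reported for a panel run: per-line detections and cohort hits."""
    if len(per_line):
        counts = (
            per_line[per_line["detected"]]
            .groupby("line_id")["snp_id"]
            .size()
            .to_dict()
        )
    else:
        counts = {}
    n_responsive = int(cohort["responsive"].sum()) if len(cohort) else 0
    genes = 0
    if len(cohort) and "gene" in cohort.columns:
        genes = int(cohort.loc[cohort["responsive"], "gene"].nunique())
    return {
        "per_line_detected": counts,
        "n_detected_records": int(per_line["detected"].sum()) if len(per_line) else 0,
        "n_responsive_snps": n_responsive,
        "n_responsive_genes": genes,
    }


@dataclass
class EaiResults:
    """Per-line EAI records plus the per-SNP cohort analysis.

    ``per_line`` carries one row per heterozygous (line, SNP) pair;
    ``cohort`` one row per SNP with >= 1 analysable heterozygous line.
    """

    per_line: pd.DataFrame
    cohort: pd.DataFrame
    dropped: dict[str, int]
    params: dict = field(default_factory=dict)

    @property
    def responsive(self) -> pd.DataFrame:
        return self.cohort[self.cohort["responsive"]]

    def summary_counts(self) -> dict:
        return cohort_summary(self.cohort, self.per_line)

    def summary(self) -> str:
        p = self.params
        counts = self.summary_counts()
        lines = [
            "Drug-induced expression allelic imbalance analysis",
            "=" * 52,
            f"heterozygous pairs analysed   {len(self.per_line)}"
            f"  (dropped: {self.dropped})",
            f"per-line EAI ratio threshold  >= {p.get('threshold')}"
            f"  -> {counts['n_detected_records']} detections",
            f"cohort test                   alpha={p.get('alpha')},"
            f" min het={p.get('min_het')}, fold >= {p.get('fold_min')}"
            f" ({p.get('fold_rule')})",
            f"responsive SNPs               {counts['n_responsive_snps']}"
            f"  in {counts['n_responsive_genes']} genes",
            "",
        ]
        top = self.cohort.sort_values(
            ["responsive", "max_fold"], ascending=[False, False]
        ).head(10)
        cols = [c for c in ("snp_id", "gene", "n_het", "p_ancova", "p_ttest",
                            "max_fold", "responsive") if c in top.columns]
        lines.append(top[cols].to_string(index=False,
                                         float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def plot_line_counts(self, ax=None):
        """Bar chart of detected drug-induced EAIs per cell line."""
        import matplotlib.pyplot as plt

        counts = self.summary_counts()["per_line_detected"]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        keys = sorted(counts)
        ax.bar(range(len(keys)), [counts[k] for k in keys])
        ax.set_xticks(range(len(keys)), keys, rotation=90, fontsize=6)
        ax.set_ylabel("drug-induced EAIs")
        return ax


class EaiAnalysis:
    """Panel-wide EAI analysis over allele-resolved signals and genotypes.

    Parameters mirror the published decision rules: per-line EAI ratio
    threshold 2, cohort alpha 0.01, at least 3 heterozygous lines, and a
    2-fold inter-allelic ratio requirement.
    """

    def __init__(
        self,
        signals: pd.DataFrame,
        genotypes: pd.DataFrame,
        *,
        threshold: float = 2.0,
        alpha: float = 0.01,
        min_het: int = 3,
        fold_min: float = 2.0,
        fold_rule: str = "drug_abs",
        regions: frozenset[str] | set[str] = _GENIC,
        background_floor: float | None = None,
    ) -> None:
        self.signals = signals
        self.genotypes = genotypes
        self.threshold = threshold
        self.alpha = alpha
        self.min_het = min_het
        self.fold_min = fold_min
        self.fold_rule = fold_rule
        self.regions = frozenset(regions)
        self.background_floor = background_floor

    @classmethod
    def from_files(cls, signal_path, genotype_path, **kwargs) -> "EaiAnalysis":
        from . import io

        return cls(io.read_allele_signals(signal_path),
                   io.read_genotypes(genotype_path), **kwargs)

    def fit(self) -> EaiResults:
        wide, dropped = _het_wide(
            self.signals, self.genotypes, self.regions, self.background_floor
        )
        v_max = eai_max(wide["va"], wide["vb"])
        d_max = eai_max(wide["da"], wide["db"])
        ratio, detected = eai_ratio(d_max, v_max, self.threshold)
        per_line = pd.DataFrame(
            {
                "line_id": wide["line_id"],
                "snp_id": wide["snp_id"],
                "vehicle_eai_max": v_max,
                "drug_eai_max": d_max,
                "eai_ratio": ratio,
                "detected": detected,
            }
        ).sort_values(["snp_id", "line_id"], ignore_index=True)

        rows = [
            het_cohort_test(
                snp_id, grp, self.alpha, self.min_het, self.fold_min, self.fold_rule
            )
            for snp_id, grp in wide.groupby("snp_id", sort=True)
        ]
        cohort = pd.DataFrame(
            rows,
            columns=["snp_id", "n_het", "p_ancova", "p_ttest", "max_fold",
                     "responsive", "reason"],
        )
        if len(cohort) and "gene" in self.genotypes.columns:
            cohort.insert(
                1, "gene", cohort["snp_id"].map(self.genotypes["gene"]).fillna("")
            )
        if len(cohort):
            tested = cohort["p_ttest"].notna()
            bh = pd.Series(np.nan, index=cohort.index)
            if tested.any():
                bh[tested] = multipletests(
                    cohort.loc[tested, "p_ttest"], method="fdr_bh"
                )[1]
            cohort["bh_fdr_ttest"] = bh
        return EaiResults(
            per_line=per_line,
            cohort=cohort,
            dropped=dropped,
            params={
                "threshold": self.threshold,
                "alpha": self.alpha,
                "min_het": self.min_het,
                "fold_min": self.fold_min,
                "fold_rule": self.fold_rule,
            },
        )
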