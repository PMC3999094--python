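"""Clinical genotype vs 6-TGN risk-ratio correlation screen.

The risk ratio is the blood 6-TGN concentration divided by the daily AZA
dose — a dose-normalised metabolite exposure.  Patients co-medicated with
less than 2000 mg/day 5-ASA are excluded (5-ASA inhibits TPMT, so low-dose
co-medication breaks the cohort's exposure homogeneity).  Each SNP is then
tested for a linear trend of the risk ratio across additively coded
genotypes (AA=0, AB=1, BB=2) by Pearson correlation; a SNP is a biomarker
candidate when every genotype class is observed in at least ``min_per_class``
samples, r^2 >= ``r2_min`` and p < ``alpha``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_CALL_CODES = {"AA": 0.0, "AB": 1.0, "BB": 2.0}
_MISSING_CALLS = {"NOCALL", "NC", "NO CALL", "NA", ""}


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested on a constant vector."""


def risk_ratio(tgn: float, aza_dose: float) -> float:
    """6-TGN concentration (pmol/8x10^8 RBCs) per mg/day of AZA.

    Returned at full precision; Table-style display rounds to 2 decimals.
    """
    if aza_dose <= 0:
        raise ValueError("risk ratio undefined: aza_dose must be > 0")
    if tgn <= 0:
        raise ValueError("tgn must be > 0")
    return tgn / aza_dose


def add_risk_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a clinical table with a ``risk_ratio`` column."""
    if (records["aza_dose"] <= 0).any():
        bad = records.loc[records["aza_dose"] <= 0, "sample_number"].tolist()
        raise ValueError(f"aza_dose must be > 0 (samples {bad})")
    out = records.copy()
    out["risk_ratio"] = out["tgn"] / out["aza_dose"]
    return out


def apply_asa_exclusion(
    records: pd.DataFrame, min_dose: float = 2000.0
) -> tuple[pd.DataFrame, list]:
    """Drop patients whose 5-ASA dose is below ``min_dose`` mg/day.

    Returns (retained records, excluded sample numbers in input order).
    """
    keep = records["asa_dose"] >= min_dose
    excluded = records.loc[~keep, "sample_number"].tolist()
    return records.loc[keep].copy(), excluded


def encode_genotype(call: object) -> float:
    """Additive coding AA=0, AB=1, BB=2; NoCall maps to NaN.

    Input is case-insensitive; unrecognised strings raise ValueError.
    """
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return np.nan
    norm = str(call).strip().upper()
    if norm in _MISSING_CALLS:
        return np.nan
    if norm in ("AA", "AB", "BB"):
        return _CALL_CODES[norm]
    if norm == "BA":
        return 1.0
    raise ValueError(f"unrecognised genotype call: {call!r}")


def encode_genotypes(calls: Iterable[object]) -> np.ndarray:
    return np.array([encode_genotype(c) for c in calls], dtype=float)


def class_count_filter(codes: Sequence[float], min_per_class: int = 2) -> bool:
    """True iff each genotype class {0, 1, 2} occurs >= ``min_per_class``."""
    arr = np.asarray(codes, dtype=float)
    arr = arr[~np.isnan(arr)]
    return all(int((arr == k).sum()) >= min_per_class for k in (0.0, 1.0, 2.0))


def correlate_snp(
    codes: Sequence[float],
    ratios: Sequence[float],
    method: str = "pearson",
) -> tuple[float, float, float]:
    """(r, r^2, two-sided p) for genotype codes against risk ratios.

    Pairwise-complete; p comes from the t distribution on n-2 df.  Raises
    ZeroVarianceError when either vector is constant after missing removal.
    """
    x = np.asarray(codes, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.shape != y.shape:
        raise ValueError("codes and ratios must be paired")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ZeroVarianceError("fewer than 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("zero variance in codes or ratios")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def hematology_correlates(records: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation of 6-TGN with MCV and with WBC.

    6-TGN therapy raises MCV (macrocytosis) and depresses the white count,
    so the expected signs are positive and negative respectively.
    Pairwise-complete per variable; constant or short columns raise
    ZeroVarianceError.
    """
    out: dict[str, float] = {}
    for name in ("mcv", "wbc"):
        if name not in records.columns:
            raise ZeroVarianceError(f"column {name!r} absent")
        sub = records[["tgn", name]].dropna()
        if len(sub) < 3:
            raise ZeroVarianceError(f"fewer than 3 complete pairs for {name}")
        if np.ptp(sub[name].to_numpy()) == 0 or np.ptp(sub["tgn"].to_numpy()) == 0:
            raise ZeroVarianceError(f"zero variance in {name} or tgn")
        res = stats.pearsonr(sub["tgn"], sub[name])
        out[f"r_{name}"] = float(res.statistic)
        out[f"p_{name}"] = float(res.pvalue)
    return out


@dataclass
class ClinicalScreenResults:
    """Per-SNP correlation screen output.

    ``hits`` has one row per analysable SNP, sorted by descending r^2 with
    lexicographic snp_id tie-break; ``skipped`` lists SNPs dropped with the
    reason (zero variance / too few pairs); ``excluded_samples`` is the
    5-ASA exclusion report in input order.
    """

    hits: pd.DataFrame
    skipped: pd.DataFrame
    excluded_samples: list
    n_retained: int
    params: dict = field(default_factory=dict)
    _records: pd.DataFrame | None = None
    _genotypes: pd.DataFrame | None = None

    @property
    def passing(self) -> pd.DataFrame:
        return self.hits[self.hits["passes_threshold"]]

    def summary(self) -> str:
        p = self.params
        lines = [
            "Clinical genotype vs 6-TGN risk-ratio screen",
            "=" * 52,
            f"patients retained       {self.n_retained}"
            f"  (excluded for 5-ASA < {p.get('min_dose')} mg/day:"
            f" {len(self.excluded_samples)})",
            f"SNPs tested             {len(self.hits)}"
            f"  (skipped: {len(self.skipped)})",
            f"threshold               {p.get('threshold_on')} >= {p.get('r2_min')}"
            f" and p < {p.get('alpha')}",
            f"class filter            each genotype in >= {p.get('min_per_class')}"
            " samples",
            f"biomarker candidates    {int(self.hits['passes_threshold'].sum())}",
            "",
        ]
        top = self.hits.head(10)[
            ["snp_id", "gene", "r", "r2", "p", "n_aa", "n_ab", "n_bb",
             "passes_threshold"]
        ]
        lines.append(top.to_string(index=False,
                                   float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def plot_snp(self, snp_id: str, ax=None):
        """Scatter of risk ratio against genotype code for one SNP."""
        import matplotlib.pyplot as plt

        if self._records is None or self._genotypes is None:
            raise ValueError("plotting requires the fitted model's data")
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        samples = self._records["sample_number"].astype(str)
        codes = encode_genotypes(self._genotypes.loc[snp_id, samples])
        rr = self._records["risk_ratio"].to_numpy()
        ok = ~np.isnan(codes)
        jitter = (np.arange(ok.sum()) % 7 - 3) * 0.015
        ax.scatter(codes[ok] + jitter, rr[ok], s=18, alpha=0.8)
        ax.set_xticks([0, 1, 2], ["AA", "AB", "BB"])
        ax.set_xlabel("genotype")
        ax.set_ylabel("6-TGN / AZA dose")
        ax.set_title(snp_id)
        return ax


class ClinicalScreen:
    """Genotype vs risk-ratio correlation screen over a patient cohort.

    Parameters
    ----------
    genotypes : DataFrame
        SNP x sample call table (gene/region annotation columns plus one
        call column per patient), as written by the simulator or readers.
    records : DataFrame
        Clinical table with sample_number, aza_dose, asa_dose, tgn and
        optional wbc/mcv columns.
    r2_min, alpha : float
        Biomarker thresholds (defaults 0.4 and 0.01).
    threshold_on : {"r2", "abs_r"}
        Whether the 0.4 floor applies to r^2 or to |r|.
    min_dose : float
        5-ASA exclusion threshold in mg/day.
    min_per_class : int
        Minimum samples per genotype class.
    method : {"pearson", "spearman"}
    """

    def __init__(
        self,
        genotypes: pd.DataFrame,
        records: pd.DataFrame,
        *,
        r2_min: float = 0.4,
        alpha: float = 0.01,
        threshold_on: str = "r2",
        min_dose: float = 2000.0,
        min_per_class: int = 2,
        method: str = "pearson",
    ) -> None:
        if threshold_on not in ("r2", "abs_r"):
            raise ValueError("threshold_on must be 'r2' or 'abs_r'")
        self.genotypes = genotypes
        self.records = records
        self.r2_min = r2_min
        self.alpha = alpha
        self.threshold_on = threshold_on
        self.min_dose = min_dose
        self.min_per_class = min_per_class
        self.method = method

    @classmethod
    def from_files(cls, genotype_path, clinical_path, **kwargs) -> "ClinicalScreen":
        from . import io

        return cls(io.read_genotypes(genotype_path),
                   io.load_clinical(clinical_path), **kwargs)

    def fit(self) -> ClinicalScreenResults:
        records = add_risk_ratios(self.records)
        retained, excluded = apply_asa_exclusion(records, self.min_dose)
        samples = retained["sample_number"].astype(str).tolist()
        geno_samples = [
            c for c in self.genotypes.columns if c not in ("gene", "region")
        ]
        missing = set(samples) - set(geno_samples)
        if missing:
            raise ValueError(
                f"retained samples absent from genotype table: {sorted(missing)[:5]}"
            )
        rr = retained["risk_ratio"].to_numpy(float)

        rows, skipped = [], []
        for snp_id in self.genotypes.index:
            calls = self.genotypes.loc[snp_id, samples]
            codes = encode_genotypes(calls)
            counts = {
                k: int((codes == v).sum())
                for k, v in (("n_aa", 0.0), ("n_ab", 1.0), ("n_bb", 2.0))
            }
            passes_class = class_count_filter(codes, self.min_per_class)
            try:
                r, r2, p = correlate_snp(codes, rr, method=self.method)
            except ZeroVarianceError as err:
                skipped.append({"snp_id": snp_id, "reason": str(err)})
                continue
            stat = r2 if self.threshold_on == "r2" else abs(r)
            rows.append(
                {
                    "snp_id": snp_id,
                    "gene": self.genotypes.loc[snp_id, "gene"]
                    if "gene" in self.genotypes.columns
                    else "",
                    "r": r,
                    "r2": r2,
                    "p": p,
                    **counts,
                    "passes_class_filter": passes_class,
                    "passes_threshold": bool(
                        passes_class and stat >= self.r2_min and p < self.alpha
                    ),
                }
            )
        hits = pd.DataFrame(
            rows,
            columns=["snp_id", "gene", "r", "r2", "p", "n_aa", "n_ab", "n_bb",
                     "passes_class_filter", "passes_threshold"],
        )
        if len(hits):
            # informational only: the decision rule stays on raw p
            hits["bh_fdr"] = multipletests(hits["p"], method="fdr_bh")[1]
            hits = hits.sort_values(
                ["r2", "snp_id"], ascending=[False, True], ignore_index=True
            )
        else:
            hits["bh_fdr"] = pd.Series(dtype=float)
        return ClinicalScreenResults(
            hits=hits,
            skipped=pd.DataFrame(skipped, columns=["snp_id", "reason"]),
            excluded_samples=excluded,
            n_retained=len(retained),
            params={
                "r2_min": self.r2_min,
                "alpha": self.alpha,
                "threshold_on": self.threshold_on,
                "min_dose": self.min_dose,
                "min_per_class": self.min_per_class,
                "method": self.method,
            },
            _records=retained,
            _genotypes=self.genotypes,
        )
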