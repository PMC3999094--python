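"""Intersection of clinical biomarker hits with drug-induced EAI evidence.

A SNP is a coincident biomarker when it passes the clinical correlation
threshold and the cell-line panel shows drug-induced allelic imbalance at
the same SNP — either a per-line EAI ratio >= 2 in at least one line, the
cohort-level responsive call, or either of the two (the default, since a
single supporting line can carry the signal).
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

MODES = ("any_line", "cohort_responsive", "either")


def _check_unique(df: pd.DataFrame, col: str, what: str) -> None:
    dup = df[col][df[col].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate SNP ids in {what}: {sorted(set(dup))[:5]}")


def intersect(
    clinical_hits: pd.DataFrame,
    eai_records: pd.DataFrame,
    het_results: pd.DataFrame,
    mode: str = "either",
) -> pd.DataFrame:
    """One row per clinically passing SNP with its EAI support and verdict.

    ``clinical_hits`` is the screen output (needs snp_id, gene, r, r2, p,
    passes_threshold), ``eai_records`` the per-line EAI table (snp_id,
    detected), ``het_results`` the cohort table (snp_id, responsive).
    Output is sorted by descending clinical r2 (snp_id tie-break).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    _check_unique(clinical_hits, "snp_id", "clinical hits")
    if len(het_results):
        _check_unique(het_results, "snp_id", "cohort EAI results")

    passing = clinical_hits[clinical_hits["passes_threshold"]].copy()
    if len(eai_records):
        support = (
            eai_records[eai_records["detected"]]
            .groupby("snp_id")["line_id"]
            .nunique()
        )
    else:
        support = pd.Series(dtype=int)
    responsive = (
        het_results.set_index("snp_id")["responsive"]
        if len(het_results)
        else pd.Series(dtype=bool)
    )

    passing["eai_line_support"] = (
        passing["snp_id"].map(support).fillna(0).astype(int)
    )
    passing["cohort_responsive"] = (
        responsive.reindex(passing["snp_id"], fill_value=False)
        .astype(bool)
        .to_numpy()
    )
    any_line = passing["eai_line_support"] >= 1
    if mode == "any_line":
        coincident = any_line
    elif mode == "cohort_responsive":
        coincident = passing["cohort_responsive"]
    else:
        coincident = any_line | passing["cohort_responsive"]
    passing["coincident"] = coincident

    cols = ["snp_id", "gene", "r", "r2", "p", "eai_line_support",
            "cohort_responsive", "coincident"]
    cols = [c for c in cols if c in passing.columns]
    return (
        passing[cols]
        .sort_values(["r2", "snp_id"], ascending=[False, True],
                     ignore_index=True)
    )


def gene_rollup(hits: pd.DataFrame) -> pd.DataFrame:
    """Gene-level view: a gene is flagged when any of its SNPs is coincident."""
    if not len(hits):
        return pd.DataFrame(columns=["gene", "n_snps", "n_coincident", "flagged"])
    g = hits.groupby("gene").agg(
        n_snps=("snp_id", "size"), n_coincident=("coincident", "sum")
    )
    g["flagged"] = g["n_coincident"] >= 1
    return g.reset_index()


def report(hits: pd.DataFrame, config: dict | None = None) -> dict:
    """Machine-readable report with the full threshold configuration echoed."""
    return {
        "config": dict(config or {}),
        "n_clinical_pass": int(len(hits)),
        "n_coincident": int(hits["coincident"].sum()) if len(hits) else 0,
        "hits": hits.to_dict(orient="records"),
    }


def write_report(rep: dict, path) -> None:
    Path(path).write_text(json.dumps(rep, indent=2, default=str) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
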