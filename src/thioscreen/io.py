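"""Readers and writers for the pipeline's plain-text table formats.

Everything is self-describing TSV/CSV with explicit headers; there is no
community standard for allele-resolved array signal tables, so the formats
defined here are the interchange contract between pipeline stages.
"""
from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

CLINICAL_REQUIRED = ("sample_number", "aza_dose", "asa_dose", "tgn")
CLINICAL_OPTIONAL = ("catalog_id", "wbc", "mcv")


# ---------------------------------------------------------------- genotypes

def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    out = genotypes.copy()
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "snp_id" not in df.columns:
        raise ValueError(f"{path}: genotype table must have a snp_id column")
    return df.set_index("snp_id")


# ------------------------------------------------------------ allele signals

def write_allele_signals(signals: pd.DataFrame, path) -> None:
    cols = ["line_id", "snp_id", "condition", "signal_a", "signal_b", "detect"]
    signals[cols].to_csv(path, sep="\t", index=False)


def read_allele_signals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("signal_a", "signal_b"):
        df[col] = df[col].astype(float)
    return df


# ------------------------------------------------------------- probe signals

def write_probe_signals(signals: pd.DataFrame, path) -> None:
    cols = ["probe_id", "gene", "condition", "signal", "detect"]
    signals[cols].to_csv(path, sep="\t", index=False)


def read_probe_signals(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["signal"] = df["signal"].astype(float)
    return df


# ------------------------------------------------------------------ clinical

def load_clinical(path) -> pd.DataFrame:
    """Typed clinical records from CSV; row-numbered errors on bad fields.

    Requires sample_number, aza_dose, asa_dose and tgn columns; catalog_id,
    wbc and mcv are carried through when present.  Rows with a missing or
    non-numeric mandatory field are rejected, naming the row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(CLINICAL_REQUIRED) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
    out = pd.DataFrame()
    out["sample_number"] = raw["sample_number"].astype(str)
    for col in ("aza_dose", "asa_dose", "tgn", "wbc", "mcv"):
        if col not in raw.columns:
            continue
        values = []
        for row, cell in enumerate(raw[col], start=2):  # 1-based + header
            cell = cell.strip()
            if cell == "":
                if col in CLINICAL_REQUIRED:
                    raise ValueError(
                        f"{path}: row {row}, column {col!r}: missing mandatory value"
                    )
                values.append(np.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError as err:
                raise ValueError(
                    f"{path}: row {row}, column {col!r}: "
                    f"malformed numeric value {cell!r}"
                ) from err
        out[col] = values
    if "catalog_id" in raw.columns:
        out.insert(1, "catalog_id", raw["catalog_id"].astype(str))
    return out


def write_clinical(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def load_table2() -> pd.DataFrame:
    """The packaged 38-patient clinical fixture (doses, 6-TGN, printed ratios)."""
    with resources.as_file(
        resources.files("thioscreen.data").joinpath("table2.csv")
    ) as p:
        df = load_clinical(p)
        printed = pd.read_csv(p)["risk_ratio_printed"].astype(float)
    df["risk_ratio_printed"] = printed.to_numpy()
    return df


# --------------------------------------------------------------- result files

def write_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("passes_class_filter", "passes_threshold", "detected",
                "responsive", "coincident", "cohort_responsive"):
        if col in df.columns:
            df[col] = (
                df[col]
                .map({True: True, False: False, "True": True, "False": False})
                .astype(bool)
            )
    return df


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_truth(truth, path) -> None:
    write_json(
        {
            "eai_snp_ids": sorted(truth.eai_snp_ids),
            "clinical_snp_ids": sorted(truth.clinical_snp_ids),
        },
        path,
    )
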