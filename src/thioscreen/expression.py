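"""Total mRNA normalisation and fold-change filtering.

Signals are scaled per condition so the trimmed mean hits a common target
(100 by default), mimicking array target-signal scaling; probes must carry
a Present detection call to enter the fold-change comparison, and a >= 2-fold
increase (or <= 0.5-fold decrease) of drug over vehicle flags a probe as
regulated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("probe_id", "gene", "condition", "signal", "detect")


def _check_columns(signals: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(signals.columns)
    if missing:
        raise ValueError(f"probe signal table missing columns: {sorted(missing)}")


def scale_normalize(
    signals: pd.DataFrame, target: float = 100.0, trim: float = 0.02
) -> pd.DataFrame:
    """Scale each condition so its symmetric trimmed mean equals ``target``.

    The trim fraction is cut from each tail.  Scaling is linear, so the
    operation is idempotent and the post-normalisation trimmed mean equals
    the target to relative 1e-9 or better.
    """
    _check_columns(signals)
    if target <= 0:
        raise ValueError("target must be positive")
    out = signals.copy()
    for condition, idx in out.groupby("condition").groups.items():
        values = out.loc[idx, "signal"].to_numpy(float)
        if np.any(values < 0):
            raise ValueError(f"negative signal in condition {condition!r}")
        tm = stats.trim_mean(values, trim)
        if tm <= 0:
            raise ValueError(
                f"condition {condition!r} has nonpositive trimmed mean; "
                "cannot scale-normalize"
            )
        out.loc[idx, "signal"] = values * (target / tm)
    return out


@dataclass
class FoldChangeResult:
    """Regulated probe sets and per-gene rollups from a two-condition filter."""

    up_probes: set[str]
    down_probes: set[str]
    up_genes: set[str]
    down_genes: set[str]
    ratios: pd.DataFrame

    def summary(self) -> dict[str, int]:
        return {
            "n_up_probes": len(self.up_probes),
            "n_up_genes": len(self.up_genes),
            "n_down_probes": len(self.down_probes),
            "n_down_genes": len(self.down_genes),
        }


def fold_change_filter(
    signals: pd.DataFrame,
    up_min: float = 2.0,
    down_max: float = 0.5,
    eps: float = 1.0,
    present_rule: str = "any",
) -> FoldChangeResult:
    """Split probes into up-/down-regulated sets by drug/vehicle ratio.

    Only probes with a Present call in at least one condition (``present_rule
    = "any"``; ``"both"`` requires both) are eligible.  The denominator is
    floored at ``eps`` normalized units so background-level vehicle signals
    cannot blow the ratio up.  Boundaries are inclusive: ratio exactly 2 is
    up, exactly 0.5 is down.
    """
    _check_columns(signals)
    if present_rule not in ("any", "both"):
        raise ValueError("present_rule must be 'any' or 'both'")
    wide = signals.pivot_table(
        index=["probe_id", "gene"],
        columns="condition",
        values="signal",
        aggfunc="first",
    )
    det = signals.pivot_table(
        index=["probe_id", "gene"],
        columns="condition",
        values="detect",
        aggfunc="first",
    )
    for cond in ("vehicle", "drug"):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} missing from signal table")
    if wide[["vehicle", "drug"]].isna().any().any():
        bad = wide.index[wide[["vehicle", "drug"]].isna().any(axis=1)][:5]
        raise ValueError(f"probes present in only one condition: {list(bad)}")

    present = det == "Present"
    eligible = (
        present.any(axis=1) if present_rule == "any" else present.all(axis=1)
    )
    sub = wide[eligible]
    denom = np.maximum(sub["vehicle"].to_numpy(float), eps)
    ratio = sub["drug"].to_numpy(float) / denom
    probe_ids = sub.index.get_level_values("probe_id")
    genes = sub.index.get_level_values("gene")

    up_mask = ratio >= up_min
    down_mask = ratio <= down_max
    ratios = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene": genes,
            "vehicle": sub["vehicle"].to_numpy(float),
            "drug": sub["drug"].to_numpy(float),
            "ratio": ratio,
            "direction": np.select([up_mask, down_mask], ["up", "down"], "none"),
        }
    ).sort_values("probe_id", ignore_index=True)
    return FoldChangeResult(
        up_probes=set(probe_ids[up_mask]),
        down_probes=set(probe_ids[down_mask]),
        up_genes=set(genes[up_mask]),
        down_genes=set(genes[down_mask]),
        ratios=ratios,
    )
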