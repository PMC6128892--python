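"""Threshold selection on a differential-expression table.

The DE fit itself (per-gene log2 fold change and p-value, knockdown vs
control) is consumed as a table from upstream software.  Selection uses a
linear fold-change cutoff of 1.5 (inclusive at the bound) together with a
strict p < 0.05: up-regulated genes satisfy log2fc >= log2(1.5), p < 0.05;
down-regulated genes log2fc <= -log2(1.5), p < 0.05.  Internally all fold
changes are log2; the signed linear convention (-1.5 meaning a 1.5-fold
decrease) is converted once at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    log2fc: float
    p_value: float
    status: str  # up | down | unchanged


def log2_transform_fc(fold_change: float) -> float:
    """Map a signed linear fold change to log2 scale, preserving sign.

    +1.5 -> +log2(1.5), -1.5 -> -log2(1.5), +1 -> 0.  Zero has no image.
    """
    if fold_change == 0:
        raise ValueError("fold change of 0 has no log2 representation")
    return math.copysign(math.log2(abs(fold_change)), fold_change)


def assign_status(
    table: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Return the table with a derived status column (up/down/unchanged)."""
    _check(table, fc_threshold, alpha)
    cut = math.log2(fc_threshold)
    fc = table["log2fc"].to_numpy(dtype=float)
    p = table["p_value"].to_numpy(dtype=float)
    status = np.where(
        (fc >= cut) & (p < alpha),
        "up",
        np.where((fc <= -cut) & (p < alpha), "down", "unchanged"),
    )
    out = table.copy()
    out["status"] = status
    return out


def select_de(
    table: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Select (up, down) gene lists at the fold-change and p-value cutoffs."""
    with_status = assign_status(table, fc_threshold, alpha)
    up = with_status.loc[with_status["status"] == "up", "gene_id"].tolist()
    down = with_status.loc[with_status["status"] == "down", "gene_id"].tolist()
    return up, down


def _check(table: pd.DataFrame, fc_threshold: float, alpha: float) -> None:
    missing = [c for c in ("gene_id", "log2fc", "p_value") if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    if not fc_threshold > 1:
        raise ValueError("fc_threshold must be > 1 (linear fold change)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
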