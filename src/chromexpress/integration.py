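"""Correlate promoter histone-mark changes with expression changes.

For each gene, the mark change is the difference of mean normalized
ChIP signal (knockdown minus control) over a window around the TSS
(default +/- 2 kb) or over the gene body.  Per expression-enrichment
class and mark, Spearman's rank correlation is computed between these
changes and the RNA-seq log2 fold changes, once over all class genes and
once restricted to |log2FC| >= 1, with significance called at p < 0.001.

Spearman's rho uses average ranks for ties.  The two-sided p-value comes
from exact enumeration over all n! orderings for n < 10 and from the
t-approximation t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of
freedom otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneModel
from .spike_norm import CoverageTrack

logger = logging.getLogger(__name__)

REGIONS = ("tss_window", "gene_body")
FILTERS = ("none", "abs_log2fc_ge_1")
SIGNIFICANCE_ALPHA = 1e-3
EXACT_N_MAX = 9  # exact permutation p below this+1 observations


class ConstantInputError(ValueError):
    """Spearman's rho is undefined when either vector is constant."""


class WindowError(ValueError):
    """A gene's signal window does not fit on its chromosome."""


@dataclass(frozen=True)
class GeneSignalChange:
    gene_id: str
    region: str
    window_bp: int
    delta: float  # mean(knockdown) - mean(control), normalized signal units


@dataclass(frozen=True)
class CorrelationResult:
    class_label: str
    mark: str
    region: str
    filter: str
    n: int
    rho: float
    p_value: float
    significant: bool
    reason: str | None = None


# ---------------------------------------------------------------------------
# per-gene signal change
# ---------------------------------------------------------------------------

def gene_signal_change(
    kd_track: CoverageTrack,
    ctrl_track: CoverageTrack,
    gene: GeneModel,
    region: str = "tss_window",
    window: int = 2000,
) -> GeneSignalChange:
    """Mean signal difference for one gene over the chosen region.

    The TSS window is strand-agnostic (a symmetric +/- window bp around the
    TSS); the gene body is [start, end).  Both tracks must share state and
    binning.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if window <= 0:
        raise ValueError("window must be > 0")
    if kd_track.state != ctrl_track.state or not kd_track.same_shape(ctrl_track):
        raise ValueError("tracks differ in normalization state or shape")
    bs = kd_track.bin_size
    chrom_len = kd_track.chrom_len(gene.chrom)
    if region == "tss_window":
        lo, hi = gene.tss - window, gene.tss + window
        if lo < 0 or hi > chrom_len:
            raise WindowError(
                f"gene {gene.gene_id!r}: window [{lo},{hi}) outside chromosome"
            )
    else:
        lo, hi = gene.start, gene.end
    b0, b1 = lo // bs, -(-hi // bs)
    kd_mean = float(kd_track.values[gene.chrom][b0:b1].mean())
    ctrl_mean = float(ctrl_track.values[gene.chrom][b0:b1].mean())
    return GeneSignalChange(gene.gene_id, region, window, kd_mean - ctrl_mean)


def signal_change_table(
    kd_track: CoverageTrack,
    ctrl_track: CoverageTrack,
    genes: list[GeneModel],
    region: str = "tss_window",
    window: int = 2000,
) -> pd.DataFrame:
    """Per-gene signal changes for a whole annotation; edge genes skipped."""
    rows = []
    skipped = []
    for gene in genes:
        try:
            change = gene_signal_change(kd_track, ctrl_track, gene, region, window)
        except WindowError:
            skipped.append(gene.gene_id)
            continue
        rows.append({"gene_id": change.gene_id, "region": region, "delta": change.delta})
    if skipped:
        logger.info("signal_change_table: skipped %d gene(s) at edges: %s",
                    len(skipped), skipped[:5])
    return pd.DataFrame(rows, columns=["gene_id", "region", "delta"])


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho with a two-sided p-value.

    Average ranks for ties; rho is the Pearson correlation of the ranks.
    Exact permutation p for n < 10, t-approximation otherwise.  A constant
    input raises :class:`ConstantInputError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _pearson(rx, ry)
    if n <= EXACT_N_MAX:
        p = _exact_p(rx, ry, rho)
    else:
        denom = max(1.0 - rho * rho, 1e-300)
        t = rho * math.sqrt((n - 2) / denom)
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, min(p, 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    return float(ac @ bc / math.sqrt((ac @ ac) * (bc @ bc)))


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p: share of the n! orderings of y with |rho| >= |obs|."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    scale = math.sqrt((rxc @ rxc) * (ryc @ ryc))
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    rhos = (ryc[perms] @ rxc) / scale
    hits = int(np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return hits / len(perms)


# ---------------------------------------------------------------------------
# per-class correlation report
# ---------------------------------------------------------------------------

def correlate_by_class(
    de_table: pd.DataFrame,
    signal_changes: pd.DataFrame,
    class_labels: pd.DataFrame,
    mark: str,
    filters: tuple[str, ...] = FILTERS,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Spearman correlation of expression change vs mark change, per class.

    *signal_changes* holds one mark's per-gene deltas (columns gene_id,
    region, delta); classes and filters multiply out to one row each.
    Genes missing from any of the three tables are excluded and counted in
    ``n_excluded``.  Rows with n < 3 or constant input carry NaN rho and a
    reason code.  A Benjamini-Hochberg column over the emitted p-values is
    appended for transparency; the ``significant`` flag itself uses the raw
    per-row p < alpha rule.
    """
    for f in filters:
        if f not in FILTERS:
            raise ValueError(f"unknown filter {f!r}")
    merged = (
        de_table[["gene_id", "log2fc"]]
        .merge(signal_changes, on="gene_id", how="inner")
        .merge(class_labels[["gene_id", "class_label"]], on="gene_id", how="inner")
    )
    n_universe = len(set(de_table["gene_id"]) | set(signal_changes["gene_id"])
                     | set(class_labels["gene_id"]))
    n_excluded = n_universe - merged["gene_id"].nunique()
    rows = []
    for region in sorted(merged["region"].unique()):
        sub_r = merged[merged["region"] == region]
        for label in sorted(sub_r["class_label"].unique()):
            sub_c = sub_r[sub_r["class_label"] == label]
            for filt in filters:
                sub = sub_c if filt == "none" else sub_c[sub_c["log2fc"].abs() >= 1.0]
                rho, p, reason = np.nan, np.nan, None
                if len(sub) < 3:
                    reason = "n_lt_3"
                else:
                    try:
                        rho, p = spearman(sub["log2fc"].to_numpy(), sub["delta"].to_numpy())
                    except ConstantInputError:
                        reason = "constant_input"
                rows.append(
                    {
                        "class_label": label,
                        "mark": mark,
                        "region": region,
                        "filter": filt,
                        "n": len(sub),
                        "n_excluded": n_excluded,
                        "rho": rho,
                        "p_value": p,
                        "significant": bool(p < alpha) if reason is None else False,
                        "reason": reason,
                    }
                )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = np.nan
        defined = out["p_value"].notna()
        if defined.any():
            out.loc[defined, "p_bh"] = stats.false_discovery_control(
                out.loc[defined, "p_value"].to_numpy(), method="bh"
            )
    return out
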