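"""TSS-centered metagene profiles with per-class dispersion bands.

A profile matrix holds one row per gene: the track values in a window of
``flank`` bp either side of the TSS, in gene orientation (column 0 is the
most upstream bin; minus-strand rows are reversed relative to genome
order).  Genes whose window would cross a chromosome end are dropped and
logged rather than padded, so edge effects cannot bias class means.

Per-class aggregation takes the arithmetic mean and population standard
deviation across genes at each bin.  The between-condition log2-ratio
profile is computed on scaled (pre-subtraction) profiles by default with a
pseudocount, because subtracted signal can be negative; computing it on
subtracted profiles is the caller's choice of inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel
from .spike_norm import CoverageTrack

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Per-gene TSS windows: rows = genes (gene order), columns = bins 5'->3'."""

    matrix: np.ndarray          # (n_genes_kept, 2 * flank / bin_size)
    gene_ids: list[str]
    flank: int
    bin_size: int
    dropped: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def center_cols(self) -> tuple[int, int]:
        """The twin center columns flanking the TSS (even column count)."""
        half = self.n_bins // 2
        return (half - 1, half)


@dataclass
class ClassProfile:
    mean: np.ndarray
    sd: np.ndarray
    n_genes: int


@dataclass
class MetageneProfile:
    """Per-class mean/SD profile vectors over a common bin grid."""

    classes: dict[str, ClassProfile]
    flank: int
    bin_size: int

    @property
    def n_bins(self) -> int:
        first = next(iter(self.classes.values()))
        return len(first.mean)


def tss_matrix(track: CoverageTrack, genes: list[GeneModel], flank: int = 2000) -> ProfileMatrix:
    """Extract TSS +/- flank windows for every gene, in gene orientation.

    The track must already be normalized (scaled or subtracted).  Genes
    whose window leaves the chromosome are dropped and recorded in
    ``dropped``.
    """
    if track.state == "raw":
        raise ValueError("tss_matrix expects a scaled or subtracted track")
    if flank % track.bin_size != 0:
        raise ValueError(f"flank {flank} is not a multiple of bin size {track.bin_size}")
    half = flank // track.bin_size
    rows: list[np.ndarray] = []
    kept: list[str] = []
    dropped: list[str] = []
    for gene in genes:
        vals = track.values.get(gene.chrom)
        if vals is None:
            raise ValueError(f"gene {gene.gene_id!r}: chromosome {gene.chrom!r} not in track")
        chrom_len = track.chrom_len(gene.chrom)
        if gene.tss - flank < 0 or gene.tss + flank > chrom_len:
            dropped.append(gene.gene_id)
            continue
        center = gene.tss // track.bin_size
        row = vals[center - half : center + half]
        if gene.strand == "-":
            row = row[::-1]
        rows.append(np.asarray(row, dtype=np.float64))
        kept.append(gene.gene_id)
    if dropped:
        logger.info("tss_matrix: dropped %d gene(s) at chromosome edges: %s",
                    len(dropped), dropped[:5])
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * half))
    return ProfileMatrix(matrix=matrix, gene_ids=kept, flank=flank,
                         bin_size=track.bin_size, dropped=dropped)


def aggregate(matrix: ProfileMatrix, class_labels: pd.DataFrame) -> MetageneProfile:
    """Per-class mean and population SD over the profile matrix rows.

    *class_labels* maps gene_id -> class_label and must cover every kept
    gene.  Classes with no genes in the matrix are omitted with a warning.
    """
    label_map = dict(zip(class_labels["gene_id"], class_labels["class_label"]))
    missing = [g for g in matrix.gene_ids if g not in label_map]
    if missing:
        raise ValueError(f"class labels missing for gene(s): {missing[:5]}")
    labels = np.array([label_map[g] for g in matrix.gene_ids], dtype=object)
    classes: dict[str, ClassProfile] = {}
    for label in sorted(set(label_map.values())):
        mask = labels == label
        n = int(mask.sum())
        if n == 0:
            logger.warning("aggregate: class %r has no genes in matrix; omitted", label)
            continue
        sub = matrix.matrix[mask]
        classes[label] = ClassProfile(
            mean=sub.mean(axis=0), sd=sub.std(axis=0, ddof=0), n_genes=n
        )
    return MetageneProfile(classes=classes, flank=matrix.flank, bin_size=matrix.bin_size)


def log2_ratio_profile(
    knockdown: MetageneProfile, control: MetageneProfile, pseudocount: float = 1.0
) -> dict[str, np.ndarray]:
    """Per-class log2((knockdown + pc) / (control + pc)) profile.

    Positive values mean the knockdown gained signal at that position.
    Intended for scaled (non-negative) profiles; with equal profiles the
    ratio is exactly zero everywhere.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if set(knockdown.classes) != set(control.classes):
        raise ValueError("profiles have different class sets")
    out: dict[str, np.ndarray] = {}
    for label, kd in knockdown.classes.items():
        ctrl = control.classes[label]
        if kd.mean.shape != ctrl.mean.shape:
            raise ValueError(f"class {label!r}: profile shapes differ")
        out[label] = np.log2((kd.mean + pseudocount) / (ctrl.mean + pseudocount))
    return out


def profile_frame(profile: MetageneProfile) -> pd.DataFrame:
    """Long-format export: class, position (bp relative to TSS), mean, sd, n."""
    half = profile.flank // profile.bin_size
    positions = (np.arange(2 * half) - half) * profile.bin_size + profile.bin_size // 2
    rows = []
    for label, cp in profile.classes.items():
        rows.append(
            pd.DataFrame(
                {
                    "class_label": label,
                    "position": positions,
                    "mean": cp.mean,
                    "sd": cp.sd,
                    "n_genes": cp.n_genes,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


CLASS_COLORS = {"X1": "#1f3b73", "X2": "#6fa8dc", "Xins": "#e69138", "none": "#999999"}


def plot_metagene(
    control: MetageneProfile,
    knockdown: MetageneProfile,
    ratio: dict[str, np.ndarray],
    title: str,
    path: str,
) -> None:
    """Mean lines with SD bands per class, plus a log2-ratio subpanel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    half = control.flank // control.bin_size
    x = (np.arange(2 * half) - half) * control.bin_size / 1000.0
    fig, axes = plt.subplots(3, 1, figsize=(6, 8), sharex=True,
                             gridspec_kw={"height_ratios": [2, 2, 1]})
    for ax, prof, label in ((axes[0], control, "control"), (axes[1], knockdown, "knockdown")):
        for cls, cp in prof.classes.items():
            color = CLASS_COLORS.get(cls, "#444444")
            ax.plot(x, cp.mean, color=color, label=f"{cls} (n={cp.n_genes})")
            ax.fill_between(x, cp.mean - cp.sd, cp.mean + cp.sd, color=color, alpha=0.2)
        ax.set_ylabel(f"{label}\nsignal")
        ax.legend(fontsize=7)
    for cls, vec in ratio.items():
        axes[2].plot(x, vec, color=CLASS_COLORS.get(cls, "#444444"), label=cls)
    axes[2].axhline(0.0, color="black", lw=0.5)
    axes[2].set_ylabel("log2 kd/ctrl")
    axes[2].set_xlabel("distance from TSS (kb)")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
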