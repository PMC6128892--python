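"""Spike-in (ChIP-Rx style) normalization of fragment coverage.

The contract that makes exogenous spike-in normalization work: the same
amount of foreign chromatin is added per target cell in every sample, so
the number of fragments mapping to the spike-in genome measures immuno-
precipitation and library efficiency.  Dividing a sample's target-genome
coverage by its spike-in fragment count (times a presentation constant)
puts all samples on a common "signal per million spike-in fragments"
scale, on which genuine genome-wide shifts between conditions survive —
unlike library-size scaling, which forces every sample to the same total
and erases them.

Processing order per sample: partition fragments by genome namespace,
deduplicate each side on exact (chrom, start, end, strand), count the
spike side for the scale factor, bin the target side into coverage,
scale, and subtract the matching scaled input track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import FragmentSet, GenomeSpace, ValidationError

logger = logging.getLogger(__name__)

STATES = ("raw", "scaled", "subtracted")


@dataclass(frozen=True)
class PartitionResult:
    """Fragments split into target-genome and spike-in-genome subsets."""

    target: FragmentSet
    spike: FragmentSet

    @property
    def counts(self) -> tuple[int, int]:
        return (len(self.target), len(self.spike))


@dataclass(frozen=True)
class ScaleFactor:
    """Multiplier putting a sample on the per-million-spike-in scale."""

    alpha: float
    spike_count: int
    reference_count: int = 1_000_000


class CoverageTrack:
    """Binned per-chromosome signal with an explicit normalization state.

    ``state`` moves only forward along raw -> scaled -> subtracted; the
    constructors and arithmetic below enforce this so a track can never be
    double-scaled or subtracted twice by accident.
    """

    def __init__(
        self,
        values: dict[str, np.ndarray],
        bin_size: int,
        state: str = "raw",
        metadata: dict | None = None,
    ) -> None:
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = {c: np.asarray(v, dtype=np.float64) for c, v in values.items()}
        self.bin_size = int(bin_size)
        self.state = state
        self.metadata = dict(metadata or {})

    @classmethod
    def zeros(
        cls,
        space: GenomeSpace,
        bin_size: int = 10,
        state: str = "raw",
        target_only: bool = False,
        metadata: dict | None = None,
    ) -> "CoverageTrack":
        chroms = space.target_chroms if target_only else list(space.chrom_sizes)
        values = {
            c: np.zeros(-(-space.chrom_sizes[c] // bin_size), dtype=np.float64)
            for c in chroms
        }
        track = cls(values, bin_size, state, metadata)
        track.metadata.setdefault("chrom_sizes", {c: space.chrom_sizes[c] for c in chroms})
        return track

    def chrom_len(self, chrom: str) -> int:
        sizes = self.metadata.get("chrom_sizes", {})
        return sizes.get(chrom, len(self.values[chrom]) * self.bin_size)

    def copy(self, state: str | None = None, metadata: dict | None = None) -> "CoverageTrack":
        out = CoverageTrack(
            {c: v.copy() for c, v in self.values.items()},
            self.bin_size,
            state or self.state,
            {**self.metadata, **(metadata or {})},
        )
        return out

    def same_shape(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )

    def mean(self) -> float:
        """Genome-wide mean bin value across all chromosomes in the track."""
        total = sum(float(v.sum()) for v in self.values.values())
        nbins = sum(len(v) for v in self.values.values())
        return total / nbins if nbins else 0.0

    def total(self) -> float:
        return sum(float(v.sum()) for v in self.values.values())


def partition(fragments: FragmentSet, space: GenomeSpace) -> PartitionResult:
    """Split fragments by genome namespace (spike-in name prefix).

    Every chromosome must be known to *space*; an unknown name is an error
    naming it, never a silent drop.
    """
    for chrom in set(fragments.chroms.tolist()):
        space.require(chrom, context="partition")
    if len(fragments) == 0:
        result = PartitionResult(FragmentSet.empty(), FragmentSet.empty())
    else:
        is_spike = np.array([space.is_spike(c) for c in fragments.chroms], dtype=bool)
        result = PartitionResult(fragments.take(~is_spike), fragments.take(is_spike))
    logger.info("partition: %d target, %d spike fragments", *result.counts)
    return result


def deduplicate(fragments: FragmentSet) -> FragmentSet:
    """Keep one fragment per exact (chrom, start, end, strand) tuple.

    The surviving record is the first occurrence; output preserves input
    order, matching coordinate-based duplicate removal on alignments.
    """
    if len(fragments) == 0:
        return fragments
    keys = np.array(
        [
            f"{c}\x00{s}\x00{e}\x00{t}"
            for c, s, e, t in zip(
                fragments.chroms, fragments.starts, fragments.ends, fragments.strands
            )
        ],
        dtype=object,
    )
    _, first_idx = np.unique(keys, return_index=True)
    keep = np.sort(first_idx)
    out = fragments.take(keep)
    logger.info("deduplicate: %d -> %d fragments", len(fragments), len(out))
    return out


def scale_factor(spike_count: int, reference_count: int = 1_000_000) -> ScaleFactor:
    """Spike-in scale factor alpha = reference_count / spike_count.

    A sample with zero spike-in fragments cannot be normalized: hard error.
    """
    if spike_count <= 0:
        raise ValidationError(
            "spike-in fragment count is zero; spike-in normalization undefined"
        )
    return ScaleFactor(
        alpha=reference_count / spike_count,
        spike_count=int(spike_count),
        reference_count=int(reference_count),
    )


def coverage(
    fragments: FragmentSet,
    space: GenomeSpace,
    bin_size: int = 10,
    target_only: bool = True,
    metadata: dict | None = None,
) -> CoverageTrack:
    """Bin fragments into overlap coverage: a bin counts every fragment
    overlapping it by at least one bp (a fragment spanning k bins adds k).

    By default only target-genome chromosomes get a vector; spike-in
    fragments should be counted, not piled up.
    """
    track = CoverageTrack.zeros(
        space, bin_size=bin_size, state="raw", target_only=target_only, metadata=metadata
    )
    if len(fragments) == 0:
        return track
    chrom_arr = fragments.chroms
    for chrom, vals in track.values.items():
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        starts = fragments.starts[mask]
        ends = fragments.ends[mask]
        b0 = starts // bin_size
        b1 = (ends + bin_size - 1) // bin_size  # exclusive bin end
        nbins = len(vals)
        diff = np.bincount(b0, minlength=nbins + 1).astype(np.float64)
        diff -= np.bincount(np.minimum(b1, nbins), minlength=nbins + 1)
        vals += np.cumsum(diff)[:nbins]
    return track


def scale(track: CoverageTrack, sf: ScaleFactor) -> CoverageTrack:
    """Multiply a raw track by its spike-in scale factor (state -> scaled)."""
    if track.state != "raw":
        raise ValueError(f"can only scale a raw track, got state {track.state!r}")
    out = track.copy(state="scaled", metadata={"alpha": sf.alpha, "spike_count": sf.spike_count})
    for v in out.values.values():
        v *= sf.alpha
    return out


def normalize_subtract(
    chip: CoverageTrack,
    input_track: CoverageTrack,
    chip_sf: ScaleFactor,
    input_sf: ScaleFactor,
    clip_negative: bool = False,
) -> CoverageTrack:
    """Spike-in scale both raw tracks, then subtract input from ChIP per bin.

    value = chip_sf.alpha * chip - input_sf.alpha * input.  Negative values
    are retained unless *clip_negative*; the subtraction is linear in each
    input track.
    """
    if chip.state != "raw" or input_track.state != "raw":
        raise ValueError("normalize_subtract expects raw tracks")
    if not chip.same_shape(input_track):
        raise ValueError("ChIP and input tracks differ in binning or chromosomes")
    out = chip.copy(
        state="subtracted",
        metadata={
            "chip_alpha": chip_sf.alpha,
            "input_alpha": input_sf.alpha,
            "clip_negative": clip_negative,
        },
    )
    for c in out.values:
        out.values[c] = chip_sf.alpha * chip.values[c] - input_sf.alpha * input_track.values[c]
        if clip_negative:
            np.clip(out.values[c], 0.0, None, out=out.values[c])
    return out


def average_tracks(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Average replicate tracks bin-wise (all must share state and shape)."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if t.state != first.state or not first.same_shape(t):
            raise ValueError("replicate tracks differ in state or shape")
    out = first.copy(metadata={"n_replicates": len(tracks)})
    for c in out.values:
        for t in tracks[1:]:
            out.values[c] += t.values[c]
        out.values[c] /= len(tracks)
    return out
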