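"""Readers and writers for every on-disk format the pipeline touches.

All internal coordinates are 0-based half-open, on both strands.  GFF3 is
converted on read (1-based closed -> 0-based half-open) and back on write.
The TSS of a plus-strand gene is ``start``; of a minus-strand gene ``end - 1``
(the last base of the half-open interval).

Spike-in versus target genome membership is decided purely by chromosome
name: chromosomes whose name starts with :attr:`GenomeSpace.spike_prefix`
belong to the exogenous spike-in genome, everything else to the target
genome.  This mirrors alignment to a combined target+spike-in reference
followed by read separation, without requiring an aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A line of an input file could not be parsed; carries the line number."""


class ValidationError(ValueError):
    """Parsed content violates a documented invariant (names the offender)."""


@dataclass(frozen=True)
class GenomeSpace:
    """The combined reference: chromosome sizes plus the spike-in name rule.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.  Lengths must be positive.
    spike_prefix
        Chromosomes whose names start with this prefix are spike-in.
    """

    chrom_sizes: dict[str, int]
    spike_prefix: str = "spike_"

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {chrom!r} has non-positive length {size}")

    def is_spike(self, chrom: str) -> bool:
        return chrom.startswith(self.spike_prefix)

    @property
    def target_chroms(self) -> list[str]:
        return [c for c in self.chrom_sizes if not self.is_spike(c)]

    @property
    def spike_chroms(self) -> list[str]:
        return [c for c in self.chrom_sizes if self.is_spike(c)]

    def require(self, chrom: str, context: str = "") -> int:
        """Return the size of *chrom*, raising if it is unknown."""
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            suffix = f" ({context})" if context else ""
            raise ValidationError(f"unknown chromosome {chrom!r}{suffix}") from None


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene: the unit of classification, profiling and correlation."""

    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} not < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base in gene orientation."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment (surrogate for an aligned, deduplicated pair)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"


class FragmentSet:
    """Fragments from one sample, stored columnar for speed.

    Columns are parallel arrays; ``chroms`` is an object array of names.
    Spans both target and spike-in namespaces of a :class:`GenomeSpace`.
    """

    __slots__ = ("chroms", "starts", "ends", "strands")

    def __init__(
        self,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        strands: np.ndarray,
    ) -> None:
        n = len(chroms)
        if not (len(starts) == len(ends) == len(strands) == n):
            raise ValueError("column length mismatch")
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=object)

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord]) -> "FragmentSet":
        recs = list(records)
        return cls(
            np.array([r.chrom for r in recs], dtype=object),
            np.array([r.start for r in recs], dtype=np.int64),
            np.array([r.end for r in recs], dtype=np.int64),
            np.array([r.strand for r in recs], dtype=object),
        )

    @classmethod
    def empty(cls) -> "FragmentSet":
        z = np.array([], dtype=object)
        return cls(z, np.array([], dtype=np.int64), np.array([], dtype=np.int64), z.copy())

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[FragmentRecord]:
        for c, s, e, t in zip(self.chroms, self.starts, self.ends, self.strands):
            yield FragmentRecord(c, int(s), int(e), t)

    def take(self, index: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            self.chroms[index], self.starts[index], self.ends[index], self.strands[index]
        )

    def concat(self, other: "FragmentSet") -> "FragmentSet":
        return FragmentSet(
            np.concatenate([self.chroms, other.chroms]),
            np.concatenate([self.starts, other.starts]),
            np.concatenate([self.ends, other.ends]),
            np.concatenate([self.strands, other.strands]),
        )

    def validate(self, space: GenomeSpace) -> None:
        """Check every record lies inside a chromosome of *space*."""
        for i, (c, s, e) in enumerate(zip(self.chroms, self.starts, self.ends)):
            size = space.require(c, context=f"fragment {i}")
            if s < 0 or e > size:
                raise ValidationError(
                    f"fragment {i} [{s},{e}) outside chromosome {c!r} of length {size}"
                )
            if not s < e:
                raise ValidationError(f"fragment {i}: start {s} not < end {e}")


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path, spike_prefix: str = "spike_") -> GenomeSpace:
    """Read a two-column TSV (name, length) into a :class:`GenomeSpace`."""
    sizes: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            name, raw_size = parts[0], parts[1]
            try:
                size = int(raw_size)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length {raw_size!r}") from None
            if name in sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = size
    return GenomeSpace(chrom_sizes=sizes, spike_prefix=spike_prefix)


def write_chrom_sizes(space: GenomeSpace, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, size in space.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")


# ---------------------------------------------------------------------------
# gene annotations (BED6 / BED12 / GFF3)
# ---------------------------------------------------------------------------

def _looks_like_gff3(path: Path) -> bool:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#") or not line.strip():
                continue
            return len(line.rstrip("\n").split("\t")) == 9
    return False


def _gff3_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr_field.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key] = value
    return out


def read_annotation(path: str | Path, space: GenomeSpace) -> list[GeneModel]:
    """Read gene models from GFF3 or BED (detected by content).

    GFF3 ``gene`` features (or every feature, if no ``gene`` rows exist) are
    converted from 1-based closed to 0-based half-open coordinates.  BED is
    taken as-is.  Every feature is validated against *space*; input order is
    preserved.
    """
    path = Path(path)
    genes = read_gff3_genes(path) if _looks_like_gff3(path) else read_bed_genes(path)
    seen: set[str] = set()
    for g in genes:
        size = space.require(g.chrom, context=f"gene {g.gene_id!r}")
        if g.start < 0 or g.end > size:
            raise ValidationError(
                f"gene {g.gene_id!r} [{g.start},{g.end}) outside chromosome "
                f"{g.chrom!r} of length {size}"
            )
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def read_bed_genes(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: BED gene line needs >= 4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = parts[5] if len(parts) >= 6 else "+"
            try:
                genes.append(GeneModel(parts[3], parts[0], start, end, strand))
            except ValidationError as err:
                raise ParseError(f"{path}:{lineno}: {err}") from None
    return genes


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 line needs 9 columns")
            if parts[2] != "gene":
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = _gff3_attributes(parts[8])
            gene_id = attrs.get("ID") or attrs.get("Name")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: gene feature lacks ID attribute")
            try:
                # 1-based closed -> 0-based half-open
                genes.append(GeneModel(gene_id, parts[0], start1 - 1, end1, parts[6]))
            except ValidationError as err:
                raise ParseError(f"{path}:{lineno}: {err}") from None
    return genes


def write_bed_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tchromexpress\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# fragments (BED3/BED6, optional SAM/BAM adapter)
# ---------------------------------------------------------------------------

def read_fragments(path: str | Path, space: GenomeSpace) -> FragmentSet:
    """Read fragment intervals from a BED3/BED6 file and validate them.

    Column 6 (strand) is optional and defaults to ``+``.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED fragment line needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if not start < end:
                raise ParseError(f"{path}:{lineno}: start {start} not < end {end}")
            chrom = parts[0]
            size = space.require(chrom, context=f"{path}:{lineno}")
            if start < 0 or end > size:
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start},{end}) outside "
                    f"chromosome {chrom!r} of length {size}"
                )
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(parts[5] if len(parts) >= 6 else "+")
    if not chroms:
        logger.warning("no fragments read from %s", path)
        return FragmentSet.empty()
    frags = FragmentSet(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(strands, dtype=object),
    )
    logger.info("read %d fragments from %s", len(frags), path)
    return frags


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c, s, e, t in zip(frags.chroms, frags.starts, frags.ends, frags.strands):
            fh.write(f"{c}\t{s}\t{e}\t.\t0\t{t}\n")


def read_fragments_alignment(path: str | Path, space: GenomeSpace) -> FragmentSet:
    """Adapter: convert properly paired alignments (SAM/BAM) to fragments.

    Each proper pair contributes one fragment spanning the pair's outer
    coordinates, taken once from the forward-oriented mate (template length
    > 0).  Requires pysam.
    """
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or not read.is_proper_pair or read.is_secondary:
                continue
            if read.template_length <= 0:  # count each pair once
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + read.template_length)
    strands = ["+"] * len(chroms)
    frags = FragmentSet(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(strands, dtype=object),
    )
    frags.validate(space)
    return frags


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track, path: str | Path) -> None:
    """Write a CoverageTrack as bedGraph, merging equal-valued adjacent bins.

    Values use fixed 6-decimal formatting; a write-then-read round trip
    reproduces the binned values exactly (values are quantized to 1e-6 on
    write, so the track written should already be at that precision or the
    caller accepts the quantization).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.values:
            vals = track.values[chrom]
            n = len(vals)
            if n == 0:
                continue
            chrom_len = track.chrom_len(chrom)
            # run-length merge over bins
            change = np.flatnonzero(np.diff(vals)) + 1
            run_starts = np.concatenate([[0], change])
            run_ends = np.concatenate([change, [n]])
            for b0, b1 in zip(run_starts, run_ends):
                start = int(b0) * track.bin_size
                end = min(int(b1) * track.bin_size, chrom_len)
                fh.write(f"{chrom}\t{start}\t{end}\t{vals[b0]:.6f}\n")


def read_bedgraph(path: str | Path, space: GenomeSpace, bin_size: int):
    """Read a bedGraph written by :func:`write_bedgraph` back into a track."""
    from .spike_norm import CoverageTrack

    track = CoverageTrack.zeros(space, bin_size=bin_size, state="raw")
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: bedGraph line needs 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            space.require(chrom, context=f"{path}:{lineno}")
            b0 = start // bin_size
            b1 = (end + bin_size - 1) // bin_size
            track.values[chrom][b0:b1] = value
    return track


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

EXPRESSION_COLUMNS = ("gene_id", "prop_X1", "prop_X2", "prop_Xins")
DE_COLUMNS = ("gene_id", "log2fc", "p_value")


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read the per-gene proportional-expression table (X1/X2/Xins)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing expression columns {missing}")
    return df


def read_de_table(
    path: str | Path,
    gene_col: str = "gene_id",
    fc_col: str = "log2fc",
    p_col: str = "p_value",
) -> pd.DataFrame:
    """Read a differential-expression table (gene id, log2 FC, p-value)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in (gene_col, fc_col, p_col) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing DE columns {missing}")
    return df.rename(columns={gene_col: "gene_id", fc_col: "log2fc", p_col: "p_value"})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
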