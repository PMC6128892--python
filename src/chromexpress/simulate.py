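"""Synthetic dataset generator with planted, recorded ground truth.

Emulates the study design the pipeline targets: three histone marks
(H3K4me3, H3K4me1, H3K27me3) plus an input sample, two conditions
(knockdown vs control), an exogenous spike-in genome contributing roughly
15% of each sample's fragments, three FACS expression-enrichment classes
(X1 / X2 / Xins, plus unclassified), and a differential-expression table
with a few percent of genes mis-regulated in each direction.

Generative model
----------------
Genes tile the target chromosome at regular spacing on alternating
strands.  Each ChIP sample is a mixture of uniform background fragments
and promoter fragments whose centers are Gaussian around gene TSSs; the
expected promoter fragment count of a gene is proportional to its planted
enrichment rate, which differs by expression class and mark.  The spike-in
chromosome receives a fixed fragment count in every sample — the spike-in
contract.  In the knockdown condition the target-genome yield of every
sample (input included) is multiplied by ``global_chip_shift``, modeling a
global change in recovered target chromatin per spiked cell: this is the
signal spike-in normalization must recover and library-size scaling must
erase.

Within one designated (class, mark) cell, per-gene knockdown/control
enrichment changes are rank-coupled to the planted expression log2 fold
changes through a Gaussian copula at strength ``coupling_rho``, so the
integration stage has a known correlation to recover.  For that cell the
control enrichment is held constant across genes, which makes the planted
change a strictly monotone function of the copula latent and therefore
recoverable by rank correlation.

Sample fragment totals are deterministic rounded expectations; all
randomness lives in fragment placement and per-gene allocation.  Identical
configurations (including seed) produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    FragmentSet,
    GeneModel,
    GenomeSpace,
    write_bed_genes,
    write_chrom_sizes,
    write_fragments,
    write_table,
)

MARKS = ("H3K4me3", "H3K4me1", "H3K27me3")
SAMPLES = MARKS + ("input",)
CONDITIONS = ("control", "knockdown")
CLASSES = ("X1", "X2", "Xins", "none")

# Mean promoter enrichment rate by (mark, class), in arbitrary rate units.
# Shapes mimic the marks' conserved roles: the active-promoter mark highest
# at stem-cell genes, the repressive mark highest at differentiated-cell
# genes, the enhancer/promoter mono-methyl mark broad and class-neutral.
BASE_ENRICHMENT = {
    "H3K4me3": {"X1": 3.0, "X2": 2.0, "Xins": 1.2, "none": 0.8},
    "H3K4me1": {"X1": 1.5, "X2": 1.5, "Xins": 1.5, "none": 1.0},
    "H3K27me3": {"X1": 0.8, "X2": 1.2, "Xins": 2.0, "none": 1.0},
}

LOG2_15 = math.log2(1.5)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-scale conditions."""

    seed: int = 0
    n_genes: int = 1000
    gene_len: int = 2000
    chrom_len: int = 6_000_000
    spike_chrom_len: int = 1_000_000
    spike_fraction: float = 0.15
    global_chip_shift: float = 1.0
    class_proportions: dict = field(
        default_factory=lambda: {"X1": 0.3, "X2": 0.3, "Xins": 0.3, "none": 0.1}
    )
    n_de_up: int = 25
    n_de_down: int = 25
    coupling_rho: float = -0.5
    coupled_class: str = "X1"
    coupled_mark: str = "H3K4me1"
    fragment_len: int = 200
    n_fragments: int = 100_000
    peak_sd: float = 200.0
    fragment_len_sd: float = 20.0  # sonication-length spread
    background_fraction: float = 0.3
    duplication_rate: float = 0.0
    delta_scale: float = 1.0  # sd of planted per-gene log2 mark change
    enrichment_sigma: float = 0.25  # lognormal spread of uncoupled enrichments

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if any(not 0.0 <= p <= 1.0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must lie in [0, 1]")
        if total > 1.0 + 1e-9:
            raise ValueError("class proportions must sum to <= 1")
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [-1, 1]")
        for name in ("n_genes", "n_de_up", "n_de_down", "n_fragments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.spike_fraction < 1.0:
            raise ValueError("spike_fraction must lie in [0, 1)")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("more planted DE genes than genes")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted per-gene truth plus per-sample expected target-yield factors.

    ``genes`` is indexed by gene_id and carries class_label, de_status,
    log2fc, p_value and enrich_<mark>_<condition> columns.
    """

    genes: pd.DataFrame
    sample_scales: dict

    def class_gene_ids(self, label: str) -> list[str]:
        return self.genes.index[self.genes["class_label"] == label].tolist()


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


# ---------------------------------------------------------------------------
# genomes and annotation
# ---------------------------------------------------------------------------

def make_genomes(config: SimulationConfig) -> tuple[GenomeSpace, list[GeneModel]]:
    """Build the combined target+spike-in reference and the gene annotation.

    Genes tile ``chr1`` at regular pitch on alternating strands, each with
    >= 2 kb flanks inside its slot so TSS windows never cross chromosome
    ends; the spike-in chromosome carries no genes.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    pitch = config.chrom_len // config.n_genes
    margin = (pitch - config.gene_len) // 2
    if margin < 2000:
        raise ValueError(
            f"chromosome of {config.chrom_len} bp too short for {config.n_genes} "
            f"genes of {config.gene_len} bp with 2 kb flanks (pitch {pitch})"
        )
    space = GenomeSpace(
        chrom_sizes={"chr1": config.chrom_len, "spike_chr1": config.spike_chrom_len},
        spike_prefix="spike_",
    )
    width = len(str(config.n_genes))
    genes = [
        GeneModel(
            gene_id=f"g{i:0{width}d}",
            chrom="chr1",
            start=i * pitch + margin,
            end=i * pitch + margin + config.gene_len,
            strand="+" if i % 2 == 0 else "-",
        )
        for i in range(config.n_genes)
    ]
    return space, genes


# ---------------------------------------------------------------------------
# ground truth (classes, DE, enrichments, copula coupling)
# ---------------------------------------------------------------------------

def make_truth(config: SimulationConfig, genes: list[GeneModel]) -> GroundTruth:
    n = len(genes)
    rng = _rng(config, 1)

    # exact class counts (rounded proportions, remainder unclassified)
    counts = {c: round(config.class_proportions.get(c, 0.0) * n) for c in ("X1", "X2", "Xins")}
    if sum(counts.values()) > n:
        raise ValueError("class proportions leave no room at this n_genes")
    labels = np.array(
        sum(([c] * k for c, k in counts.items()), []) + ["none"] * (n - sum(counts.values())),
        dtype=object,
    )
    rng.shuffle(labels)

    # planted DE: exact counts, thresholds guaranteed by construction
    de_status = np.array(["unchanged"] * n, dtype=object)
    de_idx = rng.choice(n, size=config.n_de_up + config.n_de_down, replace=False)
    de_status[de_idx[: config.n_de_up]] = "up"
    de_status[de_idx[config.n_de_up :]] = "down"
    log2fc = np.empty(n)
    p_value = np.empty(n)
    up = de_status == "up"
    down = de_status == "down"
    flat = de_status == "unchanged"
    log2fc[up] = rng.uniform(LOG2_15 + 1e-6, 4.0, size=up.sum())
    log2fc[down] = rng.uniform(-4.0, -LOG2_15 - 1e-6, size=down.sum())
    log2fc[flat] = rng.uniform(-LOG2_15 + 1e-6, LOG2_15 - 1e-6, size=flat.sum())
    p_value[up | down] = rng.uniform(1e-12, 0.05 - 1e-9, size=(up | down).sum())
    p_value[flat] = rng.uniform(0.05 + 1e-9, 1.0, size=flat.sum())

    # enrichment rates per mark/condition
    enrich: dict[str, np.ndarray] = {}
    for mark in MARKS:
        base = np.array([BASE_ENRICHMENT[mark][c] for c in labels])
        spread = rng.lognormal(mean=0.0, sigma=config.enrichment_sigma, size=n)
        e_ctrl = base * spread
        coupled = (labels == config.coupled_class) & (mark == config.coupled_mark)
        # constant control level in the coupled cell -> monotone planted change
        e_ctrl[coupled] = BASE_ENRICHMENT[mark][config.coupled_class]
        enrich[f"enrich_{mark}_control"] = e_ctrl
        enrich[f"enrich_{mark}_knockdown"] = e_ctrl.copy()

    # Gaussian copula: couple the designated class's mark changes to log2fc
    coupled_mask = labels == config.coupled_class
    n_c = int(coupled_mask.sum())
    if n_c >= 2:
        r_star = 2.0 * math.sin(math.pi * config.coupling_rho / 6.0)
        z1 = rng.standard_normal(n_c)
        z2 = r_star * z1 + math.sqrt(max(0.0, 1.0 - r_star**2)) * rng.standard_normal(n_c)
        # mark change: strictly monotone in z1
        delta_log2 = config.delta_scale * z1
        key = f"enrich_{config.coupled_mark}_knockdown"
        base_val = enrich[f"enrich_{config.coupled_mark}_control"][coupled_mask]
        enrich[key][coupled_mask] = base_val * np.power(2.0, delta_log2)
        # expression change: permute the class's (log2fc, p, status) tuples so
        # their ranks follow z2, preserving marginals and global DE counts
        cidx = np.flatnonzero(coupled_mask)
        order_by_z2 = cidx[np.argsort(z2, kind="stable")]
        order_by_fc = cidx[np.argsort(log2fc[cidx], kind="stable")]
        log2fc[order_by_z2] = log2fc[order_by_fc]
        p_value[order_by_z2] = p_value[order_by_fc]
        de_status[order_by_z2] = de_status[order_by_fc]

    df = pd.DataFrame(
        {
            "class_label": labels,
            "de_status": de_status,
            "log2fc": log2fc,
            "p_value": p_value,
            **enrich,
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )

    scales = {}
    for mark in SAMPLES:
        for cond in CONDITIONS:
            shift = config.global_chip_shift if cond == "knockdown" else 1.0
            scales[(mark, cond)] = shift
    return GroundTruth(genes=df, sample_scales=scales)


# ---------------------------------------------------------------------------
# ChIP / input fragment samples
# ---------------------------------------------------------------------------

def simulate_chip_sample(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
    mark: str,
    condition: str,
) -> FragmentSet:
    """Draw one sample's deduplicated fragment intervals.

    Background fragments are uniform over each genome.  Non-input marks add
    promoter fragments with Gaussian-around-TSS centers, allocated across
    genes proportionally to their planted enrichment in this condition.
    The input sample carries only the uniform nonspecific background, at
    the same expected depth as the ChIP samples' background component, so
    subtracting the spike-scaled input leaves pure promoter signal in
    expectation.  The spike-in count is identical across conditions and
    samples; the knockdown target-genome yield (input included) is
    multiplied by ``global_chip_shift``.
    """
    if mark not in SAMPLES:
        raise ValueError(f"unknown mark {mark!r}; expected one of {SAMPLES}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = _rng(config, 10, SAMPLES.index(mark), CONDITIONS.index(condition))
    shift = config.global_chip_shift if condition == "knockdown" else 1.0
    frag_len = config.fragment_len

    n_spike = round(config.spike_fraction * config.n_fragments)
    n_target_base = config.n_fragments - n_spike

    chrom_len = config.chrom_len
    spike_len = config.spike_chrom_len

    parts_chrom: list[np.ndarray] = []
    parts_start: list[np.ndarray] = []

    # spike-in background: fixed count, every condition (the spike-in contract)
    if n_spike:
        s_starts = rng.integers(0, spike_len - frag_len, size=n_spike)
        parts_chrom.append(np.full(n_spike, "spike_chr1", dtype=object))
        parts_start.append(s_starts)

    if mark == "input":
        # Input models the nonspecific pulldown: the same genomic composition
        # and expected depth as the ChIP samples' uniform background, so
        # input subtraction removes exactly that component in expectation.
        n_bg = round(shift * config.background_fraction * n_target_base)
        n_peak_total = 0
    else:
        n_bg_base = round(config.background_fraction * n_target_base)
        n_peak_base = n_target_base - n_bg_base
        e_ctrl = truth.genes[f"enrich_{mark}_control"].to_numpy()
        e_cond = truth.genes[f"enrich_{mark}_{condition}"].to_numpy()
        yield_ratio = e_cond.sum() / e_ctrl.sum()
        n_bg = round(shift * n_bg_base)
        n_peak_total = round(shift * n_peak_base * yield_ratio)

    if n_bg:
        b_starts = rng.integers(0, chrom_len - frag_len, size=n_bg)
        parts_chrom.append(np.full(n_bg, "chr1", dtype=object))
        parts_start.append(b_starts)

    if n_peak_total:
        weights = e_cond / e_cond.sum()
        per_gene = rng.multinomial(n_peak_total, weights)
        tss = np.array([g.tss for g in genes])
        centers = np.repeat(tss, per_gene) + rng.normal(
            0.0, config.peak_sd, size=n_peak_total
        )
        p_starts = np.rint(centers).astype(np.int64) - frag_len // 2
        np.clip(p_starts, 0, chrom_len - frag_len, out=p_starts)
        parts_chrom.append(np.full(n_peak_total, "chr1", dtype=object))
        parts_start.append(p_starts)

    chroms = np.concatenate(parts_chrom) if parts_chrom else np.array([], dtype=object)
    starts = (
        np.concatenate(parts_start).astype(np.int64)
        if parts_start
        else np.array([], dtype=np.int64)
    )
    # per-fragment sonication lengths; variable lengths keep coincidental
    # exact-coordinate collisions (which dedup would eat) negligible
    lens = np.rint(rng.normal(frag_len, config.fragment_len_sd, size=len(starts)))
    lens = np.clip(lens, max(20, frag_len // 4), None).astype(np.int64)
    ends = starts + lens
    limits = np.where(chroms == "chr1", chrom_len, spike_len)
    np.minimum(ends, limits, out=ends)
    strands = rng.choice(np.array(["+", "-"], dtype=object), size=len(starts))
    order = rng.permutation(len(starts))
    frags = FragmentSet(chroms[order], starts[order], ends[order], strands[order])

    if config.duplication_rate > 0 and len(frags):
        n_dup = round(config.duplication_rate * len(frags))
        dup_idx = rng.choice(len(frags), size=n_dup, replace=True)
        frags = frags.concat(frags.take(dup_idx))
    return frags


# ---------------------------------------------------------------------------
# expression profiles and DE table
# ---------------------------------------------------------------------------

def simulate_expression_profiles(
    config: SimulationConfig, genes: list[GeneModel], truth: GroundTruth
) -> pd.DataFrame:
    """Per-gene proportional expression over X1/X2/Xins, honoring the class.

    A gene of class C gets prop_C ~ U(0.55, 0.95) with the remainder split
    uniformly between the other two compartments; unclassified genes get a
    symmetric Dirichlet draw rejected until no compartment exceeds 0.5.
    Rows sum to 1 to within 1e-9.
    """
    rng = _rng(config, 2)
    compartments = ("X1", "X2", "Xins")
    rows = np.empty((len(genes), 3))
    labels = truth.genes["class_label"].to_numpy()
    for i, label in enumerate(labels):
        if label == "none":
            while True:
                p = rng.dirichlet([5.0, 5.0, 5.0])
                if p.max() < 0.5:
                    break
            rows[i] = p
        else:
            j = compartments.index(label)
            major = rng.uniform(0.55, 0.95)
            split = rng.uniform()
            rest = 1.0 - major
            vals = [rest * split, rest * (1.0 - split)]
            row = np.empty(3)
            row[j] = major
            row[[k for k in range(3) if k != j]] = vals
            rows[i] = row
    rows /= rows.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "prop_X1": rows[:, 0],
            "prop_X2": rows[:, 1],
            "prop_Xins": rows[:, 2],
        }
    )


def simulate_de_table(
    config: SimulationConfig, genes: list[GeneModel], truth: GroundTruth
) -> pd.DataFrame:
    """Emit the planted differential-expression table (log2fc, p-value)."""
    return pd.DataFrame(
        {
            "gene_id": truth.genes.index,
            "log2fc": truth.genes["log2fc"].to_numpy(),
            "p_value": truth.genes["p_value"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# whole-dataset convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    space: GenomeSpace
    genes: list[GeneModel]
    truth: GroundTruth
    expression: pd.DataFrame
    de_table: pd.DataFrame
    fragments: dict  # (mark, condition) -> FragmentSet


def simulate_all(
    config: SimulationConfig, marks: tuple[str, ...] = SAMPLES
) -> SimulatedDataset:
    """Generate every pipeline input for the given marks plus ground truth."""
    space, genes = make_genomes(config)
    truth = make_truth(config, genes)
    expression = simulate_expression_profiles(config, genes, truth)
    de_table = simulate_de_table(config, genes, truth)
    fragments = {
        (mark, cond): simulate_chip_sample(config, genes, truth, mark, cond)
        for mark in marks
        for cond in CONDITIONS
    }
    return SimulatedDataset(config, space, genes, truth, expression, de_table, fragments)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every input in the formats the readers consume, plus provenance.

    Returns a name -> path map of everything written (ground_truth.tsv and
    the resolved config are provenance, not pipeline inputs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    write_chrom_sizes(dataset.space, paths["chrom_sizes"])
    paths["annotation"] = outdir / "genes.bed"
    write_bed_genes(dataset.genes, paths["annotation"])
    paths["expression_profiles"] = outdir / "expression_profiles.tsv"
    write_table(dataset.expression, paths["expression_profiles"])
    paths["de_table"] = outdir / "de_table.tsv"
    write_table(dataset.de_table, paths["de_table"])
    for (mark, cond), frags in dataset.fragments.items():
        key = f"fragments_{mark}_{cond}"
        paths[key] = outdir / f"{mark}_{cond}.bed"
        write_fragments(frags, paths[key])

    truth_out = dataset.truth.genes.reset_index()
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    write_table(truth_out, paths["ground_truth"])
    paths["config"] = outdir / "simulation_config.yaml"
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return paths
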