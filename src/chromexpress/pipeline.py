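"""End-to-end pipeline: one validated config, one deterministic run.

Stages run in dependency order — simulate (optional), normalize, classify,
DE selection, metagene profiles, correlation, enrichment — and every file
produced is listed in a manifest with SHA-256 checksums of inputs and
outputs plus the fully resolved configuration.  Reruns with an identical
config are byte-identical.  If the expression or DE table is absent the
dependent stages are skipped with an explicit notice; normalization still
runs.

Replicates are normalized independently (each with its own spike-in scale
factor) and averaged at the subtracted-track stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import differential, enrichment, expression_classes, integration, metagene
from .io_formats import (
    GenomeSpace,
    read_annotation,
    read_chrom_sizes,
    read_de_table,
    read_expression_table,
    read_fragments,
    write_bedgraph,
    write_table,
)
from .simulate import CONDITIONS, MARKS, SimulationConfig, simulate_all, write_dataset
from .spike_norm import (
    average_tracks,
    coverage,
    deduplicate,
    normalize_subtract,
    partition,
    scale,
    scale_factor,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is invalid; message names the problem."""


@dataclass
class AnalysisParameters:
    """Every analysis threshold, with its default.

    fc_threshold and de_alpha gate DE selection (linear fold change 1.5,
    p < 0.05); class_cutoff is the strict >50% expression rule; flank is
    the TSS window half-width in bp; corr_alpha the Spearman significance
    level; enrich_alpha the hypergeometric significance level; fc_filter
    the |log2FC| cutoff of the filtered correlation; spike_fraction_hint
    documents the expected spike-in share of fragments.
    """

    fc_threshold: float = 1.5
    de_alpha: float = 0.05
    class_cutoff: float = 0.5
    flank: int = 2000
    corr_alpha: float = 0.001
    enrich_alpha: float = 0.01
    fc_filter: float = 1.0
    spike_fraction_hint: float = 0.15
    bin_size: int = 10
    pseudocount: float = 1.0
    unions: bool = False
    clip_negative: bool = False

    def validate(self) -> None:
        checks = [
            (self.fc_threshold > 1, "fc_threshold must be > 1"),
            (0 < self.de_alpha < 1, "de_alpha must lie in (0, 1)"),
            (0 < self.class_cutoff < 1, "class_cutoff must lie in (0, 1)"),
            (self.flank > 0, "flank must be > 0"),
            (0 < self.corr_alpha < 1, "corr_alpha must lie in (0, 1)"),
            (0 < self.enrich_alpha < 1, "enrich_alpha must lie in (0, 1)"),
            (self.fc_filter >= 0, "fc_filter must be >= 0"),
            (0 <= self.spike_fraction_hint < 1, "spike_fraction_hint must lie in [0, 1)"),
            (self.bin_size > 0, "bin_size must be > 0"),
            (self.flank % self.bin_size == 0, "flank must be a multiple of bin_size"),
            (self.pseudocount > 0, "pseudocount must be > 0"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)


@dataclass
class PipelineConfig:
    output_dir: Path
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)
    parameters: AnalysisParameters = field(default_factory=AnalysisParameters)

    def resolved(self) -> dict:
        out = {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "parameters": asdict(self.parameters),
            "inputs": {
                k: (str(v) if isinstance(v, (str, Path)) else v)
                for k, v in self.inputs.items()
            },
        }
        if self.simulate is not None:
            out["simulate"] = self.simulate.to_dict()
        return out


_TOP_KEYS = {"output_dir", "seed", "simulate", "inputs", "parameters"}
_INPUT_KEYS = {
    "annotation",
    "chrom_sizes",
    "spike_prefix",
    "expression_profiles",
    "de_table",
    "fragments",
    "input_fragments",
    "term_map",
}


def validate_config(path: str | Path, output_dir: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config, injecting defaults.

    Unknown keys, out-of-range parameters and missing input files are each
    reported individually by name.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    params_dict = raw.get("parameters") or {}
    allowed = set(AnalysisParameters.__dataclass_fields__)
    unknown = set(params_dict) - allowed
    if unknown:
        raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
    parameters = AnalysisParameters(**params_dict)
    parameters.validate()

    sim_cfg = None
    if raw.get("simulate") is not None:
        sim_dict = dict(raw["simulate"])
        allowed = set(SimulationConfig.__dataclass_fields__)
        unknown = set(sim_dict) - allowed
        if unknown:
            raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
        sim_dict.setdefault("seed", raw.get("seed", 0))
        try:
            sim_cfg = SimulationConfig(**sim_dict)
        except ValueError as err:
            raise ConfigError(f"simulate: {err}") from None

    inputs = dict(raw.get("inputs") or {})
    unknown = set(inputs) - _INPUT_KEYS
    if unknown:
        raise ConfigError(f"unknown input key(s): {sorted(unknown)}")
    if sim_cfg is None:
        for key in ("annotation", "chrom_sizes"):
            if key not in inputs:
                raise ConfigError(f"inputs.{key} is required when not simulating")
        for key in ("annotation", "chrom_sizes", "expression_profiles", "de_table", "term_map"):
            if key in inputs and not Path(inputs[key]).exists():
                raise ConfigError(f"inputs.{key}: file not found: {inputs[key]}")
        for mark, conds in (inputs.get("fragments") or {}).items():
            for cond, paths in conds.items():
                for p in _as_list(paths):
                    if not Path(p).exists():
                        raise ConfigError(
                            f"inputs.fragments.{mark}.{cond}: file not found: {p}"
                        )

    out_dir = Path(output_dir) if output_dir is not None else Path(
        raw.get("output_dir", "chromexpress_out")
    )
    config = PipelineConfig(
        output_dir=out_dir,
        seed=int(raw.get("seed", 0)),
        simulate=sim_cfg,
        inputs=inputs,
        parameters=parameters,
    )
    return config


def _as_list(value) -> list:
    return value if isinstance(value, list) else [value]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    output_dir: Path
    manifest: dict
    tracks: dict            # (mark, condition, state) -> CoverageTrack
    classes: pd.DataFrame | None
    de_status: pd.DataFrame | None
    correlations: pd.DataFrame | None
    enrichment: pd.DataFrame | None


def run_all(config: PipelineConfig) -> RunResult:
    """Execute every stage the config allows; returns results and manifest."""
    p = config.parameters
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "resolved_config": config.resolved(),
        "inputs": {},
        "outputs": {},
        "stages": {},
        "notices": [],
    }

    inputs = dict(config.inputs)
    if config.simulate is not None:
        logger.info("stage simulate: generating inputs (seed %d)", config.simulate.seed)
        dataset = simulate_all(config.simulate)
        paths = write_dataset(dataset, outdir / "inputs")
        inputs.update(
            {
                "annotation": paths["annotation"],
                "chrom_sizes": paths["chrom_sizes"],
                "expression_profiles": paths["expression_profiles"],
                "de_table": paths["de_table"],
                "spike_prefix": "spike_",
                "fragments": {
                    mark: {
                        cond: [paths[f"fragments_{mark}_{cond}"]] for cond in CONDITIONS
                    }
                    for mark in MARKS
                },
                "input_fragments": {
                    cond: [paths[f"fragments_input_{cond}"]] for cond in CONDITIONS
                },
            }
        )
        manifest["stages"]["simulate"] = {"n_genes": config.simulate.n_genes}
        for name, pth in paths.items():
            manifest["outputs"][f"inputs/{Path(pth).name}"] = _sha256(Path(pth))

    spike_prefix = inputs.get("spike_prefix", "spike_")
    space = read_chrom_sizes(inputs["chrom_sizes"], spike_prefix=spike_prefix)
    genes = read_annotation(inputs["annotation"], space)
    for key in ("annotation", "chrom_sizes"):
        manifest["inputs"][key] = _sha256(Path(inputs[key]))

    tracks, sample_stats = _stage_normalize(config, inputs, space, manifest)

    classes = de_status = correlations = enrich_table = None
    up: list[str] = []
    down: list[str] = []

    if "expression_profiles" in inputs:
        expression = read_expression_table(inputs["expression_profiles"])
        manifest["inputs"]["expression_profiles"] = _sha256(Path(inputs["expression_profiles"]))
        classes, summary = expression_classes.classify_table(
            expression, unions=p.unions, cutoff=p.class_cutoff
        )
        write_table(classes, outdir / "classes.tsv")
        manifest["outputs"]["classes.tsv"] = _sha256(outdir / "classes.tsv")
        manifest["stages"]["classify"] = {"class_sizes": summary.to_dict()}
    else:
        manifest["notices"].append("no expression_profiles input: classification skipped")

    if "de_table" in inputs:
        de_table = read_de_table(inputs["de_table"])
        manifest["inputs"]["de_table"] = _sha256(Path(inputs["de_table"]))
        de_status = differential.assign_status(de_table, p.fc_threshold, p.de_alpha)
        up, down = differential.select_de(de_table, p.fc_threshold, p.de_alpha)
        write_table(de_status, outdir / "de_status.tsv")
        manifest["outputs"]["de_status.tsv"] = _sha256(outdir / "de_status.tsv")
        manifest["stages"]["de"] = {"n_up": len(up), "n_down": len(down)}
    else:
        de_table = None
        manifest["notices"].append("no de_table input: DE selection skipped")

    if classes is not None:
        _stage_metagene(config, tracks, genes, classes, manifest)
    else:
        manifest["notices"].append("metagene per-class aggregation skipped (no classes)")

    if classes is not None and de_table is not None:
        correlations = _stage_correlate(config, tracks, genes, de_table, classes, manifest)
        enrich_table = enrichment.enrich_de_lists(up, down, classes, alpha=p.enrich_alpha)
        write_table(enrich_table, outdir / "enrichment.tsv")
        manifest["outputs"]["enrichment.tsv"] = _sha256(outdir / "enrichment.tsv")
        manifest["stages"]["enrich"] = {
            "n_significant": int(enrich_table["significant"].sum())
        }
        if "term_map" in inputs:
            term_map = pd.read_csv(inputs["term_map"], sep="\t")
            for direction, gene_list in (("up", up), ("down", down)):
                terms = enrichment.term_enrichment(gene_list, term_map, de_table)
                write_table(terms, outdir / f"term_enrichment_{direction}.tsv")
                manifest["outputs"][f"term_enrichment_{direction}.tsv"] = _sha256(
                    outdir / f"term_enrichment_{direction}.tsv"
                )
    else:
        manifest["notices"].append(
            "correlation and enrichment skipped (need both classes and DE table)"
        )

    manifest["stages"]["normalize"] = sample_stats
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    for notice in manifest["notices"]:
        logger.warning("%s", notice)
    return RunResult(
        output_dir=outdir,
        manifest=manifest,
        tracks=tracks,
        classes=classes,
        de_status=de_status,
        correlations=correlations,
        enrichment=enrich_table,
    )


def simulate_and_normalize(sim_config: SimulationConfig, mark: str) -> tuple:
    """Simulate one mark plus input for both conditions and normalize.

    Convenience for analyses of the normalization itself: returns
    ``(space, genes, truth, per_condition)`` where ``per_condition`` maps
    condition -> {"subtracted": spike-normalized input-subtracted track,
    "scaled": spike-scaled ChIP track, "libsize": ChIP track scaled by its
    own target fragment count instead of the spike-in count}.
    """
    from .simulate import make_genomes, make_truth, simulate_chip_sample

    space, genes = make_genomes(sim_config)
    truth = make_truth(sim_config, genes)
    per_cond: dict = {}
    for cond in CONDITIONS:
        raw = {}
        sfs = {}
        counts = {}
        for m in (mark, "input"):
            frags = simulate_chip_sample(sim_config, genes, truth, m, cond)
            part = partition(frags, space)
            target = deduplicate(part.target)
            spike = deduplicate(part.spike)
            raw[m] = coverage(target, space, bin_size=10)
            sfs[m] = scale_factor(len(spike))
            counts[m] = len(target)
        per_cond[cond] = {
            "subtracted": normalize_subtract(raw[mark], raw["input"], sfs[mark], sfs["input"]),
            "scaled": scale(raw[mark], sfs[mark]),
            "libsize": scale(raw[mark].copy(), scale_factor(counts[mark])),
        }
    return space, genes, truth, per_cond


def _stage_normalize(config, inputs, space: GenomeSpace, manifest) -> tuple[dict, dict]:
    """Partition, dedup, spike-scale and input-subtract every mark/condition."""
    p = config.parameters
    outdir = config.output_dir
    frag_inputs: dict = inputs.get("fragments") or {}
    input_inputs: dict = inputs.get("input_fragments") or {}
    tracks: dict = {}
    stats: dict = {}

    def load_replicates(paths: list) -> list[tuple]:
        """-> list of (raw target track, scale factor, n_target, n_spike)."""
        out = []
        for path in paths:
            frags = read_fragments(path, space)
            manifest["inputs"][str(path)] = _sha256(Path(path))
            part = partition(frags, space)
            target = deduplicate(part.target)
            spike = deduplicate(part.spike)
            sf = scale_factor(len(spike))
            raw = coverage(target, space, bin_size=p.bin_size, target_only=True)
            out.append((raw, sf, len(target), len(spike)))
        return out

    input_reps: dict[str, list[tuple]] = {}
    for cond, paths in input_inputs.items():
        input_reps[cond] = load_replicates(_as_list(paths))
        for i, (raw, sf, n_t, n_s) in enumerate(input_reps[cond]):
            stats[f"input/{cond}/rep{i}"] = {
                "n_target": n_t, "n_spike": n_s, "alpha": sf.alpha,
            }
        scaled = average_tracks([scale(raw, sf) for raw, sf, *_ in input_reps[cond]])
        tracks[("input", cond, "scaled")] = scaled

    for mark, conds in frag_inputs.items():
        for cond, paths in conds.items():
            reps = load_replicates(_as_list(paths))
            for i, (raw, sf, n_t, n_s) in enumerate(reps):
                stats[f"{mark}/{cond}/rep{i}"] = {
                    "n_target": n_t, "n_spike": n_s, "alpha": sf.alpha,
                }
            scaled = average_tracks([scale(raw, sf) for raw, sf, *_ in reps])
            tracks[(mark, cond, "scaled")] = scaled
            if cond in input_reps and input_reps[cond]:
                in_reps = input_reps[cond]
                subtracted = average_tracks(
                    [
                        normalize_subtract(
                            raw, in_reps[min(i, len(in_reps) - 1)][0],
                            sf, in_reps[min(i, len(in_reps) - 1)][1],
                            clip_negative=p.clip_negative,
                        )
                        for i, (raw, sf, *_rest) in enumerate(reps)
                    ]
                )
                tracks[(mark, cond, "subtracted")] = subtracted
                name = f"{mark}_{cond}.subtracted.bedGraph"
                write_bedgraph(subtracted, outdir / name)
                manifest["outputs"][name] = _sha256(outdir / name)
            else:
                manifest["notices"].append(
                    f"no input sample for condition {cond!r}: {mark} left unsubtracted"
                )
    return tracks, stats


def _stage_metagene(config, tracks, genes, classes, manifest) -> None:
    p = config.parameters
    outdir = config.output_dir
    marks = sorted({m for (m, _c, s) in tracks if m != "input" and s == "subtracted"})
    for mark in marks:
        frames = []
        scaled_profiles = {}
        for cond in CONDITIONS:
            track = tracks.get((mark, cond, "subtracted"))
            if track is None:
                continue
            mat = metagene.tss_matrix(track, genes, flank=p.flank)
            prof = metagene.aggregate(mat, classes)
            df = metagene.profile_frame(prof)
            df.insert(0, "condition", cond)
            frames.append(df)
            scaled_track = tracks.get((mark, cond, "scaled"))
            if scaled_track is not None:
                scaled_profiles[cond] = metagene.aggregate(
                    metagene.tss_matrix(scaled_track, genes, flank=p.flank), classes
                )
        if len(scaled_profiles) == 2:
            ratio = metagene.log2_ratio_profile(
                scaled_profiles["knockdown"], scaled_profiles["control"],
                pseudocount=p.pseudocount,
            )
            half = p.flank // p.bin_size
            import numpy as np

            positions = (np.arange(2 * half) - half) * p.bin_size + p.bin_size // 2
            ratio_df = pd.concat(
                [
                    pd.DataFrame(
                        {"condition": "log2_ratio", "class_label": label,
                         "position": positions, "mean": vec, "sd": 0.0, "n_genes": 0}
                    )
                    for label, vec in ratio.items()
                ],
                ignore_index=True,
            )
            frames.append(ratio_df)
        if frames:
            combined = pd.concat(frames, ignore_index=True)
            name = f"metagene_{mark}.tsv"
            write_table(combined, outdir / name)
            manifest["outputs"][name] = _sha256(outdir / name)
    manifest["stages"]["metagene"] = {"marks": marks, "flank": p.flank}


def _stage_correlate(config, tracks, genes, de_table, classes, manifest) -> pd.DataFrame:
    p = config.parameters
    outdir = config.output_dir
    marks = sorted({m for (m, _c, s) in tracks if m != "input" and s == "subtracted"})
    results = []
    for mark in marks:
        kd = tracks.get((mark, "knockdown", "subtracted"))
        ctrl = tracks.get((mark, "control", "subtracted"))
        if kd is None or ctrl is None:
            continue
        changes = integration.signal_change_table(
            kd, ctrl, genes, region="tss_window", window=p.flank
        )
        results.append(
            integration.correlate_by_class(
                de_table, changes, classes, mark=mark, alpha=p.corr_alpha
            )
        )
    correlations = (
        pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    )
    write_table(correlations, outdir / "correlations.tsv")
    manifest["outputs"]["correlations.tsv"] = _sha256(outdir / "correlations.tsv")
    manifest["stages"]["correlate"] = {
        "n_rows": len(correlations),
        "n_significant": int(correlations["significant"].sum()) if len(correlations) else 0,
    }
    return correlations
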