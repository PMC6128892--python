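"""Generate the default synthetic study dataset with planted ground truth.

Writes every pipeline input (annotation, chromosome sizes, fragment BEDs
for three marks plus input in two conditions, expression proportions, DE
table) plus the ground-truth table under results/dataset/.
"""

from pathlib import Path

from chromexpress.simulate import SimulationConfig, simulate_all, write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "dataset"


def main() -> None:
    config = SimulationConfig(seed=42)
    dataset = simulate_all(config)
    paths = write_dataset(dataset, OUT)
    truth = dataset.truth.genes
    print(f"simulated {config.n_genes} genes on a {config.chrom_len/1e6:.0f} Mb chromosome")
    print(f"class sizes: {truth['class_label'].value_counts().to_dict()}")
    print(f"planted DE: {truth['de_status'].value_counts().to_dict()}")
    print(f"wrote {len(paths)} files to {OUT}")


if __name__ == "__main__":
    main()
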