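"""TSS metagene profiles per histone mark and expression class.

Normalizes each mark from the simulated dataset, extracts TSS +/- 2 kb
windows, aggregates per class with SD bands, and computes the knockdown
vs control log2-ratio profile on the scaled tracks.  Writes per-mark
profile tables and a figure per mark under results/metagene/.
"""

from pathlib import Path

import pandas as pd

from chromexpress.io_formats import read_annotation, read_chrom_sizes, read_fragments
from chromexpress.metagene import (
    aggregate,
    log2_ratio_profile,
    plot_metagene,
    profile_frame,
    tss_matrix,
)
from chromexpress.spike_norm import (
    coverage,
    deduplicate,
    normalize_subtract,
    partition,
    scale,
    scale_factor,
)

BASE = Path(__file__).resolve().parent.parent / "results"
MARKS = ("H3K4me3", "H3K4me1", "H3K27me3")


def main() -> None:
    dataset = BASE / "dataset"
    if not dataset.exists():
        raise SystemExit("run analysis/01_simulate_dataset.py first")
    out = BASE / "metagene"
    out.mkdir(parents=True, exist_ok=True)
    space = read_chrom_sizes(dataset / "chrom_sizes.tsv")
    genes = read_annotation(dataset / "genes.bed", space)
    classes = pd.read_csv(BASE / "classes.tsv", sep="\t")

    def normalized(mark, cond):
        raw = {}
        sfs = {}
        for m in (mark, "input"):
            part = partition(read_fragments(dataset / f"{m}_{cond}.bed", space), space)
            target, spike = deduplicate(part.target), deduplicate(part.spike)
            raw[m] = coverage(target, space)
            sfs[m] = scale_factor(len(spike))
        return (normalize_subtract(raw[mark], raw["input"], sfs[mark], sfs["input"]),
                scale(raw[mark], sfs[mark]))

    for mark in MARKS:
        profiles, scaled_profiles = {}, {}
        for cond in ("control", "knockdown"):
            subtracted, scaled = normalized(mark, cond)
            mat = tss_matrix(subtracted, genes, flank=2000)
            profiles[cond] = aggregate(mat, classes)
            scaled_profiles[cond] = aggregate(
                tss_matrix(scaled, genes, flank=2000), classes
            )
        ratio = log2_ratio_profile(
            scaled_profiles["knockdown"], scaled_profiles["control"], pseudocount=1.0
        )
        table = pd.concat(
            [profile_frame(profiles[c]).assign(condition=c) for c in profiles],
            ignore_index=True,
        )
        table.to_csv(out / f"{mark}_profiles.tsv", sep="\t", index=False)
        plot_metagene(profiles["control"], profiles["knockdown"], ratio,
                      title=mark, path=str(out / f"{mark}_metagene.png"))
        x1 = profiles["control"].classes.get("X1")
        print(f"{mark}: X1 control peak height {x1.mean.max():.1f} "
              f"(n={x1.n_genes} genes); mean |log2 ratio| "
              f"{abs(ratio['X1']).mean():.3f}")
    print(f"wrote profiles and figures to {out}")


if __name__ == "__main__":
    main()
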