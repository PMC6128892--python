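"""Classify genes by compartment expression and select DE genes.

Reads the dataset written by 01_simulate_dataset.py, applies the strict
>50% classification rule and the fold-change >= 1.5 / p < 0.05 selection,
and checks both against the planted truth.  Writes classes.tsv and
de_status.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from chromexpress.differential import assign_status, select_de
from chromexpress.expression_classes import classify_table
from chromexpress.io_formats import read_de_table, read_expression_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = BASE / "dataset"
    if not dataset.exists():
        raise SystemExit("run analysis/01_simulate_dataset.py first")
    expression = read_expression_table(dataset / "expression_profiles.tsv")
    labels, summary = classify_table(expression)
    labels.to_csv(BASE / "classes.tsv", sep="\t", index=False)
    print("class sizes:", summary.to_dict())

    truth = pd.read_csv(dataset / "ground_truth.tsv", sep="\t")
    merged = labels.merge(truth[["gene_id", "class_label"]], on="gene_id",
                          suffixes=("_called", "_true"))
    accuracy = (merged["class_label_called"] == merged["class_label_true"]).mean()
    print(f"classification agreement with planted truth: {accuracy:.1%}")

    de = read_de_table(dataset / "de_table.tsv")
    status = assign_status(de)
    status.to_csv(BASE / "de_status.tsv", sep="\t", index=False)
    up, down = select_de(de)
    print(f"DE selection: {len(up)} up, {len(down)} down "
          f"(planted {truth['de_status'].eq('up').sum()} / "
          f"{truth['de_status'].eq('down').sum()})")


if __name__ == "__main__":
    main()
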