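"""Classify genes by FACS-compartment expression enrichment.

A gene is enriched in a compartment (X1 = G2/M stem cells, X2 = G1 stem
cells and progeny, Xins = differentiated cells) when strictly more than
half of its expression is observed there.  With the strict rule at most
one compartment can qualify.  Optional union classes (X1X2, X2Xins) cover
genes whose expression straddles two adjacent compartments; they are off
by default because no published rule pins down their definition, and the
rule used here (summed proportion > 0.5 with each member >= 0.25) is this
package's own.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

COMPARTMENTS = ("X1", "X2", "Xins")
UNIONS = (("X1", "X2"), ("X2", "Xins"))  # adjacent along the differentiation axis
PROP_COLUMNS = ("prop_X1", "prop_X2", "prop_Xins")

CUTOFF = 0.5
SUM_TOL = 1e-6


@dataclass(frozen=True)
class ExpressionProfile:
    gene_id: str
    prop_X1: float
    prop_X2: float
    prop_Xins: float

    def proportions(self) -> tuple[float, float, float]:
        return (self.prop_X1, self.prop_X2, self.prop_Xins)


def classify(profile: ExpressionProfile, unions: bool = False, cutoff: float = CUTOFF) -> str:
    """Return the enrichment class label for one profile.

    The label is the single compartment holding strictly more than 50% of
    expression; with ``unions`` enabled, a qualifying adjacent pair (summed
    proportion > 0.5, each member >= 0.25) is used as fallback, preferring
    the pair with the larger sum; otherwise ``"none"``.
    """
    props = profile.proportions()
    total = sum(props)
    if abs(total - 1.0) > SUM_TOL:
        raise ValueError(
            f"gene {profile.gene_id!r}: proportions sum to {total!r}, not 1"
        )
    if any(p < 0.0 or p > 1.0 for p in props):
        raise ValueError(f"gene {profile.gene_id!r}: proportion outside [0, 1]")
    by_name = dict(zip(COMPARTMENTS, props))
    for name, p in by_name.items():
        if p > cutoff:
            return name
    if unions:
        best: tuple[float, str] | None = None
        for pair in UNIONS:
            s = by_name[pair[0]] + by_name[pair[1]]
            if s > cutoff and all(by_name[m] >= 0.25 for m in pair):
                if best is None or s > best[0]:
                    best = (s, "".join(pair))
        if best is not None:
            return best[1]
    return "none"


def classify_table(
    profiles: pd.DataFrame, unions: bool = False, cutoff: float = CUTOFF
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify a whole expression table; returns (labels, class-size summary).

    *profiles* needs gene_id plus the three proportion columns; gene ids
    must be unique.
    """
    missing = [c for c in ("gene_id", *PROP_COLUMNS) if c not in profiles.columns]
    if missing:
        raise ValueError(f"expression table missing columns {missing}")
    dup = profiles["gene_id"][profiles["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene_id(s): {sorted(set(dup))[:5]}")
    labels = [
        classify(
            ExpressionProfile(row.gene_id, row.prop_X1, row.prop_X2, row.prop_Xins),
            unions=unions,
            cutoff=cutoff,
        )
        for row in profiles.itertuples(index=False)
    ]
    out = pd.DataFrame({"gene_id": profiles["gene_id"].to_numpy(), "class_label": labels})
    summary = out["class_label"].value_counts().sort_index()
    return out, summary
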