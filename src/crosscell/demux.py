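"""Species assignment of barcodes in mixed-species experiments.

In combinatorial-indexing experiments cells of several species share
barcodes, so a barcode may collect reads from more than one species
(a species doublet). After reads are mapped uniquely against a
concatenated multi-species reference, each barcode carries a read count
per species. The calling rule: with total T and largest count M, a cell
is a doublet when the non-majority mass (T - M)/T exceeds a threshold
(default 20%); otherwise it is labelled with the argmax species. With
exactly three species (T - M) equals the sum of the second- and
third-largest counts, so this generalisation coincides with the
three-species formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

DOUBLET = "doublet"
UNASSIGNED = "unassigned"


@dataclass
class CellSpeciesCounts:
    """Per-species uniquely-mapped read counts for one barcode."""

    cell_id: str
    counts: dict[str, int]

    def __post_init__(self):
        if not self.counts:
            raise ValueError("at least one species required")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative read count")


def call_species(c: CellSpeciesCounts, doublet_fraction: float = 0.2) -> tuple[str, bool]:
    """Label one barcode; returns (label, tied_for_max).

    Label is a species name, ``"doublet"`` when the non-majority read
    fraction strictly exceeds ``doublet_fraction``, or ``"unassigned"``
    when the barcode has no reads. Ties for the largest count resolve to
    the lexicographically first species and set the tie flag.
    """
    if not 0.0 <= doublet_fraction <= 1.0:
        raise ValueError("doublet_fraction must be in [0, 1]")
    total = sum(c.counts.values())
    if total == 0:
        return UNASSIGNED, False
    m = max(c.counts.values())
    if (total - m) / total > doublet_fraction:
        return DOUBLET, False
    winners = sorted(s for s, v in c.counts.items() if v == m)
    return winners[0], len(winners) > 1


def demux_table(rows: list[CellSpeciesCounts],
                doublet_fraction: float = 0.2) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every barcode; returns (table, per-outcome summary counts)."""
    seen: set[str] = set()
    records = []
    for c in rows:
        if c.cell_id in seen:
            raise ValueError(f"duplicate cell_id {c.cell_id!r}")
        seen.add(c.cell_id)
        label, tie = call_species(c, doublet_fraction)
        records.append({"cell_id": c.cell_id, "label": label, "tie": tie})
    table = pd.DataFrame.from_records(records, columns=["cell_id", "label", "tie"])
    summary = table["label"].value_counts().to_dict() if len(table) else {}
    return table, summary
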