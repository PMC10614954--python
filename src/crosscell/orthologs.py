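"""One-to-one ortholog reconciliation from many-to-many homology edges.

Homology resources report orthology many-to-many, each edge carrying a
percent-identity score. Cross-species factor swapping needs a shared
gene space, i.e. every gene connected to at most one gene in each other
species. Reconciliation proceeds in two phases:

1. **Greedy matching per species pair.** Edges between a pair of species
   are ranked by decreasing percent identity (ties broken
   lexicographically on the gene-ID pair) and accepted iff neither
   endpoint already has an accepted edge within that pair — a greedy
   maximum-weight bipartite matching.

2. **Transitivity filling.** With a designated hub species, a missing
   hub edge A–C is inferred from a triangle A–B (accepted), B–C (in the
   pairwise matching between the two non-hub species) when C has no
   accepted edge at all. Non-hub species pairs are visited in a fixed
   order (by default increasing evolutionary distance) and triangles
   within a pair fire greedily by decreasing B–C score.

The species tree is deliberately not enforced: a hub gene may end up
with an ortholog in one foreign species but not another, which is the
correct representation of lineage-specific gene loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd


@dataclass(frozen=True, order=True)
class Edge:
    """Undirected scored edge; vertices are (gene_id, species) pairs."""

    gene_a: str
    species_a: str
    gene_b: str
    species_b: str
    score: float

    def __post_init__(self):
        if self.species_a == self.species_b:
            raise ValueError("same-species edge")
        if self.gene_a == self.gene_b and self.species_a == self.species_b:
            raise ValueError("self-edge")
        if not 0.0 <= self.score <= 100.0:
            raise ValueError("percent identity must be in [0, 100]")

    def oriented(self) -> "Edge":
        """Canonical orientation: species sorted lexicographically."""
        if self.species_a <= self.species_b:
            return self
        return Edge(self.gene_b, self.species_b, self.gene_a, self.species_a, self.score)


@dataclass
class OrthologGraph:
    """Species-labelled gene graph with percent-identity edges."""

    edges: list[Edge] = field(default_factory=list)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologGraph":
        """Build from a table with columns gene_a, species_a, gene_b, species_b, percent_identity."""
        edges = [
            Edge(str(r.gene_a), str(r.species_a), str(r.gene_b), str(r.species_b),
                 float(r.percent_identity))
            for r in df.itertuples(index=False)
        ]
        return cls(edges)

    def species(self) -> list[str]:
        out = set()
        for e in self.edges:
            out.update((e.species_a, e.species_b))
        return sorted(out)

    def pair_edges(self, species_a: str, species_b: str) -> list[Edge]:
        pair = {species_a, species_b}
        return [e.oriented() for e in self.edges if {e.species_a, e.species_b} == pair]


def greedy_one_to_one(g: OrthologGraph, species_a: str, species_b: str) -> list[Edge]:
    """Greedy maximum-weight one-to-one matching between two species.

    Edges are processed in decreasing percent identity; equal scores are
    broken lexicographically on (gene_a, gene_b) after canonical
    orientation, making the result deterministic.
    """
    if species_a == species_b:
        raise ValueError("species must differ")
    edges = sorted(g.pair_edges(species_a, species_b),
                   key=lambda e: (-e.score, e.gene_a, e.gene_b))
    taken: set[tuple[str, str]] = set()
    accepted: list[Edge] = []
    for e in edges:
        va, vb = (e.gene_a, e.species_a), (e.gene_b, e.species_b)
        if va in taken or vb in taken:
            continue
        taken.add(va)
        taken.add(vb)
        accepted.append(e)
    return accepted


def fill_transitive(accepted: list[Edge],
                    pairwise_maps: dict[tuple[str, str], list[Edge]],
                    hub_species: str,
                    pair_order: list[tuple[str, str]]) -> list[Edge]:
    """Add hub edges inferred from transitivity triangles.

    A triangle (A, B, C) fires when s(A) is the hub, B and C are two
    distinct non-hub species, A–B is already accepted, C is untouched by
    any accepted edge, and B–C is in the pairwise matching. Pairs are
    visited in ``pair_order``; within a pair, triangles fire greedily by
    decreasing B–C percent identity (ties lexicographic).
    """
    accepted = list(accepted)
    # hub partner lookup: non-hub vertex -> its accepted hub gene
    hub_partner: dict[tuple[str, str], str] = {}
    touched: set[tuple[str, str]] = set()
    # (hub gene, foreign species) pairs already used, to preserve the
    # one-neighbor-per-species invariant on the hub side
    hub_used: set[tuple[str, str]] = set()
    for e in accepted:
        for gene, spec, ogene, ospec in ((e.gene_a, e.species_a, e.gene_b, e.species_b),
                                         (e.gene_b, e.species_b, e.gene_a, e.species_a)):
            touched.add((gene, spec))
            if ospec == hub_species and spec != hub_species:
                hub_partner[(gene, spec)] = ogene
                hub_used.add((ogene, spec))

    added: list[Edge] = []
    for pair in pair_order:
        sb, sc = pair
        if hub_species in pair:
            continue  # triangles need two non-hub species
        candidates = sorted(pairwise_maps.get(tuple(sorted(pair)), []),
                            key=lambda e: (-e.score, e.gene_a, e.gene_b))
        for e in candidates:
            # the matching edge is between species sb and sc in either role
            for b, b_spec, c, c_spec in ((e.gene_a, e.species_a, e.gene_b, e.species_b),
                                         (e.gene_b, e.species_b, e.gene_a, e.species_a)):
                if {b_spec, c_spec} != {sb, sc}:
                    continue
                a = hub_partner.get((b, b_spec))
                if a is None:
                    continue
                if (c, c_spec) in touched or (a, c_spec) in hub_used:
                    continue
                new = Edge(a, hub_species, c, c_spec, e.score).oriented()
                accepted.append(new)
                added.append(new)
                touched.add((c, c_spec))
                hub_partner[(c, c_spec)] = a
                hub_used.add((a, c_spec))
                break
    return accepted


@dataclass
class OneToOneMap:
    """One row per hub gene, one column per species, plus provenance."""

    hub_species: str
    table: pd.DataFrame  # columns: hub gene id, one per other species, provenance
    n_direct: int
    n_transitive: int


def build_one_to_one(g: OrthologGraph, hub_species: str,
                     species_order: list[str] | None = None,
                     pair_order: list[tuple[str, str]] | None = None) -> OneToOneMap:
    """Full reconciliation: hub matchings, non-hub matchings, transitivity.

    ``pair_order`` controls the order in which non-hub species pairs are
    scanned for transitivity triangles (default: sorted pairs).
    """
    species = species_order or g.species()
    if hub_species not in species:
        raise ValueError(f"hub species {hub_species!r} not in graph")
    others = [s for s in species if s != hub_species]

    accepted: list[Edge] = []
    for other in others:
        accepted.extend(greedy_one_to_one(g, hub_species, other))

    pairwise: dict[tuple[str, str], list[Edge]] = {}
    for sa, sb in combinations(others, 2):
        key = tuple(sorted((sa, sb)))
        pairwise[key] = greedy_one_to_one(g, sa, sb)

    if pair_order is None:
        pair_order = [tuple(sorted(p)) for p in combinations(others, 2)]

    n_direct = len(accepted)
    full = fill_transitive(accepted, pairwise, hub_species, pair_order)
    transitive_edges = full[n_direct:]

    rows: dict[str, dict[str, str]] = {}
    provenance: dict[str, set[str]] = {}
    for e, kind in [(e, "direct") for e in full[:n_direct]] + \
                   [(e, "transitive") for e in transitive_edges]:
        if e.species_a == hub_species:
            hub_gene, other_gene, other_spec = e.gene_a, e.gene_b, e.species_b
        else:
            hub_gene, other_gene, other_spec = e.gene_b, e.gene_a, e.species_a
        rows.setdefault(hub_gene, {})[other_spec] = other_gene
        provenance.setdefault(hub_gene, set()).add(kind)

    records = []
    for hub_gene in sorted(rows):
        rec = {hub_species: hub_gene}
        for s in others:
            rec[s] = rows[hub_gene].get(s)
        prov = provenance[hub_gene]
        rec["provenance"] = "transitive" if "transitive" in prov else "direct"
        records.append(rec)
    table = pd.DataFrame.from_records(records, columns=[hub_species, *others, "provenance"])
    n_trans_rows = int((table["provenance"] == "transitive").sum()) if len(table) else 0
    return OneToOneMap(hub_species, table, n_direct=len(table) - n_trans_rows,
                       n_transitive=n_trans_rows)
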