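"""Coding-haplotype collapse and minimum spanning haplotype networks.

Haplotypes are built by substituting only homozygous-alternate SNP alleles
into the reference coding sequence (heterozygous and missing genotypes stay
reference), then merging identical sequences. The network over Hamming
distances is the epsilon = 0 minimum spanning network: the union of all edges
that belong to at least one minimum spanning tree. An outgroup sequence can be
added to root the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .intervals import GeneModel, reverse_complement
from .variants import HOM_ALT, VariantRecord


@dataclass
class CodingHaplotype:
    name: str
    sequence: str
    members: tuple[str, ...]
    subpop_counts: dict[str, int] = field(default_factory=dict)
    phenoclass_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.members)


def collapse_haplotypes(
    records: Sequence[VariantRecord],
    gene: GeneModel,
    reference: Mapping[str, str],
    accessions: Sequence[str],
    subpopulations: Mapping[str, str] | None = None,
    phenotype_classes: Mapping[str, str] | None = None,
) -> list[CodingHaplotype]:
    """Collapse accessions into coding haplotypes.

    Only CDS SNPs are substituted (indels would break the fixed-length Hamming
    comparison; the pipeline builds haplotypes on a shared reference, so
    sequences are already aligned). Haplotypes are named H1, H2, ... by
    decreasing member count.
    """
    chrom_seq = reference[gene.chrom]
    cds_positions = gene.cds_genomic_positions()
    pos_to_idx = {p: i for i, p in enumerate(cds_positions)}
    base = list("".join(chrom_seq[c.start : c.end] for c in gene.cds))

    cds_snps = []
    for rec in records:
        if rec.is_snp and rec.start in pos_to_idx:
            idx = pos_to_idx[rec.start]
            if base[idx] != rec.ref.upper():
                raise ValueError(
                    f"{rec.variant_id}: REF allele disagrees with reference base "
                    f"{base[idx]!r}"
                )
            cds_snps.append((idx, rec))

    seq_to_members: dict[str, list[str]] = {}
    for j, acc in enumerate(accessions):
        arr = base.copy()
        for idx, rec in cds_snps:
            if rec.genotypes[j] == HOM_ALT:
                arr[idx] = rec.alt.upper()
        seq = "".join(arr)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        seq_to_members.setdefault(seq, []).append(acc)

    ordered = sorted(seq_to_members.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
    haplotypes = []
    for i, (seq, members) in enumerate(ordered, start=1):
        sub_counts: dict[str, int] = {}
        cls_counts: dict[str, int] = {}
        for m in members:
            if subpopulations is not None:
                sp = subpopulations.get(m, "NA")
                sub_counts[sp] = sub_counts.get(sp, 0) + 1
            if phenotype_classes is not None:
                pc = phenotype_classes.get(m)
                pc = "NA" if pc is None or (isinstance(pc, float) and np.isnan(pc)) else str(pc)
                cls_counts[pc] = cls_counts.get(pc, 0) + 1
        haplotypes.append(
            CodingHaplotype(
                name=f"H{i}",
                sequence=seq,
                members=tuple(members),
                subpop_counts=sub_counts,
                phenoclass_counts=cls_counts,
            )
        )
    return haplotypes


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class HaplotypeNetwork:
    nodes: list[CodingHaplotype]
    edges: list[tuple[str, str, int]]  # (node_a, node_b, mutational steps)
    outgroup: str | None = None

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for h in self.nodes:
            g.add_node(
                h.name,
                n_members=h.n_members,
                members=",".join(h.members),
                is_outgroup=(h.name == self.outgroup),
            )
        for a, b, w in self.edges:
            g.add_edge(a, b, steps=w)
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), str(path))

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["node_a", "node_b", "steps"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for h in self.nodes:
            rows.append(
                {
                    "node": h.name,
                    "n_members": h.n_members,
                    "members": ",".join(h.members),
                    "subpopulations": ";".join(
                        f"{k}:{v}" for k, v in sorted(h.subpop_counts.items())
                    ),
                    "phenotype_classes": ";".join(
                        f"{k}:{v}" for k, v in sorted(h.phenoclass_counts.items())
                    ),
                    "is_outgroup": h.name == self.outgroup,
                }
            )
        return pd.DataFrame(rows)


class _DSU:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def minimum_spanning_network(
    names: Sequence[str], dist: np.ndarray
) -> list[tuple[str, str, int]]:
    """Union of all minimum spanning trees (epsilon = 0 network).

    Kruskal over weight classes: an edge belongs to some MST iff its endpoints
    lie in different components of the graph formed by all strictly lighter
    MSN edges. Edges within one weight class are tested against the component
    state *before* any of them is added.
    """
    n = len(names)
    edges = sorted(
        ((int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    dsu = _DSU(range(n))
    out: list[tuple[str, str, int]] = []
    idx = 0
    while idx < len(edges):
        w = edges[idx][0]
        group = []
        while idx < len(edges) and edges[idx][0] == w:
            group.append(edges[idx])
            idx += 1
        chosen = [(w, i, j) for (w, i, j) in group if dsu.find(i) != dsu.find(j)]
        for _, i, j in chosen:
            out.append((names[i], names[j], w))
        for _, i, j in chosen:
            dsu.union(i, j)
    return out


def minimum_spanning_tree_strict(
    names: Sequence[str], dist: np.ndarray
) -> list[tuple[str, str, int]]:
    """Single MST via Kruskal with lexicographic tie-break (deterministic)."""
    n = len(names)
    edges = sorted(
        ((int(dist[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (e[0], e[1], e[2]),
    )
    dsu = _DSU(range(n))
    out = []
    for w, i, j in edges:
        if dsu.find(i) != dsu.find(j):
            out.append((names[i], names[j], w))
            dsu.union(i, j)
    return out


def build_network(
    haplotypes: Sequence[CodingHaplotype],
    outgroup_sequence: str | None = None,
    method: str = "msn",
) -> HaplotypeNetwork:
    """Build the haplotype network (``msn`` for epsilon = 0, ``mst`` for a
    strict single tree). The outgroup becomes a flagged extra node."""
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    nodes = list(haplotypes)
    outgroup_name = None
    if outgroup_sequence is not None:
        if len(outgroup_sequence) != len(nodes[0].sequence):
            raise ValueError(
                f"outgroup length {len(outgroup_sequence)} != haplotype length "
                f"{len(nodes[0].sequence)}"
            )
        outgroup_name = "outgroup"
        nodes = nodes + [
            CodingHaplotype(name=outgroup_name, sequence=outgroup_sequence.upper(), members=())
        ]
    names = [h.name for h in nodes]
    n = len(nodes)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = hamming(nodes[i].sequence, nodes[j].sequence)
    if n == 1:
        return HaplotypeNetwork(nodes=nodes, edges=[], outgroup=outgroup_name)
    if method == "msn":
        edges = minimum_spanning_network(names, dist)
    elif method == "mst":
        edges = minimum_spanning_tree_strict(names, dist)
    else:
        raise ValueError(f"unknown method {method!r}")
    return HaplotypeNetwork(nodes=nodes, edges=edges, outgroup=outgroup_name)
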