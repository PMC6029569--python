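"""Protein clustering by reciprocal best hits and genome grouping by shared
clusters.

Protein clusters are connected components of the cross-genome reciprocal
best-hit (RBH) graph (edges require E <= 1e-5 and alignment coverage >= 75%
of the longer protein); genome groups are connected components of the
genome graph weighted by the Jaccard index of cluster sets.  Connected
components replace Markov/FT clustering: simpler, deterministic, and
sufficient for group-consensus strategy selection.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .align import evalue, local_alignment_span, local_score
from .errors import ParameterError

ProteinKey = tuple[str, int]  # (genome id, ORF index)


@dataclass
class ProteinCluster:
    id: int
    members: frozenset

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class GenomeGroup:
    id: int
    members: frozenset
    jaccard: dict = field(default_factory=dict)


def _shared_kmer_prefilter(a: str, b: str, k: int = 5, min_shared: int = 2) -> bool:
    """Cheap screen: unrelated random proteins share almost no 5-mers."""
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    shared = 0
    for i in range(len(b) - k + 1):
        if b[i : i + k] in kmers:
            shared += 1
            if shared >= min_shared:
                return True
    return False


def reciprocal_best_hits(
    proteomes: dict[str, list[str]],
    evalue_max: float = 1e-5,
    min_cover: float = 0.75,
) -> list[ProteinCluster]:
    """Cluster proteins across genomes by reciprocal best hits.

    For every ordered genome pair, each protein's best hit (highest local
    alignment score) in the other genome is computed; an undirected edge
    requires mutual best hits, E <= ``evalue_max`` (database size = size of
    the searched proteome) and aligned span covering >= ``min_cover`` of the
    longer protein.  Clusters are connected components; unmatched proteins
    remain singletons.
    """
    if len(proteomes) < 2:
        raise ParameterError("need at least two proteomes")
    genomes = sorted(proteomes)
    graph = nx.Graph()
    for g in genomes:
        for i in range(len(proteomes[g])):
            graph.add_node((g, i))

    scores: dict[tuple[ProteinKey, ProteinKey], float] = {}

    def _score(ka: ProteinKey, kb: ProteinKey) -> float:
        key = (ka, kb) if ka <= kb else (kb, ka)
        if key not in scores:
            a = proteomes[ka[0]][ka[1]]
            b = proteomes[kb[0]][kb[1]]
            scores[key] = local_score(a, b) if _shared_kmer_prefilter(a, b) else 0.0
        return scores[key]

    best_hit: dict[tuple[ProteinKey, str], ProteinKey | None] = {}
    for ga in genomes:
        for gb in genomes:
            if ga == gb:
                continue
            for ia, _ in enumerate(proteomes[ga]):
                ka = (ga, ia)
                hits = [((gb, ib), _score(ka, (gb, ib))) for ib in range(len(proteomes[gb]))]
                hits = [h for h in hits if h[1] > 0]
                best_hit[(ka, gb)] = max(hits, key=lambda h: (h[1], -h[0][1]))[0] if hits else None

    db_sizes = {g: sum(len(p) for p in proteomes[g]) for g in genomes}
    for ga in genomes:
        for gb in genomes:
            if ga >= gb:
                continue
            for ia, pa in enumerate(proteomes[ga]):
                ka = (ga, ia)
                kb = best_hit.get((ka, gb))
                if kb is None or best_hit.get((kb, ga)) != ka:
                    continue
                pb = proteomes[gb][kb[1]]
                score, span_a, span_b = local_alignment_span(pa, pb)
                if evalue(score, len(pa), db_sizes[gb]) > evalue_max:
                    continue
                longer_span = span_a if len(pa) >= len(pb) else span_b
                cover = (longer_span[1] - longer_span[0]) / max(len(pa), len(pb))
                if cover >= min_cover:
                    graph.add_edge(ka, kb)

    clusters = [
        ProteinCluster(i, frozenset(comp))
        for i, comp in enumerate(sorted(nx.connected_components(graph), key=sorted))
    ]
    return clusters


def group_genomes(clusters: list[ProteinCluster], min_jaccard: float = 0.35) -> list[GenomeGroup]:
    """Group genomes by Jaccard similarity of their protein-cluster sets.

    Groups are connected components of the genome graph with edges where
    Jaccard >= ``min_jaccard``; they partition the genome set (singletons
    allowed)."""
    memberships: dict[str, set[int]] = {}
    for cl in clusters:
        for g in cl.genomes():
            memberships.setdefault(g, set()).add(cl.id)
    genomes = sorted(memberships)
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    jaccard: dict[tuple[str, str], float] = {}
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            inter = len(memberships[ga] & memberships[gb])
            union = len(memberships[ga] | memberships[gb])
            j = inter / union if union else 0.0
            jaccard[(ga, gb)] = j
            if j >= min_jaccard:
                graph.add_edge(ga, gb)
    groups = []
    for i, comp in enumerate(sorted(nx.connected_components(graph), key=sorted)):
        sub = {pair: j for pair, j in jaccard.items()
               if pair[0] in comp and pair[1] in comp}
        groups.append(GenomeGroup(i, frozenset(comp), sub))
    return groups


def identical_proteome_pairs(clusters: list[ProteinCluster]) -> list[tuple[str, str]]:
    """Genome pairs sharing 100% of proteins: equal cluster sets, and every
    one of those clusters contains a member from both genomes."""
    memberships: dict[str, set[int]] = {}
    for cl in clusters:
        for g in cl.genomes():
            memberships.setdefault(g, set()).add(cl.id)
    by_id = {cl.id: cl for cl in clusters}
    genomes = sorted(memberships)
    pairs = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            if memberships[ga] != memberships[gb]:
                continue
            if all(
                ga in by_id[c].genomes() and gb in by_id[c].genomes()
                for c in memberships[ga]
            ):
                pairs.append((ga, gb))
    return pairs
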