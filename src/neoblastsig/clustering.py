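"""Gene-proxy clustering of transcripts and primary-contig-set selection.

Assembled transcripts that share mapped reads are grouped into clusters used
as a gene proxy for counting and testing.  The input is an equivalence-class
table (reads compatible with exactly a given set of transcripts), which keeps
the contract alignment-free; two transcripts join when their shared reads are
a sufficient fraction of the smaller transcript's total, and clusters are the
connected components of that graph.

The primary transcript set is the shortest support-ranked prefix whose
cumulative mapped-read support reaches a target fraction (default 90%) of all
reads — the rule used to designate a main assembly from merged contigs.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations

import networkx as nx

EquivalenceClassTable = list[tuple[frozenset[str], int]]


class ClusteringError(ValueError):
    pass


def cluster_transcripts(
    eq_table: EquivalenceClassTable, min_shared_fraction: float = 0.01
) -> dict[str, str]:
    """Connected-component clusters from shared-read evidence.

    An edge joins transcripts t1, t2 when shared_reads / min(total_1, total_2)
    >= min_shared_fraction (pairs must co-occur in at least one class).
    Cluster ids are the lexicographically smallest member id; row order of the
    table does not affect the result.
    """
    totals: dict[str, int] = defaultdict(int)
    shared: dict[tuple[str, str], int] = defaultdict(int)
    for ids, count in eq_table:
        if count < 1 or not ids:
            raise ClusteringError("equivalence classes need >= 1 read and >= 1 transcript")
        for t in ids:
            totals[t] += count
        for a, b in combinations(sorted(ids), 2):
            shared[(a, b)] += count

    graph = nx.Graph()
    graph.add_nodes_from(totals)
    for (a, b), s in shared.items():
        if s / min(totals[a], totals[b]) >= min_shared_fraction:
            graph.add_edge(a, b)

    cluster_map: dict[str, str] = {}
    for component in nx.connected_components(graph):
        cid = min(component)
        for t in component:
            cluster_map[t] = cid
    return cluster_map


def aggregate_counts(transcript_counts, cluster_map: dict[str, str]):
    """Sum transcript-level counts to cluster level; per-sample totals are conserved."""
    unmapped = [t for t in transcript_counts.index if t not in cluster_map]
    if unmapped:
        raise ClusteringError(f"transcripts missing from cluster map: {unmapped[:5]}")
    grouped = transcript_counts.groupby(
        transcript_counts.index.map(cluster_map), sort=True
    ).sum()
    grouped.index.name = "cluster_id"
    return grouped


def select_primary_set(support: dict[str, int], target_fraction: float = 0.9) -> list[str]:
    """Shortest support-ranked transcript prefix explaining the target read fraction.

    Transcripts are ordered by support descending (ties by id ascending); the
    prefix is cut as soon as cumulative support reaches target_fraction of the
    total.  Because the order is greedy-by-support, the prefix is also the
    minimum-cardinality subset meeting the target.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ClusteringError("target_fraction must be in (0, 1]")
    if any(c < 0 for c in support.values()):
        raise ClusteringError("support counts must be >= 0")
    total = sum(support.values())
    if total <= 0:
        raise ClusteringError("total read support is zero")
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    selected: list[str] = []
    cum = 0
    for tid, c in ranked:
        if cum >= target_fraction * total:
            break
        selected.append(tid)
        cum += c
    return selected
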