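"""Coexpression network: Pearson edges, HRR selection, HCCA clustering.

The network is built from expression profiles (FPKM after low-expression
filtering) in three stages:

1. :func:`pearson_all_pairs` — every transcript pair with Pearson r at or
   above the cutoff (signed rule, default 0.8) becomes a candidate edge;
   evaluation is chunked so the full correlation matrix is never held for
   large inputs, with the contract that chunked output equals the full
   computation.
2. :func:`hrr_edges` — highest reciprocal rank.  Each node ranks its
   candidate partners by descending r (rank 1 = best, ties broken by
   ascending partner id); HRR(i, j) = max(rank_i(j), rank_j(i)) and only
   edges with HRR <= the limit (default 30) are kept.  A small HRR means the
   two transcripts are mutually among each other's strongest correlates.
3. :func:`hcca_cluster` — heuristic cluster chiseling.  For every node the
   node vicinity network (NVN; all nodes within 3 steps) is chiseled by
   repeatedly removing peripheral nodes with more edges leaving the set than
   inside it; surviving candidates within the size bounds are scored by
   internal-edge fraction E_in / (E_in + E_out) and accepted greedily
   without overlap.

:func:`extract_subnetwork` returns seed transcripts plus their first
neighbors with all induced edges, mirroring the ACR-seed subnetwork readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


def pearson_all_pairs(
    matrix: ExpressionMatrix,
    r_cutoff: float = 0.8,
    chunk_size: int = 512,
    use_absolute: bool = False,
) -> pd.DataFrame:
    """Candidate edges (node_a, node_b, r) with r >= cutoff, each pair once.

    The threshold is applied to the signed correlation by default; set
    ``use_absolute`` to admit strong negative correlations as well.
    Constant-valued transcripts (undefined r) are excluded up front.
    """
    data = matrix.data
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    arr = data.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    arr = arr[keep]
    ids = np.asarray(data.index)[keep]
    n, m = arr.shape
    if n < 2:
        return pd.DataFrame(columns=["node_a", "node_b", "r"])
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[keep, None]
    z /= np.sqrt(m - 1)

    rows_a, rows_b, rows_r = [], [], []
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        block = z[start:stop] @ z.T  # (stop-start) x n correlations
        np.clip(block, -1.0, 1.0, out=block)
        vals = np.abs(block) if use_absolute else block
        loc_i, loc_j = np.nonzero(vals >= r_cutoff)
        glob_i = loc_i + start
        upper = glob_i < loc_j  # each unordered pair exactly once, no self-pairs
        rows_a.append(glob_i[upper])
        rows_b.append(loc_j[upper])
        rows_r.append(block[loc_i[upper], loc_j[upper]])
    ia = np.concatenate(rows_a) if rows_a else np.array([], dtype=int)
    ib = np.concatenate(rows_b) if rows_b else np.array([], dtype=int)
    rr = np.concatenate(rows_r) if rows_r else np.array([], dtype=float)
    return pd.DataFrame({"node_a": ids[ia], "node_b": ids[ib], "r": rr})


def hrr_edges(
    candidates: pd.DataFrame,
    hrr_limit: int = 30,
    nodes=None,
) -> nx.Graph:
    """Build the HRR-filtered graph from candidate Pearson edges.

    Each node ranks its candidate partners by descending r (ties resolved by
    ascending partner id, making the result deterministic and input-order
    invariant); an edge survives iff max(rank_i(j), rank_j(i)) <= hrr_limit.
    Edge attributes: ``r`` and ``hrr``.
    """
    if hrr_limit < 1:
        raise ValueError("hrr_limit must be >= 1")
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    if not len(candidates):
        return graph

    partners: dict = {}
    for a, b, r in candidates[["node_a", "node_b", "r"]].itertuples(index=False):
        partners.setdefault(a, []).append((b, float(r)))
        partners.setdefault(b, []).append((a, float(r)))

    rank: dict = {}
    for node, plist in partners.items():
        plist.sort(key=lambda pr: (-pr[1], pr[0]))
        rank[node] = {p: k for k, (p, _) in enumerate(plist, start=1)}

    graph.add_nodes_from(partners)
    for a, b, r in candidates[["node_a", "node_b", "r"]].itertuples(index=False):
        hrr = max(rank[a][b], rank[b][a])
        if hrr <= hrr_limit:
            graph.add_edge(a, b, r=float(r), hrr=int(hrr))
    return graph


@dataclass
class ClusterSet:
    clusters: list                      # list of node sets
    scores: list                        # internal-edge fraction per cluster
    unassigned: set
    assignment: dict = field(default_factory=dict)  # node -> cluster index or -1

    def membership_frame(self) -> pd.DataFrame:
        rows = [(n, c) for n, c in sorted(self.assignment.items())]
        return pd.DataFrame(rows, columns=["transcript_id", "cluster"])


def _chisel(graph: nx.Graph, seed, nvn: set) -> set:
    """Iteratively strip nodes with more outside than inside edges; keep the
    connected component containing the seed so candidates stay connected."""
    current = set(nvn)
    while True:
        removal = []
        for v in current:
            if v == seed:
                continue
            inside = sum(1 for u in graph[v] if u in current)
            outside = graph.degree(v) - inside
            if outside > inside:
                removal.append(v)
        if not removal:
            break
        current -= set(removal)
    if len(current) > 1:
        comp = nx.node_connected_component(graph.subgraph(current), seed)
        current = set(comp)
    return current


def _cut_score(graph: nx.Graph, members: set) -> float:
    e_in = e_out = 0
    for v in members:
        for u in graph[v]:
            if u in members:
                e_in += 1
            else:
                e_out += 1
    e_in //= 2
    if e_in + e_out == 0:
        return 0.0
    return e_in / (e_in + e_out)


def hcca_cluster(
    graph: nx.Graph,
    nvn_steps: int = 3,
    s_min: int = 40,
    s_max: int = 200,
) -> ClusterSet:
    """Heuristic cluster chiseling over node-vicinity networks.

    Every node seeds an NVN (BFS to ``nvn_steps``); chiseling strips
    peripheral nodes until stable; when the chiseled set falls outside
    [s_min, s_max] the seed retries from shallower vicinities (down to one
    step) before being dropped.  Surviving candidates are scored by
    internal-edge fraction and accepted greedily by descending score
    (ties: larger set, then lowest seed id), skipping overlaps.
    Leftover nodes join the accepted cluster holding most of their neighbors
    (ties: lowest cluster index) provided the cluster is below s_max; nodes
    with no neighbor in any cluster with room remain unassigned.
    """
    if s_min > s_max:
        raise ValueError("s_min must be <= s_max")
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")

    candidates = []
    for seed in sorted(graph.nodes):
        # size control: if the chiseled full-depth vicinity falls outside the
        # bounds, retry from progressively shallower vicinities before
        # giving up on this seed
        for depth in range(nvn_steps, 0, -1):
            nvn = set(nx.single_source_shortest_path_length(graph, seed,
                                                            cutoff=depth))
            members = _chisel(graph, seed, nvn)
            if s_min <= len(members) <= s_max:
                candidates.append(
                    (_cut_score(graph, members), len(members), seed, members))
                break

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    clusters: list = []
    scores: list = []
    taken: set = set()
    for score, _, _, members in candidates:
        if members & taken:
            continue
        clusters.append(set(members))
        scores.append(score)
        taken |= members

    assignment = {}
    for idx, members in enumerate(clusters):
        for v in members:
            assignment[v] = idx
    core = [set(c) for c in clusters]  # attachment counts neighbors in the cores
    unassigned = set()
    for v in sorted(set(graph.nodes) - taken):
        counts = [(sum(1 for u in graph[v] if u in core[i]), i)
                  for i in range(len(clusters))]
        counts = [(c, i) for c, i in counts if c > 0 and len(clusters[i]) < s_max]
        if not counts:
            unassigned.add(v)
            continue
        counts.sort(key=lambda ci: (-ci[0], ci[1]))
        best = counts[0][1]
        clusters[best].add(v)
        assignment[v] = best
    for v in unassigned:
        assignment[v] = -1
    return ClusterSet(clusters=clusters, scores=scores, unassigned=unassigned,
                      assignment=assignment)


@dataclass
class Subnetwork:
    seeds: set
    members: set
    graph: nx.Graph

    def edge_frame(self) -> pd.DataFrame:
        rows = [(min(a, b), max(a, b), d.get("r"), d.get("hrr"))
                for a, b, d in self.graph.edges(data=True)]
        rows.sort()
        return pd.DataFrame(rows, columns=["node_a", "node_b", "r", "hrr"])


def extract_subnetwork(graph: nx.Graph, seeds) -> Subnetwork:
    """Seeds plus first neighbors with all induced edges.

    Seed ids absent from the graph are reported and skipped; an empty seed
    set yields an empty subnetwork with a warning.
    """
    seeds = set(seeds)
    missing = seeds - set(graph.nodes)
    if missing:
        warnings.warn(f"{len(missing)} seed ids not in the graph; skipped: "
                      f"{sorted(missing)[:5]}")
    present = seeds - missing
    if not present:
        warnings.warn("empty seed set; returning an empty subnetwork")
        return Subnetwork(seeds=set(), members=set(), graph=nx.Graph())
    members = set(present)
    for s in present:
        members.update(graph[s])
    sub = graph.subgraph(members).copy()
    return Subnetwork(seeds=present, members=members, graph=sub)


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [(min(a, b), max(a, b), d.get("r"), d.get("hrr"))
            for a, b, d in graph.edges(data=True)]
    rows.sort()
    pd.DataFrame(rows, columns=["node_a", "node_b", "r", "hrr"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
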