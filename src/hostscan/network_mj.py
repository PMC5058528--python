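"""Median-joining haplotype networks.

The construction follows the Bandelt median-joining scheme on Hamming
distances over {A,C,G,T} (columns with gaps or Ns are excluded first):

1. compute the minimum spanning network (MSN, the union of all minimum
   spanning trees) of the current sequence set;
2. for every connected triple (u - v - w) in the MSN, form the sitewise
   majority (median) vector; collect new medians and add those whose
   connection cost d(u,m) + d(v,m) + d(w,m) is within ``epsilon`` of the round
   minimum;
3. repeat until no new medians appear, then prune median vectors of degree
   <= 1 and return the MSN of the remaining set.

Tie-breaking is deterministic: nodes are processed in lexicographic id order
and a three-way site tie (all states distinct) resolves to the state of the
first node of the triple.  Observed haplotypes carry per-group counts; median
vectors are flagged as unsampled.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import HaplotypeSet


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _clean_columns(seqs: dict) -> dict:
    """Drop alignment columns containing anything but A/C/G/T."""
    ids = sorted(seqs)
    length = len(seqs[ids[0]])
    keep = [c for c in range(length)
            if all(seqs[i][c] in "ACGT" for i in ids)]
    return {i: "".join(seqs[i][c] for c in keep) for i in ids}


def _msn_edges(nodes: list, seqs: dict) -> set:
    """Edges of the minimum spanning network (union of all MSTs).

    Kruskal by distance class: an edge belongs to some MST iff its endpoints
    lie in different components of the graph built from all strictly shorter
    edges.
    """
    dist = {}
    for u, v in itertools.combinations(nodes, 2):
        dist[(u, v)] = _hamming(seqs[u], seqs[v])
    edges_by_d: dict = {}
    for (u, v), d in dist.items():
        edges_by_d.setdefault(d, []).append((u, v))

    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    msn = set()
    for d in sorted(edges_by_d):
        batch = edges_by_d[d]
        keep = [(u, v) for u, v in batch if find(u) != find(v)]
        msn.update(keep)
        for u, v in keep:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return msn


def _median(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(x)        # three-way tie: state of the first sequence
    return "".join(out)


def build_mj_network(haps, epsilon: int = 0, max_rounds: int = 50) -> nx.Graph:
    """Build the median-joining network of a haplotype set.

    ``haps`` is a :class:`HaplotypeSet` or a plain mapping ``id -> sequence``.
    Returns a networkx graph whose nodes carry ``seq``, ``is_median`` and (for
    observed haplotypes from a HaplotypeSet) per-group copy counts; edge
    attribute ``weight`` is the Hamming distance (mutation steps).
    """
    if isinstance(haps, HaplotypeSet):
        raw = dict(haps.haplotypes)
        counts = haps.group_counts("host") if haps.pairs else None
    else:
        raw = dict(haps)
        counts = None
    if len(set(raw.values())) < 2:
        raise ValueError("need at least 2 distinct haplotypes")
    lens = {len(s) for s in raw.values()}
    if len(lens) > 1:
        raise ValueError("haplotypes have unequal lengths")

    seqs = _clean_columns(raw)
    # collapse ids that became identical after column cleaning
    by_seq: dict = {}
    for hid in sorted(seqs):
        by_seq.setdefault(seqs[hid], []).append(hid)
    node_seq = {ids[0]: s for s, ids in by_seq.items()}
    observed = set(node_seq)

    median_serial = itertools.count(1)
    for _ in range(max_rounds):
        nodes = sorted(node_seq)
        msn = _msn_edges(nodes, node_seq)
        adj: dict = {n: set() for n in nodes}
        for u, v in msn:
            adj[u].add(v)
            adj[v].add(u)
        existing = set(node_seq.values())
        candidates: dict = {}
        for v in nodes:
            for u, w in itertools.combinations(sorted(adj[v]), 2):
                m = _median(node_seq[u], node_seq[v], node_seq[w])
                if m in existing:
                    continue
                cost = (_hamming(m, node_seq[u]) + _hamming(m, node_seq[v])
                        + _hamming(m, node_seq[w]))
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        added = False
        for m in sorted(candidates):
            if candidates[m] <= lam + epsilon:
                node_seq[f"median_{next(median_serial):03d}"] = m
                added = True
        if not added:
            break

    # prune dangling medians, recomputing the MSN until stable
    while True:
        nodes = sorted(node_seq)
        msn = _msn_edges(nodes, node_seq)
        degree = {n: 0 for n in nodes}
        for u, v in msn:
            degree[u] += 1
            degree[v] += 1
        dangling = [n for n in nodes if n not in observed and degree[n] <= 1]
        if not dangling:
            break
        for n in dangling:
            del node_seq[n]

    g = nx.Graph()
    for n in sorted(node_seq):
        attrs = {"seq": node_seq[n], "is_median": n not in observed}
        if counts is not None and n in observed:
            merged = by_seq[node_seq[n]]
            for group in counts.columns:
                attrs[f"count_{group}"] = int(counts.loc[
                    [h for h in merged if h in counts.index], group].sum())
        g.add_node(n, **attrs)
    for u, v in msn:
        g.add_edge(u, v, weight=_hamming(node_seq[u], node_seq[v]))
    return g


def annotate_root(network: nx.Graph, outgroup_seqs) -> nx.Graph:
    """Mark the ingroup node(s) closest to the outgroups (annotation only).

    Each node's total Hamming distance to all outgroup sequences is computed
    on the network's cleaned columns; all nodes attaining the minimum are
    marked ``root_adjacent`` (ties kept, not broken).  Outgroups must match
    the original alignment length.
    """
    outgroups = list(outgroup_seqs)
    if not outgroups:
        raise ValueError("empty outgroup set")
    nodes = sorted(network.nodes)
    any_seq = network.nodes[nodes[0]]["seq"]
    totals = {}
    for n in nodes:
        seq = network.nodes[n]["seq"]
        if len(seq) != len(any_seq):
            raise ValueError("network node sequences have unequal lengths")
        totals[n] = sum(
            sum(1 for x, y in zip(seq, og) if y in "ACGT" and x != y)
            for og in outgroups)
    best = min(totals.values())
    for n in nodes:
        network.nodes[n]["root_adjacent"] = bool(totals[n] == best)
        network.nodes[n]["outgroup_distance"] = int(totals[n])
    return network


def export_network(network: nx.Graph, path, format: str = "graphml"):
    """Lossless export: ``graphml``, ``dot``, or ``tsv`` (node + edge tables)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, str(path))
        return path
    if format == "dot":
        lines = ["graph haplotype_network {"]
        for n, attrs in sorted(network.nodes(data=True)):
            shape = "point" if attrs.get("is_median") else "circle"
            lines.append(f'  "{n}" [shape={shape}];')
        for u, v, attrs in sorted(network.edges(data=True)):
            lines.append(f'  "{u}" -- "{v}" [label="{attrs.get("weight", 1)}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return path
    if format == "tsv":
        node_rows = []
        for n, attrs in sorted(network.nodes(data=True)):
            row = {"node": n}
            row.update(attrs)
            node_rows.append(row)
        nodes_path = path.with_suffix(".nodes.tsv")
        edges_path = path.with_suffix(".edges.tsv")
        pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
        pd.DataFrame(
            [{"source": u, "target": v, "weight": d.get("weight", 1)}
             for u, v, d in sorted(network.edges(data=True))]
        ).to_csv(edges_path, sep="\t", index=False)
        return nodes_path
    raise ValueError(f"unknown export format {format!r}")
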