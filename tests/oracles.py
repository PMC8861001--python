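"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the algorithms used by the package: local alignment
is enumerated over aligned-pair chains, duplex penalties over recursive
alignment paths, and neighbor joining is checked against least-squares
fitting over an explicit enumeration of all unrooted topologies.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np


# --- local alignment ------------------------------------------------------

def brute_local_align(query: str, subject: str, score_fn,
                      gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score by enumerating aligned-pair chains.

    A local alignment is a chain of aligned index pairs, strictly
    increasing in both sequences; unaligned residues between consecutive
    pairs form one gap run per sequence with affine cost
    open + k * extend.  The empty chain scores 0.
    """
    n, m = len(query), len(subject)
    best = 0.0
    indices_q = range(n)
    indices_s = range(m)
    for k in range(1, min(n, m) + 1):
        for qs in itertools.combinations(indices_q, k):
            for ss in itertools.combinations(indices_s, k):
                score = 0.0
                for a in range(k):
                    score += score_fn(query[qs[a]], subject[ss[a]])
                    if a:
                        di = qs[a] - qs[a - 1] - 1
                        dj = ss[a] - ss[a - 1] - 1
                        if di:
                            score -= gap_open + di * gap_extend
                        if dj:
                            score -= gap_open + dj * gap_extend
                best = max(best, score)
    return best


# --- duplex penalty -------------------------------------------------------

def brute_duplex(mirna: str, window: str, scheme) -> float:
    """Minimum duplex penalty by recursive enumeration of alignment paths."""
    from splnet.targets import _base_penalty

    rev = window[::-1]
    L, M = len(mirna), len(rev)
    best = [math.inf]

    def rec(i, k, gaps, score):
        if score >= best[0]:
            return
        if i == L and k == M:
            best[0] = score
            return
        if i < L and k < M:
            rec(i + 1, k + 1, gaps,
                score + scheme.weight(i + 1)
                * _base_penalty(mirna[i], rev[k], scheme))
        if gaps < scheme.max_gaps:
            if i < L:   # miRNA base unpaired (target-strand gap)
                rec(i + 1, k, gaps + 1,
                    score + scheme.weight(i + 1) * scheme.gap)
            if k < M:   # target base unpaired (miRNA-strand gap)
                rec(i, k + 1, gaps + 1,
                    score + scheme.weight(min(i + 1, L)) * scheme.gap)

    rec(0, 0, 0, 0.0)
    return best[0]


def brute_best_site(mirna: str, sequence: str, scheme) -> float:
    """Minimum penalty over every admissible window of a sequence."""
    L = len(mirna)
    lengths = [L] if scheme.max_gaps == 0 else [L - 1, L, L + 1]
    best = math.inf
    for wlen in lengths:
        for start in range(0, len(sequence) - wlen + 1):
            best = min(best, brute_duplex(
                mirna, sequence[start:start + wlen], scheme))
    return best


# --- domain scan ----------------------------------------------------------

def brute_domain_scan(protein: str, profile):
    """Max per-window PSSM sum over all placements incl. overhangs."""
    from splnet.family import AA_ORDER

    W = profile.width
    n = len(protein)
    best = None
    for offset in range(-(W - 1), n):
        score = 0.0
        for c in range(W):
            pos = offset + c
            if 0 <= pos < n:
                score += profile.pssm[c, AA_ORDER.index(protein[pos])]
        if best is None or score > best[0]:
            best = (score, max(0, offset) + 1, min(n, offset + W))
    return best


# --- phylogeny ------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, taxa: Sequence[str]):
    """Random unrooted binary tree with positive lengths; returns
    (edge list [(u, v, length)], leaf-pair distance dict)."""
    nodes = list(taxa[:3])
    internal = ["I0"]
    edges = {(t, "I0"): float(rng.uniform(0.2, 2.0)) for t in taxa[:3]}
    counter = 1
    for taxon in taxa[3:]:
        u, v = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop((u, v))
        new = f"I{counter}"
        counter += 1
        split = float(rng.uniform(0.2, 0.8)) * length
        edges[(u, new)] = split
        edges[(new, v)] = length - split
        edges[(taxon, new)] = float(rng.uniform(0.2, 2.0))
        internal.append(new)
        nodes.append(taxon)
    # leaf-pair path lengths by BFS
    adjacency: Dict[str, List[Tuple[str, float]]] = {}
    for (u, v), w in edges.items():
        adjacency.setdefault(u, []).append((v, w))
        adjacency.setdefault(v, []).append((u, w))
    dist = {}
    for a in taxa:
        seen = {a: 0.0}
        stack = [a]
        while stack:
            cur = stack.pop()
            for nxt, w in adjacency[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        for b in taxa:
            if (b, a) in dist:
                dist[(a, b)] = dist[(b, a)]  # exact float symmetry
            else:
                dist[(a, b)] = seen[b]
    return list(edges.items()), dist


def enumerate_topologies(taxa: Sequence[str]):
    """All unrooted binary topologies as lists of edges (u, v)."""
    if len(taxa) == 3:
        return [[(t, "I0") for t in taxa]]
    out = []

    def build(current_edges, counter, remaining):
        if not remaining:
            out.append(list(current_edges))
            return
        taxon = remaining[0]
        for idx in range(len(current_edges)):
            u, v = current_edges[idx]
            new = f"I{counter}"
            next_edges = (current_edges[:idx]
                          + [(u, new), (new, v), (taxon, new)]
                          + current_edges[idx + 1:])
            build(next_edges, counter + 1, remaining[1:])

    base = [(t, "I0") for t in taxa[:3]]
    build(base, 1, list(taxa[3:]))
    return out


def topology_bipartitions(edges, taxa) -> frozenset:
    """Canonical internal bipartitions of a topology given as edge pairs."""
    adjacency: Dict[str, List[str]] = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    taxa_set = frozenset(taxa)
    bps = set()
    for u, v in edges:
        if u in taxa_set or v in taxa_set:
            continue
        # leaves on v's side when edge (u, v) is cut
        seen = {v, u}
        stack = [v]
        side = set()
        while stack:
            cur = stack.pop()
            for nxt in adjacency[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
                    if nxt in taxa_set:
                        side.add(nxt)
            if cur in taxa_set:
                side.add(cur)
        side = frozenset(side)
        other = taxa_set - side
        a = min((side, other), key=lambda s: (len(s), tuple(sorted(s))))
        if 2 <= len(a) <= len(taxa_set) - 2:
            bps.add(a)
    return frozenset(bps)


def least_squares_fit(edges, taxa, dist) -> float:
    """Ordinary least-squares residual of fitting branch lengths to the
    distance matrix on a fixed topology."""
    edge_list = list(edges)
    adjacency: Dict[str, List[Tuple[str, int]]] = {}
    for idx, (u, v) in enumerate(edge_list):
        adjacency.setdefault(u, []).append((v, idx))
        adjacency.setdefault(v, []).append((u, idx))
    pairs = list(itertools.combinations(taxa, 2))
    A = np.zeros((len(pairs), len(edge_list)))
    b = np.zeros(len(pairs))
    for row, (x, y) in enumerate(pairs):
        # path from x to y
        prev = {x: None}
        stack = [x]
        while stack:
            cur = stack.pop()
            for nxt, idx in adjacency[cur]:
                if nxt not in prev:
                    prev[nxt] = (cur, idx)
                    stack.append(nxt)
        cur = y
        while prev[cur] is not None:
            cur, idx = prev[cur]
            A[row, idx] = 1.0
        b[row] = dist[(x, y)]
    x, residuals, _, _ = np.linalg.lstsq(A, b, rcond=None)
    return float(((A @ x - b) ** 2).sum())


def best_ls_topology(taxa, dist):
    """Bipartition set of the least-squares-optimal topology."""
    best = None
    for edges in enumerate_topologies(taxa):
        rss = least_squares_fit(edges, taxa, dist)
        if best is None or rss < best[0]:
            best = (rss, topology_bipartitions(edges, taxa))
    return best
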