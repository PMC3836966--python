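"""Contig assembly from the clone overlap graph, two ways.

LTC-style assembly clusters at a permissive Sulston cutoff and then enforces
*linear topology*: the clone overlap graph of a genuine contig must be a
proper interval graph (clones orderable along the chromosome so that edges
connect only order-consecutive windows).  Contigs violating linearity
(Q-contigs, typically caused by chimeric or well-contaminated fingerprints)
are rebuilt at successively stricter cutoffs, and remaining offending clones
are fragmented to singletons.

FPC-style assembly starts at a very stringent cutoff and relaxes step-wise,
merging contigs end-to-end, with a DQer pass that re-splits any contig whose
questionable-clone fraction grows too large.

A minimum tiling path (MTP) is the smallest clone subset covering a contig's
span with a guaranteed pairwise overlap; the final backbone is the LTC
assembly complemented by FPC MTP clones the LTC assembly dropped.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .fingerprints import AssemblyParams, Fingerprint, build_overlap_graph

__all__ = [
    "Contig",
    "Backbone",
    "cluster_at_cutoff",
    "proper_interval_order",
    "is_linear",
    "q_clones",
    "resolve_q_contigs",
    "assemble_ltc_style",
    "assemble_fpc_style",
    "select_mtp",
    "merge_backbone",
    "estimate_contig_length",
    "write_contigs_tsv",
    "read_contigs_tsv",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class Contig:
    """Ordered clones with relative offsets (band-size units scaled to bases)."""

    contig_id: str
    clones: list
    offsets: list
    source: str = "ltc"
    linear: bool = True
    clone_lengths: dict | None = None

    def __post_init__(self):
        if len(self.clones) != len(self.offsets):
            raise ValueError("clones and offsets must have equal length")
        if any(b < a - 1e-9 for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be non-decreasing along the clone order")

    def __len__(self) -> int:
        return len(self.clones)

    def clone_length(self, clone: str, default: float) -> float:
        if self.clone_lengths and clone in self.clone_lengths:
            return self.clone_lengths[clone]
        return default


@dataclass
class Backbone:
    contigs: list
    singletons: list

    def clone_universe(self) -> set:
        u = set(self.singletons)
        for c in self.contigs:
            u.update(c.clones)
        return u

    def contig_of(self) -> dict:
        """clone id -> contig id for clones placed in contigs."""
        out = {}
        for c in self.contigs:
            for cl in c.clones:
                out[cl] = c.contig_id
        return out

    def summary(self, default_clone_length: float = 111_000.0) -> dict:
        lengths = sorted(
            (estimate_contig_length(c, default_clone_length) for c in self.contigs),
            reverse=True,
        )
        total = sum(lengths)
        n50_len, n50_count, acc = 0.0, 0, 0.0
        for i, ln in enumerate(lengths, start=1):
            acc += ln
            if acc >= total / 2.0:
                n50_len, n50_count = ln, i
                break
        return {
            "contig_count": len(self.contigs),
            "clone_count": sum(len(c) for c in self.contigs),
            "singleton_count": len(self.singletons),
            "cumulative_length": total,
            "n50_length": n50_len,
            "n50_count": n50_count,
        }


# ---------------------------------------------------------------------------
# Proper-interval-graph recognition (linear topology test)


def _lexbfs(graph: nx.Graph, nodes, prev_order=None) -> list:
    """Lexicographic BFS; with ``prev_order`` given, runs LBFS+ (ties broken
    toward the vertex appearing *latest* in the previous sweep)."""
    nodes = list(nodes)
    if prev_order is None:
        rank = {v: i for i, v in enumerate(sorted(nodes))}
    else:
        rank = {v: i for i, v in enumerate(prev_order)}
    seq = [list(nodes)]
    order = []
    while seq:
        cls = seq[0]
        v = max(cls, key=lambda u: rank[u])
        cls.remove(v)
        if not cls:
            seq.pop(0)
        order.append(v)
        nbrs = set(graph[v])
        new_seq = []
        for c in seq:
            inside = [u for u in c if u in nbrs]
            outside = [u for u in c if u not in nbrs]
            if inside:
                new_seq.append(inside)
            if outside:
                new_seq.append(outside)
        seq = new_seq
    return order


def _is_umbrella(graph: nx.Graph, order) -> bool:
    """True iff every closed neighbourhood occupies consecutive positions."""
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        ps = [pos[u] for u in graph[v]]
        ps.append(pos[v])
        if max(ps) - min(ps) != len(ps) - 1:
            return False
    return True


def _component_order(graph: nx.Graph, nodes):
    s1 = _lexbfs(graph, nodes)
    s2 = _lexbfs(graph, nodes, prev_order=s1)
    s3 = _lexbfs(graph, nodes, prev_order=s2)
    return s3


def proper_interval_order(graph: nx.Graph, nodes=None):
    """An umbrella (proper-interval) ordering of ``nodes``, or None.

    Three-sweep LBFS recognition: the third sweep of a proper interval graph
    is an umbrella ordering, so checking the final sweep decides membership.
    Disconnected inputs are ordered component by component.
    """
    if nodes is None:
        nodes = list(graph.nodes)
    nodes = list(nodes)
    if len(nodes) <= 2:
        return sorted(nodes)
    sub = graph.subgraph(nodes)
    order = []
    for comp in sorted(nx.connected_components(sub), key=min):
        comp_order = _component_order(sub, comp)
        if not _is_umbrella(sub, comp_order):
            return None
        if comp_order[-1] < comp_order[0]:
            comp_order.reverse()
        order.extend(comp_order)
    return order


def _umbrella_violations(graph: nx.Graph, order) -> dict:
    """Per-vertex count of (v, u) conflicts: u sits inside v's neighbourhood
    span without being adjacent to v."""
    pos = {v: i for i, v in enumerate(order)}
    counts = defaultdict(int)
    for v in order:
        nbrs = set(graph[v])
        ps = [pos[u] for u in nbrs]
        ps.append(pos[v])
        lo, hi = min(ps), max(ps)
        for k in range(lo, hi + 1):
            u = order[k]
            if u != v and u not in nbrs:
                counts[v] += 1
                counts[u] += 1
    return counts


def is_linear(contig, graph: nx.Graph):
    """Test a contig for linear topology.

    Returns ``(flag, offending)`` where ``flag`` is True iff the induced
    subgraph is a proper interval graph and ``offending`` is a greedily
    chosen (approximately minimal) vertex set whose removal restores the
    property.  Contigs of one or two clones are trivially linear.
    """
    nodes = list(contig.clones) if isinstance(contig, Contig) else list(contig)
    if len(nodes) <= 2:
        return True, []
    sub = nx.Graph(graph.subgraph(nodes))
    if proper_interval_order(sub) is not None:
        return True, []
    offending = []
    while proper_interval_order(sub) is None:
        order = []
        for comp in sorted(nx.connected_components(sub), key=min):
            order.extend(_component_order(sub, comp))
        counts = _umbrella_violations(sub, order)
        worst = max(sorted(counts), key=lambda v: counts[v])
        offending.append(worst)
        sub.remove_node(worst)
    return False, offending


def _reachable_without(graph: nx.Graph, v, frm, to, depth: int = 4) -> bool:
    """Can any node of ``frm`` reach a node of ``to`` within ``depth`` hops
    when ``v`` is excluded?  Used to decide whether a clone's neighbourhood
    groups are genuinely distant regions or a local coverage dip."""
    to = set(to)
    frontier = set(frm)
    seen = set(frontier) | {v}
    for _ in range(depth):
        nxt = set()
        for u in frontier:
            for w in graph[u]:
                if w in to:
                    return True
                if w not in seen:
                    nxt.add(w)
                    seen.add(w)
        if not nxt:
            return False
        frontier = nxt
    return False


def q_clones(contig, graph: nx.Graph, min_side: int = 3, violation_min: int = 8) -> list:
    """Questionable clones of a contig.

    The union of (a) clones found by iteratively removing the worst
    umbrella-violation offender while the worst count is *substantial*
    (>= ``violation_min`` conflicts in the 3-sweep ordering) — a clone whose
    fingerprint links two distant regions scores on the order of the glued
    component's size, while band-sampling noise and short clones leave only
    a handful of conflicts — and (b) articulation clones bridging two
    otherwise unconnected dense regions (an articulation vertex whose
    removal leaves components of at least ``min_side`` clones on each side,
    with at least two neighbours on each).  A chimeric clone joining two
    distant regions can form two cliques sharing one vertex, which *is*
    proper-interval, so rule (b) backstops rule (a).  Removal is iterative
    because a single bridge clone pollutes the whole ordering, inflating
    innocent clones' counts; once the bridge is gone the counts collapse.
    """
    nodes = list(contig.clones) if isinstance(contig, Contig) else list(contig)
    work = nx.Graph(graph.subgraph(nodes))
    qset = set()
    # rule (a'): clones not supported by parallel clones — the neighbourhood
    # splits into groups that cannot reach each other without this clone
    changed = True
    while changed:
        changed = False
        for v in sorted(work.nodes):
            nbrs = list(work[v])
            if len(nbrs) < 2:
                continue
            ncomps = sorted(nx.connected_components(work.subgraph(nbrs)), key=len)
            if len(ncomps) < 2:
                continue
            if not _reachable_without(work, v, ncomps[0], ncomps[-1], depth=4):
                qset.add(v)
                work.remove_node(v)
                changed = True
    # backstop: iteratively remove the worst umbrella-violation offender
    # while the worst count stays substantial
    while True:
        worst, wcount = None, 0
        for comp in sorted(nx.connected_components(work), key=min):
            if len(comp) <= 2:
                continue
            order = _component_order(work, comp)
            counts = _umbrella_violations(work, order)
            for v in sorted(counts):
                if counts[v] > wcount:
                    worst, wcount = v, counts[v]
        if worst is None or wcount < violation_min:
            break
        qset.add(worst)
        work.remove_node(worst)
    sub = graph.subgraph(nodes)
    for comp in nx.connected_components(sub):
        if len(comp) < 2 * min_side + 1:
            continue
        csub = sub.subgraph(comp)
        for v in nx.articulation_points(csub):
            rest = csub.subgraph(set(comp) - {v})
            sides = list(nx.connected_components(rest))
            big = [s for s in sides if len(s) >= min_side]
            if len(big) >= 2:
                nbrs = set(csub[v])
                if sum(1 for s in big if len(nbrs & s) >= 2) >= 2:
                    qset.add(v)
    return sorted(qset)


# ---------------------------------------------------------------------------
# Clustering and contig construction


def cluster_at_cutoff(graph: nx.Graph, cutoff: float) -> list:
    """Partition clones into connected components of the thresholded graph.

    Components below the minimum contig size are retained at this stage.
    Returned as clone-id sets, sorted by smallest member for determinism.
    """
    thr = nx.Graph()
    thr.add_nodes_from(graph.nodes)
    thr.add_edges_from(
        (a, b) for a, b, d in graph.edges(data=True) if d["score"] <= cutoff
    )
    return sorted(nx.connected_components(thr), key=min)


def _order_nodes(nodes, graph: nx.Graph) -> list:
    order = proper_interval_order(graph, nodes)
    if order is None:
        sub = graph.subgraph(nodes)
        order = []
        for comp in sorted(nx.connected_components(sub), key=min):
            order.extend(_component_order(sub, comp))
        if order and order[-1] < order[0]:
            order.reverse()
    return order


def _offsets_for_order(order, graph: nx.Graph, params: AssemblyParams) -> list:
    """Offsets from shared-band fractions.

    step = (1 - shared/(retention * n_left)) * insert estimate, where
    n_left is the band count of the earlier clone in the order: the shared
    fraction of the *left* clone's bands estimates the overlap as a fraction
    of that clone's length, which is what separates the two start positions
    (the min band count would overstate the fraction whenever the next
    clone is short or nested).  The retention factor corrects for shared
    bands lost to sizing noise.  Each clone's offset is the median of the
    offsets implied by all its edges to already-placed clones, which pools
    several noisy shared-band estimates per step.
    """
    pos = {v: i for i, v in enumerate(order)}
    offs = [0.0]
    for i, v in enumerate(order[1:], start=1):
        implied = []
        for u, d in graph[v].items():
            j = pos.get(u)
            if j is None or j >= i:
                continue
            n_left = graph.nodes[u].get("n_bands") or d["shared"]
            frac = min(1.0, d["shared"] / max(params.band_retention * n_left, 1.0))
            implied.append(offs[j] + (1.0 - frac) * params.insert_size_estimate)
        if implied:
            off = float(np.median(implied))
        else:
            off = offs[-1] + params.insert_size_estimate
        offs.append(max(off, offs[-1]))
    return offs


def make_contig(
    contig_id: str,
    nodes,
    graph: nx.Graph,
    params: AssemblyParams,
    source: str = "ltc",
) -> Contig:
    order = _order_nodes(nodes, graph)
    flag = proper_interval_order(graph, order) is not None
    return Contig(
        contig_id=contig_id,
        clones=order,
        offsets=_offsets_for_order(order, graph, params),
        source=source,
        linear=flag,
    )


def _annotate_band_counts(graph: nx.Graph, fps) -> None:
    for fp in fps:
        if fp.clone_id in graph:
            graph.nodes[fp.clone_id]["n_bands"] = fp.n_bands


# ---------------------------------------------------------------------------
# LTC-style assembly


def _cut_bridges(work: nx.Graph) -> list:
    """Cut single-clone connections between otherwise unconnected regions.

    A clone whose neighbourhood splits into groups unreachable without it
    is either chimeric (its fingerprint glues two distant regions) or the
    sole clone spanning a local coverage pinch; either way the contig is
    cut there.  The clone keeps its edges to the side sharing the most
    bands with it and loses the others, so a chimeric clone stays with its
    genuine locus.  Returns the cut clones.
    """
    cut = []
    changed = True
    while changed:
        changed = False
        for v in sorted(work.nodes):
            nbrs = list(work[v])
            if len(nbrs) < 2:
                continue
            ncomps = sorted(nx.connected_components(work.subgraph(nbrs)), key=len)
            if len(ncomps) < 2:
                continue
            if _reachable_without(work, v, ncomps[0], ncomps[-1], depth=4):
                continue
            support = [sum(work[v][u].get("shared", 1) for u in comp) for comp in ncomps]
            best = max(range(len(ncomps)), key=lambda i: (support[i], len(ncomps[i])))
            for i, comp in enumerate(ncomps):
                if i == best:
                    continue
                for u in comp:
                    work.remove_edge(v, u)
            cut.append(v)
            changed = True
    return cut


def _resolve_nodes(nodes: set, graph: nx.Graph, params: AssemblyParams) -> list:
    """Cut chimeric/pinch bridges and fragment irreducible offenders.

    Single-clone bridges between distant regions are cut (the clone stays
    with its better-supported side); clones with substantial umbrella
    violations that survive the cuts are removed to singletons.  Returns
    the resulting clone sets.
    """
    work = nx.Graph(graph.subgraph(nodes))
    _cut_bridges(work)
    out = []
    removed = []
    while True:
        worst, wcount = None, 0
        for comp in sorted(nx.connected_components(work), key=min):
            if len(comp) <= 2:
                continue
            order = _component_order(work, comp)
            counts = _umbrella_violations(work, order)
            for v in sorted(counts):
                if counts[v] > wcount:
                    worst, wcount = v, counts[v]
        if worst is None or wcount < params.q_violation_min:
            break
        removed.append(worst)
        work.remove_node(worst)
    out.extend(set(c) for c in sorted(nx.connected_components(work), key=min))
    out.extend({r} for r in removed)
    return out


def resolve_q_contigs(contigs, graph: nx.Graph, params: AssemblyParams) -> list:
    """Fragment chimera-bridged contigs; keep only sufficiently large parts.

    Output contains no contig with questionable clones (substantial
    non-linear structure or chimeric bridges) and retains only contigs with
    at least ``params.min_contig_clones`` clones; compliant contigs pass
    through unchanged.
    """
    out = []
    for contig in contigs:
        nodes = set(contig.clones)
        if len(nodes) <= 2 or not q_clones(nodes, graph):
            if len(nodes) >= params.min_contig_clones:
                out.append(contig)
            continue
        parts = _resolve_nodes(nodes, graph, params)
        k = 0
        for part in sorted(parts, key=min):
            if len(part) < params.min_contig_clones:
                continue
            k += 1
            out.append(make_contig(f"{contig.contig_id}.{k}", part, graph, params, contig.source))
    return out


def assemble_ltc_style(fps, params: AssemblyParams | None = None, graph: nx.Graph | None = None) -> Backbone:
    """Permissive clustering + linear-topology QC + size filter."""
    params = params or AssemblyParams()
    if graph is None:
        graph = build_overlap_graph(fps, params, cutoff=params.cutoff_ladder[0])
        _annotate_band_counts(graph, fps)
    raw = [
        make_contig(f"ltc{i}", comp, graph, params, "ltc")
        for i, comp in enumerate(cluster_at_cutoff(graph, params.cutoff_ladder[0]), start=1)
        if len(comp) >= 2
    ]
    contigs = resolve_q_contigs(raw, graph, params)
    contigs = [
        Contig(f"ltc{i}", c.clones, c.offsets, c.source, c.linear, c.clone_lengths)
        for i, c in enumerate(sorted(contigs, key=lambda c: min(c.clones)), start=1)
    ]
    placed = set()
    for c in contigs:
        placed.update(c.clones)
    singletons = sorted(set(fp.clone_id for fp in fps) - placed)
    return Backbone(contigs=contigs, singletons=singletons)


# ---------------------------------------------------------------------------
# FPC-style assembly


def _end_region(order, window: int) -> set:
    if len(order) <= 2 * window:
        return set(order)
    return set(order[:window]) | set(order[-window:])


def assemble_fpc_style(fps, params: AssemblyParams | None = None, graph: nx.Graph | None = None) -> Backbone:
    """Incremental build at the strictest cutoff, then step-wise end merging.

    At each relaxation step singletons join contig ends (single-to-end), then
    contigs whose end clones connect merge (end-to-end); after each step any
    contig whose questionable-clone fraction exceeds ``q_fraction`` is
    re-split at the previous, stricter cutoff (the DQer rule).
    """
    params = params or AssemblyParams()
    ladder = params.fpc_ladder
    if graph is None:
        graph = build_overlap_graph(fps, params, cutoff=max(ladder))
        _annotate_band_counts(graph, fps)

    groups = [set(c) for c in cluster_at_cutoff(graph, ladder[0]) if len(c) >= 2]
    singles = set(fp.clone_id for fp in fps) - set().union(*groups) if groups else set(
        fp.clone_id for fp in fps
    )

    for step, cutoff in enumerate(ladder[1:], start=1):
        stricter = ladder[step - 1]

        # incremental building: remaining singletons that connect at this
        # stringency form new contigs
        if singles:
            for comp in cluster_at_cutoff(graph.subgraph(singles), cutoff):
                if len(comp) >= 2:
                    groups.append(set(comp))
                    singles -= set(comp)

        orders = [_order_nodes(g, graph) for g in groups]
        ends = [_end_region(o, params.end_window) for o in orders]
        end_of = {}
        for gi, end in enumerate(ends):
            for e in end:
                end_of[e] = gi

        # single-to-end: attach each singleton to the best-connecting contig end
        for s in sorted(singles):
            best, best_score = None, cutoff
            for nbr, d in graph[s].items():
                gi = end_of.get(nbr)
                if gi is not None and d["score"] <= best_score:
                    best, best_score = gi, d["score"]
            if best is not None:
                groups[best].add(s)
                singles.discard(s)
                orders[best] = _order_nodes(groups[best], graph)
                for e in _end_region(orders[best], params.end_window):
                    end_of.setdefault(e, best)

        # end-to-end merging via union-find over end-region edges
        parent = list(range(len(groups)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        clone_group = {}
        for gi, g in enumerate(groups):
            for e in _end_region(_order_nodes(g, graph), params.end_window):
                clone_group[e] = gi
        for a, b, d in graph.edges(data=True):
            if d["score"] > cutoff:
                continue
            ga, gb = clone_group.get(a), clone_group.get(b)
            if ga is None or gb is None:
                continue
            ra, rb = find(ga), find(gb)
            if ra != rb:
                parent[rb] = ra
        merged = defaultdict(set)
        for gi, g in enumerate(groups):
            merged[find(gi)].update(g)
        groups = [merged[r] for r in sorted(merged, key=lambda r: min(merged[r]))]

        # DQer: re-split contigs with too many questionable clones
        next_groups = []
        for g in groups:
            q = q_clones(g, graph)
            if len(g) >= 3 and len(q) / len(g) > params.q_fraction:
                for comp in cluster_at_cutoff(graph.subgraph(g), stricter):
                    if len(comp) >= 2:
                        next_groups.append(set(comp))
                    else:
                        singles.update(comp)
            else:
                next_groups.append(g)
        groups = next_groups

    contigs = [
        make_contig(f"fpc{i}", g, graph, params, "fpc")
        for i, g in enumerate(sorted(groups, key=min), start=1)
    ]
    return Backbone(contigs=contigs, singletons=sorted(singles))


# ---------------------------------------------------------------------------
# Minimum tiling path, backbone merge, length estimate


def select_mtp(
    contig: Contig,
    min_overlap: float = 10_000.0,
    default_clone_length: float = 111_000.0,
) -> list:
    """Greedy left-to-right minimum interval cover of the contig span.

    Successive MTP clones must overlap by at least ``min_overlap``; ties are
    broken by lexicographic clone id.  Single-clone contigs return that clone.
    """
    if len(contig) == 1:
        return list(contig.clones)
    iv = {
        c: (off, off + contig.clone_length(c, default_clone_length))
        for c, off in zip(contig.clones, contig.offsets)
    }
    span_end = max(e for _, e in iv.values())
    start_clone = min(iv, key=lambda c: (iv[c][0], -iv[c][1], c))
    chosen = [start_clone]
    cur_end = iv[start_clone][1]
    remaining = set(iv) - {start_clone}
    while cur_end < span_end - 1e-9 and remaining:
        reach = [c for c in remaining if iv[c][0] <= cur_end - min_overlap and iv[c][1] > cur_end]
        if reach:
            pick = sorted(reach, key=lambda c: (-iv[c][1], c))[0]
        else:
            ahead = [c for c in remaining if iv[c][1] > cur_end]
            if not ahead:
                break
            pick = sorted(ahead, key=lambda c: (iv[c][0], -iv[c][1], c))[0]
        chosen.append(pick)
        cur_end = iv[pick][1]
        remaining.discard(pick)
    return chosen


def merge_backbone(ltc: Backbone, fpc: Backbone, fpc_mtp=None) -> Backbone:
    """LTC contigs plus FPC-MTP clones the LTC assembly left out.

    Added clones are grouped by their FPC contig membership and flagged with
    the ``fpc`` source/prefix; no clone appears twice.  Both backbones must
    cover the same clone universe.
    """
    if ltc.clone_universe() != fpc.clone_universe():
        raise ValueError("backbones cover different clone universes")
    if fpc_mtp is None:
        fpc_mtp = set()
        for c in fpc.contigs:
            fpc_mtp.update(select_mtp(c))
    else:
        fpc_mtp = set(fpc_mtp)
    in_ltc = set()
    for c in ltc.contigs:
        in_ltc.update(c.clones)
    leftover = fpc_mtp - in_ltc
    contigs = list(ltc.contigs)
    for c in fpc.contigs:
        group = [cl for cl in c.clones if cl in leftover]
        if not group:
            continue
        offs = {cl: off for cl, off in zip(c.clones, c.offsets)}
        base = min(offs[cl] for cl in group)
        contigs.append(
            Contig(
                contig_id=f"fpc_{c.contig_id}",
                clones=group,
                offsets=[offs[cl] - base for cl in group],
                source="fpc",
                linear=c.linear,
                clone_lengths=c.clone_lengths,
            )
        )
    placed = set()
    for c in contigs:
        placed.update(c.clones)
    singletons = sorted(ltc.clone_universe() - placed)
    return Backbone(contigs=contigs, singletons=singletons)


def estimate_contig_length(contig: Contig, default_clone_length: float = 111_000.0) -> float:
    """Span from the leftmost offset to rightmost offset + rightmost clone length."""
    if not contig.clones:
        return 0.0
    last = contig.clones[-1]
    return (contig.offsets[-1] - contig.offsets[0]) + contig.clone_length(
        last, default_clone_length
    )


# ---------------------------------------------------------------------------
# Tabular IO


def write_contigs_tsv(backbone: Backbone, path) -> None:
    rows = [
        {"contig_id": c.contig_id, "source": c.source, "clone_id": cl, "offset": off}
        for c in backbone.contigs
        for cl, off in zip(c.clones, c.offsets)
    ]
    rows += [
        {"contig_id": "singleton", "source": "none", "clone_id": s, "offset": 0.0}
        for s in backbone.singletons
    ]
    pd.DataFrame(rows, columns=["contig_id", "source", "clone_id", "offset"]).to_csv(
        path, sep="\t", index=False
    )


def read_contigs_tsv(path) -> Backbone:
    df = pd.read_csv(path, sep="\t")
    contigs, singles = [], []
    for cid, grp in df.groupby("contig_id", sort=True):
        if cid == "singleton":
            singles.extend(str(c) for c in grp.clone_id)
            continue
        grp = grp.sort_values("offset", kind="stable")
        contigs.append(
            Contig(
                contig_id=str(cid),
                clones=[str(c) for c in grp.clone_id],
                offsets=[float(o) for o in grp.offset],
                source=str(grp.source.iloc[0]),
            )
        )
    contigs.sort(key=lambda c: min(c.clones))
    return Backbone(contigs=contigs, singletons=sorted(singles))
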