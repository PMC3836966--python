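"""Contig assembly: clustering, linear topology, Q-resolution, MTP, merging."""

import itertools

import networkx as nx
import numpy as np
import pytest

from physmap.assembly import (
    Backbone,
    Contig,
    assemble_fpc_style,
    assemble_ltc_style,
    cluster_at_cutoff,
    estimate_contig_length,
    is_linear,
    merge_backbone,
    proper_interval_order,
    q_clones,
    read_contigs_tsv,
    resolve_q_contigs,
    select_mtp,
    write_contigs_tsv,
)
from physmap.fingerprints import AssemblyParams
from physmap.synthdata import build_truth


def brute_force_proper_interval(g):
    """Exhaustive search for an umbrella ordering."""
    nodes = list(g)
    for perm in itertools.permutations(nodes):
        pos = {v: i for i, v in enumerate(perm)}
        ok = True
        for v in nodes:
            ps = [pos[u] for u in g[v]] + [pos[v]]
            if max(ps) - min(ps) != len(ps) - 1:
                ok = False
                break
        if ok:
            return True
    return False


def scored_graph(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for e in edges:
        a, b, *rest = e
        score = rest[0] if rest else 1e-20
        shared = rest[1] if len(rest) > 1 else 20
        g.add_edge(a, b, score=score, shared=shared)
        g.nodes[a].setdefault("n_bands", 35)
        g.nodes[b].setdefault("n_bands", 35)
    return g


class TestClusterAtCutoff:
    def test_edgeless_graph_all_singletons(self):
        g = scored_graph([], nodes=list("abcd"))
        parts = cluster_at_cutoff(g, 1e-15)
        assert sorted(len(p) for p in parts) == [1, 1, 1, 1]

    def test_path_graph_single_contig(self):
        g = scored_graph([(i, i + 1) for i in range(7)])
        parts = cluster_at_cutoff(g, 1e-15)
        assert len(parts) == 1 and len(parts[0]) == 8

    def test_stricter_cutoff_refines_partition(self, small_world):
        g = small_world["graph"]
        loose = cluster_at_cutoff(g, 1e-15)
        strict = cluster_at_cutoff(g, 1e-50)
        member_loose = {v: i for i, p in enumerate(loose) for v in p}
        # refinement: co-membership at 1e-50 implies co-membership at 1e-15
        for p in strict:
            assert len({member_loose[v] for v in p}) == 1


class TestLinearTopology:
    def test_path_and_clique_are_linear(self):
        path = scored_graph([(i, i + 1) for i in range(5)])
        clique = scored_graph([(a, b) for a, b in itertools.combinations(range(5), 2)])
        assert is_linear(list(path), path)[0]
        assert is_linear(list(clique), clique)[0]

    def test_claw_is_not_linear(self):
        claw = scored_graph([("c", "x"), ("c", "y"), ("c", "z")])
        flag, offending = is_linear(list(claw), claw)
        assert not flag
        assert not brute_force_proper_interval(claw)
        assert offending  # removing the reported clones restores the property
        claw.remove_nodes_from(offending)
        assert brute_force_proper_interval(claw)

    def test_three_sweep_recognition_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            n = int(rng.integers(3, 8))
            p = float(rng.uniform(0.25, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            sg = scored_graph(list(g.edges), nodes=list(g))
            want = brute_force_proper_interval(sg)
            got = proper_interval_order(sg) is not None
            assert got == want, f"n={n} edges={sorted(sg.edges)}"
            assert is_linear(list(sg), sg)[0] == want

    def test_two_clone_contigs_trivially_linear(self):
        g = scored_graph([("a", "b")])
        assert is_linear(["a", "b"], g) == (True, [])


class TestQClones:
    def test_chimeric_bridge_between_two_regions_is_flagged(self):
        # two dense regions joined only through one clone with >=2 neighbours
        # on each side: two cliques sharing the vertex "x"
        left = [("l" + str(i), "l" + str(j)) for i, j in itertools.combinations(range(4), 2)]
        right = [("r" + str(i), "r" + str(j)) for i, j in itertools.combinations(range(4), 2)]
        bridge = [("x", "l0"), ("x", "l1"), ("x", "r0"), ("x", "r1")]
        g = scored_graph(left + right + bridge)
        assert "x" in q_clones(list(g), g)

    def test_clean_chain_has_no_q_clones(self):
        # chain with parallel support: consecutive and skip-one edges
        edges = [(i, i + 1) for i in range(9)] + [(i, i + 2) for i in range(8)]
        g = scored_graph(edges)
        assert q_clones(list(g), g) == []


class TestResolveQContigs:
    def params(self):
        return AssemblyParams(min_contig_clones=4)

    def chain(self, prefix, n, shared=30):
        edges = []
        for i in range(n - 1):
            edges.append((f"{prefix}{i}", f"{prefix}{i+1}", 1e-30, shared))
        for i in range(n - 2):
            edges.append((f"{prefix}{i}", f"{prefix}{i+2}", 1e-18, shared // 2))
        return edges

    def test_all_linear_input_unchanged(self):
        g = scored_graph(self.chain("a", 6) + self.chain("b", 5))
        contigs = [
            Contig("c1", [f"a{i}" for i in range(6)], list(np.arange(6) * 1.0)),
            Contig("c2", [f"b{i}" for i in range(5)], list(np.arange(5) * 1.0)),
        ]
        out = resolve_q_contigs(contigs, g, self.params())
        assert [c.contig_id for c in out] == ["c1", "c2"]
        assert [c.clones for c in out] == [contigs[0].clones, contigs[1].clones]

    def test_contaminated_fingerprint_splits_glued_contigs(self):
        # two genuine chains glued by one clone whose fingerprint carries a
        # second locus: the join is cut and the chimera stays with the side
        # it shares more bands with
        edges = self.chain("a", 6) + self.chain("b", 6)
        edges += [("a5", "X", 1e-25, 28), ("a4", "X", 1e-18, 15), ("b0", "X", 1e-20, 12)]
        g = scored_graph(edges)
        nodes = [f"a{i}" for i in range(6)] + ["X"] + [f"b{i}" for i in range(6)]
        contig = Contig("c1", nodes, list(np.arange(len(nodes)) * 1.0))
        out = resolve_q_contigs([contig], g, self.params())
        assert len(out) == 2
        sides = {frozenset(c.clones) for c in out}
        assert frozenset({f"b{i}" for i in range(6)}) in sides
        assert frozenset({f"a{i}" for i in range(6)} | {"X"}) in sides

    def test_small_parts_dropped_by_min_size(self):
        g = scored_graph(self.chain("a", 3))
        contig = Contig("c1", ["a0", "a1", "a2"], [0.0, 1.0, 2.0])
        out = resolve_q_contigs([contig], g, self.params())
        assert out == []


class TestAssemblyModes:
    def test_noise_free_stacks_agree_across_modes(self, clean_stacks):
        ltc = assemble_ltc_style(clean_stacks["fps"], clean_stacks["params"])
        fpc = assemble_fpc_style(clean_stacks["fps"], clean_stacks["params"])
        pl = sorted(tuple(sorted(c.clones)) for c in ltc.contigs)
        pf = sorted(tuple(sorted(c.clones)) for c in fpc.contigs)
        assert pl == pf
        assert len(pl) == clean_stacks["n_stacks"]
        assert all(len(p) == clean_stacks["stack_size"] for p in pl)

    def test_clone_conservation_in_both_modes(self, small_world):
        fps, params, graph = small_world["fps"], small_world["params"], small_world["graph"]
        universe = {fp.clone_id for fp in fps}
        for mode in (assemble_ltc_style, assemble_fpc_style):
            bb = mode(fps, params, graph=graph)
            assert bb.clone_universe() == universe
            placed = [c for contig in bb.contigs for c in contig.clones]
            assert len(placed) == len(set(placed))  # no clone twice

    def test_noisy_library_fpc_yields_more_smaller_contigs(self, small_world):
        fps, params, graph = small_world["fps"], small_world["params"], small_world["graph"]
        ltc = assemble_ltc_style(fps, params, graph=graph)
        fpc = assemble_fpc_style(fps, params, graph=graph)
        assert len(ltc.contigs) <= len(fpc.contigs)

    def test_offsets_nondecreasing_and_summary_consistent(self, small_world):
        fps, params, graph = small_world["fps"], small_world["params"], small_world["graph"]
        bb = assemble_ltc_style(fps, params, graph=graph)
        for c in bb.contigs:
            assert all(b >= a for a, b in zip(c.offsets, c.offsets[1:]))
        s = bb.summary(params.insert_size_estimate)
        assert s["cumulative_length"] == pytest.approx(
            sum(estimate_contig_length(c, params.insert_size_estimate) for c in bb.contigs)
        )
        assert s["n50_length"] > 0


class TestSelectMtp:
    def brute_minimum_cover(self, iv, min_overlap):
        """Smallest clone subset covering the span with consecutive overlaps
        of at least ``min_overlap`` (assumes a gap-free contig)."""
        clones = list(iv)
        span_end = max(e for _, e in iv.values())
        span_start = min(s for s, _ in iv.values())
        for r in range(1, len(clones) + 1):
            for sub in itertools.combinations(clones, r):
                ivs = sorted(iv[c] for c in sub)
                if ivs[0][0] > span_start:
                    continue
                covered = ivs[0][1]
                ok = True
                for _, nxt in zip(ivs, ivs[1:]):
                    if nxt[0] > covered - min_overlap:
                        ok = False
                        break
                    covered = max(covered, nxt[1])
                if ok and covered >= span_end:
                    return r
        return len(clones)

    def test_single_clone_contig_is_its_own_mtp(self):
        c = Contig("c", ["a"], [0.0])
        assert select_mtp(c) == ["a"]

    def test_greedy_matches_exhaustive_minimum_on_half_overlap_tiling(self):
        clones = [f"c{i}" for i in range(6)]
        offsets = [i * 55_000.0 for i in range(6)]
        contig = Contig("t", clones, offsets)
        got = select_mtp(contig, min_overlap=10_000.0)
        iv = {c: (o, o + 111_000.0) for c, o in zip(clones, offsets)}
        assert len(got) == self.brute_minimum_cover(iv, 10_000.0)

    def test_greedy_matches_exhaustive_on_random_contigs(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(2, 10))
            # gap-free tiling: steps small enough that overlaps stay feasible
            offs = np.concatenate(([0.0], np.cumsum(rng.uniform(5_000, 75_000, n - 1))))
            lengths = rng.uniform(90_000, 130_000, n)
            clones = [f"c{i}" for i in range(n)]
            contig = Contig("t", clones, offs.tolist(), clone_lengths=dict(zip(clones, lengths)))
            got = select_mtp(contig, min_overlap=10_000.0)
            iv = {c: (o, o + contig.clone_lengths[c]) for c, o in zip(clones, offs)}
            # the greedy pick must cover and be no larger than the brute minimum
            want = self.brute_minimum_cover(iv, 10_000.0)
            assert len(got) == want

    def test_mtp_covers_contig_span(self, small_world):
        fps, params, graph = small_world["fps"], small_world["params"], small_world["graph"]
        bb = assemble_ltc_style(fps, params, graph=graph)
        for contig in bb.contigs:
            picked = select_mtp(contig, params.min_mtp_overlap, params.insert_size_estimate)
            iv = {c: (o, o + params.insert_size_estimate) for c, o in zip(contig.clones, contig.offsets)}
            span = max(e for _, e in iv.values()) - min(s for s, _ in iv.values())
            covered = 0.0
            cur = None
            for s, e in sorted(iv[c] for c in picked):
                if cur is None or s > cur:
                    covered += e - s
                    cur = e
                elif e > cur:
                    covered += e - cur
                    cur = e
            assert covered >= 0.99 * span


class TestMergeBackbone:
    def test_empty_fpc_leftover_returns_ltc(self):
        ltc = Backbone([Contig("l1", ["a", "b"], [0.0, 1.0])], ["c"])
        fpc = Backbone([Contig("f1", ["a", "b"], [0.0, 1.0], source="fpc")], ["c"])
        merged = merge_backbone(ltc, fpc)
        assert [c.contig_id for c in merged.contigs] == ["l1"]
        assert merged.singletons == ["c"]

    def test_counts_contract_and_no_duplicates(self):
        ltc = Backbone([Contig("l1", ["a", "b"], [0.0, 1.0])], ["c", "d", "e"])
        fpc = Backbone(
            [Contig("f1", ["c", "d", "e"], [0.0, 50_000.0, 100_000.0], source="fpc")],
            ["a", "b"],
        )
        merged = merge_backbone(ltc, fpc)
        assert len(merged.contigs) == 2
        added = [c for c in merged.contigs if c.source == "fpc"]
        assert len(added) == 1 and added[0].contig_id.startswith("fpc")
        placed = [cl for c in merged.contigs for cl in c.clones]
        assert len(placed) == len(set(placed))
        assert merged.clone_universe() == {"a", "b", "c", "d", "e"}

    def test_clone_universe_mismatch_rejected(self):
        ltc = Backbone([Contig("l1", ["a"], [0.0])], [])
        fpc = Backbone([Contig("f1", ["b"], [0.0], source="fpc")], [])
        with pytest.raises(ValueError):
            merge_backbone(ltc, fpc)


class TestEstimateContigLength:
    def test_single_clone(self):
        c = Contig("c", ["a"], [0.0])
        assert estimate_contig_length(c, 111_000.0) == 111_000.0

    def test_two_offset_clones(self):
        c = Contig("c", ["a", "b"], [0.0, 50_000.0])
        assert estimate_contig_length(c, 111_000.0) == 161_000.0

    def test_synthetic_contigs_close_to_true_span(self, small_world):
        fps, params, graph = small_world["fps"], small_world["params"], small_world["graph"]
        library = small_world["library"]
        truth = build_truth(small_world["arm"], library)
        coords = dict(zip(truth.clone_order.clone_id, zip(truth.clone_order.start, truth.clone_order.end)))
        bb = assemble_ltc_style(fps, params, graph=graph)
        rel_errors = []
        for c in bb.contigs:
            if len(c) < 10:
                continue
            spans = [coords[cl] for cl in c.clones]
            true_span = max(e for _, e in spans) - min(s for s, _ in spans)
            est = estimate_contig_length(c, params.insert_size_estimate)
            rel_errors.append(abs(est - true_span) / true_span)
        assert rel_errors and np.median(rel_errors) < 0.10


def test_contig_tsv_round_trip(tmp_path, small_world):
    fps, params, graph = small_world["fps"], small_world["params"], small_world["graph"]
    bb = assemble_ltc_style(fps, params, graph=graph)
    path = tmp_path / "contigs.tsv"
    write_contigs_tsv(bb, path)
    back = read_contigs_tsv(path)
    assert {c.contig_id: c.clones for c in back.contigs} == {
        c.contig_id: c.clones for c in bb.contigs
    }
    assert back.singletons == sorted(bb.singletons)
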