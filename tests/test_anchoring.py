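"""Three-level anchoring: deconvolution, evidence, ordering, markers, bins."""

import numpy as np
import pandas as pd
import pytest

from physmap.anchoring import (
    Anchor,
    DeconvolutionParams,
    DeconvolutionResult,
    Evidence,
    MarkerRecord,
    OrderedMap,
    PoolLayout,
    anchor_illumina_by_bes,
    anchor_illumina_by_unigene,
    anchor_level2,
    consensus_map,
    deconvolve_pools,
    estimate_bin_boundaries,
    gene_density,
    genes_from_bes,
    genes_from_hybridisation,
    integrate_markers,
    map_ests_to_zipper,
    recombination_profile,
    utr_rescue,
)
from physmap.assembly import Backbone, Contig
from physmap.homology import HomologyHit
from physmap.zipper import ZipperGene


def layout_3d(n_plates=10, rows="ABCDEFGH", cols=range(1, 13), clones=()):
    pools = {}
    for p in range(1, n_plates + 1):
        pools[f"P{p:02d}"] = ("plate", p)
    for r in rows:
        pools[f"R_{r}"] = ("row", r)
    for c in cols:
        pools[f"C{c:02d}"] = ("column", c)
    return PoolLayout(pools=pools, addresses=dict(clones))


def signal_frame(layout, probes, hot=(), value=1000.0, background=0.0):
    cols = sorted(layout.pools)
    df = pd.DataFrame(background, index=probes, columns=cols, dtype=float)
    for probe, pool in hot:
        df.loc[probe, pool] += value
    return df


class TestDeconvolvePools:
    def clones(self):
        return {(2, "B", 3): "cl_x", (5, "E", 7): "cl_y", (2, "E", 7): "cl_z"}

    def test_flat_signals_give_no_positives(self):
        layout = layout_3d(clones=self.clones().items())
        sig = signal_frame(layout, ["p1"], background=100.0)
        res = deconvolve_pools(sig, layout, DeconvolutionParams(method="msd"))
        assert res.clones["p1"] == [] and not res.ambiguous

    def test_single_elevated_triple_yields_one_address(self):
        layout = layout_3d(clones=self.clones().items())
        sig = signal_frame(layout, ["p1"], hot=[("p1", "P02"), ("p1", "R_B"), ("p1", "C03")])
        for method in ("msd", "ttest"):
            res = deconvolve_pools(sig, layout, DeconvolutionParams(method=method))
            assert res.clones["p1"] == ["cl_x"], method
            assert "p1" not in res.ambiguous

    def test_two_plates_sharing_row_and_column_flagged_ambiguous(self):
        layout = layout_3d(clones=self.clones().items())
        hot = [("p1", "P02"), ("p1", "P05"), ("p1", "R_E"), ("p1", "C07")]
        sig = signal_frame(layout, ["p1"], hot=hot)
        res = deconvolve_pools(sig, layout, DeconvolutionParams(method="msd"))
        assert sorted(res.clones["p1"]) == ["cl_y", "cl_z"]
        assert "p1" in res.ambiguous

    def test_missing_dimension_rejected(self):
        pools = {"P01": ("plate", 1), "R_A": ("row", "A")}
        layout = PoolLayout(pools=pools, addresses={})
        sig = pd.DataFrame(0.0, index=["p"], columns=["P01", "R_A"])
        with pytest.raises(ValueError):
            deconvolve_pools(sig, layout)


def backbone_two_contigs():
    return Backbone(
        [
            Contig("ctgA", ["c1", "c2"], [0.0, 50_000.0]),
            Contig("ctgB", ["c3", "c4"], [0.0, 50_000.0]),
        ],
        ["c5"],
    )


class TestLevel1Evidence:
    def test_probes_of_one_gene_collapse_on_contig(self):
        bb = backbone_two_contigs()
        deconv = DeconvolutionResult(
            clones={"pr1": ["c1"], "pr2": ["c2"]}, candidates={}, ambiguous=set()
        )
        ev = genes_from_hybridisation(deconv, bb, {"pr1": "geneG", "pr2": "geneG"})
        assert set(ev) == {"ctgA"}
        assert {e.gene for e in ev["ctgA"]} == {"geneG"}
        assert len(ev["ctgA"]) == 2  # two evidence rows, one gene

    def test_unknown_address_logged_and_skipped(self):
        bb = backbone_two_contigs()
        deconv = DeconvolutionResult(clones={"pr1": ["c5"]}, candidates={}, ambiguous=set())
        log = []
        ev = genes_from_hybridisation(deconv, bb, {"pr1": "g"}, log=log)
        assert ev == {} and log == [("pr1", "c5")]

    def test_bes_evidence_attaches_through_clone(self):
        bb = backbone_two_contigs()
        hits = [HomologyHit("bes1", "geneZ", 120, 0.92, 80.0, 1e-20, 1, 120, 1, 120)]
        ev = genes_from_bes(hits, bb, {"bes1": "c3"})
        assert set(ev) == {"ctgB"}
        assert ev["ctgB"][0].channel == "bac_end" and ev["ctgB"][0].gene == "geneZ"


def hom(query, subject, length, identity, score=100.0):
    return HomologyHit(query, subject, length, identity, score, 1e-30, 1, length, 1, length)


class TestIlluminaAnchoring:
    def test_bes_thresholds_are_strict(self):
        bb = backbone_two_contigs()
        hits = [hom("s1", "bes1", 501, 0.985), hom("s2", "bes1", 499, 0.999)]
        placed = anchor_illumina_by_bes(hits, {"bes1": "c1"}, bb)
        assert set(placed) == {"s1"}
        assert placed["s1"].contig == "ctgA"

    def test_sequence_hitting_two_contigs_placed_once_by_best_score(self):
        bb = backbone_two_contigs()
        hits = [hom("s1", "besA", 800, 0.99, score=300.0), hom("s1", "besB", 800, 0.99, score=200.0)]
        placed = anchor_illumina_by_bes(hits, {"besA": "c1", "besB": "c3"}, bb)
        assert placed["s1"].contig == "ctgA"

    def test_unigene_thresholds(self):
        placed = anchor_illumina_by_unigene(
            [hom("s1", "u1", 201, 0.905), hom("s2", "u1", 199, 0.99)],
            {"u1": "ctgB"},
        )
        assert set(placed) == {"s1"} and placed["s1"].channel == "illumina_unigene"

    def test_no_hits_unplaced(self):
        assert anchor_illumina_by_bes([], {}, backbone_two_contigs()) == {}


class TestUtrRescue:
    def test_unigene_next_to_gene_on_shotgun_contig_rescued(self):
        uhits = [hom("uni1", "shc1", 300, 0.95)]
        ghits = [hom("geneA", "shc1", 400, 0.9)]
        out = utr_rescue(["uni1"], uhits, ghits, zipper_genes={"geneA"})
        assert len(out) == 1
        r = out[0]
        assert (r.unigene, r.gene, r.in_zipper) == ("uni1", "geneA", True)

    def test_unigene_alone_on_contig_not_rescued(self):
        uhits = [hom("uni1", "shc1", 300, 0.95)]
        ghits = [hom("geneA", "shc2", 400, 0.9)]
        assert utr_rescue(["uni1"], uhits, ghits) == []


class TestAnchorLevel2:
    def zipper(self):
        return [ZipperGene(i, f"zg{i}", ("ref",), False) for i in range(1, 100)]

    def test_minimum_zipper_position_wins(self):
        bb = backbone_two_contigs()
        ev = {
            "ctgA": [Evidence("zg56", "hybridisation", "p1", "c1"), Evidence("zg61", "hybridisation", "p2", "c2")]
        }
        omap = anchor_level2(bb, ev, self.zipper())
        assert omap.anchors[0].contig_id == "ctgA"
        assert omap.anchors[0].zipper_position == 56

    def test_adding_nonzipper_evidence_does_not_move_contig(self):
        bb = backbone_two_contigs()
        ev = {"ctgA": [Evidence("zg10", "hybridisation", "p1", "c1")]}
        base = anchor_level2(bb, ev, self.zipper())
        ev2 = {"ctgA": ev["ctgA"] + [Evidence("novelX", "bac_end", "b1", "c2")]}
        again = anchor_level2(bb, ev2, self.zipper())
        assert base.position_of()["ctgA"] == again.position_of()["ctgA"]
        assert again.anchors[0].nonsyntenic_genes == 1

    def test_cereba_only_contigs_form_terminal_centromere_segment(self):
        bb = backbone_two_contigs()
        ev = {"ctgB": [Evidence("zg5", "hybridisation", "p", "c3")]}
        omap = anchor_level2(bb, ev, self.zipper(), cereba_contigs={"ctgA"})
        assert [a.contig_id for a in omap.anchors] == ["ctgB", "ctgA"]
        assert omap.anchors[-1].centromeric and omap.anchors[-1].zipper_position is None

    def test_duplicated_zipper_genes_flagged(self):
        bb = backbone_two_contigs()
        ev = {
            "ctgA": [Evidence("zg7", "hybridisation", "p1", "c1")],
            "ctgB": [Evidence("zg7", "bac_end", "b1", "c3")],
        }
        omap = anchor_level2(bb, ev, self.zipper())
        assert omap.duplicated_zipper_genes == {"zg7"}


class TestConsensusMap:
    # published per-map positions and their consensus values
    PUBLISHED = [
        ("psp2999", {"TmGxG": 4.8, "TaBxT": 3, "TaAxF": 1, "TaSxO": 14, "Com2004": 12}, 7),
        ("barc148", {"TaNxW": 55, "TaSxO": 33.4, "ConSSR": 56.8}, 48),
        ("cfd58", {"TaAxF": 52.9}, 53),
        ("bcd1434", {"TmGxG": 5.1}, 5),
        ("cfa2153", {"TaAxF": 1, "TaNxW": 13.8, "TaSxO": 5.4, "Com2004": 15}, 9),
        ("wmc24", {"TaNxW": 45, "TaSxO": 35, "ConSSR": 48.8, "Com2004": 37}, 41),
        ("gpw2142", {"TaSxO": 43.1, "Com2004": 54}, 49),
        ("gpw2005", {"TaCxCS": 27.3, "Com2004": 31}, 29),
        ("fba393", {"TaCxCS": 12.5, "Com2004": 21}, 17),
        ("mwg2245b", {"ConSSR": 22}, 22),
    ]

    def test_reproduces_published_consensus_positions(self):
        markers = [MarkerRecord(n, p) for n, p, _ in self.PUBLISHED]
        out = consensus_map(markers)
        got = {m.name: m.consensus for m in out}
        for name, positions, want in self.PUBLISHED:
            mean = sum(positions.values()) / len(positions)
            assert got[name] == want, f"{name}: mean {mean}"

    def test_agrees_with_direct_mean_oracle_and_map_order_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            k = int(rng.integers(1, 8))
            pos = {f"m{j}": float(np.round(rng.uniform(0, 60), 1)) for j in range(k)}
            import math

            rec = consensus_map([MarkerRecord("x", pos)])[0]
            mean = math.fsum(pos.values()) / len(pos)
            want = int(np.floor(mean + 0.5))
            assert rec.consensus == want
            shuffled = dict(sorted(pos.items(), key=lambda kv: kv[1]))
            assert consensus_map([MarkerRecord("x", shuffled)])[0].consensus == want

    def test_marker_without_positions_passes_through(self):
        rec = consensus_map([MarkerRecord("m", {})])[0]
        assert rec.consensus is None


class TestIntegrateMarkers:
    def omap(self):
        anchors = [
            Anchor(f"ctg{i}", i * 10, [], 1, 0) for i in range(1, 7)
        ]
        return OrderedMap(anchors=anchors, unplaced=[])

    def test_agreeing_orders_have_no_conflicts(self):
        markers = [MarkerRecord(f"m{i}", {"M1": float(i * 5)}) for i in range(1, 7)]
        links = {f"m{i}": f"ctg{i}" for i in range(1, 7)}
        _, conflicts = integrate_markers(self.omap(), markers, links)
        assert conflicts == []

    def test_planted_discordant_marker_reported(self):
        markers = [MarkerRecord(f"m{i}", {"M1": float(i * 5)}) for i in range(1, 7)]
        markers[5] = MarkerRecord("m6", {"M1": 1.0})  # telomeric cM...
        links = {f"m{i}": f"ctg{i}" for i in range(1, 7)}  # ...centromeric contig
        _, conflicts = integrate_markers(self.omap(), markers, links)
        assert conflicts == ["m6"]


class TestBins:
    def test_ests_collapse_to_distinct_genes(self):
        zipper = [ZipperGene(i, f"zg{i}", ("ref",), False) for i in range(1, 20)]
        hits = []
        genes = [1, 1, 2, 5, 5, 5, 9, 12, 12, 17]  # 10 ESTs on 6 genes
        for k, g in enumerate(genes):
            hits.append(hom(f"est{k}", f"zg{g}", 150, 0.9))
        out = map_ests_to_zipper({"binA": hits}, zipper)
        assert out["binA"]["positions"] == [1, 2, 5, 9, 12, 17]
        assert out["binA"]["genes"]["zg5"] == 3

    def test_no_hits_empty(self):
        zipper = [ZipperGene(1, "zg1", ("ref",), False)]
        out = map_ests_to_zipper({"binA": []}, zipper)
        assert out["binA"]["positions"] == []

    def test_separated_bins_boundary_at_midpoint(self):
        bins = {"telo": list(range(1, 201, 4)), "central": list(range(201, 651, 4))}
        (b,) = estimate_bin_boundaries(bins)
        assert abs(b - 200) <= 1

    def test_single_outlier_discarded(self):
        telo = list(range(1, 200, 4)) + [400]  # one stray distal EST deep in the central bin
        central = list(range(201, 651, 4))
        (b,) = estimate_bin_boundaries({"telo": telo, "central": central})
        assert abs(b - 200) <= 2

    def test_empty_proximal_bin_bounded_by_neighbour(self):
        bins = {"central": list(range(200, 650, 5)), "centromeric": []}
        (b,) = estimate_bin_boundaries(bins)
        assert b == 645

    def test_fewer_than_two_bins_rejected(self):
        with pytest.raises(ValueError):
            estimate_bin_boundaries({"only": [1, 2, 3]})


class TestGeneDensity:
    def test_published_densities_from_truncation(self):
        got = gene_density([(39, 200), (107, 450), (129, 100), (275, 749)])
        assert got == [5.12, 4.20, 0.77, 2.72]

    def test_zero_genes_zero_density(self):
        assert gene_density([(10, 0)]) == [0.0]

    def test_zero_size_rejected(self):
        with pytest.raises(ValueError):
            gene_density([(0, 5)])


class TestRecombinationProfile:
    def omap_uniform(self, n=11):
        anchors = [Anchor(f"ctg{i}", i, [], 1, 0) for i in range(1, n)]
        return OrderedMap(anchors=anchors, unplaced=[])

    def test_uniform_map_puts_half_length_at_half_span(self):
        omap = self.omap_uniform()
        markers = [
            MarkerRecord(f"m{i}", {"M1": float(i * 5)}, consensus=i * 5, contig=f"ctg{i}")
            for i in range(1, 11)
        ]
        prof = recombination_profile(omap, markers)
        assert prof["distal_fraction_half_map"] == pytest.approx(0.5, abs=0.06)

    def test_distally_skewed_map_concentrates_early(self):
        # markers drawn from the generator's distal-decay intensity over a
        # uniform physical axis: half the map falls in the first ~14 %
        from physmap.synthdata import AssayParams, genetic_position

        ap = AssayParams()
        n = 25
        anchors = [Anchor(f"ctg{i}", i, [], 1, 0) for i in range(1, n + 1)]
        omap = OrderedMap(anchors=anchors, unplaced=[])
        markers = []
        for i in range(1, n + 1):
            x = i / n
            cm = genetic_position(x * 1e6, 1e6, ap)
            markers.append(MarkerRecord(f"m{i}", {"M1": cm}, consensus=int(round(cm)), contig=f"ctg{i}"))
        prof = recombination_profile(omap, markers)
        oracle = 0.137  # solve M(x) = 0.5 for the generating intensity
        assert prof["distal_fraction_half_map"] < 0.25
        assert prof["distal_fraction_half_map"] == pytest.approx(oracle, abs=0.06)

    def test_cumulative_curve_monotone(self):
        omap = self.omap_uniform()
        rng = np.random.default_rng(8)
        markers = [
            MarkerRecord(f"m{i}", {"M1": float(rng.uniform(0, 50))}, consensus=int(rng.uniform(0, 50)), contig=f"ctg{i}")
            for i in range(1, 11)
        ]
        prof = recombination_profile(omap, markers)
        ys = prof["cumulative_cm"]
        assert all(b >= a for a, b in zip(ys, ys[1:]))
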