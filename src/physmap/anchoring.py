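"""Three-level anchoring of BAC contigs.

Level 1 assigns genes to contigs: microarray probes hybridised to
three-dimensional (plate/row/column) pools of the minimum tiling path are
deconvolved to clone addresses; BAC-end sequences (BES) and anchored shotgun
contigs contribute further gene evidence.  Level 2 orders contigs along the
reference zipper (minimum zipper position among a contig's syntenic genes;
contigs carrying only centromere-specific retrotransposon evidence form a
terminal centromere segment with arbitrary internal order).  Level 3
integrates genetic markers: per-map centimorgan positions are averaged into
a consensus map, linked to contigs through sequence matches, and checked for
rank conflicts against the synteny order.  Deletion-bin EST evidence yields
bin boundaries on the zipper and per-bin gene densities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import Backbone
from .homology import best_hit

__all__ = [
    "PoolLayout",
    "DeconvolutionParams",
    "DeconvolutionResult",
    "Evidence",
    "Anchor",
    "OrderedMap",
    "MarkerRecord",
    "deconvolve_pools",
    "genes_from_hybridisation",
    "genes_from_bes",
    "anchor_illumina_by_bes",
    "anchor_illumina_by_unigene",
    "utr_rescue",
    "anchor_level2",
    "consensus_map",
    "integrate_markers",
    "map_ests_to_zipper",
    "estimate_bin_boundaries",
    "gene_density",
    "recombination_profile",
    "write_map_tsv",
    "write_marker_tsv",
]

_DIMS = ("plate", "row", "column")
_MAX_CARRIERS = 4  # most positives callable per dimension by the peeling detector


@dataclass
class PoolLayout:
    """Pool id -> (dimension, label) plus the clone address book.

    ``addresses`` maps (plate, row, column) labels to the pooled clone id.
    """

    pools: dict
    addresses: dict

    def __post_init__(self):
        for pool, (dim, _) in self.pools.items():
            if dim not in _DIMS:
                raise ValueError(f"pool {pool}: unknown dimension {dim}")

    def pools_of(self, dim: str) -> list:
        return sorted(p for p, (d, _) in self.pools.items() if d == dim)


@dataclass
class DeconvolutionParams:
    x_plate: float = 2.4
    x_row: float = 2.7
    x_column: float = 2.8
    p_value: float = 0.01
    method: str = "msd"  # "msd" | "ttest"

    def __post_init__(self):
        if min(self.x_plate, self.x_row, self.x_column) <= 0:
            raise ValueError("m+xSD multipliers must be positive")
        if not 0 < self.p_value < 1:
            raise ValueError("p-value threshold must lie in (0, 1)")
        if self.method not in ("msd", "ttest"):
            raise ValueError("method must be 'msd' or 'ttest'")

    def multiplier(self, dim: str) -> float:
        return {"plate": self.x_plate, "row": self.x_row, "column": self.x_column}[dim]


@dataclass
class DeconvolutionResult:
    clones: dict  # probe -> list of clone ids
    candidates: dict  # probe -> list of (plate, row, column) label triples
    ambiguous: set  # probes with >1 consistent address


def _passes(val: float, bg: np.ndarray, params: DeconvolutionParams, dim: str) -> bool:
    if val <= bg.mean():
        return False
    if params.method == "msd":
        return val > bg.mean() + params.multiplier(dim) * bg.std(ddof=0)
    # one-sample t of the candidate pool against the background pools,
    # prediction-interval form: positive when the candidate is an upper
    # outlier of the background population
    s = bg.std(ddof=1)
    if s == 0.0:
        return True
    t = (val - bg.mean()) / (s * math.sqrt(1.0 + 1.0 / len(bg)))
    return stats.t.sf(t, df=len(bg) - 1) < params.p_value


def _positive_pools(values: pd.Series, dim_pools, params: DeconvolutionParams, dim: str):
    """Positive pools of one dimension by top-k peeling.

    The candidate positives are the k highest pools; they are accepted at
    the smallest k for which *every* candidate stands out against the
    remaining pools (the background).  Peeling is what lets two carriers in
    a small dimension both be called — either one alone would be masked by
    the other inflating the background.
    """
    v = values[dim_pools].to_numpy(dtype=float)
    n = len(v)
    order = np.argsort(-v, kind="stable")
    # at least 3 background pools; at most _MAX_CARRIERS positives per
    # dimension (a single-copy gene sits on only a few MTP clones)
    k_max = min(n - 3, _MAX_CARRIERS)
    for k in range(k_max, 0, -1):
        bg = v[order[k:]]
        if all(_passes(v[order[j]], bg, params, dim) for j in range(k)):
            return sorted(dim_pools[i] for i in order[:k])
    return []


def deconvolve_pools(signals: pd.DataFrame, layout: PoolLayout, params: DeconvolutionParams | None = None) -> DeconvolutionResult:
    """Call clone addresses from 3D pool intensities.

    Per probe and dimension a pool is positive iff its intensity exceeds
    mean + x*SD over that dimension's pools (or, with ``method='ttest'``, a
    one-sample t-test of the remaining pools against the candidate value
    rejects at the threshold with the candidate above the rest).  A clone
    address is called iff its plate, row and column pools are all positive;
    probes with several consistent addresses are flagged ambiguous but kept.
    """
    params = params or DeconvolutionParams()
    dim_pools = {d: layout.pools_of(d) for d in _DIMS}
    for d in _DIMS:
        if not dim_pools[d]:
            raise ValueError(f"pool layout is missing the {d} dimension")
        missing = [p for p in dim_pools[d] if p not in signals.columns]
        if missing:
            raise ValueError(f"signal matrix lacks pools {missing}")
    label = {p: layout.pools[p][1] for p in layout.pools}
    clones, candidates, ambiguous = {}, {}, set()
    for probe, row in signals.iterrows():
        pos = {d: [label[p] for p in _positive_pools(row, dim_pools[d], params, d)] for d in _DIMS}
        combos = [
            (pl, rw, co)
            for pl, rw, co in itertools.product(pos["plate"], pos["row"], pos["column"])
            if (pl, rw, co) in layout.addresses
        ]
        candidates[probe] = combos
        clones[probe] = [layout.addresses[c] for c in combos]
        if len(combos) > 1:
            ambiguous.add(probe)
    return DeconvolutionResult(clones=clones, candidates=candidates, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# Level 1: gene evidence on contigs


@dataclass(frozen=True)
class Evidence:
    gene: str
    channel: str  # hybridisation | bac_end | illumina_bes | illumina_unigene | pcr
    ref: str  # probe / BES / sequence the evidence came from
    clone: str | None = None


def _attach(contig_of: dict, clone: str):
    return contig_of.get(clone)


def genes_from_hybridisation(deconv: DeconvolutionResult, backbone: Backbone, probe_gene_map: dict, log: list | None = None) -> dict:
    """Attach deconvolved probe evidence to contigs; probes covering the same
    gene collapse to one gene (evidence rows are retained per probe)."""
    contig_of = backbone.contig_of()
    out: dict = {}
    for probe, clones in deconv.clones.items():
        gene = probe_gene_map.get(probe)
        if gene is None:
            continue
        for clone in clones:
            contig = _attach(contig_of, clone)
            if contig is None:
                if log is not None:
                    log.append((probe, clone))
                continue
            out.setdefault(contig, []).append(
                Evidence(gene=gene, channel="hybridisation", ref=probe, clone=clone)
            )
    return out


def genes_from_bes(bes_hits, backbone: Backbone, bes_clone_map: dict, log: list | None = None) -> dict:
    """Attach gene evidence through a BES's clone's contig (channel bac_end).

    ``bes_hits`` is a filtered hit table with BES ids as queries and gene ids
    as subjects; the best hit per BES names the gene."""
    contig_of = backbone.contig_of()
    out: dict = {}
    for bes in sorted({h.query for h in bes_hits}):
        hit = best_hit(bes_hits, bes)
        clone = bes_clone_map.get(bes)
        if clone is None:
            if log is not None:
                log.append((bes, None))
            continue
        contig = _attach(contig_of, clone)
        if contig is None:
            if log is not None:
                log.append((bes, clone))
            continue
        out.setdefault(contig, []).append(
            Evidence(gene=hit.subject, channel="bac_end", ref=bes, clone=clone)
        )
    return out


def collapse_genes(evidence_map: dict) -> dict:
    """contig -> {gene: [evidence rows]} with probes of one gene collapsed."""
    return {
        contig: {
            gene: [e for e in evs if e.gene == gene]
            for gene in sorted({e.gene for e in evs})
        }
        for contig, evs in evidence_map.items()
    }


@dataclass(frozen=True)
class Placement:
    sequence: str
    contig: str
    channel: str
    via: str  # BES or unigene used
    clone: str | None
    score: float


def _place_once(hits, min_len, min_identity, resolve):
    """Best qualifying hit per query; strict > thresholds; one placement each."""
    placements = {}
    for q in sorted({h.query for h in hits}):
        qualifying = [
            h for h in hits if h.query == q and h.length > min_len and h.identity > min_identity
        ]
        if not qualifying:
            continue
        top = sorted(qualifying, key=lambda h: (-h.score, -h.identity, h.subject))[0]
        placed = resolve(top)
        if placed is not None:
            placements[q] = placed
    return placements


def anchor_illumina_by_bes(hits, bes_clone_map: dict, backbone: Backbone, min_len: int = 500, min_identity: float = 0.98) -> dict:
    """Place shotgun sequences on contigs through BES matches (>500 bp and
    >98 % identity by default, strict).  Each sequence is placed at most once,
    by its best qualifying hit."""
    contig_of = backbone.contig_of()

    def resolve(h):
        clone = bes_clone_map.get(h.subject)
        contig = contig_of.get(clone) if clone else None
        if contig is None:
            return None
        return Placement(h.query, contig, "illumina_bes", h.subject, clone, h.score)

    return _place_once(hits, min_len, min_identity, resolve)


def anchor_illumina_by_unigene(hits, unigene_contig_map: dict, min_len: int = 200, min_identity: float = 0.90) -> dict:
    """As :func:`anchor_illumina_by_bes` with the looser unigene thresholds
    (>200 bp, >90 %); the unigene's own contig assignment places the sequence."""

    def resolve(h):
        contig = unigene_contig_map.get(h.subject)
        if contig is None:
            return None
        return Placement(h.query, contig, "illumina_unigene", h.subject, None, h.score)

    return _place_once(hits, min_len, min_identity, resolve)


@dataclass(frozen=True)
class Rescue:
    unigene: str
    gene: str
    shotgun_contig: str
    in_zipper: bool


def utr_rescue(unplaced_unigenes, unigene_hits, gene_hits, zipper_genes=None) -> list:
    """Associate a unigene without direct gene homology with the gene whose
    qualifying hit lies on the same shotgun contig (the unigene presumably
    covers untranslated parts of that gene's transcript).  The nearest gene
    hit on the contig wins; ties break lexicographically."""
    zipper_genes = set(zipper_genes or ())
    by_contig: dict = {}
    for h in gene_hits:
        by_contig.setdefault(h.subject, []).append(h)
    out = []
    for u in sorted(set(unplaced_unigenes)):
        uhits = [h for h in unigene_hits if h.query == u]
        best = None
        for uh in uhits:
            for gh in by_contig.get(uh.subject, ()):  # same shotgun contig
                gap = max(
                    0,
                    max(min(gh.sstart, gh.send), min(uh.sstart, uh.send))
                    - min(max(gh.sstart, gh.send), max(uh.sstart, uh.send)),
                )
                key = (gap, gh.query)
                if best is None or key < best[0]:
                    best = (key, gh.query, uh.subject)
        if best is not None:
            gene = best[1]
            out.append(Rescue(u, gene, best[2], gene in zipper_genes))
    return out


# ---------------------------------------------------------------------------
# Level 2: synteny ordering


@dataclass
class Anchor:
    contig_id: str
    zipper_position: int | None
    evidence: list
    syntenic_genes: int
    nonsyntenic_genes: int
    centromeric: bool = False


@dataclass
class OrderedMap:
    anchors: list  # ordered telomere -> centromere, centromere segment last
    unplaced: list
    duplicated_zipper_genes: set = field(default_factory=set)

    def rank_of(self) -> dict:
        return {a.contig_id: i for i, a in enumerate(self.anchors)}

    def position_of(self) -> dict:
        return {a.contig_id: a.zipper_position for a in self.anchors}


def anchor_level2(backbone: Backbone, evidence_map: dict, zipper, cereba_contigs=()) -> OrderedMap:
    """Order contigs along the zipper.

    A contig with zipper-gene evidence anchors at the *minimum* zipper
    position among its genes.  Contigs without zipper evidence but with
    centromere-specific retrotransposon BES form a terminal centromere
    segment ordered by contig id (the internal order is arbitrary).  Adding
    non-zipper evidence never changes a contig's position.
    """
    zindex = {z.gene_id: z.zipper_index for z in zipper} if not isinstance(zipper, dict) else dict(zipper)
    cereba = set(cereba_contigs)
    anchored, centromeric = [], []
    gene_claims: dict = {}
    for contig in backbone.contigs:
        evs = evidence_map.get(contig.contig_id, [])
        genes = sorted({e.gene for e in evs})
        syn = [g for g in genes if g in zindex]
        nonsyn = [g for g in genes if g not in zindex]
        if syn:
            pos = min(zindex[g] for g in syn)
            anchored.append(
                Anchor(contig.contig_id, pos, evs, len(syn), len(nonsyn), False)
            )
            for g in syn:
                gene_claims.setdefault(g, []).append(contig.contig_id)
        elif contig.contig_id in cereba:
            centromeric.append(
                Anchor(contig.contig_id, None, evs, 0, len(nonsyn), True)
            )
    anchored.sort(key=lambda a: (a.zipper_position, a.contig_id))
    centromeric.sort(key=lambda a: a.contig_id)
    placed = {a.contig_id for a in anchored} | {a.contig_id for a in centromeric}
    unplaced = sorted(c.contig_id for c in backbone.contigs if c.contig_id not in placed)
    dup = {g for g, cs in gene_claims.items() if len(cs) > 1}
    return OrderedMap(anchors=anchored + centromeric, unplaced=unplaced, duplicated_zipper_genes=dup)


# ---------------------------------------------------------------------------
# Level 3: genetic markers and deletion bins


@dataclass
class MarkerRecord:
    name: str
    positions: dict  # map name -> cM
    consensus: int | None = None
    contig: str | None = None


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def consensus_map(markers) -> list:
    """Consensus position = arithmetic mean of the available per-map cM
    positions, rounded to the nearest integer (half away from zero);
    markers without positions pass through unpositioned."""
    out = []
    for m in markers:
        vals = [v for v in m.positions.values() if v is not None]
        # exact summation keeps the mean independent of map order at
        # half-integer boundaries
        cons = _round_half_away(math.fsum(vals) / len(vals)) if vals else None
        out.append(MarkerRecord(m.name, dict(m.positions), cons, m.contig))
    return out


def integrate_markers(ordered_map: OrderedMap, markers, marker_contig_links: dict, rank_window: int = 2):
    """Attach markers to contigs and report synteny/genetics order conflicts.

    ``marker_contig_links`` maps marker name -> contig id (obtained from
    perfect primer matches or >97 %-identity probe matches against BES or
    anchored shotgun sequences).  A conflict is a marker whose rank by
    consensus cM disagrees with its contig's rank in the zipper order by
    more than ``rank_window``.
    """
    markers = consensus_map(markers)
    rank = ordered_map.rank_of()
    linked = []
    for m in markers:
        contig = marker_contig_links.get(m.name)
        linked.append(MarkerRecord(m.name, m.positions, m.consensus, contig))
    usable = [
        m for m in linked if m.consensus is not None and m.contig in rank
    ]
    by_cm = sorted(usable, key=lambda m: (m.consensus, m.name))
    by_zip = sorted(usable, key=lambda m: (rank[m.contig], m.name))
    cm_rank = {m.name: i for i, m in enumerate(by_cm)}
    zip_rank = {m.name: i for i, m in enumerate(by_zip)}
    conflicts = [
        m.name
        for m in usable
        if abs(cm_rank[m.name] - zip_rank[m.name]) > rank_window
    ]
    return linked, conflicts


def map_ests_to_zipper(bin_est_hits: dict, zipper) -> dict:
    """Per deletion bin, the zipper positions hit by the bin's ESTs.

    ``bin_est_hits`` maps bin name -> filtered hit list (EST query vs zipper
    gene subject).  Multiple ESTs hitting one gene collapse to one gene with
    the EST multiplicity recorded.  Returns
    ``bin -> {"positions": sorted unique-gene positions, "genes": {gene: n_ests}}``.
    """
    zindex = {z.gene_id: z.zipper_index for z in zipper} if not isinstance(zipper, dict) else dict(zipper)
    out = {}
    for bin_name, hits in bin_est_hits.items():
        genes: dict = {}
        for est in sorted({h.query for h in hits}):
            hit = best_hit(hits, est)
            if hit is None or hit.subject not in zindex:
                continue
            genes[hit.subject] = genes.get(hit.subject, 0) + 1
        positions = sorted(zindex[g] for g in genes)
        out[bin_name] = {"positions": positions, "genes": genes}
    return out


def estimate_bin_boundaries(bin_positions: dict, k_outlier: int = 5) -> list:
    """Boundary zipper indices between adjacent bins (given distal first).

    Positions lying on the wrong side of at least ``k_outlier`` opposing
    points are discarded as outliers; the boundary is the midpoint between
    the distal bin's maximum and the proximal bin's minimum.  A bin with no
    hits is bounded by the last hit-bearing position of its neighbour.
    """
    names = list(bin_positions)
    if len(names) < 2:
        raise ValueError("need at least two bins")
    series = [sorted(bin_positions[n]) for n in names]
    bounds = []
    for a, b in zip(range(len(names) - 1), range(1, len(names))):
        da, pb = series[a], series[b]
        if da and pb:
            da_kept = [p for p in da if sum(1 for q in pb if q < p) < k_outlier]
            pb_kept = [p for p in pb if sum(1 for q in da if q > p) < k_outlier]
            da_kept = da_kept or da
            pb_kept = pb_kept or pb
            bounds.append((max(da_kept) + min(pb_kept)) / 2.0)
        elif da:
            bounds.append(float(max(da)))
        elif pb:
            bounds.append(float(min(pb)))
        else:
            bounds.append(float("nan"))
    return bounds


def gene_density(bins) -> list:
    """Genes per Mbp, truncated to two decimals, per (size_mbp, count) pair."""
    out = []
    for size, count in bins:
        if size <= 0:
            raise ValueError("bin size must be positive")
        out.append(math.floor(count / size * 100.0 + 1e-9) / 100.0)
    return out


def recombination_profile(ordered_map: OrderedMap, markers) -> dict:
    """Cumulative genetic length against physical fraction along the arm.

    The physical coordinate of a marker is its contig's zipper position,
    normalised by the largest zipper position on the map (a gene-index proxy
    for physical position).  Returns the piecewise-linear curve and the
    physical fraction containing the distal 50 % of the map length.
    """
    pos = ordered_map.position_of()
    pts = []
    for m in markers:
        if m.consensus is None or m.contig not in pos or pos[m.contig] is None:
            continue
        pts.append((pos[m.contig], float(m.consensus)))
    if len(pts) < 2:
        raise ValueError("need at least two positioned markers")
    zmax = max(p for p, _ in pts)
    pts = sorted((p / zmax, cm) for p, cm in pts)
    xs = [0.0]
    ys = [0.0]
    run = 0.0
    for x, cm in pts:
        run = max(run, cm)  # cumulative map length is non-decreasing
        xs.append(x)
        ys.append(run)
    total = ys[-1]
    half = 0.5 * total
    frac = float(np.interp(half, ys, xs))
    return {
        "physical_fraction": np.asarray(xs),
        "cumulative_cm": np.asarray(ys),
        "total_cm": total,
        "distal_fraction_half_map": frac,
    }


# ---------------------------------------------------------------------------
# Tabular IO


def write_map_tsv(ordered_map: OrderedMap, markers, path) -> None:
    marker_by_contig: dict = {}
    for m in markers:
        if m.contig:
            marker_by_contig.setdefault(m.contig, []).append(m.name)
    rows = [
        {
            "rank": i + 1,
            "contig_id": a.contig_id,
            "zipper_position": "CEN" if a.centromeric else a.zipper_position,
            "syntenic_genes": a.syntenic_genes,
            "nonsyntenic_genes": a.nonsyntenic_genes,
            "markers": ",".join(sorted(marker_by_contig.get(a.contig_id, []))),
        }
        for i, a in enumerate(ordered_map.anchors)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_marker_tsv(markers, path) -> None:
    map_names = sorted({k for m in markers for k in m.positions})
    rows = []
    for m in markers:
        row = {"marker": m.name}
        for k in map_names:
            row[k] = m.positions.get(k, "")
        row["consensus"] = m.consensus if m.consensus is not None else ""
        row["contig"] = m.contig or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
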