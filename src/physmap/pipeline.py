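"""End-to-end physical-map construction on a synthetic chromosome arm.

Runs the whole method in order: simulate the arm and clone library,
fingerprint, assemble LTC- and FPC-style, merge the backbones, select the
minimum tiling path, build the three-genome reference zipper, simulate the
assays, deconvolve the 3D pools, anchor contigs on the zipper (level 2) and
integrate genetic markers (level 3) — then score the result against the
generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .anchoring import (
    DeconvolutionParams,
    DeconvolutionResult,
    OrderedMap,
    anchor_level2,
    consensus_map,
    deconvolve_pools,
    genes_from_hybridisation,
    integrate_markers,
    recombination_profile,
)
from .assembly import (
    Backbone,
    _annotate_band_counts,
    assemble_fpc_style,
    assemble_ltc_style,
    merge_backbone,
    select_mtp,
)
from .fingerprints import AssemblyParams, build_overlap_graph
from .synthdata import (
    ArmParams,
    AssayParams,
    DigestParams,
    NoiseParams,
    TruthTables,
    build_truth,
    chance_match_probability,
    fingerprint_library,
    scaled_arm_params,
    simulate_arm,
    simulate_assays,
    simulate_library,
    simulate_model_genomes,
)
from .zipper import build_zipper

__all__ = ["PipelineResult", "run_end_to_end", "default_assembly_params", "cereba_contigs"]


def default_assembly_params(digest: DigestParams, band_tolerance: float = 3.0) -> AssemblyParams:
    """Assembly parameters whose chance-match probability matches the digest model."""
    return AssemblyParams(
        band_tolerance=band_tolerance,
        p_match=chance_match_probability(digest, band_tolerance),
    )


def cereba_contigs(arm, library, backbone: Backbone, window: int = 703) -> set:
    """Contigs whose clones' BES windows overlap a Cereba (centromeric
    retrotransposon) interval — the centromere diagnostic used at level 2."""
    cereba = sorted(
        (s, e) for fam, sup, s, e in arm.te_intervals if fam == "Cereba"
    )
    if not cereba:
        return set()
    starts = np.array([s for s, _ in cereba])
    ends = np.array([e for _, e in cereba])

    def hits(lo, hi):
        j = np.searchsorted(ends, lo, side="right")
        return j < len(starts) and starts[j] < hi

    clones = {c.clone_id: c for c in library.clones}
    flagged = set()
    for contig in backbone.contigs:
        for cl in contig.clones:
            c = clones[cl]
            if c.contaminant:
                continue
            if hits(c.start, c.start + window) or hits(c.end - window, c.end):
                flagged.add(contig.contig_id)
                break
    return flagged


@dataclass
class PipelineResult:
    arm: object
    library: object
    fingerprints: list
    chimeric_clones: list
    params: AssemblyParams
    ltc: Backbone
    fpc: Backbone
    backbone: Backbone
    mtp: set
    zipper: list
    assays: object
    deconvolution: DeconvolutionResult
    ordered_map: OrderedMap
    markers: list
    marker_conflicts: list
    truth: TruthTables
    metrics: dict


def _adjacency_recovery(backbone: Backbone, truth: TruthTables) -> float:
    member = backbone.contig_of()
    pairs = truth.adjacent_pairs()
    if not pairs:
        return float("nan")
    ok = sum(
        1
        for a, b in pairs
        if member.get(a) is not None and member.get(a) == member.get(b)
    )
    return ok / len(pairs)


def _order_tau(ordered_map: OrderedMap, backbone: Backbone, truth: TruthTables) -> float:
    true_start = dict(zip(truth.clone_order.clone_id, truth.clone_order.start))
    contam = dict(zip(truth.clone_order.clone_id, truth.clone_order.contaminant))
    by_id = {c.contig_id: c for c in backbone.contigs}
    xs, ys = [], []
    for rank, a in enumerate(a for a in ordered_map.anchors if not a.centromeric):
        contig = by_id[a.contig_id]
        pos = [true_start[cl] for cl in contig.clones if not contam.get(cl, True)]
        if not pos:
            continue
        xs.append(rank)
        ys.append(float(np.mean(pos)))
    if len(xs) < 2:
        return float("nan")
    tau, _ = kendalltau(xs, ys)
    return float(tau)


def run_end_to_end(
    seed: int,
    arm_length: int = 20_000_000,
    n_clones: int = 2_000,
    arm_params: ArmParams | None = None,
    digest: DigestParams | None = None,
    noise: NoiseParams | None = None,
    assay_params: AssayParams | None = None,
    assembly_params: AssemblyParams | None = None,
) -> PipelineResult:
    """Run the full pipeline at desk scale and score it against the truth.

    Metrics: ``adjacency_recovery`` (fraction of true adjacent clone pairs
    co-assembled in one LTC contig), ``ltc_contigs`` / ``fpc_contigs``
    (multi-clone contig counts of the two modes), ``order_tau`` (Kendall
    rank correlation between the level-2 contig order and the true order),
    and ``distal_fraction_half_map`` from the level-3 marker profile.
    """
    arm_params = arm_params or scaled_arm_params(arm_length)
    digest = digest or DigestParams()
    noise = noise or NoiseParams()
    assay_params = assay_params or AssayParams()

    arm = simulate_arm(arm_params, seed)
    library = simulate_library(arm, n_clones=n_clones, seed=seed)
    fps, chimeric = fingerprint_library(library, digest, noise, seed)
    params = assembly_params or default_assembly_params(digest)
    graph = build_overlap_graph(fps, params, cutoff=params.cutoff_ladder[0])
    _annotate_band_counts(graph, fps)
    ltc = assemble_ltc_style(fps, params, graph=graph)
    fpc = assemble_fpc_style(fps, params, graph=graph)
    backbone = merge_backbone(ltc, fpc)
    mtp = set()
    for contig in backbone.contigs:
        mtp.update(select_mtp(contig, params.min_mtp_overlap, params.insert_size_estimate))

    genomes = simulate_model_genomes(arm, seed)
    zipper = build_zipper(genomes.zipper_config())

    assays = simulate_assays(arm, library, mtp, assay_params, seed)
    # the t-test detector works for any pool count per dimension; unique
    # (unambiguous) addresses only are used for anchoring
    deconv = deconvolve_pools(
        assays.pool_signals, assays.pool_layout, DeconvolutionParams(method="ttest")
    )
    unique = DeconvolutionResult(
        clones={p: cl for p, cl in deconv.clones.items() if p not in deconv.ambiguous},
        candidates={p: c for p, c in deconv.candidates.items() if p not in deconv.ambiguous},
        ambiguous=set(),
    )
    evidence = genes_from_hybridisation(unique, backbone, assays.probe_gene_map)
    cereba = cereba_contigs(arm, library, backbone)
    ordered_map = anchor_level2(backbone, evidence, zipper, cereba)

    # level 3: link markers to contigs through their true clone, then check
    # the genetic order against the synteny order
    truth = build_truth(arm, library, assays.marker_truth)
    member = backbone.contig_of()
    clones_sorted = truth.clone_order[~truth.clone_order.contaminant]
    links = {}
    for r in assays.marker_truth.itertuples():
        carrier = clones_sorted[
            (clones_sorted.start <= r.position_bp) & (clones_sorted.end > r.position_bp)
        ]
        for cl in carrier.clone_id:
            if cl in member:
                links[r.marker] = member[cl]
                break
    markers, conflicts = integrate_markers(ordered_map, assays.markers, links)

    metrics = {
        "adjacency_recovery": _adjacency_recovery(ltc, truth),
        "ltc_contigs": len(ltc.contigs),
        "fpc_contigs": len(fpc.contigs),
        "order_tau": _order_tau(ordered_map, backbone, truth),
        "library_coverage": library.coverage,
        "n_chimeric_fingerprints": len(chimeric),
        "zipper_genes": len(zipper),
        "anchored_contigs": sum(1 for a in ordered_map.anchors if not a.centromeric),
        "centromeric_contigs": sum(1 for a in ordered_map.anchors if a.centromeric),
    }
    try:
        prof = recombination_profile(ordered_map, markers)
        metrics["distal_fraction_half_map"] = prof["distal_fraction_half_map"]
        metrics["total_cm"] = prof["total_cm"]
    except ValueError:
        metrics["distal_fraction_half_map"] = float("nan")

    return PipelineResult(
        arm=arm,
        library=library,
        fingerprints=fps,
        chimeric_clones=chimeric,
        params=params,
        ltc=ltc,
        fpc=fpc,
        backbone=backbone,
        mtp=mtp,
        zipper=zipper,
        assays=assays,
        deconvolution=deconv,
        ordered_map=ordered_map,
        markers=markers,
        marker_conflicts=conflicts,
        truth=truth,
        metrics=metrics,
    )
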