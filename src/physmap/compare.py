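"""Correspondence analysis between two assemblies of the same clone set.

For each contig of a target assembly, find the source-assembly contigs that
share clones with it.  A target contig spanning two or more source contigs is
a *merge event*: the target assembly fused source contigs, and the size of
the coordinate overlap at each junction (projected onto the target contig)
measures how much the fused contigs actually overlapped.  Junctions bridged
with the help of source-assembly singletons are tracked separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import Backbone, Contig

__all__ = [
    "Correspondence",
    "MergeJunction",
    "correspond_contigs",
    "merged_overlap_stats",
    "write_correspondence_tsv",
]


@dataclass
class MergeJunction:
    source_pair: tuple
    overlap: float
    singletons_used: int


@dataclass
class Correspondence:
    target_contig: str
    shared: list  # (source contig id, shared clone count)
    merge_junctions: list = field(default_factory=list)

    @property
    def is_merge(self) -> bool:
        return len(self.merge_junctions) > 0


def _projected_ranges(target: Contig, members: dict, default_len: float):
    """Source contig id -> (start, end) projected onto the target contig."""
    ranges = {}
    offs = dict(zip(target.clones, target.offsets))
    for cl in target.clones:
        src = members.get(cl)
        if src is None:
            continue
        s = offs[cl]
        e = s + target.clone_length(cl, default_len)
        if src in ranges:
            lo, hi = ranges[src]
            ranges[src] = (min(lo, s), max(hi, e))
        else:
            ranges[src] = (s, e)
    return ranges


def correspond_contigs(
    a: Backbone, b: Backbone, default_clone_length: float = 111_000.0
) -> list:
    """For each contig of ``a``, all contigs of ``b`` sharing clones with it.

    ``a``-contigs spanning two or more multi-clone ``b``-contigs are recorded
    as merge events with one junction per consecutive pair of ``b``-contigs
    along the ``a``-contig; junction overlap is measured in projected
    ``a``-contig coordinates.
    """
    if a.clone_universe() != b.clone_universe():
        raise ValueError("assemblies cover different clone universes")
    b_member = b.contig_of()
    b_single = set(b.singletons)
    out = []
    for tc in a.contigs:
        counts = {}
        for cl in tc.clones:
            src = b_member.get(cl)
            if src is not None:
                counts[src] = counts.get(src, 0) + 1
        shared = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        junctions = []
        if len(counts) >= 2:
            ranges = _projected_ranges(tc, b_member, default_clone_length)
            ordered = sorted(ranges, key=lambda s: (ranges[s][0], s))
            offs = dict(zip(tc.clones, tc.offsets))
            pos = {cl: i for i, cl in enumerate(tc.clones)}
            for left, right in zip(ordered, ordered[1:]):
                overlap = max(0.0, ranges[left][1] - ranges[right][0])
                left_last = max(
                    (pos[cl] for cl in tc.clones if b_member.get(cl) == left)
                )
                right_first = min(
                    (pos[cl] for cl in tc.clones if b_member.get(cl) == right)
                )
                lo, hi = sorted((left_last, right_first))
                gap_clones = [tc.clones[k] for k in range(lo + 1, hi)]
                n_single = sum(1 for cl in gap_clones if cl in b_single)
                junctions.append(MergeJunction((left, right), overlap, n_single))
        out.append(Correspondence(tc.contig_id, shared, junctions))
    return out


def merged_overlap_stats(correspondences, bin_width: float = 10_000.0) -> dict:
    """Histogram + means of junction overlaps, split by singleton involvement.

    Returns a dict with keys ``all``, ``with_singletons``, ``without_singletons``,
    each holding ``overlaps``, ``mean`` (nan when empty), and ``histogram``
    as (bin_edges, counts).  No merge events -> empty histograms, no error.
    """
    overlaps, with_s, without_s = [], [], []
    for corr in correspondences:
        for j in corr.merge_junctions:
            overlaps.append(j.overlap)
            (with_s if j.singletons_used > 0 else without_s).append(j.overlap)

    def _series(vals):
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            return {"overlaps": vals, "mean": float("nan"), "histogram": (np.array([0.0]), np.array([], dtype=int))}
        top = max(vals.max(), bin_width)
        edges = np.arange(0.0, top + bin_width, bin_width)
        counts, edges = np.histogram(vals, bins=edges)
        return {"overlaps": vals, "mean": float(vals.mean()), "histogram": (edges, counts)}

    return {
        "all": _series(overlaps),
        "with_singletons": _series(with_s),
        "without_singletons": _series(without_s),
        "n_merge_contigs": sum(1 for c in correspondences if c.is_merge),
        "n_source_contigs_fused": sum(
            len({s for s, _ in c.shared}) for c in correspondences if c.is_merge
        ),
    }


def write_correspondence_tsv(correspondences, path) -> None:
    rows = []
    for c in correspondences:
        for src, n in c.shared:
            rows.append(
                {
                    "target_contig": c.target_contig,
                    "source_contig": src,
                    "shared_clones": n,
                    "is_merge": c.is_merge,
                }
            )
    pd.DataFrame(
        rows, columns=["target_contig", "source_contig", "shared_clones", "is_merge"]
    ).to_csv(path, sep="\t", index=False)
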