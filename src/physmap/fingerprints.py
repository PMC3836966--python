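"""Band matching and Sulston overlap scoring between clone fingerprints.

A HICF fingerprint is the multiset of restriction-fragment sizes observed for
one BAC clone.  Two clones that overlap on the chromosome share the fragments
from the overlapping stretch, so the number of shared bands measures overlap.
The Sulston score converts a shared-band count into the probability that the
agreement arose by chance; clone pairs scoring below a stringency cutoff
(e.g. 1e-15) become edges of the clone overlap graph from which contigs are
assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import binom

__all__ = [
    "Fingerprint",
    "OverlapEdge",
    "AssemblyParams",
    "match_bands",
    "sulston_score",
    "build_overlap_graph",
    "read_fingerprints_tsv",
    "write_fingerprints_tsv",
    "write_edge_list_tsv",
]


@dataclass(frozen=True)
class Fingerprint:
    """One clone's fingerprint: sorted band sizes plus its well address."""

    clone_id: str
    bands: tuple
    plate: int = 0
    row: str = "A"
    column: int = 1

    def __post_init__(self):
        bands = tuple(sorted(float(b) for b in self.bands))
        if any(b <= 0 for b in bands):
            raise ValueError(f"{self.clone_id}: band sizes must be positive")
        object.__setattr__(self, "bands", bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)


@dataclass(frozen=True)
class OverlapEdge:
    clone_a: str
    clone_b: str
    shared_bands: int
    score: float

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must be a probability in [0, 1]")


@dataclass
class AssemblyParams:
    """Knobs shared by both assembly modes.

    ``cutoff_ladder`` is ordered loose -> stringent (LTC rebuilds Q-contigs at
    successively stricter cutoffs); ``fpc_ladder`` is ordered stringent ->
    loose (FPC builds at the strictest cutoff and then merges step-wise).
    ``p_match`` is the chance probability that two unrelated bands coincide
    within ``band_tolerance``; it depends on the band-size scale and should be
    derived from the digest model when one is available.
    """

    band_tolerance: float = 3.0
    p_match: float = 0.03
    cutoff_ladder: Sequence[float] = (1e-15, 1e-20, 1e-25, 1e-30, 1e-35, 1e-40, 1e-45, 1e-50)
    fpc_ladder: Sequence[float] = (1e-75, 1e-70, 1e-65, 1e-60, 1e-55, 1e-50, 1e-45)
    min_contig_clones: int = 6
    q_fraction: float = 0.10
    q_violation_min: int = 8
    min_mtp_overlap: float = 10_000.0
    insert_size_estimate: float = 111_000.0
    band_retention: float = 0.95  # chance a shared band survives sizing noise
    end_window: int = 2

    def __post_init__(self):
        if not 0 < self.p_match < 1:
            raise ValueError("p_match must lie strictly between 0 and 1")
        lad = tuple(float(c) for c in self.cutoff_ladder)
        if any(b >= a for a, b in zip(lad, lad[1:])):
            raise ValueError("cutoff_ladder must be strictly decreasing (ever more stringent)")
        self.cutoff_ladder = lad
        self.fpc_ladder = tuple(float(c) for c in self.fpc_ladder)


def match_bands(a: Fingerprint, b: Fingerprint, tolerance: float) -> int:
    """Count the maximum one-to-one matching of bands within ``tolerance``.

    Greedy two-pointer sweep over the sorted band lists; each band is used at
    most once.  For this interval-compatibility structure the greedy sweep is
    a maximum matching (verified against exhaustive matching in the tests).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    xs, ys = a.bands, b.bands
    i = j = shared = 0
    while i < len(xs) and j < len(ys):
        d = xs[i] - ys[j]
        if abs(d) <= tolerance:
            shared += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return shared


def sulston_score(n_a: int, n_b: int, shared: int, p_match: float) -> float:
    """Probability that >= ``shared`` of the smaller print's bands match by chance.

    Binomial tail over the ``min(n_a, n_b)`` bands of the smaller fingerprint,
    each matching some band of the larger one with probability
    ``1 - (1 - p_match)**max(n_a, n_b)``.  Monotonically non-increasing in
    ``shared``; ``shared == 0`` gives 1.0.
    """
    if min(n_a, n_b) < 0 or shared < 0:
        raise ValueError("band counts and shared count must be non-negative")
    if shared > min(n_a, n_b):
        raise ValueError("shared bands cannot exceed the smaller band count")
    if not 0 < p_match < 1:
        raise ValueError("p_match must lie strictly between 0 and 1")
    if shared == 0:
        return 1.0
    n = min(n_a, n_b)
    p = 1.0 - (1.0 - p_match) ** max(n_a, n_b)
    return float(binom.sf(shared - 1, n, p))


def _min_shared_for_cutoff(n_min: int, n_max: int, p_match: float, cutoff: float) -> int:
    """Smallest shared-band count that could reach ``cutoff`` over any pair
    of prints with band counts in [n_min, n_max].

    The score is minimised (for fixed shared count) by the smallest equal
    pair, so the bound is the threshold at n_min; it is conservative for
    every other pair and safe for candidate prescreening.
    """
    best = n_max + 1
    for n in range(max(1, n_min), n_max + 1):
        p = 1.0 - (1.0 - p_match) ** n
        for s in range(1, n + 1):
            if binom.sf(s - 1, n, p) <= cutoff:
                best = min(best, s)
                break
    return best


def _candidate_pairs(fps: Sequence[Fingerprint], tolerance: float, min_shared: int):
    """Indices of fingerprint pairs whose shared-band count could reach ``min_shared``.

    Bands are hashed into bins of width ``tolerance + 1``; a sparse
    clone-by-bin product gives an upper bound on shared bands (each band also
    votes into the two neighbouring bins so no within-tolerance match is
    missed).  Only pairs whose bound reaches ``min_shared`` are returned.
    """
    n = len(fps)
    width = max(tolerance, 1.0) + 1.0
    rows_q, cols_q, rows_s, cols_s = [], [], [], []
    for idx, fp in enumerate(fps):
        bins = {int(b // width) for b in fp.bands}
        for bn in bins:
            rows_s.append(idx)
            cols_s.append(bn)
            for nb in (bn - 1, bn, bn + 1):
                rows_q.append(idx)
                cols_q.append(nb)
    ncols = max(cols_q, default=0) + 2
    S = sparse.csr_matrix(
        (np.ones(len(rows_s), dtype=np.int32), (rows_s, np.asarray(cols_s) + 1)),
        shape=(n, ncols),
    )
    Q = sparse.csr_matrix(
        (np.ones(len(rows_q), dtype=np.int32), (rows_q, np.asarray(cols_q) + 1)),
        shape=(n, ncols),
    )
    upper = sparse.triu(Q @ S.T, k=1).tocoo()
    keep = upper.data >= min_shared
    return zip(upper.row[keep].tolist(), upper.col[keep].tolist())


def build_overlap_graph(
    fps: Sequence[Fingerprint],
    params: AssemblyParams,
    cutoff: float | None = None,
) -> nx.Graph:
    """Build the undirected clone overlap graph at a Sulston-score cutoff.

    Every clone is a node (so singletons survive clustering); an edge is
    present iff ``sulston_score <= cutoff``.  Edges carry ``shared`` and
    ``score`` attributes.  ``cutoff`` defaults to the loosest cutoff of the
    LTC ladder.
    """
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    if cutoff is None:
        cutoff = max(params.cutoff_ladder)
    by_id = {}
    for fp in fps:
        if fp.clone_id in by_id:
            raise ValueError(f"duplicate clone id {fp.clone_id}")
        by_id[fp.clone_id] = fp
    g = nx.Graph()
    g.add_nodes_from(by_id)
    n_max = max(fp.n_bands for fp in fps)
    n_min = min(fp.n_bands for fp in fps)
    if n_max == 0:
        return g
    min_shared = _min_shared_for_cutoff(n_min, n_max, params.p_match, cutoff)
    fps = list(fps)
    for i, j in _candidate_pairs(fps, params.band_tolerance, min_shared):
        a, b = fps[i], fps[j]
        shared = match_bands(a, b, params.band_tolerance)
        if shared == 0:
            continue
        score = sulston_score(a.n_bands, b.n_bands, shared, params.p_match)
        if score <= cutoff:
            g.add_edge(a.clone_id, b.clone_id, shared=shared, score=score)
    return g


# ---------------------------------------------------------------------------
# Tabular IO


def write_fingerprints_tsv(fps: Iterable[Fingerprint], path) -> None:
    rows = [
        {
            "clone_id": fp.clone_id,
            "plate": fp.plate,
            "row": fp.row,
            "column": fp.column,
            "bands": ",".join(format(b, "g") for b in fp.bands),
        }
        for fp in fps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fingerprints_tsv(path) -> list[Fingerprint]:
    df = pd.read_csv(path, sep="\t", dtype={"bands": str})
    return [
        Fingerprint(
            clone_id=str(r.clone_id),
            bands=tuple(float(x) for x in str(r.bands).split(",")) if r.bands else (),
            plate=int(r.plate),
            row=str(r.row),
            column=int(r.column),
        )
        for r in df.itertuples()
    ]


def write_edge_list_tsv(graph: nx.Graph, path) -> None:
    rows = [
        {"clone_a": a, "clone_b": b, "shared": d["shared"], "score": d["score"]}
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["clone_a", "clone_b", "shared", "score"]).to_csv(
        path, sep="\t", index=False
    )
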