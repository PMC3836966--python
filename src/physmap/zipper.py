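"""Reference genome zipper: a virtual gene order for an unsequenced arm.

Genes of a reference model genome (here called ``ref``; *Brachypodium* in
the original wheat work) are TE-filtered, required to have DNA-level
homologs in two further model genomes (``g2``, ``g3``; rice and sorghum),
restricted to the syntenic interval, augmented by "zipping in" genes whose
homologs sit inside the syntenic region of both other genomes, corrected for
lineage-specific inversions, and finally numbered consecutively from the
telomere (index 1) to the centromere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .homology import HomologyHit, best_hit

__all__ = [
    "GenomeGeneTable",
    "ZipperGene",
    "ZipperConfig",
    "filter_te_genes",
    "intersect_three_genomes",
    "extract_interval",
    "zip_in",
    "correct_inversion",
    "build_zipper",
    "write_zipper_tsv",
    "read_zipper_tsv",
]


@dataclass
class GenomeGeneTable:
    """Ordered gene positions for one genome: gene_id, chrom, position."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        required = {"gene_id", "chrom", "position"}
        if not required.issubset(df.columns):
            raise ValueError(f"gene table needs columns {sorted(required)}")
        df = df.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)
        for _, grp in df.groupby("chrom", sort=False):
            pos = grp.position.to_numpy()
            if len(pos) > 1 and (pos[1:] <= pos[:-1]).any():
                raise ValueError("positions must be strictly increasing within a chromosome")
        if df.gene_id.duplicated().any():
            raise ValueError("duplicate gene ids")
        self.table = df
        self._chrom = dict(zip(df.gene_id, df.chrom))
        self._pos = dict(zip(df.gene_id, df.position))

    def chrom(self, gene: str):
        return self._chrom[gene]

    def position(self, gene: str) -> float:
        return self._pos[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._pos

    def genes_on(self, chrom) -> list:
        sub = self.table[self.table.chrom == chrom]
        return list(sub.gene_id)

    @property
    def gene_ids(self) -> list:
        return list(self.table.gene_id)


@dataclass
class ZipperGene:
    zipper_index: int  # 1-based consecutive; 1 = telomeric end
    gene_id: str
    origin: tuple  # genomes placing the gene in the syntenic interval
    zipped_in: bool = False


def filter_te_genes(genes, repeat_hits) -> list:
    """Drop genes with any qualifying repeat-library hit (TEs annotated as genes)."""
    te_like = {h.query for h in repeat_hits}
    return [g for g in genes if g not in te_like]


def intersect_three_genomes(ref_genes, hits_vs_g2, hits_vs_g3) -> list:
    """Keep reference genes with at least one qualifying hit in *each* of the
    two other genomes (pre-filtered hit tables)."""
    in2 = {h.query for h in hits_vs_g2}
    in3 = {h.query for h in hits_vs_g3}
    return [g for g in ref_genes if g in in2 and g in in3]


def extract_interval(ref_table: GenomeGeneTable, flank_start: str, flank_end: str, retained=None) -> list:
    """All retained genes between two flanking genes inclusive, in
    chromosomal order.  Flank order is normalised; flanks on different
    chromosomes are an input error."""
    for g in (flank_start, flank_end):
        if g not in ref_table:
            raise ValueError(f"flank gene {g} not in reference table")
    ca, cb = ref_table.chrom(flank_start), ref_table.chrom(flank_end)
    if ca != cb:
        raise ValueError("flank genes lie on different chromosomes")
    lo = min(ref_table.position(flank_start), ref_table.position(flank_end))
    hi = max(ref_table.position(flank_start), ref_table.position(flank_end))
    keep = set(retained) if retained is not None else None
    out = []
    for g in ref_table.genes_on(ca):
        p = ref_table.position(g)
        if lo <= p <= hi and (keep is None or g in keep or g in (flank_start, flank_end)):
            out.append(g)
    return out


def _flank_slot(interval_index: dict, homolog_pos: dict, pos: float):
    """Insertion slot implied by one genome: indices of the interval genes
    whose homologs flank ``pos``; open ends use -1 / len(interval)."""
    left, right = -1, len(interval_index)
    left_pos, right_pos = float("-inf"), float("inf")
    for g, p in homolog_pos.items():
        i = interval_index[g]
        if p <= pos and p > left_pos:
            left, left_pos = i, p
        if p >= pos and p < right_pos:
            right, right_pos = i, p
    return (left, right) if left <= right else (right, left)


def zip_in(
    interval,
    candidates,
    g2_table: GenomeGeneTable,
    g3_table: GenomeGeneTable,
    g2_region,
    g3_region,
    hits_vs_g2,
    hits_vs_g3,
    log: list | None = None,
):
    """Insert displaced reference genes whose homologs lie inside the
    syntenic region of *both* other genomes.

    ``g2_region``/``g3_region`` are ``(chrom, start, end)``.  Each candidate
    is inserted between the two interval genes whose homologs flank it in the
    other genomes (midpoint of the implied slots, ties toward the lower
    index); candidates whose two genomes disagree on the flanks are excluded
    and logged.  Pre-existing interval genes are never reordered.  Returns
    ``(augmented gene list, set of zipped-in gene ids)``.
    """

    def region_pos(table, region, gene):
        chrom, lo, hi = region
        if gene in table and table.chrom(gene) == chrom and lo <= table.position(gene) <= hi:
            return table.position(gene)
        return None

    h2 = {}
    for h in hits_vs_g2:
        cur = h2.get(h.query)
        if cur is None or (h.score, h.identity, cur.subject) > (cur.score, cur.identity, h.subject):
            h2[h.query] = h
    h3 = {}
    for h in hits_vs_g3:
        cur = h3.get(h.query)
        if cur is None or (h.score, h.identity, cur.subject) > (cur.score, cur.identity, h.subject):
            h3[h.query] = h

    interval = list(interval)
    idx = {g: i for i, g in enumerate(interval)}
    pos2 = {}
    pos3 = {}
    for g in interval:
        if g in h2:
            p = region_pos(g2_table, g2_region, h2[g].subject)
            if p is not None:
                pos2[g] = p
        if g in h3:
            p = region_pos(g3_table, g3_region, h3[g].subject)
            if p is not None:
                pos3[g] = p

    insertions = []  # (slot key, tiebreak pos, gene)
    zipped = set()
    for c in candidates:
        if c in idx:
            continue
        p2 = region_pos(g2_table, g2_region, h2[c].subject) if c in h2 else None
        p3 = region_pos(g3_table, g3_region, h3[c].subject) if c in h3 else None
        if p2 is None or p3 is None:
            continue
        s2 = _flank_slot(idx, pos2, p2)
        s3 = _flank_slot(idx, pos3, p3)
        lo = max(s2[0], s3[0])
        hi = min(s2[1], s3[1])
        if lo > hi:
            if log is not None:
                log.append((c, s2, s3))
            continue
        key = (lo + hi) / 2.0
        insertions.append((key, p2, c))
        zipped.add(c)

    out = list(interval)
    # insert from the right so earlier slots stay valid; an integer slot key
    # (a tie) inserts before that interval gene, i.e. toward the lower index
    for key, p2, c in sorted(insertions, key=lambda t: (-t[0], -t[1], t[2])):
        at = max(0, min(math.ceil(key), len(out)))
        out.insert(at, c)
    return out, zipped


def correct_inversion(zipper, from_index: int, to_index: int) -> list:
    """Reverse the gene order in [from_index, to_index] (1-based, inclusive)
    and renumber consecutively; applying the same inversion twice restores
    the original order."""
    n = len(zipper)
    if not (1 <= from_index < to_index <= n):
        if from_index == to_index and 1 <= from_index <= n:
            return [ZipperGene(i + 1, z.gene_id, z.origin, z.zipped_in) for i, z in enumerate(zipper)]
        raise ValueError("inversion range out of bounds")
    genes = list(zipper)
    genes[from_index - 1 : to_index] = reversed(genes[from_index - 1 : to_index])
    return [ZipperGene(i + 1, z.gene_id, z.origin, z.zipped_in) for i, z in enumerate(genes)]


@dataclass
class ZipperConfig:
    ref_table: GenomeGeneTable
    g2_table: GenomeGeneTable
    g3_table: GenomeGeneTable
    te_hits: list
    hits_vs_g2: list
    hits_vs_g3: list
    flank_start: str
    flank_end: str
    g2_region: tuple
    g3_region: tuple
    inversions: list = field(default_factory=list)  # (from_index, to_index), applied in order
    exclusion_log: list = field(default_factory=list)


def build_zipper(config: ZipperConfig) -> list:
    """filter TE genes -> intersect three genomes -> extract interval ->
    zip in displaced genes -> correct inversions -> number from the telomere."""
    kept = filter_te_genes(config.ref_table.gene_ids, config.te_hits)
    kept = intersect_three_genomes(kept, config.hits_vs_g2, config.hits_vs_g3)
    interval = extract_interval(config.ref_table, config.flank_start, config.flank_end, retained=kept)
    augmented, zipped = zip_in(
        interval,
        kept,
        config.g2_table,
        config.g3_table,
        config.g2_region,
        config.g3_region,
        config.hits_vs_g2,
        config.hits_vs_g3,
        log=config.exclusion_log,
    )
    in2 = {h.query for h in config.hits_vs_g2}
    in3 = {h.query for h in config.hits_vs_g3}
    zipper = []
    for i, g in enumerate(augmented, start=1):
        origin = tuple(
            name
            for name, ok in (("ref", g not in zipped), ("g2", g in in2), ("g3", g in in3))
            if ok
        )
        zipper.append(ZipperGene(i, g, origin, g in zipped))
    for frm, to in config.inversions:
        zipper = correct_inversion(zipper, frm, to)
    return zipper


def write_zipper_tsv(zipper, path) -> None:
    pd.DataFrame(
        [
            {
                "zipper_index": z.zipper_index,
                "gene_id": z.gene_id,
                "origin": ",".join(z.origin),
                "zipped_in": int(z.zipped_in),
            }
            for z in zipper
        ]
    ).to_csv(path, sep="\t", index=False)


def read_zipper_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        ZipperGene(
            int(r.zipper_index),
            str(r.gene_id),
            tuple(str(r.origin).split(",")) if pd.notna(r.origin) and r.origin else (),
            bool(r.zipped_in),
        )
        for r in df.itertuples()
    ]
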