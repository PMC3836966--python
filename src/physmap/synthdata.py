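"""Synthetic chromosome arm, BAC library and assay data with ground truth.

The generator emulates the statistical structure the physical-mapping
analysis assumes for a Triticeae chromosome arm: a ~275 Mb arm with a
distal-to-proximal gene-density gradient, ~82 % TE content including a
centromere-specific Cereba-type retrotransposon family, an ~11.8x clone
library with ~6 % contaminating clones (off-target chromosome content) and
well-to-well fingerprint contamination, HICF fingerprints from a simulated
restriction digest, 3D pools of a minimum tiling path with hybridisation
noise, paired ~703 bp BAC-end sequences, shotgun contigs, deletion-bin EST
assignments, and genetic maps with distally concentrated recombination.
All coordinates are 0-based half-open; a single global seed feeds per-stage
derived substreams, so identical seeds and parameters give identical output.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fingerprints import Fingerprint
from .homology import HomologyHit
from .zipper import GenomeGeneTable, ZipperConfig

__all__ = [
    "ArmParams",
    "ArmModel",
    "LibraryModel",
    "CloneModel",
    "DigestParams",
    "NoiseParams",
    "AssayParams",
    "AssayData",
    "TruthTables",
    "ModelGenomeSet",
    "simulate_arm",
    "scaled_arm_params",
    "simulate_library",
    "DigestSiteIndex",
    "ArmSequence",
    "true_bands",
    "fingerprint_clone",
    "fingerprint_library",
    "simulate_assays",
    "simulate_model_genomes",
    "build_truth",
    "detectable_overlap_fraction",
    "chance_match_probability",
]

# per-stage substream ids (single global seed, derived substreams)
_STAGE_ARM, _STAGE_DECOY, _STAGE_LIB, _STAGE_FP, _STAGE_ASSAY, _STAGE_GENOME = range(6)


def _rng(seed: int, stage: int, extra: tuple = ()) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stage, *extra)))


# ---------------------------------------------------------------------------
# Chromosome arm


# TE family catalogue: (family, superfamily, weight outside the centromere).
# Weights follow the Triticeae BES surveys: Gypsy dominates, Fatima is the
# single most abundant family, Cereba is centromere-specific.
_TE_CATALOG = (
    ("Fatima", "Gypsy", 0.16),
    ("Wilma", "Gypsy", 0.13),
    ("Sabrina", "Gypsy", 0.12),
    ("WHAM", "Gypsy", 0.11),
    ("Erika", "Gypsy", 0.08),
    ("Cereba", "Gypsy", 0.0),
    ("Angela", "Copia", 0.08),
    ("Barbara", "Copia", 0.06),
    ("Maximus", "Copia", 0.09),
    ("Caspar", "CACTA", 0.05),
    ("Jorge", "CACTA", 0.04),
    ("Karin", "LINE", 0.03),
    ("Paula", "LINE", 0.02),
    ("Harbinger1", "Harbinger", 0.02),
    ("Hades", "Mariner", 0.01),
)
_CEREBA_CENTROMERE_WEIGHT = 0.6  # Cereba share of TE bases inside the centromere zone


@dataclass
class ArmParams:
    """Defaults describe the full-scale arm; :func:`scaled_arm_params` shrinks
    them proportionally for desk-scale runs."""

    arm_length: int = 275_000_000
    genes_per_bin: tuple = (450, 1_020, 225)  # telomeric 14% / central / proximal 47%
    syntenic_fraction: float = 0.44
    deletion_breakpoints: tuple = (0.14, 0.53)  # fractions of arm length from the telomere
    centromere_fraction: float = 0.05  # proximal zone carrying Cereba
    te_fraction: float = 0.817
    gene_length_mean: float = 2_000.0
    gene_length_sigma: float = 0.5  # lognormal shape
    te_length_mean: float = 8_000.0
    te_length_sigma: float = 0.6

    def __post_init__(self):
        if self.arm_length <= 0 or any(n < 0 for n in self.genes_per_bin):
            raise ValueError("arm length must be positive and gene counts non-negative")
        a, b = self.deletion_breakpoints
        if not (0 < a < b < 1):
            raise ValueError("deletion breakpoints must be strictly increasing in (0, 1)")
        if not 0 <= self.te_fraction < 1:
            raise ValueError("te_fraction must lie in [0, 1)")


def scaled_arm_params(arm_length: int, base: ArmParams | None = None) -> ArmParams:
    base = base or ArmParams()
    f = arm_length / base.arm_length
    return replace(
        base,
        arm_length=int(arm_length),
        genes_per_bin=tuple(max(1, round(n * f)) for n in base.genes_per_bin),
    )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    start: int
    end: int
    syntenic: bool
    zipper_index: int | None


@dataclass
class ArmModel:
    arm_length: int
    genes: list
    te_intervals: list  # (family, superfamily, start, end)
    centromere_zone: tuple
    deletion_breakpoints: tuple
    seed: int

    def __post_init__(self):
        for g in self.genes:
            if not (0 <= g.start < g.end <= self.arm_length):
                raise ValueError(f"gene {g.gene_id} outside the arm")
        for fam, sup, s, e in self.te_intervals:
            if not (0 <= s < e <= self.arm_length):
                raise ValueError(f"TE {fam} interval outside the arm")
        a, b = self.deletion_breakpoints
        if not (0 < a < b < 1):
            raise ValueError("deletion breakpoints must be strictly increasing in (0, 1)")
        if self.centromere_zone[1] != self.arm_length:
            raise ValueError("centromere zone must be the proximal end of the arm")

    def bin_of(self, position: float) -> int:
        """Deletion bin index: 0 = telomeric, 1 = central, 2 = centromeric."""
        a, b = self.deletion_breakpoints
        x = position / self.arm_length
        return 0 if x < a else (1 if x < b else 2)

    @property
    def syntenic_genes(self) -> list:
        return sorted((g for g in self.genes if g.syntenic), key=lambda g: g.start)


def _place_genes(rng, lo: int, hi: int, n: int, params: ArmParams):
    if n == 0:
        return []
    lengths = np.exp(rng.normal(math.log(params.gene_length_mean), params.gene_length_sigma, n))
    lengths = np.clip(lengths, 500, 8_000).astype(int)
    free = (hi - lo) - int(lengths.sum())
    if free <= 0:
        raise ValueError(f"cannot place {n} non-overlapping genes in {hi - lo} bp")
    gaps = np.sort(rng.uniform(0, free, n))
    starts = (lo + gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))).astype(int)
    return list(zip(starts.tolist(), (starts + lengths).tolist()))


def _tile_tes(rng, arm_length: int, gene_iv, params: ArmParams, centromere_zone):
    if params.te_fraction <= 0:
        return []
    spacer_mean = params.te_length_mean * (1.0 - params.te_fraction) / params.te_fraction
    fams, sups, base_w = zip(*((f, s, w) for f, s, w in _TE_CATALOG))
    base_w = np.asarray(base_w) / sum(base_w)
    cen_w = np.array(
        [
            _CEREBA_CENTROMERE_WEIGHT if f == "Cereba" else w * (1 - _CEREBA_CENTROMERE_WEIGHT)
            for f, w in zip(fams, base_w)
        ]
    )
    cen_w /= cen_w.sum()
    gaps = []
    cursor = 0
    for gs, ge in sorted(gene_iv):
        if gs > cursor:
            gaps.append((cursor, gs))
        cursor = max(cursor, ge)
    if cursor < arm_length:
        gaps.append((cursor, arm_length))
    out = []
    for lo, hi in gaps:
        pos = lo + rng.exponential(spacer_mean / 2.0)
        while pos < hi:
            ln = float(np.clip(np.exp(rng.normal(math.log(params.te_length_mean), params.te_length_sigma)), 500, 25_000))
            s, e = int(pos), int(min(pos + ln, hi))
            if e - s >= 200:
                w = cen_w if s >= centromere_zone[0] else base_w
                k = rng.choice(len(fams), p=w)
                out.append((fams[k], sups[k], s, e))
            pos = e + rng.exponential(spacer_mean)
    return out


def simulate_arm(params: ArmParams | None = None, seed: int = 0) -> ArmModel:
    """Simulate a chromosome arm with a distal gene-density gradient.

    Genes are placed non-overlapping within the three deletion-bin regions
    (telomeric, central, centromeric); syntenic genes are numbered 1..N from
    the telomere.  TEs tile the intergenic space to the target fraction,
    with the Cereba family confined to the proximal centromere zone.
    Deterministic given the seed.
    """
    params = params or ArmParams()
    rng = _rng(seed, _STAGE_ARM)
    L = params.arm_length
    a, b = params.deletion_breakpoints
    regions = [(0, int(a * L)), (int(a * L), int(b * L)), (int(b * L), L)]
    intervals = []
    for (lo, hi), n in zip(regions, params.genes_per_bin):
        intervals.extend(_place_genes(rng, lo, hi, n, params))
    intervals.sort()
    n_genes = len(intervals)
    n_syn = round(params.syntenic_fraction * n_genes)
    syn_idx = set(rng.choice(n_genes, size=n_syn, replace=False).tolist())
    genes = []
    z = 0
    for i, (s, e) in enumerate(intervals):
        if i in syn_idx:
            z += 1
            genes.append(GeneModel(f"sg{z:04d}", s, e, True, z))
        else:
            genes.append(GeneModel(f"ng{i:05d}", s, e, False, None))
    cen = (int((1 - params.centromere_fraction) * L), L)
    tes = _tile_tes(rng, L, intervals, params, cen)
    return ArmModel(
        arm_length=L,
        genes=genes,
        te_intervals=tes,
        centromere_zone=cen,
        deletion_breakpoints=params.deletion_breakpoints,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# BAC library


_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well plate: 16 rows x 24 columns


@dataclass(frozen=True)
class CloneModel:
    clone_id: str
    plate: int
    row: str
    column: int
    start: int
    end: int
    contaminant: bool


@dataclass
class LibraryModel:
    clones: list
    mean_insert: float
    purity: float
    arm: ArmModel
    decoy_arm: ArmModel | None = None

    @property
    def coverage(self) -> float:
        """Library coverage of the arm: n * mean_insert * purity / arm_length."""
        return len(self.clones) * self.mean_insert * self.purity / self.arm.arm_length

    def by_plate(self) -> dict:
        out: dict = {}
        for c in self.clones:
            out.setdefault(c.plate, []).append(c)
        return out


def simulate_library(
    arm: ArmModel,
    n_clones: int = 31_104,
    mean_insert: float = 111_000.0,
    purity: float = 0.94,
    seed: int = 0,
) -> LibraryModel:
    """Uniform clone starts; truncated-normal insert sizes (sd 0.15*mean,
    truncated to 0.5-1.5x mean); contaminants drawn with probability
    1 - purity take their interval from a second, unrelated synthetic arm."""
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if mean_insert >= arm.arm_length:
        raise ValueError("mean insert size must be smaller than the arm")
    rng = _rng(seed, _STAGE_LIB)
    decoy = None
    contam = rng.random(n_clones) >= purity
    if contam.any():
        decoy = simulate_arm(
            scaled_arm_params(arm.arm_length), seed=int(_rng(seed, _STAGE_DECOY).integers(0, 2**31 - 1))
        )
    sizes = rng.normal(mean_insert, 0.15 * mean_insert, n_clones)
    lo, hi = 0.5 * mean_insert, 1.5 * mean_insert
    while True:  # redraw out-of-range sizes (truncation)
        bad = (sizes < lo) | (sizes > hi)
        if not bad.any():
            break
        sizes[bad] = rng.normal(mean_insert, 0.15 * mean_insert, int(bad.sum()))
    sizes = sizes.astype(int)
    starts = rng.integers(0, arm.arm_length - sizes)
    clones = []
    for i in range(n_clones):
        plate = i // 384 + 1
        well = i % 384
        row, col = _ROWS[well // 24], well % 24 + 1
        cid = f"cl{plate:03d}{row}{col:02d}"
        clones.append(
            CloneModel(cid, plate, row, col, int(starts[i]), int(starts[i] + sizes[i]), bool(contam[i]))
        )
    return LibraryModel(clones=clones, mean_insert=mean_insert, purity=purity, arm=arm, decoy_arm=decoy)


# ---------------------------------------------------------------------------
# HICF fingerprints from a simulated digest


@dataclass
class DigestParams:
    mean_spacing: float = 2_500.0  # geometric recognition-site spacing
    band_range: tuple = (500.0, 10_000.0)  # observable fragment sizes
    block: int = 1_000_000

    def __post_init__(self):
        if self.mean_spacing <= 1:
            raise ValueError("mean site spacing must exceed 1 bp")


@dataclass
class NoiseParams:
    band_sigma: float = 1e-4  # multiplicative sizing error
    well_contamination_rate: float = 0.03
    contamination_min_fraction: float = 0.3
    contamination_max_fraction: float = 0.8


class DigestSiteIndex:
    """Deterministic restriction-site positions for an arm.

    Sites follow a geometric spacing (renewal process), generated lazily in
    fixed blocks so overlapping clones see identical sites regardless of
    query order.
    """

    def __init__(self, arm_seed: int, params: DigestParams, salt: int = 0xD16E):
        self.seed = int(arm_seed)
        self.params = params
        self.salt = salt
        self._cache: dict = {}

    def _block_sites(self, b: int) -> np.ndarray:
        if b not in self._cache:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=[self.seed, self.salt], spawn_key=(b,))
            )
            block = self.params.block
            n = int(block / self.params.mean_spacing * 1.3) + 20
            steps = rng.geometric(1.0 / self.params.mean_spacing, n)
            while steps.sum() < block:
                steps = np.concatenate([steps, rng.geometric(1.0 / self.params.mean_spacing, n)])
            pos = b * block + np.cumsum(steps)
            self._cache[b] = pos[pos < (b + 1) * block]
        return self._cache[b]

    def sites_in(self, start: int, end: int) -> np.ndarray:
        blocks = range(start // self.params.block, end // self.params.block + 1)
        sites = np.concatenate([self._block_sites(b) for b in blocks])
        return sites[(sites >= start) & (sites <= end)]


def true_bands(clone: CloneModel, sites: DigestSiteIndex, digest: DigestParams) -> np.ndarray:
    """Noise-free fragment sizes of the clone's interval, filtered to the
    observable band range."""
    s = sites.sites_in(clone.start, clone.end)
    frags = np.diff(s)
    lo, hi = digest.band_range
    return np.sort(frags[(frags >= lo) & (frags <= hi)]).astype(float)


def chance_match_probability(digest: DigestParams, tolerance: float) -> float:
    """Probability that two unrelated observable fragments agree within
    ``tolerance`` — the p_match the Sulston score should use for prints
    produced by this digest model."""
    lo, hi = int(digest.band_range[0]), int(digest.band_range[1])
    k = np.arange(lo, hi + 1, dtype=float)
    p = 1.0 / digest.mean_spacing
    pmf = (1 - p) ** (k - 1) * p
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    t = int(tolerance)
    idx_hi = np.minimum(np.arange(len(k)) + t, len(k) - 1)
    idx_lo = np.arange(len(k)) - t - 1
    window = cdf[idx_hi] - np.where(idx_lo >= 0, cdf[idx_lo], 0.0)
    return float((pmf * window).sum())


def fingerprint_clone(
    clone: CloneModel,
    sites: DigestSiteIndex,
    digest: DigestParams,
    noise: NoiseParams,
    seed: int,
    contaminant_source: CloneModel | None = None,
    contaminant_sites: DigestSiteIndex | None = None,
) -> Fingerprint:
    """Fingerprint one clone: digest fragments in the observable range, each
    perturbed by multiplicative sizing noise and rounded to integer units.
    When ``contaminant_source`` is given (a same-plate clone), a random
    subset (>= ``contamination_min_fraction``) of its bands is appended —
    well-to-well contamination."""
    rng = _rng(seed, _STAGE_FP, (zlib.crc32(clone.clone_id.encode()),))
    bands = true_bands(clone, sites, digest)
    bands = bands * (1.0 + rng.normal(0.0, noise.band_sigma, len(bands)))
    if contaminant_source is not None:
        other = true_bands(contaminant_source, contaminant_sites or sites, digest)
        frac = rng.uniform(noise.contamination_min_fraction, noise.contamination_max_fraction)
        take = max(1, int(frac * len(other))) if len(other) else 0
        if take:
            picked = rng.choice(other, size=take, replace=False)
            picked = picked * (1.0 + rng.normal(0.0, noise.band_sigma, take))
            bands = np.concatenate([bands, picked])
    bands = np.unique(np.round(bands))
    return Fingerprint(
        clone_id=clone.clone_id,
        bands=tuple(float(b) for b in bands if b > 0),
        plate=clone.plate,
        row=clone.row,
        column=clone.column,
    )


def fingerprint_library(
    library: LibraryModel,
    digest: DigestParams | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
):
    """Fingerprint every clone; contaminant clones digest the decoy arm, and
    well-to-well contamination picks a random same-plate partner.  Returns
    ``(fingerprints, contaminated clone ids)``."""
    digest = digest or DigestParams()
    noise = noise or NoiseParams()
    arm_sites = DigestSiteIndex(library.arm.seed, digest)
    decoy_sites = (
        DigestSiteIndex(library.decoy_arm.seed, digest, salt=0xDEC0)
        if library.decoy_arm is not None
        else None
    )
    rng = _rng(seed, _STAGE_FP)
    plates = library.by_plate()
    fps, chimeric = [], []
    for clone in library.clones:
        own_sites = decoy_sites if clone.contaminant else arm_sites
        source = source_sites = None
        if noise.well_contamination_rate > 0 and rng.random() < noise.well_contamination_rate:
            mates = [c for c in plates[clone.plate] if c.clone_id != clone.clone_id]
            if mates:
                source = mates[int(rng.integers(0, len(mates)))]
                source_sites = decoy_sites if source.contaminant else arm_sites
                chimeric.append(clone.clone_id)
        fps.append(
            fingerprint_clone(clone, own_sites, digest, noise, seed, source, source_sites)
        )
    return fps, chimeric


# ---------------------------------------------------------------------------
# Lazy deterministic arm sequence (for BES / shotgun records)


class ArmSequence:
    """Deterministic random sequence for an arm, generated in blocks."""

    _BASES = np.frombuffer(b"ACGT", dtype="S1")

    def __init__(self, arm_seed: int, block: int = 100_000, salt: int = 0x5E0):
        self.seed = int(arm_seed)
        self.block = block
        self.salt = salt
        self._cache: dict = {}

    def _block_seq(self, b: int) -> np.ndarray:
        if b not in self._cache:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=[self.seed, self.salt], spawn_key=(b,))
            )
            self._cache[b] = rng.integers(0, 4, self.block)
            if len(self._cache) > 64:
                self._cache.pop(next(iter(self._cache)))
        return self._cache[b]

    def get(self, start: int, end: int) -> str:
        parts = []
        for b in range(start // self.block, (end - 1) // self.block + 1):
            seq = self._block_seq(b)
            lo = max(start, b * self.block) - b * self.block
            hi = min(end, (b + 1) * self.block) - b * self.block
            parts.append(seq[lo:hi])
        codes = np.concatenate(parts)
        return self._BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# Assays: 3D pools, BES, shotgun contigs, genetic maps, deletion-bin ESTs


@dataclass
class AssayParams:
    background_mean: float = 100.0
    background_sd: float = 10.0
    signal: float = 1_000.0
    cross_hyb_rate: float = 0.01  # per probe: one random wrong pool elevated
    nonsyntenic_probe_fraction: float = 0.5
    bes_length_mean: float = 703.0
    bes_length_sd: float = 60.0
    shotgun_per_mb: float = 10.0
    shotgun_length_mean: float = 950.0
    shotgun_length_sigma: float = 0.8
    n_markers: int = 16
    map_names: tuple = ("M1", "M2", "M3", "M4", "M5", "M6", "M7", "M8")
    map_presence: float = 0.35
    cm_jitter_sd: float = 2.0
    total_cm: float = 50.0
    recombination_scale: float = 0.2  # decay length of the distal cM intensity, arm fractions
    n_ests: int = 120


@dataclass
class AssayData:
    pool_signals: pd.DataFrame
    pool_layout: object  # anchoring.PoolLayout
    probe_gene_map: dict
    truth_incidence: dict  # probe -> set of MTP clone ids carrying the gene
    bes_records: list
    bes_clone_map: dict
    bes_truth: pd.DataFrame
    shotgun_records: list
    shotgun_truth: pd.DataFrame
    markers: list
    marker_truth: pd.DataFrame
    bin_est_hits: dict
    est_truth: pd.DataFrame


def genetic_position(x: float, arm_length: float, params: AssayParams) -> float:
    """Cumulative cM at physical position x: exponential-decay recombination
    intensity concentrates the map in the distal (telomeric) region."""
    s = params.recombination_scale
    return params.total_cm * (1.0 - math.exp(-x / (s * arm_length))) / (1.0 - math.exp(-1.0 / s))


def _mk_hit(query, subject, length=400, identity=0.95, score=600.0, evalue=1e-80, spos=1):
    return HomologyHit(
        query=query,
        subject=subject,
        length=length,
        identity=identity,
        score=score,
        evalue=evalue,
        qstart=1,
        qend=length,
        sstart=spos,
        send=spos + length - 1,
    )


def simulate_assays(
    arm: ArmModel,
    library: LibraryModel,
    mtp,
    params: AssayParams | None = None,
    seed: int = 0,
) -> AssayData:
    """Derived assay data for an MTP clone subset.

    3D pool signals are elevated iff a pooled clone carries the probe's gene
    (midpoint rule), on Gaussian background with a configurable
    cross-hybridisation rate; two ~703 bp BES per MTP clone come from the
    clone ends; shotgun contigs tile the arm with a lognormal length
    distribution; marker cM positions are drawn per map around a shared
    truth with map-specific jitter and distally inflated cM-per-Mb; ESTs are
    assigned to deletion bins by true gene position.
    """
    from .anchoring import MarkerRecord, PoolLayout  # local import to avoid a cycle

    params = params or AssayParams()
    rng = _rng(seed, _STAGE_ASSAY)
    clones = {c.clone_id: c for c in library.clones}
    mtp_clones = [clones[m] for m in sorted(mtp)]

    # --- probes and 3D pools
    probes = {}
    for g in arm.genes:
        if g.syntenic or rng.random() < params.nonsyntenic_probe_fraction:
            probes[f"pr_{g.gene_id}"] = g
    pools = {}
    addresses = {}
    for c in mtp_clones:
        pools[f"P{c.plate:03d}"] = ("plate", c.plate)
        pools[f"R_{c.row}"] = ("row", c.row)
        pools[f"C{c.column:02d}"] = ("column", c.column)
        addresses[(c.plate, c.row, c.column)] = c.clone_id
    layout = PoolLayout(pools=pools, addresses=addresses)
    pool_ids = sorted(pools)
    truth_incidence = {}
    sig = np.clip(
        rng.normal(params.background_mean, params.background_sd, (len(probes), len(pool_ids))),
        0.0,
        None,
    )
    pool_pos = {p: i for i, p in enumerate(pool_ids)}
    for pi, (probe, gene) in enumerate(sorted(probes.items())):
        mid = (gene.start + gene.end) // 2
        carriers = {
            c.clone_id
            for c in mtp_clones
            if not c.contaminant and c.start <= mid < c.end
        }
        truth_incidence[probe] = carriers
        hot = set()
        for cid in carriers:
            c = clones[cid]
            hot.update((f"P{c.plate:03d}", f"R_{c.row}", f"C{c.column:02d}"))
        for p in hot:
            sig[pi, pool_pos[p]] += params.signal
        if params.cross_hyb_rate > 0 and rng.random() < params.cross_hyb_rate:
            sig[pi, int(rng.integers(0, len(pool_ids)))] += params.signal
    signals = pd.DataFrame(sig, index=sorted(probes), columns=pool_ids)

    # --- BAC-end sequences (two per MTP clone, taken from the clone ends)
    arm_seq = ArmSequence(arm.seed)
    decoy_seq = ArmSequence(library.decoy_arm.seed, salt=0x5ED) if library.decoy_arm else None
    bes_records, bes_clone_map, bes_rows = [], {}, []
    for c in mtp_clones:
        src = decoy_seq if c.contaminant else arm_seq
        if src is None:
            continue
        for tag, left in (("L", True), ("R", False)):
            ln = int(np.clip(rng.normal(params.bes_length_mean, params.bes_length_sd), 300, 1_200))
            if left:
                s, e = c.start, min(c.start + ln, c.end)
            else:
                s, e = max(c.end - ln, c.start), c.end
            seq = src.get(s, e)
            if not left:
                seq = str(Seq(seq).reverse_complement())
            bid = f"{c.clone_id}_{tag}"
            bes_records.append(SeqRecord(Seq(seq), id=bid, description=""))
            bes_clone_map[bid] = c.clone_id
            bes_rows.append(
                {"bes_id": bid, "clone_id": c.clone_id, "start": s, "end": e, "contaminant": c.contaminant}
            )

    # --- shotgun survey contigs tiling the arm
    n_sh = int(params.shotgun_per_mb * arm.arm_length / 1e6)
    sh_len = np.clip(
        np.exp(rng.normal(math.log(params.shotgun_length_mean), params.shotgun_length_sigma, n_sh)),
        200,
        20_000,
    ).astype(int)
    sh_start = rng.integers(0, np.maximum(arm.arm_length - sh_len, 1))
    shotgun_records, sh_rows = [], []
    for i in range(n_sh):
        sid = f"shc{i:06d}"
        s, e = int(sh_start[i]), int(sh_start[i] + sh_len[i])
        shotgun_records.append(SeqRecord(Seq(arm_seq.get(s, e)), id=sid, description=""))
        sh_rows.append({"contig_id": sid, "start": s, "end": e})

    # --- genetic markers on several maps around a shared truth
    syn = arm.syntenic_genes
    n_mark = min(params.n_markers, len(syn))
    # distally weighted marker picks mirror the published map density
    weights = np.array([math.exp(-g.start / (0.35 * arm.arm_length)) for g in syn])
    weights /= weights.sum()
    picks = sorted(rng.choice(len(syn), size=n_mark, replace=False, p=weights).tolist())
    markers, mrows = [], []
    for k, gi in enumerate(picks):
        g = syn[gi]
        x = (g.start + g.end) / 2.0
        true_cm = genetic_position(x, arm.arm_length, params)
        present = [m for m in params.map_names if rng.random() < params.map_presence]
        if not present:
            present = [params.map_names[int(rng.integers(0, len(params.map_names)))]]
        positions = {
            m: round(max(0.0, true_cm + rng.normal(0.0, params.cm_jitter_sd)), 1) for m in present
        }
        name = f"mk{k + 1:02d}_{g.gene_id}"
        markers.append(MarkerRecord(name=name, positions=positions))
        mrows.append({"marker": name, "gene_id": g.gene_id, "position_bp": x, "true_cm": true_cm})

    # --- deletion-bin ESTs hitting zipper (syntenic) genes
    bins = ("bin_telomeric", "bin_central", "bin_centromeric")
    bin_est_hits: dict = {b: [] for b in bins}
    est_rows = []
    gene_pool = list(arm.genes)
    for k in range(params.n_ests):
        g = gene_pool[int(rng.integers(0, len(gene_pool)))]
        b = bins[arm.bin_of((g.start + g.end) / 2.0)]
        est = f"est{k:04d}"
        if g.syntenic:
            bin_est_hits[b].append(_mk_hit(est, g.gene_id, identity=0.9, score=300.0))
        est_rows.append({"est_id": est, "gene_id": g.gene_id, "bin": b, "syntenic": g.syntenic})

    return AssayData(
        pool_signals=signals,
        pool_layout=layout,
        probe_gene_map={p: g.gene_id for p, g in probes.items()},
        truth_incidence=truth_incidence,
        bes_records=bes_records,
        bes_clone_map=bes_clone_map,
        bes_truth=pd.DataFrame(bes_rows),
        shotgun_records=shotgun_records,
        shotgun_truth=pd.DataFrame(sh_rows),
        markers=markers,
        marker_truth=pd.DataFrame(mrows),
        bin_est_hits=bin_est_hits,
        est_truth=pd.DataFrame(est_rows),
    )


# ---------------------------------------------------------------------------
# Three model genomes for zipper construction


@dataclass
class ModelGenomeSet:
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
    inversion: tuple | None
    true_order: list  # gene ids in true telomere -> centromere order
    displaced: list

    def zipper_config(self) -> ZipperConfig:
        return ZipperConfig(
            ref_table=self.ref_table,
            g2_table=self.g2_table,
            g3_table=self.g3_table,
            te_hits=self.te_hits,
            hits_vs_g2=self.hits_vs_g2,
            hits_vs_g3=self.hits_vs_g3,
            flank_start=self.flank_start,
            flank_end=self.flank_end,
            g2_region=self.g2_region,
            g3_region=self.g3_region,
            inversions=[self.inversion] if self.inversion else [],
        )


def simulate_model_genomes(
    arm: ArmModel,
    seed: int = 0,
    displaced_fraction: float = 0.15,
    inversion_fraction: float = 0.2,
    n_te_genes: int = 20,
    n_ref_only: int = 40,
    n_extra_other: int = 60,
) -> ModelGenomeSet:
    """Three synthetic model genomes whose syntenic interval mirrors the
    arm's syntenic genes.

    The reference genome presents the true order except for a planted
    lineage-specific inversion and a set of displaced genes moved outside
    the syntenic interval; the two other genomes keep the true order, so
    zip-in and inversion correction can recover it exactly.  TE-contaminated
    pseudo-genes and genes lacking homologs exercise the filtering steps.
    """
    rng = _rng(seed, _STAGE_GENOME)
    truth = [g.gene_id for g in arm.syntenic_genes]
    n = len(truth)
    if n < 8:
        raise ValueError("need at least 8 syntenic genes")

    # planted rearrangements: an inverted block and displaced genes outside it
    inv_len = max(2, int(inversion_fraction * n))
    inv_start = int(rng.integers(1, max(2, n - inv_len - 1)))
    inv_block = set(range(inv_start, inv_start + inv_len))
    # a displaced gene's true slot must not touch the inverted block: the
    # flank-implied insertion position is ill-defined across the inversion
    forbidden = inv_block | {inv_start - 1, inv_start + inv_len}
    candidates = [i for i in range(1, n - 1) if i not in forbidden]
    n_disp = min(len(candidates) // 2, max(1, int(displaced_fraction * n)))
    displaced_idx = set(
        sorted(rng.choice(candidates, size=n_disp, replace=False).tolist())
    )
    # avoid two consecutive displaced genes flanking nothing retained between them
    displaced_idx = {i for i in displaced_idx if (i - 1) not in displaced_idx}

    spacing = 10_000
    ref_rows, far = [], []
    pos = 0
    order_for_ref = list(range(n))
    # the inverted block appears reversed in the reference genome
    order_for_ref[inv_start : inv_start + inv_len] = reversed(
        order_for_ref[inv_start : inv_start + inv_len]
    )
    interval_payload = []  # true-order indices laid onto the ref interval
    for i in order_for_ref:
        if i in displaced_idx:
            far.append(i)
        else:
            interval_payload.append(i)
    # interleave ref-only and TE-like pseudo-genes into the interval
    te_ids = [f"tg{k:03d}" for k in range(n_te_genes)]
    ro_ids = [f"rg{k:03d}" for k in range(n_ref_only)]
    extras = te_ids + ro_ids
    rng.shuffle(extras)
    slots = sorted(rng.integers(1, max(2, len(interval_payload)), len(extras)).tolist())
    merged_ids = []
    ei = 0
    for k, i in enumerate(interval_payload):
        while ei < len(extras) and slots[ei] <= k:
            merged_ids.append(extras[ei])
            ei += 1
        merged_ids.append(truth[i])
    merged_ids.extend(extras[ei:])
    for gid in merged_ids:
        pos += spacing
        ref_rows.append({"gene_id": gid, "chrom": "chr2", "position": pos})
    # displaced genes sit far outside the interval on the same chromosome
    pos += 2_000_000
    for i in far:
        pos += spacing
        ref_rows.append({"gene_id": truth[i], "chrom": "chr2", "position": pos})
    ref_table = GenomeGeneTable(pd.DataFrame(ref_rows))

    # g2/g3 keep the true order; extra genes pad the regions' flanks
    def other_genome(prefix: str, gspacing: int):
        rows = []
        p = 500_000
        for k in range(n_extra_other // 2):
            p += gspacing
            rows.append({"gene_id": f"{prefix}x{k:03d}", "chrom": "chr1", "position": p})
        start_region = p + 50_000
        p = start_region
        homolog = {}
        for i, gid in enumerate(truth):
            p += gspacing
            rows.append({"gene_id": f"{prefix}_{i:04d}", "chrom": "chr1", "position": p})
            homolog[gid] = f"{prefix}_{i:04d}"
        end_region = p + 50_000
        p = end_region
        for k in range(n_extra_other // 2, n_extra_other):
            p += gspacing
            rows.append({"gene_id": f"{prefix}x{k:03d}", "chrom": "chr1", "position": p})
        return GenomeGeneTable(pd.DataFrame(rows)), homolog, ("chr1", start_region, end_region)

    g2_table, hom2, g2_region = other_genome("g2", 5_000)
    g3_table, hom3, g3_region = other_genome("g3", 7_000)

    hits2 = [_mk_hit(g, hom2[g], score=600.0 + float(rng.random()), spos=int(g2_table.position(hom2[g]))) for g in truth]
    hits3 = [_mk_hit(g, hom3[g], score=600.0 + float(rng.random()), spos=int(g3_table.position(hom3[g]))) for g in truth]
    # ref-only genes get a homolog in g2 but not g3: dropped by intersection
    for k, rid in enumerate(ro_ids[: n_ref_only // 2]):
        hits2.append(_mk_hit(rid, f"g2x{k % max(1, n_extra_other):03d}", score=200.0))
    te_hits = [_mk_hit(t, f"RLG_Fatima#{k}", score=400.0) for k, t in enumerate(te_ids)]

    flank_start, flank_end = truth[0], truth[-1]

    # final zipper indices of the inverted block (computed on the augmented order)
    retained = [i for i in range(n)]  # all truth genes end up in the zipper
    # augmented order before inversion correction = ref interval order with
    # displaced genes zipped back into their true slots
    aug = []
    for i in order_for_ref:
        if i in displaced_idx:
            continue
        aug.append(i)
    for i in sorted(displaced_idx):
        # insert at the true slot among current augmented order
        left = i - 1
        at = aug.index(left) + 1 if left in aug else 0
        aug.insert(at, i)
    block_positions = [k + 1 for k, i in enumerate(aug) if i in inv_block]
    inversion = (min(block_positions), max(block_positions)) if inv_len >= 2 else None

    return ModelGenomeSet(
        ref_table=ref_table,
        g2_table=g2_table,
        g3_table=g3_table,
        te_hits=te_hits,
        hits_vs_g2=hits2,
        hits_vs_g3=hits3,
        flank_start=flank_start,
        flank_end=flank_end,
        g2_region=g2_region,
        g3_region=g3_region,
        inversion=inversion,
        true_order=truth,
        displaced=[truth[i] for i in sorted(displaced_idx)],
    )


# ---------------------------------------------------------------------------
# Ground truth tables


@dataclass
class TruthTables:
    clone_order: pd.DataFrame  # clone_id, start, end, contaminant, true_contig
    gene_clone_incidence: pd.DataFrame  # gene_id, clone_id
    marker_positions: pd.DataFrame | None = None

    def adjacent_pairs(self) -> list:
        """Consecutive non-contaminant clone pairs within one true contig."""
        df = self.clone_order[~self.clone_order.contaminant]
        pairs = []
        for _, grp in df.groupby("true_contig", sort=False):
            ids = list(grp.clone_id)
            pairs.extend(zip(ids, ids[1:]))
        return pairs

    def to_dir(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.clone_order.to_csv(out / "clone_order.tsv", sep="\t", index=False)
        self.gene_clone_incidence.to_csv(out / "gene_clone_incidence.tsv", sep="\t", index=False)
        if self.marker_positions is not None:
            self.marker_positions.to_csv(out / "marker_positions.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, outdir) -> "TruthTables":
        from pathlib import Path

        out = Path(outdir)
        mp = out / "marker_positions.tsv"
        clone_order = pd.read_csv(out / "clone_order.tsv", sep="\t")
        # contaminant clones carry an empty contig label, not missing data
        clone_order["true_contig"] = clone_order["true_contig"].fillna("")
        return cls(
            clone_order=clone_order,
            gene_clone_incidence=pd.read_csv(out / "gene_clone_incidence.tsv", sep="\t"),
            marker_positions=pd.read_csv(mp, sep="\t") if mp.exists() else None,
        )


def detectable_overlap_fraction(
    digest: DigestParams | None = None,
    tolerance: float = 3.0,
    cutoff: float = 1e-15,
    mean_insert: float = 111_000.0,
    noise_retention: float = 0.95,
) -> float:
    """Smallest overlap fraction the fingerprint method can call at ``cutoff``.

    Derived from the digest model: the expected observable band count of a
    mean-size clone, the chance band-match probability, and the smallest
    shared-band count whose Sulston score reaches the cutoff.  ``noise_retention``
    is the chance a genuinely shared band survives sizing noise within the
    match tolerance.  This defines "true contig membership": two clones
    belong to one true contig when the method could in principle link them.
    """
    from scipy.stats import binom

    digest = digest or DigestParams()
    lo, hi = digest.band_range
    mu = digest.mean_spacing
    frac_obs = math.exp(-lo / mu) - math.exp(-hi / mu)
    n = mean_insert / mu * frac_obs
    p_match = chance_match_probability(digest, tolerance)
    p_band = 1.0 - (1.0 - p_match) ** n
    n_int = max(1, round(n))
    k = n_int
    for s in range(1, n_int + 1):
        if binom.sf(s - 1, n_int, p_band) <= cutoff:
            k = s
            break
    return min(1.0, k / (n * noise_retention))


def build_truth(
    arm: ArmModel,
    library: LibraryModel,
    marker_truth: pd.DataFrame | None = None,
    min_overlap_fraction: float | None = None,
) -> TruthTables:
    """Ground-truth clone order, contig membership and gene incidence.

    True contigs chain clones (sorted by start) while each next clone
    overlaps the covered span by at least ``min_overlap_fraction`` of its
    own length (default: the digest model's detectable overlap fraction at
    the standard assembly cutoff); contaminant clones are excluded from
    contig membership.
    """
    if min_overlap_fraction is None:
        min_overlap_fraction = detectable_overlap_fraction()
    rows = []
    ordered = sorted(library.clones, key=lambda c: (c.start, c.clone_id))
    contig_no = 0
    cur_end = None
    for c in ordered:
        if c.contaminant:
            rows.append(
                {"clone_id": c.clone_id, "start": c.start, "end": c.end, "contaminant": True, "true_contig": ""}
            )
            continue
        need = min_overlap_fraction * (c.end - c.start)
        if cur_end is None or cur_end - c.start < need:
            contig_no += 1
            cur_end = c.end
        else:
            cur_end = max(cur_end, c.end)
        rows.append(
            {
                "clone_id": c.clone_id,
                "start": c.start,
                "end": c.end,
                "contaminant": False,
                "true_contig": f"tc{contig_no:04d}",
            }
        )
    clone_order = pd.DataFrame(rows)
    inc = []
    non_contam = [c for c in library.clones if not c.contaminant]
    gene_mid = [(g.gene_id, (g.start + g.end) // 2) for g in arm.genes]
    starts = np.array([c.start for c in non_contam])
    order_idx = np.argsort(starts, kind="stable")
    sorted_clones = [non_contam[i] for i in order_idx]
    sorted_starts = starts[order_idx]
    for gid, mid in gene_mid:
        j = np.searchsorted(sorted_starts, mid, side="right")
        for c in sorted_clones[max(0, j - 60) : j]:
            if c.start <= mid < c.end:
                inc.append({"gene_id": gid, "clone_id": c.clone_id})
    return TruthTables(
        clone_order=clone_order,
        gene_clone_incidence=pd.DataFrame(inc, columns=["gene_id", "clone_id"]),
        marker_positions=marker_truth,
    )


# ---------------------------------------------------------------------------
# Exports


def write_arm_gff(arm: ArmModel, path) -> None:
    """Genes and TE intervals as a GFF3-like tab file (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in arm.genes:
            attrs = f"ID={g.gene_id};syntenic={int(g.syntenic)}"
            if g.zipper_index is not None:
                attrs += f";zipper_index={g.zipper_index}"
            fh.write(f"arm\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t{attrs}\n")
        for fam, sup, s, e in arm.te_intervals:
            fh.write(
                f"arm\tsynth\trepeat_region\t{s + 1}\t{e}\t.\t+\t.\tID=te_{s};family={fam};superfamily={sup}\n"
            )


def write_clones_tsv(library: LibraryModel, path) -> None:
    pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "plate": c.plate,
                "row": c.row,
                "column": c.column,
                "start": c.start,
                "end": c.end,
                "contaminant": int(c.contaminant),
            }
            for c in library.clones
        ]
    ).to_csv(path, sep="\t", index=False)
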