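"""Integrated sequence model and BES composition summary.

Anchored shotgun sequences are ordered telomere -> centromere along the
physical map and written as a FASTA flatfile whose definition (DE) lines
carry the record's identity: arm + zipper position, original sequence name,
approximate gene positions, the placement on the BAC contig in kb, and the
hybridisation probe that produced the signal.  BES base pairs are classified
into known TE / novel TE / gene / rDNA / organellar / unclassified fractions
by precedence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ModelRecord",
    "CompositionSummary",
    "order_records",
    "emit_de_line",
    "parse_de_line",
    "classify_composition",
    "write_model_fasta",
    "read_model_fasta",
]


@dataclass
class ModelRecord:
    """One ordered sequence of the integrated model.

    ``genes`` holds (gene_id, start, end) with 1-based inclusive coordinates
    on the record; ``contig_range_kb`` is the placement on the BAC contig in
    integer kb; absent annotations are None/empty.
    """

    identifier: str  # arm + zipper position, e.g. 1AS_z_110
    source_id: str
    genes: list = field(default_factory=list)
    contig_id: str | None = None
    contig_range_kb: tuple | None = None
    probe: str | None = None
    sequence: str | None = None


@dataclass
class CompositionSummary:
    fractions: dict  # category -> base-pair weighted fraction
    te_by_superfamily: dict = field(default_factory=dict)
    te_by_family: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fractions must be non-negative")


def order_records(placements, ordered_map, arm: str = "1AS") -> list:
    """Order anchored sequences telomere -> centromere.

    ``placements`` is an iterable of dicts (or objects) with ``sequence``,
    ``contig``, ``clone_offset``, ``hit_position`` and optional annotation
    fields (``genes``, ``probe``, ``contig_range_kb``, ``seq``).  The sort
    key is (contig rank in the ordered map, clone offset within the contig,
    hit position within the clone); sequences on unplaced contigs are
    excluded, and each source sequence appears at most once.
    """
    rank = ordered_map.rank_of()
    zpos = ordered_map.position_of()

    def get(p, k, default=None):
        if isinstance(p, dict):
            return p.get(k, default)
        return getattr(p, k, default)

    rows = []
    seen = set()
    for p in placements:
        seq_id = get(p, "sequence")
        contig = get(p, "contig")
        if seq_id in seen or contig not in rank:
            continue
        seen.add(seq_id)
        rows.append(
            (
                rank[contig],
                float(get(p, "clone_offset", 0.0) or 0.0),
                float(get(p, "hit_position", 0.0) or 0.0),
                seq_id,
                p,
            )
        )
    rows.sort(key=lambda t: t[:4])
    out = []
    for rk, off, hp, seq_id, p in rows:
        contig = get(p, "contig")
        z = zpos.get(contig)
        ident = f"{arm}_z_{z}" if z is not None else f"{arm}_z_CEN"
        kb = get(p, "contig_range_kb")
        if kb is None:
            lo = int(off // 1000)
            hi = int((off + len(get(p, "seq") or "")) // 1000) if get(p, "seq") else lo
            kb = (lo, max(hi, lo))
        out.append(
            ModelRecord(
                identifier=ident,
                source_id=seq_id,
                genes=list(get(p, "genes", []) or []),
                contig_id=contig,
                contig_range_kb=(int(kb[0]), int(kb[1])),
                probe=get(p, "probe"),
                sequence=get(p, "seq"),
            )
        )
    return out


def emit_de_line(record: ModelRecord) -> str:
    """Definition line: identifier, source name, gene content, contig
    position in kb, probe signal — in that order, absent fields omitted."""
    parts = [record.identifier, record.source_id]
    for gene, s, e in record.genes:
        parts.append(f"{gene} {s}–{e}")
    if record.contig_range_kb is not None:
        a, b = record.contig_range_kb
        parts.append(f"on ctg: {a}–{b}")
    if record.probe:
        parts.append(f"signal = {record.probe}")
    return " ".join(parts)


_GENE_RE = re.compile(r"^(\S+) (\d+)[–-](\d+)$")


def parse_de_line(line: str) -> ModelRecord:
    """Inverse of :func:`emit_de_line` (round-trips all emitted fields)."""
    probe = None
    m = re.search(r" signal = (\S+)$", line)
    if m:
        probe = m.group(1)
        line = line[: m.start()]
    contig_range = None
    m = re.search(r" on ctg: (\d+)[–-](\d+)$", line)
    if m:
        contig_range = (int(m.group(1)), int(m.group(2)))
        line = line[: m.start()]
    tokens = line.split(" ")
    if len(tokens) < 2:
        raise ValueError(f"unparseable DE line: {line!r}")
    identifier, source = tokens[0], tokens[1]
    genes = []
    rest = tokens[2:]
    for i in range(0, len(rest) - 1, 2):
        m = _GENE_RE.match(f"{rest[i]} {rest[i + 1]}")
        if not m:
            raise ValueError(f"unparseable gene field: {rest[i]} {rest[i + 1]}")
        genes.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return ModelRecord(
        identifier=identifier,
        source_id=source,
        genes=genes,
        contig_range_kb=contig_range,
        probe=probe,
    )


# ---------------------------------------------------------------------------
# BES composition


_PRECEDENCE = ("known_te", "novel_te", "gene", "rdna", "organellar")


def _superfamily_of(subject: str) -> str:
    # TE naming convention: three-letter code underscore family, e.g. RLG_Fatima
    code = subject.split("_", 1)[0].upper()
    return {
        "RLG": "Gypsy",
        "RLC": "Copia",
        "RLX": "LTR_unknown",
        "RIX": "LINE",
        "RIL": "LINE",
        "RSX": "SINE",
        "DTC": "CACTA",
        "DTM": "Mutator",
        "DTH": "Harbinger",
        "DTT": "Mariner",
        "DHH": "Helitron",
    }.get(code, "other")


def _family_of(subject: str) -> str:
    parts = subject.split("_")
    return parts[1] if len(parts) > 1 else subject


def classify_composition(
    bes_records,
    repeat_hits,
    gene_hits,
    organellar_hits=(),
    novel_te_hits=(),
    rdna_hits=(),
) -> CompositionSummary:
    """Base-pair weighted sequence composition of a BES set.

    Each base is assigned by precedence known TE > novel TE > gene > rDNA >
    organellar > unclassified, using the subject-side hit coordinates on the
    BES (hit queries are BES ids; ``qstart``/``qend`` give the covered BES
    range, 1-based inclusive).  TE fractions are additionally broken down by
    superfamily and family from the repeat subject names.
    """
    lengths = {}
    for rec in bes_records:
        if isinstance(rec, SeqRecord):
            lengths[rec.id] = len(rec.seq)
        else:
            bes_id, seq_or_len = rec
            lengths[bes_id] = seq_or_len if isinstance(seq_or_len, int) else len(seq_or_len)
    masks = {b: np.zeros(n, dtype=np.uint8) for b, n in lengths.items()}
    # category codes by precedence; 0 = unclassified
    tables = [
        ("known_te", 1, repeat_hits),
        ("novel_te", 2, novel_te_hits),
        ("gene", 3, gene_hits),
        ("rdna", 4, rdna_hits),
        ("organellar", 5, organellar_hits),
    ]
    te_cover: dict = {}
    for name, code, hits in tables:
        for h in hits:
            if h.query not in masks:
                continue
            m = masks[h.query]
            lo, hi = sorted((h.qstart, h.qend))
            lo = max(1, lo)
            hi = min(len(m), hi)
            if hi < lo:
                continue
            sl = slice(lo - 1, hi)
            free = m[sl] == 0
            if name == "known_te":
                fam = _family_of(h.subject)
                sup = _superfamily_of(h.subject)
                te_cover.setdefault((sup, fam), 0)
                te_cover[(sup, fam)] += int(free.sum())
            m[sl][free] = code
    total = sum(lengths.values())
    if total == 0:
        return CompositionSummary(fractions={})
    counts = {name: 0 for name, _, _ in tables}
    unclassified = 0
    for m in masks.values():
        binc = np.bincount(m, minlength=6)
        unclassified += int(binc[0])
        for name, code, _ in tables:
            counts[name] += int(binc[code])
    fractions = {k: v / total for k, v in counts.items()}
    fractions["unclassified"] = unclassified / total
    by_sup: dict = {}
    by_fam: dict = {}
    for (sup, fam), n in te_cover.items():
        by_sup[sup] = by_sup.get(sup, 0) + n / total
        by_fam[fam] = by_fam.get(fam, 0) + n / total
    return CompositionSummary(fractions=fractions, te_by_superfamily=by_sup, te_by_family=by_fam)


# ---------------------------------------------------------------------------
# FASTA IO with DE lines


def write_model_fasta(records, path) -> None:
    seq_records = []
    for r in records:
        de = emit_de_line(r)
        seq = r.sequence or ""
        sr = SeqRecord(Seq(seq), id=r.identifier, description=de[len(r.identifier) + 1 :] if de.startswith(r.identifier + " ") else de)
        seq_records.append(sr)
    SeqIO.write(seq_records, path, "fasta")


def read_model_fasta(path) -> list:
    out = []
    for sr in SeqIO.parse(path, "fasta"):
        de = sr.description if sr.description.startswith(sr.id) else f"{sr.id} {sr.description}"
        rec = parse_de_line(de)
        rec.sequence = str(sr.seq)
        out.append(rec)
    return out


def write_composition_tsv(summary: CompositionSummary, path) -> None:
    rows = [{"category": k, "fraction": v} for k, v in sorted(summary.fractions.items())]
    rows += [
        {"category": f"te_superfamily:{k}", "fraction": v}
        for k, v in sorted(summary.te_by_superfamily.items())
    ]
    rows += [
        {"category": f"te_family:{k}", "fraction": v}
        for k, v in sorted(summary.te_by_family.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
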