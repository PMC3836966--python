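"""Homology hit tables and a small seeded local aligner.

Downstream anchoring consumes thresholded DNA homology hits (alignment
length, identity, significance).  At desk scale the hits are produced by an
exact-seed, ungapped-extension aligner over both strands; externally computed
tables in the common 12-column tabular dialect (query, subject, %identity,
length, mismatches, gaps, qstart, qend, sstart, send, evalue, bitscore) drop
in through the reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "HomologyHit",
    "seeded_align",
    "filter_hits",
    "best_hit",
    "read_hits_tsv",
    "write_hits_tsv",
]

# Karlin-Altschul-like constants for the built-in aligner's significance;
# only the ordering and thresholding of scores matter at desk scale.
_MATCH, _MISMATCH = 2, -3
_LAMBDA, _K = 0.625, 0.41
_SEARCH_SPACE = 1e9


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    length: int
    identity: float  # fraction in [0, 1]
    score: float  # bit score
    evalue: float
    qstart: int  # 1-based inclusive, forward query coordinates
    qend: int
    sstart: int
    send: int
    strand: str = "+"

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be a fraction in [0, 1]")
        if self.length < 1:
            raise ValueError("alignment length must be positive")


def _bit_score(matches: int, mismatches: int) -> float:
    raw = _MATCH * matches + _MISMATCH * mismatches
    return (_LAMBDA * raw - math.log(_K)) / math.log(2.0)


def _evalue(bits: float) -> float:
    return _SEARCH_SPACE * 2.0 ** (-bits)


def _extend(q: str, s: str, qi: int, si: int, seed_len: int, x_drop: int = 12):
    """Ungapped extension of an exact seed in both directions."""
    # left
    best_drop = 0
    score = drop = 0
    li = 0
    best_li = 0
    while qi - li - 1 >= 0 and si - li - 1 >= 0:
        li += 1
        score += _MATCH if q[qi - li] == s[si - li] else _MISMATCH
        if score > best_drop:
            best_drop, best_li = score, li
        if best_drop - score > x_drop:
            break
    # right
    score = 0
    best_score = 0
    ri = 0
    best_ri = 0
    j = 0
    while qi + seed_len + j < len(q) and si + seed_len + j < len(s):
        score += _MATCH if q[qi + seed_len + j] == s[si + seed_len + j] else _MISMATCH
        j += 1
        if score > best_score:
            best_score, best_ri = score, j
        if best_score - score > x_drop:
            break
    qs, qe = qi - best_li, qi + seed_len + best_ri  # half-open on query
    ss = si - best_li
    matches = sum(1 for k in range(qe - qs) if q[qs + k] == s[ss + k])
    return qs, qe, ss, matches


def seeded_align(
    query,
    subjects: dict,
    seed_len: int = 12,
    min_len: int = 50,
    min_identity: float = 0.8,
) -> list:
    """Exact-seed chaining with ungapped extension against each subject.

    ``query`` is ``(id, sequence)`` or a plain sequence (id "query");
    ``subjects`` maps subject id to sequence.  Both strands are searched;
    hits shorter than ``min_len`` or below ``min_identity`` are discarded.
    Empty query -> empty result.
    """
    if isinstance(query, (tuple, list)):
        qid, qseq = query
    else:
        qid, qseq = "query", query
    qseq = str(qseq).upper()
    if not qseq:
        return []
    hits = []
    for sid, sseq in subjects.items():
        sseq = str(sseq).upper()
        if len(sseq) < seed_len:
            continue
        index = {}
        for i in range(len(sseq) - seed_len + 1):
            index.setdefault(sseq[i : i + seed_len], []).append(i)
        for strand in ("+", "-"):
            q = qseq if strand == "+" else str(Seq(qseq).reverse_complement())
            if len(q) < seed_len:
                continue
            seen_diag = {}
            for qi in range(len(q) - seed_len + 1):
                word = q[qi : qi + seed_len]
                if "N" in word:
                    continue
                for si in index.get(word, ()):  # noqa: B905
                    diag = si - qi
                    # skip seeds inside an already-extended alignment on this diagonal
                    if seen_diag.get(diag, -1) >= qi:
                        continue
                    qs, qe, ss, matches = _extend(q, sseq, qi, si, seed_len)
                    seen_diag[diag] = qe
                    length = qe - qs
                    identity = matches / length
                    if length < min_len or identity < min_identity:
                        continue
                    bits = _bit_score(matches, length - matches)
                    if strand == "+":
                        qstart, qend = qs + 1, qe
                        sstart, send = ss + 1, ss + length
                    else:
                        # report forward query coordinates, reversed subject
                        qstart = len(qseq) - qe + 1
                        qend = len(qseq) - qs
                        sstart, send = ss + length, ss + 1
                    hits.append(
                        HomologyHit(
                            query=qid,
                            subject=sid,
                            length=length,
                            identity=identity,
                            score=bits,
                            evalue=_evalue(bits),
                            qstart=qstart,
                            qend=qend,
                            sstart=sstart,
                            send=send,
                            strand=strand,
                        )
                    )
    # deduplicate identical spans (same alignment found from several seeds)
    uniq = {}
    for h in hits:
        key = (h.subject, h.strand, h.qstart, h.qend, h.sstart, h.send)
        if key not in uniq or h.score > uniq[key].score:
            uniq[key] = h
    return sorted(uniq.values(), key=lambda h: (-h.score, h.subject, h.qstart))


def filter_hits(
    hits,
    min_len: int = 50,
    min_identity: float = 0.8,
    max_significance: float = 1e-10,
) -> list:
    """Keep hits of at least ``min_len`` bp with identity strictly above
    ``min_identity`` and significance strictly below ``max_significance``."""
    return [
        h
        for h in hits
        if h.length >= min_len and h.identity > min_identity and h.evalue < max_significance
    ]


def best_hit(hits, query: str):
    """Highest-scoring hit for ``query``; ties broken by higher identity,
    then lexicographically smaller subject id.  None when no hit."""
    mine = [h for h in hits if h.query == query]
    if not mine:
        return None
    return sorted(mine, key=lambda h: (-h.score, -h.identity, h.subject))[0]


_COLS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_hits_tsv(hits, path) -> None:
    rows = []
    for h in hits:
        mism = round(h.length * (1.0 - h.identity))
        rows.append(
            {
                "query": h.query,
                "subject": h.subject,
                "pident": round(h.identity * 100.0, 3),
                "length": h.length,
                "mismatch": mism,
                "gapopen": 0,
                "qstart": h.qstart,
                "qend": h.qend,
                "sstart": h.sstart,
                "send": h.send,
                "evalue": h.evalue,
                "bitscore": h.score,
            }
        )
    pd.DataFrame(rows, columns=_COLS).to_csv(path, sep="\t", index=False, header=False)


def read_hits_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", names=_COLS, comment="#")
    out = []
    for r in df.itertuples():
        strand = "+" if r.send >= r.sstart else "-"
        out.append(
            HomologyHit(
                query=str(r.query),
                subject=str(r.subject),
                length=int(r.length),
                identity=float(r.pident) / 100.0,
                score=float(r.bitscore),
                evalue=float(r.evalue),
                qstart=int(r.qstart),
                qend=int(r.qend),
                sstart=int(r.sstart),
                send=int(r.send),
                strand=strand,
            )
        )
    return out
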