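"""Isoform classification and regulatory-context calls.

The residue four positions upstream of the catalytic Cys separates PCS
sequences into the "N" isoform (Asn; group 1, the short half-PCS-like form)
and the "E"/"D" isoforms (Glu or Asp; group 2, the plant-like form). A
Ser/Thr at -7 combined with an acidic residue at -4 completes the casein
kinase 2 context [ST]-X2-[DE] that makes the -7 threonine a plausible
phosphorylation target. Conserved cysteine pairs (CC and CXXXC) between the
catalytic Cys and His, the total Cys count and the C-terminal tail length
complete the per-sequence feature set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord
from .triad import TriadAnnotation

_GROUP_OF = {"N": "1", "E": "2", "D": "2"}


@dataclass
class IsoformCall:
    """Per-sequence isoform and regulatory-context call."""

    subtype: str  # N, E, D or "unclassified"
    group: str  # "1", "2" or "none"
    minus4_residue: str
    minus3_residue: str
    thr7_residue: str | None
    ck2_competent: bool
    cc_hits: list = field(default_factory=list)
    cxxxc_hits: list = field(default_factory=list)
    conserved_cys_count: int = 0
    cys_total: int = 0
    cterm_tail_length: int = 0


def check_ck2_context(record: SequenceRecord, triad: TriadAnnotation) -> bool:
    """True iff S/T at -7 and D/E at -4 from the catalytic Cys."""
    c = triad.cys_pos
    if c - 7 < 1:
        return False
    res = record.residues
    return res[c - 8] in "ST" and res[c - 5] in "DE"


def find_conserved_cys(record: SequenceRecord, triad: TriadAnnotation
                       ) -> tuple[list[int], list[int]]:
    """CC and C-X(3)-C hits strictly between the catalytic Cys and His.

    Returns (cc_starts, cxxxc_starts), 1-based positions of the first C of
    each hit; overlapping hits are all reported.
    """
    res = record.residues
    lo, hi = triad.cys_pos, triad.his_pos  # open interval (lo, hi)
    cc, cxxxc = [], []
    for p in range(lo + 1, hi):  # 1-based position of a candidate first C
        if res[p - 1] != "C":
            continue
        if p + 1 < hi and res[p] == "C":
            cc.append(p)
        if p + 4 < hi and res[p + 3] == "C":
            cxxxc.append(p)
    return cc, cxxxc


def count_cys(record: SequenceRecord) -> int:
    """Number of C residues in the whole sequence."""
    return record.residues.count("C")


def cterm_tail(record: SequenceRecord, triad: TriadAnnotation) -> int:
    """Number of residues after the catalytic Asp."""
    return len(record) - triad.asp_pos


def classify_isoform(record: SequenceRecord, triad: TriadAnnotation) -> IsoformCall:
    """Classify one sequence from its annotated triad.

    The -4 residue maps N -> subtype N / group 1 and E or D -> group 2;
    anything else is retained as unclassified with group "none".
    """
    c = triad.cys_pos
    if c - 4 < 1:
        raise ValueError(f"{record.seq_id}: catalytic Cys at {c} has no -4 residue")
    res = record.residues
    minus4 = res[c - 5]
    minus3 = res[c - 4]
    thr7 = res[c - 8] if c - 7 >= 1 else None
    subtype = minus4 if minus4 in _GROUP_OF else "unclassified"
    group = _GROUP_OF.get(minus4, "none")
    cc, cxxxc = find_conserved_cys(record, triad)
    participating = set()
    for p in cc:
        participating.update((p, p + 1))
    for p in cxxxc:
        participating.update((p, p + 4))
    return IsoformCall(
        subtype=subtype,
        group=group,
        minus4_residue=minus4,
        minus3_residue=minus3,
        thr7_residue=thr7,
        ck2_competent=check_ck2_context(record, triad),
        cc_hits=cc,
        cxxxc_hits=cxxxc,
        conserved_cys_count=min(len(participating), 4),
        cys_total=count_cys(record),
        cterm_tail_length=cterm_tail(record, triad),
    )


def classify_form_string(form: str) -> tuple[str, str]:
    """Classify a 7-mer PCS form string (ending at the catalytic Cys).

    Convenience for form strings as printed in comparative tables, e.g.
    "QNNQAYC" -> ("N", "1"). The -4 residue is the third letter.
    """
    if len(form) != 7 or form[-1] != "C":
        raise ValueError(f"form string must be a 7-mer ending in C, got {form!r}")
    minus4 = form[2]
    return (minus4 if minus4 in _GROUP_OF else "unclassified",
            _GROUP_OF.get(minus4, "none"))


def column_information(aligned_block: list[str]) -> np.ndarray:
    """Per-column information content (bits) of an ungapped aligned block.

    IC_j = log2(20) - H_j with H_j the Shannon entropy of the empirical
    residue frequencies in column j; ranges from 0 (uniform) to log2(20)
    (invariant column). This is the matrix behind a sequence logo.
    """
    if not aligned_block:
        raise ValueError("empty aligned block")
    lengths = {len(s) for s in aligned_block}
    if len(lengths) != 1:
        raise ValueError("aligned block rows must have equal length")
    (width,) = lengths
    out = np.empty(width)
    n = len(aligned_block)
    for j in range(width):
        counts: dict[str, int] = {}
        for row in aligned_block:
            counts[row[j]] = counts.get(row[j], 0) + 1
        h = -sum((c / n) * math.log2(c / n) for c in counts.values())
        out[j] = math.log2(20) - h
    return out
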