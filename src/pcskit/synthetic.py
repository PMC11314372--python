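"""Synthetic PCS-like protein scaffolds with known ground truth.

Real phytochelatin synthases carry a catalytic Cys/His/Asp triad with a
variable Cys–His spacing, an invariant 17-residue His–Asp spacing, an
isoform-defining residue (Asn vs Glu/Asp) four positions upstream of the
catalytic Cys, an optional phospho-competent Thr at -7, paired conserved
cysteines (CC and CXXXC) between the catalytic Cys and His, and — in the
plant-like isoform — a Cys-rich C-terminal extension. The generator emits
sequences with exactly that anatomy and records every planted position, so
the triad, classification, phylogeny and motif stages can all be tested
against known truth without any downloads.

It also simulates sequence pairs under the JTT substitution model for
distance-estimation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import jtt
from .seqio import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: residues never drawn at free scaffold positions, so the planted triad is
#: the only (C, H, D) combination satisfying the spacing constraints
_RESERVED = set("CHD")
_SAFE = [aa for aa in AA20 if aa not in _RESERVED]

#: observed range of Cys–His spacings in the real feature table
CH_SPACING_RANGE = (94, 155)

#: the His–Asp spacing is invariant across all known PCS sequences
HD_SPACING = 17


class ScaffoldError(ValueError):
    """Inconsistent scaffold specification."""


@dataclass(frozen=True)
class ScaffoldSpec:
    """Blueprint for one synthetic PCS-like sequence.

    ``ch_spacing`` is the number of residues strictly between the catalytic
    Cys and His; ``None`` draws uniformly from the observed range.
    """

    subtype: str = "N"
    nterm_len: int = 40
    ch_spacing: int | None = None
    include_thr7: bool = True
    include_cc: bool = True
    include_cxxxc: bool = True
    cterm_len: int = 60
    cterm_cys_frac: float = 0.15
    background: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.subtype not in {"N", "E", "D"}:
            raise ScaffoldError(f"subtype must be N, E or D, got {self.subtype!r}")
        if self.nterm_len < 0 or self.cterm_len < 0:
            raise ScaffoldError("segment lengths must be non-negative")
        if self.ch_spacing is not None and self.ch_spacing < 8:
            raise ScaffoldError("ch_spacing must leave room for CC and CXXXC (>= 8)")
        if not 0.0 <= self.cterm_cys_frac <= 1.0:
            raise ScaffoldError("cterm_cys_frac must be within [0, 1]")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
                raise ScaffoldError("background must be a 20-point probability simplex")


@dataclass
class TruthRecord:
    """Planted ground truth for one generated sequence (1-based positions)."""

    seq_id: str
    subtype: str
    cys_pos: int
    his_pos: int
    asp_pos: int
    thr_pos: int | None = None
    cc_positions: list = field(default_factory=list)
    cxxxc_positions: list = field(default_factory=list)
    motif_span: tuple | None = None


def _draw_safe(rng: np.random.Generator, n: int, background: tuple | None) -> list[str]:
    """Draw n residues, excluding C/H/D (renormalising any background)."""
    if n == 0:
        return []
    if background is None:
        idx = rng.integers(0, len(_SAFE), size=n)
        return [_SAFE[i] for i in idx]
    bg = np.asarray(background, dtype=float).copy()
    for aa in _RESERVED:
        bg[AA20.index(aa)] = 0.0
    bg /= bg.sum()
    idx = rng.choice(20, size=n, p=bg)
    return [AA20[i] for i in idx]


def generate_pcs_sequence(
    spec: ScaffoldSpec, seq_id: str = "synthetic_pcs"
) -> tuple[SequenceRecord, TruthRecord]:
    """Generate one PCS-like sequence and its ground truth.

    Layout: [N-term] [T or filler] [2] [subtype letter] [P/Q] [2] [C]
    [Cys–His segment with optional CC and CXXXC] [H] [17 spacer] [D]
    [Cys-rich tail]. All free positions avoid C/H/D so the planted triad is
    unique; the residue right before the catalytic Cys is Y or F, matching
    the aromatic position conserved in real PCS forms. Deterministic for a
    fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    ch = spec.ch_spacing
    if ch is None:
        ch = int(rng.integers(CH_SPACING_RANGE[0], CH_SPACING_RANGE[1] + 1))
    if ch < 8:
        raise ScaffoldError("ch_spacing must be >= 8")

    nterm = _draw_safe(rng, spec.nterm_len, spec.background)

    # 7-mer context ending at the catalytic Cys: positions -7 .. -1 then C
    if spec.include_thr7:
        minus7 = "T"
    else:
        while True:
            (minus7,) = _draw_safe(rng, 1, spec.background)
            if minus7 not in "ST":
                break
    minus65 = _draw_safe(rng, 2, spec.background)
    minus3 = "Q" if spec.subtype == "N" else "P"
    (minus2,) = _draw_safe(rng, 1, spec.background)
    minus1 = "Y" if rng.integers(0, 2) == 0 else "F"
    context = [minus7, *minus65, spec.subtype, minus3, minus2, minus1]

    # Cys–His segment: plant CC and CXXXC at non-overlapping offsets. Any
    # planted C could pair with the true His/Asp as a spurious triad start,
    # so the four residues upstream of each planted C are kept out of
    # {N, E, D}: a spurious candidate can then never outscore the true one,
    # and ties resolve to the smaller (true) Cys position.
    seg = _draw_safe(rng, ch, spec.background)
    cc_off = cxxxc_off = None
    if spec.include_cc and spec.include_cxxxc:
        if ch < 8:
            raise ScaffoldError("ch_spacing too small for CC plus CXXXC")
        cc_off = int(rng.integers(0, ch - 7))
        lo = cc_off + 2
        cxxxc_off = int(rng.integers(lo, ch - 4))
        if cxxxc_off < cc_off + 2:
            raise ScaffoldError("cannot place CXXXC after CC")
    elif spec.include_cc:
        if ch < 2:
            raise ScaffoldError("ch_spacing too small for CC")
        cc_off = int(rng.integers(0, ch - 1))
    elif spec.include_cxxxc:
        if ch < 5:
            raise ScaffoldError("ch_spacing too small for CXXXC")
        cxxxc_off = int(rng.integers(0, ch - 4))
    if cc_off is not None:
        seg[cc_off] = seg[cc_off + 1] = "C"
    if cxxxc_off is not None:
        seg[cxxxc_off] = seg[cxxxc_off + 4] = "C"

    spacer = _draw_safe(rng, HD_SPACING, spec.background)

    tail = _draw_safe(rng, spec.cterm_len, spec.background)
    if spec.cterm_len and spec.cterm_cys_frac > 0:
        n_cys = int(round(spec.cterm_cys_frac * spec.cterm_len))
        pos = rng.choice(spec.cterm_len, size=min(n_cys, spec.cterm_len), replace=False)
        for p in pos:
            tail[p] = "C"

    residues = "".join(nterm) + "".join(context) + "C" + "".join(seg) + "H" + "".join(spacer) + "D" + "".join(tail)

    cys_pos = spec.nterm_len + 8
    his_pos = cys_pos + ch + 1
    asp_pos = his_pos + HD_SPACING + 1

    # sanitise the 4-window upstream of each planted C (see comment above)
    chars = list(residues)
    planted_cs = []
    if cc_off is not None:
        planted_cs += [cys_pos + 1 + cc_off, cys_pos + 2 + cc_off]
    if cxxxc_off is not None:
        planted_cs += [cys_pos + 1 + cxxxc_off, cys_pos + 5 + cxxxc_off]
    for cpos in planted_cs:
        i = cpos - 1 - 4  # 0-based index of the -4 residue
        if i >= 0 and chars[i] in "NED":
            chars[i] = "A" if chars[i] != "A" else "G"
    residues = "".join(chars)

    truth = TruthRecord(
        seq_id=seq_id,
        subtype=spec.subtype,
        cys_pos=cys_pos,
        his_pos=his_pos,
        asp_pos=asp_pos,
        thr_pos=cys_pos - 7 if spec.include_thr7 else None,
        cc_positions=sorted({cys_pos + 1 + cc_off} if cc_off is not None else set()),
        cxxxc_positions=sorted({cys_pos + 1 + cxxxc_off} if cxxxc_off is not None else set()),
    )
    rec = SequenceRecord(seq_id, residues, description=f"synthetic PCS {spec.subtype}")
    return rec, truth


def generate_dataset(
    n_per_subtype: int, spec_template: ScaffoldSpec | None = None, seed: int = 0
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Generate ``3 * n_per_subtype`` scaffolds (N, E and D subtypes).

    A single seed drives a splittable generator: each record gets its own
    child seed, so the whole dataset is reproducible from one integer.
    """
    if n_per_subtype < 1:
        raise ScaffoldError("n_per_subtype must be >= 1")
    if spec_template is None:
        spec_template = ScaffoldSpec()
    root = np.random.SeedSequence(seed)
    children = root.spawn(3 * n_per_subtype)
    records, truths = [], []
    k = 0
    for subtype in ("N", "E", "D"):
        for i in range(n_per_subtype):
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            spec = replace(spec_template, subtype=subtype, seed=child_seed)
            sid = f"syn_{subtype}_{i:03d}"
            rec, truth = generate_pcs_sequence(spec, seq_id=sid)
            records.append(rec)
            truths.append(truth)
            k += 1
    return records, truths


def plant_motif(
    records: Sequence[SequenceRecord],
    consensus: str,
    occurrence_prob: float = 1.0,
    seed: int = 0,
    noise_prob: float = 0.0,
    region: tuple | None = None,
) -> tuple[list[SequenceRecord], dict[str, tuple]]:
    """Overwrite <=1 copy of ``consensus`` into each sequence (ZOOPS truth).

    Each sequence independently receives a copy with probability
    ``occurrence_prob``, at a uniform random insertable offset; with
    ``noise_prob`` each motif position is replaced by a random residue.
    ``region`` restricts the insertable offsets to a (start, end) 1-based
    inclusive window (e.g. the C-terminal tail). Returns new records plus a
    map seq_id -> (start, end) 1-based span.
    """
    w = len(consensus)
    if not 6 <= w <= 50:
        raise ValueError("consensus width must be within [6, 50]")
    if not 0.0 < occurrence_prob <= 1.0:
        raise ValueError("occurrence_prob must be in (0, 1]")
    shortest = min(len(r) for r in records)
    if w > shortest:
        raise ValueError("consensus longer than the shortest sequence")
    rng = np.random.default_rng(seed)
    out, spans = [], {}
    for rec in records:
        residues = rec.residues
        if rng.random() <= occurrence_prob:
            lo, hi = 0, len(residues) - w
            if region is not None:
                lo = max(lo, region[0] - 1)
                hi = min(hi, region[1] - w)
                if hi < lo:
                    raise ValueError(f"{rec.seq_id}: region too short for motif")
            start = int(rng.integers(lo, hi + 1))
            copy = list(consensus)
            if noise_prob > 0:
                for i in range(w):
                    if rng.random() < noise_prob:
                        copy[i] = AA20[rng.integers(0, 20)]
            residues = residues[:start] + "".join(copy) + residues[start + w:]
            spans[rec.seq_id] = (start + 1, start + w)
        out.append(SequenceRecord(rec.seq_id, residues, description=rec.description,
                                  metadata=dict(rec.metadata)))
    return out, spans


def evolve_pair(length: int, t: float, seed: int = 0) -> tuple[str, str]:
    """Simulate an ancestor/descendant pair under the JTT model.

    The ancestor is drawn from the JTT equilibrium frequencies; each site of
    the descendant is drawn from the corresponding row of P(t) = exp(Qt).
    """
    if t < 0:
        raise ValueError("divergence t must be non-negative")
    rng = np.random.default_rng(seed)
    pi = jtt.equilibrium_frequencies()
    anc_idx = rng.choice(20, size=length, p=pi)
    if t == 0:
        des_idx = anc_idx.copy()
    else:
        P = jtt.probability_matrix(t)
        u = rng.random(length)
        cum = np.cumsum(P, axis=1)
        des_idx = np.array([np.searchsorted(cum[a], x) for a, x in zip(anc_idx, u)])
        des_idx = np.minimum(des_idx, 19)
    order = jtt.ORDER
    return ("".join(order[i] for i in anc_idx), "".join(order[i] for i in des_idx))


def mutate_sequence(residues: str, t: float, seed: int = 0,
                    frozen: Sequence[int] = ()) -> str:
    """Substitute sites of an existing sequence under JTT at divergence t.

    ``frozen`` lists 1-based positions left untouched (e.g. the triad and
    its classification context), so scaffold ground truth survives the
    mutation. X residues are left as-is.
    """
    if t < 0:
        raise ValueError("divergence t must be non-negative")
    if t == 0:
        return residues
    rng = np.random.default_rng(seed)
    P = jtt.probability_matrix(t)
    frozen_set = set(frozen)
    idx = jtt.encode(residues)
    out = list(residues)
    for i, a in enumerate(idx):
        if a < 0 or (i + 1) in frozen_set:
            continue
        out[i] = jtt.ORDER[rng.choice(20, p=P[a])]
    return "".join(out)


def two_group_dataset(
    n_per_group: int = 5,
    divergence: float = 0.1,
    seed: int = 0,
    tail_motif: str | None = None,
    group1_tail: int = 8,
    group2_tail: int = 80,
) -> tuple[list[SequenceRecord], dict[str, str], dict[str, tuple], dict]:
    """Two clusters of PCS-like scaffolds for the grouping analysis.

    Two independent ancestors share the catalytic-domain segment lengths —
    a group-1 ("N") scaffold with only a short C-terminal stub and no
    conserved cysteine pairs, and a group-2 ("E") scaffold with CC/CXXXC
    and a Cys-rich tail, matching the anatomy that separates the two
    isoform groups. ``n_per_group`` descendants are evolved from each at
    the given divergence with the triad and its 7-mer context frozen.
    ``tail_motif``, when given, is planted only in the C-terminal tails of
    the group-2 descendants.

    Returns (records, seq_id -> group label in {"1", "2"}, motif spans,
    info). ``info["domain_end"]`` is the catalytic Asp position, identical
    in every record, so ``residues[:domain_end]`` is an aligned block of
    the conserved domain suitable for tree building.
    """
    root = np.random.SeedSequence(seed)
    s_anc, s_mut, s_motif = (int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(3))
    common = dict(nterm_len=45, ch_spacing=110)
    anc_n, truth_n = generate_pcs_sequence(
        ScaffoldSpec(subtype="N", include_cc=False, include_cxxxc=False,
                     cterm_len=group1_tail, cterm_cys_frac=0.02,
                     seed=s_anc, **common), "anc_N")
    anc_e, truth_e = generate_pcs_sequence(
        ScaffoldSpec(subtype="E", cterm_len=group2_tail, cterm_cys_frac=0.2,
                     seed=s_anc + 1, **common), "anc_E")

    frozen_n = list(range(truth_n.cys_pos - 7, truth_n.cys_pos + 1)) + [truth_n.his_pos, truth_n.asp_pos]
    frozen_e = list(range(truth_e.cys_pos - 7, truth_e.cys_pos + 1)) + [truth_e.his_pos, truth_e.asp_pos]

    rng = np.random.default_rng(s_mut)
    records, groups = [], {}
    for anc, frozen, label, group in ((anc_n, frozen_n, "N", "1"), (anc_e, frozen_e, "E", "2")):
        for i in range(n_per_group):
            sub_seed = int(rng.integers(0, 2**31))
            res = mutate_sequence(anc.residues, divergence, seed=sub_seed, frozen=frozen)
            sid = f"g{group}_{label}_{i:02d}"
            records.append(SequenceRecord(sid, res, description=f"group {group}"))
            groups[sid] = group

    spans: dict[str, tuple] = {}
    if tail_motif is not None:
        tail_start = truth_e.asp_pos + 1
        group2 = [r for r in records if groups[r.seq_id] == "2"]
        planted, spans = plant_motif(group2, tail_motif, occurrence_prob=1.0,
                                     seed=s_motif, region=(tail_start, len(anc_e)))
        by_id = {r.seq_id: r for r in planted}
        records = [by_id.get(r.seq_id, r) for r in records]
    info = {"domain_end": truth_e.asp_pos,
            "truth_n": truth_n, "truth_e": truth_e}
    return records, groups, spans, info
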