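"""ProtParam-style physicochemical profile, computed from first principles.

Average molecular weight, isoelectric point (Bjellqvist pKa set, bisection
on the Henderson–Hasselbalch net-charge function), charged-residue
percentages, the Guruprasad dipeptide instability index with its < 40
stability threshold, and Ikai's aliphatic index. Constant tables (average
residue masses, DIWV dipeptide weights) come from Biopython's published
data modules; the formulas are implemented here.

Ambiguity code X contributes to sequence length (percentages use total
length) but 0 to mass/charge/instability sums, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV

log = logging.getLogger(__name__)

_WATER = 18.0153  # average mass of one water, Da

#: average residue (not free amino acid) masses, Da
RESIDUE_MASS = {aa: w - _WATER for aa, w in protein_weights.items()}

#: Bjellqvist pKa values as used by the Expasy ProtParam pI computation
POSITIVE_PKS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
NEGATIVE_PKS = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PK_NTERMINAL = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
                "V": 7.44, "E": 7.7, "G": 7.5}
PK_CTERMINAL = {"D": 4.55, "E": 4.75}

INSTABILITY_THRESHOLD = 40.0


@dataclass
class PhyschemProfile:
    """The per-protein physicochemical feature block."""

    length: int
    mw_kda: float
    pI: float
    pct_neg: float
    pct_pos: float
    instability: float
    stable: bool
    aliphatic: float


def _strip_x(residues: str, what: str) -> str:
    if "X" in residues:
        log.warning("sequence contains X; excluded from %s", what)
        return residues.replace("X", "")
    return residues


def molecular_weight(residues: str) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    if not residues:
        raise ValueError("empty sequence")
    core = _strip_x(residues, "molecular weight")
    return (sum(RESIDUE_MASS[aa] for aa in core) + _WATER) / 1000.0


def net_charge(residues: str, ph: float) -> float:
    """Net charge at a given pH (Henderson–Hasselbalch over charged groups)."""
    seq = _strip_x(residues, "charge")
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}

    def pos(pk: float, n: float) -> float:
        return n / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float, n: float) -> float:
        return n / (1.0 + 10.0 ** (pk - ph))

    nterm_pk = PK_NTERMINAL.get(seq[0], POSITIVE_PKS["Nterm"]) if seq else POSITIVE_PKS["Nterm"]
    cterm_pk = PK_CTERMINAL.get(seq[-1], NEGATIVE_PKS["Cterm"]) if seq else NEGATIVE_PKS["Cterm"]
    charge = pos(nterm_pk, 1.0) - neg(cterm_pk, 1.0)
    for aa, pk in (("K", POSITIVE_PKS["K"]), ("R", POSITIVE_PKS["R"]),
                   ("H", POSITIVE_PKS["H"])):
        charge += pos(pk, counts[aa])
    for aa, pk in (("D", NEGATIVE_PKS["D"]), ("E", NEGATIVE_PKS["E"]),
                   ("C", NEGATIVE_PKS["C"]), ("Y", NEGATIVE_PKS["Y"])):
        charge -= neg(pk, counts[aa])
    return charge


def isoelectric_point(residues: str, tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection to ``tol``.

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    if not residues:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(residues, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def percent_negative(residues: str) -> float:
    """100 * (D + E) / total length."""
    if not residues:
        raise ValueError("empty sequence")
    return 100.0 * (residues.count("D") + residues.count("E")) / len(residues)


def percent_positive(residues: str) -> float:
    """100 * (R + K) / total length."""
    if not residues:
        raise ValueError("empty sequence")
    return 100.0 * (residues.count("R") + residues.count("K")) / len(residues)


def instability_index(residues: str) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV dipeptide weights.

    Values below 40 predict a stable protein. Dipeptides containing X
    contribute 0.
    """
    if len(residues) < 2:
        raise ValueError("instability index needs at least 2 residues")
    if "X" in residues:
        log.warning("sequence contains X; affected dipeptides contribute 0")
    total = 0.0
    for a, b in zip(residues, residues[1:]):
        if a == "X" or b == "X":
            continue
        total += DIWV[a][b]
    return 10.0 / len(residues) * total


def aliphatic_index(residues: str) -> float:
    """Ikai aliphatic index: X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu).

    X_aa is the mole percent of the residue over the total length.
    """
    if not residues:
        raise ValueError("empty sequence")
    n = len(residues)
    x = {aa: 100.0 * residues.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def profile(residues: str) -> PhyschemProfile:
    """Compute the full physicochemical profile of one sequence."""
    inst = instability_index(residues)
    return PhyschemProfile(
        length=len(residues),
        mw_kda=molecular_weight(residues),
        pI=isoelectric_point(residues),
        pct_neg=percent_negative(residues),
        pct_pos=percent_positive(residues),
        instability=inst,
        stable=inst < INSTABILITY_THRESHOLD,
        aliphatic=aliphatic_index(residues),
    )
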