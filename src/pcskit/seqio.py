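"""Reading and writing the file formats the pipeline touches.

FASTA (60-column wrapped), tab-separated metadata / annotation tables, and
Newick trees. All coordinates in emitted tables are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

log = logging.getLogger(__name__)

#: the 20 standard residues plus the ambiguity code X
ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

#: habitat codes: soil, fresh water, marine, or a combination
HABITATS = {"S", "FW", "M", "mixed"}

#: column order of the annotation table. The first block mirrors the paper's
#: per-protein feature table (form 7-mer, length, MW, triad spacings, Cys
#: count, ProtParam block); classification columns are appended.
ANNOTATION_COLUMNS = [
    "seq_id",
    "form",
    "length",
    "mw_kda",
    "c_h_distance",
    "h_d_distance",
    "cys_count",
    "pI",
    "pct_neg",
    "pct_pos",
    "instability",
    "stable",
    "aliphatic",
    "subtype",
    "group",
    "ck2",
    "cc",
    "cxxxc",
    "conserved_cys",
    "cterm_tail",
]


@dataclass
class SequenceRecord:
    """One protein sequence with optional per-taxon metadata."""

    seq_id: str
    residues: str
    description: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.seq_id}: empty sequence")
        self.residues = self.residues.upper()
        for i, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"{self.seq_id}: illegal residue {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file, preserving record order.

    Multi-line records are concatenated; the description is everything after
    the first whitespace in the header. Illegal residues raise ``ValueError``
    naming the record and position; an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), description=desc))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA; byte-deterministic."""
    records = list(records)
    ids = [r.seq_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sequence ids")
    bio = [
        _BioRecord(Seq(r.residues), id=r.seq_id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def _normalise_habitat(raw: str) -> str:
    raw = raw.strip()
    if "/" in raw or raw.lower() == "mixed":
        return "mixed"
    return raw


def read_metadata(path: str | Path, records: Sequence[SequenceRecord] | None = None) -> dict[str, dict]:
    """Read a per-sequence metadata TSV keyed by seq_id.

    Recognised columns: taxon, lineage_class, habitat, exon_count,
    group_label. Habitat combinations like ``FW/M`` are stored as ``mixed``.
    If *records* is given, their metadata dicts are updated in place and
    unknown seq_ids trigger a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed metadata TSV {path}: {exc}") from exc
    if "seq_id" not in df.columns:
        raise ValueError(f"{path}: metadata TSV needs a 'seq_id' column")
    meta: dict[str, dict] = {}
    for _, row in df.iterrows():
        entry = {}
        for key in ("taxon", "lineage_class", "habitat", "exon_count", "group_label"):
            if key in df.columns and pd.notna(row[key]):
                val = str(row[key])
                if key == "habitat":
                    val = _normalise_habitat(val)
                elif key == "exon_count":
                    val = int(val)
                entry[key] = val
        meta[str(row["seq_id"])] = entry
    if records is not None:
        known = {r.seq_id: r for r in records}
        for sid, entry in meta.items():
            if sid in known:
                known[sid].metadata.update(entry)
            else:
                warnings.warn(f"metadata for unknown seq_id {sid!r}", stacklevel=2)
    return meta


def write_annotation_table(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write the per-sequence annotation table (TSV, LF, header row).

    Each row dict may omit fields (e.g. sequences with no detected triad);
    missing values are written as NA. Column order is fixed by
    :data:`ANNOTATION_COLUMNS`.
    """
    df = pd.DataFrame(list(rows))
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[ANNOTATION_COLUMNS]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="NA")
    return df


def write_newick(tree, path: str | Path) -> None:
    """Serialise a :class:`pcskit.phylo.TreeNode` to a Newick file.

    Bootstrap supports, when present, appear as internal-node labels.
    """
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
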