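"""End-to-end orchestration: annotate, tree, motifs, statistics.

Pure dataflow between stages via files: each stage reads its inputs,
writes its outputs, and never mutates another stage's products, so any
stage can be re-run alone and reproduces its outputs from the same seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, motifs, physchem, phylo, seqio, triad

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for a full run; mirrors the CLI flags."""

    fasta: str = ""
    metadata: str | None = None
    out_dir: str = "pcskit_out"
    triad_mode: str = "auto"
    ch_bounds: tuple = triad.DEFAULT_CH_BOUNDS
    bootstrap: int = 100
    nmotifs: int = 15
    wmin: int = 6
    wmax: int = 50
    oops: bool = False
    distance_cap: float = phylo.DEFAULT_DISTANCE_CAP
    seed: int = 0
    group_col: str = "group"
    stat_parameters: tuple = ("pI", "pct_neg", "pct_pos", "instability", "aliphatic")

    def validate(self) -> None:
        if self.fasta and not Path(self.fasta).exists():
            raise FileNotFoundError(self.fasta)
        if self.metadata is not None and not Path(self.metadata).exists():
            raise FileNotFoundError(self.metadata)
        if self.triad_mode not in {"auto", "align", "scan"}:
            raise ValueError(f"bad triad mode {self.triad_mode!r}")


def annotate_records(records, references=None, mode: str = "auto",
                     ch_bounds=triad.DEFAULT_CH_BOUNDS) -> list[dict]:
    """One annotation row per sequence (triad, classification, physchem).

    Sequences with no detectable triad get NA feature fields and a log
    line; they are retained in the table.
    """
    rows = []
    for rec in records:
        row: dict = {"seq_id": rec.seq_id}
        prof = physchem.profile(rec.residues)
        row.update(length=prof.length, mw_kda=round(prof.mw_kda, 2),
                   pI=round(prof.pI, 2), pct_neg=round(prof.pct_neg, 2),
                   pct_pos=round(prof.pct_pos, 2),
                   instability=round(prof.instability, 2), stable=prof.stable,
                   aliphatic=round(prof.aliphatic, 2))
        try:
            ann = triad.detect_triad(rec, references=references,
                                     ch_bounds=ch_bounds, mode=mode)
        except ValueError as exc:
            log.warning("%s: %s", rec.seq_id, exc)
            ann = None
        if ann is None:
            log.warning("%s: no triad; classification columns set to NA", rec.seq_id)
            rows.append(row)
            continue
        call = classify.classify_isoform(rec, ann)
        row.update(
            form=ann.context7,
            c_h_distance=ann.c_h_distance,
            h_d_distance=ann.h_d_distance,
            cys_count=call.cys_total,
            subtype=call.subtype,
            group=call.group,
            ck2=call.ck2_competent,
            cc=",".join(map(str, call.cc_hits)) or "-",
            cxxxc=",".join(map(str, call.cxxxc_hits)) or "-",
            conserved_cys=call.conserved_cys_count,
            cterm_tail=call.cterm_tail_length,
        )
        rows.append(row)
    return rows


def stacked_alignment(records, reference: triad.ReferenceProtein) -> tuple[list[str], list[str]]:
    """Reference-anchored stacking of pairwise alignments.

    Each sequence is aligned to the reference and projected onto the
    reference columns (insertions relative to the reference are dropped);
    the result is a rectangular block suitable for distance estimation
    with pairwise gap deletion. If all inputs already share one length
    they are taken as aligned and returned unchanged.
    """
    if len({len(r) for r in records}) == 1:
        return [r.seq_id for r in records], [r.residues for r in records]
    labels, rows = [], []
    ref_len = len(reference.residues)
    for rec in records:
        aln = triad.align_global(rec.residues, reference.residues)
        mapped = triad.map_positions(aln, list(range(1, ref_len + 1)))
        row = "".join(
            rec.residues[m - 1] if m is not None else "-" for m in mapped
        )
        labels.append(rec.seq_id)
        rows.append(row)
    return labels, rows


def run_annotate(config: PipelineConfig) -> pd.DataFrame:
    """Annotate stage: FASTA in, annotation TSV out."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = seqio.read_fasta(config.fasta)
    if config.metadata:
        seqio.read_metadata(config.metadata, records)
    rows = annotate_records(records, mode=config.triad_mode,
                            ch_bounds=config.ch_bounds)
    return seqio.write_annotation_table(rows, out / "annotation.tsv")


def run_phylo(config: PipelineConfig) -> phylo.TreeNode:
    """Tree stage: JTT ML distances + NJ + bootstrap, Newick out."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = seqio.read_fasta(config.fasta)
    labels, aligned = stacked_alignment(records, triad.synthetic_reference())
    dm = phylo.distance_matrix(labels, aligned, cap=config.distance_cap)
    pd.DataFrame(dm.matrix, index=labels, columns=labels).to_csv(
        out / "distances.tsv", sep="\t", lineterminator="\n")
    tree = phylo.bootstrap_supports(labels, aligned,
                                    n_replicates=config.bootstrap,
                                    seed=config.seed, cap=config.distance_cap)
    seqio.write_newick(tree, out / "tree.nwk")
    return tree


def run_motifs(config: PipelineConfig) -> list[motifs.MotifModel]:
    """Motif stage: ZOOPS EM discovery, report + presence table out."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = seqio.read_fasta(config.fasta)
    found = motifs.discover_motifs(records, nmotifs=config.nmotifs,
                                   wmin=config.wmin, wmax=config.wmax,
                                   seed=config.seed, oops=config.oops)
    bg = motifs.background_frequencies(records)
    motifs.write_motif_report(found, out / "motifs.txt", background=bg)
    table = motifs.motif_presence_table(found, records, background=bg)
    pd.DataFrame(table, index=[r.seq_id for r in records],
                 columns=[f"motif_{k+1}" for k in range(len(found))]).to_csv(
        out / "motif_presence.tsv", sep="\t", lineterminator="\n")
    return found


def run_stats(config: PipelineConfig, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Statistics stage: per-parameter group comparison TSV."""
    from . import stats as st

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if annotation is None:
        annotation = pd.read_csv(out / "annotation.tsv", sep="\t")
    table = annotation.dropna(subset=[config.group_col])
    report = st.compare_table(table, config.group_col,
                              list(config.stat_parameters))
    report.to_csv(out / "stats.tsv", sep="\t", index=False, lineterminator="\n")
    return report


def run_all(config: PipelineConfig) -> dict:
    """Full run; returns a manifest of outputs with content checksums."""
    config.validate()
    out = Path(config.out_dir)
    annotation = run_annotate(config)
    run_phylo(config)
    run_motifs(config)
    groups = annotation[config.group_col].dropna().unique() if config.group_col in annotation else []
    if len(groups) == 2:
        run_stats(config, annotation)
    else:
        log.info("stats stage skipped: grouping has %d levels", len(groups))
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.is_file():
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
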