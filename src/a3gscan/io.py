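"""Readers and writers for the interchange formats.

All coordinates are 0-based half-open internally; BED is native, aligned
FASTA / MAF carry one record per species, and TSV tables use headers so the
stage outputs stay greppable and diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import array_to_seq, seq_to_array
from .errors import FormatError

SPECIES_ROLES = ("target", "sister", "outgroup1", "outgroup2")

MUTATION_COLUMNS = ["chrom", "pos0", "anc", "der", "lineage", "context", "window"]
TRUTH_COLUMNS = ["chrom", "pos0", "lineage", "anc", "der", "event_id", "event_class"]


@dataclass
class Alignment:
    """A four-species alignment of one chromosome, target coordinates.

    ``species`` maps role -> uint8 sequence array; all sequences have equal
    length (the synthetic alignments contain no indels, so target position
    equals alignment column).
    """

    chrom: str
    species: dict[str, np.ndarray]

    def __post_init__(self):
        lengths = {k: v.size for k, v in self.species.items()}
        if len(set(lengths.values())) != 1:
            raise FormatError(f"aligned sequences differ in length: {lengths}")
        missing = [r for r in SPECIES_ROLES if r not in self.species]
        if missing:
            raise FormatError(f"alignment lacks roles {missing}")

    @property
    def length(self) -> int:
        return next(iter(self.species.values())).size

    def reverse_complement(self) -> "Alignment":
        from ._seq import revcomp_array
        return Alignment(self.chrom,
                         {k: revcomp_array(v) for k, v in self.species.items()})


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(array_to_seq(aln.species[r])), id=r, description=aln.chrom)
               for r in SPECIES_ROLES]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | Path, chrom: str | None = None) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    species = {rec.id: seq_to_array(str(rec.seq)) for rec in records}
    if chrom is None:
        chrom = records[0].description.split()[-1] if records else "chr?"
    return Alignment(chrom, species)


def write_alignment_maf(aln: Alignment, path: str | Path) -> None:
    length = aln.length
    records = []
    for role in SPECIES_ROLES:
        rec = SeqRecord(Seq(array_to_seq(aln.species[role])),
                        id=f"{role}.{aln.chrom}")
        rec.annotations = {"start": 0, "size": length, "strand": 1, "srcSize": length}
        records.append(rec)
    AlignIO.write([MultipleSeqAlignment(records)], str(path), "maf")


def read_alignment_maf(path: str | Path) -> Alignment:
    blocks = list(AlignIO.parse(str(path), "maf"))
    if len(blocks) != 1:
        raise FormatError(f"expected a single MAF block, found {len(blocks)}")
    species = {}
    chrom = "chr?"
    for rec in blocks[0]:
        role, _, src_chrom = rec.id.partition(".")
        species[role] = seq_to_array(str(rec.seq))
        if role == "target" and src_chrom:
            chrom = src_chrom
    return Alignment(chrom, species)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/BED5, 0-based half-open.  Returns chrom,start,end[,name,level]."""
    names = ["chrom", "start", "end", "name", "level"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :5]
    df.columns = names[: df.shape[1]]
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise FormatError(f"{path}: interval start > end at {bad.chrom}:{bad.start}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path, level_col: str | None = None) -> None:
    cols = df[["chrom", "start", "end"]].copy()
    if level_col is not None and level_col in df:
        cols["name"] = df.get("name", ".")
        cols["level"] = df[level_col]
    cols.to_csv(path, sep="\t", header=False, index=False)


def write_mutations(muts: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in MUTATION_COLUMNS if c in muts.columns]
    muts[cols].to_csv(path, sep="\t", index=False)


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos0", "anc", "der"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: mutation table lacks columns {needed - set(df.columns)}")
    return df


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_allele_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks[["chrom", "pos0", "lineage", "allele"]].to_csv(path, sep="\t", index=False)


def read_allele_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"chrom", "pos0", "lineage", "allele"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: allele track lacks columns {needed - set(df.columns)}")
    return df


def write_fixture(sim, outdir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory for one simulation.

    Files: aligned multi-FASTA and MAF of the four species, truth TSV,
    per-lineage allele TSV, one BED5 per annotation track, and the YAML
    configuration (so the run can be reproduced byte-for-byte).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln = Alignment(sim.chrom, sim.sequences)
    paths = {
        "alignment_fasta": outdir / "alignment.fa",
        "alignment_maf": outdir / "alignment.maf",
        "truth": outdir / "truth.tsv",
        "allele_tracks": outdir / "allele_tracks.tsv",
        "config": outdir / "config.yaml",
    }
    write_alignment_fasta(aln, paths["alignment_fasta"])
    write_alignment_maf(aln, paths["alignment_maf"])
    write_truth(sim.truth, paths["truth"])
    write_allele_tracks(sim.allele_tracks, paths["allele_tracks"])
    for label, df in sim.annotations.items():
        p = outdir / f"{label}.bed"
        write_bed(df.assign(name=label), p, level_col="level")
        paths[f"bed_{label}"] = p
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(sim.config.to_dict(), fh, sort_keys=True)
    return paths
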