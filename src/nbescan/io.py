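"""Readers, writers and run manifests for the pipeline's file formats.

Sequence formats go through Biopython; genome slices for BED-defined TSS
windows go through pyfaidx.  BED inputs are 0-based half-open; TSS = start
on the + strand and end-1 on the - strand; minus-strand windows are
reverse-complemented so offsets always run 5'->3' along the gene.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .motif import canonicalize
from .scan import PromoterWindow, WINDOW_START, WINDOW_END

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "read_tss_bed",
    "read_group_table",
    "read_titration_tsv",
    "write_run_manifest",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) records; sequences uppercased with U -> T."""
    records = [(rec.id, canonicalize(str(rec.seq)))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        logger.warning("no records in %s", path)
    return records


def read_fastq(path) -> list[tuple[str, str]]:
    """(id, sequence) from FASTQ; qualities are parsed but ignored."""
    records = [(rec.id, canonicalize(str(rec.seq)))
               for rec in SeqIO.parse(str(path), "fastq")]
    if not records:
        logger.warning("no records in %s", path)
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i:i + 70] + "\n")


def read_group_table(path) -> dict[str, str]:
    """Two-column TSV (gene_id, group) -> mapping."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["gene_id", "group"], dtype=str, comment="#")
    return dict(zip(frame["gene_id"], frame["group"]))


def read_tss_bed(bed_path, genome_fasta,
                 window: tuple[int, int] = (WINDOW_START, WINDOW_END),
                 groups: dict[str, str] | None = None
                 ) -> list[PromoterWindow]:
    """Extract TSS-anchored windows from a genome given a 6-column BED.

    Windows extending past a contig edge are skipped with a warning.
    """
    from pyfaidx import Fasta

    groups = groups or {}
    genome = Fasta(str(genome_fasta))
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    lo, hi = window
    windows = []
    for row in bed.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"bad strand {row.strand!r} for {row.name}")
        contig = genome[row.chrom]
        if row.strand == "+":
            tss = int(row.start)
            begin, stop = tss + lo, tss + hi + 1
        else:
            tss = int(row.end) - 1
            begin, stop = tss - hi, tss - lo + 1
        if begin < 0 or stop > len(contig):
            logger.warning("window for %s out of contig bounds; skipped",
                           row.name)
            continue
        seq = str(contig[begin:stop])
        if row.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        windows.append(PromoterWindow(
            gene_id=row.name, sequence=canonicalize(seq),
            group=groups.get(row.name), start_offset=lo,
        ))
    return windows


def read_titration_tsv(path, assay: str = "femsa", rna: str = "",
                       protein: str = ""):
    """One titration TSV -> HillModel (see binding.HillModel.from_dataframe)."""
    from .binding import HillModel

    frame = pd.read_csv(path, sep="\t")
    return HillModel.from_dataframe(frame, assay=assay, rna=rna,
                                    protein=protein)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(path, config: dict, inputs: list = (),
                       version: str | None = None) -> dict:
    """JSON manifest (version, config, input checksums) for exact re-runs."""
    if version is None:
        from . import __version__ as version
    manifest = {
        "version": version,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
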