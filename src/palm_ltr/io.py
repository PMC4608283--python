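"""File-format helpers: FASTA, FASTQ, GFF3, BED, TSV and the bundled libraries.

Coordinates are 0-based half-open everywhere in memory; GFF3 output converts
to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class DomainRef:
    """One labelled amino-acid reference: `>id|kind|superfamily|lineage`."""

    ref_id: str
    kind: str
    superfamily: str
    lineage: str
    sequence: str


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence}; raises on unparseable records."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"unnamed FASTA record in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]],
                width: int = 60) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
            fh, "fasta")
    # Biopython wraps at 60 columns, matching the stated convention
    assert width == 60, "only 60-column wrapping is supported"


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def load_domain_library(path: str | Path | None = None) -> list[DomainRef]:
    """Load the labelled domain library (bundled synthetic stand-in by default)."""
    if path is None:
        source = resources.files("palm_ltr.data") / "synthetic_domain_refs.faa"
        path = str(source)
    refs = []
    for rec_id, seq in read_fasta(path).items():
        parts = rec_id.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"domain reference header {rec_id!r} is not id|kind|superfamily|lineage")
        refs.append(DomainRef(parts[0], parts[1], parts[2], parts[3], seq))
    if not refs:
        raise ValueError("empty domain reference library")
    return refs


def load_trna_library(path: str | Path | None = None) -> dict[str, str]:
    """tRNA 3'-end sequences for the PBS search (bundled stand-in by default)."""
    if path is None:
        source = resources.files("palm_ltr.data") / "synthetic_trna_three_prime.fa"
        path = str(source)
    return read_fasta(path)


def write_gff3(path: str | Path, features: Iterable[tuple]) -> None:
    """Write (seqid, source, type, start0, end0, score, strand, attrs) features.

    ``start0``/``end0`` are 0-based half-open and converted to GFF3 1-based
    inclusive on output; ``attrs`` is a dict.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, start0, end0, score, strand, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            score_s = f"{score:.3f}" if isinstance(score, float) else str(score)
            fh.write(f"{seqid}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t"
                     f"{score_s}\t{strand}\t.\t{attr_s}\n")


def write_bed(path: str | Path, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    """Write (seqid, start, end, name) as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for seqid, start, end, name in intervals:
            fh.write(f"{seqid}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out
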