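"""Sequence I/O and coordinate primitives.

All internal coordinates are 0-based, half-open. GenBank emission converts to
the flat-file format's 1-based inclusive locations; the conversion is
bijective on valid intervals. DNA is uppercase text over {A, C, G, T, N};
other IUPAC ambiguity codes are rejected because downstream design arithmetic
assumes unambiguous bases. ``U`` on input is mapped to ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    BoundsError,
    DuplicateIdError,
    OutOfBoundsError,
)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Fixed LOCUS date so that re-running a design emits byte-identical files.
_GENBANK_DATE = "01-JAN-2000"


def check_dna(seq: str, context: str = "sequence") -> None:
    """Raise :class:`AlphabetError` unless ``seq`` is over {A,C,G,T,N}."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{context} contains characters outside ACGTN: {sorted(bad)!r}"
        )


def revcomp(seq: str) -> str:
    """Reverse complement of an {A,C,G,T,N} string (N maps to N)."""
    check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a sequence and its reverse complement.

    Used for strand-independent spacer identity when the array leader
    orientation is unknown.
    """
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass
class GenomeRecord:
    """One contig: identifier, sequence, and topology (linear/circular)."""

    contig_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        check_dna(self.sequence, f"contig {self.contig_id!r}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"contig {self.contig_id!r}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """Gene locus in 0-based half-open genome coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Interval:
    """Half-open genomic interval, optionally stranded.

    On circular contigs ``end`` may exceed the contig length by at most one
    wrap; :func:`extract_interval` normalizes the origin crossing.
    """

    contig_id: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


def read_fasta(path, topology: str = "linear") -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is mapped to T; any residue outside
    {A,C,G,T,N} raises :class:`AlphabetError`, and duplicate headers raise
    :class:`DuplicateIdError`.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA header {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(GenomeRecord(rec.id, seq, topology))
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    """Write records to FASTA with fixed line width (deterministic output)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def extract_interval(genome: GenomeRecord, iv: Interval) -> str:
    """Substring of the genome for ``iv``; minus-strand intervals are
    reverse complemented; circular contigs may wrap across the origin."""
    n = len(genome.sequence)
    start, end = iv.start, iv.end
    if genome.topology == "circular":
        if end - start > n:
            raise OutOfBoundsError(
                f"interval of length {end - start} exceeds circular contig of {n} bp"
            )
        if start < 0:
            start += n
            end += n
        start %= n
        end = start + (iv.end - iv.start)
        sub = (genome.sequence + genome.sequence)[start:end]
    else:
        if start < 0 or end > n:
            raise OutOfBoundsError(
                f"interval [{iv.start}, {iv.end}) outside linear contig of {n} bp"
            )
        sub = genome.sequence[start:end]
    return revcomp(sub) if iv.strand == "-" else sub


def write_genbank(
    record_name: str,
    sequence: str,
    features: Sequence[tuple[str, Interval, str]],
    path,
    circular: bool = False,
) -> None:
    """Emit a GenBank flat file with 1-based inclusive feature locations.

    ``features`` is a list of ``(label, interval, feature_type)``;
    minus-strand intervals are written with complement() notation.
    """
    n = len(sequence)
    seq_features = []
    for label, iv, ftype in features:
        if iv.start < 0 or iv.end > n:
            raise BoundsError(
                f"feature {label!r} at [{iv.start}, {iv.end}) outside sequence of {n} bp"
            )
        strand = -1 if iv.strand == "-" else 1
        seq_features.append(
            SeqFeature(
                SimpleLocation(iv.start, iv.end, strand=strand),
                type=ftype or "misc_feature",
                qualifiers={"label": [label]},
            )
        )
    name = (record_name or "record")[:16].replace(" ", "_")
    rec = SeqRecord(
        Seq(sequence),
        id=name,
        name=name,
        description="",
        features=seq_features,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if circular else "linear",
            "data_file_division": "SYN",
            "date": _GENBANK_DATE,
        },
    )
    SeqIO.write(rec, str(path), "genbank")


def _sniff_gene_table(path) -> str:
    text = Path(path).read_text()
    for line in text.splitlines():
        if line.startswith("##gff-version"):
            return "gff3"
        if line.startswith("#") or not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) >= 9 and "=" in cols[8]:
            return "gff3"
        return "tsv"
    return "tsv"


def read_gene_table(path, fmt: Optional[str] = None) -> list[GeneFeature]:
    """Read gene annotations from GFF3 (``type == gene``, ``ID=`` attribute)
    or a minimal 5-column TSV (gene_id, contig, start, end, strand).

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; the TSV is taken to already use it.
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        if suffix in (".gff", ".gff3"):
            fmt = "gff3"
        elif suffix in (".tsv", ".txt", ".tab"):
            fmt = "tsv"
        else:
            fmt = _sniff_gene_table(path)
    genes: list[GeneFeature] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if fmt == "gff3":
            if len(cols) < 9 or cols[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise ValueError(f"gene line without ID attribute: {line!r}")
            feat = GeneFeature(gene_id, cols[0], int(cols[3]) - 1, int(cols[4]), cols[6])
        else:
            if len(cols) < 5:
                raise ValueError(f"gene TSV line with <5 columns: {line!r}")
            if not cols[2].lstrip("-").isdigit():  # header row
                continue
            feat = GeneFeature(cols[0], cols[1], int(cols[2]), int(cols[3]), cols[4])
        if feat.gene_id in seen:
            raise DuplicateIdError(f"duplicate gene id {feat.gene_id!r} in {path}")
        seen.add(feat.gene_id)
        genes.append(feat)
    return genes


def write_gene_table(genes: Iterable[GeneFeature], path) -> None:
    """Write genes as the minimal TSV accepted by :func:`read_gene_table`."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig_id\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.contig_id}\t{g.start}\t{g.end}\t{g.strand}\n")
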