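"""Genome and annotation I/O, ORF finding, translation and basic stats.

Coordinates are 0-based half-open on the forward strand throughout the
package; GenBank and tabular interchange formats use 1-based inclusive
coordinates and are converted on read/write.  Translation uses the
bacterial code (NCBI table 11) with the initiator codon always rendered
as methionine.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
TRANSLATION_TABLE = 11
FASTA_WRAP = 70


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence with topology and free-text description."""

    id: str
    sequence: str
    topology: str = "linear"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("genome record requires a non-empty id")
        if not self.sequence:
            raise ParseError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"genome {self.id!r}: characters outside ACGTN: {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"genome {self.id!r}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """An ORF on a genome: 0-based half-open span, strand and protein."""

    orf_id: str
    start: int
    end: int
    strand: str
    protein: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"orf {self.orf_id!r}: bad span {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"orf {self.orf_id!r}: bad strand {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class AnnotatedPhage:
    """A genome together with its ordered ORF complement."""

    genome: GenomeRecord
    orfs: list[OrfRecord] = field(default_factory=list)
    host: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.orfs = sorted(self.orfs, key=lambda o: (o.start, o.end))
        seen: set[str] = set()
        for orf in self.orfs:
            if orf.end > len(self.genome):
                raise ValueError(
                    f"phage {self.genome.id!r}: orf {orf.orf_id!r} exceeds genome"
                )
            if orf.orf_id in seen:
                raise ValueError(
                    f"phage {self.genome.id!r}: duplicate orf id {orf.orf_id!r}"
                )
            seen.add(orf.orf_id)

    @property
    def id(self) -> str:
        return self.genome.id

    def proteins(self) -> dict[str, str]:
        """Mapping of globally unique protein ids to sequences."""
        return {f"{self.id}|{o.orf_id}": o.protein for o in self.orfs}


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_cds(dna: str, *, strand: str = "+") -> str:
    """Translate a CDS span (table 11), dropping one trailing stop if present.

    The initiator codon is always rendered as M regardless of whether it
    is ATG, GTG or TTG.
    """
    if strand == "-":
        dna = reverse_complement(dna)
    if len(dna) % 3 != 0:
        raise ValueError(f"CDS length {len(dna)} not divisible by 3")
    protein = str(Seq(dna).translate(table=TRANSLATION_TABLE))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    if protein:
        protein = "M" + protein[1:]
    return protein


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read nucleotide FASTA; sequences are uppercased and validated."""
    path = Path(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(
            GenomeRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write FASTA wrapped at 70 columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), FASTA_WRAP):
                fh.write(rec.sequence[i : i + FASTA_WRAP] + "\n")


def write_protein_fasta(proteins: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def _orfs_from_genbank(path: Path, genome: GenomeRecord) -> list[OrfRecord]:
    rec = SeqIO.read(str(path), "genbank")
    orfs: list[OrfRecord] = []
    n = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        n += 1
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "+" if (feat.location.strand or 1) >= 0 else "-"
        if end > len(genome) or start < 0:
            raise ParseError(
                f"{path}: CDS {start + 1}..{end} outside genome {genome.id!r}"
            )
        orf_id = (
            feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("gene", [None])[0]
            or f"cds{n}"
        )
        label = feat.qualifiers.get("product", [None])[0]
        translation = feat.qualifiers.get("translation", [None])[0]
        if translation is None:
            translation = translate_cds(genome.sequence[start:end], strand=strand)
        orfs.append(
            OrfRecord(
                orf_id=orf_id,
                start=start,
                end=end,
                strand=strand,
                protein=translation,
                label=label,
            )
        )
    return orfs


def _orfs_from_table(path: Path, genome: GenomeRecord) -> list[OrfRecord]:
    """TSV: phage_id, orf_id, start_1based, end_1based, strand, label."""
    orfs: list[OrfRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("phage_id", "genome_id"):  # header
                continue
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 columns")
            phage_id, orf_id, s1, e1, strand = parts[:5]
            label = parts[5] if len(parts) > 5 and parts[5] else None
            if phage_id != genome.id:
                continue
            start, end = int(s1) - 1, int(e1)
            if end > len(genome) or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: CDS {s1}..{e1} outside genome {genome.id!r}"
                )
            protein = translate_cds(genome.sequence[start:end], strand=strand)
            orfs.append(OrfRecord(orf_id, start, end, strand, protein, label))
    return orfs


def read_annotations(path: str | Path, genome: GenomeRecord) -> AnnotatedPhage:
    """Read CDS annotations (GenBank flat file or the tabular ORF format).

    GenBank is detected by the leading LOCUS line; anything else is
    parsed as the TSV format.  Coordinates in both formats are 1-based
    inclusive and converted to internal 0-based half-open.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(5)
    if head.startswith("LOCUS"):
        orfs = _orfs_from_genbank(path, genome)
    else:
        orfs = _orfs_from_table(path, genome)
    return AnnotatedPhage(genome=genome, orfs=orfs)


def write_annotations(phage: AnnotatedPhage, path: str | Path) -> None:
    """Write the tabular ORF format (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("phage_id\torf_id\tstart_1based\tend_1based\tstrand\tlabel\n")
        for o in phage.orfs:
            fh.write(
                f"{phage.id}\t{o.orf_id}\t{o.start + 1}\t{o.end}\t{o.strand}\t"
                f"{o.label or ''}\n"
            )


def _scan_strand(seq: str, strand: str, glen: int, min_codons: int,
                 starts: frozenset[str]) -> Iterator[tuple[int, int, str, str]]:
    """Yield (fwd_start, fwd_end, strand, protein) for longest-per-stop ORFs."""
    n = len(seq)
    for frame in range(3):
        pending: int | None = None  # earliest open start codon in frame
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if pending is not None:
                    ncod = (pos + 3 - pending) // 3
                    if ncod >= min_codons:
                        dna = seq[pending : pos + 3]
                        try:
                            protein = translate_cds(dna)
                        except ValueError:
                            protein = None
                        if protein is not None:
                            if strand == "+":
                                yield pending, pos + 3, "+", protein
                            else:
                                # map back to forward-strand coordinates
                                yield glen - (pos + 3), glen - pending, "-", protein
                    pending = None
            elif pending is None and codon in starts:
                pending = pos


def find_orfs(
    genome: GenomeRecord,
    min_codons: int = 30,
    starts: Iterable[str] = ("ATG", "GTG", "TTG"),
) -> list[OrfRecord]:
    """Simple longest-ORF-per-stop finder on both strands.

    Each ORF runs from an allowed start codon to the first in-frame stop
    and spans at least ``min_codons`` codons including the stop.  Nested
    ORFs sharing a stop are collapsed to the longest.  This is an
    explicit approximation for synthetic/test genomes, not a gene caller.
    """
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2")
    starts = frozenset(s.upper() for s in starts)
    seq = genome.sequence
    found: list[OrfRecord] = []
    hits = list(_scan_strand(seq, "+", len(seq), min_codons, starts))
    hits += list(_scan_strand(reverse_complement(seq), "-", len(seq), min_codons, starts))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    for i, (start, end, strand, protein) in enumerate(hits, 1):
        found.append(OrfRecord(f"orf{i}", start, end, strand, protein))
    return found


def gc_content(genome: GenomeRecord) -> float:
    """GC fraction over unambiguous bases; N is excluded from the denominator."""
    counts = {b: genome.sequence.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"genome {genome.id!r}: no unambiguous bases")
    return (counts["G"] + counts["C"]) / total


def gc_percent(genome: GenomeRecord) -> float:
    """GC content as a percentage rounded to 2 decimals."""
    return round(100.0 * gc_content(genome), 2)


def genome_stats(phage: AnnotatedPhage) -> dict[str, object]:
    return {
        "phage_id": phage.id,
        "length_bp": len(phage.genome),
        "length_kb": round(len(phage.genome) / 1000.0, 3),
        "gc_percent": gc_percent(phage.genome),
        "n_orfs": len(phage.orfs),
    }


def as_dict(obj) -> dict:
    return dataclasses.asdict(obj)
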