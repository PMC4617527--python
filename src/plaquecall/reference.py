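"""Reporter-gene reference handling.

The transgenic rodent reporter assay scores loss-of-function mutations in a
bacterial reporter transgene; for Muta™Mouse this is the *E. coli* lacZ
coding sequence (3096 bp).  Everything downstream of alignment works in
1-based coordinates on the coding strand of that sequence.  This module loads
the reference from FASTA, applies colony-specific sequence corrections,
discovers mononucleotide (homopolymer) runs and CpG-type C/G stretches --
both of which matter because semiconductor sequencing makes elevated indel
errors there -- and classifies the protein-level impact of individual
mutation events via the standard codon table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FastaFormatError(ValueError):
    """Raised when the reference FASTA does not contain exactly one record."""


class ReferenceMismatchError(ValueError):
    """Raised when a correction's stated reference base does not match."""


class OutOfFrameError(ValueError):
    """Raised when an impact is requested outside the coding region."""


class ProteinImpact(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SILENT = "silent"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of a single base, 1-based inclusive start."""

    start: int
    length: int
    base: str

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class ReferenceGene:
    """A reporter gene sequence with its coding frame.

    ``coding_offset`` is the 1-based position where codon 1 begins; for a
    FASTA that contains the bare coding sequence it is 1.  ``variants_applied``
    records colony-specific corrections as (position, ref_base, colony_base)
    in the order they were applied.
    """

    name: str
    sequence: str
    coding_offset: int = 1
    variants_applied: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("reference sequence is empty")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"reference contains non-ACGT characters: {sorted(bad)}")
        if not 1 <= self.coding_offset <= len(self.sequence):
            raise ValueError("coding_offset outside the sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"position {position} outside 1..{len(self)}")
        return self.sequence[position - 1]

    @property
    def coding_length(self) -> int:
        return len(self) - self.coding_offset + 1

    def in_coding_region(self, position: int) -> bool:
        n_codons = self.coding_length // 3
        end = self.coding_offset + 3 * n_codons - 1
        return self.coding_offset <= position <= end

    def codon_at(self, position: int) -> tuple[int, int, str]:
        """Return (codon_number, offset_in_codon, codon) for a coding position.

        Codon numbers start at 1; offset_in_codon is 0, 1 or 2.
        """
        if not self.in_coding_region(position):
            raise OutOfFrameError(f"position {position} is outside the coding region")
        rel = position - self.coding_offset
        codon_no, offset = divmod(rel, 3)
        start = self.coding_offset + 3 * codon_no - 1
        return codon_no + 1, offset, self.sequence[start : start + 3]

    def protein(self) -> str:
        """Translate the complete codons of the coding region (with ``*`` stops)."""
        n = self.coding_length // 3
        cds = self.sequence[self.coding_offset - 1 : self.coding_offset - 1 + 3 * n]
        return str(Seq(cds).translate())


def load_reference(
    fasta_path,
    variant_list: Sequence[tuple[int, str, str]] = (),
    name: str | None = None,
    coding_offset: int = 1,
) -> ReferenceGene:
    """Load a single-record FASTA and apply colony-specific corrections.

    Each variant is (1-based position, reference base, colony base); the
    stated reference base must match the pre-correction sequence.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FastaFormatError(
            f"expected exactly one FASTA record in {fasta_path}, found {len(records)}"
        )
    record = records[0]
    gene = ReferenceGene(
        name=name or record.id,
        sequence=str(record.seq).upper(),
        coding_offset=coding_offset,
    )
    return apply_variants(gene, variant_list)


def apply_variants(gene: ReferenceGene, variant_list: Sequence[tuple[int, str, str]]) -> ReferenceGene:
    """Apply substitution corrections, verifying the stated reference base."""
    seq = list(gene.sequence)
    applied = list(gene.variants_applied)
    for position, ref_base, alt_base in variant_list:
        ref_base, alt_base = ref_base.upper(), alt_base.upper()
        if not 1 <= position <= len(seq):
            raise ReferenceMismatchError(f"variant position {position} outside 1..{len(seq)}")
        if seq[position - 1] != ref_base:
            raise ReferenceMismatchError(
                f"variant at position {position}: stated reference base {ref_base} "
                f"does not match sequence base {seq[position - 1]}"
            )
        seq[position - 1] = alt_base
        applied.append((position, ref_base, alt_base))
    return ReferenceGene(
        name=gene.name,
        sequence="".join(seq),
        coding_offset=gene.coding_offset,
        variants_applied=applied,
    )


def revert_variants(gene: ReferenceGene) -> ReferenceGene:
    """Undo every applied correction (inverse of :func:`apply_variants`)."""
    seq = list(gene.sequence)
    for position, ref_base, alt_base in reversed(gene.variants_applied):
        if seq[position - 1] != alt_base:
            raise ReferenceMismatchError(
                f"cannot revert variant at {position}: expected {alt_base}, "
                f"found {seq[position - 1]}"
            )
        seq[position - 1] = ref_base
    return ReferenceGene(name=gene.name, sequence="".join(seq), coding_offset=gene.coding_offset)


def read_variant_tsv(path) -> list[tuple[int, str, str]]:
    """Read a variant list TSV with columns position, ref, alt (header optional)."""
    variants: list[tuple[int, str, str]] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in {"position", "pos"}:
                continue
            if len(fields) < 3:
                raise ValueError(f"variant line needs 3 columns: {line!r}")
            variants.append((int(fields[0]), fields[1], fields[2]))
    return variants


def _sequence_of(gene) -> str:
    return gene.sequence if hasattr(gene, "sequence") else str(gene).upper()


def find_homopolymers(gene, min_len: int = 2) -> list[HomopolymerRun]:
    """Maximal mononucleotide runs of length >= min_len, sorted by start."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = _sequence_of(gene)
    runs: list[HomopolymerRun] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append(HomopolymerRun(start=i + 1, length=j - i, base=seq[i]))
        i = j
    return runs


def homopolymer_census(runs: Iterable[HomopolymerRun]) -> dict:
    """Summarize runs by length class (2 / 3 / >=4) and bases covered."""
    runs = list(runs)
    by_class = {"len2": 0, "len3": 0, "len4plus": 0}
    for run in runs:
        if run.length == 2:
            by_class["len2"] += 1
        elif run.length == 3:
            by_class["len3"] += 1
        else:
            by_class["len4plus"] += 1
    return {
        "n_runs": len(runs),
        **by_class,
        "bases_covered": sum(run.length for run in runs),
    }


def find_cpg_stretches(gene, min_len: int = 5, strategy: str = "alternating") -> list[tuple[int, int]]:
    """Maximal CpG-type stretches of total length >= min_len as (start, length).

    ``alternating`` (default): maximal substrings over {C, G} in which no two
    adjacent bases are equal, i.e. perfectly alternating ...CGCG... or
    ...GCGC... runs.  ``cg_runs``: maximal runs of tandem CG dinucleotides
    (CGCGCG...), the stricter reading.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = _sequence_of(gene)
    stretches: list[tuple[int, int]] = []
    if strategy == "alternating":
        i = 0
        n = len(seq)
        while i < n:
            if seq[i] not in "CG":
                i += 1
                continue
            j = i + 1
            while j < n and seq[j] in "CG" and seq[j] != seq[j - 1]:
                j += 1
            if j - i >= min_len:
                stretches.append((i + 1, j - i))
            i = j
    elif strategy == "cg_runs":
        i = 0
        n = len(seq)
        while i < n - 1:
            if seq[i] == "C" and seq[i + 1] == "G":
                j = i
                while j + 1 < n and seq[j] == "C" and seq[j + 1] == "G":
                    j += 2
                if j - i >= min_len:
                    stretches.append((i + 1, j - i))
                i = j
            else:
                i += 1
    else:
        raise ValueError(f"unknown CpG strategy {strategy!r}")
    return stretches


def classify_impact(gene: ReferenceGene, position: int, event) -> ProteinImpact:
    """Protein-level impact of a single mutation event at a coding position.

    ``event`` carries ``kind`` (sub / ins / del) and ``detail`` (alternate
    base, inserted sequence, or deleted length); a plain (kind, detail) tuple
    is accepted too.  Substitutions are judged per single event against the
    unmutated codon; indels are frameshift unless their length is a multiple
    of three.
    """
    kind, detail = (event.kind, event.detail) if hasattr(event, "kind") else event
    if not gene.in_coding_region(position):
        raise OutOfFrameError(f"position {position} is outside the coding region")
    if kind == "sub":
        alt = str(detail).upper()
        if alt not in VALID_BASES:
            raise ValueError(f"invalid substitution base {detail!r}")
        if alt == gene.base(position):
            raise ValueError("substitution alternate equals the reference base")
        _, offset, codon = gene.codon_at(position)
        mutant_codon = codon[:offset] + alt + codon[offset + 1 :]
        old_aa = str(Seq(codon).translate())
        new_aa = str(Seq(mutant_codon).translate())
        if new_aa == old_aa:
            return ProteinImpact.SILENT
        if new_aa == "*":
            return ProteinImpact.NONSENSE
        return ProteinImpact.MISSENSE
    if kind == "ins":
        length = len(str(detail))
    elif kind == "del":
        length = int(detail)
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    if length <= 0:
        raise ValueError("indel length must be positive")
    return ProteinImpact.INFRAME_INDEL if length % 3 == 0 else ProteinImpact.FRAMESHIFT_INDEL


def write_annotation_tsv(gene: ReferenceGene, runs, stretches, path) -> None:
    """Write homopolymer/CpG annotations as a BED-like TSV (1-based inclusive)."""
    with open(path, "w") as handle:
        handle.write("# plaquecall annotations v1; coordinates 1-based inclusive\n")
        handle.write("gene\tfeature\tstart\tend\tdetail\n")
        for run in runs:
            handle.write(f"{gene.name}\thomopolymer\t{run.start}\t{run.end}\t{run.base}x{run.length}\n")
        for start, length in stretches:
            handle.write(f"{gene.name}\tcpg_stretch\t{start}\t{start + length - 1}\tlen{length}\n")
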