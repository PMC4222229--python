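"""Candidate-mHA peptide construction from coding variants.

Each nonsynonymous SNV is mapped onto its transcript, the variant residue is
flanked by up to 8 reference residues on each side (a 17-mer when the protein
is long enough — the window that contains every 9-mer covering the variant,
HLA class I's modal ligand length), and all 9-mer sliding windows containing
the variant position are enumerated. For a full 17-mer the variant occupies
nonamer positions 9 down to 1 across the nine windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from Bio.Seq import Seq

from .errors import ReferenceMismatchError
from .transcripts import TranscriptModel
from .variants import GenomicVariant

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CodingConsequence:
    """Effect of one SNV on one transcript's protein."""

    variant: GenomicVariant
    transcript_id: str
    gene_id: str
    protein_pos: int  # 1-based residue index; len(protein)+1 addresses the stop codon
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


@dataclass(frozen=True)
class PaddedPeptide:
    """Variant-centered peptide: up to `flank` reference residues per side."""

    sequence: str
    variant_offset: int  # 1-based position of the variant residue
    consequence: CodingConsequence

    def __post_init__(self) -> None:
        if not 1 <= self.variant_offset <= len(self.sequence):
            raise ValueError("variant_offset outside sequence")
        if self.sequence[self.variant_offset - 1] != self.consequence.alt_aa:
            raise ValueError("sequence does not carry alt_aa at variant_offset")


@dataclass(frozen=True)
class Nonamer:
    sequence: str
    variant_pos: int  # 1-based position (1-9) of the variant residue
    parent: PaddedPeptide

    def __post_init__(self) -> None:
        if len(self.sequence) != 9:
            raise ValueError("nonamer must have length 9")
        if not 1 <= self.variant_pos <= 9:
            raise ValueError("variant_pos must be in 1..9")


def annotate_coding_consequence(
    variant: GenomicVariant, model: TranscriptModel
) -> Optional[CodingConsequence]:
    """Map a genomic SNV onto a transcript codon; None when outside the CDS.

    Strand-aware: on minus-strand transcripts the VCF (plus-strand) alleles
    are complemented before codon substitution. Raises ReferenceMismatchError
    when the transcript base disagrees with the variant's REF allele.
    """
    offset = model.cds_offset(variant.chrom, variant.pos)
    if offset is None:
        return None
    ref = variant.ref if model.strand == "+" else _COMPLEMENT[variant.ref]
    alt = variant.alt if model.strand == "+" else _COMPLEMENT[variant.alt]
    if model.cds_sequence[offset] != ref:
        raise ReferenceMismatchError(
            model.cds_sequence[offset], ref, f"{model.transcript_id} CDS offset {offset}"
        )
    codon_idx = offset // 3
    within = offset % 3
    ref_codon = model.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodingConsequence(
        variant=variant,
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        protein_pos=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def build_padded_peptide(
    consequence: CodingConsequence, model: TranscriptModel, flank: int = 8
) -> Optional[PaddedPeptide]:
    """Variant-centered peptide with up to ``flank`` residues per side.

    Returns None (to be logged by the caller) for stop-gain, stop-loss, or
    variants that address the reference stop codon — there is no substituted
    residue to center a peptide on. Synonymous input is a contract violation.
    """
    if consequence.synonymous:
        raise ValueError("build_padded_peptide requires a nonsynonymous consequence")
    if consequence.ref_aa == "*" or consequence.alt_aa == "*":
        return None
    protein = model.protein_sequence
    p = consequence.protein_pos
    if p > len(protein):
        return None
    left = min(flank, p - 1)
    right = min(flank, len(protein) - p)
    seq = protein[p - 1 - left : p - 1] + consequence.alt_aa + protein[p : p + right]
    return PaddedPeptide(sequence=seq, variant_offset=left + 1, consequence=consequence)


def nonamer_window_count(length: int, variant_offset: int, width: int = 9) -> int:
    """Number of length-``width`` windows of a length-``length`` peptide that
    contain position ``variant_offset`` (the truncation formula)."""
    if length < width:
        return 0
    first = max(1, variant_offset - (width - 1))
    last = min(variant_offset, length - (width - 1))
    return max(0, last - first + 1)


def enumerate_nonamers(padded: PaddedPeptide, width: int = 9) -> List[Nonamer]:
    """All length-9 windows containing the variant residue, by window start.

    For a full 17-mer with the variant at offset 9 this yields nine nonamers
    with the variant at positions 9, 8, ..., 1.
    """
    L, v = len(padded.sequence), padded.variant_offset
    if L < width:
        return []
    out: List[Nonamer] = []
    for start in range(max(1, v - (width - 1)), min(v, L - (width - 1)) + 1):
        out.append(
            Nonamer(
                sequence=padded.sequence[start - 1 : start + width - 1],
                variant_pos=v - start + 1,
                parent=padded,
            )
        )
    return out


def deduplicate_complexes(
    records: Iterable[Tuple[str, str]],
) -> Tuple[Set[Tuple[str, str]], Dict[Tuple[str, str], List[int]]]:
    """Collapse (peptide, allele) pairs to unique complexes.

    Returns the unique set and a provenance map from each unique key to the
    input indices that produced it (splice isoforms of one gene commonly emit
    the same nonamer).
    """
    unique: Set[Tuple[str, str]] = set()
    provenance: Dict[Tuple[str, str], List[int]] = {}
    for i, key in enumerate(records):
        key = (key[0], key[1])
        unique.add(key)
        provenance.setdefault(key, []).append(i)
    return unique, provenance


@dataclass
class PeptideBuildReport:
    n_consequences: int = 0
    n_synonymous: int = 0
    n_nonsynonymous: int = 0
    n_stop_involved: int = 0
    n_too_short: int = 0
    n_padded: int = 0
    n_nonamers: int = 0


def build_peptide_library(
    variants: Iterable[GenomicVariant],
    models: Iterable[TranscriptModel],
    flank: int = 8,
) -> Tuple[List[Nonamer], PeptideBuildReport]:
    """Run consequence -> padded peptide -> nonamer for every variant against
    every transcript it falls in (per-transcript generation: one variant in k
    isoforms yields up to k padded peptides)."""
    report = PeptideBuildReport()
    nonamers: List[Nonamer] = []
    models = list(models)
    for variant in sorted(set(variants)):
        for model in models:
            cons = annotate_coding_consequence(variant, model)
            if cons is None:
                continue
            report.n_consequences += 1
            if cons.synonymous:
                report.n_synonymous += 1
                continue
            report.n_nonsynonymous += 1
            padded = build_padded_peptide(cons, model, flank=flank)
            if padded is None:
                report.n_stop_involved += 1
                continue
            report.n_padded += 1
            windows = enumerate_nonamers(padded)
            if not windows:
                report.n_too_short += 1
            nonamers.extend(windows)
    report.n_nonamers = len(nonamers)
    return nonamers, report
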