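"""Transcript/protein models for coding-consequence annotation.

A TranscriptModel carries the spliced coding sequence (sense strand) and its
translation, plus the genomic CDS segments needed to map a genomic SNV to a
codon. Models can be loaded from GFF3 + genome FASTA or from a simplified
tab-separated transcript table (used in tests and emitted by the simulator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

from .errors import InputFormatError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Standard-code translation; a single terminal stop is stripped."""
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


@dataclass
class TranscriptModel:
    """One coding transcript.

    ``cds_segments`` are (start, end) genomic 1-based inclusive intervals on
    ``chrom``, ordered 5'->3' in transcript orientation (descending genomic
    coordinate for minus-strand transcripts). ``cds_sequence`` is the spliced
    coding sequence on the sense (coding) strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_segments: List[Tuple[int, int]]
    cds_sequence: str
    protein_sequence: str = field(default="")

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if len(self.cds_sequence) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds_sequence)} not a multiple of 3"
            )
        if not self.protein_sequence:
            self.protein_sequence = translate_cds(self.cds_sequence)

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    def cds_offset(self, chrom: str, pos: int) -> Optional[int]:
        """0-based offset of genomic position into the sense-strand CDS.

        Returns None when the position is not inside any CDS segment.
        """
        if chrom != self.chrom:
            return None
        cum = 0
        for start, end in self.cds_segments:
            if start <= pos <= end:
                if self.strand == "+":
                    return cum + (pos - start)
                return cum + (end - pos)
            cum += end - start + 1
        return None

    def genomic_position(self, offset: int) -> int:
        """Inverse of :meth:`cds_offset` (0-based CDS offset -> genomic pos)."""
        if not 0 <= offset < self.cds_length:
            raise ValueError(f"CDS offset {offset} out of range for {self.transcript_id}")
        cum = 0
        for start, end in self.cds_segments:
            seg = end - start + 1
            if offset < cum + seg:
                within = offset - cum
                return start + within if self.strand == "+" else end - within
            cum += seg
        raise AssertionError("unreachable")


@dataclass
class TranscriptLoadReport:
    n_loaded: int = 0
    rejected: List[Tuple[str, str]] = field(default_factory=list)  # (transcript_id, reason)


def load_transcript_models(
    gff_path: str | Path, fasta_path: str | Path
) -> Tuple[List[TranscriptModel], TranscriptLoadReport]:
    """Build transcript models from GFF3 CDS features and a genome FASTA.

    Transcripts whose CDS length is not a multiple of 3, or whose translation
    contains an internal stop, are rejected and logged rather than fatal.
    """
    report = TranscriptLoadReport()
    try:
        db = gffutils.create_db(
            str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils raises a zoo of types on bad input
        raise InputFormatError(f"cannot parse GFF3 {gff_path}: {exc}") from exc
    genome = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    by_transcript: Dict[str, List[gffutils.Feature]] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("transcript_id")
        if not parents:
            report.rejected.append((cds.id or "?", "CDS without Parent/transcript_id"))
            continue
        by_transcript.setdefault(parents[0], []).append(cds)

    models: List[TranscriptModel] = []
    for tid, features in sorted(by_transcript.items()):
        chrom = features[0].seqid
        strand = features[0].strand
        gene = _gene_of(db, tid, features[0])
        if chrom not in genome:
            raise InputFormatError(f"contig {chrom!r} referenced by {tid} missing from FASTA")
        genomic_order = sorted(features, key=lambda f: f.start)
        pieces = [str(genome[chrom][f.start - 1 : f.end]) for f in genomic_order]
        seq = "".join(pieces)
        if strand == "-":
            seq = reverse_complement(seq)
            segments = [(f.start, f.end) for f in reversed(genomic_order)]
        else:
            segments = [(f.start, f.end) for f in genomic_order]
        if len(seq) % 3 != 0:
            report.rejected.append((tid, f"CDS length {len(seq)} not a multiple of 3"))
            continue
        protein = translate_cds(seq)
        if "*" in protein:
            report.rejected.append((tid, "internal stop codon in translation"))
            continue
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                cds_segments=segments,
                cds_sequence=seq,
                protein_sequence=protein,
            )
        )
        report.n_loaded += 1
    return models, report


def _gene_of(db: "gffutils.FeatureDB", tid: str, cds: "gffutils.Feature") -> str:
    if "gene_id" in cds.attributes:
        return cds.attributes["gene_id"][0]
    try:
        mrna = db[tid]
    except Exception:
        return tid
    parent = mrna.attributes.get("Parent")
    return parent[0] if parent else tid


# --- simplified transcript-table dialect -----------------------------------
# Tab-separated columns: transcript_id, gene_id, strand, chrom,
# comma-separated CDS segments "start-end" in transcript order, CDS sequence.

def write_transcript_table(models: List[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            segs = ",".join(f"{s}-{e}" for s, e in m.cds_segments)
            fh.write(
                f"{m.transcript_id}\t{m.gene_id}\t{m.strand}\t{m.chrom}\t{segs}\t{m.cds_sequence}\n"
            )


def load_transcript_table(path: str | Path) -> Tuple[List[TranscriptModel], TranscriptLoadReport]:
    report = TranscriptLoadReport()
    models: List[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise InputFormatError(f"{path}:{lineno}: expected 6 tab-separated columns")
            tid, gene, strand, chrom, segs, seq = parts
            segments = []
            for token in segs.split(","):
                s, e = token.split("-")
                segments.append((int(s), int(e)))
            if len(seq) % 3 != 0:
                report.rejected.append((tid, f"CDS length {len(seq)} not a multiple of 3"))
                continue
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene,
                    chrom=chrom,
                    strand=strand,
                    cds_segments=segments,
                    cds_sequence=seq.upper(),
                )
            )
            report.n_loaded += 1
    return models, report
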