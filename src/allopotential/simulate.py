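"""Seeded synthetic inputs with known ground truth.

Every pipeline input — genome FASTA + GFF3 gene models, donor/recipient VCFs,
scoring matrices, a second-predictor output table, and a gene-by-tissue
expression table — can be generated here with a recorded truth table, so the
whole pipeline is testable offline with exact expectations. The generator
keeps its own coordinate bookkeeping (exon layout, codon arithmetic) separate
from the pipeline's transcript mapping, so recovering the truth end to end is
a genuine cross-check rather than a tautology.

Also ships the printed nine-pair reference cohort used for the statistical
checks (per-pair presented / strongly-presented counts by two predictors, with
matched-related vs unrelated donor labels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .binding import AMINO_ACIDS, BindingRecord, ScoringMatrix, write_scoring_matrix
from .errors import ConfigError
from .expression import ExpressionTable
from .summary import SummaryTable
from .transcripts import TranscriptModel, reverse_complement, write_transcript_table
from .variants import GenomicVariant

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# the 16 tissues of the body-map expression resource
BODY_MAP_TISSUES = [
    "adipose",
    "adrenal",
    "brain",
    "breast",
    "colon",
    "heart",
    "kidney",
    "leukocyte",
    "liver",
    "lung",
    "lymph_node",
    "ovary",
    "prostate",
    "skeletal_muscle",
    "testis",
    "thyroid",
]

DEFAULT_HLA_ALLELES = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-B*07:02",
    "HLA-B*08:01",
    "HLA-C*07:01",
    "HLA-C*07:02",
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are sized for a fast desk-scale exome stand-in: tens of genes,
    tens of variants per sample, and matrix targets in the regime where ~10%
    of random nonamers bind below 500 nM and ~1% below 50 nM.
    """

    seed: int = 0
    n_genes: int = 20
    transcripts_per_gene: int = 1  # 2 adds an exon-skipped isoform per multi-exon gene
    cds_length_range: Tuple[int, int] = (120, 300)
    multi_exon_fraction: float = 0.5
    minus_strand_fraction: float = 0.3
    n_recipient_variants: int = 40
    n_donor_variants: int = 30
    shared_fraction: float = 0.5  # of min(recipient, donor) variants present in both
    fraction_nonsynonymous: float = 0.8
    target_presented_fraction: float = 0.10
    target_strong_fraction: float = 0.01
    n_tissues: int = 16
    expression_lognormal_params: Tuple[float, float] = (1.5, 1.5)  # (mu, sigma) of log REU
    hla_alleles: Tuple[str, ...] = DEFAULT_HLA_ALLELES
    contig: str = "chr1"

    def __post_init__(self) -> None:
        for name in (
            "shared_fraction",
            "fraction_nonsynonymous",
            "target_presented_fraction",
            "target_strong_fraction",
            "multi_exon_fraction",
            "minus_strand_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.cds_length_range
        if lo < 30 or hi < lo:
            raise ConfigError(f"invalid cds_length_range {self.cds_length_range}")
        if self.target_strong_fraction > self.target_presented_fraction:
            raise ConfigError("target_strong_fraction cannot exceed target_presented_fraction")
        if self.transcripts_per_gene not in (1, 2):
            raise ConfigError("transcripts_per_gene must be 1 or 2")


# --- reference genome + gene models -----------------------------------------


@dataclass
class SimulatedReference:
    config: SimulationConfig
    contigs: Dict[str, str]  # contig -> sequence
    models: List[TranscriptModel]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.contigs):
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        genes: Dict[str, List[TranscriptModel]] = {}
        for m in self.models:
            genes.setdefault(m.gene_id, []).append(m)
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene_id in sorted(genes):
                isoforms = genes[gene_id]
                chrom = isoforms[0].chrom
                strand = isoforms[0].strand
                starts = [s for m in isoforms for s, _ in m.cds_segments]
                ends = [e for m in isoforms for _, e in m.cds_segments]
                fh.write(
                    f"{chrom}\tsim\tgene\t{min(starts)}\t{max(ends)}\t.\t{strand}\t.\tID={gene_id}\n"
                )
                for m in isoforms:
                    ts = [s for s, _ in m.cds_segments]
                    te = [e for _, e in m.cds_segments]
                    fh.write(
                        f"{chrom}\tsim\tmRNA\t{min(ts)}\t{max(te)}\t.\t{strand}\t.\t"
                        f"ID={m.transcript_id};Parent={gene_id}\n"
                    )
                    for i, (s, e) in enumerate(sorted(m.cds_segments)):
                        fh.write(
                            f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                            f"ID=cds-{m.transcript_id}-{i};Parent={m.transcript_id}\n"
                        )

    def write_transcript_table(self, path: str | Path) -> None:
        write_transcript_table(self.models, path)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + a stop codon."""
    middle = []
    while len(middle) < n_codons - 2:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            middle.append(codon)
    stop = rng.choice(sorted(_STOPS))
    return "ATG" + "".join(middle) + stop


def simulate_reference(config: SimulationConfig) -> SimulatedReference:
    """Place non-overlapping genes on a synthetic contig.

    A configurable fraction of genes is multi-exon and minus-strand; every
    CDS is a valid ORF (start codon, terminal stop, no internal stop). With
    ``transcripts_per_gene == 2``, multi-exon genes gain an exon-skipped
    isoform whose skipped exon length is a multiple of 3 (frame preserved).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cds_length_range
    cursor = 1001  # leave a 5' pad of background sequence
    pieces: List[str] = ["".join(rng.choice(list(_BASES), size=1000))]
    models: List[TranscriptModel] = []
    chrom = config.contig

    for g in range(config.n_genes):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        cds = _random_cds(rng, n_codons)
        L = len(cds)
        multi = rng.random() < config.multi_exon_fraction and L >= 90
        want_isoform = config.transcripts_per_gene == 2 and multi
        if multi:
            if want_isoform:
                # three exons; middle exon codon-multiple so skipping keeps frame
                e1 = int(rng.integers(30, L - 60))
                mid_len = 3 * int(rng.integers(5, max(6, (L - e1 - 30) // 3)))
                cuts = [e1, e1 + mid_len]
            else:
                n_exons = int(rng.integers(2, 4))
                cuts = sorted(rng.choice(np.arange(20, L - 20), size=n_exons - 1, replace=False).tolist())
        else:
            cuts = []
        bounds = [0] + [int(c) for c in cuts] + [L]
        exon_lens = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        intron_lens = [int(rng.integers(30, 120)) for _ in range(len(exon_lens) - 1)]
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"

        # region in transcript order: exon, intron, exon, ...
        region_parts: List[str] = []
        exon_bounds_region: List[Tuple[int, int]] = []  # 0-based inclusive within region
        off = 0
        for i, elen in enumerate(exon_lens):
            exon_bounds_region.append((off, off + elen - 1))
            region_parts.append(cds[bounds[i] : bounds[i + 1]])
            off += elen
            if i < len(intron_lens):
                region_parts.append("".join(rng.choice(list(_BASES), size=intron_lens[i])))
                off += intron_lens[i]
        region = "".join(region_parts)
        R = len(region)
        gstart = cursor  # 1-based genomic start of the region
        if strand == "+":
            genomic = region
            segments = [(gstart + s, gstart + e) for s, e in exon_bounds_region]
        else:
            genomic = reverse_complement(region)
            segments = [
                (gstart + (R - 1 - e), gstart + (R - 1 - s)) for s, e in exon_bounds_region
            ]
        gene_id = f"GENE{g + 1:03d}"
        tid = f"{gene_id}.t1"
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                cds_segments=segments,
                cds_sequence=cds,
            )
        )
        if want_isoform and len(segments) == 3:
            iso_cds = cds[: bounds[1]] + cds[bounds[2] :]
            iso_prot = str(Seq(iso_cds).translate())
            if "*" not in iso_prot[:-1]:  # skipping must not create an internal stop
                models.append(
                    TranscriptModel(
                        transcript_id=f"{gene_id}.t2",
                        gene_id=gene_id,
                        chrom=chrom,
                        strand=strand,
                        cds_segments=[segments[0], segments[2]],
                        cds_sequence=iso_cds,
                    )
                )
        pieces.append(genomic)
        gap = int(rng.integers(200, 500))
        pieces.append("".join(rng.choice(list(_BASES), size=gap)))
        cursor = gstart + R + gap

    return SimulatedReference(
        config=config, contigs={chrom: "".join(pieces)}, models=models
    )


# --- donor/recipient variant planting ---------------------------------------


def _tx_genomic_position(model: TranscriptModel, offset: int) -> int:
    # generator-side mapping, kept separate from TranscriptModel.genomic_position
    cum = 0
    for start, end in model.cds_segments:
        seg = end - start + 1
        if offset < cum + seg:
            within = offset - cum
            return start + within if model.strand == "+" else end - within
        cum += seg
    raise AssertionError("offset outside CDS")


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulatedPair:
    reference: SimulatedReference
    recipient: List[GenomicVariant]
    donor: List[GenomicVariant]
    truth: pd.DataFrame
    recipient_id: str = "RECIPIENT"
    donor_id: str = "DONOR"

    def true_gvh(self) -> set:
        keys = self.truth.loc[self.truth.direction == "GVH", ["chrom", "pos", "ref", "alt"]]
        return {
            GenomicVariant(r.chrom, int(r.pos), r.ref, r.alt)
            for r in keys.drop_duplicates().itertuples()
        }

    def write_vcfs(self, recipient_path: str | Path, donor_path: str | Path) -> None:
        contigs = {c: len(s) for c, s in self.reference.contigs.items()}
        _write_sample_vcf(self.recipient, self.recipient_id, contigs, recipient_path)
        _write_sample_vcf(self.donor, self.donor_id, contigs, donor_path)


def _write_sample_vcf(
    variants: Sequence[GenomicVariant],
    sample: str,
    contigs: Dict[str, int],
    path: str | Path,
) -> None:
    header = pysam.VariantHeader()
    for c, ln in sorted(contigs.items()):
        header.contigs.add(c, length=ln)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(set(variants)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.samples[sample]["GT"] = (0, 1)
            out.write(rec)


def _plant_variant(
    rng: np.random.Generator,
    models_by_gene: Dict[str, List[TranscriptModel]],
    used_positions: set,
    synonymous: bool,
) -> Optional[Tuple[GenomicVariant, List[dict]]]:
    """Sample one CDS SNV of the requested class; None when attempts exhaust."""
    gene_ids = sorted(models_by_gene)
    for _ in range(200):
        gene = gene_ids[int(rng.integers(len(gene_ids)))]
        primary = models_by_gene[gene][0]
        n_res = len(primary.protein_sequence)
        codon_idx = int(rng.integers(1, n_res))  # residues 2..n (skip start, skip stop)
        within = int(rng.integers(3))
        offset = codon_idx * 3 + within
        codon = primary.cds_sequence[codon_idx * 3 : codon_idx * 3 + 3]
        ref_aa = str(Seq(codon).translate())
        choices = []
        for alt_base in _BASES:
            if alt_base == codon[within]:
                continue
            alt_codon = codon[:within] + alt_base + codon[within + 1 :]
            alt_aa = str(Seq(alt_codon).translate())
            if synonymous and alt_aa == ref_aa:
                choices.append((alt_base, alt_aa))
            elif not synonymous and alt_aa != ref_aa and alt_aa != "*":
                choices.append((alt_base, alt_aa))
        if not choices:
            continue
        alt_base, alt_aa = choices[int(rng.integers(len(choices)))]
        pos = _tx_genomic_position(primary, offset)
        if (primary.chrom, pos) in used_positions:
            continue
        sense_ref, sense_alt = codon[within], alt_base
        if primary.strand == "-":
            g_ref, g_alt = _COMP[sense_ref], _COMP[sense_alt]
        else:
            g_ref, g_alt = sense_ref, sense_alt
        variant = GenomicVariant(primary.chrom, pos, g_ref, g_alt)
        used_positions.add((primary.chrom, pos))
        rows = []
        for model in models_by_gene[gene]:
            # independent per-isoform bookkeeping: locate pos in this isoform
            iso_offset = _iso_offset(model, pos)
            if iso_offset is None:
                continue
            iso_codon_idx = iso_offset // 3
            iso_within = iso_offset % 3
            iso_codon = model.cds_sequence[iso_codon_idx * 3 : iso_codon_idx * 3 + 3]
            iso_alt_codon = (
                iso_codon[:iso_within] + sense_alt + iso_codon[iso_within + 1 :]
            )
            r_aa = str(Seq(iso_codon).translate())
            a_aa = str(Seq(iso_alt_codon).translate())
            rows.append(
                {
                    "chrom": variant.chrom,
                    "pos": variant.pos,
                    "ref": variant.ref,
                    "alt": variant.alt,
                    "gene": gene,
                    "transcript": model.transcript_id,
                    "protein_pos": iso_codon_idx + 1,
                    "ref_aa": r_aa,
                    "alt_aa": a_aa,
                    "synonymous": r_aa == a_aa,
                }
            )
        return variant, rows
    return None


def _iso_offset(model: TranscriptModel, pos: int) -> Optional[int]:
    cum = 0
    for start, end in model.cds_segments:
        if start <= pos <= end:
            return cum + (pos - start if model.strand == "+" else end - pos)
        cum += end - start + 1
    return None


def simulate_pair(reference: SimulatedReference, config: SimulationConfig) -> SimulatedPair:
    """Plant recipient/donor SNVs with a known overlap so the true GVH and HVG
    sets (and every per-transcript coding consequence) are recorded."""
    rng = np.random.default_rng(config.seed + 1)
    models_by_gene: Dict[str, List[TranscriptModel]] = {}
    for m in reference.models:
        models_by_gene.setdefault(m.gene_id, []).append(m)

    n_shared = round(config.shared_fraction * min(config.n_recipient_variants, config.n_donor_variants))
    n_r_only = config.n_recipient_variants - n_shared
    n_d_only = config.n_donor_variants - n_shared
    total_needed = n_shared + n_r_only + n_d_only
    capacity = sum(len(m[0].cds_sequence) for m in models_by_gene.values())
    if total_needed * 4 > capacity:
        raise ConfigError(
            f"requested {total_needed} variants but only ~{capacity // 4} CDS positions are safely available"
        )

    used: set = set()
    recipient: List[GenomicVariant] = []
    donor: List[GenomicVariant] = []
    rows: List[dict] = []

    def plant(n: int, membership: str) -> None:
        for _ in range(n):
            synonymous = rng.random() >= config.fraction_nonsynonymous
            planted = _plant_variant(rng, models_by_gene, used, synonymous)
            if planted is None:
                raise ConfigError("could not place all requested variants; reduce counts")
            variant, vrows = planted
            in_r = membership in ("shared", "recipient")
            in_d = membership in ("shared", "donor")
            if in_r:
                recipient.append(variant)
            if in_d:
                donor.append(variant)
            direction = {"shared": "SHARED", "recipient": "GVH", "donor": "HVG"}[membership]
            for row in vrows:
                row.update(in_recipient=in_r, in_donor=in_d, direction=direction)
                rows.append(row)

    plant(n_shared, "shared")
    plant(n_r_only, "recipient")
    plant(n_d_only, "donor")

    truth = pd.DataFrame(rows).sort_values(["chrom", "pos", "transcript"]).reset_index(drop=True)
    return SimulatedPair(reference=reference, recipient=recipient, donor=donor, truth=truth)


def truth_nonamers(pair: SimulatedPair, flank: int = 8) -> pd.DataFrame:
    """Expected GVH nonamers by brute-force substring enumeration.

    Built from the truth table and the generator's protein sequences only:
    for each nonsynonymous GVH consequence the padded peptide is an explicit
    slice-and-substitute of the protein, and nonamers are every length-9
    substring containing the variant residue.
    """
    proteins = {m.transcript_id: m.protein_sequence for m in pair.reference.models}
    rows = []
    truth = pair.truth
    sel = truth[(truth.direction == "GVH") & (~truth.synonymous) & (truth.alt_aa != "*")]
    for r in sel.itertuples():
        prot = proteins[r.transcript]
        p = int(r.protein_pos)
        left = min(flank, p - 1)
        right = min(flank, len(prot) - p)
        padded = prot[p - 1 - left : p - 1] + r.alt_aa + prot[p : p + right]
        v = left + 1
        for start in range(len(padded) - 8):
            window = padded[start : start + 9]
            if start < v <= start + 9:
                rows.append(
                    {
                        "transcript": r.transcript,
                        "gene": r.gene,
                        "pos": r.pos,
                        "padded_peptide": padded,
                        "nonamer": window,
                        "variant_pos": v - start,
                    }
                )
    return pd.DataFrame(rows)


# --- scoring matrices --------------------------------------------------------


def simulate_scoring_matrix(
    allele: str, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> ScoringMatrix:
    """Random additive matrix tuned so random nonamers hit the presentation
    targets: intercept and scale are set from the empirical quantiles of
    10,000 random-peptide raw scores so that P(IC50 < 500) ~
    target_presented_fraction and P(IC50 < 50) ~ target_strong_fraction."""
    if config.target_strong_fraction > config.target_presented_fraction:
        raise ConfigError("strong fraction cannot exceed presented fraction")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cells = rng.normal(0.0, 0.25, size=(9, 20))
    sample = rng.integers(0, 20, size=(10000, 9))
    raw = cells[np.arange(9)[None, :], sample].sum(axis=1)
    tp, ts = config.target_presented_fraction, config.target_strong_fraction
    if tp <= 0:
        # even the most favourable peptide must stay above the ceiling
        floor = math.log10(50000.0) - float(cells.min(axis=1).sum())
        return ScoringMatrix(allele=allele, cells=cells, intercept=floor)
    q_p = float(np.quantile(raw, tp))
    if ts > 0:
        q_s = float(np.quantile(raw, ts))
        spread = q_p - q_s
        # one log10 unit must separate the 500 and 50 nM quantiles
        scale = 1.0 / spread if spread > 1e-9 else 1.0
    else:
        scale = 1.0
    cells = cells * scale
    intercept = math.log10(500.0) - scale * q_p
    return ScoringMatrix(allele=allele, cells=cells, intercept=intercept)


def simulate_matrices(
    config: SimulationConfig, alleles: Optional[Sequence[str]] = None
) -> Dict[str, ScoringMatrix]:
    alleles = tuple(alleles or config.hla_alleles)
    out = {}
    for i, allele in enumerate(alleles):
        rng = np.random.default_rng([config.seed, 7919 + i])
        out[allele] = simulate_scoring_matrix(allele, config, rng)
    return out


# --- expression --------------------------------------------------------------


def simulate_expression(genes: Sequence[str], config: SimulationConfig) -> ExpressionTable:
    """I.i.d. lognormal REU per (gene, tissue); seeded and reproducible."""
    rng = np.random.default_rng(config.seed + 2)
    tissues = BODY_MAP_TISSUES[: config.n_tissues]
    if config.n_tissues > len(BODY_MAP_TISSUES):
        tissues = tissues + [f"tissue{i}" for i in range(len(BODY_MAP_TISSUES), config.n_tissues)]
    mu, sigma = config.expression_lognormal_params
    values = rng.lognormal(mu, sigma, size=(len(genes), len(tissues)))
    df = pd.DataFrame(values, index=list(genes), columns=tissues)
    return ExpressionTable(df)


# --- correlated second predictor ---------------------------------------------


def simulate_pan_predictions(
    smm_records: Sequence[BindingRecord],
    config: SimulationConfig,
    noise_sigma: float = 0.4,
) -> str:
    """Emulated captured output of a pan-specific predictor.

    Affinities are the matrix predictions perturbed by multiplicative
    lognormal noise (sigma in log10 units), written in the whitespace-
    delimited table layout the parser consumes.
    """
    rng = np.random.default_rng(config.seed + 3)
    lines = ["pos HLA Peptide Identity Aff(nM)"]
    seen = set()
    for r in sorted(smm_records, key=lambda r: (r.peptide, r.allele)):
        if r.key in seen:
            continue
        seen.add(r.key)
        aff = r.ic50_nM * 10.0 ** rng.normal(0.0, noise_sigma)
        aff = min(max(aff, 0.01), 50000.0)
        lines.append(f"1 {r.allele} {r.peptide} seq {aff:.2f}")
    lines.append(f"# {len(seen)} predictions")
    return "\n".join(lines) + "\n"


# --- bundle writer ------------------------------------------------------------


def simulate_bundle(config: SimulationConfig, outdir: str | Path) -> Dict[str, Path]:
    """Write a complete, self-consistent input bundle into a directory.

    Emits genome FASTA, GFF3, the simplified transcript table, donor and
    recipient VCFs, one scoring matrix per allele, an expression CSV, the
    truth tables, and a ready-to-run pipeline config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = simulate_reference(config)
    pair = simulate_pair(reference, config)
    paths = {
        "genome": outdir / "genome.fa",
        "gff3": outdir / "models.gff3",
        "transcripts": outdir / "transcripts.tsv",
        "recipient_vcf": outdir / "recipient.vcf",
        "donor_vcf": outdir / "donor.vcf",
        "expression": outdir / "expression.csv",
        "truth": outdir / "truth_variants.csv",
        "truth_nonamers": outdir / "truth_nonamers.csv",
        "config": outdir / "pipeline.yaml",
    }
    reference.write_fasta(paths["genome"])
    reference.write_gff3(paths["gff3"])
    reference.write_transcript_table(paths["transcripts"])
    pair.write_vcfs(paths["recipient_vcf"], paths["donor_vcf"])
    genes = sorted({m.gene_id for m in reference.models})
    expr = simulate_expression(genes, config)
    expr.data.to_csv(paths["expression"], index_label="gene")
    pair.truth.to_csv(paths["truth"], index=False)
    truth_nonamers(pair).to_csv(paths["truth_nonamers"], index=False)

    matrix_dir = outdir / "matrices"
    matrix_dir.mkdir(exist_ok=True)
    matrices = simulate_matrices(config)
    matrix_paths = {}
    for allele, matrix in matrices.items():
        safe = allele.replace("*", "").replace(":", "")
        p = matrix_dir / f"{safe}.mat"
        write_scoring_matrix(matrix, p)
        matrix_paths[allele] = str(p)
    paths["matrices"] = matrix_dir

    import yaml

    cfg = {
        "recipient_vcf": str(paths["recipient_vcf"]),
        "donor_vcf": str(paths["donor_vcf"]),
        "direction": "GVH",
        "transcript_table": str(paths["transcripts"]),
        "hla_alleles": list(config.hla_alleles),
        "matrix_paths": matrix_paths,
        "expression_table": str(paths["expression"]),
        "thresholds": {
            "presented_nM": 500.0,
            "strong_nM": 50.0,
            "auc_cutoff_nM": 100.0,
            "reu_threshold": 10.0,
        },
        "seed": config.seed,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


# --- printed nine-pair reference cohort --------------------------------------

_REFERENCE_ROWS = [
    # pair_id, donor_type, n_nssnp_gvh, smm_presented, smm_strong,
    # pan_presented, pan_strong, shared_presented
    ("2", "MRD", 4446, 1926, 250, 3883, 1376, 1332),
    ("4", "MRD", 4448, 5412, 825, 3962, 885, 2441),
    ("16", "MRD", 3290, 2111, 177, 1071, 427, 417),
    ("23", "MRD", 3657, 13456, 705, 787, 118, 534),
    ("3", "URD", 7227, 72294, 21339, 7242, 2509, 4881),
    ("5", "URD", 6572, 30730, 2254, 2759, 538, 1865),
    ("7", "URD", 6725, 58209, 21548, 5231, 2178, 2931),
    ("8", "URD", 6573, 65298, 19275, 4831, 2000, 2445),
    ("10", "URD", 9203, 18396, 2283, 5002, 989, 2065),
]


def reference_cohort() -> SummaryTable:
    """Per-pair peptide counts for the published nine-pair transplant cohort.

    Nine HLA-matched donor–recipient pairs (four matched-related, five
    unrelated donors) with, per pair: the GVH-direction nonsynonymous SNV
    count and the unique presented / strongly-presented peptide-HLA counts
    from the matrix predictor and the pan-specific predictor, plus the count
    of complexes presented by both.
    """
    df = pd.DataFrame(
        _REFERENCE_ROWS,
        columns=[
            "pair_id",
            "donor_type",
            "n_nssnp_gvh",
            "smm_presented",
            "smm_strong",
            "pan_presented",
            "pan_strong",
            "shared_presented",
        ],
    )
    return SummaryTable(rows=df)
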