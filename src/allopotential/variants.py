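"""Directional variant sets from donor/recipient variant calls.

In an HLA-matched stem-cell transplant, single-nucleotide variants present in
the recipient but absent from the donor (the graft-versus-host, GVH, direction)
encode candidate minor histocompatibility antigens that donor T cells may
recognise. The reverse direction (host-versus-graft, HVG) is relevant to graft
rejection. This module loads SNV calls from VCF and computes the two
directional set differences.

A variant is "present" in a sample when the genotype carries at least one copy
of the ALT allele; zygosity is ignored because a single allele suffices to
encode a variant peptide. Multiallelic records are decomposed so comparisons
are allele-level, not site-level. Only SNVs enter the pipeline; indels, MNVs
and symbolic alleles are dropped and tallied in the load report.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import FrozenSet, Iterable, Optional, Set, Tuple

import pysam

from .errors import InputFormatError

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """One biallelic SNV. Identity is exactly (chrom, pos, ref, alt)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"alleles must be single bases in ACGT: {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


class Direction(str, enum.Enum):
    GVH = "GVH"  # present in recipient, absent in donor
    HVG = "HVG"  # present in donor, absent in recipient


@dataclass(frozen=True)
class DirectionalVariantSet:
    direction: Direction
    variants: FrozenSet[GenomicVariant]
    recipient_id: str = ""
    donor_id: str = ""

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(sorted(self.variants))


@dataclass
class VcfLoadReport:
    """Attrition accounting for one VCF load."""

    n_records: int = 0
    n_snv_kept: int = 0
    n_non_snv_dropped: int = 0
    n_no_alt_copy: int = 0  # genotype carries no ALT (e.g. 0/0)
    n_missing_genotype: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class VariantCallSet:
    """SNVs present in one sample, plus the load report."""

    sample: str
    variants: Set[GenomicVariant] = field(default_factory=set)
    missing_sites: Set[Tuple[str, int]] = field(default_factory=set)
    report: VcfLoadReport = field(default_factory=VcfLoadReport)


def read_variant_calls(
    path: str | Path,
    sample: Optional[str] = None,
    missing_as_unknown: bool = False,
) -> VariantCallSet:
    """Load the SNVs a sample carries from a VCF 4.x file (plain or bgzipped).

    Presence means the genotype contains >= 1 ALT copy. Sites-only VCFs (no
    sample columns) treat every record as present. Missing genotypes (./.) are
    treated as absent by default; with ``missing_as_unknown`` the site is
    instead recorded in ``missing_sites`` so it can be excluded from both
    directional sets downstream.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputFormatError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    if samples:
        if sample is None:
            if len(samples) > 1:
                raise InputFormatError(
                    f"{path} is multi-sample; specify one of {samples}"
                )
            sample = samples[0]
        elif sample not in samples:
            raise InputFormatError(
                f"sample {sample!r} not in {path}; available samples: {samples}"
            )
    result = VariantCallSet(sample=sample or "")
    rep = result.report

    try:
        for rec in vf:
            rep.n_records += 1
            alts = rec.alts or ()
            if samples:
                gt = rec.samples[sample].get("GT") or ()
                called = [a for a in gt if a is not None]
                if not called:
                    rep.n_missing_genotype += 1
                    if missing_as_unknown:
                        result.missing_sites.add((rec.chrom, rec.pos))
                    continue
                present_idx = {a for a in called if a >= 1}
            else:
                present_idx = set(range(1, len(alts) + 1))
            kept_any = False
            dropped_non_snv = False
            for i, alt in enumerate(alts, start=1):
                if i not in present_idx:
                    continue
                if (
                    alt is None
                    or len(rec.ref) != 1
                    or len(alt) != 1
                    or rec.ref.upper() not in _BASES
                    or alt.upper() not in _BASES
                ):
                    dropped_non_snv = True
                    continue
                result.variants.add(
                    GenomicVariant(rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
                )
                kept_any = True
            if kept_any:
                rep.n_snv_kept += 1
            elif dropped_non_snv:
                rep.n_non_snv_dropped += 1
            elif samples:
                rep.n_no_alt_copy += 1
    except (OSError, ValueError) as exc:
        raise InputFormatError(f"malformed VCF record in {path}: {exc}") from exc
    finally:
        vf.close()
    return result


def compute_directional_set(
    recipient: Iterable[GenomicVariant],
    donor: Iterable[GenomicVariant],
    direction: Direction | str,
    recipient_id: str = "",
    donor_id: str = "",
) -> DirectionalVariantSet:
    """Set difference in the requested direction.

    GVH -> recipient \\ donor; HVG -> donor \\ recipient. Deterministic and
    order-independent (pure set semantics).
    """
    direction = Direction(direction)
    r, d = set(recipient), set(donor)
    members = r - d if direction is Direction.GVH else d - r
    return DirectionalVariantSet(
        direction=direction,
        variants=frozenset(members),
        recipient_id=recipient_id,
        donor_id=donor_id,
    )


def directional_set_from_calls(
    recipient: VariantCallSet,
    donor: VariantCallSet,
    direction: Direction | str,
    missing_as_unknown: bool = False,
) -> DirectionalVariantSet:
    """Directional set from two loaded call sets.

    With ``missing_as_unknown``, sites where either sample had a missing
    genotype are excluded from the result (no-abstention default otherwise).
    """
    out = compute_directional_set(
        recipient.variants,
        donor.variants,
        direction,
        recipient_id=recipient.sample,
        donor_id=donor.sample,
    )
    if missing_as_unknown:
        bad = recipient.missing_sites | donor.missing_sites
        kept = frozenset(v for v in out.variants if (v.chrom, v.pos) not in bad)
        out = DirectionalVariantSet(out.direction, kept, out.recipient_id, out.donor_id)
    return out


def write_variant_csv(variants: Iterable[GenomicVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom,pos,ref,alt\n")
        for v in sorted(set(variants)):
            fh.write(f"{v.chrom},{v.pos},{v.ref},{v.alt}\n")


def read_variant_csv(path: str | Path) -> Set[GenomicVariant]:
    out: Set[GenomicVariant] = set()
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise InputFormatError(f"{path}: expected header chrom,pos,ref,alt")
        for line in fh:
            if not line.strip():
                continue
            chrom, pos, ref, alt = line.strip().split(",")[:4]
            out.add(GenomicVariant(chrom, int(pos), ref, alt))
    return out


def write_variant_vcf(variants: Iterable[GenomicVariant], path: str | Path) -> None:
    """Serialise a variant set as a minimal sites-only VCF (CHROM..ALT)."""
    variants = sorted(set(variants))
    contigs = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")
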