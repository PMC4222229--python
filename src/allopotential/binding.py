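"""Peptide–HLA class I binding affinity scoring and presentation classes.

The built-in scorer is a position-specific scoring matrix additive in
log10(IC50 nM): score = intercept + sum of per-position residue contributions,
IC50 = 10**score, clipped to [0.01, 50000] nM. Presentation classes follow the
conventional affinity thresholds with strict inequalities: IC50 < 500 nM is
"presented" (intermediate affinity), IC50 < 50 nM is "strongly presented"
(high affinity); equality at a boundary falls to the weaker class.

Output of an external pan-specific predictor (run separately in 9-mer mode)
is consumed from its captured whitespace-delimited result tables; the two
predictors are merged on the (peptide, allele) key to find the complexes both
call presented, the unit of predictor agreement.
"""

from __future__ import annotations

import enum
import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .errors import InputFormatError, InsufficientDataError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

IC50_FLOOR_NM = 0.01
IC50_CEIL_NM = 50000.0
PRESENTED_NM = 500.0
STRONG_NM = 50.0


class Predictor(str, enum.Enum):
    SMM = "SMM"
    PAN = "PAN"


class Presentation(str, enum.Enum):
    NONE = "none"
    PRESENTED = "presented"
    STRONGLY_PRESENTED = "strongly_presented"


def classify_presentation(
    ic50_nM: float, presented_nM: float = PRESENTED_NM, strong_nM: float = STRONG_NM
) -> Presentation:
    """Strict-threshold presentation class (<50 strong, <500 presented)."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    if ic50_nM < strong_nM:
        return Presentation.STRONGLY_PRESENTED
    if ic50_nM < presented_nM:
        return Presentation.PRESENTED
    return Presentation.NONE


@dataclass(frozen=True)
class HlaGenotype:
    """Up to six HLA class I alleles (A/B/C loci) for one patient."""

    patient_id: str
    alleles: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 6:
            raise ValueError("genotype must carry 1-6 alleles")
        for a in self.alleles:
            allele_locus(a)  # raises if unparsable

    @property
    def distinct_alleles(self) -> Tuple[str, ...]:
        """Homozygous alleles are scored once."""
        seen: Dict[str, None] = {}
        for a in self.alleles:
            seen.setdefault(a, None)
        return tuple(seen)


_LOCUS_RE = re.compile(r"^(?:HLA-)?([ABC])[\*:0-9']*", re.IGNORECASE)


def allele_locus(allele: str) -> str:
    """Locus tag (A/B/C) of an HLA class I allele name."""
    m = _LOCUS_RE.match(allele.strip())
    if not m:
        raise ValueError(f"cannot parse HLA class I locus from allele name {allele!r}")
    return m.group(1).upper()


@dataclass
class ScoringMatrix:
    """Additive log10(IC50) matrix for 9-mers against one allele."""

    allele: str
    cells: np.ndarray  # shape (9, 20), columns in AMINO_ACIDS order
    intercept: float
    peptide_length: int = 9

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (self.peptide_length, 20):
            raise ValueError(
                f"matrix must be {self.peptide_length}x20, got {self.cells.shape}"
            )
        if not np.all(np.isfinite(self.cells)) or not math.isfinite(self.intercept):
            raise ValueError("matrix cells and intercept must be finite")


def predict_ic50_smm(peptide: str, matrix: ScoringMatrix) -> float:
    """IC50 (nM) = 10 ** (intercept + sum of position/residue cells), clipped."""
    if len(peptide) != matrix.peptide_length:
        raise ValueError(
            f"peptide length {len(peptide)} != matrix length {matrix.peptide_length}"
        )
    score = matrix.intercept
    for i, aa in enumerate(peptide):
        j = _AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"nonstandard residue {aa!r} at position {i + 1} in {peptide!r}")
        score += matrix.cells[i, j]
    # round away sub-nano-nM float noise so intended boundary scores
    # (e.g. a score of exactly log10(500)) classify deterministically
    ic50 = round(10.0**score, 9)
    return float(np.clip(ic50, IC50_FLOOR_NM, IC50_CEIL_NM))


def write_scoring_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"allele {matrix.allele}\n")
        fh.write(f"length {matrix.peptide_length}\n")
        fh.write(f"intercept {matrix.intercept!r}\n")
        for row in matrix.cells:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def load_scoring_matrix(path: str | Path) -> ScoringMatrix:
    """Read the plain-text matrix dialect (allele/length/intercept + 9x20 rows)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        if not lines[0].startswith("allele "):
            raise InputFormatError(f"{path}: first line must be 'allele <name>'")
        allele = lines[0].split(None, 1)[1]
        length = int(lines[1].split()[1])
        intercept = float(lines[2].split()[1])
    except (IndexError, ValueError) as exc:
        raise InputFormatError(f"{path}: malformed matrix header: {exc}") from exc
    rows = []
    for ln in lines[3:]:
        vals = ln.split()
        if len(vals) != 20:
            raise InputFormatError(
                f"{path}: expected 20 values per row, got {len(vals)}"
            )
        rows.append([float(v) for v in vals])
    if len(rows) != length:
        raise InputFormatError(
            f"{path}: expected {length}x20 matrix, got {len(rows)} rows"
        )
    return ScoringMatrix(allele=allele, cells=np.array(rows), intercept=intercept, peptide_length=length)


@dataclass(frozen=True)
class BindingRecord:
    """(peptide, allele, predictor, IC50) with its presentation class."""

    peptide: str
    allele: str
    predictor: Predictor
    ic50_nM: float
    presentation: Presentation
    provenance: Tuple[Tuple[str, object], ...] = ()  # e.g. (("gene","G1"),("pos",123))

    @classmethod
    def make(
        cls,
        peptide: str,
        allele: str,
        predictor: Predictor | str,
        ic50_nM: float,
        provenance: Optional[Mapping[str, object]] = None,
    ) -> "BindingRecord":
        ic50 = float(np.clip(ic50_nM, IC50_FLOOR_NM, IC50_CEIL_NM))
        return cls(
            peptide=peptide,
            allele=allele,
            predictor=Predictor(predictor),
            ic50_nM=ic50,
            presentation=classify_presentation(ic50),
            provenance=tuple(sorted((provenance or {}).items())),
        )

    @property
    def key(self) -> Tuple[str, str]:
        return (self.peptide, self.allele)

    def provenance_dict(self) -> Dict[str, object]:
        return dict(self.provenance)


def score_peptides(
    nonamers: Iterable,
    genotype: HlaGenotype,
    matrices: Mapping[str, ScoringMatrix],
) -> List[BindingRecord]:
    """Score every nonamer against each distinct allele of the genotype.

    ``nonamers`` may be Nonamer objects (provenance is attached from the
    parent consequence) or bare 9-mer strings.
    """
    records: List[BindingRecord] = []
    alleles = genotype.distinct_alleles
    missing = [a for a in alleles if a not in matrices]
    if missing:
        raise InputFormatError(f"no scoring matrix for alleles {missing}")
    for nm in nonamers:
        if isinstance(nm, str):
            seq, prov = nm, {}
        else:
            cons = nm.parent.consequence
            seq = nm.sequence
            prov = {
                "gene": cons.gene_id,
                "transcript": cons.transcript_id,
                "chrom": cons.variant.chrom,
                "pos": cons.variant.pos,
                "variant_pos": nm.variant_pos,
            }
        for allele in alleles:
            ic50 = predict_ic50_smm(seq, matrices[allele])
            records.append(BindingRecord.make(seq, allele, Predictor.SMM, ic50, prov))
    return records


# --- external pan-specific predictor output --------------------------------

DEFAULT_PAN_COLUMNS = {"allele": "HLA", "peptide": "Peptide", "affinity": "Aff(nM)"}

_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


def parse_pan_predictor_output(
    stream: io.TextIOBase | str,
    columns: Optional[Mapping[str, str]] = None,
) -> List[BindingRecord]:
    """Parse captured tabular output of a pan-specific predictor.

    The stream must contain at least one header line naming the mapped
    columns; data rows are whitespace-delimited. Separator/summary lines are
    skipped; rows whose affinity does not parse are counted and skipped.
    Concatenations of several runs (repeated headers) are accepted.
    Raises InputFormatError when no data row parses at all.
    """
    colmap = dict(DEFAULT_PAN_COLUMNS)
    if columns:
        colmap.update(columns)
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: List[BindingRecord] = []
    idx: Optional[Dict[str, int]] = None
    n_bad = 0
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith(("#", "-", "=")):
            continue
        tokens = line.split()
        if colmap["peptide"] in tokens and colmap["affinity"] in tokens:
            idx = {k: tokens.index(v) for k, v in colmap.items()}
            continue
        if idx is None:
            continue
        needed = max(idx.values())
        if len(tokens) <= needed:
            continue  # summary / footer line
        peptide = tokens[idx["peptide"]]
        if not _PEPTIDE_RE.match(peptide):
            continue
        try:
            aff = float(tokens[idx["affinity"]])
        except ValueError:
            n_bad += 1
            continue
        allele = tokens[idx["allele"]]
        records.append(BindingRecord.make(peptide, allele, Predictor.PAN, aff))
    if not records:
        raise InputFormatError(
            f"no data rows parsed from pan-predictor output ({n_bad} unparsable rows)"
        )
    return records


# --- predictor agreement ----------------------------------------------------


@dataclass(frozen=True)
class PeptideHlaComplex:
    """A (peptide, allele) complex with one IC50 per predictor."""

    peptide: str
    allele: str
    ic50_by_predictor: Tuple[Tuple[str, float], ...]

    @property
    def key(self) -> Tuple[str, str]:
        return (self.peptide, self.allele)

    def ic50(self, predictor: Predictor | str) -> float:
        return dict(self.ic50_by_predictor)[Predictor(predictor).value]


def best_ic50_by_key(records: Iterable[BindingRecord]) -> Dict[Tuple[str, str], float]:
    """Deduplicate records on (peptide, allele), keeping the best (lowest) IC50."""
    out: Dict[Tuple[str, str], float] = {}
    for r in records:
        cur = out.get(r.key)
        if cur is None or r.ic50_nM < cur:
            out[r.key] = r.ic50_nM
    return out


def shared_complexes(
    smm_records: Iterable[BindingRecord],
    pan_records: Iterable[BindingRecord],
    presented_nM: float = PRESENTED_NM,
) -> Set[PeptideHlaComplex]:
    """(peptide, allele) complexes called presented (<500 nM) by BOTH predictors."""
    smm = best_ic50_by_key(smm_records)
    pan = best_ic50_by_key(pan_records)
    out: Set[PeptideHlaComplex] = set()
    for key in smm.keys() & pan.keys():
        if smm[key] < presented_nM and pan[key] < presented_nM:
            out.add(
                PeptideHlaComplex(
                    peptide=key[0],
                    allele=key[1],
                    ic50_by_predictor=(
                        (Predictor.SMM.value, smm[key]),
                        (Predictor.PAN.value, pan[key]),
                    ),
                )
            )
    return out


def correlate_predictions(
    shared: Iterable[PeptideHlaComplex], log_scale: bool = False
) -> Tuple[float, float, int]:
    """Pearson correlation between the two predictors' IC50s over the shared set.

    Raw nM scale by default; ``log_scale`` correlates log10 affinities instead
    (affinities are log-distributed, so this is often the better-behaved axis).
    """
    shared = sorted(shared, key=lambda c: c.key)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared complexes for a correlation, got {len(shared)}"
        )
    x = np.array([c.ic50(Predictor.SMM) for c in shared])
    y = np.array([c.ic50(Predictor.PAN) for c in shared])
    if log_scale:
        x, y = np.log10(x), np.log10(y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(shared)


def write_binding_csv(records: Sequence[BindingRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide,allele,predictor,ic50_nM,presentation,gene,chrom,pos\n")
        for r in sorted(records, key=lambda r: (r.peptide, r.allele, r.predictor.value, r.ic50_nM)):
            prov = r.provenance_dict()
            fh.write(
                f"{r.peptide},{r.allele},{r.predictor.value},{r.ic50_nM:.6g},"
                f"{r.presentation.value},{prov.get('gene','')},{prov.get('chrom','')},{prov.get('pos','')}\n"
            )


def read_binding_csv(path: str | Path) -> List[BindingRecord]:
    records: List[BindingRecord] = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(",")
            prov = {}
            for k in ("gene", "chrom"):
                if col.get(k) is not None and parts[col[k]]:
                    prov[k] = parts[col[k]]
            if col.get("pos") is not None and parts[col["pos"]]:
                prov["pos"] = int(parts[col["pos"]])
            records.append(
                BindingRecord.make(
                    parts[col["peptide"]],
                    parts[col["allele"]],
                    parts[col["predictor"]],
                    float(parts[col["ic50_nM"]]),
                    prov,
                )
            )
    return records
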