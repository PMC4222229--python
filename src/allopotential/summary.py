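"""Alloreactivity-potential summary statistics.

The pipeline's output layer condenses each donor–recipient pair's library of
predicted peptide–HLA affinities into:

* the **alloreactivity potential**: peptides with IC50 at or below a cutoff
  (default 100 nM) are ranked by ascending IC50; a second-order polynomial is
  fitted to IC50 as a function of rank, and its definite integral over the
  rank axis (a = 1 to b = N) gives an area in nM·Peptide. A steep, long curve
  (many strong binders) yields a large potential;
* an expression-weighted potential: sum over complexes of
  relative-expression(gene, tissue) × (1 / IC50) — a per-clone antigenic
  pressure proxy;
* a rank/affinity power-law fit on reciprocal IC50 (log-log least squares);
* per-pair presented / strongly-presented counts with medians and ranges, and
  exact Mann–Whitney U comparisons between donor-type groups (complete
  enumeration of labelings for small samples, the regime of a nine-pair
  cohort).
"""

from __future__ import annotations

import enum
import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .binding import (
    BindingRecord,
    PeptideHlaComplex,
    Predictor,
    Presentation,
    allele_locus,
    best_ic50_by_key,
    shared_complexes,
)
from .errors import InsufficientDataError
from .expression import ExpressionTable

PRESENTED_NM = 500.0
STRONG_NM = 50.0
AUC_CUTOFF_NM = 100.0


# --- rank curve, quadratic fit, closed-form integral ------------------------


def rank_ic50_curve(
    records: Iterable[BindingRecord], cutoff_nM: float = AUC_CUTOFF_NM
) -> List[Tuple[int, float]]:
    """Ascending-IC50 rank series of records with IC50 <= cutoff.

    Duplicate complexes are retained (the potential is computed on the raw
    library). Ties break on (peptide, allele) lexicographic order so runs are
    reproducible.
    """
    if not cutoff_nM > 0:
        raise ValueError("cutoff must be positive")
    kept = [r for r in records if r.ic50_nM <= cutoff_nM]
    kept.sort(key=lambda r: (r.ic50_nM, r.peptide, r.allele))
    return [(i + 1, r.ic50_nM) for i, r in enumerate(kept)]


def fit_quadratic(series: Sequence[Tuple[float, float]]) -> Tuple[Tuple[float, float, float], float]:
    """OLS fit of y on (x^2, x, 1). Returns ((c2, c1, c0), rmse)."""
    if len(series) < 3:
        raise InsufficientDataError(f"quadratic fit needs >= 3 points, got {len(series)}")
    x = np.array([p[0] for p in series], dtype=float)
    y = np.array([p[1] for p in series], dtype=float)
    c2, c1, c0 = np.polyfit(x, y, 2)
    resid = y - (c2 * x**2 + c1 * x + c0)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return (float(c2), float(c1), float(c0)), rmse


def integrate_curve(c2: float, c1: float, c0: float, a: float, b: float) -> float:
    """Closed-form definite integral of c2 x^2 + c1 x + c0 over [a, b]."""
    if a > b:
        raise ValueError(f"lower bound {a} exceeds upper bound {b}")
    return c2 * (b**3 - a**3) / 3.0 + c1 * (b**2 - a**2) / 2.0 + c0 * (b - a)


@dataclass(frozen=True)
class AucResult:
    """Alloreactivity potential of one donor–recipient pair, in nM·Peptide."""

    coefficients: Tuple[float, float, float]  # (c2, c1, c0)
    a: float
    b: float
    auc: float
    n_points: int
    cutoff_nM: float
    fit_rmse: float
    fallback: bool  # True when < 3 points forced a trapezoid (or zero) area


def compute_alloreactivity_potential(
    records: Iterable[BindingRecord], cutoff_nM: float = AUC_CUTOFF_NM
) -> AucResult:
    """Rank -> quadratic fit -> closed-form integral over ranks 1..N.

    With fewer than 3 retained points the quadratic is unidentifiable; the
    trapezoid area of the raw series is reported with the fallback flag set
    (0 for an empty series).
    """
    series = rank_ic50_curve(records, cutoff_nM=cutoff_nM)
    n = len(series)
    if n == 0:
        return AucResult((0.0, 0.0, 0.0), 0.0, 0.0, 0.0, 0, cutoff_nM, 0.0, True)
    if n < 3:
        x = [p[0] for p in series]
        y = [p[1] for p in series]
        area = float(np.trapezoid(y, x))
        return AucResult((0.0, 0.0, 0.0), 1.0, float(n), area, n, cutoff_nM, 0.0, True)
    (c2, c1, c0), rmse = fit_quadratic(series)
    a, b = 1.0, float(n)
    auc = integrate_curve(c2, c1, c0, a, b)
    return AucResult((c2, c1, c0), a, b, auc, n, cutoff_nM, rmse, False)


# --- expression-weighted potential ------------------------------------------


@dataclass
class WeightedPotential:
    value: float
    tissue: str
    terms: pd.DataFrame  # peptide, allele, gene, ic50_nM, reu, term
    n_missing_genes: int


def weighted_potential(
    records: Iterable[BindingRecord], expression: ExpressionTable, tissue: str
) -> WeightedPotential:
    """Sum over records of REU(gene, tissue) * (1 / IC50 nM).

    Records whose gene is absent from the expression table contribute 0 and
    are counted in ``n_missing_genes``.
    """
    if tissue not in expression.tissues:
        raise KeyError(
            f"unknown tissue {tissue!r}; available tissues: {sorted(expression.tissues)}"
        )
    rows = []
    missing = set()
    for r in sorted(records, key=lambda r: (r.peptide, r.allele)):
        gene = r.provenance_dict().get("gene")
        if gene is not None and gene in expression.genes:
            reu = expression.value(gene, tissue)
        else:
            reu = 0.0
            missing.add(gene)
        rows.append(
            {
                "peptide": r.peptide,
                "allele": r.allele,
                "gene": gene,
                "ic50_nM": r.ic50_nM,
                "reu": reu,
                "term": reu / r.ic50_nM,
            }
        )
    terms = pd.DataFrame(rows, columns=["peptide", "allele", "gene", "ic50_nM", "reu", "term"])
    return WeightedPotential(
        value=float(terms["term"].sum()) if len(terms) else 0.0,
        tissue=tissue,
        terms=terms,
        n_missing_genes=len(missing),
    )


# --- power-law fit on reciprocal affinity -----------------------------------


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    intercept: float
    r_squared: float
    n: int


def fit_power_law(records: Iterable) -> PowerLawFit:
    """Fit log10(1/IC50) = intercept + exponent * log10(rank).

    Reciprocal affinities are sorted descending (rank 1 = strongest binder);
    ``records`` may be BindingRecord objects or raw IC50 floats.
    """
    ic50s = [r.ic50_nM if hasattr(r, "ic50_nM") else float(r) for r in records]
    if any(v <= 0 for v in ic50s):
        raise ValueError("IC50 values must be positive")
    if len(ic50s) < 3:
        raise InsufficientDataError(f"power-law fit needs >= 3 records, got {len(ic50s)}")
    recip = np.sort(1.0 / np.asarray(ic50s, dtype=float))[::-1]
    rank = np.arange(1, len(recip) + 1, dtype=float)
    res = stats.linregress(np.log10(rank), np.log10(recip))
    return PowerLawFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(recip),
    )


# --- exact Mann-Whitney U ----------------------------------------------------


class MwMethod(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


@dataclass(frozen=True)
class GroupComparison:
    group_a_values: Tuple[float, ...]
    group_b_values: Tuple[float, ...]
    u_statistic: float
    p_two_sided: float
    method: MwMethod


def _u_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """U for group a: #(a > b) + 0.5 * #(a == b) over all pairs."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def exact_u_distribution(n: int, m: int) -> Dict[int, float]:
    """Null distribution of U for sample sizes (n, m) without ties, by
    complete enumeration of all C(n+m, n) labelings of the pooled ranks."""
    total = math.comb(n + m, n)
    counts: Counter = Counter()
    base = n * (n + 1) // 2
    for combo in itertools.combinations(range(1, n + m + 1), n):
        counts[sum(combo) - base] += 1
    return {u: c / total for u, c in sorted(counts.items())}


def exact_mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], max_exact_n: int = 20
) -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    For pooled sample size <= ``max_exact_n`` with no ties the exact null
    distribution of U is built by complete enumeration and
    p = min(1, 2·min(P(U <= u), P(U >= u))). Otherwise a tie-corrected normal
    approximation with continuity correction is used and the method flag says
    so.
    """
    a = [float(v) for v in group_a]
    b = [float(v) for v in group_b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    n, m = len(a), len(b)
    u = _u_statistic(a, b)
    pooled = a + b
    has_ties = len(set(pooled)) < len(pooled)
    if n + m <= max_exact_n and not has_ties:
        dist = exact_u_distribution(n, m)
        p_le = sum(p for uu, p in dist.items() if uu <= u)
        p_ge = sum(p for uu, p in dist.items() if uu >= u)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = MwMethod.EXACT
    else:
        N = n + m
        mean = n * m / 2.0
        tie_counts = Counter(pooled).values()
        tie_term = sum(t**3 - t for t in tie_counts) / (N * (N - 1))
        var = n * m / 12.0 * ((N + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mean) - 0.5) / math.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * stats.norm.sf(z))
        method = MwMethod.NORMAL_APPROX
    return GroupComparison(
        group_a_values=tuple(a),
        group_b_values=tuple(b),
        u_statistic=u,
        p_two_sided=p,
        method=method,
    )


# --- per-pair summary table --------------------------------------------------

COUNT_COLUMNS = [
    "smm_presented",
    "smm_strong",
    "pan_presented",
    "pan_strong",
    "shared_presented",
]


@dataclass
class SummaryTable:
    """Per-pair counts plus aggregate statistics, mirroring a cohort table."""

    rows: pd.DataFrame

    def aggregate(self) -> Dict[str, Dict[str, float]]:
        """Median and min-max range per count column (order-statistic median)."""
        out: Dict[str, Dict[str, float]] = {}
        for col in self.rows.columns:
            if col in ("pair_id", "donor_type"):
                continue
            vals = self.rows[col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            out[col] = {
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        return out

    def compare_donor_types(
        self, column: str, group_a: str = "MRD", group_b: str = "URD"
    ) -> GroupComparison:
        """Exact Mann–Whitney between donor-type groups on one count column."""
        a = self.rows.loc[self.rows["donor_type"] == group_a, column].tolist()
        b = self.rows.loc[self.rows["donor_type"] == group_b, column].tolist()
        return exact_mann_whitney(a, b)


def per_locus_presented_counts(
    records: Iterable[BindingRecord], presented_nM: float = PRESENTED_NM
) -> Dict[str, int]:
    """Distinct presented (peptide, allele) complexes per HLA locus (A/B/C)."""
    best = best_ic50_by_key(records)
    counts: Dict[str, int] = {"A": 0, "B": 0, "C": 0}
    for (pep, allele), ic50 in best.items():
        if ic50 < presented_nM:
            counts[allele_locus(allele)] += 1
    return counts


def summarize_counts(
    pair_records: Mapping[str, Mapping[str, Sequence[BindingRecord]]],
    donor_types: Optional[Mapping[str, str]] = None,
    presented_nM: float = PRESENTED_NM,
    strong_nM: float = STRONG_NM,
    dedup: bool = True,
) -> SummaryTable:
    """Per-pair presented / strongly-presented counts per predictor.

    ``pair_records`` maps pair id -> {"SMM": records, "PAN": records}; either
    predictor may be absent. Counts are over unique (peptide, allele)
    complexes by default (set ``dedup=False`` to count raw records, the
    convention used for the rank-curve potential, not for count tables).
    """
    rows = []
    for pair_id in sorted(pair_records):
        preds = pair_records[pair_id]
        row: Dict[str, object] = {"pair_id": pair_id}
        if donor_types:
            row["donor_type"] = donor_types.get(pair_id, "")
        for predictor, prefix in ((Predictor.SMM, "smm"), (Predictor.PAN, "pan")):
            recs = list(preds.get(predictor.value, []))
            if dedup:
                best = best_ic50_by_key(recs)
                vals = list(best.values())
            else:
                vals = [r.ic50_nM for r in recs]
            row[f"{prefix}_presented"] = sum(1 for v in vals if v < presented_nM)
            row[f"{prefix}_strong"] = sum(1 for v in vals if v < strong_nM)
        smm = list(preds.get(Predictor.SMM.value, []))
        pan = list(preds.get(Predictor.PAN.value, []))
        if smm and pan:
            row["shared_presented"] = len(shared_complexes(smm, pan, presented_nM))
        for locus, cnt in per_locus_presented_counts(smm, presented_nM).items():
            row[f"smm_presented_locus_{locus}"] = cnt
        rows.append(row)
    return SummaryTable(rows=pd.DataFrame(rows))


# --- optional plotting -------------------------------------------------------


def plot_rank_curve(result: AucResult, series: Sequence[Tuple[int, float]], path) -> None:
    """Rank-vs-IC50 scatter with the fitted quadratic overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if series:
        x = [p[0] for p in series]
        y = [p[1] for p in series]
        ax.plot(x, y, ".", ms=3, label="peptide-HLA complexes")
        if not result.fallback:
            c2, c1, c0 = result.coefficients
            xx = np.linspace(result.a, result.b, 200)
            ax.plot(xx, c2 * xx**2 + c1 * xx + c0, "-", label="quadratic fit")
        ax.legend(frameon=False)
    ax.set_xlabel("rank (ascending IC50)")
    ax.set_ylabel("IC50 (nM)")
    ax.set_title(f"alloreactivity potential = {result.auc:.4g} nM·Peptide")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
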