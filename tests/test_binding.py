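import math

import numpy as np
import pytest

import allopotential as ap
from allopotential.binding import (
    AMINO_ACIDS,
    BindingRecord,
    Predictor,
    Presentation,
    allele_locus,
    best_ic50_by_key,
)
from allopotential.errors import InputFormatError, InsufficientDataError


def zero_matrix(intercept=0.0, allele="HLA-A*02:01"):
    return ap.ScoringMatrix(allele=allele, cells=np.zeros((9, 20)), intercept=intercept)


class TestScoringMatrix:
    def test_zero_matrix_scores_any_peptide_to_one_nM(self):
        assert ap.predict_ic50_smm("KLAETVAKL", zero_matrix()) == 1.0

    def test_intercept_log500_lands_exactly_on_boundary(self):
        m = zero_matrix(intercept=math.log10(500.0))
        ic50 = ap.predict_ic50_smm("KLAETVAKL", m)
        assert ic50 == 500.0
        assert ap.classify_presentation(ic50) is Presentation.NONE

    def test_cells_summing_to_one_with_half_intercept(self):
        peptide = "KLAETVAKL"
        cells = np.zeros((9, 20))
        for i, aa in enumerate(peptide):
            cells[i, AMINO_ACIDS.index(aa)] = 1.0 / 9.0
        m = ap.ScoringMatrix(allele="HLA-A*02:01", cells=cells, intercept=0.5)
        assert ap.predict_ic50_smm(peptide, m) == pytest.approx(10**1.5, rel=1e-9)

    def test_nonstandard_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            ap.predict_ic50_smm("KLXETVAKL", zero_matrix())

    def test_extreme_scores_clipped(self):
        assert ap.predict_ic50_smm("AAAAAAAAA", zero_matrix(intercept=9.0)) == 50000.0
        assert ap.predict_ic50_smm("AAAAAAAAA", zero_matrix(intercept=-9.0)) == 0.01

    def test_wrong_dimensions_rejected(self):
        with pytest.raises(ValueError, match="9x20|\\(9, 20\\)"):
            ap.ScoringMatrix(allele="x", cells=np.zeros((8, 20)), intercept=0.0)

    def test_file_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        m = ap.ScoringMatrix(
            allele="HLA-B*07:02", cells=rng.normal(size=(9, 20)), intercept=rng.normal()
        )
        path = tmp_path / "m.mat"
        ap.write_scoring_matrix(m, path)
        back = ap.load_scoring_matrix(path)
        assert back.allele == m.allele
        assert back.intercept == m.intercept
        assert np.array_equal(back.cells, m.cells)

    def test_truncated_file_is_a_dimension_error(self, tmp_path):
        m = zero_matrix()
        path = tmp_path / "m.mat"
        ap.write_scoring_matrix(m, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(InputFormatError, match="9x20"):
            ap.load_scoring_matrix(path)

    def test_position_permutation_changes_scores(self):
        rng = np.random.default_rng(4)
        cells = rng.normal(size=(9, 20))
        m = ap.ScoringMatrix(allele="x", cells=cells, intercept=0.0)
        permuted = ap.ScoringMatrix(allele="x", cells=cells[::-1].copy(), intercept=0.0)
        peptide = "KLAETVAKW"
        assert ap.predict_ic50_smm(peptide, m) != ap.predict_ic50_smm(peptide, permuted)

    def test_scoring_monotone_in_single_cell(self):
        peptide = "KLAETVAKL"
        base = zero_matrix()
        bumped = zero_matrix()
        bumped.cells[0, AMINO_ACIDS.index("K")] += 0.3
        assert ap.predict_ic50_smm(peptide, bumped) > ap.predict_ic50_smm(peptide, base)


class TestClassification:
    @pytest.mark.parametrize(
        "ic50,expected",
        [
            (49.9, Presentation.STRONGLY_PRESENTED),
            (50.0, Presentation.PRESENTED),
            (499.99, Presentation.PRESENTED),
            (500.0, Presentation.NONE),
            (1.0, Presentation.STRONGLY_PRESENTED),
            (50000.0, Presentation.NONE),
        ],
    )
    def test_strict_thresholds(self, ic50, expected):
        assert ap.classify_presentation(ic50) is expected

    def test_non_positive_ic50_rejected(self):
        with pytest.raises(ValueError):
            ap.classify_presentation(0.0)

    def test_strong_class_is_nested_in_presented(self, bundle):
        records = _scored_records(bundle)
        strong = {r.key for r in records if r.presentation is Presentation.STRONGLY_PRESENTED}
        presented = {
            r.key for r in records if r.presentation is not Presentation.NONE
        }
        assert strong <= presented


class TestHlaGenotype:
    def test_locus_parsing(self):
        assert allele_locus("HLA-A*02:01") == "A"
        assert allele_locus("B*07:02") == "B"
        with pytest.raises(ValueError):
            allele_locus("DRB1*15:01")

    def test_homozygous_alleles_scored_once(self):
        g = ap.HlaGenotype("p", ("HLA-A*01:01", "HLA-A*01:01", "HLA-B*07:02"))
        assert g.distinct_alleles == ("HLA-A*01:01", "HLA-B*07:02")

    def test_allele_count_bounds(self):
        with pytest.raises(ValueError):
            ap.HlaGenotype("p", tuple())
        with pytest.raises(ValueError):
            ap.HlaGenotype("p", tuple(f"HLA-A*{i:02d}:01" for i in range(7)))


PAN_FIXTURE = """\
# NetMHCpan-style captured output
pos HLA Peptide Identity Aff(nM)
---------------------------------
1 HLA-A*02:01 KLAETVAKL seq1 32.50
2 HLA-A*02:01 LAETVAKLW seq1 1200.00
3 HLA-B*07:02 KLAETVAKL seq1 450.00
---------------------------------
Protein seq1. Allele HLA-A*02:01. Number of high binders 1
"""


class TestPanParser:
    def test_fixture_rows_parsed_verbatim(self):
        records = ap.parse_pan_predictor_output(PAN_FIXTURE)
        assert len(records) == 3
        by_key = {r.key: r for r in records}
        assert by_key[("KLAETVAKL", "HLA-A*02:01")].ic50_nM == 32.5
        assert by_key[("KLAETVAKL", "HLA-A*02:01")].presentation is Presentation.STRONGLY_PRESENTED
        assert by_key[("LAETVAKLW", "HLA-A*02:01")].presentation is Presentation.NONE
        assert all(r.predictor is Predictor.PAN for r in records)

    def test_trailing_summary_lines_ignored(self):
        records = ap.parse_pan_predictor_output(PAN_FIXTURE + "\nsome trailing note\n")
        assert len(records) == 3

    def test_concatenated_runs_accepted(self):
        records = ap.parse_pan_predictor_output(PAN_FIXTURE + PAN_FIXTURE)
        assert len(records) == 6

    def test_empty_stream_is_an_error(self):
        with pytest.raises(InputFormatError):
            ap.parse_pan_predictor_output("")


def _scored_records(bundle):
    import pandas as pd

    cfg = ap.PipelineConfig.from_yaml(bundle["config"])
    matrices = {a: ap.load_scoring_matrix(p) for a, p in cfg.matrix_paths.items()}
    nona = pd.read_csv(bundle["truth_nonamers"])
    genotype = ap.HlaGenotype("p", tuple(cfg.hla_alleles))
    records = []
    for nm in nona.nonamer.unique():
        for allele in genotype.distinct_alleles:
            ic50 = ap.predict_ic50_smm(nm, matrices[allele])
            records.append(BindingRecord.make(nm, allele, "SMM", ic50))
    return records


class TestSharedComplexes:
    def test_disjoint_peptide_sets_share_nothing(self):
        smm = [BindingRecord.make("AAAAAAAAA", "HLA-A*01:01", "SMM", 10.0)]
        pan = [BindingRecord.make("CCCCCCCCC", "HLA-A*01:01", "PAN", 10.0)]
        assert ap.shared_complexes(smm, pan) == set()

    def test_one_predictor_above_threshold_excludes_pair(self):
        smm = [BindingRecord.make("AAAAAAAAA", "HLA-A*01:01", "SMM", 40.0)]
        pan = [BindingRecord.make("AAAAAAAAA", "HLA-A*01:01", "PAN", 900.0)]
        assert ap.shared_complexes(smm, pan) == set()

    def test_against_nested_loop_oracle(self):
        rng = np.random.default_rng(9)
        aas = list(AMINO_ACIDS)
        peptides = ["".join(rng.choice(aas, size=9)) for _ in range(30)]
        allele = "HLA-A*01:01"
        smm = [
            BindingRecord.make(p, allele, "SMM", float(rng.uniform(5, 1500)))
            for p in peptides[:20]
        ]
        pan = [
            BindingRecord.make(p, allele, "PAN", float(rng.uniform(5, 1500)))
            for p in peptides[10:25]
        ]
        shared = ap.shared_complexes(smm, pan)
        oracle = set()
        for s in smm:
            for q in pan:
                if s.key == q.key and s.ic50_nM < 500 and q.ic50_nM < 500:
                    oracle.add(s.key)
        assert {c.key for c in shared} == oracle
        smm_presented = {r.key for r in smm if r.ic50_nM < 500}
        pan_presented = {r.key for r in pan if r.ic50_nM < 500}
        assert {c.key for c in shared} <= smm_presented
        assert {c.key for c in shared} <= pan_presented

    def test_duplicates_collapse_to_best_ic50(self):
        recs = [
            BindingRecord.make("AAAAAAAAA", "HLA-A*01:01", "SMM", 300.0),
            BindingRecord.make("AAAAAAAAA", "HLA-A*01:01", "SMM", 100.0),
        ]
        assert best_ic50_by_key(recs) == {("AAAAAAAAA", "HLA-A*01:01"): 100.0}


class TestCorrelation:
    def _complexes(self, x, y):
        return {
            ap.PeptideHlaComplex(
                peptide=f"PEP{i:03d}AAAA"[:9],
                allele="HLA-A*01:01",
                ic50_by_predictor=(("SMM", float(a)), ("PAN", float(b))),
            )
            for i, (a, b) in enumerate(zip(x, y))
        }

    def test_identical_vectors_give_r_one(self):
        # distinct peptides needed: build keys explicitly
        vals = [10.0, 50.0, 200.0, 400.0]
        shared = {
            ap.PeptideHlaComplex(f"AAAAAAAA{c}", "HLA-A*01:01", (("SMM", v), ("PAN", v)))
            for c, v in zip("CDEF", vals)
        }
        r, p, n = ap.correlate_predictions(shared)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_perfect_negative_affine_map_gives_minus_one(self):
        vals = [10.0, 50.0, 200.0, 400.0]
        shared = {
            ap.PeptideHlaComplex(f"AAAAAAAA{c}", "HLA-A*01:01", (("SMM", v), ("PAN", 500.0 - v)))
            for c, v in zip("CDEF", vals)
        }
        r, _, _ = ap.correlate_predictions(shared)
        assert r == pytest.approx(-1.0)

    def test_generating_correlation_recovered(self):
        rng = np.random.default_rng(42)
        n = 500
        rho = 0.6
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([2.0, 2.0], cov, size=n)
        aas = list(AMINO_ACIDS)
        shared = set()
        for i, (a, b) in enumerate(xy):
            pep = "".join(aas[(i // 20**k) % 20] for k in range(9))
            shared.add(
                ap.PeptideHlaComplex(pep, "HLA-A*01:01", (("SMM", float(a)), ("PAN", float(b))))
            )
        r, p, m = ap.correlate_predictions(shared)
        assert m == n
        assert r == pytest.approx(rho, abs=0.1)
        assert p < 0.01

    def test_fewer_than_three_points_is_an_error(self):
        shared = self._complexes([1.0], [2.0])
        with pytest.raises(InsufficientDataError):
            ap.correlate_predictions(shared)
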