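"""Aggregation, correlation, agreement, contingency and group comparisons."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import isopept as ip
from isopept.assignment import AssignmentResult, Strategy
from isopept.integration_stats import IntegrationRow
from isopept.transcript_layer import CONTROL, DEPLETED

from conftest import expression_from_medians, intensity_matrix


def rows_from(rna, protein):
    return [
        IntegrationRow(f"t{i}", float(r), float(p), 1)
        for i, (r, p) in enumerate(zip(rna, protein))
    ]


def assignment_for(transcript, peptides):
    return AssignmentResult(Strategy.UNIQUE_ONLY, {p: transcript for p in peptides})


class TestTranscriptProteinFC:
    def test_sum_doubling(self):
        m = intensity_matrix({"p1": {CONTROL: [10, 10, 10], DEPLETED: [20, 20, 20]}})
        res = ip.transcript_protein_fc_sum(assignment_for("t", ["p1"]), m, "t")
        assert res == pytest.approx(1.0)

    def test_sum_preserves_common_ratio(self):
        m = intensity_matrix(
            {"p1": {CONTROL: [10, 10, 10], DEPLETED: [20, 20, 20]},
             "p2": {CONTROL: [4, 4, 4], DEPLETED: [8, 8, 8]}}
        )
        res = ip.transcript_protein_fc_sum(assignment_for("t", ["p1", "p2"]), m, "t")
        assert res == pytest.approx(1.0)

    def test_identity_is_zero(self):
        m = intensity_matrix({"p1": {CONTROL: [5, 5, 5], DEPLETED: [5, 5, 5]}})
        assert ip.transcript_protein_fc_sum(assignment_for("t", ["p1"]), m, "t") == 0.0

    @pytest.mark.parametrize(
        "ratios,expected_log2", [((2, 2, 8), 1.0), ((0.5, 1.0, 2.0), 0.0)]
    )
    def test_median_of_peptide_fold_changes(self, ratios, expected_log2):
        m = intensity_matrix(
            {f"p{i}": {CONTROL: [10, 10, 10], DEPLETED: [10 * f] * 3}
             for i, f in enumerate(ratios)}
        )
        res = ip.transcript_protein_fc_median(
            assignment_for("t", [f"p{i}" for i in range(len(ratios))]), m, "t"
        )
        assert res == pytest.approx(expected_log2)

    def test_sum_equals_median_for_single_peptide(self):
        m = intensity_matrix({"p": {CONTROL: [3, 4, 5], DEPLETED: [9, 8, 10]}})
        a = assignment_for("t", ["p"])
        assert ip.transcript_protein_fc_sum(a, m, "t") == pytest.approx(
            ip.transcript_protein_fc_median(a, m, "t")
        )

    def test_no_peptides_raises(self):
        m = intensity_matrix({"p": {CONTROL: [1, 1], DEPLETED: [1, 1]}})
        with pytest.raises(KeyError):
            ip.transcript_protein_fc_sum(assignment_for("t", []), m, "other")


class TestCorrelate:
    def test_worked_four_point_example(self):
        summ = ip.correlate(rows_from([1, 2, 3, 4], [1, 3, 2, 4]))
        assert summ.spearman_rho == pytest.approx(0.8)

    def test_identical_vectors(self):
        summ = ip.correlate(rows_from([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))
        assert summ.spearman_rho == pytest.approx(1.0)
        assert summ.pearson_r == pytest.approx(1.0)
        assert summ.agreement_pct == 100.0

    def test_agreement_tally_example(self):
        assert ip.agreement_pct(21, 9) == pytest.approx(70.0)

    def test_zero_fold_change_counts_as_disagreement(self):
        summ = ip.correlate(rows_from([1.0, -1.0, 0.5], [0.0, -2.0, 1.0]))
        assert summ.n_agree == 2
        assert summ.n_disagree == 1
        assert summ.agreement_pct + 100.0 * summ.n_disagree / 3 == pytest.approx(100.0)

    def test_under_three_rows_counts_only(self):
        summ = ip.correlate(rows_from([1, 2], [2, 4]))
        assert math.isnan(summ.spearman_rho)
        assert summ.n_transcripts == 2
        assert summ.n_agree == 2

    @given(
        st.lists(
            st.tuples(st.integers(-4000, 4000), st.integers(-4000, 4000)),
            min_size=5, max_size=30, unique_by=lambda t: t[0],
        )
    )
    def test_spearman_invariant_under_monotone_transform(self, pairs):
        rna = [r / 1000 for r, _ in pairs]
        prot = [p / 1000 for _, p in pairs]
        base = ip.correlate(rows_from(rna, prot)).spearman_rho
        warped = ip.correlate(
            rows_from([math.exp(r) for r in rna], [p**3 for p in prot])
        ).spearman_rho
        if not math.isnan(base):
            assert warped == pytest.approx(base, abs=1e-9)


class TestContingency:
    @pytest.mark.parametrize(
        "a,n1,b,n2,expected",
        [(1, 2, 1, 2, 1.0), (3, 4, 1, 4, 9.0)],
    )
    def test_odds_ratio_examples(self, a, n1, b, n2, expected):
        assert ip.contingency_from_counts(a, n1, b, n2).odds_ratio == pytest.approx(expected)

    @given(
        st.integers(1, 20), st.integers(1, 20), st.integers(1, 20), st.integers(1, 20)
    )
    def test_odds_ratio_matches_cross_product(self, a, c, b, d):
        res = ip.contingency_from_counts(a, a + c, b, b + d)
        assert res.odds_ratio == pytest.approx((a * d) / (c * b))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ip.contingency_from_counts(5, 4, 1, 2)


def exhaustive_ranksum_p(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    from scipy.stats import rankdata

    combined = np.array(list(x) + list(y))
    n = len(x)
    ranks = rankdata(combined)
    observed = ranks[:n].sum()
    mu = ranks.sum() * n / len(combined)
    stats = [
        abs(sum(ranks[list(idx)]) - mu)
        for idx in itertools.combinations(range(len(combined)), n)
    ]
    return sum(s >= abs(observed - mu) - 1e-12 for s in stats) / len(stats)


class TestIrAnalysis:
    def test_ranksum_matches_exhaustive_enumeration(self):
        x = [0.1, -0.4, -1.2, 0.3]
        y = [0.8, 1.5, 0.2, 1.1, 0.6]
        fc = {f"i{k}": v for k, v in enumerate(x)}
        fc.update({f"n{k}": v for k, v in enumerate(y)})
        calls = ip.DifferentialCalls(
            ir_genes=frozenset(k for k in fc if k.startswith("i")),
            non_ir_genes=frozenset(k for k in fc if k.startswith("n")),
        )
        p, _ = ip.ir_protein_ratio_test(fc, calls)
        assert p == pytest.approx(exhaustive_ranksum_p(x, y), abs=1e-9)

    def test_down_regulated_counting(self):
        fc = {"i1": -0.5, "i2": -0.1, "i3": 0.2, "n1": 0.4, "n2": -0.3, "n3": 0.0}
        calls = ip.DifferentialCalls(
            ir_genes=frozenset({"i1", "i2", "i3"}),
            non_ir_genes=frozenset({"n1", "n2", "n3"}),
        )
        _, cont = ip.ir_protein_ratio_test(fc, calls)
        assert (cont.a, cont.n1, cont.b, cont.n2) == (2, 3, 1, 3)

    def test_empty_group_rejected(self):
        calls = ip.DifferentialCalls(ir_genes=frozenset({"g"}))
        with pytest.raises(ValueError):
            ip.ir_protein_ratio_test({"g": -1.0}, calls)


class TestCodingFraction:
    def test_fraction_examples(self):
        expr = expression_from_medians(
            {
                "c1": {CONTROL: [9] * 3, DEPLETED: [9] * 3},
                "r1": {CONTROL: [1] * 3, DEPLETED: [1] * 3},
                "c2": {CONTROL: [5] * 3, DEPLETED: [1] * 3},
                "r2": {CONTROL: [1] * 3, DEPLETED: [3] * 3},
            },
            {"c1": "Gup", "r1": "Gup", "c2": "Gdown", "r2": "Gdown"},
        )
        transcripts = [
            ip.TranscriptRecord("c1", "Gup", ip.Biotype.PROTEIN_CODING, "MAAAK"),
            ip.TranscriptRecord("r1", "Gup", ip.Biotype.RETAINED_INTRON, None),
            ip.TranscriptRecord("c2", "Gdown", ip.Biotype.PROTEIN_CODING, "MCCCK"),
            ip.TranscriptRecord("r2", "Gdown", ip.Biotype.RETAINED_INTRON, None),
        ]
        calls = ip.DifferentialCalls(ir_genes=frozenset({"Gup", "Gdown"}))
        res = ip.coding_fraction_analysis(
            expr, transcripts, {"Gup": 0.8, "Gdown": -0.9}, calls
        )
        assert res.fractions["Gup"] == pytest.approx(0.9)
        assert res.fractions["Gdown"] == pytest.approx(0.25)
        assert res.median_up == pytest.approx(0.9)
        assert res.median_down == pytest.approx(0.25)

    def test_all_coding_gene_fraction_is_one(self):
        expr = expression_from_medians(
            {"c1": {CONTROL: [4] * 3, DEPLETED: [4] * 3},
             "c2": {CONTROL: [2] * 3, DEPLETED: [2] * 3}},
            {"c1": "G", "c2": "G"},
        )
        transcripts = [
            ip.TranscriptRecord("c1", "G", ip.Biotype.PROTEIN_CODING, "MAAAK"),
            ip.TranscriptRecord("c2", "G", ip.Biotype.PROTEIN_CODING, "MCCCK"),
        ]
        calls = ip.DifferentialCalls(ir_genes=frozenset({"G"}))
        res = ip.coding_fraction_analysis(expr, transcripts, {"G": 0.5}, calls)
        assert res is None  # one-sided split -> warned and skipped

    def test_empty_ir_set_returns_none(self, toy_expression):
        res = ip.coding_fraction_analysis(
            toy_expression, [], {"GA": 1.0}, ip.DifferentialCalls()
        )
        assert res is None


class TestDgeCorrelation:
    def test_permuted_protein_fold_changes_decorrelate(self):
        """Permutation oracle: scrambling one axis should kill the correlation."""
        rng = np.random.default_rng(1)
        rna = rng.normal(0, 1, 200)
        prot = rna + rng.normal(0, 0.3, 200)
        assert ip.correlate(rows_from(rna, prot)).spearman_rho > 0.9
        permuted = rng.permutation(prot)
        assert abs(ip.correlate(rows_from(rna, permuted)).spearman_rho) < 0.25

    def test_perfect_coupling_zero_noise(self):
        ds = ip.simulate_dataset(
            ip.SimulationConfig(n_genes=120, noise_sd=0.0, seed=2)
        )
        res = ip.run_on_dataset(ds, dge_rna_pseudocount=0.0)
        # Pearson is exactly 1; Spearman can dip a hair below when float
        # rounding splits within-gene ties in opposite orders on the two axes
        assert res.dge.all_peptides.spearman_rho == pytest.approx(1.0, abs=0.005)
        assert res.dge.all_peptides.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_gene_summarised_variant_reported(self, small_result):
        dge = small_result.dge
        assert dge.gene_summarised.n_transcripts <= dge.all_peptides.n_transcripts
        assert dge.non_dge_genes.n_transcripts > 0
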