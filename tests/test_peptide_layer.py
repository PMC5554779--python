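"""Digestion, mapping, normalization, fold changes and significance."""
import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import isopept as ip
from isopept.peptide_layer import Uniqueness
from isopept.transcript_layer import CONTROL, DEPLETED

from conftest import intensity_matrix

PROTEIN = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=120)


class TestDigest:
    @pytest.mark.parametrize(
        "seq,mc,expected",
        [
            ("AKRPGKR", 0, ["AK", "RPGK", "R"]),
            ("MMMM", 0, ["MMMM"]),
            ("AKGK", 1, ["AK", "GK", "AKGK"]),
        ],
    )
    def test_worked_examples(self, seq, mc, expected):
        out = ip.digest(seq, min_len=1, max_len=None, max_missed_cleavages=mc)
        assert sorted(out) == sorted(expected)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            ip.digest("AKZ", min_len=1, max_len=None)

    @given(PROTEIN)
    def test_fully_cleaved_fragments_partition_the_protein(self, seq):
        frags = ip.digest(seq, min_len=1, max_len=None, max_missed_cleavages=0)
        assert "".join(frags) == seq

    @given(PROTEIN, st.integers(0, 3))
    def test_matches_external_digestion_engine(self, seq, mc):
        """Cross-check against pyteomics with the same K/R-not-before-P rule."""
        parser = pytest.importorskip("pyteomics.parser")
        ours = set(ip.digest(seq, min_len=1, max_len=None, max_missed_cleavages=mc))
        theirs = parser.cleave(seq, r"[KR](?=[^P])", missed_cleavages=mc)
        assert ours == set(theirs)

    def test_length_filter(self):
        out = ip.digest("AAAAAAKGGGGGGGGR", min_len=7, max_len=10,
                        max_missed_cleavages=1)
        assert out == ["AAAAAAK", "GGGGGGGGR"]  # 16-mer joined product excluded


class TestMapping:
    @pytest.fixture
    def transcripts(self):
        shared, unique_a, unique_b, other = (
            "AAADDDK", "CCCEEEK", "FFFGGGK", "HHHIIIK"
        )
        return [
            ip.TranscriptRecord("tA", "G1", ip.Biotype.PROTEIN_CODING, shared + unique_a),
            ip.TranscriptRecord("tB", "G1", ip.Biotype.PROTEIN_CODING, shared + unique_b),
            ip.TranscriptRecord("tC", "G2", ip.Biotype.PROTEIN_CODING, unique_a + other),
        ]

    def test_uniqueness_classes(self, transcripts):
        peptides = {p.sequence: p for p in ip.map_peptides(transcripts, max_missed_cleavages=0)}
        assert peptides["AAADDDK"].uniqueness is Uniqueness.GENE_SHARED
        assert peptides["FFFGGGK"].uniqueness is Uniqueness.UNIQUE_TRANSCRIPT
        assert peptides["CCCEEEK"].uniqueness is Uniqueness.MULTI_GENE  # in G1 and G2

    def test_multi_gene_removal(self, transcripts):
        peptides = ip.map_peptides(transcripts, max_missed_cleavages=0)
        kept, removed = ip.remove_multi_gene(peptides)
        assert {p.sequence for p in removed} == {"CCCEEEK"}
        assert all(len(p.mapped_genes) == 1 for p in kept)

    def test_classes_partition_peptide_set(self, small_dataset):
        peptides = ip.map_peptides(small_dataset.transcripts)
        counts = {u: 0 for u in Uniqueness}
        for p in peptides:
            counts[p.uniqueness] += 1
        assert sum(counts.values()) == len(peptides)
        assert counts[Uniqueness.UNIQUE_TRANSCRIPT] > 0
        assert counts[Uniqueness.GENE_SHARED] > 0

    def test_empty_transcript_set_rejected(self):
        with pytest.raises(ValueError):
            ip.map_peptides([])


class TestQuantileNormalize:
    def test_hand_computed_reference(self):
        m = intensity_matrix(
            {
                "p1": {CONTROL: [5.0], DEPLETED: [2.0]},
                "p2": {CONTROL: [1.0], DEPLETED: [4.0]},
                "p3": {CONTROL: [3.0], DEPLETED: [6.0]},
            },
            normalized=False,
        )
        out = ip.quantile_normalize(m).values
        assert list(out[(CONTROL, 1)]) == pytest.approx([5.5, 1.5, 3.5])
        assert list(out[(DEPLETED, 1)]) == pytest.approx([1.5, 3.5, 5.5])

    def test_identical_columns_are_fixed_point(self):
        m = intensity_matrix(
            {"p1": {CONTROL: [3.0, 3.0], DEPLETED: [3.0, 3.0]},
             "p2": {CONTROL: [7.0, 7.0], DEPLETED: [7.0, 7.0]}},
            normalized=False,
        )
        out = ip.quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent_and_equal_column_multisets(self):
        rng = np.random.default_rng(0)
        m = intensity_matrix(
            {f"p{i}": {CONTROL: list(rng.lognormal(5, 1, 3)),
                       DEPLETED: list(rng.lognormal(5, 1, 3))}
             for i in range(40)},
            normalized=False,
        )
        once = ip.quantile_normalize(m)
        twice = ip.quantile_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        cols = [np.sort(once.values[c].to_numpy()) for c in once.values.columns]
        for c in cols[1:]:
            np.testing.assert_allclose(c, cols[0])

    def test_matches_limma_reference(self, tmp_path):
        """Independent oracle: limma::normalizeQuantiles via Rscript."""
        rng = np.random.default_rng(42)
        arr = rng.lognormal(6, 1.2, size=(30, 4))
        inp = tmp_path / "m.tsv"
        outp = tmp_path / "out.tsv"
        np.savetxt(inp, arr, delimiter="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.table("{inp}", sep="\t"))
            write.table(normalizeQuantiles(m), "{outp}", sep="\t",
                        row.names=FALSE, col.names=FALSE)
        """)
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr[:200]}")
        expected = np.loadtxt(outp, delimiter="\t")
        cols = pd.MultiIndex.from_tuples(
            [(CONTROL, 1), (CONTROL, 2), (DEPLETED, 1), (DEPLETED, 2)],
            names=["condition", "replicate"],
        )
        m = ip.IntensityMatrix(
            pd.DataFrame(arr, index=[f"p{i}" for i in range(30)], columns=cols)
        )
        np.testing.assert_allclose(ip.quantile_normalize(m).values.to_numpy(), expected,
                                   rtol=1e-10)

    def test_single_column_warns_and_passes_through(self):
        df = pd.DataFrame(
            {("control", 1): [1.0, 2.0]},
        )
        df.columns = pd.MultiIndex.from_tuples(df.columns,
                                               names=["condition", "replicate"])
        with pytest.warns(UserWarning, match=">= 2 columns"):
            out = ip.quantile_normalize(ip.IntensityMatrix(df))
        assert out.normalized


class TestPeptideFoldChange:
    @pytest.mark.parametrize(
        "ctrl,depl,expected",
        [
            ([100, 100, 100], [200, 200, 200], 1.0),
            ([50, 50, 50], [50, 50, 50], 0.0),
            ([4, 4, 4], [1, 1, 1], -2.0),
        ],
    )
    def test_examples(self, ctrl, depl, expected):
        m = intensity_matrix({"pep": {CONTROL: ctrl, DEPLETED: depl}})
        assert ip.peptide_fold_change(m, "pep") == pytest.approx(expected)

    def test_missing_peptide_raises(self):
        m = intensity_matrix({"pep": {CONTROL: [1, 1], DEPLETED: [1, 1]}})
        with pytest.raises(KeyError):
            ip.peptide_fold_change(m, "nope")

    def test_pseudocount_only_enters_on_zero_median(self):
        m = intensity_matrix(
            {"zero": {CONTROL: [0, 0, 0], DEPLETED: [8, 8, 8]},
             "clean": {CONTROL: [2, 2, 2], DEPLETED: [4, 4, 4]}}
        )
        # clean ratio stays exact; zero side uses half-min (= 1.0) on both sides
        assert ip.peptide_fold_change(m, "clean") == pytest.approx(1.0)
        assert ip.peptide_fold_change(m, "zero") == pytest.approx(np.log2(9.0 / 1.0))


class TestSignificance:
    def test_holm_matches_stepdown_formula(self):
        rng = np.random.default_rng(3)
        values = {}
        for i in range(6):
            shift = [1.0, 1.1, 1.3, 2.0, 4.0, 8.0][i]
            values[f"p{i}"] = {
                CONTROL: list(rng.lognormal(5, 0.05, 3)),
                DEPLETED: list(shift * rng.lognormal(5, 0.05, 3)),
            }
        m = intensity_matrix(values)
        stats_out = {s.peptide: s for s in ip.peptide_significance(m)}
        raw = np.array([stats_out[f"p{i}"].raw_p for i in range(6)])
        order = np.argsort(raw)
        expected = np.empty(6)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (6 - rank) * raw[idx])
            expected[idx] = min(1.0, running)
        adjusted = np.array([stats_out[f"p{i}"].adjusted_p for i in range(6)])
        np.testing.assert_allclose(adjusted, expected, rtol=1e-12)

    def test_single_peptide_adjusted_equals_raw(self):
        m = intensity_matrix(
            {"p": {CONTROL: [10.0, 11.0, 9.0], DEPLETED: [30.0, 29.0, 31.0]}}
        )
        (s,) = ip.peptide_significance(m)
        assert s.adjusted_p == pytest.approx(s.raw_p)

    def test_identical_groups_not_significant(self):
        m = intensity_matrix(
            {"p": {CONTROL: [5.0, 5.0, 5.0], DEPLETED: [5.0, 5.0, 5.0]}}
        )
        (s,) = ip.peptide_significance(m)
        assert s.raw_p == 1.0
        assert not s.significant

    def test_adjustment_is_monotone(self, small_dataset):
        out = ip.peptide_significance(small_dataset.intensities)
        by_raw = sorted(out, key=lambda s: s.raw_p)
        adj = [s.adjusted_p for s in by_raw]
        assert adj == sorted(adj)
        assert all(s.adjusted_p >= s.raw_p for s in out)
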