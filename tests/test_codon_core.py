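"""Composition statistics: parsing, counting conventions, RSCU, FWHM and
codon-codon correlation structure."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonshift.codon_core import (
    CodingSequence,
    codon_correlation_matrix,
    composition_profile,
    correlation_sign_summary,
    count_codons,
    gc3_distribution_summary,
    pairwise_pearson,
    parse_cds,
    per_aa_fractions,
    rscu,
)
from codonshift.genetic_code import (
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
)


def _fasta(text: str):
    return io.StringIO(text)


class TestParsing:
    def test_simple_record(self):
        res = parse_cds(_fasta(">g1\nATGGCCAAATAA\n"))
        assert len(res) == 1
        assert res.records[0].n_codons == 4

    def test_strict_rejects_frameshifted_record_with_reason(self):
        res = parse_cds(_fasta(">ok\nATGGCCAAATAA\n>bad\nATGGCCAAAT\n"))
        assert [r.gene_id for r in res.records] == ["ok"]
        assert res.rejected[0].gene_id == "bad"
        assert "multiple of 3" in res.rejected[0].reason

    def test_rna_lowercase_normalises_to_dna(self):
        dna = parse_cds(_fasta(">g1\nATGGCCAAATAA\n")).records[0]
        rna = parse_cds(_fasta(">g1\nauggccaaauaa\n")).records[0]
        assert rna == dna

    def test_duplicate_ids_keep_first_with_warning(self):
        with pytest.warns(UserWarning, match="duplicate"):
            res = parse_cds(_fasta(">g1\nATGTAA\n>g1\nGCCGCC\n"))
        assert len(res) == 1
        assert res.records[0].sequence == "ATGTAA"

    def test_no_valid_records_is_an_error(self):
        with pytest.raises(ValueError):
            parse_cds(_fasta(">bad\nATGT\n"))

    def test_lenient_drops_ambiguous_triplets(self):
        res = parse_cds(_fasta(">g1\nATGNNNTAA\n"), policy="lenient")
        assert res.records[0].sequence == "ATGTAA"


class TestCountsAndProfiles:
    def test_count_codons_enumerates_triplets(self):
        t = count_codons(CodingSequence("g", "ATGGCCAAATAA"))
        assert t.counts == {"ATG": 1, "GCC": 1, "AAA": 1, "TAA": 1}
        assert (t.n_sense, t.n_stop) == (3, 1)

    def test_count_codons_no_stop(self):
        t = count_codons(CodingSequence("g", "GCCGCC"))
        assert t.counts == {"GCC": 2} and t.n_stop == 0

    def test_profile_conventions_on_four_codons(self):
        p = composition_profile(count_codons(CodingSequence("g", "ATGGCCAAATAA")))
        assert p.pct["ATG"] == pytest.approx(100 / 3)
        assert p.gc3_pct == pytest.approx(50.0)   # ATG, GCC of 4 codons
        assert p.au3_pct == pytest.approx(25.0)   # AAA; stop excluded

    def test_all_gc_ending(self):
        p = composition_profile(count_codons(CodingSequence("g", "GCC" * 7)))
        assert p.gc3_pct == 100.0 and p.au3_pct == 0.0

    def test_count_conservation_and_closure(self, small_genome):
        seqs, _ = small_genome
        for seq in seqs[:50]:
            t = count_codons(seq)
            assert sum(t.counts.values()) == len(seq.sequence) // 3
            p = composition_profile(t)
            assert sum(p.pct.values()) == pytest.approx(100.0, abs=1e-9)
            stop_frac = 100.0 * t.n_stop / t.n_codons
            assert p.gc3_pct + p.au3_pct + stop_frac == pytest.approx(100, abs=1e-9)


class TestVamp2Anchor:
    """The worked VAMP2 example: 85 G/C-ending and 31 A/T-ending sense
    codons of 117 total, i.e. 72.65% GC3 / 26.50% AU3."""

    def test_wobble_tallies(self, vamp2_seq):
        t = count_codons(vamp2_seq)
        assert t.n_codons == 117
        gc = sum(n for c, n in t.counts.items()
                 if c[2] in "GC" and c not in STOP_CODONS)
        at = sum(n for c, n in t.counts.items()
                 if c[2] in "AT" and c not in STOP_CODONS)
        assert (gc, at) == (85, 31)

    def test_printed_percentages(self, vamp2_seq):
        p = composition_profile(count_codons(vamp2_seq))
        assert p.gc3_pct == pytest.approx(72.65, abs=0.01)
        assert p.au3_pct == pytest.approx(26.50, abs=0.01)


class TestPerAAFractionsAndRSCU:
    def test_fractions_examples(self):
        fr = per_aa_fractions(count_codons(CodingSequence("g", "GCCGCCGCCGCA")))
        assert fr.fractions[("A", "GCC")] == pytest.approx(0.75)
        assert fr.fractions[("A", "GCA")] == pytest.approx(0.25)
        assert ("K", "AAA") not in fr.fractions

    def test_single_codon_family(self):
        fr = per_aa_fractions(count_codons(CodingSequence("g", "ATGATG")))
        assert fr.fractions[("M", "ATG")] == 1.0

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([2, 2, 2, 2], [1, 1, 1, 1]),
            ([4, 0, 0, 0], [4, 0, 0, 0]),
            ([2, 1, 1, 0], [2, 1, 1, 0]),
        ],
    )
    def test_rscu_alanine_examples(self, counts, expected):
        seq = "".join(c * n for c, n in zip(["GCA", "GCC", "GCG", "GCT"], counts))
        table = rscu(count_codons(CodingSequence("g", seq)))
        got = [table.values[c] for c in ["GCA", "GCC", "GCG", "GCT"]]
        assert got == pytest.approx(expected)

    def test_rscu_family_means_are_one(self, small_genome):
        seqs, _ = small_genome
        table = rscu(count_codons(s) for s in seqs)
        for aa, family in SYNONYMOUS_FAMILIES.items():
            vals = [table.values[c] for c in family if c in table.values]
            if vals:
                assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)
        # zero-count families are missing, not zero
        empty = rscu(count_codons(CodingSequence("g", "ATGATG")))
        assert "GCA" not in empty.values


def _fwhm_bruteforce(centers, counts):
    """Exhaustive scan for the half-max crossings around the global mode."""
    k = int(np.argmax(counts))
    half = counts[k] / 2
    left = right = None
    for i in range(k, 0, -1):
        if counts[i - 1] < half <= counts[i]:
            left = np.interp(half, [counts[i - 1], counts[i]],
                             [centers[i - 1], centers[i]])
            break
    for i in range(k, len(counts) - 1):
        if counts[i + 1] < half <= counts[i]:
            right = np.interp(half, [counts[i + 1], counts[i]],
                              [centers[i + 1], centers[i]])
            break
    return None if left is None or right is None else right - left


class TestDistributionSummary:
    def test_gaussian_fwhm_matches_closed_form(self):
        rng = np.random.default_rng(0)
        vals = np.clip(rng.normal(57.5, 10, 100_000), 0, 100)
        s = gc3_distribution_summary(vals, bin_width=1.0)
        assert s.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 10, abs=0.5)
        assert s.median == pytest.approx(57.5, abs=0.2)

    def test_point_mass_has_undefined_fwhm(self):
        s = gc3_distribution_summary([50.0] * 10)
        assert s.median == 50.0 and s.fwhm is None

    def test_bimodal_fwhm_matches_bruteforce_within_one_bin(self, small_comp):
        s = gc3_distribution_summary(small_comp["gc3_pct"], bin_width=2.0,
                                     smooth_window=1)
        centers = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
        oracle = _fwhm_bruteforce(centers, s.counts.astype(float))
        assert oracle is not None
        assert s.fwhm == pytest.approx(oracle, abs=2.0)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            gc3_distribution_summary([50.0])


class TestCorrelationMatrix:
    def test_two_codon_family_is_perfectly_anticorrelated(self):
        # genes using only GCC/GCA for Ala: fraction(GCC) = 1 - fraction(GCA)
        seqs = [
            CodingSequence(f"g{i}", "GCC" * (i + 1) + "GCA" * (5 - i))
            for i in range(4)
        ]
        mat = codon_correlation_matrix(seqs, codons=("GCA", "GCC"))
        assert mat.r.loc["GCA", "GCC"] == pytest.approx(-1.0)
        assert mat.r.loc["GCA", "GCA"] == pytest.approx(1.0)

    def test_zero_variance_codon_is_nan_not_zero(self):
        seqs = [CodingSequence(f"g{i}", "GCC" * 5 + "AAA" * (i + 1))
                for i in range(3)]
        mat = codon_correlation_matrix(seqs, codons=("GCA", "GCC", "AAA"))
        assert np.isnan(mat.r.loc["GCC", "AAA"])

    def test_sign_structure_on_synthetic_genome(self, small_genome):
        seqs, _ = small_genome
        summary = correlation_sign_summary(codon_correlation_matrix(seqs))
        assert summary["within_gc3"] > 0
        assert summary["within_au3"] > 0
        assert summary["between"] < 0

    def test_split_half_equals_full_for_self_similar_genes(self, small_genome):
        seqs, _ = small_genome
        doubled = []
        for s in seqs[:40]:
            body = s.sequence[:-3]  # strip stop, duplicate the body
            doubled.append(CodingSequence(s.gene_id, body + body + "TAA"))
        full = codon_correlation_matrix(doubled, mode="full")
        split = codon_correlation_matrix(doubled, mode="split_half")
        a, b = full.r.to_numpy(), split.r.to_numpy()
        mask = np.isfinite(a) & np.isfinite(b)
        assert np.allclose(a[mask], b[mask], atol=1e-12)

    def test_full_matrix_is_symmetric_with_unit_diagonal(self, small_genome):
        seqs, _ = small_genome
        r = codon_correlation_matrix(seqs[:100], mode="full").r.to_numpy()
        finite = np.isfinite(r)
        assert np.allclose(r[finite], r.T[finite.T], atol=1e-12)
        diag = np.diag(r)
        assert np.allclose(diag[np.isfinite(diag)], 1.0)


class TestCompositionProperties:
    """Closure invariants over arbitrary valid coding sequences."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.sampled_from(sorted(SENSE_CODONS + STOP_CODONS)),
            min_size=1, max_size=200,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_closure_holds_for_any_codon_string(self, codons):
        seq = CodingSequence("g", "".join(codons))
        t = count_codons(seq)
        assert sum(t.counts.values()) == len(codons)
        p = composition_profile(t)
        if t.n_sense > 0:
            assert sum(p.pct.values()) == pytest.approx(100.0, abs=1e-9)
        stop_frac = 100.0 * t.n_stop / t.n_codons
        assert p.gc3_pct + p.au3_pct + stop_frac == pytest.approx(100, abs=1e-9)
        assert 0 <= p.gc3_pct <= 100 and 0 <= p.au3_pct <= 100


class TestPearsonOracle:
    def test_pairwise_pearson_matches_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(5, 50)
            a = pd.DataFrame(rng.normal(size=(n, 4)))
            b = pd.DataFrame(rng.normal(size=(n, 3)))
            got = pairwise_pearson(a, b)
            for i in range(4):
                for j in range(3):
                    want = stats.pearsonr(a[i], b[j]).statistic
                    assert got.iloc[i, j] == pytest.approx(want, abs=1e-10)
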