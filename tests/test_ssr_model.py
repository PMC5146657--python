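"""Cross-type classification, Mendelian enumeration, single-copy verdicts, I/O."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salixploidy.ssr_model import (AlleleSet, CrossType, FailureReason,
                                   GenotypeParseError, PedigreeError,
                                   PedigreeGenotypes, check_single_copy,
                                   classify_cross_type,
                                   enumerate_offspring_genotypes,
                                   read_genotype_table, write_genotype_table)
from salixploidy.synthetic import simulate_f1_family

from conftest import aset


class TestAlleleSet:
    def test_alleles_are_deduplicated_and_sorted(self):
        a = aset("M", "s", 180, 168, 180)
        assert a.alleles == (168, 180)
        assert not a.missing

    def test_empty_is_missing(self):
        assert aset("M", "s").missing

    def test_nonpositive_allele_rejected(self):
        with pytest.raises(ValueError):
            aset("M", "s", 0, 168)


class TestClassifyCrossType:
    @pytest.mark.parametrize(
        "mother,father,expected",
        [
            ((168, 172), (176, 180), CrossType.ABxCD),
            ((168, 172), (172, 176), CrossType.ABxBC),
            ((168, 172), (168, 172), CrossType.ABxAB),
            ((168,), (172, 176), CrossType.uninformative),
            ((168, 172), (176,), CrossType.uninformative),
            ((168, 172, 176), (180, 184), CrossType.invalid),
        ],
    )
    def test_sharing_pattern_determines_label(self, mother, father, expected):
        got = classify_cross_type(aset("M", "mom", *mother), aset("M", "dad", *father))
        assert got is expected

    def test_fully_informative_labels(self):
        assert CrossType.ABxCD.fully_informative
        assert CrossType.ABxBC.fully_informative
        assert not CrossType.ABxAB.fully_informative
        assert not CrossType.uninformative.fully_informative

    def test_missing_parent_is_an_error(self):
        with pytest.raises(PedigreeError):
            classify_cross_type(aset("M", "mom"), aset("M", "dad", 172, 176))

    @given(
        mother=st.sets(st.integers(150, 450), min_size=1, max_size=2),
        father=st.sets(st.integers(150, 450), min_size=1, max_size=2),
        shift=st.integers(1, 500),
    )
    @settings(deadline=None)
    def test_invariant_under_allele_relabelling(self, mother, father, shift):
        """The label depends only on the allele-sharing pattern, not sizes."""
        base = classify_cross_type(aset("M", "m", *mother), aset("M", "f", *father))
        relabelled = classify_cross_type(
            aset("M", "m", *(a + shift for a in mother)),
            aset("M", "f", *(a + shift for a in father)),
        )
        assert base is relabelled


def brute_force_offspring(mother: tuple[int, ...], father: tuple[int, ...]):
    """Oracle: enumerate equally likely gamete pairs and tally unordered sets."""
    out: dict[tuple[int, int], float] = {}
    pairs = list(itertools.product(mother, father))
    for m, f in pairs:
        key = tuple(sorted((m, f)))
        out[key] = out.get(key, 0.0) + 1.0 / len(pairs)
    return out


class TestEnumerateOffspring:
    def test_abxcd_gives_four_equal_classes(self):
        got = enumerate_offspring_genotypes(
            aset("M", "m", 1, 2), aset("M", "f", 3, 4))
        assert got == {(1, 3): 0.25, (1, 4): 0.25, (2, 3): 0.25, (2, 4): 0.25}

    def test_abxbc_includes_homozygote_class(self):
        got = enumerate_offspring_genotypes(
            aset("M", "m", 1, 2), aset("M", "f", 2, 3))
        assert got == pytest.approx(
            {(1, 2): 0.25, (1, 3): 0.25, (2, 2): 0.25, (2, 3): 0.25})

    def test_homozygous_cross_is_single_class(self):
        got = enumerate_offspring_genotypes(aset("M", "m", 1), aset("M", "f", 2))
        assert got == {(1, 2): 1.0}

    @pytest.mark.parametrize("n_m,n_f", [(1, 1), (1, 2), (2, 1), (2, 2)])
    def test_matches_gamete_pair_oracle_for_all_parent_shapes(self, n_m, n_f):
        # overlapping and disjoint parental alleles in every shape
        for mother in itertools.combinations(range(1, 5), n_m):
            for father in itertools.combinations(range(1, 5), n_f):
                got = enumerate_offspring_genotypes(
                    aset("M", "m", *mother), aset("M", "f", *father))
                expected = brute_force_offspring(mother, father)
                assert got == pytest.approx(expected, abs=1e-15)
                assert sum(got.values()) == pytest.approx(1.0, abs=1e-12)


def legal_progeny_sets(mother, father):
    """Oracle: every allele set reachable as {maternal, paternal} gamete."""
    return {frozenset((m, f)) for m in mother for f in father}


class TestCheckSingleCopy:
    def test_clean_abxcd_family_is_fully_informative(self, abxcd_family):
        verdict = check_single_copy(abxcd_family)
        assert verdict.single_copy and verdict.fully_informative
        assert verdict.failure_reasons == ()
        assert verdict.n_progeny == 6

    def test_three_allele_progeny_flags_extra_allele(self):
        ped = PedigreeGenotypes(
            "M", aset("M", "m", 1, 2), aset("M", "f", 3, 4),
            (aset("M", "p", 1, 3, 4),))
        verdict = check_single_copy(ped)
        assert not verdict.single_copy
        assert FailureReason.progeny_extra_allele in verdict.failure_reasons

    def test_single_maternal_allele_under_abxcd_is_null_signature(self):
        ped = PedigreeGenotypes(
            "M", aset("M", "m", 1, 2), aset("M", "f", 3, 4), (aset("M", "p", 1),))
        verdict = check_single_copy(ped)
        assert FailureReason.null_allele_signature in verdict.failure_reasons
        assert not verdict.single_copy

    def test_bb_homozygote_under_abxbc_is_legal(self):
        ped = PedigreeGenotypes(
            "M", aset("M", "m", 1, 2), aset("M", "f", 2, 3), (aset("M", "p", 2),))
        verdict = check_single_copy(ped)
        assert verdict.single_copy and verdict.fully_informative

    def test_nonparental_allele_flagged(self):
        ped = PedigreeGenotypes(
            "M", aset("M", "m", 1, 2), aset("M", "f", 3, 4), (aset("M", "p", 1, 9),))
        verdict = check_single_copy(ped)
        assert FailureReason.progeny_allele_not_parental in verdict.failure_reasons

    def test_two_maternal_alleles_under_abxcd_is_gamete_inconsistent(self):
        ped = PedigreeGenotypes(
            "M", aset("M", "m", 1, 2), aset("M", "f", 3, 4), (aset("M", "p", 1, 2),))
        verdict = check_single_copy(ped)
        assert FailureReason.null_allele_signature in verdict.failure_reasons

    def test_identical_heterozygous_parents_not_fully_informative(self):
        ped = PedigreeGenotypes(
            "M", aset("M", "m", 1, 2), aset("M", "f", 1, 2), (aset("M", "p", 1, 2),))
        verdict = check_single_copy(ped)
        assert verdict.single_copy and not verdict.fully_informative
        assert FailureReason.identical_parent_genotypes in verdict.failure_reasons

    def test_marker_mismatch_rejected(self):
        with pytest.raises(PedigreeError):
            PedigreeGenotypes(
                "M1", aset("M1", "m", 1, 2), aset("M2", "f", 3, 4),
                (aset("M1", "p", 1, 3),))

    @given(
        mother=st.sets(st.integers(1, 6), min_size=1, max_size=2),
        father=st.sets(st.integers(1, 6), min_size=1, max_size=2),
        picks=st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                       min_size=1, max_size=8),
    )
    @settings(deadline=None)
    def test_accepted_progeny_are_legal_gamete_pairs(self, mother, father, picks):
        """Any family accepted as single-copy only contains oracle-legal sets."""
        mother_t, father_t = tuple(sorted(mother)), tuple(sorted(father))
        progeny = tuple(
            aset("M", f"p{i}",
                 mother_t[i_m % len(mother_t)], father_t[i_f % len(father_t)])
            for i, (i_m, i_f) in enumerate(picks)
        )
        ped = PedigreeGenotypes(
            "M", aset("M", "m", *mother_t), aset("M", "f", *father_t), progeny)
        verdict = check_single_copy(ped)
        legal = legal_progeny_sets(mother_t, father_t)
        assert verdict.single_copy  # constructed from real gametes
        for child in progeny:
            assert frozenset(child.alleles) in legal
            assert set(child.alleles) <= set(mother_t) | set(father_t)

    def test_null_corruption_detection_increases_with_rate(self):
        """Detection probability of null alleles grows with the silencing rate."""
        mother, father = aset("M", "m", 1, 2), aset("M", "f", 3, 4)
        rates = [0.0, 0.1, 0.3, 0.6]
        detected = []
        for q in rates:
            rng = np.random.default_rng(42)
            hits = 0
            n_rep = 300
            for _ in range(n_rep):
                ped, _ = simulate_f1_family(mother, father, n_progeny=6,
                                            null_rate=q, rng=rng)
                if not check_single_copy(ped).single_copy:
                    hits += 1
            detected.append(hits / n_rep)
        assert detected[0] == 0.0
        assert detected == sorted(detected)
        assert detected[-1] > 0.9


class TestGenotypeTableIO:
    def test_three_allele_row_parses(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tmarker_id\talleles\nSsu_90\tWSSR_100\t168;176;184\n")
        matrix = read_genotype_table(path)
        assert matrix.get("Ssu_90", "WSSR_100").alleles == (168, 176, 184)

    def test_empty_allele_field_is_missing(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tmarker_id\talleles\nS1\tM1\t\n")
        matrix = read_genotype_table(path)
        assert matrix.get("S1", "M1") is None
        assert matrix.cells[("S1", "M1")].missing

    def test_round_trip_identity(self, tmp_path, rng):
        from salixploidy.ssr_model import GenotypeMatrix
        records = [
            aset(f"M{m}", f"S{s}", *rng.choice(range(150, 450), size=2, replace=False))
            for s in range(5) for m in range(3)
        ]
        matrix = GenotypeMatrix.from_records(records)
        path = tmp_path / "rt.tsv"
        write_genotype_table(matrix, path)
        assert read_genotype_table(path) == matrix

    def test_non_integer_token_names_the_line(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\tmarker_id\talleles\nS1\tM1\t168\nS2\tM1\tabc\n")
        with pytest.raises(GenotypeParseError, match="line 3"):
            read_genotype_table(path)

    def test_duplicate_sample_marker_row_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "sample_id\tmarker_id\talleles\nS1\tM1\t168\nS1\tM1\t170\n")
        with pytest.raises(GenotypeParseError, match="duplicate"):
            read_genotype_table(path)
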