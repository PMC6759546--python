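from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psekgcc import (
    DnaRecord,
    PsekgccParams,
    encode_3w_ktuple,
    encode_matrix,
    encode_psekgcc,
    enumerate_kgcc_words,
    feature_names,
    gc_skew,
    kgcc_composition,
    partition_windows,
    reduce_alphabet,
    reverse_complement,
    theta_tier,
)
from psekgcc.features import (
    DegeneratePartitionError,
    KgccComposition,
    NumericDegeneracyError,
    ParameterSequenceError,
    ThetaTiers,
    assemble_feature_vector,
    cached_encode,
    read_features_tsv,
    sweep_encode,
    write_features_tsv,
)

from ._reference import ref_encode, ref_theta


class TestPartitionWindows:
    @pytest.mark.parametrize(
        "L,eps,delta,eta,xi",
        [
            (12, 0.25, 0.75, 3, 9),
            (10, 0.15, 0.55, 2, 6),  # ceil(1.5)=2, ceil(5.5)=6
            (40, 0.15, 0.55, 6, 22),  # 40*0.15 must not float up to 7
        ],
    )
    def test_ceiling_split(self, L, eps, delta, eta, xi):
        part = partition_windows(L, eps, delta)
        assert (part.eta, part.xi) == (eta, xi)
        (f0, f1), (m0, m1), (r0, r1) = part.bounds
        assert (f0, f1, m0, m1, r0, r1) == (1, eta, eta + 1, xi, xi + 1, L)

    def test_empty_rear_window_is_error(self):
        with pytest.raises(DegeneratePartitionError, match="rear"):
            partition_windows(4, 0.15, 0.85)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            partition_windows(10, 0.6, 0.5)

    @settings(deadline=None)
    @given(
        st.integers(min_value=10, max_value=5000),
        st.floats(min_value=0.05, max_value=0.45),
        st.floats(min_value=0.55, max_value=0.95),
    )
    def test_windows_tile_the_sequence(self, L, eps, delta):
        part = partition_windows(L, eps, delta)
        assert sum(part.window_lengths) == L
        assert all(w >= 1 for w in part.window_lengths)


class TestKgccWordsAndComposition:
    def test_canonical_order(self):
        assert enumerate_kgcc_words(1) == ["C", "G", "*"]
        assert enumerate_kgcc_words(2) == [
            "CC", "CG", "C*", "GC", "GG", "G*", "*C", "*G", "**",
        ]
        assert len(enumerate_kgcc_words(3)) == 27

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            enumerate_kgcc_words(0)

    def test_homopolymer_composition(self):
        f = kgcc_composition("GGG", 2)
        assert f[enumerate_kgcc_words(2).index("GG")] == 1.0
        assert f.sum() == 1.0

    def test_mixed_window_counts(self):
        f = dict(zip(enumerate_kgcc_words(2), kgcc_composition("CCC***", 2)))
        assert f["CC"] == pytest.approx(0.4)
        assert f["C*"] == pytest.approx(0.2)
        assert f["**"] == pytest.approx(0.4)

    def test_window_shorter_than_k_is_error(self):
        with pytest.raises(ValueError):
            kgcc_composition("GC", 3)

    @settings(deadline=None)
    @given(st.text(alphabet="GC*", min_size=4, max_size=60),
           st.integers(min_value=1, max_value=4))
    def test_frequencies_sum_to_one(self, window, k):
        f = kgcc_composition(window, k)
        assert f.shape == (3**k,)
        assert np.all(f >= 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)


class TestGcSkew:
    @pytest.mark.parametrize(
        "tup,expected",
        [("GGC", 1 / 3), ("GGG", 1.0), ("CCC", -1.0), ("G*C*", 0.0), ("***", 0.0)],
    )
    def test_known_values(self, tup, expected):
        assert gc_skew(tup) == pytest.approx(expected)

    def test_empty_tuple_rejected(self):
        with pytest.raises(ValueError):
            gc_skew("")

    def test_antisymmetry_under_revcomp_exhaustive(self):
        """Reverse-complementing a DNA tuple flips the sign of its GC skew
        (G and C exchange); exhaustive over all DNA tuples with k <= 5."""
        for k in range(1, 6):
            for tup in map("".join, product("ACGT", repeat=k)):
                rec = DnaRecord(id="t", sequence=tup)
                fwd = gc_skew(reduce_alphabet(rec).symbols)
                rev = gc_skew(reduce_alphabet(reverse_complement(rec)).symbols)
                assert rev == -fwd


class TestThetaTier:
    @pytest.mark.parametrize(
        "window,j,k,expected",
        [
            ("GGG", 1, 2, 1.0),
            ("CCC***", 1, 2, -0.6),
            ("GCGCG", 3, 3, 1 / 6),  # terminal tuple truncated to CG
        ],
    )
    def test_hand_worked_tiers(self, window, j, k, expected):
        assert theta_tier(window, j, k) == pytest.approx(expected)

    def test_window_not_longer_than_k_is_single_truncated_tuple(self):
        assert theta_tier("GG", 1, 5) == 1.0

    def test_spacing_beyond_window_rejected(self):
        with pytest.raises(ValueError):
            theta_tier("GCG", 4, 2)

    @settings(deadline=None)
    @given(st.text(alphabet="GC*", min_size=3, max_size=50),
           st.integers(min_value=1, max_value=6),
           st.integers(min_value=1, max_value=6))
    def test_matches_reference_and_bounded(self, window, j, k):
        if j > len(window):
            return
        theta = theta_tier(window, j, k)
        assert -1.0 <= theta <= 1.0
        assert theta == pytest.approx(ref_theta(window, j, k), abs=1e-12)


class TestAssembleAndEncode:
    def test_front_block_hand_example(self):
        comp = KgccComposition(
            front=kgcc_composition("GGG", 2),
            middle=kgcc_composition("CCC***", 2),
            rear=kgcc_composition("***", 2),
            k=2,
        )
        tiers = ThetaTiers(
            front=np.array([theta_tier("GGG", 1, 2)]),
            middle=np.array([theta_tier("CCC***", 1, 2)]),
            rear=np.array([theta_tier("***", 1, 2)]),
        )
        phi = assemble_feature_vector(comp, tiers, w=0.5)
        named = dict(zip(feature_names(PsekgccParams(0.25, 0.75, 2, 1, 0.5)), phi))
        assert named["front:GG"] == pytest.approx(2 / 3)
        assert named["front:theta1"] == pytest.approx(1 / 3)
        assert named["middle:CC"] == pytest.approx(0.4 / 0.7)
        assert named["middle:theta1"] == pytest.approx(-0.3 / 0.7)
        assert named["rear:**"] == pytest.approx(1.0)
        assert named["rear:theta1"] == 0.0

    def test_worked_micro_example_end_to_end(self, micro_record):
        params = PsekgccParams(0.25, 0.75, 2, 1, 0.5)
        fv = encode_psekgcc(micro_record, params)
        assert fv.dimension == 30
        named = dict(zip(feature_names(params), fv.phi))
        nonzero = {k: v for k, v in named.items() if abs(v) > 1e-15}
        assert nonzero == {
            "front:GG": pytest.approx(2 / 3),
            "front:theta1": pytest.approx(1 / 3),
            "middle:CC": pytest.approx(0.5714, abs=1e-4),
            "middle:C*": pytest.approx(0.2857, abs=1e-4),
            "middle:**": pytest.approx(0.5714, abs=1e-4),
            "middle:theta1": pytest.approx(-0.4286, abs=1e-4),
            "rear:**": pytest.approx(1.0),
        }

    def test_w_zero_collapses_to_plain_composition(self, micro_record):
        params = PsekgccParams(0.25, 0.75, 2, 1, 0.0)
        fv = encode_psekgcc(micro_record, params)
        named = dict(zip(feature_names(params), fv.phi))
        assert named["front:GG"] == 1.0
        assert named["middle:CC"] == pytest.approx(0.4)
        assert all(named[f"{w}:theta1"] == 0.0 for w in ("front", "middle", "rear"))

    def test_degenerate_denominator_names_window(self):
        comp = KgccComposition(
            front=kgcc_composition("CCC", 1),
            middle=kgcc_composition("CCC", 1),
            rear=kgcc_composition("CCC", 1),
            k=1,
        )
        tiers = ThetaTiers(
            front=np.array([0.0]), middle=np.array([-1.0, -1.0]),
            rear=np.array([0.0]),
        )
        with pytest.raises(NumericDegeneracyError, match="middle"):
            assemble_feature_vector(comp, tiers, w=0.6)

    def test_lambda_constraint_error_lists_geometry(self, micro_record):
        with pytest.raises(ParameterSequenceError, match="eta=3"):
            encode_psekgcc(micro_record, PsekgccParams(0.25, 0.75, 2, 5, 0.5))

    def test_k_exceeding_window_is_error(self, micro_record):
        with pytest.raises(ParameterSequenceError, match="k=4"):
            encode_psekgcc(micro_record, PsekgccParams(0.25, 0.75, 4, 1, 0.5))

    @pytest.mark.parametrize("k,lam", [(1, 0), (2, 1), (3, 2)])
    def test_dimension_law_and_block_sums(self, rng, k, lam):
        from .conftest import random_records

        params = PsekgccParams(0.25, 0.75, k, lam, 0.4)
        for rec in random_records(rng, 10, lo=30, hi=120):
            fv = encode_psekgcc(rec, params)
            assert fv.dimension == 3 * (3**k + lam)
            block = 3**k + lam
            for b in range(3):
                assert fv.phi[b * block : (b + 1) * block].sum() == pytest.approx(
                    1.0, abs=1e-12
                )

    def test_matches_naive_reference_on_random_inputs(self, rng):
        from .conftest import random_records

        records = random_records(rng, 15, lo=40, hi=120)
        grid = [
            PsekgccParams(e, d, k, lam, w)
            for e, d, k, lam, w in [
                (0.25, 0.75, 2, 1, 0.5),
                (0.15, 0.55, 3, 2, 0.3),
                (0.4, 0.85, 1, 3, 1.0),
                (0.3, 0.6, 2, 0, 0.7),
            ]
        ]
        for rec in records:
            for params in grid:
                phi = encode_psekgcc(rec, params).phi
                ref = ref_encode(
                    rec.sequence, params.epsilon, params.delta,
                    params.k, params.lam, params.w,
                )
                np.testing.assert_allclose(phi, ref, atol=1e-12, rtol=0)

    def test_sweep_encode_agrees_with_single_encoding(self, rng):
        from .conftest import random_records

        (rec,) = random_records(rng, 1, lo=80, hi=80)
        results = list(
            sweep_encode(rec, (0.2, 0.3), (0.6, 0.8), (2, 3), (1, 2), (0.2, 0.9))
        )
        assert len(results) == 32
        for params, phi, reason in results:
            if reason:
                continue
            np.testing.assert_array_equal(phi, encode_psekgcc(rec, params).phi)


class TestBaselineEncoder:
    def test_homopolymer(self):
        rec = DnaRecord(id="a", sequence="A" * 40)
        vec = encode_3w_ktuple(rec, 0.25, 0.75, 2)
        assert vec.shape == (3 * 16,)
        # AA is word 0 in each window block
        assert vec[0] == vec[16] == vec[32] == 1.0

    def test_uniform_k1(self):
        rec = DnaRecord(id="a", sequence="ACGT" * 3)
        vec = encode_3w_ktuple(rec, 1 / 3, 2 / 3, 1)
        np.testing.assert_allclose(vec, 0.25)

    def test_blocks_sum_to_one(self, rng):
        from .conftest import random_records

        for rec in random_records(rng, 5, lo=50, hi=150):
            vec = encode_3w_ktuple(rec, 0.25, 0.75, 3)
            for b in range(3):
                assert vec[b * 64 : (b + 1) * 64].sum() == pytest.approx(1.0)


class TestMatrixIo:
    def test_tsv_round_trip_and_names(self, tmp_path, skew_dataset_small):
        records, _ = skew_dataset_small
        params = PsekgccParams(0.25, 0.75, 2, 1, 0.5)
        df = encode_matrix(records[:4], params)
        assert list(df.columns) == feature_names(params)
        assert list(df.index) == [r.id for r in records[:4]]
        path = tmp_path / "features.tsv"
        write_features_tsv(df, path)
        back = read_features_tsv(path)
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), atol=1e-9)

    def test_cached_encode_hits_and_matches(self, tmp_path, micro_record):
        params = PsekgccParams(0.25, 0.75, 2, 1, 0.5)
        first = cached_encode(micro_record, params, tmp_path)
        cached = cached_encode(micro_record, params, tmp_path)
        np.testing.assert_array_equal(first.phi, cached.phi)
        np.testing.assert_array_equal(
            first.phi, encode_psekgcc(micro_record, params).phi
        )


def test_params_validation():
    with pytest.raises(ValueError):
        PsekgccParams(0.7, 0.5, 2, 1, 0.5)
    with pytest.raises(ValueError):
        PsekgccParams(0.2, 0.8, 0, 1, 0.5)
    with pytest.raises(ValueError):
        PsekgccParams(0.2, 0.8, 2, -1, 0.5)
    with pytest.raises(ValueError):
        PsekgccParams(0.2, 0.8, 2, 1, 1.5)
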