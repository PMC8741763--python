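import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle
from ctag.features import (
    FEATURE_NAMES,
    FeatureMatrix,
    build_feature_matrix,
    categorize_missense,
    count_categories,
    entropy_features,
    per_kb,
    ratio_feature,
)
from ctag.io import ValidationError
from conftest import make_table


class TestCategorizeMissense:
    @pytest.mark.parametrize("score,expected", [
        (0.9, "HiFI"), (0.85, "HiFI"),
        (0.15, "LoFI"), (0.05, "LoFI"),
        (0.5, "MiFI"), (0.151, "MiFI"), (0.849, "MiFI"),
        (None, "MiFI"), (float("nan"), "MiFI"),
    ])
    def test_threshold_bins(self, score, expected):
        assert categorize_missense(score) == expected


class TestCountCategories:
    def test_derived_category_identities(self):
        rows = (
            [("S", "G1", "nonsense", p) for p in range(1, 4)]
            + [("S", "G1", "frameshift", p) for p in range(10, 12)]
            + [("S", "G1", "missense", p, "A", "T", s)
               for p, s in zip(range(20, 30), [0.1] * 3 + [0.9] * 1 + [0.5] * 6)]
            + [("S", "G1", "complex", 40), ("S", "G1", "inframe", 41),
               ("S", "G1", "inframe", 42)]
            + [("S", "G1", "silent", p) for p in range(50, 54)]
        )
        c = count_categories(make_table(rows)).loc["G1"]
        assert c["LOF"] == 5  # nonsense + frameshift
        assert c["LoFI"] == 3 and c["HiFI"] == 1 and c["MiFI"] == 6
        assert c["benign"] == c["silent"] + c["LoFI"] == 7
        assert c["damaging"] == c["HiFI"] + c["MiFI"] == 7
        # missense + complex + inframe + nonstop - LoFI
        assert c["compound"] == 10 + 1 + 2 + 0 - 3
        assert c["total"] == len(rows)

    def test_unscored_missense_default_mifi_vs_drop(self):
        t = make_table([("S", "G1", "missense", 1)])
        assert count_categories(t).loc["G1", "MiFI"] == 1
        dropped = count_categories(t, unscored="drop").loc["G1"]
        assert dropped["MiFI"] == 0 and dropped["missense"] == 1

    def test_impact_partition_invariant(self):
        rng = np.random.default_rng(0)
        rows = [("S", "G", "missense", i + 1, "A", "T", float(rng.random()))
                for i in range(50)]
        c = count_categories(make_table(rows)).loc["G"]
        assert c["HiFI"] + c["MiFI"] + c["LoFI"] == c["missense"] == 50


class TestRatioFeature:
    def test_direct_division(self):
        assert ratio_feature(6, 3, 10) == pytest.approx(2.0)

    def test_zero_denominator_branch(self):
        assert ratio_feature(4, 0, 9) == pytest.approx(18.0)

    def test_all_zero(self):
        assert ratio_feature(0, 0, 0) == 0.0

    def test_piecewise_oracle_agreement_random_triples(self):
        rng = np.random.default_rng(42)
        a = rng.integers(0, 50, 10_000)
        b = rng.integers(0, 5, 10_000)  # many zeros
        m = rng.integers(0, 50, 10_000)
        for ai, bi, mi in zip(a, b, m):
            expected = ai / bi if bi != 0 else 2 * mi
            assert ratio_feature(ai, bi, mi) == pytest.approx(expected, abs=1e-12)


class TestEntropyFeatures:
    def test_single_identity(self):
        e, hf = entropy_features([5])
        assert e == pytest.approx(0.0) and hf == pytest.approx(1.0)

    def test_two_uniform(self):
        e, hf = entropy_features([1, 1])
        assert e == pytest.approx(2 * math.log(2), abs=1e-12)
        assert hf == pytest.approx(0.5)

    def test_skewed_pair(self):
        e, hf = entropy_features([2, 1])
        s = (2 / 3) * math.log(2 / 3) + (1 / 3) * math.log(1 / 3)
        assert e == pytest.approx(math.log(2) - s, abs=1e-12)
        assert e == pytest.approx(1.3296613, abs=1e-6)
        assert hf == pytest.approx(2 / 3)

    @pytest.mark.parametrize("k", range(1, 11))
    def test_uniform_counts_closed_form(self, k):
        e, hf = entropy_features([3] * k)
        assert e == pytest.approx(2 * math.log(k), abs=1e-12)
        assert hf == pytest.approx(1 / k)

    def test_empty_spectrum(self):
        assert entropy_features([]) == (0.0, 0.0)

    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_entropy_zero_iff_single_identity_and_hf_bounds(self, counts):
        e, hf = entropy_features(counts)
        assert (abs(e) < 1e-12) == (len(counts) == 1)
        assert 0 < hf <= 1
        assert e >= -1e-12


class TestPerKb:
    @pytest.mark.parametrize("count,bp,expected", [(10, 2000, 5.0), (0, 1500, 0.0),
                                                   (3, 1000, 3.0)])
    def test_values(self, count, bp, expected):
        assert per_kb(count, bp) == pytest.approx(expected)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValidationError):
            per_kb(1, 0)


def _random_cohort_rows(rng, n_genes, max_records=25):
    """Random per-gene mutation profiles shared by engine and oracle tests."""
    types = ["silent", "missense", "splicing", "nonsense", "frameshift",
             "inframe", "nonstop", "complex"]
    rows, lengths = [], {}
    for g in range(n_genes):
        gene = f"G{g:04d}"
        lengths[gene] = int(rng.integers(300, 5000))
        for _ in range(int(rng.integers(1, max_records))):
            t = types[rng.integers(len(types))]
            score = None
            if t == "missense" and rng.random() < 0.8:
                score = float(np.round(rng.random(), 3))
            rows.append(
                (f"S{rng.integers(40)}", gene, t, int(rng.integers(1, 60)),
                 "ACGT"[rng.integers(4)], "ACGT"[rng.integers(4)], score)
            )
    return rows, lengths


class TestBuildFeatureMatrix:
    def test_exactly_37_columns_with_canonical_names(self, small_matrix):
        assert list(small_matrix.df.columns) == FEATURE_NAMES
        assert len(FEATURE_NAMES) == 37

    def test_minimal_single_silent_gene(self):
        t = make_table([("S1", "G1", "silent", 10)])
        fm = build_feature_matrix(t, pd.Series({"G1": 1000}))
        row = fm.df.loc["G1"]
        assert row["Silent/kb"] == pytest.approx(1.0)
        for col in ("Missense entropy", "Frameshift entropy", "Splicing entropy",
                    "Nonsense entropy"):
            assert row[col] == 0.0
        assert row["LOF/Silent"] == 0.0
        # zero-denominator branches with an all-zero numerator collapse to 0
        assert row["LOF/Missense"] == 0.0 and row["HiFI/LoFI"] == 0.0

    def test_matches_scalar_oracle_on_random_profiles(self):
        rng = np.random.default_rng(2024)
        rows, lengths = _random_cohort_rows(rng, 200)
        fm = build_feature_matrix(make_table(rows), pd.Series(lengths))
        by_gene = {}
        for r in rows:
            by_gene.setdefault(r[1], []).append(
                {"mutation_type": r[2], "position": r[3], "ref_allele": r[4] or "A",
                 "alt_allele": r[5] or "T", "impact_score": r[6]}
            )
        expected = oracle.feature_table(by_gene, lengths)
        assert set(fm.df.index) == set(expected)
        for gene, feats in expected.items():
            for name in FEATURE_NAMES:
                assert fm.df.loc[gene, name] == pytest.approx(
                    feats[name], abs=1e-9
                ), f"{gene} {name}"

    def test_gene_without_length_dropped_with_warning(self):
        t = make_table([("S1", "G1", "silent", 1), ("S1", "G2", "silent", 2)])
        with pytest.warns(UserWarning, match="without coding length"):
            fm = build_feature_matrix(t, pd.Series({"G1": 1000}))
        assert list(fm.df.index) == ["G1"] and fm.dropped == ["G2"]

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(ValidationError):
            build_feature_matrix(make_table([]), pd.Series({"G1": 1000}))

    def test_doubling_records_scales_totals_but_not_ratios(self):
        # duplicating every record doubles counts and /kb features but leaves
        # entropies, frequencies and (non-degenerate) ratios unchanged; the
        # zero-denominator substitute 2*max(A) doubles along with max(A)
        from ctag.features import RATIO_FEATURES

        rng = np.random.default_rng(5)
        rows, lengths = _random_cohort_rows(rng, 30)
        t1, t2 = make_table(rows), make_table(rows + rows)
        fm1 = build_feature_matrix(t1, pd.Series(lengths))
        fm2 = build_feature_matrix(t2, pd.Series(lengths))
        counts = count_categories(t1)
        for name, (num, den) in RATIO_FEATURES.items():
            nonzero = counts.index[counts[den] > 0]
            assert np.allclose(fm1.df.loc[nonzero, name],
                               fm2.df.loc[nonzero, name], atol=1e-9)
            zero = counts.index[counts[den] == 0]
            assert np.allclose(2 * fm1.df.loc[zero, name],
                               fm2.df.loc[zero, name], atol=1e-9)
        for c in ("High Missense frequency", "Missense entropy",
                  "average Polyphen2 score", "LOF/Total", "Missense/Total"):
            pd.testing.assert_series_equal(fm1.df[c], fm2.df[c], atol=1e-9,
                                           check_exact=False)
        for c in ("Total Missense", "Total LOF", "Silent/kb", "Missense/kb"):
            assert np.allclose(2 * fm1.df[c], fm2.df[c])

    def test_per_kb_inverse_in_length(self):
        t = make_table([("S1", "G1", "silent", 1), ("S1", "G2", "silent", 1)])
        fm = build_feature_matrix(t, pd.Series({"G1": 1000, "G2": 2000}))
        assert fm.df.loc["G1", "Silent/kb"] == 2 * fm.df.loc["G2", "Silent/kb"]

    def test_entropy_mode_flag_changes_sign_of_s_term(self):
        rows = [("S", "G", "missense", 1, "A", "T", 0.5),
                ("S", "G", "missense", 1, "A", "T", 0.5),
                ("S", "G", "missense", 2, "A", "G", 0.5)]
        printed = build_feature_matrix(make_table(rows), pd.Series({"G": 1000}))
        deficit = build_feature_matrix(make_table(rows), pd.Series({"G": 1000}),
                                       entropy_mode="deficit")
        s = (2 / 3) * math.log(2 / 3) + (1 / 3) * math.log(1 / 3)
        assert printed.df.loc["G", "Missense entropy"] == pytest.approx(
            math.log(2) - s)
        assert deficit.df.loc["G", "Missense entropy"] == pytest.approx(
            math.log(2) + s)


class TestFeatureMatrixRoundTrip:
    def test_tsv_round_trip(self, small_matrix, tmp_path):
        p = tmp_path / "features.tsv"
        small_matrix.to_tsv(p)
        back = FeatureMatrix.read_tsv(p)
        pd.testing.assert_frame_equal(
            small_matrix.df, back.df, atol=1e-8, check_exact=False
        )
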