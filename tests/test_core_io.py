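import numpy as np
import pandas as pd
import pytest

from nbprog.core_io import (
    ClinicalTable,
    DataError,
    LabelPair,
    OmicsMatrix,
    concatenate,
    encode_clinical,
    filter_missing_features,
    fit_encoding_stats,
    impute_mean,
    make_labels,
    read_matrix,
    write_matrix,
)


def _write(tmp_path, text, name="m.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadMatrix:
    def test_missing_cell_is_marked_not_zeroed(self, tmp_path):
        p = _write(tmp_path, "id,f1,f2\ns1,1.0,\ns2,2.0,5.0\ns3,3.0,6.0\n")
        m = read_matrix(p)
        assert m.sample_ids == ["s1", "s2", "s3"]
        assert np.isnan(m.values[0, 1])
        assert np.isnan(m.values).sum() == 1

    def test_features_in_rows_is_transposed(self, tmp_path):
        p = _write(tmp_path, "id,s1,s2\nf1,1,2\nf2,3,4\n")
        m = read_matrix(p, orientation="features")
        assert m.sample_ids == ["s1", "s2"]
        assert m.feature_ids == ["f1", "f2"]
        assert m.values[1, 0] == 2.0

    def test_duplicate_feature_id_raises_with_name(self, tmp_path):
        p = _write(tmp_path, "id,f1,f1\ns1,1,2\n")
        with pytest.raises(DataError, match="f1"):
            read_matrix(p)

    def test_non_numeric_cell_raises_with_location(self, tmp_path):
        p = _write(tmp_path, "id,f1,f2\ns1,1,2\ns2,oops,4\n")
        with pytest.raises(DataError, match="oops"):
            read_matrix(p)

    def test_roundtrip_is_bit_exact(self, tmp_path, rng):
        m = OmicsMatrix(
            ["a", "b", "c"], ["x", "y"], rng.normal(size=(3, 2)) * 1e-7, "expression"
        )
        path = tmp_path / "rt.csv"
        write_matrix(m, path)
        back = read_matrix(path)
        assert back.sample_ids == m.sample_ids
        assert back.feature_ids == m.feature_ids
        assert (back.values == m.values).all()  # exact, not approx

    def test_tsv_autodetected(self, tmp_path):
        p = _write(tmp_path, "id\tf1\ns1\t1.5\ns2\t2.5\n", name="m.tsv")
        assert read_matrix(p).values[1, 0] == 2.5


class TestFilterAndImpute:
    def test_five_percent_rule_boundary(self):
        # fractions 0, 0.04(->1/10 over), exactly 0.05 impossible at n=10; use n=20
        vals = np.ones((20, 4))
        vals[:0, 0] = np.nan  # 0
        vals[:1, 1] = np.nan  # 5% exactly -> retained
        vals[:2, 2] = np.nan  # 10% -> dropped
        vals[:, 3] = np.nan  # all missing -> dropped
        m = OmicsMatrix([f"s{i}" for i in range(20)], list("abcd"), vals)
        out = filter_missing_features(m, 0.05)
        assert out.feature_ids == ["a", "b"]

    def test_clean_matrix_unchanged(self, rng):
        m = OmicsMatrix(["s1", "s2"], ["a", "b"], rng.normal(size=(2, 2)))
        out = filter_missing_features(m, 0.0)
        assert out.feature_ids == m.feature_ids
        assert (out.values == m.values).all()

    @pytest.mark.parametrize(
        "column,expected",
        [
            ([1.0, np.nan, 3.0], 2.0),
            ([0.0, 0.0, np.nan, 4.0], 4.0 / 3.0),
        ],
    )
    def test_mean_imputation(self, column, expected):
        col = np.asarray(column)
        m = OmicsMatrix([f"s{i}" for i in range(len(col))], ["f"], col[:, None])
        out = impute_mean(m)
        assert out.values[np.isnan(col), 0] == pytest.approx(expected)
        observed = ~np.isnan(col)
        assert (out.values[observed, 0] == col[observed]).all()

    def test_all_missing_column_raises(self):
        m = OmicsMatrix(["s1", "s2"], ["f"], np.full((2, 1), np.nan))
        with pytest.raises(DataError):
            impute_mean(m)

    def test_pipeline_idempotent_on_clean_data(self, rng):
        m = OmicsMatrix(["s1", "s2", "s3"], ["a", "b"], rng.normal(size=(3, 2)))
        once = impute_mean(filter_missing_features(m))
        twice = impute_mean(filter_missing_features(once))
        assert (once.values == twice.values).all()


def _clinical(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "age_days", "inss_stage", "mycn_status",
            "survival_years", "vital_status",
        ],
    )
    return ClinicalTable(df)


class TestMakeLabels:
    def test_four_outcome_combinations(self):
        c = _clinical(
            [
                ["p1", 100, "4", "amplified", 4.9, "dead"],   # (0,0)
                ["p2", 100, "4", "amplified", 6.0, "alive"],  # (1,1)
                ["p3", 100, "4", "amplified", 4.0, "alive"],  # indeterminate (0,1)
                ["p4", 100, "4", "amplified", 7.0, "dead"],   # (1,0)
            ]
        )
        lp = make_labels(c, 5.0)
        assert lp.survival_label.tolist() == [0, 1, 0, 1]
        assert lp.vital_label.tolist() == [0, 1, 1, 0]

    def test_exactly_at_threshold_is_long_term(self):
        c = _clinical([["p1", 1, "4", "amplified", 5.0, "alive"]])
        assert make_labels(c, 5.0).survival_label.tolist() == [1]

    def test_missing_outcome_errors_with_sample_ids(self):
        c = _clinical([["p1", 1, "4", "amplified", np.nan, "alive"]])
        with pytest.raises(DataError, match="p1"):
            make_labels(c)

    def test_threshold_monotonicity(self, small_cohort):
        low = make_labels(small_cohort.clinical, 3.0)
        high = make_labels(small_cohort.clinical, 7.0)
        # raising the threshold can only turn long-term into short-term
        assert (high.survival_label <= low.survival_label).all()


class TestEncodeClinical:
    def test_minmax_endpoints(self):
        c = _clinical(
            [
                ["p1", 0, "1", "amplified", 1, "dead"],
                ["p2", 500, "3", "amplified", 1, "dead"],
                ["p3", 1000, "4", "amplified", 1, "dead"],
            ]
        )
        m = encode_clinical(c, ["age_days"])
        assert m.values[:, 0].tolist() == [0.0, 0.5, 1.0]
        assert m.modality == "clinical-derived"

    def test_onehot_fixed_vocabulary(self):
        c = _clinical([["p1", 1, "4", "amplified", 1, "dead"]])
        m = encode_clinical(c, ["inss_stage"], vocabularies={"inss_stage": ("1", "3", "4")})
        assert m.feature_ids == ["inss_stage=1", "inss_stage=3", "inss_stage=4"]
        assert m.values[0].tolist() == [0.0, 0.0, 1.0]

    def test_unknown_category_all_zero(self):
        c = _clinical([["p1", 1, "4", "unknown", 1, "dead"]])
        m = encode_clinical(c, ["mycn_status"])
        assert m.values[0].tolist() == [0.0, 0.0]

    def test_test_split_scaled_with_train_stats_and_clamped(self):
        train = _clinical(
            [
                ["p1", 0, "4", "amplified", 1, "dead"],
                ["p2", 1000, "4", "amplified", 1, "dead"],
            ]
        )
        test = _clinical([["q1", 1200, "4", "amplified", 1, "dead"]])
        stats = fit_encoding_stats(train, ["age_days"])
        m = encode_clinical(test, ["age_days"], fit_stats=stats)
        assert m.values[0, 0] == 1.0  # clamped above train max

    def test_constant_age_errors(self):
        c = _clinical([["p1", 5, "4", "amplified", 1, "dead"],
                       ["p2", 5, "4", "amplified", 1, "dead"]])
        with pytest.raises(DataError):
            encode_clinical(c, ["age_days"])


class TestConcatenate:
    def test_widths_add_and_ids_prefixed(self, rng):
        sids = ["s1", "s2"]
        widths = [3, 69, 250]
        mods = ["clinical-derived", "expression", "methylation"]
        blocks = [
            OmicsMatrix(sids, [f"f{i}" for i in range(w)], rng.normal(size=(2, w)), mod)
            for w, mod in zip(widths, mods)
        ]
        out = concatenate(blocks)
        assert out.n_features == 322
        assert out.feature_ids[0] == "clinical-derived:f0"
        assert out.feature_ids[3] == "expression:f0"

    def test_single_block_identity(self, rng):
        b = OmicsMatrix(["s1"], ["f"], rng.normal(size=(1, 1)))
        assert concatenate([b]) is b

    def test_sample_order_mismatch_errors(self, rng):
        a = OmicsMatrix(["s1", "s2"], ["f"], rng.normal(size=(2, 1)))
        b = OmicsMatrix(["s2", "s1"], ["g"], rng.normal(size=(2, 1)))
        with pytest.raises(DataError):
            concatenate([a, b])


def test_label_pair_validates_binary():
    with pytest.raises(DataError):
        LabelPair(np.array([0, 2]), np.array([0, 1]))
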