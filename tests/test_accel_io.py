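"""Reading, cleaning, scaling and stratified partitioning of streams."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herdsense.accel_io import (
    CSV_COLUMNS,
    FormatError,
    LabelCodec,
    ScalerParams,
    apply_scaler,
    clean_labels,
    fit_scaler,
    invert_scaler,
    read_accel_csv,
    split_train_test,
    write_accel_csv,
)
from herdsense.simulate import preset_table1, simulate_stream

from conftest import make_window_dataset

CSV_3ROWS = """TimeStamp_UNIX,TimeStamp_JST,AccX,AccY,AccZ,Label
1641000000.0,2022-01-01 09:00:00.000,0.1,-0.2,0.95,RES
1641000000.04,2022-01-01 09:00:00.040,0.11,-0.21,0.94,RES
1641000000.08,2022-01-01 09:00:00.080,0.5,0.4,-0.3,GRZ
"""


class TestReadCsv:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "cow.csv"
        p.write_text(CSV_3ROWS)
        s = read_accel_csv(p)
        assert len(s) == 3
        assert list(s.labels) == ["RES", "RES", "GRZ"]
        assert s.acc[0, 2] == pytest.approx(0.95)
        assert s.n_dropped_rows == 0

    def test_header_driven_column_order(self, tmp_path):
        lines = CSV_3ROWS.strip().split("\n")
        perm = [5, 2, 0, 4, 1, 3]  # Label,AccX,TimeStamp_UNIX,AccZ,TimeStamp_JST,AccY
        permuted = "\n".join(
            ",".join(row.split(",")[j] for j in perm) for row in lines
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p1.write_text(CSV_3ROWS)
        p2.write_text(permuted + "\n")
        s1, s2 = read_accel_csv(p1), read_accel_csv(p2)
        np.testing.assert_array_equal(s1.acc, s2.acc)
        assert list(s1.labels) == list(s2.labels)

    def test_unparseable_row_dropped_and_counted(self, tmp_path):
        p = tmp_path / "cow.csv"
        p.write_text(CSV_3ROWS.replace("0.11", "NaN"))
        s = read_accel_csv(p)
        assert len(s) == 2
        assert s.n_dropped_rows == 1

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "cow.csv"
        p.write_text("TimeStamp_UNIX,TimeStamp_JST,AccX,AccY,Label\n1,a,0,0,RES\n")
        with pytest.raises(FormatError, match="AccZ"):
            read_accel_csv(p)

    def test_missing_label_column_gives_empty_labels(self, tmp_path):
        p = tmp_path / "cow.csv"
        p.write_text("TimeStamp_UNIX,TimeStamp_JST,AccX,AccY,AccZ\n1,a,0.1,0.2,0.3\n")
        s = read_accel_csv(p)
        assert list(s.labels) == [""]

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "cow.csv"
        p.write_text(",".join(CSV_COLUMNS) + "\n")
        with pytest.warns(UserWarning, match="no valid samples"):
            s = read_accel_csv(p)
        assert len(s) == 0

    def test_round_trip_bit_exact(self, tmp_path):
        stream = simulate_stream(preset_table1(20.0, seed=3))
        p = tmp_path / "rt.csv"
        write_accel_csv(stream, p)
        back = read_accel_csv(p)
        assert back.n_dropped_rows == 0
        np.testing.assert_array_equal(stream.t_unix, back.t_unix)
        np.testing.assert_array_equal(stream.acc, back.acc)
        assert list(stream.labels) == list(back.labels)
        # second cycle is byte-stable
        p2 = tmp_path / "rt2.csv"
        write_accel_csv(back, p2)
        assert p.read_text() == p2.read_text()


class TestCleanLabels:
    @staticmethod
    def _stream_with_labels(labels):
        n = len(labels)
        from herdsense.accel_io import AccelStream
        return AccelStream(
            t_unix=np.arange(n, dtype=float),
            t_jst=np.array(["x"] * n, dtype=object),
            acc=np.zeros((n, 3)),
            labels=np.array(labels, dtype=object),
        )

    def test_fifteen_label_inventory_reduces_to_thirteen(self):
        behaviours = ["RES", "RUS", "MOV", "GRZ", "SLT", "FES", "DRN", "LCK",
                      "REL", "URI", "ATT", "ESC", "BMN"]
        raw = behaviours * 2 + ["", "other"] * 2
        s = self._stream_with_labels(raw)
        assert len(s.label_inventory()) == 15
        cleaned = clean_labels(s)
        assert sorted(set(cleaned.labels)) == sorted(behaviours)
        assert len(set(cleaned.labels)) == 13

    def test_other_matched_case_insensitively_and_whitespace_blank(self):
        s = self._stream_with_labels(["RES", "Other", "OTHER", "  ", "GRZ"])
        cleaned = clean_labels(s)
        assert list(cleaned.labels) == ["RES", "GRZ"]

    def test_no_op_when_nothing_to_drop(self):
        s = self._stream_with_labels(["RES", "GRZ", "RES"])
        cleaned = clean_labels(s)
        assert list(cleaned.labels) == ["RES", "GRZ", "RES"]

    def test_all_blank_gives_empty_stream_with_warning(self):
        s = self._stream_with_labels(["", " ", ""])
        with pytest.warns(UserWarning, match="no samples left"):
            cleaned = clean_labels(s)
        assert len(cleaned) == 0

    def test_order_preserved(self):
        s = self._stream_with_labels(["B", "", "A", "other", "C", "B"])
        cleaned = clean_labels(s)
        assert list(cleaned.labels) == ["B", "A", "C", "B"]
        np.testing.assert_array_equal(cleaned.t_unix, [0.0, 2.0, 4.0, 5.0])


class TestScaler:
    def test_two_point_axis(self):
        x = np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        p = fit_scaler(x)
        np.testing.assert_allclose(p.mean, [2.0, 2.0, 2.0])
        np.testing.assert_allclose(p.std, [1.0, 1.0, 1.0])

    def test_constant_axis_guard(self):
        x = np.full((5, 3), 0.7)
        p = fit_scaler(x)
        assert np.all(p.std == 1e-8)
        np.testing.assert_allclose(apply_scaler(x, p), 0.0)

    def test_standardises_random_matrix(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 3.0, size=(1000, 3))
        z = apply_scaler(x, fit_scaler(x))
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-6)

    def test_mean_maps_to_zero_and_identity_params(self):
        p = fit_scaler(np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]]))
        np.testing.assert_allclose(apply_scaler(p.mean, p), 0.0)
        ident = ScalerParams(mean=np.zeros(3), std=np.ones(3))
        x = np.array([0.3, -0.1, 0.9])
        np.testing.assert_array_equal(apply_scaler(x, ident), x)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fit_scaler(np.zeros((0, 3)))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=6, max_size=30))
    def test_round_trip_inverse(self, flat):
        vals = np.array(flat[: 3 * (len(flat) // 3)]).reshape(-1, 3)
        p = fit_scaler(np.array([[0.1, -0.5, 0.9], [0.4, 0.5, -0.9], [0.0, 0.0, 0.1]]))
        np.testing.assert_allclose(invert_scaler(apply_scaler(vals, p), p), vals,
                                   atol=1e-9)


class TestSplit:
    def test_stratified_counts(self):
        ds = make_window_dataset({"A": 80, "B": 20})
        train, test = split_train_test(ds, 0.2, seed=0)
        a = ds.codec.code_of("A")
        assert int((test.y == a).sum()) == 16
        assert int((test.y != a).sum()) == 4
        assert len(train) == 80

    def test_deterministic_for_fixed_seed(self):
        ds = make_window_dataset({"A": 33, "B": 11, "C": 7})
        t1, s1 = split_train_test(ds, 0.25, seed=42)
        t2, s2 = split_train_test(ds, 0.25, seed=42)
        np.testing.assert_array_equal(t1.y, t2.y)
        np.testing.assert_array_equal(s1.X, s2.X)

    def test_partition_disjoint_exhaustive(self):
        ds = make_window_dataset({"A": 31, "B": 12, "C": 5})
        train, test = split_train_test(ds, 0.3, seed=1)
        assert len(train) + len(test) == len(ds)
        # spans identify original windows uniquely here via X content
        all_rows = np.concatenate([train.X, test.X]).reshape(len(ds), -1)
        orig = ds.X.reshape(len(ds), -1)
        assert {tuple(r) for r in all_rows} == {tuple(r) for r in orig}

    def test_singleton_class_goes_to_train(self):
        ds = make_window_dataset({"A": 10, "B": 1})
        with pytest.warns(UserWarning, match="single window"):
            train, test = split_train_test(ds, 0.2, seed=0)
        b = ds.codec.code_of("B")
        assert int((train.y == b).sum()) == 1
        assert int((test.y == b).sum()) == 0

    @settings(max_examples=20, deadline=None)
    @given(
        counts=st.lists(st.integers(2, 40), min_size=2, max_size=5),
        frac=st.floats(0.1, 0.5),
        seed=st.integers(0, 1000),
    )
    def test_per_class_proportion_bound(self, counts, frac, seed):
        ds = make_window_dataset({f"C{i}": c for i, c in enumerate(counts)})
        train, test = split_train_test(ds, frac, seed=seed)
        for c, n_c in enumerate(counts):
            n_test = int((test.y == c).sum())
            assert abs(n_test / n_c - frac) <= 1.0 / n_c + 1e-12


def test_label_codec_is_lexicographic_and_bijective():
    codec = LabelCodec.from_labels(["RUS", "RES", "BMN", "RES"])
    assert codec.names == ("BMN", "RES", "RUS")
    codes = codec.encode(["RES", "BMN", "RUS"])
    np.testing.assert_array_equal(codes, [1, 0, 2])
    assert list(codec.decode(codes)) == ["RES", "BMN", "RUS"]
    with pytest.raises(KeyError, match="GRZ"):
        codec.encode(["GRZ"])
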