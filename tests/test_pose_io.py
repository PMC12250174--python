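import json

import numpy as np
import pytest

from neomotion import (
    FormatError,
    InsufficientDataError,
    OrderingError,
    UnknownRegionError,
    project,
    read_landmark_csv,
    region_indices,
    write_landmark_csv,
)
from neomotion.pose_io import DEFAULT_REGIONS, N_LANDMARKS, REGION_NAMES
from neomotion.synthetic import MotionProfile, generate_sequence

from conftest import make_seq


def _tuple_csv(path, rows):
    """rows: list of (timestamp, [(x, y, z)] * 33)."""
    header = "timestamp," + ",".join(f"landmark_{i}" for i in range(N_LANDMARKS))
    lines = [header]
    for ts, pts in rows:
        cells = [f'"({x},{y},{z})"' for x, y, z in pts]
        lines.append(f"{ts}," + ",".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def _rows(timestamps, point=(0.5, 0.5, -0.1)):
    return [(t, [point] * N_LANDMARKS) for t in timestamps]


class TestReadCsv:
    def test_well_formed_file(self, tmp_path):
        p = _tuple_csv(tmp_path / "a.csv", _rows([1000, 1040, 1080, 1120]))
        seq = read_landmark_csv(p)
        assert len(seq) == 4
        assert seq.n_points == N_LANDMARKS
        assert seq.fps == pytest.approx(25.0)  # 1000 / median(40)
        assert seq.coords[0, 0, 2] == pytest.approx(-0.1)

    def test_row_order_matches_file_order(self, tmp_path):
        rows = [(1000 + 40 * i, [(0.1 * i + 0.05, 0.5, 0.0)] * N_LANDMARKS)
                for i in range(5)]
        seq = read_landmark_csv(_tuple_csv(tmp_path / "o.csv", rows))
        assert np.all(np.diff(seq.coords[:, 0, 0]) > 0)

    def test_out_of_range_row_rejected(self, tmp_path):
        rows = _rows([1000, 1040, 1080, 1120])
        rows[1] = (1040, [(1.7, 0.5, 0.0)] * N_LANDMARKS)
        seq = read_landmark_csv(_tuple_csv(tmp_path / "b.csv", rows))
        assert len(seq) == 3
        assert seq.n_rejected == 1

    def test_out_of_range_clamped_under_clamp_policy(self, tmp_path):
        rows = _rows([1000, 1040, 1080, 1120])
        rows[1] = (1040, [(1.7, -0.2, 0.0)] * N_LANDMARKS)
        seq = read_landmark_csv(_tuple_csv(tmp_path / "c.csv", rows), validation="clamp")
        assert len(seq) == 4
        assert seq.coords[1, 0, 0] == 1.0
        assert seq.coords[1, 0, 1] == 0.0

    def test_missing_columns_is_format_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("timestamp,landmark_0\n1000,\"(0.5,0.5,0)\"\n")
        with pytest.raises(FormatError):
            read_landmark_csv(p)

    def test_missing_timestamp_column(self, tmp_path):
        header = ",".join(f"landmark_{i}" for i in range(N_LANDMARKS))
        p = tmp_path / "nots.csv"
        p.write_text(header + "\n")
        with pytest.raises(FormatError):
            read_landmark_csv(p)

    def test_too_few_rows(self, tmp_path):
        p = _tuple_csv(tmp_path / "short.csv", _rows([1000, 1040]))
        with pytest.raises(InsufficientDataError):
            read_landmark_csv(p)

    def test_non_monotone_timestamps_named(self, tmp_path):
        p = _tuple_csv(tmp_path / "mono.csv", _rows([1000, 1080, 1040, 1120]))
        with pytest.raises(OrderingError) as exc:
            read_landmark_csv(p)
        assert exc.value.row == 2

    def test_flat_dialect_accepted(self, tmp_path):
        cols = ["timestamp"] + [
            f"landmark_{i}_{a}" for i in range(N_LANDMARKS) for a in "xyz"
        ]
        lines = [",".join(cols)]
        for t in (1000, 1100, 1200):
            lines.append(",".join([str(t)] + ["0.4", "0.6", "-0.05"] * N_LANDMARKS))
        p = tmp_path / "flat.csv"
        p.write_text("\n".join(lines))
        seq = read_landmark_csv(p)
        assert len(seq) == 3
        assert seq.coords[0, 10, 1] == pytest.approx(0.6)

    def test_nan_cells_kept_as_invalid_landmarks(self, tmp_path):
        rows = _rows([1000, 1040, 1080, 1120])
        pts = [(0.5, 0.5, -0.1)] * N_LANDMARKS
        pts[30] = ("nan", "nan", "nan")
        rows[2] = (1080, pts)
        seq = read_landmark_csv(_tuple_csv(tmp_path / "n.csv", rows))
        assert len(seq) == 4
        assert np.isnan(seq.coords[2, 30]).all()


def test_write_read_round_trip(tmp_path, rng):
    coords = rng.uniform(0.05, 0.95, size=(6, N_LANDMARKS, 3))
    coords[:, :, 2] -= 0.5
    seq = make_seq(coords)
    path = tmp_path / "rt.csv"
    write_landmark_csv(seq, path)
    back = read_landmark_csv(path)
    np.testing.assert_array_equal(back.timestamps_ms, seq.timestamps_ms)
    np.testing.assert_allclose(back.coords, seq.coords, atol=5e-7)


def test_generated_sequence_round_trip(tmp_path):
    seq, _ = generate_sequence(MotionProfile(duration_s=5, seed=9))
    write_landmark_csv(seq, tmp_path / "g.csv")
    back = read_landmark_csv(tmp_path / "g.csv")
    np.testing.assert_array_equal(back.timestamps_ms, seq.timestamps_ms)
    np.testing.assert_allclose(back.coords, seq.coords, atol=5e-7)


class TestRegions:
    def test_whole_body_has_all_33(self):
        assert len(region_indices("whole_body")) == N_LANDMARKS

    def test_upper_lower_partition(self):
        up = set(region_indices("upper_body").indices)
        lo = set(region_indices("lower_body").indices)
        assert up & lo == set()
        assert up | lo == set(range(N_LANDMARKS))

    def test_limb_subsets(self):
        up = set(region_indices("upper_body").indices)
        lo = set(region_indices("lower_body").indices)
        for r in ("head", "left_arm", "right_arm"):
            assert set(region_indices(r).indices) <= up
        for r in ("left_leg", "right_leg"):
            assert set(region_indices(r).indices) <= lo

    def test_left_leg_indices(self):
        assert set(region_indices("left_leg").indices) == {23, 25, 27, 29, 31}

    def test_unknown_region(self):
        with pytest.raises(UnknownRegionError):
            region_indices("tail")

    def test_overrides(self, tmp_path):
        ov_file = tmp_path / "regions.json"
        ov_file.write_text(json.dumps({"head": [0, 1, 2]}))
        from neomotion.pose_io import load_region_overrides
        ov = load_region_overrides(ov_file)
        assert region_indices("head", overrides=ov).indices == (0, 1, 2)
        # untouched regions keep their defaults
        assert len(region_indices("whole_body", overrides=ov)) == N_LANDMARKS

    def test_names_complete(self):
        assert set(REGION_NAMES) == set(DEFAULT_REGIONS)


class TestProject:
    def test_whole_body_identity(self, random_seq):
        view = project(random_seq, "whole_body")
        np.testing.assert_array_equal(view.coords, random_seq.coords)
        np.testing.assert_array_equal(view.timestamps_ms, random_seq.timestamps_ms)

    def test_idempotent(self, random_seq):
        once = project(random_seq, "lower_body")
        twice = project(once, "lower_body")
        np.testing.assert_array_equal(once.coords, twice.coords)
        np.testing.assert_array_equal(once.landmark_indices, twice.landmark_indices)

    def test_cardinality(self, random_seq):
        view = project(random_seq, "trunk")
        assert view.n_points == len(region_indices("trunk"))
        assert view.region == "trunk"

    def test_partition_point_counts(self, random_seq):
        n_up = project(random_seq, "upper_body").n_points
        n_lo = project(random_seq, "lower_body").n_points
        assert n_up + n_lo == N_LANDMARKS
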