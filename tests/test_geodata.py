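import csv
import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lisakit as lk
from lisakit.errors import (
    DataFormatError,
    DuplicateIdError,
    JoinError,
    UnsupportedGeometryError,
)


def _square(x, y):
    return {
        "type": "Polygon",
        "coordinates": [[[x, y], [x + 1, y], [x + 1, y + 1], [x, y + 1], [x, y]]],
    }


def _fc(features):
    return {"type": "FeatureCollection", "features": features}


def write_geojson(tmp_path, features, name="areas.geojson"):
    path = tmp_path / name
    path.write_text(json.dumps(_fc(features)))
    return path


def feat(area_id, geom, id_key="id"):
    return {"type": "Feature", "properties": {id_key: area_id}, "geometry": geom}


def write_csv(tmp_path, rows, header=("area_id", "time", "value"), name="values.csv"):
    path = tmp_path / name
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
    return path


class TestReadGeometries:
    def test_reads_features_in_file_order(self, tmp_path):
        path = write_geojson(
            tmp_path, [feat(i, _square(k, 0)) for k, i in enumerate("ABCD")]
        )
        geoms = lk.read_geometries(path, id_property="id")
        assert [g.area_id for g in geoms] == list("ABCD")

    def test_missing_id_names_feature_index(self, tmp_path):
        features = [feat("A", _square(0, 0))]
        features.append({"type": "Feature", "properties": {}, "geometry": _square(1, 0)})
        path = write_geojson(tmp_path, features)
        with pytest.raises(DataFormatError, match="feature 1"):
            lk.read_geometries(path, id_property="id")

    def test_duplicate_ids_rejected(self, tmp_path):
        path = write_geojson(tmp_path, [feat("A", _square(0, 0)), feat("A", _square(1, 0))])
        with pytest.raises(DuplicateIdError):
            lk.read_geometries(path, id_property="id")

    def test_point_geometry_rejected(self, tmp_path):
        features = [feat("A", {"type": "Point", "coordinates": [0, 0]})]
        path = write_geojson(tmp_path, features)
        with pytest.raises(UnsupportedGeometryError):
            lk.read_geometries(path, id_property="id")

    def test_multipolygon_round_trip_preserves_parts(self, tmp_path):
        mp = {
            "type": "MultiPolygon",
            "coordinates": [_square(0, 0)["coordinates"], _square(5, 5)["coordinates"]],
        }
        path = write_geojson(tmp_path, [feat("X", mp), feat("A", _square(2, 0))])
        geoms = lk.read_geometries(path, id_property="id")
        assert len(geoms[0].geometry.geoms) == 2
        out = tmp_path / "roundtrip.geojson"
        lk.write_geometries(geoms, out, id_property="id")
        again = lk.read_geometries(out, id_property="id")
        assert len(again[0].geometry.geoms) == 2


class TestReadValueTable:
    def test_long_layout(self, tmp_path):
        path = write_csv(tmp_path, [("A", "1999", "10.0"), ("A", "2000", "11.0")])
        vals = lk.read_value_table(path, layout="long")
        assert vals == {("A", "1999"): 10.0, ("A", "2000"): 11.0}

    def test_wide_layout_with_missing(self, tmp_path):
        path = write_csv(tmp_path, [("A", "10.0", "")], header=("area_id", "1999", "2000"))
        vals = lk.read_value_table(path, layout="wide", id_col="area_id")
        assert vals[("A", "1999")] == 10.0
        assert vals[("A", "2000")] is None

    def test_duplicate_record_rejected(self, tmp_path):
        path = write_csv(tmp_path, [("A", "1999", "10.0"), ("A", "1999", "12.0")])
        with pytest.raises(DuplicateIdError):
            lk.read_value_table(path, layout="long")

    def test_parse_error_names_row(self, tmp_path):
        path = write_csv(tmp_path, [("A", "1999", "10.0"), ("B", "1999", "oops")])
        with pytest.raises(DataFormatError, match="row 3"):
            lk.read_value_table(path, layout="long")

    def test_custom_sentinel_maps_to_missing(self, tmp_path):
        path = write_csv(tmp_path, [("A", "1999", "NA")])
        vals = lk.read_value_table(path, layout="long", missing_sentinel="NA")
        assert vals[("A", "1999")] is None


class TestJoinDataset:
    def geoms(self):
        spec = lk.LatticeSpec(rows=2, cols=2, times=1)
        return lk.grid_lattice(spec)

    def test_full_join(self):
        geoms = self.geoms()
        vals = {(g.area_id, t): 1.0 * i for i, g in enumerate(geoms) for t in ("1999", "2000")}
        ds = lk.join_dataset(geoms, vals)
        assert ds.values.shape == (4, 2)
        assert not np.isnan(ds.values).any()
        assert ds.times == ["1999", "2000"]

    def test_area_without_values_gets_missing_row(self):
        geoms = self.geoms()
        vals = {(g.area_id, "1999"): 1.0 for g in geoms[:3]}
        ds = lk.join_dataset(geoms, vals)
        assert np.isnan(ds.values[3, 0])

    def test_strict_join_rejects_unknown_area(self):
        geoms = self.geoms()
        vals = {("E", "1999"): 1.0}
        with pytest.raises(JoinError, match="E"):
            lk.join_dataset(geoms, vals, strict=True)

    def test_lenient_join_drops_unknown_area(self):
        geoms = self.geoms()
        vals = {("E", "1999"): 1.0, (geoms[0].area_id, "1999"): 2.0}
        ds = lk.join_dataset(geoms, vals, strict=False)
        assert ds.values[0, 0] == 2.0

    def test_times_sorted_numerically(self):
        geoms = self.geoms()
        vals = {(geoms[0].area_id, t): 1.0 for t in ("10", "9", "2")}
        ds = lk.join_dataset(geoms, vals)
        assert ds.times == ["2", "9", "10"]

    @given(st.randoms(use_true_random=False))
    def test_join_invariant_to_record_order(self, rnd):
        geoms = self.geoms()
        items = [
            ((g.area_id, t), float(i + j))
            for i, g in enumerate(geoms)
            for j, t in enumerate(("1999", "2000"))
        ]
        rnd.shuffle(items)
        ds = lk.join_dataset(geoms, dict(items))
        ref = lk.join_dataset(geoms, dict(sorted(items)))
        assert np.array_equal(ds.values, ref.values)
        assert ds.times == ref.times


@pytest.fixture(scope="module")
def small_run():
    spec = lk.LatticeSpec(rows=2, cols=2, times=2, seed=7)
    ds = lk.plant_patterns(spec, [])
    ds.values[3, 0] = np.nan  # one suppressed cell
    cfg = lk.RunConfig(seed=7, methods=("local_moran", "gi_star"), permutations=99)
    return ds, lk.run_analysis(ds, cfg)


class TestResultOutput:

    def test_row_count_areas_times_methods(self, small_run):
        _, res = small_run
        assert len(res.local) == 4 * 2 * 2

    def test_results_csv_deterministic_bytes(self, small_run, tmp_path):
        _, res = small_run
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        lk.write_results_csv(res.local, p1)
        lk.write_results_csv(res.local, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_geojson_round_trip_preserves_area_order(self, small_run, tmp_path):
        ds, res = small_run
        out = tmp_path / "labeled.geojson"
        lk.write_labeled_geojson(ds, res, ds.times[0], out)
        again = lk.read_geometries(out, id_property="area_id")
        assert [g.area_id for g in again] == ds.area_ids

    def test_missing_cell_written_as_null_with_missing_label(self, small_run, tmp_path):
        ds, res = small_run
        out = tmp_path / "labeled.geojson"
        lk.write_labeled_geojson(ds, res, ds.times[0], out)
        doc = json.loads(out.read_text())
        props = doc["features"][3]["properties"]
        assert props["value"] is None
        assert props["local_moran"]["label"] == "missing"

    def test_unknown_time_rejected(self, small_run, tmp_path):
        ds, res = small_run
        with pytest.raises(KeyError):
            lk.write_labeled_geojson(ds, res, "1850", tmp_path / "x.geojson")
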