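import numpy as np
import pandas as pd
import pytest

from phasormp.classify import (
    Cursor,
    LabelMap,
    ParticleTable,
    PARTICLE_COLUMNS,
    classify_pixels,
    auto_cursors,
    composition_fractions,
    extract_particles,
    load_cursors_yaml,
    mosaic_aggregate,
    save_cursors_yaml,
)
from phasormp.errors import ConfigurationError, UnitError
from phasormp.phasor import PhasorImage


def make_phasor_image(points, shape=None, pixel_size=None):
    """PhasorImage whose pixels hold the given (X, Y) points row-major."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if shape is None:
        shape = (1, n)
    x = np.full(shape, np.nan)
    y = np.full(shape, np.nan)
    w = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    flat = np.arange(n)
    ys, xs = np.unravel_index(flat, shape)
    x[ys, xs] = pts[:, 0]
    y[ys, xs] = pts[:, 1]
    w[ys, xs] = 1.0
    valid[ys, xs] = True
    return PhasorImage(x, y, w, valid, pixel_size=pixel_size)


class TestCursor:
    def test_validation(self):
        with pytest.raises(ConfigurationError):
            Cursor("a", (0.0, 0.0), radius=0.0)
        with pytest.raises(ConfigurationError):
            Cursor("a", (1.5, 0.0))

    def test_contains(self):
        c = Cursor("a", (0.5, 0.0), radius=0.1)
        assert c.contains(0.5, 0.05)
        assert not c.contains(0.5, 0.2)

    def test_yaml_round_trip(self, tmp_path):
        cursors = [
            Cursor("PP", (0.5, 0.7), 0.08, (0.0, 0.3, 1.0)),
            Cursor("PET", (-0.5, -0.2), 0.1, (1.0, 0.1, 0.1)),
        ]
        path = save_cursors_yaml(cursors, tmp_path / "cursors.yaml")
        loaded = load_cursors_yaml(path)
        assert loaded == cursors


class TestClassifyPixels:
    def test_pixel_at_cursor_center(self):
        pim = make_phasor_image([(0.5, 0.5)])
        lm = classify_pixels(pim, [Cursor("A", (0.5, 0.5), 0.08)])
        assert lm.labels[0, 0] == 1
        assert lm.classes == ("A",)

    def test_outside_all_cursors(self):
        pim = make_phasor_image([(0.99, 0.0)])
        lm = classify_pixels(pim, [Cursor("A", (0.0, 0.0), 0.08)])
        assert lm.labels[0, 0] == 0

    def test_nearest_center_wins(self):
        pim = make_phasor_image([(0.1, 0.0)])
        cursors = [Cursor("far", (0.3, 0.0), 0.3), Cursor("near", (0.05, 0.0), 0.3)]
        lm = classify_pixels(pim, cursors)
        assert lm.classes[lm.labels[0, 0] - 1] == "near"

    def test_tie_goes_to_first_listed(self):
        pim = make_phasor_image([(0.0, 0.0)])
        cursors = [Cursor("first", (0.1, 0.0), 0.3), Cursor("second", (-0.1, 0.0), 0.3)]
        lm = classify_pixels(pim, cursors)
        assert lm.classes[lm.labels[0, 0] - 1] == "first"

    def test_invalid_pixels_stay_zero(self):
        pim = make_phasor_image([(0.0, 0.0)], shape=(2, 2))
        lm = classify_pixels(pim, [Cursor("A", (0.0, 0.0), 0.5)])
        assert lm.labels[0, 0] == 1
        assert (lm.labels.ravel()[1:] == 0).all()

    def test_duplicate_labels_rejected(self):
        pim = make_phasor_image([(0.0, 0.0)])
        with pytest.raises(ConfigurationError, match="duplicate"):
            classify_pixels(pim, [Cursor("A", (0.0, 0.0)), Cursor("A", (0.5, 0.5))])

    def test_no_cursors_rejected(self):
        pim = make_phasor_image([(0.0, 0.0)])
        with pytest.raises(ConfigurationError):
            classify_pixels(pim, [])

    def test_back_mapping_consistency(self, rng):
        pts = rng.uniform(-0.9, 0.9, size=(200, 2))
        pim = make_phasor_image(pts, shape=(10, 20))
        cursors = [
            Cursor("A", (0.4, 0.4), 0.3),
            Cursor("B", (-0.4, 0.1), 0.35),
            Cursor("C", (0.0, -0.5), 0.25),
        ]
        lm = classify_pixels(pim, cursors)
        for ci, c in enumerate(cursors, start=1):
            ys, xs = np.nonzero(lm.labels == ci)
            assert c.contains(pim.x[ys, xs], pim.y[ys, xs]).all()


class TestAutoCursors:
    def test_two_separated_clusters(self, rng):
        a = rng.normal((0.5, 0.5), 0.01, size=(300, 2))
        b = rng.normal((-0.5, -0.2), 0.01, size=(300, 2))
        pim = make_phasor_image(np.vstack([a, b]), shape=(20, 30))
        cursors = auto_cursors(pim, k=2, radius=0.1, seed=0)
        assert len(cursors) == 2
        lm = classify_pixels(pim, cursors)
        # each cluster captured by one cursor
        first = lm.labels.ravel()[:300]
        second = lm.labels.ravel()[300:600]
        assert (first == first[0]).mean() > 0.99
        assert (second == second[0]).mean() > 0.99
        assert first[0] != second[0]

    def test_k1_center_is_weighted_centroid(self, rng):
        pts = rng.uniform(-0.3, 0.3, size=(50, 2))
        pim = make_phasor_image(pts, shape=(5, 10))
        # uneven weights
        pim.weight[pim.valid_mask] = np.linspace(1, 5, 50)
        (cursor,) = auto_cursors(pim, k=1, seed=0)
        w = pim.weight[pim.valid_mask]
        expected = np.average(pts, axis=0, weights=w)
        assert cursor.center[0] == pytest.approx(expected[0], abs=1e-9)
        assert cursor.center[1] == pytest.approx(expected[1], abs=1e-9)

    def test_deterministic(self, rng):
        pts = rng.uniform(-0.5, 0.5, size=(100, 2))
        pim = make_phasor_image(pts, shape=(10, 10))
        c1 = auto_cursors(pim, k=3, seed=7)
        c2 = auto_cursors(pim, k=3, seed=7)
        assert c1 == c2

    def test_too_few_pixels(self):
        pim = make_phasor_image([(0.0, 0.0), (0.1, 0.1)])
        with pytest.raises(ConfigurationError, match="2.*5|5.*2"):
            auto_cursors(pim, k=5)


class TestExtractParticles:
    def test_two_blobs(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[2:4, 2:7] = 1  # 10 px
        labels[10:12, 10:15] = 1  # 10 px
        lm = LabelMap(labels, ("A",))
        pt = extract_particles(lm, min_particle_size=4)
        assert len(pt) == 2
        assert (pt.frame["area_px"] == 10).all()
        assert pt.frame["particle_id"].is_unique

    def test_min_size_filter(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[0, 0:3] = 1  # 3 px blob
        lm = LabelMap(labels, ("A",))
        assert len(extract_particles(lm, min_particle_size=5)) == 0
        assert len(extract_particles(lm, min_particle_size=3)) == 1

    def test_connectivity(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[1:3, 1:3] = 1
        labels[3:5, 3:5] = 1  # touches diagonally at (2,2)-(3,3)
        lm = LabelMap(labels, ("A",))
        assert len(extract_particles(lm, min_particle_size=1, connectivity=8)) == 1
        assert len(extract_particles(lm, min_particle_size=1, connectivity=4)) == 2

    def test_classes_kept_separate(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:5, 2:5] = 1
        labels[2:5, 5:8] = 2  # touching blob of another class
        lm = LabelMap(labels, ("A", "B"))
        pt = extract_particles(lm, min_particle_size=1)
        assert sorted(pt.frame["class"]) == ["A", "B"]

    def test_micron_units(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[0:2, 0:2] = 1
        lm = LabelMap(labels, ("A",), pixel_size=5.0)
        pt = extract_particles(lm, min_particle_size=1)
        row = pt.frame.iloc[0]
        assert row["area_um2"] == pytest.approx(4 * 25.0)
        assert row["eq_diameter_um"] == pytest.approx(row["eq_diameter_px"] * 5.0)

    def test_empty_map(self):
        lm = LabelMap(np.zeros((5, 5), dtype=int), ("A",))
        pt = extract_particles(lm)
        assert pt.is_empty

    def test_bad_connectivity(self):
        lm = LabelMap(np.zeros((5, 5), dtype=int), ("A",))
        with pytest.raises(ValueError):
            extract_particles(lm, connectivity=6)


def _table(rows, pixel_size=None):
    df = pd.DataFrame(rows)
    for col in PARTICLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col != "tile" else ""
    return ParticleTable(df[PARTICLE_COLUMNS], pixel_size=pixel_size)


class TestCompositionFractions:
    def test_single_class(self):
        pt = _table([{"particle_id": 1, "class": "A", "area_px": 50}])
        assert composition_fractions(pt, "pixel_area") == {"A": 1.0}

    def test_area_basis(self):
        pt = _table(
            [
                {"particle_id": 1, "class": "A", "area_px": 300},
                {"particle_id": 2, "class": "B", "area_px": 100},
            ]
        )
        out = composition_fractions(pt, "pixel_area")
        assert out == {"A": pytest.approx(0.75), "B": pytest.approx(0.25)}

    def test_count_basis(self):
        pt = _table(
            [
                {"particle_id": 1, "class": "A", "area_px": 300},
                {"particle_id": 2, "class": "B", "area_px": 100},
                {"particle_id": 3, "class": "B", "area_px": 10},
            ]
        )
        out = composition_fractions(pt, "particle_count")
        assert out["A"] == pytest.approx(1 / 3)
        assert out["B"] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("basis", ["pixel_area", "particle_count"])
    def test_sums_to_one(self, rng, basis):
        rows = [
            {"particle_id": i, "class": rng.choice(list("ABCD")), "area_px": int(rng.integers(1, 100))}
            for i in range(1, 40)
        ]
        out = composition_fractions(_table(rows), basis)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in out.values())

    def test_empty_table_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = composition_fractions(ParticleTable(), "pixel_area")
        assert out == {}
        assert any("empty" in r.message for r in caplog.records)

    def test_bad_basis(self):
        with pytest.raises(ValueError):
            composition_fractions(ParticleTable(), "volume")


class TestMosaicAggregate:
    def test_concatenation(self):
        t1 = _table([{"particle_id": i, "class": "A", "area_px": 10} for i in range(1, 4)])
        t2 = _table([{"particle_id": i, "class": "B", "area_px": 5} for i in range(1, 5)])
        agg = mosaic_aggregate([t1, t2])
        assert len(agg) == 7
        assert agg.frame["particle_id"].is_unique
        assert set(agg.frame["tile"]) == {"tile_0", "tile_1"}

    def test_fractions_invariant_under_duplication(self):
        t = _table(
            [
                {"particle_id": 1, "class": "A", "area_px": 30},
                {"particle_id": 2, "class": "B", "area_px": 10},
            ]
        )
        single = composition_fractions(mosaic_aggregate([t]), "pixel_area")
        double = composition_fractions(mosaic_aggregate([t, t]), "pixel_area")
        assert single == pytest.approx(double)
        doubled_area = mosaic_aggregate([t, t]).frame.groupby("class")["area_px"].sum()
        assert doubled_area["A"] == 60 and doubled_area["B"] == 20

    def test_empty_list(self):
        assert mosaic_aggregate([]).is_empty

    def test_mixed_pixel_size_rejected(self):
        t1 = _table([{"particle_id": 1, "class": "A", "area_px": 10}], pixel_size=5.0)
        t2 = _table([{"particle_id": 1, "class": "A", "area_px": 10}], pixel_size=2.0)
        with pytest.raises(UnitError):
            mosaic_aggregate([t1, t2])

    def test_pooling_equals_per_tile_pooled_counts(self):
        t1 = _table(
            [
                {"particle_id": 1, "class": "A", "area_px": 10},
                {"particle_id": 2, "class": "B", "area_px": 30},
            ]
        )
        t2 = _table([{"particle_id": 1, "class": "A", "area_px": 60}])
        agg = mosaic_aggregate([t1, t2])
        out = composition_fractions(agg, "pixel_area")
        assert out == {"A": pytest.approx(0.7), "B": pytest.approx(0.3)}


class TestLabelMapExport:
    def test_png_and_legend(self, tmp_path):
        labels = np.zeros((8, 8), dtype=int)
        labels[1:3, 1:3] = 1
        labels[5:7, 5:7] = 2
        lm = LabelMap(labels, ("PP", "PET"))
        from phasormp.classify import save_labelmap

        png = save_labelmap(lm, tmp_path / "sel.png", tmp_path / "legend.json")
        import imageio.v3 as iio
        import json

        rgb = iio.imread(png)
        assert rgb.shape == (8, 8, 3)
        # PET is red-dominant, PP blue-dominant
        assert rgb[5, 5, 0] > rgb[5, 5, 2]
        assert rgb[1, 1, 2] > rgb[1, 1, 0]
        legend = json.loads((tmp_path / "legend.json").read_text())
        assert legend["1"]["class"] == "PP"
        assert legend["2"]["class"] == "PET"
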