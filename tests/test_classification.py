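"""classification: ring means, thresholds, positivity and summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_label_map
from cytoquant.classification import (
    CellClassification,
    ChannelRule,
    ClassificationConfig,
    classify_cells,
    compute_cell_intensity,
    derive_threshold,
    read_summary_csv,
    summarize,
    write_cell_csv,
    write_summary_csv,
)
from cytoquant.errors import (
    ConfigurationError,
    DataIntegrityError,
    DegenerateCellWarning,
    DomainError,
    PairingError,
)
from cytoquant.expansion import ExpansionSettings, expand_labels, ring_mask
from cytoquant.image_io import CalibratedImage
from cytoquant.measurement import MeasurementTable, measure_cells


def _table(rows, state, sample="s"):
    """rows: list of (label, channel, area_px, mean, integrated)."""
    df = pd.DataFrame(
        [
            {
                "label_id": lid,
                "channel_index": ch,
                "area_px": area,
                "area_um2": float(area),
                "mean_intensity": mean,
                "integrated_intensity": integ,
                "min_intensity": 0.0,
                "max_intensity": mean * 2,
                "centroid_y": 0.0,
                "centroid_x": 0.0,
                "touches_border": False,
            }
            for lid, ch, area, mean, integ in rows
        ]
    )
    return MeasurementTable(df, sample_id=sample, enlargement_state=state, pixel_size_um=1.0)


class TestComputeCellIntensity:
    def test_worked_ring_example(self):
        without = _table([(1, 1, 10, 10.0, 100.0)], "without")
        with_enl = _table([(1, 1, 15, 250.0 / 15, 250.0)], "with")
        ci = compute_cell_intensity(without, with_enl, "ring")
        assert ci.data.iloc[0]["new_mean_intensity"] == pytest.approx(30.0)

    def test_uniform_image_ring_equals_value(self, rng):
        lm = random_label_map(rng, size=20)
        v = 42.5
        img = CalibratedImage(np.full((1, 1, 20, 20), v), pixel_size_um=0.5)
        fp = expand_labels(lm, ExpansionSettings(1.0))
        ci = compute_cell_intensity(
            measure_cells(img, lm), measure_cells(img, fp), "ring"
        )
        ok = ~ci.data["degenerate"]
        np.testing.assert_allclose(ci.data.loc[ok, "new_mean_intensity"], v)

    def test_ring_matches_pixel_oracle(self, rng):
        for _ in range(5):
            lm = random_label_map(rng, size=24)
            pixels = rng.random((1, 2, 24, 24)) * 500
            img = CalibratedImage(pixels, pixel_size_um=0.5)
            fp = expand_labels(lm, ExpansionSettings(1.0))
            ci = compute_cell_intensity(
                measure_cells(img, lm), measure_cells(img, fp), "ring"
            )
            for rec in ci.data.itertuples(index=False):
                ring = ring_mask(fp, lm, int(rec.label_id))
                if ring.sum() == 0:
                    assert rec.degenerate
                    continue
                oracle = pixels[0, int(rec.channel_index)][ring].mean()
                assert rec.new_mean_intensity == pytest.approx(oracle, rel=1e-9)

    def test_expanded_mean_method(self):
        without = _table([(1, 1, 10, 10.0, 100.0)], "without")
        with_enl = _table([(1, 1, 15, 250.0 / 15, 250.0)], "with")
        ci = compute_cell_intensity(without, with_enl, "expanded_mean")
        assert ci.data.iloc[0]["new_mean_intensity"] == pytest.approx(250.0 / 15)

    def test_degenerate_falls_back_to_nucleus_mean(self):
        without = _table([(1, 1, 10, 12.0, 120.0)], "without")
        with_enl = _table([(1, 1, 10, 12.0, 120.0)], "with")  # fully clipped
        with pytest.warns(DegenerateCellWarning):
            ci = compute_cell_intensity(without, with_enl, "ring")
        row = ci.data.iloc[0]
        assert row["degenerate"]
        assert row["new_mean_intensity"] == pytest.approx(12.0)

    def test_unpaired_rows(self):
        without = _table([(1, 1, 10, 1.0, 10.0)], "without")
        with_enl = _table([(2, 1, 15, 1.0, 15.0)], "with")
        with pytest.raises(PairingError):
            compute_cell_intensity(without, with_enl)

    def test_negative_ring_mean_rejected(self):
        without = _table([(1, 1, 10, 50.0, 500.0)], "without")
        with_enl = _table([(1, 1, 15, 20.0, 300.0)], "with")  # IntDen shrank
        with pytest.raises(DataIntegrityError):
            compute_cell_intensity(without, with_enl, "ring")

    def test_ring_invariant_to_outside_offset(self, rng):
        # adding a constant outside every footprint leaves ring means unchanged
        lm = random_label_map(rng, size=24)
        pixels = rng.random((1, 1, 24, 24)) * 100
        img = CalibratedImage(pixels, pixel_size_um=0.5)
        fp = expand_labels(lm, ExpansionSettings(1.0))
        outside = ~fp.union()
        shifted = pixels.copy()
        shifted[0, 0][outside] += 777.0
        img2 = CalibratedImage(shifted, pixel_size_um=0.5)
        ci1 = compute_cell_intensity(measure_cells(img, lm), measure_cells(img, fp))
        ci2 = compute_cell_intensity(measure_cells(img2, lm), measure_cells(img2, fp))
        np.testing.assert_allclose(
            ci1.data["new_mean_intensity"], ci2.data["new_mean_intensity"], rtol=1e-12
        )


class TestDeriveThreshold:
    def test_printed_factor(self):
        assert derive_threshold(250.0) == pytest.approx(150.0)

    def test_consistent_with_published_table(self):
        assert derive_threshold(66.67) == pytest.approx(40.0, abs=0.01)

    def test_identity_factor(self):
        assert derive_threshold(123.4, factor=1.0) == pytest.approx(123.4)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            derive_threshold(bad)


def _intensity(values_by_cell_channel, sample="s"):
    from cytoquant.classification import CellIntensity

    rows = [
        (lid, ch, v, False) for (lid, ch), v in sorted(values_by_cell_channel.items())
    ]
    df = pd.DataFrame(
        rows, columns=["label_id", "channel_index", "new_mean_intensity", "degenerate"]
    )
    return CellIntensity(data=df, method="ring", sample_id=sample)


class TestClassifyCells:
    def test_strict_inequality(self):
        cfg = ClassificationConfig(channels=[ChannelRule(1, 40.0, "cpep")])
        ci = _intensity({(1, 1): 55.0, (2, 1): 40.0})
        cls = classify_cells(ci, cfg)
        assert cls.positives[1] == frozenset({"cpep"})
        assert cls.positives[2] == frozenset()  # ties classify negative

    def test_all_thresholds_above(self):
        cfg = ClassificationConfig(channels=[ChannelRule(1, 1e9, "m")])
        ci = _intensity({(1, 1): 55.0, (2, 1): 400.0})
        cls = classify_cells(ci, cfg)
        assert all(not s for s in cls.positives.values())

    def test_nested_thresholds_same_channel(self):
        cfg = ClassificationConfig(
            channels=[ChannelRule(1, 50.0, "gcg"), ChannelRule(1, 150.0, "gcg_high")]
        )
        ci = _intensity({(1, 1): 200.0, (2, 1): 100.0, (3, 1): 10.0})
        cls = classify_cells(ci, cfg)
        for pos in cls.positives.values():
            if "gcg_high" in pos:
                assert "gcg" in pos  # monotone nesting
        assert cls.positives[1] == frozenset({"gcg", "gcg_high"})
        assert cls.positives[2] == frozenset({"gcg"})
        assert cls.positives[3] == frozenset()

    def test_missing_channel(self):
        cfg = ClassificationConfig(channels=[ChannelRule(3, 10.0)])
        ci = _intensity({(1, 1): 55.0})
        with pytest.raises(ConfigurationError):
            classify_cells(ci, cfg)

    def test_disabled_rule_ignored(self):
        cfg = ClassificationConfig(
            channels=[ChannelRule(1, 10.0, "on"), ChannelRule(2, 0.0, "off", enabled=False)]
        )
        ci = _intensity({(1, 1): 55.0})
        cls = classify_cells(ci, cfg)  # disabled rule's channel may be absent
        assert cls.positives[1] == frozenset({"on"})


class TestSummarize:
    def _cfg(self):
        return ClassificationConfig(
            channels=[ChannelRule(2, 10.0, "ch2"), ChannelRule(3, 10.0, "ch3")]
        )

    def test_worked_ten_cell_example(self):
        # 4 only ch2, 3 only ch3, 1 both, 2 neither
        positives = {}
        lid = 1
        for _ in range(4):
            positives[lid] = frozenset({"ch2"}); lid += 1
        for _ in range(3):
            positives[lid] = frozenset({"ch3"}); lid += 1
        positives[lid] = frozenset({"ch2", "ch3"}); lid += 1
        for _ in range(2):
            positives[lid] = frozenset(); lid += 1
        cls = CellClassification(positives, ["ch2", "ch3"], sample_id="s")
        s = summarize(cls, self._cfg())
        assert s.total_cells == 10
        assert s.positive == {"ch2": 5, "ch3": 4}
        assert s.pct(s.positive["ch2"]) == pytest.approx(50.0)
        assert s.pct(s.positive["ch3"]) == pytest.approx(40.0)
        assert s.exclusive == {"ch2": 4, "ch3": 3}
        assert s.combinations == {("ch2", "ch3"): 1}
        assert s.negative == 2

    def test_all_negative(self):
        cls = CellClassification({i: frozenset() for i in range(1, 6)}, ["ch2", "ch3"])
        s = summarize(cls, self._cfg())
        assert s.positive == {"ch2": 0, "ch3": 0}
        assert s.negative == s.total_cells == 5
        assert s.combinations == {}

    def test_triple_positive_single_cell(self):
        cfg = ClassificationConfig(
            channels=[ChannelRule(1, 1.0, "a"), ChannelRule(2, 1.0, "b"), ChannelRule(3, 1.0, "c")]
        )
        cls = CellClassification({1: frozenset({"a", "b", "c"})}, ["a", "b", "c"])
        s = summarize(cls, cfg)
        assert s.combinations == {("a", "b", "c"): 1}
        assert s.exclusive == {"a": 0, "b": 0, "c": 0}

    def test_zero_cells_percentages_nan(self):
        cls = CellClassification({}, ["ch2", "ch3"])
        s = summarize(cls, self._cfg())
        assert s.total_cells == 0
        assert np.isnan(s.pct(0))

    def test_partition_conservation_random(self, rng):
        names = ["a", "b", "c"]
        cfg = ClassificationConfig(channels=[ChannelRule(i, 1.0, n) for i, n in enumerate(names, 1)])
        for _ in range(200):
            n = int(rng.integers(0, 40))
            positives = {
                lid: frozenset(np.array(names)[rng.random(3) < 0.4].tolist())
                for lid in range(1, n + 1)
            }
            s = summarize(CellClassification(positives, names), cfg)
            part = sum(s.exclusive.values()) + sum(s.combinations.values()) + s.negative
            assert part == s.total_cells == n
            for name in names:
                contrib = s.exclusive[name] + sum(
                    c for combo, c in s.combinations.items() if name in combo
                )
                assert s.positive[name] == contrib

    def test_threshold_monotonicity(self, rng):
        names = ["a", "b"]
        for _ in range(30):
            vals = {
                (lid, ch): float(rng.random() * 100)
                for lid in range(1, 21)
                for ch in (1, 2)
            }
            ci = _intensity(vals)
            t = float(rng.random() * 100)
            for bumped in (t, t + rng.random() * 50):
                cfg = ClassificationConfig(
                    channels=[ChannelRule(1, bumped, "a"), ChannelRule(2, 30.0, "b")]
                )
                s = summarize(classify_cells(ci, cfg), cfg)
                if bumped == t:
                    base = s
            assert s.positive["a"] <= base.positive["a"]
            assert s.exclusive["a"] <= base.exclusive["a"]
            assert s.combinations.get(("a", "b"), 0) <= base.combinations.get(("a", "b"), 0)


class TestConfigYaml:
    def test_roundtrip(self, tmp_path):
        cfg = ClassificationConfig(
            channels=[
                ChannelRule(1, 40.0, "cpep"),
                ChannelRule(2, 50.0, "gcg"),
                ChannelRule(2, 150.0, "gcg_high", enabled=False),
            ],
            intensity_method="expanded_mean",
            note="test run",
        )
        path = cfg.to_yaml(tmp_path / "cfg.yaml")
        back = ClassificationConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_extra_blocks_tolerated(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "channels:\n- {channel_index: 1, threshold: 40}\n"
            "segmentation: {backend: classical}\nexpansion: {distance_um: 1.0}\n"
        )
        cfg = ClassificationConfig.from_yaml(path)
        assert cfg.channels[0].threshold == 40.0

    def test_no_enabled_channel_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassificationConfig(channels=[ChannelRule(1, 10.0, enabled=False)])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigurationError):
            ClassificationConfig(channels=[ChannelRule(1, 10.0, "x"), ChannelRule(2, 5.0, "x")])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            ChannelRule(1, -1.0)


class TestSummaryCsv:
    def _summaries(self):
        cfg = ClassificationConfig(
            channels=[ChannelRule(1, 10.0, "a"), ChannelRule(2, 10.0, "b")]
        )
        out = []
        for sid, sets in (
            ("s1", [{"a"}, {"a", "b"}, set()]),
            ("s2", [{"b"}, {"b"}, {"a"}, set()]),
        ):
            positives = {i: frozenset(s) for i, s in enumerate(sets, 1)}
            out.append(summarize(CellClassification(positives, ["a", "b"], sample_id=sid), cfg))
        return out

    def test_two_samples_one_header(self, tmp_path):
        path = write_summary_csv(self._summaries(), tmp_path / "summary.csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 samples

    def test_roundtrip_counts(self, tmp_path):
        summaries = self._summaries()
        path = write_summary_csv(summaries, tmp_path / "summary.csv")
        df = read_summary_csv(path).set_index("sample_id")
        assert df.loc["s1", "total_cells"] == 3
        assert df.loc["s1", "a_positive"] == 2
        assert df.loc["s1", "a+b_combo"] == 1
        assert df.loc["s2", "negative"] == 1
        assert df.loc["s2", "a+b_combo"] == 0  # zero-filled shared column

    def test_mismatched_rule_sets_rejected(self, tmp_path):
        s1 = self._summaries()[0]
        other_cfg = ClassificationConfig(channels=[ChannelRule(1, 10.0, "a")])
        cls = CellClassification({1: frozenset({"a"})}, ["a"], sample_id="s3")
        s3 = summarize(cls, other_cfg)
        with pytest.raises(ConfigurationError):
            write_summary_csv([s1, s3], tmp_path / "x.csv")

    def test_cell_csv(self, tmp_path):
        ci = _intensity({(1, 1): 55.0, (1, 2): 5.0, (2, 1): 1.0, (2, 2): 99.0})
        cfg = ClassificationConfig(
            channels=[ChannelRule(1, 10.0, "a"), ChannelRule(2, 10.0, "b")]
        )
        cls = classify_cells(ci, cfg)
        path = write_cell_csv(ci, cls, tmp_path / "cells.csv")
        df = pd.read_csv(path)
        assert list(df["positive_for"]) == ["a", "b"]
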