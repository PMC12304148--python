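"""Threshold classification of cells from paired intensity measurements.

From each pair of without/with-enlargement tables a per-cell "new mean
intensity" is derived — by default the mean over the interspace ring,
computed from the paired-measurement identity

    ring_mean = (IntDen_with - IntDen_without) / (Area_with - Area_without)

without re-touching pixels. Cells whose new mean intensity strictly
exceeds a channel rule's threshold are positive for that rule; the sample
summary partitions cells into exclusive singles, exact multi-positive
combinations and all-negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DataIntegrityError,
    DegenerateCellWarning,
    DomainError,
    InputFormatError,
    PairingError,
)
from .measurement import MeasurementTable

__all__ = [
    "ChannelRule",
    "ClassificationConfig",
    "CellIntensity",
    "CellClassification",
    "SampleSummary",
    "compute_cell_intensity",
    "derive_threshold",
    "classify_cells",
    "summarize",
    "write_summary_csv",
    "read_summary_csv",
    "write_cell_csv",
]

DEFAULT_THRESHOLD_FACTOR = 0.6

_INTENSITY_METHODS = ("ring", "expanded_mean")


@dataclass
class ChannelRule:
    """One positivity rule: a marker channel, a name and a threshold.

    Several rules may target the same channel index with different
    thresholds (e.g. a "high-expressing" rule on top of the base rule);
    rule names must then be unique.
    """

    channel_index: int
    threshold: float
    name: str = ""
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError(f"threshold must be >= 0, got {self.threshold}")
        if self.channel_index < 0:
            raise ConfigurationError(f"channel_index must be >= 0, got {self.channel_index}")
        if not self.name:
            self.name = f"ch{self.channel_index}"


@dataclass
class ClassificationConfig:
    """Per-channel rules plus the intensity derivation method.

    Round-trips losslessly to/from YAML; unknown top-level YAML blocks
    (segmentation, expansion, ...) are tolerated and ignored here.
    """

    channels: list[ChannelRule]
    intensity_method: str = "ring"
    note: str = ""

    def __post_init__(self) -> None:
        if self.intensity_method not in _INTENSITY_METHODS:
            raise ConfigurationError(
                f"intensity_method must be one of {_INTENSITY_METHODS}, "
                f"got {self.intensity_method!r}"
            )
        if not any(r.enabled for r in self.channels):
            raise ConfigurationError("at least one channel rule must be enabled")
        names = [r.name for r in self.channels]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"channel rule names must be unique, got {names}")

    @property
    def enabled_rules(self) -> list[ChannelRule]:
        return [r for r in self.channels if r.enabled]

    def to_dict(self) -> dict:
        return {
            "channels": [
                {
                    "channel_index": r.channel_index,
                    "name": r.name,
                    "threshold": r.threshold,
                    "enabled": r.enabled,
                }
                for r in self.channels
            ],
            "intensity_method": self.intensity_method,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassificationConfig":
        try:
            rules = [
                ChannelRule(
                    channel_index=int(c["channel_index"]),
                    threshold=float(c["threshold"]),
                    name=str(c.get("name", "")),
                    enabled=bool(c.get("enabled", True)),
                )
                for c in d["channels"]
            ]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed classification config: {exc}") from exc
        return cls(
            channels=rules,
            intensity_method=d.get("intensity_method", "ring"),
            note=str(d.get("note", "")),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassificationConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse YAML config {path}: {exc}") from exc
        if not isinstance(d, dict) or "channels" not in d:
            raise ConfigurationError(f"{path} is not a classification config (no 'channels')")
        return cls.from_dict(d)


@dataclass
class CellIntensity:
    """Per (label, rule-channel) derived intensity.

    ``data`` columns: label_id, channel_index, new_mean_intensity,
    degenerate (True when the interspace was empty and the nucleus mean
    was used as fallback).
    """

    data: pd.DataFrame
    method: str
    sample_id: str

    def per_channel(self, channel_index: int) -> pd.Series:
        sub = self.data[self.data["channel_index"] == channel_index]
        return sub.set_index("label_id")["new_mean_intensity"]

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.data["label_id"].unique().tolist())

    @property
    def channels(self) -> list[int]:
        return sorted(self.data["channel_index"].unique().tolist())


@dataclass
class CellClassification:
    """Positive rule-name set per cell (possibly empty)."""

    positives: dict[int, frozenset[str]]
    rule_names: list[str]
    degenerate: dict[int, frozenset[str]] = field(default_factory=dict)
    sample_id: str = "sample"


@dataclass
class SampleSummary:
    """Population counts and percentages for one sample.

    The partition {exclusive singles, exact combinations, all-negative}
    sums to ``total_cells``; per-rule positive counts include cells that
    are also positive for other rules. Percentages are NaN when the
    sample has zero cells.
    """

    sample_id: str
    total_cells: int
    rule_names: list[str]
    positive: dict[str, int]
    exclusive: dict[str, int]
    combinations: dict[tuple[str, ...], int]
    negative: int

    def pct(self, count: int) -> float:
        if self.total_cells == 0:
            return float("nan")
        return 100.0 * count / self.total_cells


def compute_cell_intensity(
    without: MeasurementTable,
    with_enl: MeasurementTable,
    method: str = "ring",
) -> CellIntensity:
    """Derive each cell's new mean intensity from a paired table.

    ``ring``: mean over interspace pixels via the integrated-intensity /
    area differences. ``expanded_mean``: the with-enlargement mean. Cells
    whose expansion was fully clipped (equal areas) are flagged degenerate
    and fall back to the nucleus mean, with a warning.
    """
    if method not in _INTENSITY_METHODS:
        raise ConfigurationError(f"unknown intensity method {method!r}")
    keys = ["label_id", "channel_index"]
    merged = without.data.merge(
        with_enl.data, on=keys, how="outer", suffixes=("_wo", "_w"), indicator=True
    )
    unpaired = merged[merged["_merge"] != "both"]
    if len(unpaired):
        raise PairingError(
            f"{len(unpaired)} unpaired (label, channel) rows between tables "
            f"(e.g. {unpaired[keys].iloc[0].tolist()})"
        )
    rows = []
    for rec in merged.itertuples(index=False):
        lid = int(rec.label_id)
        ch = int(rec.channel_index)
        d_area = rec.area_px_w - rec.area_px_wo
        if d_area < 0:
            raise DataIntegrityError(
                f"label {lid} ch {ch}: with-enlargement area {rec.area_px_w} "
                f"< without-enlargement area {rec.area_px_wo}"
            )
        degenerate = False
        if method == "expanded_mean":
            value = rec.mean_intensity_w
        elif d_area == 0:
            degenerate = True
            value = rec.mean_intensity_wo
            warnings.warn(
                f"label {lid} ch {ch}: expansion fully clipped; "
                "falling back to nucleus mean",
                DegenerateCellWarning,
                stacklevel=2,
            )
        else:
            d_int = rec.integrated_intensity_w - rec.integrated_intensity_wo
            value = d_int / d_area
            scale = max(abs(rec.integrated_intensity_w), 1.0)
            if value < -1e-9 * scale:
                raise DataIntegrityError(
                    f"label {lid} ch {ch}: negative ring mean {value}; "
                    "tables are inconsistent"
                )
            value = max(value, 0.0)
        rows.append((lid, ch, float(value), degenerate))
    df = pd.DataFrame(
        rows, columns=["label_id", "channel_index", "new_mean_intensity", "degenerate"]
    )
    return CellIntensity(data=df, method=method, sample_id=without.sample_id)


def derive_threshold(
    representative_intensity: float, factor: float = DEFAULT_THRESHOLD_FACTOR
) -> float:
    """Final threshold from a manually measured representative intensity."""
    if not representative_intensity > 0:
        raise DomainError(
            f"representative_intensity must be > 0, got {representative_intensity}"
        )
    return representative_intensity * factor


def classify_cells(
    intensities: CellIntensity, config: ClassificationConfig
) -> CellClassification:
    """Apply every enabled rule: positive iff new mean intensity > threshold.

    The comparator is strictly greater; ties classify negative. Degenerate
    intensities classify using their fallback value and propagate the flag.
    """
    available = set(intensities.channels)
    for rule in config.enabled_rules:
        if rule.channel_index not in available:
            raise ConfigurationError(
                f"rule {rule.name!r} targets channel {rule.channel_index}, "
                f"absent from intensities (have {sorted(available)})"
            )
    positives: dict[int, set[str]] = {lid: set() for lid in intensities.label_ids}
    degenerate: dict[int, set[str]] = {}
    for rule in config.enabled_rules:
        sub = intensities.data[intensities.data["channel_index"] == rule.channel_index]
        for rec in sub.itertuples(index=False):
            lid = int(rec.label_id)
            if rec.new_mean_intensity > rule.threshold:
                positives[lid].add(rule.name)
            if rec.degenerate:
                degenerate.setdefault(lid, set()).add(rule.name)
    return CellClassification(
        positives={lid: frozenset(s) for lid, s in positives.items()},
        rule_names=[r.name for r in config.enabled_rules],
        degenerate={lid: frozenset(s) for lid, s in degenerate.items()},
        sample_id=intensities.sample_id,
    )


def summarize(
    classification: CellClassification,
    config: ClassificationConfig,
    sample_id: str | None = None,
) -> SampleSummary:
    """Count totals, per-rule positives, exclusive singles, combinations
    and all-negative cells.

    Combinations are enumerated for observed positive sets of size >= 2;
    zero-count combinations are omitted (single-rule counts always appear).
    """
    names = [r.name for r in config.enabled_rules]
    order = {n: i for i, n in enumerate(names)}
    total = len(classification.positives)
    positive = {n: 0 for n in names}
    exclusive = {n: 0 for n in names}
    combinations: dict[tuple[str, ...], int] = {}
    negative = 0
    for pos_set in classification.positives.values():
        if not pos_set:
            negative += 1
            continue
        for n in pos_set:
            positive[n] += 1
        if len(pos_set) == 1:
            (only,) = pos_set
            exclusive[only] += 1
        else:
            combo = tuple(sorted(pos_set, key=order.__getitem__))
            combinations[combo] = combinations.get(combo, 0) + 1
    return SampleSummary(
        sample_id=sample_id or classification.sample_id,
        total_cells=total,
        rule_names=names,
        positive=positive,
        exclusive=exclusive,
        combinations=dict(sorted(combinations.items(), key=lambda kv: [order[n] for n in kv[0]])),
        negative=negative,
    )


def _summary_columns(summaries: list[SampleSummary]) -> tuple[list[str], list[tuple[str, ...]]]:
    names = summaries[0].rule_names
    for s in summaries[1:]:
        if s.rule_names != names:
            raise ConfigurationError(
                f"summaries have mismatched rule sets: {names} vs {s.rule_names}"
            )
    order = {n: i for i, n in enumerate(names)}
    combos = sorted(
        {c for s in summaries for c in s.combinations},
        key=lambda c: [order[n] for n in c],
    )
    return names, combos


def write_summary_csv(summaries: list[SampleSummary], out_path: str | Path) -> Path:
    """Write one row per sample with a stable column order.

    Columns: total, per-rule counts/percentages in config order, exclusive
    counts/percentages, combination counts/percentages (lexicographic by
    rule order), then all-negative count/percentage.
    """
    if not summaries:
        raise ConfigurationError("no summaries to write")
    names, combos = _summary_columns(summaries)
    rows = []
    for s in summaries:
        row: dict[str, object] = {"sample_id": s.sample_id, "total_cells": s.total_cells}
        for n in names:
            row[f"{n}_positive"] = s.positive[n]
            row[f"{n}_positive_pct"] = s.pct(s.positive[n])
        for n in names:
            row[f"{n}_exclusive"] = s.exclusive[n]
            row[f"{n}_exclusive_pct"] = s.pct(s.exclusive[n])
        for combo in combos:
            key = "+".join(combo)
            count = s.combinations.get(combo, 0)
            row[f"{key}_combo"] = count
            row[f"{key}_combo_pct"] = s.pct(count)
        row["negative"] = s.negative
        row["negative_pct"] = s.pct(s.negative)
        rows.append(row)
    df = pd.DataFrame(rows)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False, float_format="%.10g")
    return out_path


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    """Read back a summary CSV (round-trip convenience for checks)."""
    try:
        return pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputFormatError(f"malformed summary CSV {path}: {exc}") from exc


def write_cell_csv(
    intensities: CellIntensity,
    classification: CellClassification,
    out_path: str | Path,
) -> Path:
    """Per-cell debug artifact: label, per-channel intensity, positive set."""
    wide = intensities.data.pivot(
        index="label_id", columns="channel_index", values="new_mean_intensity"
    )
    wide.columns = [f"intensity_ch{c}" for c in wide.columns]
    wide["positive_for"] = [
        "+".join(sorted(classification.positives.get(lid, frozenset())))
        for lid in wide.index
    ]
    wide["degenerate_for"] = [
        "+".join(sorted(classification.degenerate.get(lid, frozenset())))
        for lid in wide.index
    ]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    wide.to_csv(out_path, float_format="%.10g")
    return out_path
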