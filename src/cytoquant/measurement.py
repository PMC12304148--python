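"""Per-label, per-channel region statistics and paired CSV export.

Measurements are taken twice per cell — over the nucleus label and over
the expanded footprint — and written as paired
``{sample}_ch{k}_without_enlargement.csv`` / ``..._with_enlargement.csv``
files, one pair per channel, which the classification stage re-pairs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyRegionWarning, InputFormatError, PairingError, UnpairedFileWarning
from .expansion import ExpandedFootprints
from .image_io import CalibratedImage
from .segmentation import LabelMap

__all__ = [
    "MeasurementTable",
    "measure_cells",
    "write_measurement_csvs",
    "read_measurement_csvs",
]

COLUMNS = [
    "label_id",
    "channel_index",
    "area_px",
    "area_um2",
    "mean_intensity",
    "integrated_intensity",
    "min_intensity",
    "max_intensity",
    "centroid_y",
    "centroid_x",
    "touches_border",
]

_CSV_COLUMNS = COLUMNS[:1] + COLUMNS[2:]  # channel is encoded in the file name

_NAME_RE = re.compile(
    r"^(?P<sample>.+)_ch(?P<channel>\d+)_(?P<state>without|with)_enlargement\.csv$"
)


@dataclass
class MeasurementTable:
    """Region statistics, one row per (label_id, channel_index).

    ``enlargement_state`` is ``"without"`` for nucleus measurements and
    ``"with"`` for expanded-footprint measurements. Empty regions carry
    NaN intensity sentinels (never 0) and area 0.
    """

    data: pd.DataFrame
    sample_id: str
    enlargement_state: str
    pixel_size_um: float

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise InputFormatError(f"measurement table lacks columns {missing}")
        if self.enlargement_state not in ("without", "with"):
            raise InputFormatError(
                f"enlargement_state must be 'without' or 'with', got {self.enlargement_state!r}"
            )
        self.data = self.data[COLUMNS].reset_index(drop=True)

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.data["label_id"].unique().tolist())

    @property
    def channels(self) -> list[int]:
        return sorted(self.data["channel_index"].unique().tolist())


def _region_masks(regions: LabelMap | ExpandedFootprints):
    if isinstance(regions, LabelMap):
        for lid in regions.label_ids:
            yield lid, regions.mask(lid)
    else:
        for lid in regions.label_ids:
            yield lid, regions.footprint(lid)


def measure_cells(
    image: CalibratedImage,
    regions: LabelMap | ExpandedFootprints,
    channels: list[int] | None = None,
    sample_id: str = "sample",
    enlargement_state: str | None = None,
) -> MeasurementTable:
    """Measure every region over every requested channel.

    Overlapping independent-mode footprints are each measured over their
    full own pixel set, so shared pixels contribute to several rows.
    """
    if image.n_z != 1:
        from .errors import ConfigurationError

        raise ConfigurationError("measure_cells requires a single-plane image")
    if channels is None:
        channels = list(range(image.n_channels))
    if enlargement_state is None:
        enlargement_state = "with" if isinstance(regions, ExpandedFootprints) else "without"
    h, w = image.frame_shape
    cal = image.pixel_size_um
    rows = []
    for lid, mask in _region_masks(regions):
        if mask.shape != (h, w):
            raise PairingError(
                f"region grid {mask.shape} does not match image grid {(h, w)}"
            )
        ys, xs = np.nonzero(mask)
        area = len(ys)
        if area == 0:
            warnings.warn(
                f"label {lid} has an empty region; intensities set to NaN",
                EmptyRegionWarning,
                stacklevel=2,
            )
            for c in channels:
                rows.append((lid, c, 0, 0.0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        cy = float(ys.mean())
        cx = float(xs.mean())
        border = bool(ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1)
        for c in channels:
            vals = image.pixels[0, c][ys, xs].astype(float)
            rows.append(
                (
                    lid,
                    c,
                    area,
                    area * cal * cal,
                    float(vals.mean()),
                    float(vals.sum()),
                    float(vals.min()),
                    float(vals.max()),
                    cy,
                    cx,
                    border,
                )
            )
    df = pd.DataFrame(rows, columns=COLUMNS)
    return MeasurementTable(
        data=df,
        sample_id=sample_id,
        enlargement_state=enlargement_state,
        pixel_size_um=cal,
    )


def write_measurement_csvs(
    without: MeasurementTable,
    with_enl: MeasurementTable,
    out_dir: str | Path,
    sample_id: str | None = None,
) -> list[tuple[Path, Path]]:
    """Write one (without, with) CSV pair per channel; returns the path pairs.

    Files are comma-separated with a header row, one data row per label in
    ascending label order, dot-decimal formatting.
    """
    if without.enlargement_state != "without" or with_enl.enlargement_state != "with":
        raise PairingError("tables passed in the wrong order (expected without, with)")
    if without.label_ids != with_enl.label_ids:
        raise PairingError(
            f"label sets differ: {without.label_ids[:5]}... vs {with_enl.label_ids[:5]}..."
        )
    if without.channels != with_enl.channels:
        raise PairingError(f"channel sets differ: {without.channels} vs {with_enl.channels}")
    sample = sample_id or without.sample_id
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for c in without.channels:
        paths = []
        for table, state in ((without, "without"), (with_enl, "with")):
            sub = (
                table.data[table.data["channel_index"] == c]
                .sort_values("label_id")
                .loc[:, _CSV_COLUMNS]
            )
            path = out_dir / f"{sample}_ch{c}_{state}_enlargement.csv"
            sub.to_csv(path, index=False, float_format="%.10g")
            paths.append(path)
        pairs.append(tuple(paths))
    return pairs


def _parse_csv(path: Path, channel: int, state: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputFormatError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path} lacks columns {missing}")
    df = df.copy()
    df["channel_index"] = channel
    return df


def read_measurement_csvs(
    directory: str | Path,
) -> dict[str, tuple[MeasurementTable, MeasurementTable]]:
    """Recover paired tables from a directory of measurement CSVs.

    Files are paired by ``(sample, channel)``; per-channel tables of each
    sample are concatenated into one table per enlargement state. Orphan
    files trigger :class:`UnpairedFileWarning` and are excluded. An empty
    directory yields an empty mapping.
    """
    directory = Path(directory)
    found: dict[tuple[str, int], dict[str, Path]] = {}
    for path in sorted(directory.glob("*.csv")):
        m = _NAME_RE.match(path.name)
        if not m:
            continue
        key = (m["sample"], int(m["channel"]))
        found.setdefault(key, {})[m["state"]] = path
    per_sample: dict[str, dict[str, list[pd.DataFrame]]] = {}
    for (sample, channel), states in sorted(found.items()):
        if set(states) != {"without", "with"}:
            (orphan,) = states.values()
            warnings.warn(
                f"unpaired measurement file: {orphan.name}", UnpairedFileWarning, stacklevel=2
            )
            continue
        bucket = per_sample.setdefault(sample, {"without": [], "with": []})
        for state, path in states.items():
            bucket[state].append(_parse_csv(path, channel, state))
    out = {}
    for sample, bucket in per_sample.items():
        tables = {}
        for state in ("without", "with"):
            df = pd.concat(bucket[state], ignore_index=True)
            # calibration is recoverable from any non-empty row
            nz = df[df["area_px"] > 0]
            cal = (
                float(np.sqrt(nz["area_um2"].iloc[0] / nz["area_px"].iloc[0]))
                if len(nz)
                else 1.0
            )
            tables[state] = MeasurementTable(
                data=df, sample_id=sample, enlargement_state=state, pixel_size_um=cal
            )
        out[sample] = (tables["without"], tables["with"])
    return out
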