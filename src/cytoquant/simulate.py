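"""Synthetic multi-channel images of densely packed cells with ground truth.

Fields emulate islet-like tissue: elliptical nuclei placed by rejection
sampling, annular cytoplasmic shells whose per-channel intensity encodes
each cell's true marker status, plus a background level and additive
Gaussian noise clipped at zero. Channel 0 is always the nuclear stain;
markers occupy channels 1..M (M <= 4).

All randomness flows through ``numpy.random.default_rng(seed)`` (the
PCG64 generator), so a fixed seed reproduces the arrays bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import ellipse

from .errors import ConfigurationError, PackingInfeasibleError
from .image_io import CalibratedImage
from .segmentation import LabelMap

__all__ = ["MarkerSpec", "SimulationParams", "GroundTruth", "simulate_image", "adjacency_scenario"]


@dataclass(frozen=True)
class MarkerSpec:
    """Intensity model for one marker channel.

    Positive cells draw their shell intensity from
    N(positive_mean, positive_sd); negatives from
    N(negative_mean, negative_sd). Draws are clipped at zero.
    """

    positive_fraction: float = 0.5
    positive_mean: float = 100.0
    positive_sd: float = 0.0
    negative_mean: float = 0.0
    negative_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ConfigurationError(
                f"positive_fraction must be in [0, 1], got {self.positive_fraction}"
            )
        for name in ("positive_mean", "positive_sd", "negative_mean", "negative_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    """Geometry, intensity and noise settings for one synthetic field."""

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    n_cells: int = 50
    nucleus_radius_um: tuple[float, float] = (2.0, 3.0)
    min_spacing_um: float = 0.5  # edge-to-edge gap; negative allows near-contact
    shell_thickness_um: float = 1.5
    markers: tuple[MarkerSpec, ...] = (MarkerSpec(),)
    nuclear_intensity: float = 200.0
    background: float = 0.0
    noise_sd: float = 0.0
    eccentricity: float = 0.2  # max relative axis stretch of the nuclei
    seed: int = 0
    max_attempts: int = 20000

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        lo, hi = self.nucleus_radius_um
        if not 0 < lo <= hi:
            raise ConfigurationError(f"invalid nucleus radius range ({lo}, {hi})")
        if self.shell_thickness_um <= 0:
            raise ConfigurationError("shell_thickness_um must be > 0")
        if not 1 <= len(self.markers) <= 4:
            raise ConfigurationError("between 1 and 4 marker channels are supported")
        if self.noise_sd < 0 or self.background < 0 or self.nuclear_intensity <= 0:
            raise ConfigurationError("intensity/noise settings must be non-negative")
        if not 0 <= self.eccentricity < 1:
            raise ConfigurationError("eccentricity must be in [0, 1)")


@dataclass
class GroundTruth:
    """Known geometry and marker status of every simulated cell.

    ``positive_sets[i]`` holds the marker channel indices (1-based within
    the image: channel 1 is the first marker) the cell truly expresses.
    """

    centers: np.ndarray  # (n, 2) float, (y, x) in pixels
    radii_um: np.ndarray  # nominal nucleus radii
    positive_sets: list[frozenset[int]]
    label_map: LabelMap

    @property
    def n_cells(self) -> int:
        return len(self.radii_um)


def _place_centers(
    rng: np.random.Generator, params: SimulationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample nucleus centers honoring the minimum spacing."""
    h, w = params.shape
    px = params.pixel_size_um
    lo, hi = params.nucleus_radius_um
    margin_um = hi + params.shell_thickness_um
    margin = margin_um / px + 1
    if 2 * margin >= min(h, w):
        raise ConfigurationError("image too small for the requested cell geometry")
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < params.n_cells:
        attempts += 1
        if attempts > params.max_attempts:
            raise PackingInfeasibleError(
                f"placed only {len(centers)}/{params.n_cells} nuclei after "
                f"{params.max_attempts} attempts",
                achieved=len(centers),
            )
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        r = rng.uniform(lo, hi)
        ok = True
        for (oy, ox), orad in zip(centers, radii):
            min_dist_um = r + orad + params.min_spacing_um
            d_um = math.hypot(cy - oy, cx - ox) * px
            if d_um < min_dist_um:
                ok = False
                break
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return np.array(centers, dtype=float), np.array(radii, dtype=float)


def _render(
    rng: np.random.Generator,
    params: SimulationParams,
    centers: np.ndarray,
    radii_um: np.ndarray,
    positive_sets: list[frozenset[int]],
) -> tuple[CalibratedImage, GroundTruth]:
    h, w = params.shape
    px = params.pixel_size_um
    n = len(radii_um)
    n_channels = 1 + len(params.markers)

    # per-cell ellipse geometry (drawn regardless of later use, to keep the
    # random stream layout stable)
    stretch = rng.uniform(-params.eccentricity, params.eccentricity, size=n)
    rotation = rng.uniform(0.0, math.pi, size=n)

    label_arr = np.zeros((h, w), dtype=np.int32)
    channels = np.zeros((n_channels, h, w), dtype=float)
    shell_members: list[tuple[int, np.ndarray, np.ndarray]] = []
    for i in range(n):
        cy, cx = centers[i]
        r_px = radii_um[i] / px
        ry = r_px * (1.0 + stretch[i])
        rx = r_px * r_px / ry  # area-preserving stretch
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rotation[i])
        # earlier cells win contested pixels, keeping labels disjoint
        free = label_arr[rr, cc] == 0
        rr, cc = rr[free], cc[free]
        label_arr[rr, cc] = i + 1
        shell_r = (radii_um[i] + params.shell_thickness_um) / px
        sry = shell_r * (1.0 + stretch[i])
        srx = shell_r * shell_r / sry
        srr, scc = ellipse(cy, cx, sry, srx, shape=(h, w), rotation=rotation[i])
        inner = np.zeros((h, w), dtype=bool)
        inner_rr, inner_cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rotation[i])
        inner[inner_rr, inner_cc] = True
        keep = ~inner[srr, scc]
        shell_members.append((i, srr[keep], scc[keep]))
        channels[0][label_arr == (i + 1)] = params.nuclear_intensity

    # shell intensities: one draw per (cell, marker), clipped at zero
    for m, spec in enumerate(params.markers, start=1):
        for i, srr, scc in shell_members:
            if m in positive_sets[i]:
                value = rng.normal(spec.positive_mean, spec.positive_sd) if spec.positive_sd else spec.positive_mean
            else:
                value = rng.normal(spec.negative_mean, spec.negative_sd) if spec.negative_sd else spec.negative_mean
            value = max(0.0, float(value))
            # overlapping shells keep the brighter signal
            np.maximum.at(channels[m], (srr, scc), value)

    channels += params.background
    if params.noise_sd > 0:
        channels = channels + rng.normal(0.0, params.noise_sd, size=channels.shape)
        channels = np.clip(channels, 0.0, None)

    image = CalibratedImage(
        pixels=channels[np.newaxis],
        pixel_size_um=px,
        channel_names=["nuclei"] + [f"marker{m}" for m in range(1, n_channels)],
        nuclear_channel_index=0,
    )
    truth = GroundTruth(
        centers=centers,
        radii_um=radii_um,
        positive_sets=positive_sets,
        label_map=LabelMap.from_array(label_arr, px),
    )
    return image, truth


def simulate_image(params: SimulationParams) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic field; same seed, same arrays, bit for bit."""
    rng = np.random.default_rng(params.seed)
    centers, radii_um = _place_centers(rng, params)
    n = len(radii_um)
    positive_sets: list[set[int]] = [set() for _ in range(n)]
    for m, spec in enumerate(params.markers, start=1):
        draws = rng.random(n) < spec.positive_fraction
        for i in np.nonzero(draws)[0]:
            positive_sets[int(i)].add(m)
    return _render(rng, params, centers, radii_um, [frozenset(s) for s in positive_sets])


def adjacency_scenario(
    params: SimulationParams, pair_gap_um: float | None = None
) -> tuple[CalibratedImage, GroundTruth]:
    """Pairs of adjacent cells, one per marker, probing footprint overlap.

    Requires exactly two markers. Each pair holds an A-only cell (marker
    channel 1) and a B-only cell (marker channel 2) at a controlled
    center-to-center distance ``2*radius + pair_gap_um`` (default: the
    params' min_spacing_um), so that independent-mode expansion can
    straddle the neighbor's shell while pairs stay far from each other.
    """
    if len(params.markers) != 2:
        raise ConfigurationError("adjacency_scenario requires exactly two markers")
    if params.n_cells % 2:
        raise ConfigurationError("adjacency_scenario requires an even n_cells")
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    px = params.pixel_size_um
    lo, hi = params.nucleus_radius_um
    r_um = 0.5 * (lo + hi)
    gap_um = params.min_spacing_um if pair_gap_um is None else pair_gap_um
    pair_dist_px = (2 * r_um + gap_um) / px
    n_pairs = params.n_cells // 2
    # pair bounding radius incl. shells and a safety margin so pairs never
    # interact with each other
    clearance_px = (2 * (r_um + params.shell_thickness_um) + 4.0) / px + pair_dist_px
    cols = max(1, int(w // clearance_px))
    rows_needed = math.ceil(n_pairs / cols)
    if rows_needed * clearance_px > h:
        raise PackingInfeasibleError(
            f"cannot place {n_pairs} pairs in a {h}x{w} field", achieved=0
        )
    centers = []
    radii = []
    positive_sets: list[frozenset[int]] = []
    for p in range(n_pairs):
        gy = (p // cols + 0.5) * clearance_px
        gx = (p % cols + 0.5) * clearance_px
        theta = rng.uniform(0.0, math.pi)
        dy = 0.5 * pair_dist_px * math.sin(theta)
        dx = 0.5 * pair_dist_px * math.cos(theta)
        centers.append((gy - dy, gx - dx))
        centers.append((gy + dy, gx + dx))
        radii.extend([r_um, r_um])
        positive_sets.append(frozenset({1}))
        positive_sets.append(frozenset({2}))
    round_params = replace(params, eccentricity=0.0)
    return _render(
        rng,
        round_params,
        np.array(centers, dtype=float),
        np.array(radii, dtype=float),
        positive_sets,
    )
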