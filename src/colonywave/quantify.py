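"""Quantification recipes for micropatterned colony data.

Implements the two radial-profile recipes used throughout the study
(DAPI-normalized nuclear intensities and non-membrane signal intensities),
half-maximum wave-front tracking with a linear front fit, cell-track
displacement statistics, and the neighbor similarity index.

All profiles are functions of *edge distance* (um from the colony boundary),
averaged in bins, first within each colony and then across colonies
(mean +/- SEM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .geometry import ColonyMask, EdgeDistanceField, bin_by_edge_distance, edge_distance


@dataclass
class RadialProfile:
    """Mean intensity vs distance from the colony edge."""

    bin_edges: np.ndarray  # um, length n_bins + 1
    mean_intensity: np.ndarray  # per bin; NaN where a bin has no pixels
    sem: np.ndarray
    n_colonies: int = 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_um": self.bin_centers,
                "mean": self.mean_intensity,
                "sem": self.sem,
                "n_colonies": self.n_colonies,
            }
        )


@dataclass
class ProfileSeries:
    """Time series of radial profiles (times in hours, strictly increasing)."""

    times: np.ndarray
    profiles: list[RadialProfile]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.profiles):
            raise ValueError("times and profiles must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def intensity_matrix(self) -> np.ndarray:
        """(time, bin) matrix of mean intensities (kymograph)."""
        return np.vstack([p.mean_intensity for p in self.profiles])


@dataclass
class WaveTrack:
    """Half-maximum front/back positions of the active signaling domain.

    ``front`` is the inner edge (largest edge distance) and ``back`` the outer
    edge of the contiguous above-threshold region; positions are NaN at times
    where no bin exceeds the threshold. The linear fit is ordinary least
    squares of front position against time over the advancing phase.
    """

    threshold: float
    times: np.ndarray
    front_position: np.ndarray  # um from edge
    back_position: np.ndarray
    slope: float = np.nan  # um / h
    intercept: float = np.nan  # um
    r_squared: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "front_um": self.front_position,
                "back_um": self.back_position,
            }
        )


class QuantifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Radial profile recipes


def _disc_kernel(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= radius_px**2).astype(float)


def _local_mean_over(
    image: np.ndarray, where: np.ndarray, radius_px: float
) -> np.ndarray:
    """Mean of ``image`` over ``where`` pixels within a disc of given radius,
    evaluated at every lattice position (NaN where the disc holds no pixels)."""
    kernel = _disc_kernel(radius_px)
    w = where.astype(float)
    num = ndimage.convolve(image * w, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(w, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _bin_profile(
    values: np.ndarray,
    keep: np.ndarray,
    mask: ColonyMask,
    bin_width: float,
    dist: EdgeDistanceField | None = None,
) -> RadialProfile:
    """Bin per-pixel values over ``keep`` pixels by edge distance."""
    if dist is None:
        dist = edge_distance(mask)
    bin_edges, idx = bin_by_edge_distance(dist, mask, bin_width)
    n_bins = len(bin_edges) - 1
    means = np.full(n_bins, np.nan)
    sems = np.zeros(n_bins)
    valid = keep & mask.grid & np.isfinite(values)
    flat_idx = idx[valid]
    flat_val = values[valid]
    for b in range(n_bins):
        sel = flat_val[flat_idx == b]
        if sel.size:
            means[b] = sel.mean()
            sems[b] = sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else 0.0
    return RadialProfile(bin_edges=bin_edges, mean_intensity=means, sem=sems)


def nuclear_radial_profile(
    marker_image: np.ndarray,
    dapi_image: np.ndarray,
    nuclear_mask: np.ndarray,
    colony_mask: ColonyMask,
    local_radius: float = 120.0,
    bin_width: float = 10.0,
) -> RadialProfile:
    """DAPI-normalized nuclear radial profile (single colony).

    Recipe: (1) extract nuclear pixels of the marker channel; (2) for each
    nuclear pixel, average the marker over nuclear pixels within a disc of
    ``local_radius`` um; (3) same for DAPI; (4) divide the two local averages;
    (5) bin the ratio by edge distance; (6) average within bins. Bins with no
    pixels are reported as NaN, never as zero. Cross-colony averaging is done
    by :func:`average_profiles`.
    """
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    if marker_image.shape != dapi_image.shape or marker_image.shape != colony_mask.shape:
        raise QuantifyError("images and masks must share the lattice")
    if not nuclear_mask.any():
        raise QuantifyError("empty nuclear mask")
    radius_px = local_radius / colony_mask.pixel_size
    marker_local = _local_mean_over(marker_image, nuclear_mask, radius_px)
    dapi_local = _local_mean_over(dapi_image, nuclear_mask, radius_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = marker_local / dapi_local
    ratio[dapi_local == 0] = np.nan
    return _bin_profile(ratio, nuclear_mask, colony_mask, bin_width)


def nonmembrane_profile(
    signal_image: np.ndarray,
    membrane_mask: np.ndarray,
    colony_mask: ColonyMask,
    bin_width: float = 10.0,
) -> RadialProfile:
    """Radial profile of a signal over non-membrane colony pixels.

    The membrane mask is subtracted from the colony mask and the profile is
    computed over the remaining pixels only (the non-membrane beta-catenin
    readout of WNT signaling activity).
    """
    membrane_mask = np.asarray(membrane_mask, dtype=bool)
    if signal_image.shape != colony_mask.shape:
        raise QuantifyError("image and mask must share the lattice")
    nonmembrane = colony_mask.grid & ~membrane_mask
    if not nonmembrane.any():
        raise QuantifyError("membrane mask covers the entire colony")
    return _bin_profile(
        np.asarray(signal_image, dtype=float), nonmembrane, colony_mask, bin_width
    )


def average_profiles(profiles: list[RadialProfile]) -> RadialProfile:
    """Cross-colony average: mean of per-colony bin means, +/- SEM."""
    if not profiles:
        raise QuantifyError("no profiles to average")
    n_bins = max(len(p.mean_intensity) for p in profiles)
    ref = max(profiles, key=lambda p: len(p.mean_intensity))
    stack = np.full((len(profiles), n_bins), np.nan)
    for i, p in enumerate(profiles):
        stack[i, : len(p.mean_intensity)] = p.mean_intensity
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        n = np.sum(np.isfinite(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    return RadialProfile(
        bin_edges=ref.bin_edges,
        mean_intensity=mean,
        sem=sem,
        n_colonies=len(profiles),
    )


# ---------------------------------------------------------------------------
# Wave-front tracking


def _active_run(row: np.ndarray, threshold: float) -> tuple[int, int] | None:
    """Contiguous above-threshold bin run containing the global maximum of the
    row; None when no finite bin exceeds the threshold."""
    finite = np.isfinite(row)
    above = finite & (row > threshold)
    if not above.any():
        return None
    peak = int(np.nanargmax(np.where(finite, row, -np.inf)))
    if not above[peak]:
        peak = int(np.argmax(above))  # fall back to first active bin
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(row) - 1 and above[hi + 1]:
        hi += 1
    return lo, hi


def track_wave(
    series: ProfileSeries, fit: bool = True, threshold: float | None = None
) -> WaveTrack:
    """Track the active signaling domain through a profile time series.

    The threshold is half of the spatiotemporal maximum of the binned mean
    intensity; a fixed ``threshold`` can be supplied instead, e.g. to compare
    the spatial extent of signaling across perturbed conditions under a
    common definition. At each time, the active region is the contiguous run of
    above-threshold bins containing the global maximum of that profile; its
    outer edge (smallest edge distance) is the back and its inner edge
    (largest) the front. The linear fit covers the advancing phase: from the
    first time the front detaches from its initial position until it stops
    advancing (reaches its maximum) or imaging ends.
    """
    if len(series.times) < 3:
        raise QuantifyError("wave tracking requires >= 3 time points")
    M = series.intensity_matrix()
    if not np.isfinite(M).any():
        raise QuantifyError("profile series has no finite values")
    if threshold is None:
        threshold = 0.5 * float(np.nanmax(M))
    nt = len(series.times)
    front = np.full(nt, np.nan)
    back = np.full(nt, np.nan)
    for i in range(nt):
        run = _active_run(M[i], threshold)
        if run is None:
            continue
        lo, hi = run
        edges = series.profiles[i].bin_edges
        back[i] = edges[lo]  # outer boundary of the outermost active bin
        front[i] = edges[hi + 1]  # inner boundary of the innermost active bin
    track = WaveTrack(
        threshold=threshold,
        times=series.times.copy(),
        front_position=front,
        back_position=back,
    )
    if fit:
        _fit_front(track)
    return track


def _fit_front(track: WaveTrack) -> None:
    """OLS fit of front position vs time over the advancing phase.

    The advancing phase is the maximal inward stretch of the front trace:
    from the (last) minimum of the front position that precedes its maximal
    inward extent, through the time that maximum is attained. For a monotone
    front this is the whole trace.
    """
    t, y = track.times, track.front_position
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return
    idx = np.nonzero(ok)[0]
    y_ok = y[idx]
    stop = int(np.argmax(y_ok))
    start = int(np.nonzero(y_ok[: stop + 1] == y_ok[: stop + 1].min())[0][-1])
    if stop <= start:
        sel = idx
    else:
        sel = idx[start : stop + 1]
    if len(sel) < 2:
        return
    tt, yy = t[sel], y[sel]
    if np.allclose(yy, yy[0]):
        track.slope, track.intercept, track.r_squared = 0.0, float(yy[0]), 0.0
        return
    res = stats.linregress(tt, yy)
    track.slope = float(res.slope)
    track.intercept = float(res.intercept)
    track.r_squared = float(res.rvalue**2)


# ---------------------------------------------------------------------------
# Cell-track statistics


@dataclass
class TrackStats:
    per_cell: pd.DataFrame  # track_id, displacement, radial, arc, progeny
    n_excluded: int
    excluded_ids: list = field(default_factory=list)

    @property
    def mean_radial_displacement(self) -> float:
        return float(self.per_cell["radial_displacement_um"].mean())


def track_stats(
    tracks: pd.DataFrame,
    colony_center: tuple[float, float],
    pixel_size: float = 1.0,
) -> TrackStats:
    """Displacement statistics for labeled cell tracks.

    ``tracks`` columns: track_id, t, x, y and optionally parent_id (for
    progeny counting). Coordinates are multiplied by ``pixel_size`` to give
    um. Per root cell: total displacement |end - start|, signed radial
    displacement r_end - r_start (negative = inward), and arc displacement
    |dtheta| * mean radius. Tracks with a single time point are excluded and
    counted. Progeny coding: 0 = no division observed, 2 = one division,
    3 = one daughter divides, 4 = both daughters divide.
    """
    cx, cy = colony_center
    rows = []
    excluded = []
    has_parent = "parent_id" in tracks.columns
    children: dict = {}
    if has_parent:
        for tid, grp in tracks.groupby("track_id"):
            pid = grp["parent_id"].iloc[0]
            if pd.notna(pid) and pid >= 0:
                children.setdefault(int(pid), []).append(int(tid))

    roots = (
        tracks[tracks["parent_id"].isna() | (tracks["parent_id"] < 0)]["track_id"].unique()
        if has_parent
        else tracks["track_id"].unique()
    )
    by_id = {int(tid): grp.sort_values("t") for tid, grp in tracks.groupby("track_id")}

    for tid in roots:
        tid = int(tid)
        grp = by_id[tid]
        if len(grp) < 2 and tid not in children:
            excluded.append(tid)
            continue
        x0, y0 = grp[["x", "y"]].iloc[0] * pixel_size
        x1, y1 = grp[["x", "y"]].iloc[-1] * pixel_size
        r0 = np.hypot(x0 - cx * pixel_size, y0 - cy * pixel_size)
        r1 = np.hypot(x1 - cx * pixel_size, y1 - cy * pixel_size)
        th0 = np.arctan2(y0 - cy * pixel_size, x0 - cx * pixel_size)
        th1 = np.arctan2(y1 - cy * pixel_size, x1 - cx * pixel_size)
        dth = np.angle(np.exp(1j * (th1 - th0)))
        progeny = _progeny_count(tid, children)
        rows.append(
            {
                "track_id": tid,
                "displacement_um": float(np.hypot(x1 - x0, y1 - y0)),
                "radial_displacement_um": float(r1 - r0),
                "arc_displacement_um": float(abs(dth) * 0.5 * (r0 + r1)),
                "start_radius_um": float(r0),
                "progeny": progeny,
            }
        )
    per_cell = pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "displacement_um",
            "radial_displacement_um",
            "arc_displacement_um",
            "start_radius_um",
            "progeny",
        ],
    )
    return TrackStats(per_cell=per_cell, n_excluded=len(excluded), excluded_ids=excluded)


def _progeny_count(tid: int, children: dict) -> int:
    kids = children.get(tid, [])
    if not kids:
        return 0
    granddivisions = sum(1 for k in kids if children.get(k))
    return 2 + granddivisions  # 2: one division; 3/4: daughters divide


# ---------------------------------------------------------------------------
# Similarity index


def similarity_index(
    positions: np.ndarray,
    labels: np.ndarray,
    neighbor_radius: float = 62.0,
    frac: float = 0.6,
) -> float:
    """Fraction of cells with > ``frac`` same-label neighbors.

    A neighbor is any other cell within ``neighbor_radius`` um. Cells with no
    neighbor are excluded from the counting fraction; if every cell is
    isolated the index is undefined and NaN is returned.
    """
    positions = np.asarray(positions, dtype=float)
    labels = np.asarray(labels)
    if len(positions) < 2:
        raise QuantifyError("similarity index requires >= 2 cells")
    tree = cKDTree(positions)
    pairs = tree.query_ball_tree(tree, neighbor_radius)
    n_with_neighbors = 0
    n_similar = 0
    for i, neigh in enumerate(pairs):
        neigh = [j for j in neigh if j != i]
        if not neigh:
            continue
        n_with_neighbors += 1
        same = sum(1 for j in neigh if labels[j] == labels[i])
        if same / len(neigh) > frac:
            n_similar += 1
    if n_with_neighbors == 0:
        return float("nan")
    return n_similar / n_with_neighbors
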