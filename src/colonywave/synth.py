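"""Synthetic fixtures with known ground truth.

Every consumer module in the package is testable against these generators:
an inward-moving signaling wave in radial-profile coordinates, multi-channel
colony images (nuclear counterstain, membrane-localized signal, fate
markers), labeled cell tracks with drift and divisions, and an FPKM-style
gene x sample expression matrix with planted differential-expression
structure. Each generator is deterministic given its seed and returns its
ground truth alongside the data.

The defaults emulate the study conditions: 700 um colonies imaged at
14 um/pixel, a WNT signaling wave advancing at 6.02 um/h from 13.57 um
inside the edge, four bulk RNA-seq conditions (pluripotent medium and three
BMP treatments) with two replicates, and planted up-/down-regulated gene
sets whose triple overlaps are 77 and 54 genes and whose top-100 union
totals 284 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ColonyMask, edge_distance
from .quantify import ProfileSeries, RadialProfile

# Per-component seed offsets: one top-level seed fans out to independent
# streams via fixed counters.
_STREAM = {"wave": 1, "images": 2, "tracks": 3, "expression": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream]])


# ---------------------------------------------------------------------------
# Wave profile series


@dataclass(frozen=True)
class WaveSpec:
    """An inward-moving signaling wave in edge-distance coordinates.

    The mean intensity at edge distance d and time t is a plateau between a
    stationary outer (back) position and an advancing inner front
    p(t) = start_position + speed * t, with smooth logistic shoulders of
    width ``rise_width``. Time is measured from treatment; profiles are
    sampled from ``start_time`` (the front's linear trajectory extrapolates
    to ``start_position`` at t = 0, mirroring the experimental fit).
    """

    speed: float = 6.02  # um / h
    start_time: float = 24.0  # h, first sampled time point
    start_position: float = 13.57  # um from edge, front position at t = 0
    back_position: float = 10.0  # um, stationary outer edge of the domain
    amplitude: float = 1.0
    baseline: float = 0.05
    rise_width: float = 4.0  # um, logistic shoulder width
    noise_sd: float = 0.0
    seed: int = 0


def wave_intensity(spec: WaveSpec, d: np.ndarray, t: float) -> np.ndarray:
    """Noise-free mean intensity at edge distances ``d`` and time ``t``."""
    p = spec.start_position + spec.speed * t
    w = spec.rise_width
    plateau = 1.0 / (1.0 + np.exp(-(d - spec.back_position) / w))
    plateau *= 1.0 / (1.0 + np.exp((d - p) / w))
    return spec.baseline + spec.amplitude * plateau


def gen_wave_series(
    spec: WaveSpec,
    mask: ColonyMask,
    times: np.ndarray | None = None,
    bin_width: float = 10.0,
) -> tuple[ProfileSeries, pd.DataFrame]:
    """Profile series containing the planted wave, plus the ground truth.

    Returns ``(series, truth)`` where ``truth`` has columns ``time_h`` and
    ``front_um`` (the planted half-maximum front position at each time).
    """
    if times is None:
        times = np.arange(spec.start_time, 45.0, 1.0)
    times = np.asarray(times, dtype=float)
    dist = edge_distance(mask)
    max_d = dist.max_distance
    n_bins = max(1, int(np.ceil(max_d / bin_width)))
    bin_edges = np.arange(n_bins + 1, dtype=float) * bin_width
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    rng = _rng(spec.seed, "wave")
    profiles = []
    truth_rows = []
    for t in times:
        mean = wave_intensity(spec, centers, t)
        if spec.noise_sd > 0:
            mean = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
        profiles.append(
            RadialProfile(
                bin_edges=bin_edges,
                mean_intensity=mean,
                sem=np.full(n_bins, spec.noise_sd),
            )
        )
        truth_rows.append(
            {"time_h": t, "front_um": spec.start_position + spec.speed * t}
        )
    return ProfileSeries(times=times, profiles=profiles), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Colony images


@dataclass(frozen=True)
class ChannelRecipe:
    """Radial mean function for one marker channel.

    ``radial_mean`` maps edge distance (um) to the noise-free intensity of
    nuclear pixels in this channel; background pixels are 0 before noise.
    """

    name: str
    radial_mean: object  # callable d_um -> intensity


@dataclass(frozen=True)
class ColonyImageSpec:
    channels: tuple[ChannelRecipe, ...]
    nuclear_density: float = 0.03  # nuclei per px^2 of colony (confluent)
    nuclear_radius: float = 2.0  # px
    dapi_level: float = 100.0
    membrane_width: int = 1  # px, outline drawn around each nucleus
    noise_sd: float = 0.0  # additive Gaussian, intensity units
    seed: int = 0


@dataclass
class ColonyImages:
    channels: dict  # name -> image
    dapi: np.ndarray
    membrane_signal: np.ndarray
    nuclear_mask: np.ndarray
    membrane_mask: np.ndarray
    true_radial_means: dict  # name -> callable


def gen_colony_images(spec: ColonyImageSpec, mask: ColonyMask) -> ColonyImages:
    """Multi-channel synthetic colony image with exact masks.

    Nuclei are non-overlapping discs scattered uniformly inside the colony;
    the DAPI channel is uniform over nuclear pixels; each marker channel
    evaluates its radial mean at the pixel's edge distance over nuclear
    pixels; the membrane channel paints a bright one-pixel ring around every
    nucleus on top of a radially varying cytoplasmic signal. Gaussian noise
    is added to every channel when ``noise_sd > 0``.
    """
    rng = _rng(spec.seed, "images")
    H, W = mask.shape
    dist = edge_distance(mask)
    n_nuclei = int(spec.nuclear_density * mask.area_px)
    fg = np.argwhere(mask.grid)
    centers = fg[rng.choice(len(fg), size=min(n_nuclei, len(fg)), replace=False)]

    yy, xx = np.mgrid[0:H, 0:W]
    nuclear = np.zeros((H, W), dtype=bool)
    r2 = spec.nuclear_radius**2
    for cy, cx in centers:
        sl = np.s_[
            max(0, cy - 4) : cy + 5,
            max(0, cx - 4) : cx + 5,
        ]
        nuclear[sl] |= (yy[sl] - cy) ** 2 + (xx[sl] - cx) ** 2 <= r2
    nuclear &= mask.grid

    from scipy import ndimage

    dil = ndimage.binary_dilation(nuclear, iterations=spec.membrane_width)
    membrane = (dil & ~nuclear) & mask.grid

    def noisy(img: np.ndarray) -> np.ndarray:
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        return img

    dapi = noisy(np.where(nuclear, spec.dapi_level, 0.0))
    channels = {}
    true_means = {}
    for ch in spec.channels:
        img = np.where(nuclear, ch.radial_mean(dist.values), 0.0)
        channels[ch.name] = noisy(img)
        true_means[ch.name] = ch.radial_mean
    # membrane-localized signal (beta-catenin-like): cytoplasmic level set by
    # the first channel recipe when present, bright on membrane pixels
    base = (
        spec.channels[0].radial_mean(dist.values)
        if spec.channels
        else np.ones((H, W))
    )
    membrane_signal = noisy(
        np.where(membrane, 10.0 * np.asarray(base, dtype=float), np.where(mask.grid, base, 0.0))
    )
    return ColonyImages(
        channels=channels,
        dapi=dapi,
        membrane_signal=membrane_signal,
        nuclear_mask=nuclear,
        membrane_mask=membrane,
        true_radial_means=true_means,
    )


# ---------------------------------------------------------------------------
# Cell tracks


def gen_tracks(
    n_cells: int,
    mask: ColonyMask,
    drift_um: float = 0.0,
    division_prob: float = 0.0,
    jitter_um: float = 0.0,
    n_timepoints: int = 20,
    t_step_h: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Labeled cell tracks with a radial drift and optional divisions.

    Each root cell moves radially by ``drift_um`` in total over the movie
    (negative = inward) with isotropic Gaussian jitter per frame. A dividing
    cell (probability ``division_prob``, decided per root) splits at the
    movie midpoint into two daughters that may themselves divide with the
    same probability. Coordinates are in um relative to the colony center
    stored in the truth table.

    Returns ``(tracks, truth)``: tracks with columns
    (track_id, t, x, y, label, parent_id); truth with per-root
    planted radial displacement and progeny code.
    """
    rng = _rng(seed, "tracks")
    cy, cx = mask.centroid()
    px = mask.pixel_size
    fg = np.argwhere(mask.grid)
    picks = fg[rng.choice(len(fg), size=n_cells, replace=True)]
    times = np.arange(n_timepoints) * t_step_h

    rows = []
    truth = []
    next_id = 0

    def emit(track_id, parent_id, pos0, vel, t_idx0, t_idx1, label):
        for i in range(t_idx0, t_idx1):
            frac_step = times[i] - times[t_idx0]
            x = pos0[0] + vel[0] * frac_step + (
                rng.normal(0, jitter_um) if jitter_um > 0 else 0.0
            )
            y = pos0[1] + vel[1] * frac_step + (
                rng.normal(0, jitter_um) if jitter_um > 0 else 0.0
            )
            rows.append(
                {
                    "track_id": track_id,
                    "t": times[i],
                    "x": x,
                    "y": y,
                    "label": label,
                    "parent_id": parent_id,
                }
            )

    total_time = times[-1] - times[0] if n_timepoints > 1 else 1.0
    mid = n_timepoints // 2
    for (py_, px_) in picks:
        x0 = (px_ - cx) * px
        y0 = (py_ - cy) * px
        r0 = max(np.hypot(x0, y0), 1e-9)
        ux, uy = x0 / r0, y0 / r0
        vel = (ux * drift_um / total_time, uy * drift_um / total_time)
        root = next_id
        next_id += 1
        divides = rng.random() < division_prob and n_timepoints >= 4
        if not divides:
            emit(root, -1, (x0, y0), vel, 0, n_timepoints, label=0)
            truth.append(
                {"track_id": root, "radial_displacement_um": drift_um, "progeny": 0}
            )
            continue
        emit(root, -1, (x0, y0), vel, 0, mid, label=0)
        x_mid = x0 + vel[0] * (times[mid - 1] - times[0])
        y_mid = y0 + vel[1] * (times[mid - 1] - times[0])
        progeny = 2
        for d in range(2):
            did = next_id
            next_id += 1
            off = 2.0 * (1 if d == 0 else -1)
            daughter_divides = rng.random() < division_prob and n_timepoints - mid >= 4
            if daughter_divides:
                progeny += 1
            emit(did, root, (x_mid + off, y_mid), vel, mid, n_timepoints, label=0)
            if daughter_divides:
                # grand-daughters appear in the last quarter of the movie
                q = (mid + n_timepoints) // 2
                for g in range(2):
                    gid = next_id
                    next_id += 1
                    emit(
                        gid,
                        did,
                        (x_mid + off + g, y_mid + 1.0),
                        vel,
                        q,
                        n_timepoints,
                        label=0,
                    )
        truth.append(
            {"track_id": root, "radial_displacement_um": drift_um, "progeny": progeny}
        )
    tracks = pd.DataFrame(rows)
    return tracks, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass(frozen=True)
class ExpressionSpec:
    """Planted differential-expression structure for four conditions.

    Three treatment conditions are compared to the reference (pluripotent)
    condition. Per treatment, ``n_planted`` genes are up-regulated and
    ``n_planted`` down-regulated by ``effect_fold``; the planted sets share a
    common core of ``triple_up``/``triple_down`` genes across all three
    treatments and ``pair_extra`` genes per condition pair (both directions),
    with the remainder private to each condition. With the defaults, the
    union of the per-condition top-100 up and top-100 down lists is exactly
    284 genes, with triple overlaps of 77 (up) and 54 (down).
    """

    n_genes: int = 8000
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("mTeSR", "BMP", "BMP_SB", "BMP_IWP2")
    n_planted: int = 100
    triple_up: int = 77
    triple_down: int = 54
    pair_extra_up: int = 9
    pair_extra_down: int = 9
    effect_fold: float = 8.0
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.2  # multiplicative log-normal (natural-log sd)
    seed: int = 0


@dataclass
class ExpressionTruth:
    up_sets: dict  # condition -> set of gene ids
    down_sets: dict
    union_size: int
    triple_up: int
    triple_down: int


def _planted_sets(spec: ExpressionSpec, genes: list) -> tuple[dict, dict]:
    """Deterministic allocation of planted up/down sets with the requested
    overlap structure. Gene ids are consumed from the front of ``genes``."""
    conds = [c for c in spec.conditions[1:]]
    cursor = 0

    def take(n):
        nonlocal cursor
        out = genes[cursor : cursor + n]
        cursor += n
        return out

    sets = {}
    for direction, triple, pair_extra in (
        ("up", spec.triple_up, spec.pair_extra_up),
        ("down", spec.triple_down, spec.pair_extra_down),
    ):
        core = take(triple)
        pair_sets = {}
        for i in range(3):
            for j in range(i + 1, 3):
                pair_sets[(i, j)] = take(pair_extra)
        per_cond = {}
        for i, c in enumerate(conds):
            members = list(core)
            for key, extra in pair_sets.items():
                if i in key:
                    members += extra
            n_private = spec.n_planted - len(members)
            if n_private < 0:
                raise ValueError("overlap structure exceeds n_planted")
            members += take(n_private)
            per_cond[c] = set(members)
        sets[direction] = per_cond
    return sets["up"], sets["down"]


def gen_expression(spec: ExpressionSpec) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """FPKM-style matrix with planted DE structure.

    Returns ``(expr, de_flags, truth)``: ``expr`` is genes x samples with
    columns ``{condition}_{replicate}``; ``de_flags`` is a truth table of
    per-gene, per-treatment significance (the pluggable external test) with
    columns condition, gene, significant; ``truth`` carries the planted sets
    and their overlap counts.
    """
    rng = _rng(spec.seed, "expression")
    genes = [f"G{idx:05d}" for idx in range(spec.n_genes)]
    up_sets, down_sets = _planted_sets(spec, genes)

    base = 2.0 ** rng.normal(
        spec.baseline_log2_mean, spec.baseline_log2_sd, size=spec.n_genes
    )
    base = np.maximum(base, 0.05)
    # planted DE genes sit on adequately expressed baselines (>= 8 FPKM), as
    # top-ranked differentially expressed genes do in real data; this keeps
    # the abundance filter from silently dropping planted structure
    planted_idx = [
        i for i, g in enumerate(genes)
        if any(g in up_sets[c] or g in down_sets[c] for c in spec.conditions[1:])
    ]
    base[planted_idx] = np.maximum(base[planted_idx], 8.0)
    cols = {}
    log_fc = np.zeros((spec.n_genes, len(spec.conditions)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for ci, cond in enumerate(spec.conditions):
        fold = np.ones(spec.n_genes)
        if cond != spec.conditions[0]:
            for g in up_sets[cond]:
                fold[gene_index[g]] = spec.effect_fold
            for g in down_sets[cond]:
                fold[gene_index[g]] = 1.0 / spec.effect_fold
        log_fc[:, ci] = np.log2(fold)
        for rep in range(spec.n_replicates):
            noise = np.exp(rng.normal(0.0, spec.noise_sd, size=spec.n_genes))
            cols[f"{cond}_{rep + 1}"] = base * fold * noise
    expr = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    flag_rows = []
    for cond in spec.conditions[1:]:
        planted = up_sets[cond] | down_sets[cond]
        for g in genes:
            if g in planted:
                flag_rows.append({"condition": cond, "gene": g, "significant": True})
    de_flags = pd.DataFrame(flag_rows)

    all_planted = set()
    for cond in spec.conditions[1:]:
        all_planted |= up_sets[cond] | down_sets[cond]
    triple_up = set.intersection(*up_sets.values())
    triple_down = set.intersection(*down_sets.values())
    truth = ExpressionTruth(
        up_sets=up_sets,
        down_sets=down_sets,
        union_size=len(all_planted),
        triple_up=len(triple_up),
        triple_down=len(triple_down),
    )
    return expr, de_flags, truth
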