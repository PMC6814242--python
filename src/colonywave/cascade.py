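"""Three-component signaling cascade: imposed BMP drives WNT drives NODAL.

The model simulates the time evolution of WNT signaling activity u and NODAL
signaling activity v on a colony mask, driven by an imposed BMP input b(x, t):

    du/dt = D_u lap(u) + [beta_u + alpha_b b(x,t) + alpha_u u^2/(K_u^2+u^2)]
            - gamma_u u
    dv/dt = D_v lap(v) + [beta_v e(x) + alpha_w u
            + alpha_v H(v - v_th) v^2/(K_v^2+v^2)] - gamma_v v

with all production terms (square brackets) confined to the colony, and
diffusion plus degradation everywhere on the periodic lattice. Space is in
um, time in hours. The BMP input is active throughout the colony until
``t_restrict`` and restricted to an exponential edge profile afterwards,
mirroring the measured BMP signaling dynamics. WNT has basal production plus
BMP-driven production plus saturable autoactivation. NODAL is driven by WNT
and by a small edge-localized basal term (TGF-beta in the medium acting at
the colony edge); its autoactivation switches on only above the threshold
``v_th``, which makes the NODAL wave self-propagating once initiated — the
binary early/late response to WNT blockade follows from this threshold.

Chemical perturbations are instantaneous parameter switches at a stated
hour: BMP-inhibitor (LDN) addition sets the BMP->WNT coupling alpha_b to 0,
WNT-secretion inhibition (IWP2) sets WNT autoactivation alpha_u to 0, and a
full WNT block additionally sets the WNT->NODAL coupling alpha_w to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import ColonyMask, analytic_edge_distance, edge_distance, validate_mask
from .quantify import ProfileSeries, RadialProfile, WaveTrack, track_wave
from .rd import SimulationBlowup, laplacian_periodic_9pt


@dataclass(frozen=True)
class BMPInput:
    """Imposed BMP signaling field: uniform until ``t_restrict``, then
    restricted to an exponential profile of width ``edge_width`` at the
    colony edge."""

    amplitude: float = 1.0
    t_restrict: float = 12.0  # h
    edge_width: float = 140.0  # um

    def field(self, dist_um: np.ndarray, inside: np.ndarray, t: float) -> np.ndarray:
        if t < self.t_restrict:
            return np.where(inside, self.amplitude, 0.0)
        return np.where(
            inside, self.amplitude * np.exp(-dist_um / self.edge_width), 0.0
        )


@dataclass(frozen=True)
class CascadeParams:
    """Cascade model parameters (um^2/h for diffusivities, 1/h for rates)."""

    D_u: float = 60.0  # WNT effective diffusivity
    D_v: float = 800.0  # NODAL effective diffusivity
    beta_u: float = 0.001  # basal WNT production
    alpha_b: float = 0.05  # BMP -> WNT coupling
    alpha_u: float = 0.015  # WNT autoactivation strength
    K_u: float = 1.6  # WNT autoactivation half-saturation
    alpha_w: float = 0.15  # WNT -> NODAL coupling
    alpha_v: float = 0.6  # NODAL autoactivation strength
    K_v: float = 0.5  # NODAL autoactivation half-saturation
    v_th: float = 0.4  # NODAL autoactivation threshold
    beta_v: float = 0.15  # basal edge-localized NODAL production
    seed_width: float = 25.0  # um, width of the edge-localized NODAL seed
    gamma_u: float = 0.005  # WNT degradation
    gamma_v: float = 0.3  # NODAL degradation

    def __post_init__(self) -> None:
        for name in (
            "D_u", "D_v", "beta_u", "alpha_b", "alpha_u", "K_u", "alpha_w",
            "alpha_v", "K_v", "v_th", "beta_v", "seed_width",
            "gamma_u", "gamma_v",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Perturbation:
    """Switch a coupling off at a stated hour (None = never)."""

    alpha_b_off_at: float | None = None  # LDN: WNT's dependence on BMP -> 0
    alpha_u_off_at: float | None = None  # IWP2: WNT autoactivation -> 0
    alpha_w_off_at: float | None = None  # WNT->NODAL coupling -> 0

    @classmethod
    def ldn(cls, t: float) -> "Perturbation":
        return cls(alpha_b_off_at=t)

    @classmethod
    def iwp2(cls, t: float) -> "Perturbation":
        return cls(alpha_u_off_at=t)

    @classmethod
    def wnt_block(cls, t: float) -> "Perturbation":
        """Full WNT blockade: autoactivation and WNT->NODAL coupling off."""
        return cls(alpha_u_off_at=t, alpha_w_off_at=t)


@dataclass
class CascadeState:
    u: np.ndarray
    v: np.ndarray
    t: float = 0.0

    def copy(self) -> "CascadeState":
        return CascadeState(self.u.copy(), self.v.copy(), self.t)


@dataclass
class CascadeResult:
    snapshots: list[CascadeState]
    mask: ColonyMask
    params: CascadeParams
    bmp: BMPInput
    dt: float

    @property
    def final(self) -> CascadeState:
        return self.snapshots[-1]

    def profile_series(self, which: str = "u", bin_width: float = 10.0) -> ProfileSeries:
        """Radial mean profiles of u or v at every saved time."""
        from .geometry import bin_by_edge_distance

        dist = analytic_edge_distance(self.mask)
        bin_edges, idx = bin_by_edge_distance(dist, self.mask, bin_width)
        n_bins = len(bin_edges) - 1
        flat_idx = idx[self.mask.grid]
        profiles = []
        times = []
        for s in self.snapshots:
            vals = (s.u if which == "u" else s.v)[self.mask.grid]
            sums = np.bincount(flat_idx, weights=vals, minlength=n_bins)
            counts = np.bincount(flat_idx, minlength=n_bins)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = sums / counts
            mean[counts == 0] = np.nan
            profiles.append(
                RadialProfile(
                    bin_edges=bin_edges,
                    mean_intensity=mean,
                    sem=np.zeros(n_bins),
                )
            )
            times.append(s.t)
        return ProfileSeries(times=np.asarray(times), profiles=profiles)

    def wave_track(self, which: str = "u", bin_width: float = 10.0) -> WaveTrack:
        return track_wave(self.profile_series(which, bin_width))


def _switch(value: float, off_at: float | None, t: float) -> float:
    if off_at is not None and t >= off_at:
        return 0.0
    return value


def simulate_cascade(
    params: CascadeParams,
    mask: ColonyMask,
    bmp: BMPInput | None = None,
    t_end: float = 46.0,
    perturbation: Perturbation | None = None,
    save_every_h: float = 1.0,
    dt: float | None = None,
) -> CascadeResult:
    """Integrate the cascade from u = v = 0 to ``t_end`` hours.

    Deterministic (no stochastic terms). Snapshots are saved every
    ``save_every_h`` simulated hours, always including t = 0 and t = t_end.
    """
    validate_mask(mask)
    bmp = bmp or BMPInput()
    perturbation = perturbation or Perturbation()
    dx = mask.pixel_size
    dmax = max(params.D_u, params.D_v, 1e-12)
    if dt is None:
        dt = 0.8 * dx * dx / (4.0 * dmax)
    inside = mask.grid
    dist = analytic_edge_distance(mask).values
    edge_profile = np.where(inside, np.exp(-dist / params.seed_width), 0.0)
    inv_dx2 = 1.0 / (dx * dx)

    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps  # land exactly on t_end
    save_stride = max(1, int(round(save_every_h / dt)))

    H, W = mask.shape
    u = np.zeros((H, W))
    v = np.zeros((H, W))
    t = 0.0
    snapshots = [CascadeState(u.copy(), v.copy(), 0.0)]
    for step in range(1, n_steps + 1):
        a_b = _switch(params.alpha_b, perturbation.alpha_b_off_at, t)
        a_u = _switch(params.alpha_u, perturbation.alpha_u_off_at, t)
        a_w = _switch(params.alpha_w, perturbation.alpha_w_off_at, t)
        b = bmp.field(dist, inside, t)

        auto_u = a_u * u * u / (params.K_u**2 + u * u)
        prod_u = np.where(inside, params.beta_u + a_b * b + auto_u, 0.0)
        gate = v >= params.v_th
        auto_v = params.alpha_v * gate * v * v / (params.K_v**2 + v * v)
        prod_v = np.where(
            inside, params.beta_v * edge_profile + a_w * u + auto_v, 0.0
        )

        u = u + dt * (
            params.D_u * laplacian_periodic_9pt(u) * inv_dx2 + prod_u - params.gamma_u * u
        )
        v = v + dt * (
            params.D_v * laplacian_periodic_9pt(v) * inv_dx2 + prod_v - params.gamma_v * v
        )
        np.clip(u, 0.0, None, out=u)
        np.clip(v, 0.0, None, out=v)
        t = step * dt
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            raise SimulationBlowup(
                f"non-finite field at t={t:.2f} h "
                f"(max u={np.nanmax(u):.3g}, max v={np.nanmax(v):.3g})"
            )
        if step % save_stride == 0 or step == n_steps:
            snapshots.append(CascadeState(u.copy(), v.copy(), t))
    return CascadeResult(
        snapshots=snapshots, mask=mask, params=params, bmp=bmp, dt=dt
    )


def simulate_cascade_nodal_block(
    params: CascadeParams,
    mask: ColonyMask,
    bmp: BMPInput | None = None,
    t_block: float = 0.0,
    t_end: float = 46.0,
    **kw,
) -> CascadeResult:
    """Control run with a full WNT blockade (autoactivation and WNT->NODAL
    coupling off) applied at ``t_block`` hours."""
    return simulate_cascade(
        params,
        mask,
        bmp=bmp,
        t_end=t_end,
        perturbation=Perturbation.wnt_block(t_block),
        **kw,
    )


# ---------------------------------------------------------------------------
# Readouts used by the fate module and the acceptance checks


def histories(
    result: CascadeResult,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(times, b, u, v) stacks sampled at the saved snapshots; each stack has
    shape (n_times, H, W)."""
    times = np.array([s.t for s in result.snapshots])
    dist = analytic_edge_distance(result.mask).values
    inside = result.mask.grid
    b = np.stack([result.bmp.field(dist, inside, t) for t in times])
    u = np.stack([s.u for s in result.snapshots])
    v = np.stack([s.v for s in result.snapshots])
    return times, b, u, v


def center_value(result: CascadeResult, which: str = "v") -> float:
    """Field value at the pixel of maximum edge distance (the colony center)."""
    dist = analytic_edge_distance(result.mask).values
    iy, ix = np.unravel_index(np.argmax(dist), dist.shape)
    f = result.final
    return float((f.v if which == "v" else f.u)[iy, ix])


def peak_profile_position(result: CascadeResult, which: str = "u") -> float:
    """Edge distance (um) of the maximum of the final radial profile."""
    series = result.profile_series(which)
    prof = series.profiles[-1]
    i = int(np.nanargmax(prof.mean_intensity))
    return float(prof.bin_centers[i])
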