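"""Synthetic-data generators: surface-coverage arithmetic, 2D Brownian /
fractional-Brownian / crowded-disk trajectories, annihilating random
walkers (T1 + T1 -> S1 + S0) and noisy SHG-style decay traces.

These emulate the two data sources of the study design: interfacial
molecular-dynamics-like trajectories of adsorbed porphyrins (Brownian at
low surface coverage, transiently subdiffusive at full coverage) and
time-resolved SHG ground-state-recovery traces observed with ~20 ns
resolution and shot-type noise.

Geometry defaults follow the study conditions: a 15 x 15 nm periodic
interface, a maximum surface concentration of 3.6e-7 mol m^-2
(0.22 molecule nm^-2, so 24 molecules at 50% coverage), and a 1.5 nm
reaction/encounter radius.  All quantities are SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.constants import Avogadro as N_A

from .fitting import SHGTrace
from .kinetics import DEFAULT_REACTION_RADIUS, KineticTrace
from .trajectories import Trajectory2D

__all__ = [
    "GAMMA_MAX",
    "DEFAULT_BOX_L",
    "SurfaceCoverage",
    "SimulationConfig",
    "AnnihilationOutput",
    "surface_density",
    "coverage_to_count",
    "simulate_brownian",
    "simulate_fbm",
    "simulate_crowded_disks",
    "simulate_annihilation",
    "emulate_shg_trace",
    "fractional_gaussian_noise",
]

#: Maximum (full-coverage) surface concentration, mol m^-2.
GAMMA_MAX = 3.6e-7

#: Side of the square interfacial box, m (15 nm).
DEFAULT_BOX_L = 15e-9


@dataclass(frozen=True)
class SurfaceCoverage:
    """Fractional occupancy of the interface.

    phi       : coverage fraction in [0, 1] of the maximum adsorption density
    L         : box side, m
    gamma_max : maximum surface concentration, mol m^-2
    """

    phi: float
    L: float = DEFAULT_BOX_L
    gamma_max: float = GAMMA_MAX

    def __post_init__(self):
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")
        if not (self.L > 0):
            raise ValueError("L must be > 0")


def surface_density(gamma_max: float = GAMMA_MAX) -> float:
    """Molecules per nm^2 at surface concentration gamma_max (mol m^-2);
    3.6e-7 mol m^-2 corresponds to 0.22 molecule nm^-2."""
    return gamma_max * N_A * 1e-18


def coverage_to_count(cov: SurfaceCoverage, convention: str = "round") -> int:
    """Number of molecules on the L x L box at coverage phi:
    N = phi * gamma_max * N_A * L^2, rounded per ``convention``
    ("round" = nearest integer, "floor").

    On the 15 nm box the half-coverage count is 24 under either convention;
    full coverage is 48.78, i.e. 49 (round) or 48 (floor).
    """
    exact = cov.phi * cov.gamma_max * N_A * cov.L**2
    if convention == "round":
        return int(round(exact))
    if convention == "floor":
        return int(np.floor(exact))
    raise ValueError(f"unknown rounding convention {convention!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a trajectory / annihilation simulation.

    n_particles : explicit count, or None to derive from ``coverage``
    L           : box side, m
    dt          : frame step, s
    n_steps     : number of steps (frames = n_steps + 1)
    motion      : "brownian" | "fbm" | "crowded_disks"
    D           : diffusion coefficient, m^2 s^-1 (for fbm: generalised
                  coefficient, m^2 s^-2H)
    hurst       : Hurst exponent for fbm (MSD ~ t^2H)
    p0          : initially excited (triplet) fraction, in [0, 1]
    R           : reaction/encounter radius, m
    disk_diameter, repulsion : crowded-disk soft-core size (m) and strength
                  (mobility x spring constant, s^-1)
    seed        : mandatory RNG seed
    """

    seed: int
    n_particles: int | None = None
    coverage: SurfaceCoverage | None = None
    L: float = DEFAULT_BOX_L
    dt: float = 2e-11
    n_steps: int = 5000
    motion: str = "brownian"
    D: float = 2e-9
    hurst: float = 0.5
    p0: float = 1.0
    R: float = DEFAULT_REACTION_RADIUS
    disk_diameter: float = 2.0e-9
    repulsion: float = 1.0e10
    n_burnin: int = 200

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must be in [0, 1]")
        if not (self.R < self.L / 2):
            raise ValueError("R must be < L/2")
        if self.motion not in ("brownian", "fbm", "crowded_disks"):
            raise ValueError(f"unknown motion model {self.motion!r}")
        if self.motion == "fbm" and not (0.0 < self.hurst < 1.0):
            raise ValueError("hurst must be in (0, 1)")
        if self.n_particles is None and self.coverage is None:
            raise ValueError("give n_particles or coverage")

    @property
    def N(self) -> int:
        if self.n_particles is not None:
            return int(self.n_particles)
        return coverage_to_count(self.coverage)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_particles_resolved"] = self.N
        return d


@dataclass(frozen=True)
class AnnihilationOutput:
    """Result of an annihilating-walker run.

    trajectory     : positions of all particles (triplet or ground)
    triplet_counts : triplets alive at each frame (non-increasing, -2/event)
    events         : list of (time, id_a, id_b) annihilation events
    trace          : triplet surface concentration, mol m^-2 (count /
                     (N_A * box area))
    """

    trajectory: Trajectory2D
    triplet_counts: np.ndarray
    events: list
    trace: KineticTrace
    config: SimulationConfig = None


# ---------------------------------------------------------------------------
# Motion models
# ---------------------------------------------------------------------------

def _init_positions(rng, N, L):
    return rng.uniform(0.0, L, size=(N, 2))


def _check_step_scale(cfg):
    rms = np.sqrt(4.0 * cfg.D * cfg.dt) if cfg.motion != "fbm" \
        else np.sqrt(4.0 * cfg.D * cfg.dt ** (2 * cfg.hurst))
    if rms > cfg.L / 4:
        raise ValueError(
            f"RMS step {rms:.3g} m exceeds L/4; reduce dt or D"
        )
    return rms


def _wrap(p, L):
    return np.mod(p, L)


def _finalize(cfg, times, positions_unwrapped, extra_meta=None):
    meta = {"seed": cfg.seed, "motion": cfg.motion, "D": cfg.D,
            "dt": cfg.dt, "n_steps": cfg.n_steps, "L": cfg.L}
    if extra_meta:
        meta.update(extra_meta)
    wrapped = _wrap(positions_unwrapped, cfg.L)
    return Trajectory2D(times=times, positions=wrapped, box=(cfg.L, cfg.L),
                        wrapped=True, meta=meta)


def simulate_brownian(cfg: SimulationConfig) -> Trajectory2D:
    """Free 2D Brownian motion: independent Gaussian steps per axis with
    variance 2 D dt, periodic wrapping.  teMSD = 4 D t."""
    _check_step_scale(cfg)
    rng = np.random.default_rng(cfg.seed)
    N = cfg.N
    times = np.arange(cfg.n_steps + 1) * cfg.dt
    x0 = _init_positions(rng, N, cfg.L)
    if cfg.D == 0:
        pos = np.repeat(x0[:, None, :], cfg.n_steps + 1, axis=1)
        return _finalize(cfg, times, pos)
    steps = rng.normal(0.0, np.sqrt(2.0 * cfg.D * cfg.dt),
                       size=(N, cfg.n_steps, 2))
    pos = np.concatenate([x0[:, None, :],
                          x0[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    return _finalize(cfg, times, pos)


def fractional_gaussian_noise(n: int, H: float, rng,
                              size: tuple = ()) -> np.ndarray:
    """Exact unit-variance fractional Gaussian noise by Davies-Harte
    circulant embedding.

    Returns an array of shape size + (n,) of stationary Gaussian increments
    with autocovariance gamma(k) = ( |k+1|^2H - 2|k|^2H + |k-1|^2H ) / 2.
    """
    if not (0.0 < H < 1.0):
        raise ValueError("H must be in (0, 1)")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H)
                   + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])   # circulant row, length 2n
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        raise ValueError("circulant embedding not nonnegative definite")
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    shape = tuple(size) + (m,)
    U = rng.standard_normal(shape)
    V = rng.standard_normal(shape)
    a = np.empty(shape, dtype=complex)
    a[..., 0] = np.sqrt(lam[0]) * U[..., 0]
    a[..., n] = np.sqrt(lam[n]) * U[..., n]
    half = np.sqrt(lam[1:n] / 2.0)
    a[..., 1:n] = half * (U[..., 1:n] + 1j * V[..., 1:n])
    a[..., n + 1:] = np.conj(a[..., n - 1:0:-1])
    x = np.fft.ifft(a, axis=-1) * np.sqrt(m)
    return x[..., :n].real


def simulate_fbm(cfg: SimulationConfig) -> Trajectory2D:
    """2D fractional Brownian motion: two independent exact-covariance 1D
    FBM processes per particle (isotropy), with per-axis variance
    2 D t^(2H), so the 2D MSD is 4 D t^(2H).

    H = 0.5 reduces to Brownian motion; H = 0.4 gives the t^0.8
    subdiffusive scaling with stationary anticorrelated increments
    (FLE-consistent, ergodic).
    """
    _check_step_scale(cfg)
    rng = np.random.default_rng(cfg.seed)
    N, H = cfg.N, cfg.hurst
    times = np.arange(cfg.n_steps + 1) * cfg.dt
    x0 = _init_positions(rng, N, cfg.L)
    sigma = np.sqrt(2.0 * cfg.D) * cfg.dt ** H
    fgn = fractional_gaussian_noise(cfg.n_steps, H, rng, size=(N, 2))
    steps = sigma * np.transpose(fgn, (0, 2, 1))    # (N, n_steps, 2)
    pos = np.concatenate([x0[:, None, :],
                          x0[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    return _finalize(cfg, times, pos, {"hurst": H})


def _soft_disk_forces(pos, L, diameter, k_spring):
    """Pairwise harmonic soft-core repulsion F = k (d - r) r_hat for
    r < d, minimum image."""
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    r2 = np.sum(d * d, axis=2)
    np.fill_diagonal(r2, np.inf)
    r = np.sqrt(r2)
    overlap = diameter - r
    active = overlap > 0
    with np.errstate(invalid="ignore"):
        mag = np.where(active, k_spring * overlap / r, 0.0)
    return np.sum(mag[:, :, None] * d, axis=1)


def simulate_crowded_disks(cfg: SimulationConfig) -> Trajectory2D:
    """Overdamped Brownian dynamics of soft repulsive disks: ground-state
    molecules act as obstacles to each other's diffusion.

    At low coverage the long-time MSD is linear; near full coverage the
    short-lag MSD exponent drops below 1 (transient subdiffusion) and
    linearity is recovered at long lags.  A coarse mechanistic stand-in for
    crowding -- no atomistic forces.

    Disks start from random sequential addition (falling back to a jittered
    lattice at densities where RSA jams) and relax for ``n_burnin`` steps
    before recording starts.
    """
    _check_step_scale(cfg)
    rng = np.random.default_rng(cfg.seed)
    N, L, dt = cfg.N, cfg.L, cfg.dt
    sigma_d = cfg.disk_diameter
    pos = _place_disks(rng, N, L, sigma_d)

    times = np.arange(cfg.n_steps + 1) * dt
    traj = np.empty((N, cfg.n_steps + 1, 2))
    noise_sd = np.sqrt(2.0 * cfg.D * dt)
    cur = pos.copy()     # unwrapped
    for s in range(-cfg.n_burnin, cfg.n_steps + 1):
        if s >= 0:
            traj[:, s] = cur
        if s == cfg.n_steps:
            break
        F = _soft_disk_forces(_wrap(cur, L), L, sigma_d, 1.0)
        cur = cur + cfg.repulsion * dt * F + rng.normal(0.0, noise_sd, (N, 2))
    return _finalize(cfg, times, traj,
                     {"disk_diameter": sigma_d, "repulsion": cfg.repulsion})


def _place_disks(rng, N, L, sigma_d, max_tries_per_disk: int = 200):
    """Non-overlapping initial positions: RSA first, jittered square
    lattice when RSA cannot reach the requested density."""
    if N == 0:
        return np.empty((0, 2))
    pos = np.empty((N, 2))
    placed = 0
    for _ in range(max_tries_per_disk * N):
        if placed == N:
            break
        cand = rng.uniform(0.0, L, size=2)
        if placed:
            d = pos[:placed] - cand
            d -= L * np.round(d / L)
            if np.any(np.sum(d * d, axis=1) < (0.85 * sigma_d) ** 2):
                continue
        pos[placed] = cand
        placed += 1
    if placed == N:
        return pos
    side = int(np.ceil(np.sqrt(N)))
    if L / side < 0.5 * sigma_d:
        raise RuntimeError(
            f"cannot place {N} disks of diameter {sigma_d:.3g} in box {L:.3g}"
        )
    grid = (np.arange(side) + 0.5) * (L / side)
    xy = np.stack(np.meshgrid(grid, grid), axis=-1).reshape(-1, 2)[:N]
    return xy + rng.uniform(-0.05, 0.05, size=xy.shape) * (L / side)


_MOTION_MODELS = {
    "brownian": simulate_brownian,
    "fbm": simulate_fbm,
    "crowded_disks": simulate_crowded_disks,
}


# ---------------------------------------------------------------------------
# Annihilating walkers
# ---------------------------------------------------------------------------

def simulate_annihilation(cfg: SimulationConfig) -> AnnihilationOutput:
    """Annihilating random walkers implementing T1 + T1 -> S1 + S0.

    A fraction p0 of the particles starts in the triplet state.  At every
    frame (including t = 0), triplet pairs closer than R (minimum image)
    annihilate -- both leave the triplet pool but persist as ground-state
    crowders.  Multi-body clashes are resolved greedily closest-pair-first,
    re-scanning until no reactive pair remains, which is deterministic and
    label-order independent.

    The RMS frame step should stay below ~R/3 so pairs cannot tunnel
    through the reaction radius in one frame; larger steps raise an error.
    """
    if cfg.p0 <= 0:
        raise ValueError("p0 must be > 0 to have any triplets")
    rms = _check_step_scale(cfg)
    if rms > cfg.R / 3.0 * (1.0 + 1e-9):
        raise ValueError(
            f"RMS step {rms:.3g} m exceeds R/3 = {cfg.R / 3:.3g} m: "
            "triplet pairs could tunnel through the reaction radius; reduce dt"
        )
    traj = _MOTION_MODELS[cfg.motion](cfg)
    N, F = traj.n_particles, traj.n_frames
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A]))
    n_triplet0 = int(round(cfg.p0 * N))
    triplet = np.zeros(N, dtype=bool)
    triplet[rng.choice(N, size=n_triplet0, replace=False)] = True

    L = np.asarray(traj.box)
    events = []
    counts = np.empty(F, dtype=int)
    for f in range(F):
        ids = np.nonzero(triplet)[0]
        while ids.size >= 2:
            p = traj.positions[ids, f]
            d = p[:, None, :] - p[None, :, :]
            d -= L * np.round(d / L)
            dist2 = np.sum(d * d, axis=2)
            iu = np.triu_indices(ids.size, k=1)
            pair_d2 = dist2[iu]
            reactive = pair_d2 < cfg.R**2
            if not np.any(reactive):
                break
            order = np.argsort(pair_d2, kind="stable")
            used = np.zeros(ids.size, dtype=bool)
            for idx in order:
                if not reactive[idx]:
                    continue
                a, b = iu[0][idx], iu[1][idx]
                if used[a] or used[b]:
                    continue
                used[a] = used[b] = True
                triplet[ids[a]] = triplet[ids[b]] = False
                events.append((float(traj.times[f]), int(ids[a]), int(ids[b])))
            ids = np.nonzero(triplet)[0]   # re-scan survivors
        counts[f] = triplet.sum()

    area = traj.box[0] * traj.box[1]
    trace = KineticTrace(times=traj.times, conc=counts / (N_A * area))
    return AnnihilationOutput(trajectory=traj, triplet_counts=counts,
                              events=events, trace=trace, config=cfg)


# ---------------------------------------------------------------------------
# SHG-trace emulation
# ---------------------------------------------------------------------------

def emulate_shg_trace(decay: KineticTrace, noise_sd: float = 0.0,
                      resolution: float | None = None,
                      seed: int = 0) -> SHGTrace:
    """Turn a triplet decay into a noisy normalised ground-state-depletion
    trace as a ~20 ns-resolution pump-probe experiment would record it.

    The decay is averaged into bins of width ``resolution`` (default: the
    native step of the input), mapped linearly to depletion (depletion is
    proportional to triplet concentration; 1 at the first bin), and seeded
    Gaussian noise of scale ``noise_sd`` is added.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t, c = decay.times, decay.conc
    native = np.min(np.diff(t)) if t.size > 1 else 0.0
    if resolution is None:
        resolution = native
    if resolution < native - 1e-15 * max(native, 1.0):
        raise ValueError(
            f"resolution {resolution:.3g} s finer than native step {native:.3g} s"
        )
    edges = np.arange(t[0], t[-1] + resolution, resolution)
    if edges[-1] < t[-1] + 1e-30:
        edges = np.append(edges, t[-1] + resolution)
    idx = np.clip(np.digitize(t, edges) - 1, 0, len(edges) - 2)
    delays, values = [], []
    for b in range(idx.max() + 1):
        sel = idx == b
        if np.any(sel):
            delays.append(t[sel].mean())
            values.append(c[sel].mean())
    delays = np.asarray(delays)
    values = np.asarray(values)
    if values[0] <= 0:
        raise ValueError("decay starts at zero concentration")
    depletion = values / values[0]
    rng = np.random.default_rng(seed)
    noisy = depletion + rng.normal(0.0, noise_sd, size=depletion.shape) \
        if noise_sd > 0 else depletion
    sig = np.full_like(noisy, noise_sd) if noise_sd > 0 else None
    return SHGTrace(delays=delays, depletion=noisy, sigma=sig)
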