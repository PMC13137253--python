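"""Seeded Metropolis Monte Carlo of one rigid united-atom alkane in a
neutral Lennard-Jones solvent.

This module generates the synthetic inputs the analysis stages consume:
per-lambda-window energy-gap/volume samples for the FEP estimator,
thinned trajectories for radial distribution functions and brute-force
energy oracles, and Widom-insertion / low-density closed-form cross
checks.  The solvent is a charge-free LJ fluid (a "water surrogate"):
the alkane-water cross interaction physics under study - soft-core
coupling, cutoffs, shifts, tails - is preserved while electrostatics is
out of scope.  The solute is a rigid all-trans chain; conformational
sampling plays no role in any quantity computed here.

Sampling is NVT by default (the volume weights of the NPT estimator then
cancel exactly); an optional NPT mode with logarithmic volume moves
exercises the volume-weighted form.  All randomness derives from the
single ``SimSpec.seed`` through per-component substreams, so identical
seeds give bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from ._kernels import HAVE_NUMBA, sweep_kernel
from .fep_estimator import LambdaSchedule, ThermoState, WindowSamples
from .forcefield import AlkaneSpec, CutoffSpec, PairPar, SoftCorePar

__all__ = [
    "SimSpec",
    "Configuration",
    "Frame",
    "Trajectory",
    "RdfTable",
    "build_alkane_chain",
    "mc_run",
    "run_solvent",
    "widom_mu_excess",
    "low_density_mu_excess",
    "compute_rdf",
    "gaussian_gap_samples",
    "write_xyz",
    "write_rdf_tsv",
    "read_rdf_tsv",
]

#: bar -> kJ/(mol nm^3)
BAR_TO_KJ_PER_MOL_NM3 = 0.06022140857

#: all-trans chain geometry: C-C bond (nm) and C-C-C angle (degrees)
CC_BOND = 0.154
CCC_ANGLE_DEG = 114.0


@dataclass
class SimSpec:
    """Monte Carlo run specification.

    ``density`` is the solvent number density in nm^-3 (fixes the cubic
    box edge as ``(n_solvent/density)^(1/3)``).  ``n_sweeps`` counts
    post-burn-in sweeps per lambda window; one sweep attempts
    ``n_solvent`` single-particle moves.  ``cutoff_ss``/``cutoff_su``
    are the solvent-solvent and solute-solvent cutoff classes; they are
    independently configurable, mirroring the different cutoffs
    conventionally used for water-water and alkane-water interactions.
    """

    n_solvent: int
    density: float
    T: float
    seed: int
    cutoff_ss: CutoffSpec
    cutoff_su: CutoffSpec
    max_displacement: float = 0.15
    n_sweeps: int = 60
    n_burnin: int = 20
    sample_every: int = 1
    frame_every: int = 10
    npt: bool = False
    pressure: float = 1.0
    max_dlnv: float = 0.02

    def __post_init__(self) -> None:
        if self.n_solvent < 0:
            raise ValueError("n_solvent must be >= 0")
        if not (self.density > 0.0):
            raise ValueError("density must be positive")
        if not (self.n_sweeps > 0 and self.n_burnin >= 0):
            raise ValueError("need n_sweeps > 0 and n_burnin >= 0")

    @property
    def box_edge(self) -> float:
        return (max(self.n_solvent, 1) / self.density) ** (1.0 / 3.0)


@dataclass
class Configuration:
    """Solvent + solute coordinates (nm) in a cubic periodic box."""

    solvent_positions: np.ndarray
    solute_positions: np.ndarray
    box: float

    def __post_init__(self) -> None:
        if self.solute_positions.shape[0] < 1:
            raise ValueError("need at least one solute site")


@dataclass
class Frame:
    positions: np.ndarray
    box: float
    lam: float
    u_cross: float = float("nan")  # solute-solvent energy at lam, kJ/mol


@dataclass
class Trajectory:
    """Thinned configurations plus run metadata."""

    frames: list[Frame]
    solute_positions: np.ndarray | None
    labels: list[str] = field(default_factory=list)
    energy_drift: float = 0.0
    warmup_applied: bool = False
    acceptance: float = float("nan")


@dataclass
class RdfTable:
    """Binned radial distribution function."""

    r_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    rho_used: float

    def __post_init__(self) -> None:
        self.r_centers = np.asarray(self.r_centers, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0.0):
            raise ValueError("g must be nonnegative")
        if np.any(np.diff(self.r_centers) <= 0.0):
            raise ValueError("r_centers must be strictly increasing")
        if not (self.bin_width > 0.0):
            raise ValueError("bin_width must be positive")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def build_alkane_chain(spec: AlkaneSpec) -> tuple[np.ndarray, list[str]]:
    """Rigid all-trans zig-zag chain, centered at the origin.

    Consecutive sites are ``CC_BOND`` apart with a ``CCC_ANGLE_DEG``
    backbone angle; the chain lies in the xz-plane.  Returns coordinates
    (n_carbons, 3) and per-site type labels.
    """
    n = spec.n_carbons
    half = math.radians(CCC_ANGLE_DEG) / 2.0
    dx = CC_BOND * math.sin(half)
    dz = CC_BOND * math.cos(half)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * dx
    coords[:, 2] = (np.arange(n) % 2) * dz
    coords -= coords.mean(axis=0)
    return coords, spec.site_labels


# ---------------------------------------------------------------------------
# energy kernels (vectorized over pair arrays)
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _lj_sum(r2: np.ndarray, eps: float, sigma: float, rc2: float,
            u_rc: float, cap: float | None = None) -> float:
    """Sum of (optionally shifted, optionally capped) LJ energies."""
    m = r2 < rc2
    if not m.any():
        return 0.0
    x6 = (sigma * sigma / r2[m]) ** 3
    u = 4.0 * eps * (x6 * x6 - x6) - u_rc
    if cap is not None:
        u = np.minimum(u, cap)
    return float(u.sum())


def _softcore_vals(lam: float, x6: np.ndarray, eps: np.ndarray,
                   sc: SoftCorePar) -> np.ndarray:
    a = sc.alpha * (1.0 - lam) ** 2 + x6
    inv = 1.0 / a
    return lam ** sc.n_exp * 4.0 * eps * (inv * inv - inv)


class _System:
    """Mutable MC state: solvent positions, box, energy bookkeeping."""

    def __init__(self, spec: SimSpec, solute: np.ndarray | None,
                 cross: list[PairPar] | None, pair_ss: PairPar,
                 sc: SoftCorePar, rng: np.random.Generator):
        self.spec = spec
        self.sc = sc
        self.pair_ss = pair_ss
        self.box = spec.box_edge
        self.rng = rng
        if solute is not None:
            self.solute = solute - solute.mean(axis=0) + 0.5 * self.box
            self.eps_x = np.array([p.epsilon for p in cross])
            self.sig_x = np.array([p.sigma for p in cross])
        else:
            self.solute = None
            self.eps_x = np.zeros(0)
            self.sig_x = np.ones(0)
        self.pos = self._lattice_init()
        self._du_accum = 0.0
        self.set_lambda(0.0)

    def set_lambda(self, lam: float) -> None:
        """Switch coupling value and refresh cached cutoff/shift constants."""
        self.lam = lam
        self._c_rc2_ss = self._rc2_ss
        self._c_rc2_su = self._rc2_su
        self._c_u_rc_ss = self._u_rc_ss
        self._c_u_rc_su = self._u_rc_su(lam)

    # -- cutoff helpers -----------------------------------------------------
    @property
    def _rc2_ss(self) -> float:
        return min(self.spec.cutoff_ss.rc, 0.5 * self.box) ** 2

    @property
    def _rc2_su(self) -> float:
        return min(self.spec.cutoff_su.rc, 0.5 * self.box) ** 2

    @property
    def _u_rc_ss(self) -> float:
        if not self.spec.cutoff_ss.shifted:
            return 0.0
        rc = math.sqrt(self._rc2_ss)
        x6 = (self.pair_ss.sigma / rc) ** 6
        return 4.0 * self.pair_ss.epsilon * (x6 * x6 - x6)

    def _u_rc_su(self, lam: float) -> np.ndarray:
        """Per-site soft-core value at the solute-solvent cutoff (shift)."""
        if not self.spec.cutoff_su.shifted or self.solute is None:
            return np.zeros_like(self.eps_x)
        rc = math.sqrt(self._rc2_su)
        x6 = (rc / self.sig_x) ** 6
        return _softcore_vals(lam, x6, self.eps_x, self.sc)

    # -- initialization -----------------------------------------------------
    def _lattice_init(self) -> np.ndarray:
        n = self.spec.n_solvent
        if n == 0:
            return np.zeros((0, 3))
        m = math.ceil(n ** (1.0 / 3.0))
        # jittered cubic lattice, skipping sites that overlap the solute core
        grid = (np.stack(np.meshgrid(*[np.arange(m)] * 3), -1).reshape(-1, 3)
                + 0.5) * (self.box / m)
        if self.solute is not None and self.sig_x.size:
            d = _min_image(grid[:, None, :] - self.solute[None, :, :], self.box)
            r2 = (d * d).sum(-1)
            keep = (r2 > (0.8 * self.sig_x[None, :]) ** 2).all(axis=1)
            grid = grid[keep]
        if grid.shape[0] < n:
            raise ValueError(
                f"cannot place {n} solvent particles: only {grid.shape[0]} "
                "non-overlapping lattice sites; lower density or n_solvent"
            )
        idx = self.rng.choice(grid.shape[0], size=n, replace=False)
        pos = grid[idx] + self.rng.uniform(-0.02, 0.02, size=(n, 3))
        return np.mod(pos, self.box)

    # -- full energies ------------------------------------------------------
    def _total_ss(self, cap: float | None = None) -> float:
        n = self.pos.shape[0]
        if n < 2 or self.pair_ss.epsilon == 0.0:
            return 0.0
        d = _min_image(self.pos[:, None, :] - self.pos[None, :, :], self.box)
        r2 = (d * d).sum(-1)
        iu = np.triu_indices(n, k=1)
        return _lj_sum(r2[iu], self.pair_ss.epsilon, self.pair_ss.sigma,
                       self._rc2_ss, self._u_rc_ss, cap)

    def _cross_x6(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(r/sigma)^6 for solvent x solute pairs, plus within-cutoff mask."""
        d = _min_image(pos[:, None, :] - self.solute[None, :, :], self.box)
        r2 = (d * d).sum(-1)
        x6 = (r2 / self.sig_x[None, :] ** 2) ** 3
        return x6, r2 < self._rc2_su

    def _total_cross(self, lam: float, cap: float | None = None) -> float:
        if self.solute is None or self.pos.shape[0] == 0 or lam == 0.0:
            return 0.0
        x6, m = self._cross_x6(self.pos)
        eps = np.broadcast_to(self.eps_x[None, :], x6.shape)
        u = _softcore_vals(lam, x6[m], eps[m], self.sc)
        shift = np.broadcast_to(self._u_rc_su(lam)[None, :], x6.shape)[m]
        u = u - shift
        if cap is not None:
            u = np.minimum(u, cap)
        return float(u.sum())

    # -- per-particle energies ---------------------------------------------
    def _particle_ss(self, j: int, pos_j: np.ndarray, cap=None) -> float:
        if self.pos.shape[0] < 2 or self.pair_ss.epsilon == 0.0:
            return 0.0
        d = _min_image(self.pos - pos_j, self.box)
        r2 = (d * d).sum(-1)
        r2[j] = np.inf
        return _lj_sum(r2, self.pair_ss.epsilon, self.pair_ss.sigma,
                       self._rc2_ss, self._u_rc_ss, cap)

    def _particle_cross(self, pos_j: np.ndarray, lam: float, cap=None) -> float:
        if self.solute is None or lam == 0.0:
            return 0.0
        d = _min_image(self.solute - pos_j, self.box)
        r2 = (d * d).sum(-1)
        m = r2 < self._rc2_su
        if not m.any():
            return 0.0
        x6 = (r2[m] / self.sig_x[m] ** 2) ** 3
        u = _softcore_vals(lam, x6, self.eps_x[m], self.sc) - self._u_rc_su(lam)[m]
        if cap is not None:
            u = np.minimum(u, cap)
        return float(u.sum())

    # -- moves --------------------------------------------------------------
    def _move_du(self, j: int, old: np.ndarray, new: np.ndarray,
                 cap: float | None = None) -> float:
        """Energy change of moving solvent particle j from old to new.

        Both positions are evaluated in a single vectorized pass; cutoff
        and shift constants come from the ``set_lambda`` cache.
        """
        both = np.stack((new, old))
        du = 0.0
        if self.pos.shape[0] >= 2 and self.pair_ss.epsilon != 0.0:
            d = _min_image(both[:, None, :] - self.pos[None, :, :], self.box)
            r2 = (d * d).sum(-1)
            r2[:, j] = np.inf
            x6 = (self.pair_ss.sigma ** 2 / r2) ** 3
            u = 4.0 * self.pair_ss.epsilon * (x6 * x6 - x6)
            if cap is not None:
                u = np.minimum(u, cap)
            u = np.where(r2 < self._c_rc2_ss, u - self._c_u_rc_ss, 0.0)
            du += u[0].sum() - u[1].sum()
        if self.solute is not None and self.lam > 0.0:
            d = _min_image(both[:, None, :] - self.solute[None, :, :], self.box)
            r2 = (d * d).sum(-1)
            x6 = (r2 / self.sig_x[None, :] ** 2) ** 3
            a = self.sc.alpha * (1.0 - self.lam) ** 2 + x6
            inv = 1.0 / a
            u = self.lam ** self.sc.n_exp * 4.0 * self.eps_x[None, :] * (inv * inv - inv)
            if cap is not None:
                u = np.minimum(u, cap)
            u = np.where(r2 < self._c_rc2_su, u - self._c_u_rc_su[None, :], 0.0)
            du += u[0].sum() - u[1].sum()
        return float(du)

    def sweep(self, beta: float, cap: float | None = None) -> int:
        """One sweep of n_solvent Metropolis single-particle moves."""
        n = self.pos.shape[0]
        if n == 0:
            return 0
        js = self.rng.integers(0, n, size=n)
        disp = self.rng.uniform(-self.spec.max_displacement,
                                self.spec.max_displacement, size=(n, 3))
        us = self.rng.random(n)
        if HAVE_NUMBA:
            solute = self.solute if self.solute is not None else np.zeros((0, 3))
            acc, du_acc = sweep_kernel(
                self.pos, self.box, js, disp, us, beta,
                self.pair_ss.epsilon, self.pair_ss.sigma ** 2,
                self._c_rc2_ss, self._c_u_rc_ss,
                solute, self.eps_x, self.sig_x ** 2,
                self._c_rc2_su, self._c_u_rc_su,
                self.lam, self.sc.alpha, self.sc.n_exp,
                cap if cap is not None else np.inf,
            )
            self._du_accum += du_acc
            return int(acc)
        acc = 0
        for k in range(n):
            j = int(js[k])
            old = self.pos[j].copy()
            new = np.mod(old + disp[k], self.box)
            du = self._move_du(j, old, new, cap)
            if du <= 0.0 or us[k] < math.exp(-beta * min(du, 700.0 / beta)):
                self.pos[j] = new
                acc += 1
                self._du_accum += du
        return acc

    def volume_move(self, beta: float, pressure_kj: float) -> bool:
        """Logarithmic volume move (NPT): scale box and all coordinates."""
        v_old = self.box ** 3
        lnv_new = math.log(v_old) + self.rng.uniform(-self.spec.max_dlnv,
                                                     self.spec.max_dlnv)
        v_new = math.exp(lnv_new)
        s = (v_new / v_old) ** (1.0 / 3.0)
        old_box, old_pos = self.box, self.pos
        old_solute = self.solute
        u_old = self._total_ss() + self._total_cross(self.lam)
        self.box = old_box * s
        self.pos = old_pos * s
        if self.solute is not None:
            c = old_solute.mean(axis=0)
            self.solute = old_solute - c + c * s
        u_new = self._total_ss() + self._total_cross(self.lam)
        n_mol = self.pos.shape[0] + (1 if self.solute is not None else 0)
        arg = (-beta * (u_new - u_old + pressure_kj * (v_new - v_old))
               + (n_mol + 1) * math.log(v_new / v_old))
        if self.rng.random() < math.exp(min(arg, 0.0)) or arg >= 0.0:
            self.set_lambda(self.lam)  # refresh box-dependent caches
            return True
        self.box, self.pos, self.solute = old_box, old_pos, old_solute
        self.set_lambda(self.lam)
        return False


def _run_windows(system: _System, spec: SimSpec, ts: ThermoState,
                 ens_lams: list[float], gap_lams: list[float]) -> tuple[list[WindowSamples], list[Frame], float, int, int]:
    """Sample each ensemble lambda, recording gaps to the paired lambda."""
    beta = 1.0 / ts.kT
    p_kj = spec.pressure * BAR_TO_KJ_PER_MOL_NM3
    windows: list[WindowSamples] = []
    frames: list[Frame] = []
    drift = 0.0
    n_acc = 0
    n_try = 0
    for lam_i, lam_j in zip(ens_lams, gap_lams):
        system.set_lambda(lam_i)
        # re-anchor bookkeeping at the window boundary and track the drift
        u_full = system._total_ss() + system._total_cross(lam_i)
        system._du_accum = 0.0
        base = u_full
        dus, vols = [], []
        n_samp = 0
        for sweep in range(spec.n_burnin + spec.n_sweeps):
            n_acc += system.sweep(beta)
            n_try += system.pos.shape[0]
            if spec.npt:
                system.volume_move(beta, p_kj)
            if sweep < spec.n_burnin or (sweep - spec.n_burnin) % spec.sample_every:
                continue
            u_i = system._total_cross(lam_i)
            u_j = system._total_cross(lam_j)
            dus.append(u_j - u_i)
            vols.append(system.box ** 3)
            if n_samp % spec.frame_every == 0:
                frames.append(Frame(system.pos.copy(), system.box, lam_i, u_i))
            n_samp += 1
        if not spec.npt:
            u_check = system._total_ss() + system._total_cross(lam_i)
            drift = max(drift, abs(u_check - (base + system._du_accum)))
        windows.append(WindowSamples(lam_i, lam_j, np.array(dus), np.array(vols)))
    return windows, frames, drift, n_acc, n_try


def mc_run(
    spec: SimSpec,
    solute: np.ndarray,
    cross: list[PairPar],
    schedule: LambdaSchedule,
    pair_ss: PairPar,
    direction: str = "forward",
    softcore: SoftCorePar = SoftCorePar(),
    labels: list[str] | None = None,
) -> tuple[Trajectory, list[WindowSamples]]:
    """Metropolis MC across a lambda schedule, producing window samples.

    Forward runs sample each ensemble ``lam_i`` and record
    ``U(lam_{i+1}) - U(lam_i)``; reverse runs start fully coupled and
    record gaps toward the next lower lambda.  The configuration is
    carried from window to window.  Identical ``spec.seed`` gives
    bit-identical output.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    ts = ThermoState(T=spec.T, P=spec.pressure)
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    system = _System(spec, solute, cross, pair_ss, softcore, rng)

    warmup = False
    beta = 1.0 / ts.kT
    if direction == "reverse":
        # start fully coupled; relax any lattice/solute overlap under a
        # capped potential before normal Metropolis sampling
        system.set_lambda(1.0)
        u0 = system._total_ss() + system._total_cross(1.0)
        if u0 > 50.0 * ts.kT * max(spec.n_solvent, 1):
            warmup = True
            for _ in range(5):
                system.sweep(beta, cap=50.0 * ts.kT)

    vals = list(schedule.values)
    if direction == "forward":
        ens, gap = vals[:-1], vals[1:]
    else:
        ens, gap = vals[:0:-1], vals[-2::-1]

    windows, frames, drift, n_acc, n_try = _run_windows(system, spec, ts, ens, gap)
    traj = Trajectory(
        frames=frames,
        solute_positions=system.solute,
        labels=labels or [],
        energy_drift=drift,
        warmup_applied=warmup,
        acceptance=n_acc / n_try if n_try else float("nan"),
    )
    return traj, windows


def run_solvent(spec: SimSpec, pair_ss: PairPar) -> Trajectory:
    """Pure-solvent MC (lambda-independent Hamiltonian) for Widom/RDF use."""
    ts = ThermoState(T=spec.T, P=spec.pressure)
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    system = _System(spec, None, None, pair_ss, SoftCorePar(), rng)
    beta = 1.0 / ts.kT
    p_kj = spec.pressure * BAR_TO_KJ_PER_MOL_NM3
    frames: list[Frame] = []
    n_acc = n_try = 0
    n_samp = 0
    for sweep in range(spec.n_burnin + spec.n_sweeps):
        n_acc += system.sweep(beta)
        n_try += spec.n_solvent
        if spec.npt:
            system.volume_move(beta, p_kj)
        if sweep < spec.n_burnin or (sweep - spec.n_burnin) % spec.sample_every:
            continue
        if n_samp % spec.frame_every == 0 or spec.frame_every == 1:
            frames.append(Frame(system.pos.copy(), system.box, 0.0))
        n_samp += 1
    return Trajectory(frames=frames, solute_positions=None,
                      acceptance=n_acc / n_try if n_try else float("nan"))


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def widom_mu_excess(
    traj: Trajectory,
    pair: PairPar,
    ts: ThermoState,
    n_insertions: int,
    seed: int,
    rc: float | None = None,
    return_se: bool = False,
):
    """Excess chemical potential by Widom test-particle insertion.

    ``-kT ln < exp(-U_insert/kT) >`` over ``n_insertions`` uniform ghost
    insertions per frame of a pure-solvent trajectory.  ``rc`` truncates
    the insertion energy at the same solute-solvent cutoff the FEP runs
    use, so the two methods estimate the same coupling free energy.
    With ``return_se`` the frame-blocked standard error is also returned.
    """
    if n_insertions < 1:
        raise ValueError("need at least one insertion")
    if not traj.frames:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(seed)
    beta = 1.0 / ts.kT
    frame_means = []
    for fr in traj.frames:
        pts = rng.uniform(0.0, fr.box, size=(n_insertions, 3))
        if fr.positions.shape[0] == 0 or pair.epsilon == 0.0:
            frame_means.append(1.0)
            continue
        d = _min_image(pts[:, None, :] - fr.positions[None, :, :], fr.box)
        r2 = (d * d).sum(-1)
        rc_eff = min(rc if rc is not None else 0.5 * fr.box, 0.5 * fr.box)
        m = r2 < rc_eff ** 2
        x6 = np.zeros_like(r2)
        x6[m] = (pair.sigma ** 2 / r2[m]) ** 3
        u = np.where(m, 4.0 * pair.epsilon * (x6 * x6 - x6), 0.0)
        w = np.exp(-beta * np.clip(u.sum(axis=1), -700.0 / beta, 700.0 / beta))
        frame_means.append(float(w.mean()))
    frame_means = np.asarray(frame_means)
    mu = -ts.kT * math.log(frame_means.mean())
    if not return_se:
        return mu
    # frame-blocked error, propagated through the log
    n_b = max(2, min(10, len(frame_means)))
    edges = np.linspace(0, len(frame_means), n_b + 1, dtype=int)
    blocks = np.array([frame_means[a:b].mean() for a, b in zip(edges, edges[1:])
                       if b > a])
    se_w = blocks.std(ddof=1) / math.sqrt(len(blocks))
    return mu, ts.kT * se_w / frame_means.mean()


def low_density_mu_excess(
    pair: PairPar, rho: float, ts: ThermoState, rc: float | None = None
) -> float:
    """Closed-form low-density excess chemical potential.

    ``kT rho int_0^inf (1 - exp(-u(r)/kT)) 4 pi r^2 dr`` by adaptive
    quadrature; exact to first order in density.  ``rc`` truncates the
    pair potential, matching a truncated simulation Hamiltonian.  Warns
    when ``rho * |integral|`` is large enough that the first-order form
    is unreliable.
    """
    if pair.epsilon < 0.0:
        raise ValueError("non-integrable potential")
    beta = 1.0 / ts.kT
    sig = pair.sigma

    def mayer(r: float) -> float:
        if rc is not None and r >= rc:
            return 0.0
        x6 = (sig / r) ** 6
        u = 4.0 * pair.epsilon * (x6 * x6 - x6)
        return (1.0 - math.exp(-beta * min(u, 700.0 / beta))) * 4.0 * math.pi * r * r

    upper = rc if rc is not None else 10.0 * sig
    val, _ = integrate.quad(mayer, 1e-12, upper, points=[0.5 * sig, sig, 2 ** (1 / 6) * sig],
                            limit=200)
    if rho * abs(val) > 0.3:
        warnings.warn(
            f"rho*B-integral = {rho * val:.3f}: low-density expansion unreliable",
            stacklevel=2,
        )
    return ts.kT * rho * val


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

def compute_rdf(
    traj: Trajectory,
    selection: str,
    bin_width: float,
    r_max: float,
    lam: float | None = None,
) -> RdfTable:
    """Binned pair histogram normalized by ideal-gas shell counts.

    ``selection`` is ``"cross"`` (solute-site to solvent) or
    ``"solvent"`` (solvent-solvent).  ``lam`` restricts to frames
    sampled at that coupling value (e.g. 1.0 for the fully coupled
    ensemble).  ``r_max`` must not exceed half the box edge.
    """
    frames = [f for f in traj.frames if lam is None or f.lam == lam]
    if not frames:
        raise ValueError("no frames selected")
    if r_max > 0.5 * min(f.box for f in frames) + 1e-12:
        raise ValueError("r_max exceeds half the box edge")
    nbins = int(round(r_max / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    counts = np.zeros(nbins)
    n_ref_tot = 0
    rho_acc = 0.0
    for fr in frames:
        v = fr.box ** 3
        if selection == "cross":
            if traj.solute_positions is None:
                raise ValueError("trajectory has no solute")
            ref, oth = traj.solute_positions, fr.positions
            rho = oth.shape[0] / v
        elif selection == "solvent":
            ref = oth = fr.positions
            rho = (oth.shape[0] - 1) / v
        else:
            raise ValueError("selection must be 'cross' or 'solvent'")
        if ref.shape[0] == 0 or oth.shape[0] == 0:
            raise ValueError("empty selection")
        d = _min_image(ref[:, None, :] - oth[None, :, :], fr.box)
        r = np.sqrt((d * d).sum(-1)).ravel()
        if selection == "solvent":
            r = r[r > 1e-12]  # drop self pairs
        counts += np.histogram(r, bins=edges)[0]
        n_ref_tot += ref.shape[0]
        rho_acc += rho * ref.shape[0]
    rho_mean = rho_acc / n_ref_tot
    shell = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (n_ref_tot * rho_mean * shell)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RdfTable(r_centers=centers, g=g, bin_width=bin_width, rho_used=rho_mean)


# ---------------------------------------------------------------------------
# synthetic window fixtures
# ---------------------------------------------------------------------------

def gaussian_gap_samples(
    mu: float,
    sd: float,
    n: int,
    seed: int,
    v_mode: str = "constant",
    lam_i: float = 0.0,
    lam_j: float = 1.0,
) -> WindowSamples:
    """Seeded Gaussian energy gaps with constant or log-normal volumes.

    With Gaussian gaps and constant volume the exact window increment is
    ``mu - sd^2/(2 kT)``, which makes this the closed-form validation
    fixture for the FEP estimator.
    """
    if sd < 0.0 or n < 1:
        raise ValueError("need sd >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    du = mu + sd * rng.standard_normal(n) if sd > 0 else np.full(n, float(mu))
    if v_mode == "constant":
        v = np.ones(n)
    elif v_mode == "lognormal":
        v = np.exp(0.05 * rng.standard_normal(n))
    else:
        raise ValueError("v_mode must be 'constant' or 'lognormal'")
    return WindowSamples(lam_i, lam_j, du, v)


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path, solvent_label: str = "Sv") -> None:
    """Write frames as XYZ blocks (site label + coordinates in nm)."""
    with open(path, "w") as fh:
        for i, fr in enumerate(traj.frames):
            n_solute = 0 if traj.solute_positions is None else len(traj.solute_positions)
            fh.write(f"{fr.positions.shape[0] + n_solute}\n")
            fh.write(f"frame {i} box {fr.box:.6f} lambda {fr.lam:.4f}\n")
            if traj.solute_positions is not None:
                labels = traj.labels or ["C"] * n_solute
                for lab, p in zip(labels, traj.solute_positions):
                    fh.write(f"{lab} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            for p in fr.positions:
                fh.write(f"{solvent_label} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def write_energy_log(traj: Trajectory, path) -> None:
    """TSV frame-energy log: frame index, lambda, box edge, cross energy."""
    with open(path, "w") as fh:
        fh.write("frame\tlambda\tbox_nm\tu_cross_kJmol\n")
        for i, fr in enumerate(traj.frames):
            fh.write(f"{i}\t{fr.lam:.6g}\t{fr.box:.8g}\t{fr.u_cross:.8g}\n")


def write_rdf_tsv(rdf: RdfTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_width_nm\t{rdf.bin_width:.10g}\n")
        fh.write(f"# rho_nm3\t{rdf.rho_used:.10g}\n")
        fh.write("r_nm\tg\n")
        for r, g in zip(rdf.r_centers, rdf.g):
            fh.write(f"{r:.10g}\t{g:.10g}\n")


def read_rdf_tsv(path) -> RdfTable:
    bin_width = rho = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# bin_width_nm"):
                bin_width = float(line.split("\t")[1])
            elif line.startswith("# rho_nm3"):
                rho = float(line.split("\t")[1])
            elif line[0].isdigit() or line[0] in "+-.":
                r, g = line.split()
                rows.append((float(r), float(g)))
    arr = np.array(rows)
    if bin_width is None:
        bin_width = float(np.diff(arr[:, 0]).mean())
    return RdfTable(arr[:, 0], arr[:, 1], bin_width, rho if rho is not None else float("nan"))
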