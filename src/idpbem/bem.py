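"""Bias-exchange metadynamics engine.

Each replica carries a history-dependent bias: a sum of one-dimensional
Gaussian hills deposited along its own collective variable at fixed time
intervals (height 0.2 kJ/mol every 4 ps by default, matching the reference
protocol).  At exchange times a Metropolis move proposes swapping the bias
potentials of a random replica pair.  The molecular-dynamics engine itself
is replaced by pluggable desk-scale samplers: overdamped Langevin dynamics
on packaged analytic potentials, and torsion-space Metropolis Monte Carlo
for peptides (one sweep is bookkept as 1 ps so the deposit/exchange
schedule applies uniformly).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import build_backbone_from_torsions
from .colvars import CVConfig, compute_cvs, compute_single_cv
from .model import PeptideSequence, Trajectory, TorsionProfile
from .synthetic import AnalyticPotential, ToyEnergyModel, toy_energy, wrap_angle

KB = 0.0083145  # kJ/mol/K

DEFAULT_WIDTHS = (0.2, 0.2, 0.2, 2.0, 0.65, 0.5, 0.2)


@dataclass(frozen=True)
class GaussianHill:
    center: float
    width: float
    height: float
    deposit_time: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("hill width and height must be positive")


@dataclass
class BiasState:
    """Per-replica deposited-hill history along one CV (0-based index)."""

    cv_index: int
    hills: list[GaussianHill] = field(default_factory=list)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.array([h.center for h in self.hills]),
            np.array([h.width for h in self.hills]),
            np.array([h.height for h in self.hills]),
            np.array([h.deposit_time for h in self.hills]),
        )


def bias_energy(bias: BiasState, cv_value) -> float | np.ndarray:
    """Sum of deposited Gaussians at cv_value (kJ/mol); 0 for no history."""
    x = np.asarray(cv_value, dtype=float)
    if not bias.hills:
        return 0.0 if x.ndim == 0 else np.zeros(x.shape)
    c, w, h, _ = bias._arrays()
    v = np.sum(h * np.exp(-((x[..., None] - c) ** 2) / (2.0 * w**2)), axis=-1)
    return float(v) if x.ndim == 0 else v


def bias_gradient(bias: BiasState, cv_value) -> float | np.ndarray:
    """d(bias)/d(cv) at cv_value."""
    x = np.asarray(cv_value, dtype=float)
    if not bias.hills:
        return 0.0 if x.ndim == 0 else np.zeros(x.shape)
    c, w, h, _ = bias._arrays()
    d = x[..., None] - c
    v = np.sum(-h * d / w**2 * np.exp(-(d**2) / (2.0 * w**2)), axis=-1)
    return float(v) if x.ndim == 0 else v


def time_averaged_bias(
    bias: BiasState, cv_value, t_start: float, t_end: float
) -> float | np.ndarray:
    """Bias averaged over [t_start, t_end]: each hill is weighted by the
    fraction of the window during which it existed.  This damps the
    O(hill-height) fluctuation of the instantaneous converged bias."""
    x = np.asarray(cv_value, dtype=float)
    if not bias.hills or t_end <= t_start:
        return 0.0 if x.ndim == 0 else np.zeros(x.shape)
    c, w, h, tdep = bias._arrays()
    frac = np.clip((t_end - np.maximum(tdep, t_start)) / (t_end - t_start), 0.0, 1.0)
    v = np.sum(frac * h * np.exp(-((x[..., None] - c) ** 2) / (2.0 * w**2)), axis=-1)
    return float(v) if x.ndim == 0 else v


@dataclass
class BEMSchedule:
    """Deposition/exchange protocol (times in ps, energies in kJ/mol)."""

    total_time: float
    hill_height: float = 0.2
    deposit_interval: float = 4.0
    exchange_interval: float = 20.0
    widths: tuple[float, ...] = DEFAULT_WIDTHS
    temperature: float = 330.0
    seed: int = 0

    def __post_init__(self) -> None:
        ratio = self.exchange_interval / self.deposit_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("exchange interval must be a multiple of the deposit interval")
        if any(w <= 0 for w in self.widths):
            raise ValueError("all hill widths must be positive")

    @property
    def kT(self) -> float:
        return KB * self.temperature


def deposit(bias: BiasState, cv_value: float, schedule: BEMSchedule, time: float) -> BiasState:
    """Append one hill at the current CV value (in place; returns bias)."""
    k = time / schedule.deposit_interval
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"deposit time {time} is not aligned with the {schedule.deposit_interval} ps interval"
        )
    bias.hills.append(
        GaussianHill(
            center=float(cv_value),
            width=schedule.widths[bias.cv_index],
            height=schedule.hill_height,
            deposit_time=float(time),
        )
    )
    return bias


# ---------------------------------------------------------------------------
# samplers


class SamplerDivergence(RuntimeError):
    pass


class LangevinSampler:
    """Overdamped Langevin (Euler-Maruyama) on an analytic potential.

    Targets exp(-(U + bias)/kT) on the potential's domain, with reflecting
    walls at the domain bounds (the Boltzmann density inside is unchanged).
    The CV vector is the coordinate vector itself.  Advancing by zero time
    is the identity.

    For speed the bias force is linearly interpolated from a fine grid
    along the biased coordinate; the grid is refreshed incrementally as
    hills are deposited (hill widths are orders of magnitude wider than
    the grid spacing, so the interpolation error is negligible).
    """

    GRID_POINTS = 4001

    def __init__(
        self,
        potential: AnalyticPotential,
        kT: float,
        friction: float = 1.0,
        dt: float = 0.004,
        seed: int = 0,
        x0=None,
    ):
        self.potential = potential
        self.kT = kT
        self.friction = friction
        self.dt = dt
        self.rng = np.random.default_rng(seed)
        if x0 is None:
            x0 = [-1.0] * potential.ndim
        self.x = np.atleast_1d(np.asarray(x0, dtype=float))
        self.lo = potential.lo
        self.hi = potential.hi
        self._grid = np.linspace(self.lo, self.hi, self.GRID_POINTS)
        self._grid_dx = self._grid[1] - self._grid[0]
        self._bias_force = np.zeros(self.GRID_POINTS)
        self._cache_key: tuple[int, int] | None = None

    def reseed(self, seed_sequence: np.random.SeedSequence) -> None:
        self.rng = np.random.default_rng(seed_sequence)

    def cv_values(self) -> np.ndarray:
        return self.x.copy()

    def _sync_bias_grid(self, bias: BiasState) -> None:
        key = (id(bias), len(bias.hills))
        if self._cache_key == key:
            return
        start = 0
        if self._cache_key is not None and self._cache_key[0] == id(bias) and self._cache_key[1] <= len(bias.hills):
            start = self._cache_key[1]
        else:
            self._bias_force[:] = 0.0
        for hill in bias.hills[start:]:
            d = self._grid - hill.center
            self._bias_force -= -hill.height * d / hill.width**2 * np.exp(
                -(d**2) / (2.0 * hill.width**2)
            )
        self._cache_key = key

    def advance(
        self,
        duration: float,
        bias: BiasState | None = None,
        record_every: float | None = None,
    ) -> list[tuple[float, np.ndarray]] | None:
        n_steps = int(round(duration / self.dt))
        mob = self.dt / self.friction
        sigma = float(np.sqrt(2.0 * self.kT * self.dt / self.friction))
        noise = self.rng.standard_normal((n_steps, self.x.size)) * sigma
        rec_stride = (
            None if record_every is None else max(int(round(record_every / self.dt)), 1)
        )
        records = [] if record_every is not None else None
        bias_dim = None
        if bias is not None and bias.hills:
            self._sync_bias_grid(bias)
            bias_dim = bias.cv_index
        grid = self._bias_force
        lo, hi, dx = self.lo, self.hi, self._grid_dx
        npts = self.GRID_POINTS
        ndim = self.potential.ndim
        fs = self.potential.force_scalar
        coords = [float(v) for v in self.x]

        def wall(v: float) -> float:
            while v < lo or v > hi:
                if v < lo:
                    v = 2.0 * lo - v
                else:
                    v = 2.0 * hi - v
            return v

        for k in range(n_steps):
            f = list(fs(*coords))
            if bias_dim is not None:
                xb = coords[bias_dim]
                u = (xb - lo) / dx
                i0 = int(u)
                if i0 < 0:
                    i0 = 0
                elif i0 > npts - 2:
                    i0 = npts - 2
                w = u - i0
                f[bias_dim] += grid[i0] * (1.0 - w) + grid[i0 + 1] * w
            row = noise[k]
            for d in range(ndim):
                coords[d] = wall(coords[d] + f[d] * mob + row[d])
            if records is not None and (k + 1) % rec_stride == 0:
                records.append(((k + 1) * self.dt, np.array(coords)))
        if not all(np.isfinite(coords)):
            raise SamplerDivergence(f"Langevin trajectory diverged (x={coords}); reduce dt")
        self.x = np.array(coords)
        return records


class TorsionMCSampler:
    """Metropolis Monte Carlo in (phi, psi, chi) space for a peptide.

    One sweep (one single-angle move per movable angle on average) is
    bookkept as 1 ps.  Proposals mix local Gaussian steps with occasional
    uniform redraws (both symmetric, preserving detailed balance with
    respect to exp(-(U + bias)/kT)).  The bias is evaluated through the
    collective-variable layer; coordinates are rebuilt only when the
    biased CV or the excluded-volume term needs them.
    """

    UNIFORM_MOVE_PROB = 0.2

    def __init__(
        self,
        sequence: PeptideSequence,
        energy_model: ToyEnergyModel,
        kT: float,
        move_size: float = 25.0,
        seed: int = 0,
        cv_config: CVConfig | None = None,
        initial_torsions: TorsionProfile | None = None,
        with_chi: bool = True,
    ):
        self.sequence = sequence
        self.model = energy_model
        self.kT = kT
        self.move_size = move_size
        self.rng = np.random.default_rng(seed)
        self.cv_config = cv_config or CVConfig()
        n = len(sequence)
        if initial_torsions is None:
            phi = np.full(n, -135.0)
            psi = np.full(n, 135.0)
            phi[0] = np.nan
            psi[-1] = np.nan
            initial_torsions = TorsionProfile(phi=phi, psi=psi)
        self.phi = initial_torsions.phi.copy()
        self.psi = initial_torsions.psi.copy()
        ref = self.cv_config.chi_reference
        self.chi = np.full((n, 2), np.nan)
        if with_chi:
            for i, aa in enumerate(sequence.residues):
                if aa in ref["chi1"]:
                    self.chi[i, 0] = ref["chi1"][aa]
                if aa in ref["chi2"]:
                    self.chi[i, 1] = ref["chi2"][aa]
        self._conf = self._build()
        if self.model.clash_strength > 0 and not self._clash_energy_ok():
            raise ValueError("starting conformation has overlapping hard cores")
        self._moves = self._movable()

    # -- internal state helpers

    def _build(self) -> Conformation:
        return build_backbone_from_torsions(
            self.sequence,
            TorsionProfile(phi=self.phi, psi=self.psi),
            chi=self.chi,
        )

    def _torsions(self) -> TorsionProfile:
        return TorsionProfile(
            phi=self.phi, psi=self.psi, chi1=self.chi[:, 0], chi2=self.chi[:, 1]
        )

    def _well_energy_residue(self, i: int) -> float:
        e = 0.0
        for well in self.model.wells:
            dphi = wrap_angle(self.phi[i] - well.phi0)
            dpsi = wrap_angle(self.psi[i] - well.psi0)
            if np.isfinite(dphi) and np.isfinite(dpsi):
                e -= well.depth * np.exp(
                    -(dphi**2 + dpsi**2) / (2.0 * well.width**2)
                )
        return e

    def _clash_energy(self, conf: Conformation) -> float:
        if self.model.clash_strength <= 0:
            return 0.0
        ca = conf.coords["CA"]
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        iu = np.triu_indices(len(ca), 3)
        r = d[iu]
        close = r < self.model.clash_radius
        return float(
            self.model.clash_strength
            * np.sum((1.0 - r[close] / self.model.clash_radius) ** 2)
        )

    def _clash_energy_ok(self) -> bool:
        return np.isfinite(self._clash_energy(self._conf))

    def _movable(self) -> list[tuple[str, int]]:
        n = len(self.sequence)
        moves = [("phi", i) for i in range(1, n)] + [("psi", i) for i in range(n - 1)]
        for i in range(n):
            if np.isfinite(self.chi[i, 0]):
                moves.append(("chi1", i))
            if np.isfinite(self.chi[i, 1]):
                moves.append(("chi2", i))
        return moves

    # -- public sampler interface

    def reseed(self, seed_sequence: np.random.SeedSequence) -> None:
        self.rng = np.random.default_rng(seed_sequence)

    def cv_values(self) -> np.ndarray:
        return compute_cvs(self._conf, self.cv_config)

    def conformation(self) -> Conformation:
        return self._conf

    def advance(
        self,
        duration: float,
        bias: BiasState | None = None,
        record_every: float | None = None,
    ) -> list[tuple[float, np.ndarray]] | None:
        n_sweeps = int(round(duration))
        records = [] if record_every is not None else None
        rec_stride = None if record_every is None else max(int(round(record_every)), 1)
        b_idx = bias.cv_index if bias is not None else None
        need_coords = self.model.clash_strength > 0 or (
            b_idx is not None and b_idx <= 4
        )
        biased_cv = None
        if b_idx is not None:
            biased_cv = compute_single_cv(
                b_idx, self.sequence, self._conf, self._torsions(), self.cv_config
            )
        clash_old = self._clash_energy(self._conf)
        rng = self.rng
        for sweep in range(n_sweeps):
            for _ in range(len(self._moves)):
                kind, i = self._moves[rng.integers(len(self._moves))]
                if kind in ("phi", "psi"):
                    arr = self.phi if kind == "phi" else self.psi
                    col = None
                else:
                    arr = self.chi
                    col = 0 if kind == "chi1" else 1
                old = arr[i] if col is None else arr[i, col]
                if rng.random() < self.UNIFORM_MOVE_PROB:
                    new = rng.uniform(-180.0, 180.0)
                else:
                    new = float(wrap_angle(old + rng.normal(0.0, self.move_size)))

                backbone_move = col is None
                e_old = self._well_energy_residue(i) if backbone_move else 0.0
                if col is None:
                    arr[i] = new
                else:
                    arr[i, col] = new
                delta = (self._well_energy_residue(i) - e_old) if backbone_move else 0.0

                new_conf = self._conf
                clash_new = clash_old
                if backbone_move and need_coords:
                    new_conf = self._build()
                    clash_new = self._clash_energy(new_conf)
                    delta += clash_new - clash_old

                new_biased = biased_cv
                if b_idx is not None:
                    affects = (backbone_move and b_idx <= 4) or (
                        not backbone_move and b_idx == (5 if kind == "chi1" else 6)
                    )
                    if affects:
                        new_biased = compute_single_cv(
                            b_idx, self.sequence, new_conf, self._torsions(), self.cv_config
                        )
                        delta += bias_energy(bias, new_biased) - bias_energy(bias, biased_cv)

                if delta <= 0.0 or rng.random() < np.exp(-delta / self.kT):
                    if backbone_move and not need_coords:
                        self._conf = None  # rebuilt lazily below
                    else:
                        self._conf = new_conf
                    clash_old = clash_new
                    biased_cv = new_biased
                else:
                    if col is None:
                        arr[i] = old
                    else:
                        arr[i, col] = old
            if records is not None and (sweep + 1) % rec_stride == 0:
                if self._conf is None:
                    self._conf = self._build()
                records.append((float(sweep + 1), self.cv_values()))
        if self._conf is None:
            self._conf = self._build()
        return records


# ---------------------------------------------------------------------------
# exchange moves and the BEM driver


@dataclass
class Replica:
    sampler: object
    bias: BiasState


def _exchange_accept(
    bias_a: BiasState,
    bias_b: BiasState,
    cvs_a: np.ndarray,
    cvs_b: np.ndarray,
    kT: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis decision for swapping two bias potentials.

    Delta = [Va(xa) + Vb(xb) - Va(xb) - Vb(xa)] / kT; acceptance
    min(1, exp(Delta)).  Consumes exactly one RNG draw.
    """
    delta = (
        bias_energy(bias_a, cvs_a[bias_a.cv_index])
        + bias_energy(bias_b, cvs_b[bias_b.cv_index])
        - bias_energy(bias_a, cvs_b[bias_a.cv_index])
        - bias_energy(bias_b, cvs_a[bias_b.cv_index])
    ) / kT
    u = rng.random()
    return bool(delta >= 0.0 or u < np.exp(delta))


def attempt_exchange(replica_a: Replica, replica_b: Replica, kT: float, rng) -> bool:
    """Attempt a bias swap between two replicas at a common time point."""
    ok = _exchange_accept(
        replica_a.bias,
        replica_b.bias,
        replica_a.sampler.cv_values(),
        replica_b.sampler.cv_values(),
        kT,
        rng,
    )
    if ok:
        replica_a.bias, replica_b.bias = replica_b.bias, replica_a.bias
    return ok


@dataclass
class BEMResult:
    """Per-replica-slot outputs of a bias-exchange run.

    A slot keeps one bias for the whole run; an accepted exchange swaps the
    walkers between slots (dynamically identical to swapping the biases,
    and it keeps every sample series attached to a single bias, which is
    what the WHAM stage needs).
    """

    times: np.ndarray
    cv_series: list[np.ndarray]
    bias_states: list[BiasState | None]
    exchange_log: list[tuple[float, int, int, bool]]
    schedule: BEMSchedule
    trajectories: list[Trajectory] | None = None


def run_bem(
    samplers: list,
    cv_assignments: list[int | None],
    schedule: BEMSchedule,
    record_every: float | None = None,
    collect_conformations: bool = False,
) -> BEMResult:
    """Drive a bias-exchange metadynamics run; deterministic given the seed.

    ``cv_assignments`` gives the 0-based biased CV per replica (None for an
    unbiased replica).  Hills are deposited every ``deposit_interval``;
    a random replica pair attempts a bias exchange every
    ``exchange_interval``.
    """
    if len(samplers) != len(cv_assignments):
        raise ValueError("one CV assignment per sampler required")
    n_rep = len(samplers)
    master = np.random.SeedSequence(schedule.seed)
    seqs = master.spawn(n_rep + 1)
    exchange_rng = np.random.default_rng(seqs[n_rep])
    for sampler, ss in zip(samplers, seqs[:n_rep]):
        sampler.reseed(ss)

    biases = [
        BiasState(cv_index=a if a is not None else 0) if a is not None else None
        for a in cv_assignments
    ]
    record_every = record_every if record_every is not None else schedule.deposit_interval

    n_dep = int(round(schedule.total_time / schedule.deposit_interval))
    exch_stride = int(round(schedule.exchange_interval / schedule.deposit_interval))
    kT = schedule.kT

    times: list[float] = []
    series: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    conformations: list[list] = [[] for _ in range(n_rep)]
    conf_times: list[list[float]] = [[] for _ in range(n_rep)]
    exchange_log: list[tuple[float, int, int, bool]] = []

    for k in range(1, n_dep + 1):
        t = k * schedule.deposit_interval
        chunk_times: list[float] | None = None
        for r, sampler in enumerate(samplers):
            recs = sampler.advance(
                schedule.deposit_interval, biases[r], record_every=record_every
            )
            if recs is not None:
                if chunk_times is None:
                    chunk_times = [t - schedule.deposit_interval + dt for dt, _ in recs]
                series[r].extend(v for _, v in recs)
            if collect_conformations and hasattr(sampler, "conformation"):
                conformations[r].append(sampler.conformation())
                conf_times[r].append(t)
        if chunk_times:
            times.extend(chunk_times)
        for r, sampler in enumerate(samplers):
            if biases[r] is not None:
                deposit(biases[r], sampler.cv_values()[biases[r].cv_index], schedule, t)
        if k % exch_stride == 0 and n_rep >= 2:
            i, j = exchange_rng.choice(n_rep, size=2, replace=False)
            i, j = int(i), int(j)
            # an unbiased (neutral) replica enters with zero bias energy
            bi = biases[i] if biases[i] is not None else BiasState(cv_index=0)
            bj = biases[j] if biases[j] is not None else BiasState(cv_index=0)
            ok = _exchange_accept(
                bi, bj, samplers[i].cv_values(), samplers[j].cv_values(), kT, exchange_rng
            )
            if ok:
                samplers[i], samplers[j] = samplers[j], samplers[i]
            exchange_log.append((t, i, j, ok))

    trajectories = None
    if collect_conformations:
        trajectories = []
        for r in range(n_rep):
            if conformations[r]:
                trajectories.append(
                    Trajectory(
                        sequence=conformations[r][0].sequence,
                        frames=conformations[r],
                        times=np.array(conf_times[r]),
                        replica_id=r,
                    )
                )
    return BEMResult(
        times=np.array(times),
        cv_series=[np.array(s) if s else np.empty((0, 0)) for s in series],
        bias_states=biases,
        exchange_log=exchange_log,
        schedule=schedule,
        trajectories=trajectories,
    )
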