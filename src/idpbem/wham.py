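"""Free-energy reconstruction from biased runs.

The CV space is divided into a regular grid; per-replica frame histograms
are combined by the weighted-histogram self-consistency equations

    p(c) = sum_r n_r(c) / sum_r N_r exp((f_r - b_r(c)) / kT)
    f_r  = -kT log sum_c p(c) exp(-b_r(c) / kT)

with b_r the (static) metadynamics bias of replica r evaluated at the cell
centre of its biased CV.  The converged grid is normalized so the global
minimum is exactly zero; frames are then stratified into 5 kJ/mol free-
energy windows for structural analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .bem import KB, BEMSchedule, BiasState, bias_energy, time_averaged_bias

logger = logging.getLogger(__name__)

DEFAULT_EQUILIBRATION_FRACTION = 0.06  # discard, mirroring 30 ns of 500 ns
WINDOW_WIDTH = 5.0  # kJ/mol
N_WINDOWS = 5


class WhamError(RuntimeError):
    pass


@dataclass(frozen=True)
class CVGridSpec:
    """Regular grid over a subset of the CVs.

    ``cv_indices`` selects columns of the CV series; bins are half-open
    [lo, hi) except the last, which is closed.
    """

    cv_indices: tuple[int, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    bins: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.cv_indices) == len(self.lower) == len(self.upper) == len(self.bins)):
            raise ValueError("grid spec fields must have equal length")
        for lo, hi, nb in zip(self.lower, self.upper, self.bins):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("grid bounds must be finite with lower < upper")
            if nb < 2:
                raise ValueError("need at least 2 bins per dimension")

    @property
    def ndim(self) -> int:
        return len(self.cv_indices)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.bins)

    def edges(self, dim: int) -> np.ndarray:
        return np.linspace(self.lower[dim], self.upper[dim], self.bins[dim] + 1)

    def centers(self, dim: int) -> np.ndarray:
        e = self.edges(dim)
        return 0.5 * (e[:-1] + e[1:])

    def cell_of(self, cv_values: np.ndarray) -> tuple[int, ...] | None:
        """Cell multi-index of a full CV vector, or None when out of range."""
        idx = []
        for d, ci in enumerate(self.cv_indices):
            v = cv_values[ci]
            if v < self.lower[d] or v > self.upper[d]:
                return None
            e = self.edges(d)
            k = int(np.searchsorted(e, v, side="right")) - 1
            if k == self.bins[d]:  # closed upper edge of the final bin
                k -= 1
            idx.append(k)
        return tuple(idx)


@dataclass
class FreeEnergyGrid:
    """Free energy (kJ/mol) on a CV grid; unvisited cells are +inf."""

    grid_spec: CVGridSpec
    values: np.ndarray
    visited: np.ndarray
    kT: float
    meta: dict = field(default_factory=dict)

    def normalize(self) -> "FreeEnergyGrid":
        """Pin the minimum over visited cells to exactly zero (idempotent)."""
        if not self.visited.any():
            raise WhamError("no visited cells to normalize")
        self.values = self.values - self.values[self.visited].min()
        self.values[~self.visited] = np.inf
        return self


def histogram_frames(
    cv_series: list[np.ndarray],
    grid_spec: CVGridSpec,
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION,
) -> tuple[list[np.ndarray], list[int]]:
    """Per-replica cell counts after an equilibration cut.

    Returns (counts, out_of_range) with frame conservation:
    counts.sum() + out_of_range = retained frames, per replica.
    """
    edges = [grid_spec.edges(d) for d in range(grid_spec.ndim)]
    counts, oor = [], []
    total_in = 0
    for series in cv_series:
        if series.size == 0:
            counts.append(np.zeros(grid_spec.shape))
            oor.append(0)
            continue
        cut = int(np.floor(equilibration_fraction * len(series)))
        kept = series[cut:, list(grid_spec.cv_indices)]
        h, _ = np.histogramdd(kept, bins=edges)
        counts.append(h)
        oor.append(len(kept) - int(h.sum()))
        total_in += int(h.sum())
    if total_in == 0:
        raise WhamError("all frames fall outside the grid")
    return counts, oor


def _replica_bias_on_grid(
    bias: BiasState | None,
    grid_spec: CVGridSpec,
    schedule: BEMSchedule | None,
    bias_mode: str,
) -> np.ndarray:
    """Static bias of one replica evaluated at every cell centre."""
    shape = grid_spec.shape
    if bias is None or not bias.hills:
        return np.zeros(shape)
    if bias.cv_index not in grid_spec.cv_indices:
        logger.warning(
            "replica biased on CV %d which is not a grid dimension; its bias "
            "is treated as constant over the grid",
            bias.cv_index,
        )
        return np.zeros(shape)
    dim = grid_spec.cv_indices.index(bias.cv_index)
    centers = grid_spec.centers(dim)
    if bias_mode == "final":
        b1 = bias_energy(bias, centers)
    elif bias_mode == "time_average":
        t_end = max(h.deposit_time for h in bias.hills)
        b1 = time_averaged_bias(bias, centers, 0.35 * t_end, t_end)
    else:
        raise ValueError("bias_mode must be 'final' or 'time_average'")
    expand = [None] * grid_spec.ndim
    expand[dim] = slice(None)
    return np.broadcast_to(b1[tuple(expand)], shape).copy()


def _check_overlap(counts: list[np.ndarray]) -> None:
    active = [i for i, c in enumerate(counts) if c.sum() > 0]
    if len(active) < 2:
        return
    parent = {i: i for i in active}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in active:
        for b in active:
            if b <= a:
                continue
            if ((counts[a] > 0) & (counts[b] > 0)).any():
                parent[find(a)] = find(b)
    roots = {find(i) for i in active}
    if len(roots) > 1:
        comps = [[i for i in active if find(i) == r] for r in roots]
        raise WhamError(
            f"replica histograms do not overlap; disconnected components: {comps}"
        )


def wham_combine(
    histograms: list[np.ndarray],
    bias_histories: list[BiasState | None],
    kT: float,
    grid_spec: CVGridSpec,
    schedule: BEMSchedule | None = None,
    tol: float = 1e-6,
    max_iter: int = 100000,
    bias_mode: str = "time_average",
) -> FreeEnergyGrid:
    """Self-consistent WHAM combination of replica histograms.

    ``bias_mode`` selects the static-bias approximation of each replica's
    metadynamics bias: its final state, or its time average over the last
    65% of the deposition history (default; the converged bias of constant-
    height metadynamics fluctuates by O(hill height) and averaging damps
    this).  Iterates until the max free-energy change is below ``tol``.
    """
    if len(histograms) != len(bias_histories):
        raise ValueError("one bias history per histogram required")
    _check_overlap(histograms)

    n = np.stack([h.astype(float).ravel() for h in histograms])  # (R, C)
    n_tot = n.sum(axis=0)
    visited = n_tot > 0
    b = np.stack(
        [
            _replica_bias_on_grid(bh, grid_spec, schedule, bias_mode).ravel()
            for bh in bias_histories
        ]
    )
    log_nr = np.log(n.sum(axis=1).clip(min=1e-300))  # log N_r
    log_cr = -b / kT  # (R, C) log bias Boltzmann factors

    f = np.zeros(len(histograms))  # f_r / kT (dimensionless)
    log_p = np.where(visited, np.log(n_tot.clip(min=1e-300)), -np.inf)
    log_p -= logsumexp(log_p[visited])
    prev_F = None
    for it in range(max_iter):
        # log denominator per cell: logsumexp_r [log N_r + f_r + log c_r]
        log_den = logsumexp(log_nr[:, None] + f[:, None] + log_cr, axis=0)
        with np.errstate(divide="ignore"):
            log_p = np.where(visited, np.log(n_tot.clip(min=1e-300)) - log_den, -np.inf)
        log_p -= logsumexp(log_p[visited])
        f_new = -logsumexp(log_p[None, :] + log_cr, axis=1)
        F = -kT * log_p
        Fv = F[visited] - F[visited].min()
        if prev_F is not None and np.max(np.abs(Fv - prev_F)) < tol:
            f = f_new
            break
        prev_F = Fv
        f = f_new
    else:
        raise WhamError(f"WHAM did not converge within {max_iter} iterations")

    values = np.full(n_tot.shape, np.inf)
    values[visited] = F[visited] - F[visited].min()
    grid = FreeEnergyGrid(
        grid_spec=grid_spec,
        values=values.reshape(grid_spec.shape),
        visited=visited.reshape(grid_spec.shape),
        kT=kT,
        meta={"iterations": it + 1, "bias_mode": bias_mode, "tol": tol},
    )
    return grid.normalize()


def frame_free_energy(cv_values: np.ndarray, grid: FreeEnergyGrid) -> float:
    """Free energy of the cell containing the frame's CVs; NaN when the
    frame is out of grid or in an unvisited cell."""
    cell = grid.grid_spec.cell_of(np.asarray(cv_values, dtype=float))
    if cell is None or not grid.visited[cell]:
        return float("nan")
    return float(grid.values[cell])


@dataclass
class WindowAssignment:
    """Per-frame free-energy window indices.

    Window k covers [5k, 5k+5) kJ/mol; frames above the last boundary or
    in unvisited cells get -1 (out of range).
    """

    indices: np.ndarray
    free_energies: np.ndarray
    window_width: float = WINDOW_WIDTH
    n_windows: int = N_WINDOWS

    def counts(self) -> np.ndarray:
        return np.array([(self.indices == k).sum() for k in range(self.n_windows)])


def assign_windows(
    cv_series: np.ndarray,
    grid: FreeEnergyGrid,
    window_width: float = WINDOW_WIDTH,
    n_windows: int = N_WINDOWS,
) -> WindowAssignment:
    """Assign each frame to its 5 kJ/mol free-energy window."""
    fe = np.array([frame_free_energy(v, grid) for v in np.atleast_2d(cv_series)])
    idx = np.full(len(fe), -1, dtype=int)
    ok = np.isfinite(fe) & (fe < window_width * n_windows)
    idx[ok] = np.floor(fe[ok] / window_width).astype(int)
    return WindowAssignment(
        indices=idx, free_energies=fe, window_width=window_width, n_windows=n_windows
    )


def marginalize(grid: FreeEnergyGrid, keep_cvs: tuple[int, ...]) -> FreeEnergyGrid:
    """Boltzmann-weighted marginal free energy over a CV subset.

    F_marg = -kT log sum exp(-F/kT) over the integrated-out dimensions,
    re-normalized to min 0.  ``keep_cvs`` are CV indices (as in the grid
    spec), kept in the grid's dimension order.
    """
    for cv in keep_cvs:
        if cv not in grid.grid_spec.cv_indices:
            raise ValueError(f"CV {cv} is not a dimension of this grid")
    keep_dims = sorted(grid.grid_spec.cv_indices.index(cv) for cv in keep_cvs)
    drop_dims = tuple(d for d in range(grid.grid_spec.ndim) if d not in keep_dims)
    if not drop_dims:
        return FreeEnergyGrid(
            grid_spec=grid.grid_spec,
            values=grid.values.copy(),
            visited=grid.visited.copy(),
            kT=grid.kT,
            meta=dict(grid.meta),
        ).normalize()
    with np.errstate(divide="ignore"):
        logw = np.where(grid.visited, -grid.values / grid.kT, -np.inf)
    logm = logsumexp(logw, axis=drop_dims)
    visited = np.isfinite(logm)
    values = np.where(visited, -grid.kT * logm, np.inf)
    spec = grid.grid_spec
    new_spec = CVGridSpec(
        cv_indices=tuple(spec.cv_indices[d] for d in keep_dims),
        lower=tuple(spec.lower[d] for d in keep_dims),
        upper=tuple(spec.upper[d] for d in keep_dims),
        bins=tuple(spec.bins[d] for d in keep_dims),
    )
    return FreeEnergyGrid(
        grid_spec=new_spec, values=values, visited=visited, kT=grid.kT, meta=dict(grid.meta)
    ).normalize()


def boltzmann_inversion(counts: np.ndarray, grid_spec: CVGridSpec, kT: float) -> FreeEnergyGrid:
    """-kT log(counts), min-pinned: the unbiased single-histogram estimate."""
    visited = counts > 0
    values = np.full(counts.shape, np.inf)
    with np.errstate(divide="ignore"):
        values[visited] = -kT * np.log(counts[visited])
    return FreeEnergyGrid(
        grid_spec=grid_spec, values=values, visited=visited, kT=kT
    ).normalize()
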