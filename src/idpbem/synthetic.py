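"""Synthetic inputs with known ground truth.

Three generators live here:

* conformational ensembles with prescribed per-residue secondary-structure
  states (alpha, beta-hairpin, polyproline II, coil) at prescribed
  per-frame probabilities plus Gaussian dihedral noise — the parameter-
  recovery target for the structure classifiers;
* a toy torsion-space energy model (periodic dihedral wells + soft-sphere
  excluded volume) for the Monte-Carlo peptide sampler;
* analytic 1D/2D potentials with quadrature-exact free-energy references
  for validating the metadynamics engine and the WHAM estimator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .backbone import (
    ANTIPARALLEL_DIHEDRALS,
    CANONICAL_DIHEDRALS,
    build_backbone_from_torsions,
)
from .colvars import CHI_REFERENCE
from .model import Conformation, PeptideSequence, TorsionProfile, Trajectory

#: hairpin turn dihedrals (psi of the last strand-1 residue; phi/psi of the
#: two turn residues; phi of the first strand-2 residue), refined from a
#: type-I' beta-turn seed so that the two strands form the antiparallel
#: H-bond ladder the strand assigner looks for, without steric overlap
HAIRPIN_TURN = {
    "psi_pre": 154.7,
    "turn1": (-52.3, 93.5),
    "turn2": (84.6, 4.1),
    "phi_post": -113.4,
}

#: exclusion half-widths around the canonical state dihedrals; the coil
#: library draws phi uniformly over (-180, -30) and psi over (-180, 180]
#: outside these boxes, so a coil residue can never fall into a structured
#: classification box
_EXCLUSION_BOXES = [
    (*CANONICAL_DIHEDRALS["H"], 30.0),
    (*CANONICAL_DIHEDRALS["E"], 30.0),
    (*CANONICAL_DIHEDRALS["P"], 30.0),
    (*ANTIPARALLEL_DIHEDRALS, 30.0),
]


def wrap_angle(a):
    """Map angle(s) to (-180, 180]."""
    w = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return w


# ---------------------------------------------------------------------------
# ensembles with prescribed secondary structure


@dataclass(frozen=True)
class BlockSpec:
    """A contiguous residue block that adopts one state per frame with the
    given probability (0-based residue indices, ``stop`` exclusive)."""

    start: int
    stop: int
    state: str
    probability: float

    def __post_init__(self) -> None:
        if self.state not in "HEP":
            raise ValueError("block state must be H, E or P")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
        if self.stop <= self.start:
            raise ValueError("empty block")

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class SSSpec:
    """Per-frame secondary-structure drawing specification.

    Residues outside every block are coil.  Overlapping blocks drawn in the
    same frame are resolved by state priority H > E > P (then block order);
    the realized state matrix returned by the sampler always reflects what
    was actually built.  ``noise_sd`` is the Gaussian dihedral noise in
    degrees applied to structured residues.
    """

    n_residues: int
    blocks: list[BlockSpec] = field(default_factory=list)
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        n = self.n_residues
        for b in self.blocks:
            if b.start < 1 or b.stop > n - 1:
                raise ValueError(
                    f"block {b} touches a chain terminus; terminal residues have "
                    "undefined dihedrals and cannot carry a structured state"
                )
            if b.state == "H" and len(b) < 4:
                raise ValueError("helical blocks need >= 4 residues to be assignable")
            if b.state == "E" and (len(b) < 8 or len(b) % 2):
                raise ValueError("hairpin blocks need an even length >= 8")
            if b.state == "P" and len(b) < 2:
                raise ValueError("PPII blocks need >= 2 residues (run-length rule)")


_PRIORITY = {"H": 0, "E": 1, "P": 2}


def _draw_coil(rng: np.random.Generator) -> tuple[float, float]:
    # negative phi as for L-amino-acid coil; psi unrestricted
    while True:
        phi = rng.uniform(-180.0, -30.0)
        psi = rng.uniform(-180.0, 180.0)
        if not any(
            abs(wrap_angle(phi - p0)) <= eps and abs(wrap_angle(psi - s0)) <= eps
            for p0, s0, eps in _EXCLUSION_BOXES
        ):
            return phi, psi


#: minimum heavy-atom distance (nm) between residues >= 3 apart in sequence;
#: frames below this are sterically self-overlapping and are redrawn
CLASH_DISTANCE = 0.20


def _is_clash_free(conformation: Conformation) -> bool:
    n = len(conformation)
    pts, res = [], []
    for name in ("N", "CA", "C", "O", "CB"):
        arr = conformation.coords[name]
        for i in range(n):
            if np.isfinite(arr[i]).all():
                pts.append(arr[i])
                res.append(i)
    pts = np.array(pts)
    res = np.array(res)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    mask = np.abs(res[:, None] - res[None, :]) >= 3
    return bool(d2[mask].min() >= CLASH_DISTANCE**2)


def _apply_block(
    phi: np.ndarray, psi: np.ndarray, block: BlockSpec, noise, labels: np.ndarray
) -> None:
    b, e = block.start, block.stop
    if block.state == "H":
        p0, s0 = CANONICAL_DIHEDRALS["H"]
        # the carbonyl O co-rotates with the following N, so helical
        # dihedrals on exactly b..e-1 produce i->i+4 turns covering b..e-1
        for i in range(b, e):
            phi[i] = p0 + noise()
            psi[i] = s0 + noise()
        labels[b:e] = "H"
    elif block.state == "P":
        p0, s0 = CANONICAL_DIHEDRALS["P"]
        for i in range(b, e):
            phi[i] = p0 + noise()
            psi[i] = s0 + noise()
        labels[b:e] = "P"
    else:  # antiparallel hairpin: k-strand, 2-residue turn, k-strand
        k = (len(block) - 2) // 2
        p0, s0 = ANTIPARALLEL_DIHEDRALS
        for i in range(b, e):
            phi[i] = p0 + noise()
            psi[i] = s0 + noise()
        t1 = b + k  # first turn residue
        psi[t1 - 1] = HAIRPIN_TURN["psi_pre"] + noise()
        phi[t1], psi[t1] = (v + noise() for v in HAIRPIN_TURN["turn1"])
        phi[t1 + 1], psi[t1 + 1] = (v + noise() for v in HAIRPIN_TURN["turn2"])
        phi[t1 + 2] = HAIRPIN_TURN["phi_post"] + noise()
        # realized strand labels: interior strand residues pair into bridges
        labels[b + 1 : t1] = "E"
        labels[t1 + 2 : e - 1] = "E"


def sample_ensemble(
    sequence: PeptideSequence,
    ss_spec: SSSpec,
    n_frames: int,
    seed: int,
    with_chi: bool = True,
) -> tuple[Trajectory, np.ndarray]:
    """Draw an ensemble and return it with its realized state matrix.

    Per frame, each block independently adopts its state with its stated
    probability; structured residues get canonical dihedrals plus Gaussian
    noise, coil residues are drawn from a broad library excluding all the
    structured dihedral boxes.  Deterministic for a fixed seed.
    """
    if n_frames < 1:
        raise ValueError("need n_frames >= 1")
    if ss_spec.n_residues != len(sequence):
        raise ValueError("spec length does not match sequence")
    for b in ss_spec.blocks:
        if b.state == "H":
            # the i -> i+4 turns of the block need amide donors here
            donors = range(b.start + 3, min(b.stop + 1, len(sequence)))
        elif b.state == "E":
            donors = range(b.start, b.stop)
        else:
            continue
        missing = [i for i in donors if not sequence.has_amide_h(i)]
        if missing:
            raise ValueError(
                f"{b.state} block {b.start}..{b.stop} is infeasible: residues "
                f"{missing} lack the backbone amide H its H-bonds require"
            )
    rng = np.random.default_rng(seed)
    n = len(sequence)
    frames: list[Conformation] = []
    all_labels = np.full((n_frames, n), "C", dtype="U1")

    for f in range(n_frames):
        labels = all_labels[f]
        noise = lambda: rng.normal(0.0, ss_spec.noise_sd)  # noqa: E731

        # block states are drawn once per frame; the steric rejection loop
        # below redraws only dihedrals, so realized state fractions stay
        # unbiased Bernoulli draws
        active = [b for b in ss_spec.blocks if rng.random() < b.probability]
        active.sort(key=lambda b: _PRIORITY[b.state])

        for attempt in range(200):
            labels[:] = "C"
            phi = np.empty(n)
            psi = np.empty(n)
            for i in range(n):
                phi[i], psi[i] = _draw_coil(rng)
            claimed: set[int] = set()
            applied: list[BlockSpec] = []
            for b in active:
                span = set(range(b.start, b.stop))
                if span & claimed:
                    continue  # lower-priority overlapping block is dropped
                _apply_block(phi, psi, b, noise, labels)
                claimed |= span
                applied.append(b)
            for b in applied:
                # capping residues around a helical block: an extended psi
                # keeps a stray coil draw from completing an extra i -> i+4
                # turn on either side (real helices terminate through
                # capping motifs the same way)
                if b.state != "H":
                    continue
                for cap in (b.start - 1, b.stop):
                    if 1 <= cap < n - 1 and cap not in claimed:
                        while True:
                            cap_phi, cap_psi = _draw_coil(rng)
                            if cap_psi >= 120.0:
                                break
                        phi[cap], psi[cap] = cap_phi, cap_psi
            phi[0] = np.nan
            psi[-1] = np.nan
            conf = build_backbone_from_torsions(
                sequence, TorsionProfile(phi=wrap_angle(phi), psi=wrap_angle(psi))
            )
            if _is_clash_free(conf):
                break
        else:
            raise RuntimeError(
                "could not draw a sterically clash-free frame in 200 attempts"
            )

        if with_chi:
            chi = np.full((n, 2), np.nan)
            for i, aa in enumerate(sequence.residues):
                if aa in CHI_REFERENCE["chi1"]:
                    chi[i, 0] = wrap_angle(CHI_REFERENCE["chi1"][aa] + noise())
                if aa in CHI_REFERENCE["chi2"]:
                    chi[i, 1] = wrap_angle(CHI_REFERENCE["chi2"][aa] + noise())
            conf.chi = chi
        frames.append(conf)

    return Trajectory(sequence=sequence, frames=frames), all_labels


# ---------------------------------------------------------------------------
# toy torsion-space energy model


@dataclass(frozen=True)
class TorsionWell:
    """Periodic Gaussian well in (phi, psi), depth in kJ/mol, width in deg."""

    phi0: float
    psi0: float
    depth: float
    width: float

    def __post_init__(self) -> None:
        if self.depth < 0 or self.width <= 0:
            raise ValueError("well depth must be >= 0 and width > 0")


@dataclass(frozen=True)
class ToyEnergyModel:
    """Sum of per-residue torsion wells plus soft-sphere CA repulsion."""

    wells: tuple[TorsionWell, ...] = ()
    clash_radius: float = 0.40  # nm
    clash_strength: float = 0.0  # kJ/mol; 0 disables excluded volume


def alpha_well_model(depth: float = 30.0, width: float = 20.0) -> ToyEnergyModel:
    p0, s0 = CANONICAL_DIHEDRALS["H"]
    return ToyEnergyModel(wells=(TorsionWell(p0, s0, depth, width),))


def toy_energy(
    torsions: TorsionProfile,
    model: ToyEnergyModel,
    conformation: Conformation | None = None,
) -> float:
    """Energy (kJ/mol) of a torsion profile under the toy model.

    The excluded-volume term needs coordinates; it is skipped when no
    conformation is supplied or ``clash_strength`` is 0.
    """
    e = 0.0
    for well in model.wells:
        dphi = wrap_angle(torsions.phi - well.phi0)
        dpsi = wrap_angle(torsions.psi - well.psi0)
        ok = np.isfinite(dphi) & np.isfinite(dpsi)
        e -= well.depth * np.sum(
            np.exp(-(dphi[ok] ** 2 + dpsi[ok] ** 2) / (2.0 * well.width**2))
        )
    if model.clash_strength > 0.0 and conformation is not None:
        ca = conformation.coords["CA"]
        n = len(ca)
        for i in range(n):
            for j in range(i + 3, n):
                r = np.linalg.norm(ca[i] - ca[j])
                if r < model.clash_radius:
                    e += model.clash_strength * (1.0 - r / model.clash_radius) ** 2
    return float(e)


def toy_energy_gradient(
    torsions: TorsionProfile, model: ToyEnergyModel
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of the torsion-well term w.r.t. (phi, psi), in
    kJ/mol/degree.  The excluded-volume term (a function of coordinates)
    has no torsion-space gradient here."""
    dphi_tot = np.zeros(len(torsions))
    dpsi_tot = np.zeros(len(torsions))
    for well in model.wells:
        dphi = wrap_angle(torsions.phi - well.phi0)
        dpsi = wrap_angle(torsions.psi - well.psi0)
        ok = np.isfinite(dphi) & np.isfinite(dpsi)
        g = np.zeros(len(torsions))
        g[ok] = well.depth * np.exp(
            -(dphi[ok] ** 2 + dpsi[ok] ** 2) / (2.0 * well.width**2)
        ) / well.width**2
        dphi_tot += np.where(ok, g * np.nan_to_num(dphi), 0.0)
        dpsi_tot += np.where(ok, g * np.nan_to_num(dpsi), 0.0)
    return dphi_tot, dpsi_tot


# ---------------------------------------------------------------------------
# analytic validation potentials


@dataclass
class AnalyticPotential:
    """Closed-form 1D/2D potential with quadrature free-energy references.

    ``delta_f_ref`` is F(right basin) - F(left basin) at ``kT_ref`` and
    ``barrier_ref`` the profile barrier above the global-minimum basin,
    both computed to 1e-8 at construction.
    """

    kind: str
    params: dict
    ndim: int
    kT_ref: float
    lo: float
    hi: float
    saddle: float
    delta_f_ref: float
    barrier_ref: float

    def energy(self, x):
        raise NotImplementedError

    def force(self, x):
        raise NotImplementedError

    def delta_f(self, kT: float) -> float:
        """Quadrature F(right) - F(left) of the 1D profile at temperature kT."""
        za, _ = quad(lambda x: np.exp(-self.profile(x) / kT), self.lo, self.saddle,
                     epsabs=1e-12, limit=200)
        zb, _ = quad(lambda x: np.exp(-self.profile(x) / kT), self.saddle, self.hi,
                     epsabs=1e-12, limit=200)
        return float(-kT * (np.log(zb) - np.log(za)))

    def profile(self, x):
        """1D free-energy profile along the first coordinate (= U in 1D)."""
        raise NotImplementedError


class _DoubleWell1D(AnalyticPotential):
    def energy(self, x):
        h = self.params["h"]
        t = self.params["tilt"]
        x = np.asarray(x, dtype=float)
        return h * (x**2 - 1.0) ** 2 + t * x

    profile = energy

    def force(self, x):
        h = self.params["h"]
        t = self.params["tilt"]
        x = np.asarray(x, dtype=float)
        return -(4.0 * h * x * (x**2 - 1.0) + t)

    def force_scalar(self, x: float) -> tuple[float]:
        # pure-float fast path for the integrator inner loop
        h = self.params["h"]
        t = self.params["tilt"]
        return (-(4.0 * h * x * (x * x - 1.0) + t),)


class _TwoBasin2D(AnalyticPotential):
    """U(x, y) = h (x^2-1)^2 + tilt x + ky y^2 / 2 + c x y."""

    def energy(self, xy):
        p = self.params
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        return (
            p["h"] * (x**2 - 1.0) ** 2 + p["tilt"] * x + 0.5 * p["ky"] * y**2 + p["c"] * x * y
        )

    def force(self, xy):
        p = self.params
        xy = np.asarray(xy, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        fx = -(4.0 * p["h"] * x * (x**2 - 1.0) + p["tilt"] + p["c"] * y)
        fy = -(p["ky"] * y + p["c"] * x)
        return np.stack([fx, fy], axis=-1)

    def force_scalar(self, x: float, y: float) -> tuple[float, float]:
        p = self.params
        fx = -(4.0 * p["h"] * x * (x * x - 1.0) + p["tilt"] + p["c"] * y)
        fy = -(p["ky"] * y + p["c"] * x)
        return fx, fy

    def profile(self, x):
        # marginal over the Gaussian y-coordinate, closed form up to const
        p = self.params
        x = np.asarray(x, dtype=float)
        return p["h"] * (x**2 - 1.0) ** 2 + p["tilt"] * x - p["c"] ** 2 * x**2 / (2.0 * p["ky"])

    def marginal(self, dim: int, grid: np.ndarray, kT: float) -> np.ndarray:
        """Quadrature 1D marginal free energy on a grid, min-pinned to 0."""
        out = np.empty(len(grid))
        span = max(abs(self.lo), abs(self.hi)) + 4.0
        for i, v in enumerate(grid):
            if dim == 0:
                fn = lambda y: np.exp(-self.energy(np.array([v, y])) / kT)  # noqa: E731
            else:
                fn = lambda x: np.exp(-self.energy(np.array([x, v])) / kT)  # noqa: E731
            z, _ = quad(fn, -span, span, epsabs=1e-12, limit=200)
            out[i] = -kT * np.log(z)
        return out - out.min()


def make_analytic_potential(kind: str, params: dict | None = None, kT: float = 2.744) -> AnalyticPotential:
    """Packaged validation potentials with stored quadrature references.

    Kinds: ``double_well_1d`` (symmetric), ``asymmetric_double_well_1d``,
    ``two_basin_2d``.  Default parameters give well-separated basins with a
    barrier of a few kT at the default temperature (330 K).
    """
    params = dict(params or {})
    defaults = {"h": 6.0, "tilt": 0.0}
    if kind == "double_well_1d":
        pass
    elif kind == "asymmetric_double_well_1d":
        defaults["tilt"] = 1.2
    elif kind == "two_basin_2d":
        defaults.update({"tilt": 0.8, "ky": 4.0, "c": 1.5})
    else:
        raise ValueError(f"unknown analytic potential kind {kind!r}")
    defaults.update(params)
    params = defaults

    cls = _TwoBasin2D if kind == "two_basin_2d" else _DoubleWell1D
    pot = cls(
        kind=kind, params=params, ndim=2 if kind == "two_basin_2d" else 1,
        kT_ref=kT, lo=-2.5, hi=2.5, saddle=0.0,
        delta_f_ref=0.0, barrier_ref=0.0,
    )
    # locate the saddle (profile maximum between the minima) precisely
    left = minimize_scalar(pot.profile, bounds=(pot.lo, 0.0), method="bounded",
                           options={"xatol": 1e-10})
    right = minimize_scalar(pot.profile, bounds=(0.0, pot.hi), method="bounded",
                            options={"xatol": 1e-10})
    top = minimize_scalar(lambda x: -pot.profile(x), bounds=(left.x, right.x),
                          method="bounded", options={"xatol": 1e-10})
    pot.saddle = float(top.x)
    pot.delta_f_ref = pot.delta_f(kT)
    pot.barrier_ref = float(pot.profile(pot.saddle) - min(left.fun, right.fun))
    return pot
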