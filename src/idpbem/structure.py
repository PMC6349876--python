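"""Per-frame structural annotation and free-energy-windowed aggregation.

Secondary structure is assigned by a simplified DSSP: backbone H-bonds are
scored with the classical electrostatic energy

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol, r in A]

and count as hydrogen bonds below -0.5 kcal/mol.  Alpha-helix (H) requires
two consecutive i -> i+4 turns; strand (E) requires a parallel or
antiparallel bridge partner; everything else is coil (C).  Polyproline II
(P) is overlaid on coil residues whose (phi, psi) lie within +/- 29 deg of
(-75 deg, 145 deg) for at least two consecutive residues.  3-10/pi helices
and bends are not distinguished; they fall into C.

SASA is Shrake-Rupley over heavy atoms with deterministic golden-spiral
sphere points; the radius of gyration is mass-weighted over heavy atoms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Conformation, Trajectory, TorsionProfile, compute_torsions

logger = logging.getLogger(__name__)

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
HB_COUPLING = 27.888  # kcal/mol * A

PPII_PHI = -75.0
PPII_PSI = 145.0
PPII_EPS = 29.0

#: heavy-atom van der Waals radii (nm) and masses (amu) by element
ATOM_RADII = {"C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180}
ATOM_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}

PROBE_RADIUS = 0.14  # nm, water probe


# ---------------------------------------------------------------------------
# secondary structure


def hbond_energy_matrix(conformation: Conformation) -> np.ndarray:
    """(L, L) matrix; entry [i, j] is the DSSP energy (kcal/mol) of the
    H-bond donated by NH(j) to CO(i).  NaN where either group is absent."""
    n = len(conformation)
    cO = conformation.coords["O"] * 10.0  # nm -> Angstrom
    cC = conformation.coords["C"] * 10.0
    cN = conformation.coords["N"] * 10.0
    cH = conformation.coords["H"] * 10.0
    e = np.full((n, n), np.nan)
    ok_acc = np.isfinite(cO).all(axis=1) & np.isfinite(cC).all(axis=1)
    ok_don = np.isfinite(cN).all(axis=1) & np.isfinite(cH).all(axis=1)
    for i in range(n):
        if not ok_acc[i]:
            continue
        for j in range(n):
            if not ok_don[j] or abs(i - j) < 2:
                continue
            r_on = np.linalg.norm(cO[i] - cN[j])
            if r_on > 5.2:  # beyond any plausible H-bond
                continue
            r_ch = np.linalg.norm(cC[i] - cH[j])
            r_oh = np.linalg.norm(cO[i] - cH[j])
            r_cn = np.linalg.norm(cC[i] - cN[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                e[i, j] = -9.9
            else:
                e[i, j] = HB_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return e


def assign_ss(conformation: Conformation) -> np.ndarray:
    """Per-residue H/E/C labels (simplified DSSP patterns).

    Residues with missing backbone atoms are labeled C.
    """
    n = len(conformation)
    e = hbond_energy_matrix(conformation)
    hb = np.nan_to_num(e, nan=0.0) < HB_ENERGY_CUTOFF

    labels = np.full(n, "C", dtype="U1")

    # alpha helix: two consecutive i -> i+4 turns cover residues i..i+3
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        turn4[i] = hb[i, i + 4]
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            labels[i : i + 4] = "H"

    # beta bridges (parallel / antiparallel ladder rules)
    bridge = np.zeros(n, dtype=bool)

    def _hb(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and hb[i, j]

    for i in range(n):
        for j in range(i + 3, n):
            para = (_hb(i - 1, j) and _hb(j, i + 1)) or (_hb(j - 1, i) and _hb(i, j + 1))
            anti = (_hb(i, j) and _hb(j, i)) or (_hb(i - 1, j + 1) and _hb(j - 1, i + 1))
            if para or anti:
                bridge[i] = bridge[j] = True
    labels[bridge & (labels != "H")] = "E"
    return labels


def assign_ppii(torsions: TorsionProfile, ss_labels: np.ndarray) -> np.ndarray:
    """Overlay P on coil residues inside the PPII dihedral box, requiring a
    run of at least two consecutive conforming residues."""
    n = len(ss_labels)
    in_box = np.zeros(n, dtype=bool)
    for i in range(n):
        phi, psi = torsions.phi[i], torsions.psi[i]
        if not (np.isfinite(phi) and np.isfinite(psi)):
            continue  # termini are never P
        in_box[i] = (
            ss_labels[i] == "C"
            and abs(phi - PPII_PHI) <= PPII_EPS
            and abs(psi - PPII_PSI) <= PPII_EPS
        )
    out = ss_labels.copy()
    i = 0
    while i < n:
        if in_box[i]:
            j = i
            while j < n and in_box[j]:
                j += 1
            if j - i >= 2:
                out[i:j] = "P"
            i = j
        else:
            i += 1
    return out


def label_conformation(conformation: Conformation) -> np.ndarray:
    """Full H/E/P/C labeling of one frame."""
    labels = assign_ss(conformation)
    return assign_ppii(compute_torsions(conformation), labels)


# ---------------------------------------------------------------------------
# SASA and radius of gyration


def golden_spiral_points(n: int) -> np.ndarray:
    """n deterministic, nearly uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


@dataclass
class SASAProfile:
    """Per-residue and total solvent-accessible surface area (nm^2)."""

    per_residue: np.ndarray
    total: float


def sasa_points(
    points: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Shrake-Rupley accessible area (nm^2) per input atom."""
    if len(points) == 0:
        raise ValueError("SASA of zero atoms is undefined")
    sphere = golden_spiral_points(n_sphere_points)
    expanded = radii + probe_radius
    out = np.zeros(len(points))
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    for i in range(len(points)):
        ri = expanded[i]
        cutoff2 = (ri + expanded) ** 2
        nb = np.where((d2[i] < cutoff2) & (np.arange(len(points)) != i))[0]
        test = points[i] + ri * sphere
        if nb.size:
            dist2 = np.sum((test[:, None, :] - points[nb][None, :, :]) ** 2, axis=-1)
            accessible = (dist2 >= expanded[nb][None, :] ** 2).all(axis=1)
        else:
            accessible = np.ones(n_sphere_points, dtype=bool)
        out[i] = 4.0 * np.pi * ri**2 * accessible.mean()
    return out


def sasa(
    conformation: Conformation,
    probe_radius: float = PROBE_RADIUS,
    n_sphere_points: int = 960,
) -> SASAProfile:
    """Per-residue SASA over the heavy atoms of the reduced atom set."""
    n = len(conformation)
    pts, elements, owner = [], [], []
    for name in ("N", "CA", "C", "O", "CB"):
        arr = conformation.coords.get(name)
        if arr is None:
            continue
        for i in range(n):
            if np.isfinite(arr[i]).all():
                pts.append(arr[i])
                elements.append(name[0])
                owner.append(i)
    areas = sasa_points(
        np.array(pts),
        np.array([ATOM_RADII[el] for el in elements]),
        probe_radius,
        n_sphere_points,
    )
    per_res = np.zeros(n)
    np.add.at(per_res, np.array(owner), areas)
    return SASAProfile(per_residue=per_res, total=float(per_res.sum()))


def radius_of_gyration(conformation: Conformation) -> float:
    """Mass-weighted RMS distance of heavy atoms from the centre of mass (nm)."""
    pts, elements = conformation.heavy_atoms()
    masses = np.array([ATOM_MASSES[el] for el in elements])
    com = np.average(pts, axis=0, weights=masses)
    return float(np.sqrt(np.average(np.sum((pts - com) ** 2, axis=1), weights=masses)))


# ---------------------------------------------------------------------------
# windowed aggregation


@dataclass
class WindowReport:
    """Free-energy-windowed structural summary.

    ``fractions[s][w, r]`` is the fraction of frames labeled s (H/E/P) at
    residue r in window w — relative to the total retained population in
    ``total`` mode (the landscape-figure convention) or to the window's own
    population in ``within`` mode.  ``delta_sasa[w, r]`` subtracts the
    global-minimum window's per-residue mean SASA.
    """

    windows: np.ndarray
    frame_counts: np.ndarray
    fractions: dict[str, np.ndarray]
    mode: str
    delta_sasa: np.ndarray | None = None
    mean_sasa: np.ndarray | None = None
    mean_rg: np.ndarray | None = None

    def to_frame(self):
        """Long-format table: residue, window, metric, value."""
        import pandas as pd

        rows = []
        n_res = self.fractions["H"].shape[1]
        for wi, w in enumerate(self.windows):
            for r in range(n_res):
                for s in ("H", "E", "P"):
                    rows.append((r, int(w), f"frac_{s}", self.fractions[s][wi, r]))
                if self.delta_sasa is not None:
                    rows.append((r, int(w), "delta_sasa", self.delta_sasa[wi, r]))
        return pd.DataFrame(rows, columns=["residue", "window", "metric", "value"])


def window_report(
    labels: np.ndarray,
    window_assignment: np.ndarray,
    sasa_profiles: np.ndarray | None = None,
    rg_values: np.ndarray | None = None,
    mode: str = "total",
) -> WindowReport:
    """Aggregate per-frame annotations over free-energy windows.

    ``labels`` is (F, L) of 'H'/'E'/'P'/'C'; ``window_assignment`` is (F,)
    window indices with negative values marking out-of-range frames (they
    are dropped).  Empty windows are excluded with a notice.
    """
    if mode not in ("total", "within"):
        raise ValueError("mode must be 'total' or 'within'")
    labels = np.asarray(labels)
    wa = np.asarray(window_assignment)
    keep = wa >= 0
    labels = labels[keep]
    wa = wa[keep]
    if sasa_profiles is not None:
        sasa_profiles = np.asarray(sasa_profiles)[keep]
    if rg_values is not None:
        rg_values = np.asarray(rg_values)[keep]

    present = np.unique(wa)
    n_total = len(wa)
    counts = np.array([(wa == w).sum() for w in present])
    empty = [w for w in range(int(wa.max()) + 1) if w not in present] if len(wa) else []
    if empty:
        logger.info("windows with no frames excluded from report: %s", empty)

    n_res = labels.shape[1]
    fractions = {s: np.zeros((len(present), n_res)) for s in "HEP"}
    for wi, w in enumerate(present):
        sub = labels[wa == w]
        denom = n_total if mode == "total" else len(sub)
        for s in "HEP":
            fractions[s][wi] = (sub == s).sum(axis=0) / denom

    delta_sasa = mean_sasa = mean_rg = None
    if sasa_profiles is not None:
        per_window = np.array([sasa_profiles[wa == w].mean(axis=0) for w in present])
        ref = per_window[np.argmin(present)]  # global-minimum window
        delta_sasa = per_window - ref[None, :]
        mean_sasa = per_window.sum(axis=1)
    if rg_values is not None:
        mean_rg = np.array([rg_values[wa == w].mean() for w in present])

    return WindowReport(
        windows=present,
        frame_counts=counts,
        fractions=fractions,
        mode=mode,
        delta_sasa=delta_sasa,
        mean_sasa=mean_sasa,
        mean_rg=mean_rg,
    )


def annotate_trajectory(
    trajectory: Trajectory,
    with_sasa: bool = True,
    n_sphere_points: int = 960,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """(labels (F, L), per-residue SASA (F, L) or None, Rg (F,)) per frame."""
    labels = np.array([label_conformation(c) for c in trajectory.frames])
    rg = np.array([radius_of_gyration(c) for c in trajectory.frames])
    sas = None
    if with_sasa:
        sas = np.array(
            [sasa(c, n_sphere_points=n_sphere_points).per_residue for c in trajectory.frames]
        )
    return labels, sas, rg
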