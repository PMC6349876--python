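"""Peptide backbone construction from dihedral angles.

Chains are grown by sequential internal-coordinate placement (NeRF) with
ideal bond lengths and angles; carbonyl O, CB and the amide H are then
placed by ideal local geometry.  Glycine receives a constructed pseudo-CB
at the ideal tetrahedral position so that the fragment CVs (which need a
five-atom set per residue) are defined for every residue.
"""
from __future__ import annotations

import numpy as np

from .geometry import place_atom
from .model import Conformation, PeptideSequence, TorsionProfile

# ideal backbone geometry, lengths in nm and angles in degrees
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1229
BOND_CA_CB = 0.1530
BOND_N_H = 0.101
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.1
OMEGA = 180.0

#: improper torsion N-C-CA-CB placing CB with L-amino-acid chirality
CB_IMPROPER = 122.6

#: canonical (phi, psi) in degrees for the generator's secondary-structure
#: states: alpha helix, (parallel-type) beta strand, polyproline II
CANONICAL_DIHEDRALS = {
    "H": (-57.8, -47.0),
    "E": (-119.0, 113.0),
    "P": (-75.0, 145.0),
}
#: antiparallel-sheet strand dihedrals used for the antiparallel template
ANTIPARALLEL_DIHEDRALS = (-140.0, 135.0)

_EXTENDED = (-135.0, 135.0)  # fallback for undefined terminal angles

_D2R = np.pi / 180.0


def _place_f(ax, ay, az, bx, by, bz, cx, cy, cz, bond, cos_t, sin_t, chi_deg):
    """Pure-float NeRF placement (inner-loop fast path of place_atom)."""
    chi = chi_deg * _D2R
    dlx = -bond * cos_t
    dly = bond * sin_t * np.cos(chi)
    dlz = bond * sin_t * np.sin(chi)
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    ln = (bcx * bcx + bcy * bcy + bcz * bcz) ** 0.5
    bcx, bcy, bcz = bcx / ln, bcy / ln, bcz / ln
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    ln = (nx * nx + ny * ny + nz * nz) ** 0.5
    nx, ny, nz = nx / ln, ny / ln, nz / ln
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    return (
        cx + bcx * dlx + mx * dly + nx * dlz,
        cy + bcy * dlx + my * dly + ny * dlz,
        cz + bcz * dlx + mz * dly + nz * dlz,
    )


def _place_batch(a, b, c, bond, angle_deg, torsion_deg):
    """Vectorized NeRF placement for (n, 3) anchor triples."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = np.stack(
        [
            np.broadcast_to(-bond * np.cos(theta), chi.shape),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    frame = np.stack([bc, m, n], axis=-1)
    return c + np.einsum("nij,nj->ni", frame, d_local)


def build_backbone_from_torsions(
    sequence: PeptideSequence,
    torsions: TorsionProfile,
    chi: np.ndarray | None = None,
) -> Conformation:
    """Build a reduced-atom conformation realizing the given phi/psi.

    Undefined (NaN) angles at chain termini fall back to extended values;
    ``compute_torsions`` on the result round-trips the defined angles.
    Optional ``chi`` (L, 2) side-chain dihedrals are attached as metadata.
    """
    n = len(sequence)
    phi = np.where(np.isfinite(torsions.phi), torsions.phi, _EXTENDED[0])
    psi = np.where(np.isfinite(torsions.psi), torsions.psi, _EXTENDED[1])

    cN = np.empty((n, 3))
    cCA = np.empty((n, 3))
    cC = np.empty((n, 3))

    # first residue in a canonical frame
    cN[0] = (0.0, 0.0, 0.0)
    cCA[0] = (BOND_N_CA, 0.0, 0.0)
    th = np.radians(180.0 - ANGLE_N_CA_C)
    cC[0] = cCA[0] + BOND_CA_C * np.array([np.cos(th), np.sin(th), 0.0])

    cos_cn = np.cos(np.radians(ANGLE_CA_C_N))
    sin_cn = np.sin(np.radians(ANGLE_CA_C_N))
    cos_nca = np.cos(np.radians(ANGLE_C_N_CA))
    sin_nca = np.sin(np.radians(ANGLE_C_N_CA))
    cos_cac = np.cos(np.radians(ANGLE_N_CA_C))
    sin_cac = np.sin(np.radians(ANGLE_N_CA_C))
    nx, ny, nz = cN[0]
    ax, ay, az = cCA[0]
    cx, cy, cz = cC[0]
    for i in range(1, n):
        n2 = _place_f(nx, ny, nz, ax, ay, az, cx, cy, cz, BOND_C_N, cos_cn, sin_cn, psi[i - 1])
        a2 = _place_f(ax, ay, az, cx, cy, cz, *n2, BOND_N_CA, cos_nca, sin_nca, OMEGA)
        c2 = _place_f(cx, cy, cz, *n2, *a2, BOND_CA_C, cos_cac, sin_cac, phi[i])
        cN[i] = n2
        cCA[i] = a2
        cC[i] = c2
        nx, ny, nz = n2
        ax, ay, az = a2
        cx, cy, cz = c2

    # carbonyl O anti to the next amide N in the peptide plane
    cO = _place_batch(cN, cCA, cC, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    cCB = _place_batch(
        cN, cC, cCA, BOND_CA_CB, ANGLE_C_CA_CB, np.full(n, CB_IMPROPER)
    )

    conf = Conformation(
        sequence=sequence,
        coords={"N": cN, "CA": cCA, "C": cC, "O": cO, "CB": cCB},
        chi=None if chi is None else np.asarray(chi, dtype=float),
    )
    conf.coords["H"] = reconstruct_amide_hydrogens(conf)
    return conf


def reconstruct_amide_hydrogens(conformation: Conformation) -> np.ndarray:
    """Amide H on the bisector-opposed N direction (N-H = 0.101 nm).

    Prolines and the N-terminal residue get NaN: they carry no backbone
    amide hydrogen.
    """
    n = len(conformation)
    cN = conformation.coords["N"]
    cCA = conformation.coords["CA"]
    cC = conformation.coords["C"]
    out = np.full((n, 3), np.nan)
    has_h = np.array([conformation.sequence.has_amide_h(i) for i in range(n)])
    fin_C = np.isfinite(cC).all(axis=1)
    fin_N = np.isfinite(cN).all(axis=1)
    fin_CA = np.isfinite(cCA).all(axis=1)
    ok = has_h[1:] & fin_C[:-1] & fin_N[1:] & fin_CA[1:]
    idx = np.where(ok)[0] + 1
    if idx.size:
        u = cCA[idx] - cN[idx]
        v = cC[idx - 1] - cN[idx]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        d = -(u + v)
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        out[idx] = cN[idx] + BOND_N_H * d
    return out


def uniform_profile(n: int, phi: float, psi: float) -> TorsionProfile:
    """TorsionProfile with one (phi, psi) at every residue (termini NaN)."""
    phis = np.full(n, float(phi))
    psis = np.full(n, float(psi))
    phis[0] = np.nan
    psis[-1] = np.nan
    return TorsionProfile(phi=phis, psi=psis)
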