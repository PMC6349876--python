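"""The seven collective variables (CVs) used to bias and analyse the
peptide ensemble.

CV1-CV3 count 6-residue fragments whose backbone matches an ideal
alpha-helix / parallel-sheet / antiparallel-sheet template, through a
rational switching function of the superposition RMSD,

    n(RMSD) = (1 - (RMSD/r0)^8) / (1 - (RMSD/r0)^12),   r0 = 0.08 nm.

CV4 (hydrophobic) and CV5 (salt bridges) are contact numbers
C_N = sum_ij (1 - (r_ij/r0)^n) / (1 - (r_ij/r0)^m) over side-chain
interaction-site pairs.  CV6/CV7 measure side-chain chi1/chi2 similarity
to folded-protein reference angles, sum_i (1 + cos(chi_i - chi_ref))/2.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .backbone import (
    ANTIPARALLEL_DIHEDRALS,
    CANONICAL_DIHEDRALS,
    build_backbone_from_torsions,
    uniform_profile,
)
from .geometry import kabsch_rmsd
from .model import (
    Conformation,
    CVRecord,
    PeptideSequence,
    TorsionProfile,
    Trajectory,
    compute_torsions,
)

logger = logging.getLogger(__name__)

CV_NAMES = (
    "alpha_rmsd",
    "para_beta_rmsd",
    "anti_beta_rmsd",
    "hydrophobic_contacts",
    "salt_bridge_contacts",
    "chi1_similarity",
    "chi2_similarity",
)

HYDROPHOBIC_TYPES = set("AVLIMFWP")
ACIDIC_TYPES = set("DE")
BASIC_TYPES = set("RK")

#: author residue numbers of the hydrophobic-core side chains used for the
#: hydrophobic contact CV in the UVR8 C-terminal peptide
UVR8_HYDROPHOBIC_RESIDUES = (401, 403, 404, 408, 409, 410, 411)

#: folded-protein mean side-chain dihedrals (degrees), one per residue type
#: and angle; proline is excluded (ring-constrained chi).  Values are
#: rotamer-library style means for the dominant rotamer.
CHI_REFERENCE: dict[str, dict[str, float]] = {
    "chi1": {
        "R": -67.0, "N": -65.0, "D": -70.0, "C": -65.0, "Q": -66.0,
        "E": -69.0, "H": -63.0, "I": -61.0, "L": -65.0, "K": -67.0,
        "M": -65.0, "F": -66.0, "S": 64.0, "T": 62.0, "V": 175.0,
        "W": -70.0, "Y": -66.0,
    },
    "chi2": {
        "R": 180.0, "N": -58.0, "D": -15.0, "Q": 180.0, "E": 180.0,
        "H": -75.0, "I": 168.0, "L": 175.0, "K": 180.0, "M": 180.0,
        "F": 80.0, "W": 95.0, "Y": 80.0,
    },
}


@dataclass(frozen=True)
class SwitchingSpec:
    """Rational switch (1 - x^n)/(1 - x^m), x = value / r0."""

    r0: float
    n_exp: int
    m_exp: int

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not 0 < self.n_exp < self.m_exp:
            raise ValueError("need 0 < n < m for a monotone decreasing switch")


RMSD_SWITCH = SwitchingSpec(r0=0.08, n_exp=8, m_exp=12)
HYDROPHOBIC_SWITCH = SwitchingSpec(r0=0.40, n_exp=6, m_exp=12)
HYDROPHOBIC_SWITCH_WIDE = SwitchingSpec(r0=0.45, n_exp=6, m_exp=12)  # preset
SALT_BRIDGE_SWITCH = SwitchingSpec(r0=0.35, n_exp=6, m_exp=12)


def switching(value, spec: SwitchingSpec):
    """Evaluate the rational switch; total function on value >= 0.

    The removable singularity at value = r0 takes its analytic limit n/m.
    Implemented through expm1/log so the ratio stays accurate arbitrarily
    close to the singularity.  Accepts scalars or arrays.
    """
    x = np.asarray(value, dtype=float) / spec.r0
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    at_zero = x <= 0.0
    at_one = np.isclose(x, 1.0, rtol=0.0, atol=1e-13)
    regular = ~(at_zero | at_one)
    out[at_zero] = 1.0
    out[at_one] = spec.n_exp / spec.m_exp
    if regular.any():
        lx = np.log(x[regular])
        out[regular] = np.expm1(spec.n_exp * lx) / np.expm1(spec.m_exp * lx)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# fragment templates


@dataclass(frozen=True)
class FragmentTemplate:
    """Ideal 6-residue reference fragment: 30 points (6 x N,CA,C,O,CB)."""

    kind: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        if self.coordinates.shape != (30, 3):
            raise ValueError("template must have exactly 30 atom positions")


_TEMPLATE_ATOMS = ("N", "CA", "C", "O", "CB")
_SHEET_STRAND_SEPARATION = 0.48  # nm, typical CA-CA inter-strand spacing


def _interior_fragment(phi: float, psi: float, n_res: int) -> np.ndarray:
    """(n_res*5, 3) coordinates of interior residues of an ideal chain."""
    total = n_res + 2
    seq = PeptideSequence("A" * max(total, 7))
    conf = build_backbone_from_torsions(seq, uniform_profile(len(seq), phi, psi))
    pts = []
    for i in range(1, 1 + n_res):
        for name in _TEMPLATE_ATOMS:
            pts.append(conf.coords[name][i])
    return np.array(pts)


def _principal_frame(points: np.ndarray, axis_vec: np.ndarray) -> np.ndarray:
    """Rotation taking axis_vec to +x, deterministically completed."""
    x = axis_vec / np.linalg.norm(axis_vec)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(x, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    z = np.cross(x, ref)
    z /= np.linalg.norm(z)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def build_template(kind: str) -> FragmentTemplate:
    """Construct the ideal fragment template for one CV kind.

    ``alpha`` is six consecutive residues of an ideal helix; the sheet
    kinds are two ideal 3-residue strands placed side by side 0.48 nm
    apart, co-directional (parallel) or opposed (antiparallel).
    """
    if kind == "alpha":
        coords = _interior_fragment(*CANONICAL_DIHEDRALS["H"], 6)
        return FragmentTemplate(kind=kind, coordinates=coords - coords.mean(axis=0))
    if kind in ("para_beta", "anti_beta"):
        phi, psi = (
            CANONICAL_DIHEDRALS["E"] if kind == "para_beta" else ANTIPARALLEL_DIHEDRALS
        )
        strand = _interior_fragment(phi, psi, 3)
        strand = strand - strand.mean(axis=0)
        ca = strand[1::5]
        rot = _principal_frame(strand, ca[2] - ca[0])
        strand = strand @ rot.T
        if kind == "anti_beta":
            flip = np.diag([-1.0, 1.0, -1.0])  # pi rotation about y
            other = strand @ flip.T
        else:
            other = strand.copy()
        other = other + np.array([0.0, _SHEET_STRAND_SEPARATION, 0.0])
        coords = np.vstack([strand, other])
        return FragmentTemplate(kind=kind, coordinates=coords - coords.mean(axis=0))
    raise ValueError(f"unknown template kind {kind!r}")


_TEMPLATE_CACHE: dict[str, FragmentTemplate] = {}


def get_template(kind: str) -> FragmentTemplate:
    if kind not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[kind] = build_template(kind)
    return _TEMPLATE_CACHE[kind]


# ---------------------------------------------------------------------------
# CV1-CV3: secondary-structure fragment counts


def _residue_stack(conformation: Conformation) -> np.ndarray:
    """(L, 5, 3) stacked N,CA,C,O,CB coordinates; raises on missing atoms."""
    arrs = [conformation.coords[name] for name in _TEMPLATE_ATOMS]
    stack = np.stack(arrs, axis=1)
    if not np.isfinite(stack).all():
        bad = np.where(~np.isfinite(stack).all(axis=(1, 2)))[0]
        raise ValueError(f"missing backbone/CB atoms in residues {bad.tolist()}")
    return stack


def _batched_switched_rmsd(
    blocks: np.ndarray, template: np.ndarray, spec: SwitchingSpec
) -> np.ndarray:
    """Switched Kabsch RMSD of many 30-point blocks against one template."""
    a = blocks - blocks.mean(axis=1, keepdims=True)
    b = template - template.mean(axis=0)
    h = np.einsum("nai,aj->nij", a, b)
    _, s, _ = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(h))
    sign[sign == 0] = 1.0
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    msd = (np.sum(a**2, axis=(1, 2)) + np.sum(b**2) - 2.0 * trace) / len(template)
    rmsd = np.sqrt(np.clip(msd, 0.0, None))
    return switching(rmsd, spec)


def ss_rmsd_cv(
    conformation: Conformation,
    kind: str,
    spec: SwitchingSpec = RMSD_SWITCH,
    min_strand_separation: int = 4,
    strands_cutoff: float = 1.0,
) -> float:
    """Secondary-structure fragment count (CV1 alpha, CV2/CV3 sheets).

    For the sheet kinds the 6-residue fragment is a pair of 3-residue
    segments (i..i+2, j..j+2) with j - i >= ``min_strand_separation``;
    only pairs whose segment centroids lie within ``strands_cutoff`` nm
    contribute, which keeps the slowly decaying switch tail from
    accumulating over the many geometrically irrelevant far pairs.
    """
    template = get_template(kind)
    n = len(conformation)
    stack = _residue_stack(conformation)
    if kind == "alpha":
        if n < 6:
            raise ValueError("need at least 6 residues for fragment windows")
        blocks = np.stack([stack[a : a + 6].reshape(30, 3) for a in range(n - 5)])
        return float(np.sum(_batched_switched_rmsd(blocks, template.coordinates, spec)))
    if kind not in ("para_beta", "anti_beta"):
        raise ValueError(f"unknown CV kind {kind!r}")
    ca = conformation.coords["CA"]
    centroids = np.array([ca[i : i + 3].mean(axis=0) for i in range(n - 2)])
    n_seg = n - 2
    ii, jj = np.triu_indices(n_seg, min_strand_separation)
    if ii.size == 0:
        return 0.0
    near = np.linalg.norm(centroids[ii] - centroids[jj], axis=1) <= strands_cutoff
    ii, jj = ii[near], jj[near]
    if ii.size == 0:
        return 0.0
    blocks = np.concatenate(
        [
            np.stack([stack[i : i + 3].reshape(15, 3) for i in ii]),
            np.stack([stack[j : j + 3].reshape(15, 3) for j in jj]),
        ],
        axis=1,
    )
    return float(np.sum(_batched_switched_rmsd(blocks, template.coordinates, spec)))


def n_fragment_windows(n_residues: int, kind: str, min_strand_separation: int = 4) -> int:
    """Upper bound on the fragment count for a chain of given length."""
    if kind == "alpha":
        return max(n_residues - 5, 0)
    n_seg = n_residues - 2
    return sum(max(n_seg - (i + min_strand_separation), 0) for i in range(n_seg))


# ---------------------------------------------------------------------------
# CV4/CV5: contact numbers


@dataclass(frozen=True)
class ContactSet:
    """Unordered-unique site pairs plus their switching spec."""

    pairs: tuple[tuple[int, int], ...]
    switching: SwitchingSpec

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"self-pair ({i}, {j}) not allowed")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)


def hydrophobic_contact_set(
    sequence: PeptideSequence,
    residues: tuple[int, ...] | None = None,
    spec: SwitchingSpec = HYDROPHOBIC_SWITCH,
    min_separation: int = 2,
) -> ContactSet:
    """All unordered pairs among the hydrophobic interaction sites.

    ``residues`` are author numbers (e.g. the named hydrophobic core of the
    UVR8 peptide); when None, every residue of a hydrophobic type is used.
    Sequence-adjacent pairs (|i - j| < min_separation) are excluded.
    """
    if residues is not None:
        idx = [sequence.index_of(r) for r in residues]
    else:
        idx = [i for i, aa in enumerate(sequence.residues) if aa in HYDROPHOBIC_TYPES]
    pairs = tuple(
        (i, j)
        for a, i in enumerate(idx)
        for j in idx[a + 1 :]
        if abs(i - j) >= min_separation
    )
    return ContactSet(pairs=pairs, switching=spec)


def salt_bridge_contact_set(
    sequence: PeptideSequence,
    spec: SwitchingSpec = SALT_BRIDGE_SWITCH,
    min_separation: int = 2,
) -> ContactSet:
    """All (acidic, basic) site pairs: {D, E} x {R, K}."""
    acidic = [i for i, aa in enumerate(sequence.residues) if aa in ACIDIC_TYPES]
    basic = [i for i, aa in enumerate(sequence.residues) if aa in BASIC_TYPES]
    pairs = tuple(
        (i, j) for i in acidic for j in basic if abs(i - j) >= min_separation
    )
    return ContactSet(pairs=pairs, switching=spec)


def contact_cv(conformation: Conformation, contact_set: ContactSet) -> float:
    """Contact number: sum of switched site-site distances over the pairs."""
    if not contact_set.pairs:
        logger.warning("contact CV evaluated on an empty pair set; returning 0")
        return 0.0
    sites = conformation.sidechain_sites()
    idx = np.array(contact_set.pairs)
    d = np.linalg.norm(sites[idx[:, 0]] - sites[idx[:, 1]], axis=1)
    return float(np.sum(switching(d, contact_set.switching)))


# ---------------------------------------------------------------------------
# CV6/CV7: side-chain dihedral similarity


def alphabeta_cv(
    torsions: TorsionProfile,
    sequence: PeptideSequence,
    angle_kind: str,
    chi_reference: dict[str, dict[str, float]] | None = None,
) -> float:
    """Sum of (1 + cos(chi_i - chi_ref)) / 2 over residues with the angle.

    Residues lacking the angle (chemically, or NaN in the profile)
    contribute zero.
    """
    if angle_kind not in ("chi1", "chi2"):
        raise ValueError("angle_kind must be 'chi1' or 'chi2'")
    ref = (chi_reference or CHI_REFERENCE)[angle_kind]
    chis = torsions.chi1 if angle_kind == "chi1" else torsions.chi2
    if chis is None:
        return 0.0
    total = 0.0
    for aa, chi in zip(sequence.residues, chis):
        if aa in ref and np.isfinite(chi):
            total += 0.5 * (1.0 + np.cos(np.radians(chi - ref[aa])))
    return float(total)


def n_contributing_angles(sequence: PeptideSequence, angle_kind: str) -> int:
    ref = CHI_REFERENCE[angle_kind]
    return sum(aa in ref for aa in sequence.residues)


# ---------------------------------------------------------------------------
# the full 7-CV record


@dataclass
class CVConfig:
    """Everything needed to evaluate the seven CVs on one sequence."""

    rmsd_switch: SwitchingSpec = RMSD_SWITCH
    hydrophobic_switch: SwitchingSpec = HYDROPHOBIC_SWITCH
    salt_bridge_switch: SwitchingSpec = SALT_BRIDGE_SWITCH
    hydrophobic_residues: tuple[int, ...] | None = None
    min_separation: int = 2
    min_strand_separation: int = 4
    strands_cutoff: float = 1.0
    chi_reference: dict[str, dict[str, float]] = field(
        default_factory=lambda: CHI_REFERENCE
    )


def uvr8_cv_config() -> CVConfig:
    """CV configuration with the UVR8 hydrophobic-core residue list."""
    return CVConfig(hydrophobic_residues=UVR8_HYDROPHOBIC_RESIDUES)


def compute_cvs(conformation: Conformation, config: CVConfig | None = None) -> np.ndarray:
    """The 7-vector of CV values for one frame."""
    config = config or CVConfig()
    seq = conformation.sequence
    torsions = compute_torsions(conformation)
    cv4_set = hydrophobic_contact_set(
        seq, config.hydrophobic_residues, config.hydrophobic_switch, config.min_separation
    )
    cv5_set = salt_bridge_contact_set(seq, config.salt_bridge_switch, config.min_separation)
    return np.array(
        [
            ss_rmsd_cv(conformation, "alpha", config.rmsd_switch),
            ss_rmsd_cv(
                conformation, "para_beta", config.rmsd_switch,
                config.min_strand_separation, config.strands_cutoff,
            ),
            ss_rmsd_cv(
                conformation, "anti_beta", config.rmsd_switch,
                config.min_strand_separation, config.strands_cutoff,
            ),
            contact_cv(conformation, cv4_set),
            contact_cv(conformation, cv5_set),
            alphabeta_cv(torsions, seq, "chi1", config.chi_reference),
            alphabeta_cv(torsions, seq, "chi2", config.chi_reference),
        ]
    )


def compute_single_cv(
    index: int,
    sequence: PeptideSequence,
    conformation: Conformation | None = None,
    torsions: TorsionProfile | None = None,
    config: CVConfig | None = None,
) -> float:
    """Evaluate one CV (0-based index) without computing the other six.

    CV1-CV5 need coordinates; CV6/CV7 need only the side-chain dihedrals.
    """
    config = config or CVConfig()
    if index in (0, 1, 2):
        kind = ("alpha", "para_beta", "anti_beta")[index]
        if kind == "alpha":
            return ss_rmsd_cv(conformation, kind, config.rmsd_switch)
        return ss_rmsd_cv(
            conformation, kind, config.rmsd_switch,
            config.min_strand_separation, config.strands_cutoff,
        )
    if index == 3:
        cset = hydrophobic_contact_set(
            sequence, config.hydrophobic_residues, config.hydrophobic_switch,
            config.min_separation,
        )
        return contact_cv(conformation, cset)
    if index == 4:
        cset = salt_bridge_contact_set(sequence, config.salt_bridge_switch, config.min_separation)
        return contact_cv(conformation, cset)
    if index in (5, 6):
        if torsions is None:
            torsions = compute_torsions(conformation)
        return alphabeta_cv(torsions, sequence, "chi1" if index == 5 else "chi2",
                            config.chi_reference)
    raise ValueError(f"CV index {index} out of range 0..6")


def compute_all_cvs(trajectory: Trajectory, config: CVConfig | None = None) -> list[CVRecord]:
    """One CVRecord per frame, in fixed CV order; deterministic."""
    records = []
    for k, frame in enumerate(trajectory.frames):
        try:
            values = compute_cvs(frame, config)
        except Exception as exc:
            raise RuntimeError(f"CV evaluation failed at frame {k}: {exc}") from exc
        records.append(CVRecord(time=float(trajectory.times[k]), values=values))
    return records


def cv_records_to_frame(records: list[CVRecord], replica_id: int = 0):
    """CV series as a pandas DataFrame (time_ps, cv1..cv7, replica_id)."""
    import pandas as pd

    data = {"time_ps": [r.time for r in records]}
    for k in range(7):
        data[f"cv{k + 1}"] = [r.values[k] for r in records]
    data["replica_id"] = replica_id
    return pd.DataFrame(data)
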