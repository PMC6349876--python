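"""Domain types for peptide conformational-ensemble analysis.

The study object is a short intrinsically disordered peptide (the 27-residue
C-terminal region of the plant UV-B photoreceptor UVR8, residues 397-423, is
the packaged default), represented at a reduced level of detail: backbone
atoms N, CA, C, O, the amide hydrogen where chemically present, and a CB
(real, or a constructed pseudo-CB for glycine).  Internal length unit is nm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: residues carrying a chi1 (all but Gly/Ala) and a chi2 side-chain dihedral
CHI1_RESIDUES = STANDARD_AA - set("GA")
CHI2_RESIDUES = STANDARD_AA - set("GASCTV")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

#: wild-type UVR8 C-terminal 27-mer (author numbering 397-423) and its
#: P411A point mutant
UVR8_C27_WT = "GKSWVSPAERYAVVPDETGLTDGSSKG"
UVR8_C27_P411A = "GKSWVSPAERYAVVADETGLTDGSSKG"
UVR8_C27_OFFSET = 397

BACKBONE_ATOMS = ("N", "CA", "C", "O", "H", "CB")


class PipelineError(RuntimeError):
    """Base class for package errors."""


class ParseError(PipelineError):
    """Malformed or unsupported input file."""


@dataclass(frozen=True)
class PeptideSequence:
    """One-letter amino-acid sequence with an author-numbering offset.

    ``author_number(i) = numbering_offset + i`` for 0-based residue index i.
    """

    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")
        if len(self.residues) < 7:
            raise ValueError("sequence must have at least 7 residues")

    def __len__(self) -> int:
        return len(self.residues)

    def author_number(self, index: int) -> int:
        return self.numbering_offset + index

    def index_of(self, author_number: int) -> int:
        i = author_number - self.numbering_offset
        if not 0 <= i < len(self.residues):
            raise IndexError(f"author residue number {author_number} out of range")
        return i

    def has_amide_h(self, index: int) -> bool:
        """Prolines and the N-terminal residue carry no backbone amide H."""
        return index != 0 and self.residues[index] != "P"


@dataclass
class Conformation:
    """One frame: per-residue coordinates (nm) of the reduced atom set.

    ``coords`` maps atom name -> (L, 3) array; entries that do not exist
    (amide H on prolines and residue 1) are NaN.  ``coords`` may also hold
    an ``SC`` entry: the side-chain heavy-atom centroid harvested from a
    full-atom input file, used as the contact-CV interaction site (falls
    back to CB when absent).  ``chi`` optionally carries per-residue
    (chi1, chi2) side-chain dihedrals in degrees (NaN where undefined);
    the reduced atom set cannot express them in coordinates.
    """

    sequence: PeptideSequence
    coords: dict[str, np.ndarray]
    chi: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name, arr in self.coords.items():
            if arr.shape != (n, 3):
                raise ValueError(f"coords[{name!r}] has shape {arr.shape}, want ({n}, 3)")

    def __len__(self) -> int:
        return len(self.sequence)

    def atom(self, name: str, index: int) -> np.ndarray:
        return self.coords[name][index]

    def sidechain_sites(self) -> np.ndarray:
        """(L, 3) contact-CV interaction sites: side-chain centroid if the
        input carried full side chains, else CB (pseudo-CB for glycine)."""
        sites = self.coords["CB"].copy()
        sc = self.coords.get("SC")
        if sc is not None:
            ok = np.isfinite(sc).all(axis=1)
            sites[ok] = sc[ok]
        return sites

    def heavy_atoms(self) -> tuple[np.ndarray, list[str]]:
        """All finite heavy-atom coordinates with their element symbols."""
        pts: list[np.ndarray] = []
        elements: list[str] = []
        for name in ("N", "CA", "C", "O", "CB"):
            arr = self.coords.get(name)
            if arr is None:
                continue
            for i in range(len(self.sequence)):
                if np.isfinite(arr[i]).all():
                    pts.append(arr[i])
                    elements.append(name[0])
        return np.array(pts), elements

    def validate(self) -> None:
        """Check chain-connectivity invariants (finite coords, CA-CA range)."""
        ca = self.coords["CA"]
        if not np.isfinite(ca).all():
            raise ValueError("non-finite CA coordinates")
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        if d.size and (d.min() < 0.2 or d.max() > 0.45):
            raise ValueError(
                f"consecutive CA-CA distances outside [0.2, 0.45] nm: "
                f"min {d.min():.3f}, max {d.max():.3f}"
            )


@dataclass
class TorsionProfile:
    """Backbone and side-chain dihedrals (degrees) for one conformation.

    Undefined angles (chain termini, residues lacking the angle) are NaN,
    never silently zero.  All angles lie in (-180, 180].
    """

    phi: np.ndarray
    psi: np.ndarray
    chi1: np.ndarray | None = None
    chi2: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.phi)


@dataclass
class Trajectory:
    """Ordered conformations of one peptide with time stamps (ps)."""

    sequence: PeptideSequence
    frames: list[Conformation]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]
    replica_id: int = 0

    def __post_init__(self) -> None:
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class CVRecord:
    """The 7-vector of collective-variable values for one frame.

    Order is fixed: helix-fragment count, parallel-sheet fragment count,
    antiparallel-sheet fragment count, hydrophobic contacts, salt-bridge
    contacts, chi1 similarity, chi2 similarity.
    """

    time: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (7,):
            raise ValueError("CVRecord expects exactly 7 values")


def compute_torsions(conformation: Conformation) -> TorsionProfile:
    """Backbone phi/psi from coordinates (IUPAC convention); chi1/chi2 are
    passed through from the conformation's stored side-chain dihedrals.

    Termini and residues with missing backbone atoms are flagged NaN.
    """
    n = len(conformation)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    cN = conformation.coords["N"]
    cCA = conformation.coords["CA"]
    cC = conformation.coords["C"]
    for i in range(n):
        if i > 0 and _finite(cC[i - 1], cN[i], cCA[i], cC[i]):
            phi[i] = geometry.dihedral(cC[i - 1], cN[i], cCA[i], cC[i])
        if i < n - 1 and _finite(cN[i], cCA[i], cC[i], cN[i + 1]):
            psi[i] = geometry.dihedral(cN[i], cCA[i], cC[i], cN[i + 1])
    chi1 = chi2 = None
    if conformation.chi is not None:
        chi1 = conformation.chi[:, 0].copy()
        chi2 = conformation.chi[:, 1].copy()
    return TorsionProfile(phi=phi, psi=psi, chi1=chi1, chi2=chi2)


def _finite(*pts: np.ndarray) -> bool:
    return all(np.isfinite(p).all() for p in pts)
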