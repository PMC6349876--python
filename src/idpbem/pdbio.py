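"""Multi-model PDB reading and writing for reduced-atom peptide ensembles.

The on-disk dialect is ordinary PDB (coordinates in Angstrom); internally
everything is nm.  Glycine's constructed pseudo-CB is written under the
atom name ``QB`` so that re-reading never mistakes it for a chemically real
CB.  When a full-atom file is read, side-chain heavy atoms beyond CB are
collapsed into their centroid and kept as the contact-CV interaction site.
"""
from __future__ import annotations

import numpy as np
from pathlib import Path
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .backbone import reconstruct_amide_hydrogens
from .model import (
    AA_1TO3,
    AA_3TO1,
    Conformation,
    ParseError,
    PeptideSequence,
    Trajectory,
)

NM_PER_ANGSTROM = 0.1

_SLOTS = ("N", "CA", "C", "O", "CB")
_BACKBONE_SET = {"N", "CA", "C", "O", "CB", "H", "HN", "QB", "OXT", "H1", "H2", "H3"}


def read_pdb(path, reconstruct_h: bool = True) -> tuple[PeptideSequence, Trajectory]:
    """Read a (multi-)model PDB file into a Trajectory.

    Every MODEL becomes one Conformation; a single-conformation file is one
    model.  Author residue numbers are preserved through the sequence's
    ``numbering_offset``.  Missing amide hydrogens are reconstructed by
    ideal geometry unless ``reconstruct_h`` is False.
    """
    try:
        f = pdb.PDBFile.read(str(path))
        stack = f.get_structure()
    except Exception as exc:  # biotite raises various parse errors
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    arr0 = stack[0]
    chains = np.unique(arr0.chain_id)
    if len(chains) > 1:
        raise ParseError(f"multi-chain PDB files are unsupported (chains {list(chains)})")

    res_ids, res_starts = np.unique(arr0.res_id, return_index=True)
    order = np.argsort(res_starts)
    res_ids = res_ids[order]
    if not (np.diff(res_ids) == 1).all():
        raise ParseError("residue numbering must be consecutive")

    letters = []
    for rid in res_ids:
        name = arr0.res_name[arr0.res_id == rid][0]
        if name not in AA_3TO1:
            raise ParseError(f"non-standard residue {name} at position {rid}")
        letters.append(AA_3TO1[name])
    sequence = PeptideSequence("".join(letters), numbering_offset=int(res_ids[0]))
    n = len(sequence)

    frames = []
    for arr in stack:
        coords = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O", "H", "CB", "SC")}
        for i, rid in enumerate(res_ids):
            mask = arr.res_id == rid
            names = arr.atom_name[mask]
            xyz = arr.coord[mask] * NM_PER_ANGSTROM
            sc_pts = []
            for aname, pt in zip(names, xyz):
                if aname in _SLOTS:
                    coords[aname][i] = pt
                elif aname == "QB":
                    coords["CB"][i] = pt
                elif aname in ("H", "HN"):
                    coords["H"][i] = pt
                elif aname not in _BACKBONE_SET and not aname.startswith("H"):
                    sc_pts.append(pt)
            if sc_pts:
                sc = np.mean(sc_pts, axis=0)
                # centroid over CB + the rest, matching "side chain heavy atoms"
                if np.isfinite(coords["CB"][i]).all():
                    sc = np.mean(np.vstack([sc_pts, coords["CB"][i]]), axis=0)
                coords["SC"][i] = sc
        if not np.isfinite(coords["SC"]).any():
            del coords["SC"]
        conf = Conformation(sequence=sequence, coords=coords)
        if reconstruct_h:
            have = np.isfinite(conf.coords["H"]).all(axis=1)
            rebuilt = reconstruct_amide_hydrogens(conf)
            conf.coords["H"] = np.where(have[:, None], conf.coords["H"], rebuilt)
        frames.append(conf)

    return sequence, Trajectory(sequence=sequence, frames=frames)


def write_pdb(trajectory: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB file (Angstrom on disk)."""
    seq = trajectory.sequence
    n = len(seq)
    first = trajectory.frames[0]
    slots = []  # (atom_name_on_disk, coord_key, residue_index, element)
    for i in range(n):
        aa = seq.residues[i]
        for key in ("N", "CA", "C", "O", "CB", "H"):
            if key not in first.coords or not np.isfinite(first.coords[key][i]).all():
                continue
            disk_name = key
            element = key[0]
            if key == "CB" and aa == "G":
                disk_name = "QB"  # constructed pseudo-CB, not a real atom
            slots.append((disk_name, key, i, element))

    n_atoms = len(slots)
    arrays = []
    for conf in trajectory.frames:
        arr = struc.AtomArray(n_atoms)
        for j, (disk_name, key, i, element) in enumerate(slots):
            pt = conf.coords[key][i]
            if not np.isfinite(pt).all():
                raise ValueError(
                    f"frame atom pattern inconsistent: {key} of residue {i} missing"
                )
            arr.coord[j] = pt / NM_PER_ANGSTROM
            arr.chain_id[j] = "A"
            arr.res_id[j] = seq.author_number(i)
            arr.res_name[j] = AA_1TO3[seq.residues[i]]
            arr.atom_name[j] = disk_name
            arr.element[j] = element
            arr.hetero[j] = False
        arrays.append(arr)

    f = pdb.PDBFile()
    f.set_structure(struc.stack(arrays))
    f.write(str(path))
    if len(arrays) == 1:
        # keep an explicit MODEL/ENDMDL pair even for one conformation
        text = Path(path).read_text()
        if "MODEL" not in text:
            body = [ln for ln in text.splitlines() if ln.strip() and ln != "END"]
            Path(path).write_text(
                "MODEL        1\n" + "\n".join(body) + "\nENDMDL\nEND\n"
            )
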