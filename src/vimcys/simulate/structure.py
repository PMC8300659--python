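"""Toy two-chain cysteine structures and ion trajectories.

Builds a minimal pair of peptide chains (A and B, residues 326-330, one
cysteine each at position 328) whose SG atoms sit at an exact configurable
separation, optionally replicated over frames with Gaussian coordinate
jitter, plus placed ions: "pinned" ions held at a fixed coordination
distance from chain A's SG in every frame (default 2.5 A, the Zn-S bond
length), and "walk" ions performing a random walk far from the protein.
These fixtures exercise the distance, feasibility, and ion-persistence
analyses with known ground truth; they emulate no real structure.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc

from ..geometry import StructureModel, write_pdb
from .presets import StructureArrangement

__all__ = ["make_structure_fixture"]

# residue name, atom name, local offset (A) from the residue anchor
_RESIDUES = (
    ("LEU", (("N", (-0.5, 1.0, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("C", (1.2, -0.6, 0.0)), ("O", (1.3, -1.8, 0.0)))),
    ("GLN", (("N", (-0.5, 1.0, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("C", (1.2, -0.6, 0.0)), ("O", (1.3, -1.8, 0.0)))),
    ("CYS", (("N", (-0.5, 1.0, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("CB", (0.0, 0.0, 1.5)), ("SG", (0.0, 0.0, 3.3)),
             ("C", (1.2, -0.6, 0.0)), ("O", (1.3, -1.8, 0.0)))),
    ("GLU", (("N", (-0.5, 1.0, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("C", (1.2, -0.6, 0.0)), ("O", (1.3, -1.8, 0.0)))),
    ("SER", (("N", (-0.5, 1.0, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("C", (1.2, -0.6, 0.0)), ("O", (1.3, -1.8, 0.0)))),
)
_FIRST_RES_ID = 326  # cysteine lands at residue 328
_CA_SPACING = 3.8  # A along the chain axis


def _chain_atoms(chain_id: str, origin: np.ndarray):
    """One 5-residue chain; returns (annotation rows, coordinates)."""
    rows, coords = [], []
    for i, (res_name, atoms) in enumerate(_RESIDUES):
        anchor = origin + np.array([i * _CA_SPACING, 0.0, 0.0])
        for atom_name, offset in atoms:
            element = "S" if atom_name == "SG" else atom_name[0]
            rows.append((chain_id, _FIRST_RES_ID + i, res_name, atom_name,
                         element, False))
            coords.append(anchor + np.asarray(offset))
    return rows, coords


def make_structure_fixture(arr: StructureArrangement,
                           path=None) -> StructureModel:
    """Build the two-chain fixture (and optionally write it as PDB).

    Frame 1 realizes the exact SG-SG separation ``arr.sg_distance``;
    later frames add Gaussian jitter of ``arr.frame_jitter_sd`` to every
    protein coordinate.  Pinned ions track the (jittered) chain A SG at
    their coordination distance in every frame; walk ions start
    ``walk_offset`` away and diffuse there, so they stay far (>3x any
    reasonable contact cutoff) throughout.
    """
    rng = np.random.default_rng(arr.seed)

    rows_a, coords_a = _chain_atoms("A", np.zeros(3))
    # chain B is a pure translation, so its SG sits exactly sg_distance away
    rows_b, coords_b = _chain_atoms("B", np.array([0.0, arr.sg_distance, 0.0]))
    rows = rows_a + rows_b
    base = np.array(coords_a + coords_b)
    sg_index = next(i for i, r in enumerate(rows)
                    if r[0] == "A" and r[3] == "SG")

    # ion annotation rows appended after the protein
    for k, ion in enumerate(arr.ions):
        rows.append(("I", 900 + k, ion.element.upper(), ion.element.upper(),
                     ion.element.upper(), True))

    n_atoms = len(rows)
    n_prot = len(base)

    # per-frame coordinates
    frames = []
    walk_positions = {}
    for k, ion in enumerate(arr.ions):
        if ion.mode == "walk":
            direction = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
            walk_positions[k] = base[sg_index] + direction * ion.walk_offset
    for f in range(arr.n_frames):
        prot = base.copy()
        if f > 0 and arr.frame_jitter_sd > 0:
            prot = prot + rng.normal(0.0, arr.frame_jitter_sd, size=prot.shape)
        coords = np.zeros((n_atoms, 3))
        coords[:n_prot] = prot
        for k, ion in enumerate(arr.ions):
            if ion.mode == "pinned":
                coords[n_prot + k] = prot[sg_index] + np.array(
                    [0.0, 0.0, ion.contact_distance])
            else:
                if f > 0:
                    walk_positions[k] = walk_positions[k] + rng.normal(
                        0.0, ion.walk_step_sd, size=3)
                coords[n_prot + k] = walk_positions[k]
        frames.append(coords)

    atoms = struc.AtomArray(n_atoms)
    atoms.chain_id = np.array([r[0] for r in rows], dtype="U4")
    atoms.res_id = np.array([r[1] for r in rows], dtype=int)
    atoms.res_name = np.array([r[2] for r in rows], dtype="U5")
    atoms.atom_name = np.array([r[3] for r in rows], dtype="U6")
    atoms.element = np.array([r[4] for r in rows], dtype="U2")
    atoms.hetero = np.array([r[5] for r in rows], dtype=bool)
    atoms.add_annotation("atom_id", dtype=int)
    atoms.atom_id = np.arange(1, n_atoms + 1)

    stack = struc.stack([atoms] * arr.n_frames)
    stack.coord = np.array(frames)
    model = StructureModel(stack=stack)
    if path is not None:
        write_pdb(model, path)
    return model
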