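"""Structure geometry: Cys SG-SG distances, crosslink feasibility, ion contacts.

Works on single- or multi-MODEL PDB files (a multi-MODEL file is treated
as a trajectory of frames with fixed atom ordering).  Three analyses:

* inter-chain cysteine SG-SG separations, the geometric quantity that
  decides whether two thiols can be bridged;
* a feasibility classifier per crosslinker: a thiol crosslinker can bridge
  two SG atoms iff their separation <= spacer_arm + slack, and direct
  disulfide ("oxidative") crosslinking is possible below a 6 A cutoff;
* ion-contact persistence: the fraction of frames in which an ion stays
  within a cutoff of any protein atom, with ions above a 90% threshold
  called persistent.

Distances are internal to each frame, so no superposition is performed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .registry import validate_registry

__all__ = [
    "StructureModel",
    "CysPairDistance",
    "IonPersistence",
    "read_pdb",
    "write_pdb",
    "cys_sg_distances",
    "classify_crosslink_feasibility",
    "ion_contact_persistence",
    "DISULFIDE_CUTOFF",
    "DEFAULT_SLACK",
    "DEFAULT_CONTACT_CUTOFF",
]

#: Maximal SG-SG separation for direct disulfide (oxidative) crosslinking, A.
DISULFIDE_CUTOFF = 6.0
#: Default slack added to a crosslinker's spacer arm, A.  Chosen so the
#: short thiol crosslinker DBB (4.88 A arm) is feasible up to exactly the
#: disulfide cutoff: 4.88 + 1.12 = 6.00 A.
DEFAULT_SLACK = 1.12
#: Default ion-protein contact cutoff, A (covers a 2.5 A Zn-S coordination
#: bond with vibrational margin).
DEFAULT_CONTACT_CUTOFF = 3.0
#: An ion is "persistent" when its contact fraction exceeds this threshold.
PERSISTENCE_THRESHOLD = 0.9


@dataclass
class StructureModel:
    """A structure or trajectory: an atom set replicated over frames."""

    stack: struc.AtomArrayStack  # (frames, atoms)

    @property
    def n_frames(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    def frame(self, index: int) -> struc.AtomArray:
        return self.stack[index]


@dataclass
class CysPairDistance:
    chain_a: str
    chain_b: str
    res_a: int
    res_b: int
    distance: float  # A, SG-SG Euclidean


@dataclass
class IonPersistence:
    ion_serial: int
    element: str
    contact_fraction: float
    persistent: bool
    partner_residues: list[tuple[str, int, str]] = field(default_factory=list)


def _infer_missing_elements(atoms) -> None:
    elem = atoms.element
    names = atoms.atom_name
    for i in range(len(elem)):
        if elem[i] == "" or elem[i] is None:
            name = names[i].strip()
            guess = "".join(c for c in name if c.isalpha())[:2]
            # two-letter elements in these fixtures are metals (ZN, MG, NA)
            elem[i] = guess.upper() if guess.upper() in ("ZN", "MG", "NA", "CL") \
                else name.strip()[0].upper()
    atoms.element = elem


def read_pdb(source: str | Path) -> StructureModel:
    """Parse a PDB file (path or literal content) into a StructureModel.

    All MODELs are read as frames; element symbols missing from columns
    77-78 are inferred from atom names.  Raises ``ValueError`` for files
    without ATOM/HETATM records or with inconsistent atom counts across
    MODELs.
    """
    text = str(source)
    if "\n" in text or text.lstrip()[:6] in ("ATOM  ", "HETATM", "MODEL "):
        pdb = PDBFile.read(io.StringIO(text))
    else:
        pdb = PDBFile.read(str(source))
    try:
        atoms = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on ragged MODELs
        raise ValueError(f"inconsistent or unreadable MODEL records: {exc}") from exc
    if atoms.array_length() == 0:
        raise ValueError("no ATOM/HETATM records found")
    if not np.all(np.isfinite(atoms.coord)):
        raise ValueError("non-finite coordinates")
    _infer_missing_elements(atoms)
    return StructureModel(stack=atoms)


def write_pdb(model: StructureModel, path: str | Path | None = None) -> str:
    """Serialize to fixed-column PDB text; MODEL/ENDMDL for multi-frame.

    Returns the PDB content; also writes it to ``path`` when given.
    """
    stack = model.stack
    if stack.array_length() == 0:
        raise ValueError("refusing to write an empty frame")
    if any(len(str(c)) > 1 for c in np.unique(stack.chain_id)):
        bad = [c for c in np.unique(stack.chain_id) if len(str(c)) > 1]
        raise ValueError(f"chain ids must be single characters for PDB: {bad}")
    if np.any(np.abs(stack.coord) >= 10000.0):
        raise ValueError("coordinates exceed the PDB fixed-column field width")
    pdb = PDBFile()
    structure = stack if model.n_frames > 1 else stack[0]
    pdb.set_structure(structure)
    text = "\n".join(pdb.lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def cys_sg_distances(model: StructureModel, frame: int = 0,
                     inter_chain_only: bool = False) -> list[CysPairDistance]:
    """All CYS SG-SG pair distances in one frame (each pair reported once)."""
    atoms = model.frame(frame)
    mask = (atoms.res_name == "CYS") & (atoms.atom_name == "SG")
    sg = atoms[mask]
    order = np.lexsort((sg.res_id, sg.chain_id))
    sg = sg[order]
    out = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if inter_chain_only and sg.chain_id[i] == sg.chain_id[j]:
                continue
            d = float(np.linalg.norm(sg.coord[i] - sg.coord[j]))
            out.append(CysPairDistance(
                chain_a=str(sg.chain_id[i]), chain_b=str(sg.chain_id[j]),
                res_a=int(sg.res_id[i]), res_b=int(sg.res_id[j]), distance=d,
            ))
    return out


def classify_crosslink_feasibility(distance: float, registry=None,
                                   slack: float = DEFAULT_SLACK) -> dict:
    """Per-crosslinker feasibility of bridging two Cys SG atoms.

    A thiol crosslinker is feasible iff ``distance <= spacer_arm + slack``;
    oxidants (disulfide formation) iff ``distance < 6 A``; amine-reactive
    crosslinkers are not applicable to a Cys pair and reported as such.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if registry is None:
        from .registry import DEFAULT_REGISTRY
        registry = DEFAULT_REGISTRY
    registry = validate_registry(registry)
    disulfide = bool(distance < DISULFIDE_CUTOFF)
    per_agent = {}
    for xl in registry:
        if xl.chemistry == "thiol":
            per_agent[xl.name] = {
                "feasible": bool(distance <= xl.spacer_arm + slack),
                "max_distance": xl.spacer_arm + slack,
            }
        elif xl.chemistry == "oxidant":
            per_agent[xl.name] = {
                "feasible": disulfide,
                "max_distance": DISULFIDE_CUTOFF,
            }
        elif xl.chemistry == "amine":
            per_agent[xl.name] = {"feasible": None,
                                  "note": "amine chemistry; not applicable to Cys"}
        else:  # pragma: no cover - rejected by Crosslinker itself
            raise ValueError(f"unknown chemistry {xl.chemistry!r}")
    return {"distance": float(distance), "disulfide_feasible": disulfide,
            "crosslinkers": per_agent}


def ion_contact_persistence(model: StructureModel,
                            ion_elements=("ZN",),
                            cutoff: float = DEFAULT_CONTACT_CUTOFF,
                            threshold: float = PERSISTENCE_THRESHOLD,
                            ) -> list[IonPersistence]:
    """Fraction of frames each ion stays within ``cutoff`` of the protein.

    "Protein" means all ATOM-record (non-hetero) atoms.  Partner residues
    are ranked by the number of frames in which they lie within the
    cutoff of the ion.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if model.n_frames < 1:
        raise ValueError("need at least one frame")

    stack = model.stack
    elements = {e.upper() for e in ion_elements}
    ion_mask = stack.hetero & np.isin(np.char.upper(stack.element.astype(str)),
                                      list(elements))
    prot_mask = ~stack.hetero
    ion_idx = np.nonzero(ion_mask)[0]
    if ion_idx.size == 0 or not prot_mask.any():
        return []

    prot = stack.coord[:, prot_mask, :]  # (frames, prot_atoms, 3)
    res_keys = [
        (str(c), int(r), str(n))
        for c, r, n in zip(stack.chain_id[prot_mask], stack.res_id[prot_mask],
                           stack.res_name[prot_mask])
    ]
    results = []
    for ai in ion_idx:
        ion_xyz = stack.coord[:, ai, :]  # (frames, 3)
        d = np.linalg.norm(prot - ion_xyz[:, None, :], axis=2)  # (frames, atoms)
        in_contact = d <= cutoff
        frac = float(in_contact.any(axis=1).mean())
        partner_counts: dict[tuple[str, int, str], int] = {}
        for f in range(d.shape[0]):
            touched = {res_keys[k] for k in np.nonzero(in_contact[f])[0]}
            for key in touched:
                partner_counts[key] = partner_counts.get(key, 0) + 1
        partners = [k for k, _ in sorted(partner_counts.items(),
                                         key=lambda kv: (-kv[1], kv[0]))]
        serial = int(stack.atom_id[ai]) if "atom_id" in stack.get_annotation_categories() \
            else int(ai)
        results.append(IonPersistence(
            ion_serial=serial, element=str(stack.element[ai]).upper(),
            contact_fraction=frac, persistent=bool(frac > threshold),
            partner_residues=partners,
        ))
    return results
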