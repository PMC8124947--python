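"""Read, clean and subset protein-ligand complex structures.

The pipeline starts from a crystallographic complex: a protein with a bound
ligand, possibly with alternate conformers, waters and ions.  This module
provides the in-memory model (:class:`Atom`, :class:`ResidueUnit`,
:class:`ComplexStructure`), PDB/SDF input and PDB output, selection of the
major alternate conformer, solvent/ion stripping, and the distance-based
active-site selection used to decide which residues become kernels.

All coordinates are in Angstrom throughout; there is no unit-conversion
surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("kemlead")

# Residue names treated as solvent and single-atom species treated as ions.
# Extendable: pass extra names to strip_solvent / infer_role.
SOLVENT_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "SOL"})
ION_RESNAMES = frozenset(
    {"NA", "K", "MG", "ZN", "CA", "CL", "BR", "MN", "FE", "CO", "NI", "CU", "CD", "LI", "IOD"}
)

STANDARD_AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "MSE", "SEC", "PYL",
    }
)


@dataclass
class Atom:
    """A single atom: element, label, Cartesian coordinates (Angstrom).

    ``partial_charge`` (e), ``lj_sigma`` (Angstrom) and ``lj_epsilon``
    (kcal/mol) are parameters for the classical energy backend and are
    optional; structure handling never needs them.
    """

    element: str
    name: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    partial_charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        self.element = self.element.strip().capitalize()

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class ResidueUnit:
    """One residue, ligand, solvent or ion unit of the complex."""

    chain: str
    resname: str
    resnum: int
    atoms: list[Atom]
    role: str = "protein"  # protein | ligand | solvent | ion

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.uid} has no atoms")
        if self.role not in {"protein", "ligand", "solvent", "ion"}:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def uid(self) -> str:
        return f"{self.chain}:{self.resnum}"

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class ComplexStructure:
    """A protein-ligand complex as a list of :class:`ResidueUnit`."""

    units: list[ResidueUnit]
    ligand_id: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for u in self.units:
            for a in u.atoms:
                key = (u.chain, u.resnum, a.name, a.altloc)
                if key in seen:
                    raise ValueError(f"duplicate atom {key}")
                seen.add(key)

    @property
    def ligand(self) -> ResidueUnit:
        if self.ligand_id is None:
            raise ValueError("structure has no ligand reference")
        return self.unit(self.ligand_id)

    def unit(self, uid: str) -> ResidueUnit:
        for u in self.units:
            if u.uid == uid:
                return u
        raise KeyError(f"no unit with id {uid!r}")

    def units_with_role(self, role: str) -> list[ResidueUnit]:
        return [u for u in self.units if u.role == role]


def infer_role(
    resname: str,
    atoms: Sequence[Atom],
    solvent_names: frozenset[str] = SOLVENT_RESNAMES,
    ion_names: frozenset[str] = ION_RESNAMES,
) -> str:
    name = resname.strip().upper()
    if name in solvent_names:
        return "solvent"
    if name in ion_names and len(atoms) == 1:
        return "ion"
    if name in STANDARD_AMINO_ACIDS:
        return "protein"
    return "ligand"


def _prescan_pdb(path: Path) -> None:
    """Reject malformed ATOM/HETATM records with a line-numbered error."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}:{lineno}: truncated ATOM/HETATM record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable coordinates") from exc


def read_pdb(
    path: str | Path,
    ligand: str | None = None,
    solvent_names: Iterable[str] = (),
) -> ComplexStructure:
    """Read a PDB file into a :class:`ComplexStructure`.

    Roles are inferred from residue names: waters (HOH/WAT/DOD, plus any
    extra ``solvent_names``) become solvent, known single-atom ions become
    ions, standard amino acids become protein, everything else a ligand.
    The ligand reference defaults to the first ligand-role unit; pass
    ``ligand="A:301"`` to pick explicitly.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    st = gemmi.read_pdb(str(path))
    solvent = SOLVENT_RESNAMES | {s.upper() for s in solvent_names}

    units: list[ResidueUnit] = []
    if len(st) == 0:
        raise ValueError(f"{path}: structure contains no models")
    model = st[0]
    for chain in model:
        for res in chain:
            atoms = [
                Atom(
                    element=at.element.name,
                    name=at.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    altloc=at.altloc.strip() if at.altloc != "\x00" else "",
                )
                for at in res
            ]
            if not atoms:
                continue
            units.append(
                ResidueUnit(
                    chain=chain.name,
                    resname=res.name,
                    resnum=res.seqid.num,
                    atoms=atoms,
                    role=infer_role(res.name, atoms, solvent_names=solvent),
                )
            )
    if not units:
        raise ValueError(f"{path}: no ATOM/HETATM records found")

    ligand_id = ligand
    if ligand_id is None:
        ligs = [u for u in units if u.role == "ligand"]
        ligand_id = ligs[0].uid if ligs else None
    struct = ComplexStructure(
        units=units,
        ligand_id=ligand_id,
        provenance={"source": str(path), "preparation": []},
    )
    return struct


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write the complex back out as PDB (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = "kemlead"
    model = gemmi.Model("1")
    chains: dict[str, "gemmi.Chain"] = {}
    for u in structure.units:
        if u.chain not in chains:
            chains[u.chain] = gemmi.Chain(u.chain)
        res = gemmi.Residue()
        res.name = u.resname
        res.seqid = gemmi.SeqId(u.resnum, " ")
        res.het_flag = "A" if u.role == "protein" else "H"
        for a in u.atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.coords)
            at.occ = a.occupancy
            at.altloc = a.altloc if a.altloc else "\x00"
            res.add_atom(at)
        chains[u.chain].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_sdf_ligand(path: str | Path, resname: str = "LIG", chain: str = "L", resnum: int = 1) -> ResidueUnit:
    """Read the first molecule of an SDF (V2000) file as a ligand unit."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ValueError(f"{path}: no parseable molecule")
    conf = mol.GetConformer()
    atoms = [
        Atom(
            element=at.GetSymbol(),
            name=f"{at.GetSymbol()}{at.GetIdx() + 1}",
            coords=np.array(conf.GetAtomPosition(at.GetIdx())),
        )
        for at in mol.GetAtoms()
    ]
    return ResidueUnit(chain=chain, resname=resname, resnum=resnum, atoms=atoms, role="ligand")


def select_major_conformer(structure: ComplexStructure) -> ComplexStructure:
    """Keep one alternate location per atom: highest occupancy wins.

    Ties are broken by the alphabetically first altloc code; the altloc
    field is cleared on the retained atoms.  Idempotent; structures without
    altlocs pass through unchanged (as a copy).
    """
    new_units = []
    for u in structure.units:
        groups: dict[str, list[Atom]] = {}
        order: list[str] = []
        for a in u.atoms:
            if a.name not in groups:
                groups[a.name] = []
                order.append(a.name)
            groups[a.name].append(a)
        kept: list[Atom] = []
        for name in order:
            best = min(groups[name], key=lambda a: (-a.occupancy, a.altloc))
            best = best.copy()
            best.altloc = ""
            kept.append(best)
        new_units.append(replace(u, atoms=kept))
    prov = dict(structure.provenance)
    prov.setdefault("preparation", [])
    prov["preparation"] = list(prov["preparation"]) + ["select_major_conformer"]
    return ComplexStructure(units=new_units, ligand_id=structure.ligand_id, provenance=prov)


def strip_solvent(structure: ComplexStructure, remove_ions: bool = True) -> ComplexStructure:
    """Remove solvent (and, by default, ion) units; log how many went."""
    roles = {"solvent"} | ({"ion"} if remove_ions else set())
    kept = [u for u in structure.units if u.role not in roles]
    n_removed = len(structure.units) - len(kept)
    logger.info("strip_solvent: removed %d unit(s)", n_removed)
    prov = dict(structure.provenance)
    prov["preparation"] = list(prov.get("preparation", [])) + [f"strip_solvent(removed={n_removed})"]
    return ComplexStructure(units=kept, ligand_id=structure.ligand_id, provenance=prov)


def select_active_site(
    structure: ComplexStructure,
    center: str,
    radius: float,
) -> list[ResidueUnit]:
    """Protein residues with any atom within ``radius`` of the center unit.

    ``center`` is ``"ligand"`` or a unit id like ``"A:111"``.  Membership
    uses the minimum atom-atom distance with a closed boundary (distance
    <= radius).  The returned set never contains the ligand or the center
    unit itself.
    """
    from scipy.spatial import cKDTree

    if radius <= 0:
        raise ValueError("radius must be positive")
    center_unit = structure.ligand if center == "ligand" else structure.unit(center)
    tree = cKDTree(center_unit.coords_array())
    site = []
    for u in structure.units:
        if u.role != "protein" or u is center_unit:
            continue
        dmin = tree.query(u.coords_array())[0].min()
        # closed boundary; tiny epsilon guards float noise at the sphere edge
        if dmin <= radius + 1e-9:
            site.append(u)
    return site
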