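"""Cut a complex into kernels and cap the severed bonds with hydrogens.

A kernel is the unit of energy calculation: one active-site residue, or the
ligand.  Fragmenting a protein necessarily severs covalent bonds (the
peptide C-N link between consecutive residues, and disulfide S-S bridges);
each severed bond is capped by placing a hydrogen on the ray from the inside
atom toward the lost neighbour, at a standard covalent bond length.  The
fragmentation is a partition: every original atom belongs to exactly one
kernel; caps are bookkept separately from original atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .structures import Atom, ResidueUnit

logger = logging.getLogger("kemlead")


@dataclass
class CapRule:
    """Bond length (Angstrom) for the H cap replacing a severed X-Y bond.

    ``elements = (inside, outside)``: the cap hydrogen bonds to the inside
    element; the length is the standard inside-H covalent distance.
    """

    elements: tuple[str, str]
    length: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("cap bond length must be positive")


# Standard covalent X-H bond lengths; the outside element does not change
# the cap length, only where the cap points.
DEFAULT_CAP_LENGTHS: dict[str, float] = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}
GENERIC_CAP_LENGTH = 1.09

# Formal charges of ionizable residues at physiological pH; every kernel is
# closed-shell (multiplicity 1) unless overridden.
DEFAULT_RESIDUE_CHARGES: dict[str, int] = {
    "ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": 0,
    "ALA": 0, "ASN": 0, "CYS": 0, "GLN": 0, "GLY": 0, "ILE": 0, "LEU": 0,
    "MET": 0, "PHE": 0, "PRO": 0, "SER": 0, "THR": 0, "TRP": 0, "TYR": 0,
    "VAL": 0,
}


@dataclass
class Kernel:
    """A capped fragment: original atoms plus added H caps."""

    label: str
    atoms: list[Atom]
    caps: list[Atom] = field(default_factory=list)
    formal_charge: int | None = None
    multiplicity: int = 1
    origin: str = ""
    resname: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"kernel {self.label}: empty atom list")
        if self.multiplicity < 1:
            raise ValueError(f"kernel {self.label}: multiplicity must be >= 1")
        if any(c.element != "H" for c in self.caps):
            raise ValueError(f"kernel {self.label}: caps must be hydrogens")

    @property
    def all_atoms(self) -> list[Atom]:
        return list(self.atoms) + list(self.caps)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.all_atoms])


SeveredBond = tuple[Atom, Atom]


def detect_severed_bonds(units: list[ResidueUnit]) -> list[SeveredBond]:
    """Find inter-residue covalent bonds that one-residue-per-kernel cuts.

    Peptide bonds: atom named C of residue i and atom named N of residue
    i+1 on the same chain within 2.0 Angstrom.  Disulfides: SG-SG pairs
    within 2.5 Angstrom.
    """
    bonds: list[SeveredBond] = []
    by_pos = {(u.chain, u.resnum): u for u in units}
    for u in units:
        nxt = by_pos.get((u.chain, u.resnum + 1))
        if nxt is None:
            continue
        c = next((a for a in u.atoms if a.name == "C"), None)
        n = next((a for a in nxt.atoms if a.name == "N"), None)
        if c is not None and n is not None and np.linalg.norm(c.coords - n.coords) < 2.0:
            bonds.append((c, n))
    sgs = [(u, a) for u in units for a in u.atoms if a.name == "SG"]
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            (ui, ai), (uj, aj) = sgs[i], sgs[j]
            if ui is not uj and np.linalg.norm(ai.coords - aj.coords) < 2.5:
                bonds.append((ai, aj))
    return bonds


def cap_kernel(kernel: Kernel, severed_bonds: list[SeveredBond], rules: list[CapRule] | None = None) -> Kernel:
    """Place one H cap per severed bond along the inside->outside direction.

    Each bond must have exactly one endpoint inside the kernel; the cap sits
    on the ray from the inside atom toward the outside atom, at the rule's
    bond length for the inside element.
    """
    lengths = dict(DEFAULT_CAP_LENGTHS)
    if rules:
        for r in rules:
            lengths[r.elements[0]] = r.length
    inside = set(id(a) for a in kernel.atoms)
    caps = list(kernel.caps)
    for a, b in severed_bonds:
        a_in, b_in = id(a) in inside, id(b) in inside
        if a_in == b_in:
            raise ValueError(
                f"kernel {kernel.label}: severed bond {a.name}-{b.name} must have exactly one endpoint inside"
            )
        src, dst = (a, b) if a_in else (b, a)
        direction = dst.coords - src.coords
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError(f"kernel {kernel.label}: degenerate severed bond (zero length)")
        length = lengths.get(src.element, GENERIC_CAP_LENGTH)
        caps.append(
            Atom(
                element="H",
                name=f"Hcap{len(caps) + 1}",
                coords=src.coords + direction / norm * length,
            )
        )
    return replace(kernel, caps=caps)


def fragment_complex(
    site: list[ResidueUnit],
    ligand: ResidueUnit,
    severed_bonds: list[SeveredBond] | None = None,
    cap_rules: list[CapRule] | None = None,
) -> list[Kernel]:
    """One kernel per site residue plus the ligand kernel (ligand first).

    ``severed_bonds`` defaults to auto-detected peptide/disulfide links
    within the site; bonds from a site residue to anything outside the site
    are the caller's to supply (the active-site sphere already cut them).
    """
    if not site:
        raise ValueError("active site is empty")
    if ligand is None:
        raise ValueError("ligand unit is required")
    for u in site:
        if not u.atoms:
            raise ValueError(f"residue {u.uid} has no atoms")
    if severed_bonds is None:
        severed_bonds = detect_severed_bonds(site)

    kernels = [
        Kernel(
            label="ligand",
            atoms=[a.copy() for a in ligand.atoms],
            origin="ligand",
            resname=ligand.resname,
        )
    ]
    # copies must keep identity links to severed-bond endpoints
    copy_map: dict[int, Atom] = {}
    for u in site:
        copies = []
        for a in u.atoms:
            c = a.copy()
            copy_map[id(a)] = c
            copies.append(c)
        kernels.append(Kernel(label=u.uid, atoms=copies, origin=u.uid, resname=u.resname))

    remapped = [
        (copy_map.get(id(a), a), copy_map.get(id(b), b)) for a, b in severed_bonds
    ]
    capped = []
    for k in kernels:
        inside = set(id(a) for a in k.atoms)
        mine = [b for b in remapped if (id(b[0]) in inside) != (id(b[1]) in inside)]
        capped.append(cap_kernel(k, mine, cap_rules) if mine else k)

    _check_partition(site, ligand, capped)
    return capped


def _check_partition(site: list[ResidueUnit], ligand: ResidueUnit, kernels: list[Kernel]) -> None:
    n_in = sum(len(u.atoms) for u in site) + len(ligand.atoms)
    n_out = sum(len(k.atoms) for k in kernels)
    if n_in != n_out:
        raise AssertionError(f"fragmentation lost/duplicated atoms: {n_in} in, {n_out} out")


def assign_charge_multiplicity(
    kernel: Kernel,
    templates: dict[str, int] | None = None,
    charge: int | None = None,
    multiplicity: int | None = None,
) -> Kernel:
    """Set formal charge (from residue templates) and multiplicity.

    Explicit ``charge``/``multiplicity`` override the template; an unknown
    residue with no override is an error so that mis-typed residue names
    never silently become neutral.
    """
    tmpl = DEFAULT_RESIDUE_CHARGES if templates is None else templates
    if charge is None:
        if kernel.resname in tmpl:
            charge = tmpl[kernel.resname]
        else:
            raise KeyError(
                f"no charge template for residue {kernel.resname!r} (kernel {kernel.label}); "
                "pass charge= explicitly"
            )
    return replace(kernel, formal_charge=int(charge), multiplicity=int(multiplicity or 1))


def kernels_to_dict(kernels: list[Kernel]) -> list[dict]:
    """JSON-ready layout: label, atoms, caps, charge, multiplicity."""

    def atom_d(a: Atom) -> dict:
        d = {"element": a.element, "name": a.name, "coords": [float(x) for x in a.coords]}
        if a.partial_charge is not None:
            d["partial_charge"] = a.partial_charge
            d["lj_sigma"] = a.lj_sigma
            d["lj_epsilon"] = a.lj_epsilon
        return d

    return [
        {
            "label": k.label,
            "origin": k.origin,
            "resname": k.resname,
            "formal_charge": k.formal_charge,
            "multiplicity": k.multiplicity,
            "atoms": [atom_d(a) for a in k.atoms],
            "caps": [atom_d(a) for a in k.caps],
        }
        for k in kernels
    ]


def kernels_from_dict(data: list[dict]) -> list[Kernel]:
    def atom_o(d: dict) -> Atom:
        return Atom(
            element=d["element"],
            name=d["name"],
            coords=np.array(d["coords"]),
            partial_charge=d.get("partial_charge"),
            lj_sigma=d.get("lj_sigma"),
            lj_epsilon=d.get("lj_epsilon"),
        )

    return [
        Kernel(
            label=d["label"],
            atoms=[atom_o(a) for a in d["atoms"]],
            caps=[atom_o(a) for a in d["caps"]],
            formal_charge=d["formal_charge"],
            multiplicity=d["multiplicity"],
            origin=d["origin"],
            resname=d.get("resname", ""),
        )
        for d in data
    ]
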