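"""Self-contained toy complexes, pose families, scores and IC50 values.

The generator emulates the study conditions of a redocking experiment at
desk scale: a small "protein" of disjoint residues arranged on a shell
around a bound ligand, a classical parameter set (point charges +
Lennard-Jones) for which kernel-energy reconstruction is analytically
exact, families of docked poses planted as rigid transforms of the bound
geometry, docking-like fitness scores monotone in the true interaction
energy plus noise, and IC50 values log-linear in the true interaction
energy plus noise.

Binding is made attractive by construction: each residue's atom closest to
the ligand receives a partial charge opposite in sign to its nearest ligand
atom, the way a real pocket complements its ligand.  Every unit is net
neutral (unless configured otherwise), so a ligand displaced out of the
pocket sees only weak multipole interactions - the planted bound
orientation is the energetic ground truth that pose selection must find.

All generators take explicit seeds; identical seeds give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .energy import cross_energy
from .fragmentation import Kernel, fragment_complex
from .poses import LigandPose
from .structures import Atom, ComplexStructure, ResidueUnit

MIN_ATOM_SEPARATION = 1.0  # Angstrom, overlap guard on generated geometry
CONTACT_DISTANCE = 3.6  # Angstrom, closest ligand-residue approach (vdW contact)
_ELEMENTS = ("C", "N", "O", "S")
# neutral residue names, cycled: keeps toy residues recognizable as protein
# on PDB round-trips and compatible with the default charge templates
_RESNAMES = ("ALA", "GLY", "SER", "THR", "VAL", "LEU")


@dataclass
class SyntheticSpec:
    """Parameters of the toy study; defaults mirror the emulated setup.

    Three orientation types of ten poses each reproduce the 30-poses-per-
    ligand docking protocol; the inter-type displacement must exceed
    ``2 * (intra_type_jitter + 2.0)`` so that planted types can never be
    confused under the 2.0 Angstrom correctness cutoff.
    """

    n_residues: int = 6
    atoms_per_residue: int = 4
    ligand_atoms: int = 6
    charge_range: float = 0.5  # |q| bound, e
    sigma_range: tuple[float, float] = (2.5, 3.5)  # Angstrom
    epsilon_range: tuple[float, float] = (0.05, 0.3)  # kcal/mol
    total_charge: int = 0
    shell_radius: float = 6.0  # Angstrom, residue centers around the ligand
    n_pose_types: int = 3
    poses_per_type: int = 10
    intra_type_jitter: float = 0.3  # Angstrom, per-coordinate Gaussian sigma
    inter_type_displacement: float = 15.0  # Angstrom
    fitness_noise: float = 1.0  # score units
    ic50_noise: float = 0.5  # sigma of log-IC50 noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pose_types > 1 and self.inter_type_displacement <= 2 * (self.intra_type_jitter + 2.0):
            raise ValueError(
                "inter_type_displacement must exceed 2*(intra_type_jitter + 2.0) "
                "so planted orientation types are unambiguous"
            )


class SyntheticComplex(NamedTuple):
    structure: ComplexStructure
    formal_charges: dict[str, int]  # unit id -> formal charge


def _sample_cluster(
    rng: np.random.Generator,
    center: np.ndarray,
    n: int,
    radius: float,
    existing: list[np.ndarray],
    keep_out: np.ndarray | None = None,
    keep_out_dist: float = CONTACT_DISTANCE,
) -> np.ndarray:
    """Place n points near center, each >= 1 A from every point so far.

    ``keep_out`` points (the ligand, when placing residues) must stay at
    least ``keep_out_dist`` away, which keeps protein-ligand contacts at
    van der Waals distance instead of inside the repulsive wall.
    """
    pts: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(200):
            p = center + rng.uniform(-radius, radius, size=3)
            taken = pts + existing
            if taken and min(np.linalg.norm(p - t) for t in taken) < MIN_ATOM_SEPARATION:
                continue
            if keep_out is not None and np.linalg.norm(keep_out - p, axis=1).min() < keep_out_dist:
                continue
            pts.append(p)
            break
        else:
            raise RuntimeError("could not place a non-overlapping atom in 200 attempts")
    return np.array(pts)


def _make_atoms(rng: np.random.Generator, coords: np.ndarray, spec: SyntheticSpec, prefix: str) -> list[Atom]:
    atoms = []
    for i, xyz in enumerate(coords):
        el = _ELEMENTS[rng.integers(0, len(_ELEMENTS))]
        atoms.append(
            Atom(
                element=el,
                name=f"{el}{prefix}{i + 1}",
                coords=xyz,
                partial_charge=0.0,
                lj_sigma=float(rng.uniform(*spec.sigma_range)),
                lj_epsilon=float(rng.uniform(*spec.epsilon_range)),
            )
        )
    return atoms


def make_complex(spec: SyntheticSpec) -> SyntheticComplex:
    """Generate a toy residues-around-ligand complex with full parameters.

    Residue centers sit on a shell of ``spec.shell_radius`` around the
    ligand; every atom gets a partial charge, sigma and epsilon.  Geometry
    is resampled (up to 100 attempts) until all atoms are pairwise at
    least 1 Angstrom apart.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lig_coords = _sample_cluster(rng, np.zeros(3), spec.ligand_atoms, 2.2, existing=[])
    centers: list[np.ndarray] = []
    for _ in range(spec.n_residues):
        for _attempt in range(100):
            u = rng.normal(size=3)
            c = u / np.linalg.norm(u) * spec.shell_radius
            if all(np.linalg.norm(c - prev) >= 3.5 for prev in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError("could not place residue centers in 100 attempts (shell too crowded)")
    placed: list[np.ndarray] = []
    res_coords = []
    for c in centers:
        coords = _sample_cluster(rng, c, spec.atoms_per_residue, 1.2, existing=placed, keep_out=lig_coords)
        placed.extend(coords)
        res_coords.append(coords)
    assert np.all(pdist(np.vstack([lig_coords] + res_coords)) >= MIN_ATOM_SEPARATION)

    lig_atoms = _make_atoms(rng, lig_coords, spec, "L")
    qmax = spec.charge_range
    # signed charges of decent magnitude, then shift to the net charge
    q_lig = rng.uniform(0.15, qmax, size=spec.ligand_atoms) * rng.choice([-1.0, 1.0], size=spec.ligand_atoms)
    q_lig += (spec.total_charge - q_lig.sum()) / spec.ligand_atoms  # ligand carries the net charge
    for a, q in zip(lig_atoms, q_lig):
        a.partial_charge = float(q)

    units = []
    formal = {}
    for ridx, coords in enumerate(res_coords):
        atoms = _make_atoms(rng, coords, spec, f"R{ridx + 1}")
        # complementary pocket: contact atom opposes its nearest ligand atom
        d2lig = np.linalg.norm(coords[:, None, :] - lig_coords[None, :, :], axis=2)
        contact = int(np.argmin(d2lig.min(axis=1)))
        nearest_lig = int(np.argmin(d2lig[contact]))
        q = rng.uniform(-0.1, 0.1, size=spec.atoms_per_residue)
        q[contact] = -np.sign(q_lig[nearest_lig] or 1.0) * rng.uniform(0.3, qmax)
        others = [i for i in range(spec.atoms_per_residue) if i != contact]
        if others:
            q[others] -= q.sum() / len(others)  # residue stays net neutral
        else:
            q[contact] = 0.0
        # a pocket complements its ligand: orient and scale this residue's
        # charge distribution so its Coulomb term with the ligand is a
        # clear attraction (sign flip and scaling both preserve neutrality)
        coul = 332.0636 * float(np.sum(np.outer(q, q_lig) / d2lig))
        if coul > 0:
            q, coul = -q, -coul
        if abs(coul) > 1e-9 and np.abs(q).max() > 0:
            target = rng.uniform(4.0, 8.0)  # kcal/mol attraction per residue
            q *= min(target / abs(coul), qmax / np.abs(q).max())
        for a, qi in zip(atoms, q):
            a.partial_charge = float(qi)
        unit = ResidueUnit(chain="A", resname=_RESNAMES[ridx % len(_RESNAMES)], resnum=ridx + 1, atoms=atoms, role="protein")
        units.append(unit)
        formal[unit.uid] = 0

    ligand = ResidueUnit(chain="L", resname="LIG", resnum=1, atoms=lig_atoms, role="ligand")
    units.append(ligand)
    formal[ligand.uid] = spec.total_charge
    structure = ComplexStructure(units=units, ligand_id=ligand.uid, provenance={"source": f"synthetic(seed={spec.seed})"})
    return SyntheticComplex(structure=structure, formal_charges=formal)


def reference_pose(structure: ComplexStructure) -> LigandPose:
    """The crystallographic-ground-truth pose: the bound ligand geometry."""
    lig = structure.ligand
    return LigandPose(pose_id="crystal", atoms=[a.copy() for a in lig.atoms], fitness=float("nan"))


def site_kernels(structure: ComplexStructure) -> list[Kernel]:
    """Fragment the toy complex: ligand kernel first, then residue kernels."""
    site = structure.units_with_role("protein")
    return fragment_complex(site, structure.ligand)


def _pose_true_ie(pose: LigandPose, residue_kernels: Sequence[Kernel]) -> float:
    k = Kernel(label="pose", atoms=pose.atoms, origin="ligand")
    return sum(cross_energy(k, rk) for rk in residue_kernels)


class PoseSet(NamedTuple):
    poses: list[LigandPose]
    labels: list[int]  # planted type per pose, 1-based; type 1 = bound
    type_references: list[LigandPose]
    true_ies: list[float]


def make_pose_set(
    spec: SyntheticSpec,
    reference: LigandPose,
    residue_kernels: Sequence[Kernel],
    seed: int,
) -> PoseSet:
    """Plant pose families: type 1 at the bound geometry, others displaced.

    Each non-bound type is a rigid rotation of the reference about its
    centroid plus a translation of ``inter_type_displacement``; poses
    within a type add per-coordinate Gaussian jitter.  Fitness is monotone
    in the negated true classical interaction energy plus Gaussian noise,
    so with zero noise the bound type always scores best.
    """
    rng = np.random.default_rng(seed)
    ref_coords = reference.coords_array()
    centroid = ref_coords.mean(axis=0)

    type_refs: list[np.ndarray] = [ref_coords]
    for _t in range(1, spec.n_pose_types):
        rot = Rotation.random(rng=rng).as_matrix()
        u = rng.normal(size=3)
        shift = u / np.linalg.norm(u) * spec.inter_type_displacement
        type_refs.append((ref_coords - centroid) @ rot.T + centroid + shift)

    def clone_atoms(coords: np.ndarray) -> list[Atom]:
        out = []
        for a, xyz in zip(reference.atoms, coords):
            c = a.copy()
            c.coords = np.asarray(xyz, dtype=float)
            out.append(c)
        return out

    poses: list[LigandPose] = []
    labels: list[int] = []
    true_ies: list[float] = []
    for t, tref in enumerate(type_refs, start=1):
        for p in range(spec.poses_per_type):
            coords = tref + rng.normal(0.0, spec.intra_type_jitter or 0.0, size=tref.shape)
            pose = LigandPose(pose_id=f"T{t}P{p + 1}", atoms=clone_atoms(coords))
            ie = _pose_true_ie(pose, residue_kernels)
            pose.fitness = 50.0 - 0.5 * ie + rng.normal(0.0, spec.fitness_noise) if spec.fitness_noise else 50.0 - 0.5 * ie
            poses.append(pose)
            labels.append(t)
            true_ies.append(ie)

    refs = [LigandPose(pose_id=f"T{t + 1}ref", atoms=clone_atoms(c)) for t, c in enumerate(type_refs)]
    return PoseSet(poses=poses, labels=labels, type_references=refs, true_ies=true_ies)


def make_ic50(
    true_ies: Sequence[float],
    noise: float,
    seed: int,
    intercept: float = 5.0,
    slope: float = 0.05,
) -> list[float]:
    """IC50 (nM) log-linear in interaction energy: exp(a + b*IE + eps).

    ``slope`` is positive, so a more negative interaction energy gives a
    smaller (more potent) IC50; ``noise`` is the sigma of the Gaussian on
    the log scale.  With zero noise the IC50 ranking equals the IE ranking.
    """
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if slope <= 0:
        raise ValueError("slope must be positive")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise, size=len(true_ies)) if noise else np.zeros(len(true_ies))
    return [float(np.exp(intercept + slope * ie + e)) for ie, e in zip(true_ies, eps)]
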