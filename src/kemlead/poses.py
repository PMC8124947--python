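"""Docked-pose handling: in-place RMSD, orientation typing, best-pose pick.

Docking emits many poses per ligand; for adjudication they are grouped into
a few gross binding orientations ("pose types") and one representative per
type is scored.  The similarity measure is the heavy-atom in-place RMSD -
no superposition - because what matters is where the ligand sits in the
binding site, not whether two conformers could be overlaid.  A selected
pose type counts as correct when its RMSD to the crystallographic ligand
geometry is at most 2.0 Angstrom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .structures import Atom

logger = logging.getLogger("kemlead")

DEFAULT_CLUSTER_THRESHOLD = 2.0  # Angstrom, aligned with the correctness cutoff


@dataclass
class LigandPose:
    """One docked placement of a ligand, with its docking fitness score."""

    pose_id: str
    atoms: list[Atom]
    fitness: float = float("nan")
    source_rank: int | None = None

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class PoseTypeAssignment:
    """Pose -> orientation type map with per-type representatives.

    Types are 1-based and ordered by the founding representative's fitness
    (Type 1 has the best fitness).
    """

    assignments: dict[str, int]
    representatives: dict[int, LigandPose]
    populations: dict[int, int]

    @property
    def n_types(self) -> int:
        return len(self.representatives)

    def representative_fitness(self) -> dict[int, float]:
        return {t: p.fitness for t, p in self.representatives.items()}


def _heavy_identity_mapping(a: LigandPose, b: LigandPose) -> list[tuple[int, int]]:
    if len(a.atoms) != len(b.atoms):
        raise ValueError("poses differ in atom count; supply an explicit mapping")
    return [(i, i) for i, at in enumerate(a.atoms) if at.is_heavy]


def heavy_atom_rmsd(
    a: LigandPose,
    b: LigandPose,
    mapping: Sequence[tuple[int, int]] | None = None,
) -> float:
    """In-place heavy-atom RMSD between two poses (Angstrom).

    ``mapping`` is a list of (index_in_a, index_in_b) heavy-atom pairs; by
    default the identity mapping over heavy atoms (poses of the same ligand
    share atom order).  No superposition is performed: both poses must
    already sit in the same coordinate frame, and the value measures the
    displacement of the docked pose from the reference placement.
    """
    if mapping is None:
        mapping = _heavy_identity_mapping(a, b)
    if len(mapping) == 0:
        raise ValueError("empty atom mapping")
    for ia, ib in mapping:
        if not a.atoms[ia].is_heavy or not b.atoms[ib].is_heavy:
            raise ValueError(f"mapping pairs hydrogen atoms ({ia}, {ib}); heavy atoms only")
    pa = np.array([a.atoms[ia].coords for ia, _ in mapping])
    pb = np.array([b.atoms[ib].coords for _, ib in mapping])
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def cluster_pose_types(
    poses: Sequence[LigandPose],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    mapping: Sequence[tuple[int, int]] | None = None,
) -> PoseTypeAssignment:
    """Greedy leader clustering of poses into orientation types.

    Poses are processed in order of descending fitness (stable for ties).
    Each pose joins the first existing type whose representative lies
    within ``threshold`` RMSD, otherwise it founds a new type.  Because
    founding order follows fitness, type indices are ordered by the
    founding representative's fitness: Type 1 is the best-scoring
    orientation.  Deterministic for a given pose order and fitness values.
    """
    if not poses:
        raise ValueError("no poses to cluster")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    order = sorted(range(len(poses)), key=lambda i: -poses[i].fitness)
    assignments: dict[str, int] = {}
    representatives: dict[int, LigandPose] = {}
    for idx in order:
        pose = poses[idx]
        for t, rep in representatives.items():
            if heavy_atom_rmsd(pose, rep, mapping) <= threshold:
                assignments[pose.pose_id] = t
                break
        else:
            t_new = len(representatives) + 1
            representatives[t_new] = pose
            assignments[pose.pose_id] = t_new
    populations = {t: sum(1 for v in assignments.values() if v == t) for t in representatives}
    return PoseTypeAssignment(assignments=assignments, representatives=representatives, populations=populations)


def select_best_pose(
    assignment: PoseTypeAssignment | Mapping[int, float],
    criterion: str = "fitness",
    ie_by_type: Mapping[int, float | None] | None = None,
) -> int:
    """Pick the best orientation type by fitness or by averaged IE.

    ``assignment`` is a clustering result or a plain {type: fitness} map.
    ``fitness`` picks the type whose representative scores highest;
    ``avg_ie`` picks the most negative interaction energy, skipping types
    whose IE is missing or failed (None/NaN).  Ties go to the lowest type
    index and are logged.
    """
    if criterion not in {"fitness", "avg_ie"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion == "fitness":
        values = (
            assignment.representative_fitness()
            if isinstance(assignment, PoseTypeAssignment)
            else dict(assignment)
        )
        eligible = {t: v for t, v in values.items() if v is not None and np.isfinite(v)}
        sign = -1.0  # maximize
    else:
        if ie_by_type is None:
            raise ValueError("avg_ie criterion requires ie_by_type")
        eligible = {t: v for t, v in ie_by_type.items() if v is not None and np.isfinite(v)}
        sign = 1.0  # minimize (most negative IE)
    if not eligible:
        raise ValueError(f"no eligible pose type for criterion {criterion!r}")
    best_val = min(sign * v for v in eligible.values())
    winners = sorted(t for t, v in eligible.items() if sign * v == best_val)
    if len(winners) > 1:
        logger.info("select_best_pose: tie among types %s, keeping %d", winners, winners[0])
    return winners[0]


# --- file ingestion -------------------------------------------------------


def read_poses_sdf(path: str | Path, fitness_tag: str | None = None) -> list[LigandPose]:
    """Read a multi-record SDF as one pose per record.

    Fitness is taken from SD tag ``fitness_tag`` when given, else NaN (to
    be joined from a scores table).
    """
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    poses = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        conf = mol.GetConformer()
        atoms = [
            Atom(
                element=at.GetSymbol(),
                name=f"{at.GetSymbol()}{at.GetIdx() + 1}",
                coords=np.array(conf.GetAtomPosition(at.GetIdx())),
            )
            for at in mol.GetAtoms()
        ]
        fitness = float("nan")
        if fitness_tag and mol.HasProp(fitness_tag):
            fitness = float(mol.GetProp(fitness_tag))
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        poses.append(LigandPose(pose_id=name or f"pose{i + 1}", atoms=atoms, fitness=fitness))
    if not poses:
        raise ValueError(f"{path}: no poses read")
    return poses


def join_scores(poses: list[LigandPose], scores_csv: str | Path, pose_col: str = "pose_id") -> list[LigandPose]:
    """Attach fitness/rank columns from a docking-scores CSV to poses."""
    import pandas as pd

    df = pd.read_csv(scores_csv).set_index(pose_col)
    out = []
    for p in poses:
        if p.pose_id in df.index:
            row = df.loc[p.pose_id]
            p = LigandPose(
                pose_id=p.pose_id,
                atoms=p.atoms,
                fitness=float(row["fitness"]),
                source_rank=int(row["rank"]) if "rank" in row else None,
            )
        out.append(p)
    return out
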