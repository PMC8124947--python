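"""Call correct/incorrect poses, summarize per target, rank against IC50.

For each ligand the docking score (fitness) and the averaged interaction
energy each nominate a best pose type; a nomination is correct when that
type's heavy-atom RMSD to the crystallographic ligand geometry is at most
the cutoff (2.0 Angstrom by default).  Per-target summaries count correct
calls per method.  Ligand rankings by IC50 (ascending: more potent first),
interaction energy (ascending: more negative first) or fitness (descending)
are compared with Spearman rank correlation (Kendall tau available),
reported as a percentage together with the method used.

Verbatim transcriptions of published per-ligand results for three targets
(human aldose reductase, CDK2, estrogen receptor beta) ship as packaged
CSV fixtures; :func:`load_fixture_records` reads them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .poses import select_best_pose

logger = logging.getLogger("kemlead")

DEFAULT_RMSD_CUTOFF = 2.0  # Angstrom

FIXTURE_FILES = {
    "hAR": "table2_3_hAR.csv",
    "CDK2": "table4_5_CDK2.csv",
    "ERbeta": "table6_7_ERbeta.csv",
}


@dataclass
class PoseTypeStats:
    """Per-orientation-type numbers for one ligand."""

    avg_ie: float | None = None  # kcal/mol; None = failed/missing
    fitness: float | None = None
    gold_rank: int | None = None
    rmsd: float | None = None  # Angstrom, to crystal geometry


@dataclass
class LigandRecord:
    """One ligand's per-type results plus its experimental potency."""

    ligand_id: str
    types: dict[int, PoseTypeStats]
    ic50_nM: float | None = None
    ic50_err_nM: float | None = None

    def __post_init__(self) -> None:
        if not self.types:
            raise ValueError(f"ligand {self.ligand_id}: no pose types")
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise ValueError(f"ligand {self.ligand_id}: IC50 must be positive")


class AdjudicationFlags(NamedTuple):
    best_by_fitness: int
    best_by_ie: int
    fitness_correct: bool
    ie_correct: bool


@dataclass
class AdjudicationTable:
    """Per-ligand calls and per-target counts: the summary table."""

    flags: dict[str, AdjudicationFlags]
    n_ligands: int
    fitness_correct: int
    ie_correct: int
    fitness_pct: int
    ie_pct: int
    cutoff: float = DEFAULT_RMSD_CUTOFF

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ligand_id": lig,
                    "best_by_fitness": f.best_by_fitness,
                    "fitness_correct": f.fitness_correct,
                    "best_by_ie": f.best_by_ie,
                    "ie_correct": f.ie_correct,
                }
                for lig, f in self.flags.items()
            ]
        )


def adjudicate(record: LigandRecord, rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF) -> AdjudicationFlags:
    """Nominate best types by fitness and by IE; call each against RMSD.

    Types with missing/failed IE are skipped for the IE nomination (never
    for the fitness one).  A selected type without an RMSD is an error: a
    correctness call cannot be made.
    """
    fitness_by_type = {t: s.fitness for t, s in record.types.items()}
    ie_by_type = {t: s.avg_ie for t, s in record.types.items()}
    best_fit = select_best_pose(fitness_by_type, criterion="fitness")
    best_ie = select_best_pose(fitness_by_type, criterion="avg_ie", ie_by_type=ie_by_type)

    def rmsd_of(t: int) -> float:
        r = record.types[t].rmsd
        if r is None or not np.isfinite(r):
            raise ValueError(f"ligand {record.ligand_id}: selected type {t} has no RMSD")
        return r

    return AdjudicationFlags(
        best_by_fitness=best_fit,
        best_by_ie=best_ie,
        fitness_correct=rmsd_of(best_fit) <= rmsd_cutoff,
        ie_correct=rmsd_of(best_ie) <= rmsd_cutoff,
    )


def _pct(correct: int, total: int) -> int:
    # integer percentage, .5 rounds up (86% = 6/7)
    return int(np.floor(100.0 * correct / total + 0.5))


def summarize_target(
    records: Iterable[LigandRecord],
    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
) -> AdjudicationTable:
    """Counts and integer percentages of correct calls per method."""
    records = list(records)
    if not records:
        raise ValueError("no ligand records")
    flags = {r.ligand_id: adjudicate(r, rmsd_cutoff) for r in records}
    n = len(records)
    fit_ok = sum(f.fitness_correct for f in flags.values())
    ie_ok = sum(f.ie_correct for f in flags.values())
    return AdjudicationTable(
        flags=flags,
        n_ligands=n,
        fitness_correct=fit_ok,
        ie_correct=ie_ok,
        fitness_pct=_pct(fit_ok, n),
        ie_pct=_pct(ie_ok, n),
        cutoff=rmsd_cutoff,
    )


def rank_ligands(
    records: Iterable[LigandRecord],
    key: str,
    scope: str = "best-pose",
    pose_type: int | None = None,
) -> pd.Series:
    """Rank ligands by IC50, averaged IE, or fitness (ties -> mean rank).

    Rank 1 is best: smallest IC50, most negative IE, highest fitness.
    ``scope="best-pose"`` takes each ligand's own best type (by IE for the
    IE key, by fitness for the fitness key); ``scope="fixed-type"`` reads
    the value at ``pose_type`` for every ligand.
    """
    records = list(records)
    if key not in {"ic50", "avg_ie", "fitness"}:
        raise ValueError(f"unknown ranking key {key!r}")
    if scope not in {"best-pose", "fixed-type"}:
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "fixed-type" and pose_type is None:
        raise ValueError("fixed-type scope requires pose_type")

    values = {}
    for r in records:
        if key == "ic50":
            v = r.ic50_nM
        else:
            if scope == "fixed-type":
                stats_ = r.types.get(pose_type)
                v = None if stats_ is None else getattr(stats_, "avg_ie" if key == "avg_ie" else "fitness")
            else:
                f = adjudicate(r)
                t = f.best_by_ie if key == "avg_ie" else f.best_by_fitness
                v = r.types[t].avg_ie if key == "avg_ie" else r.types[t].fitness
            if key == "fitness" and v is not None:
                v = -v  # higher fitness = better = lower rank
        if v is None or not np.isfinite(v):
            raise ValueError(f"ligand {r.ligand_id}: missing value for key {key!r}")
        values[r.ligand_id] = v
    s = pd.Series(values, dtype=float)
    return s.rank(method="average")


class RankAgreement(NamedTuple):
    percent: float
    method: str


def rank_agreement(rank_a: Mapping | pd.Series, rank_b: Mapping | pd.Series, method: str = "spearman") -> RankAgreement:
    """Correlation between two rankings over the same ligand set, as %.

    Spearman by default; Kendall tau available.  The measure used is
    recorded alongside the value.
    """
    a = pd.Series(rank_a).astype(float)
    b = pd.Series(rank_b).astype(float)
    if set(a.index) != set(b.index):
        raise ValueError("rankings cover different ligand sets")
    if len(a) < 3:
        raise ValueError("rank agreement needs at least 3 ligands")
    b = b.reindex(a.index)
    if method == "spearman":
        rho = stats.spearmanr(a.values, b.values).statistic
    elif method == "kendall":
        rho = stats.kendalltau(a.values, b.values).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return RankAgreement(percent=float(100.0 * rho), method=method)


# --- packaged fixtures ----------------------------------------------------


def records_from_frame(df: pd.DataFrame) -> list[LigandRecord]:
    """Build ligand records from a long table.

    Expected columns: ligand_id, pose_type, avg_ie, fitness, gold_rank,
    rmsd, and optionally ic50_nM / ic50_err_nM.  An empty avg_ie cell means
    the IE calculation failed for that type.
    """
    records = []
    for lig, grp in df.groupby("ligand_id", sort=False):
        types = {}
        for _, row in grp.iterrows():
            types[int(row["pose_type"])] = PoseTypeStats(
                avg_ie=None if pd.isna(row["avg_ie"]) else float(row["avg_ie"]),
                fitness=None if pd.isna(row["fitness"]) else float(row["fitness"]),
                gold_rank=None if pd.isna(row.get("gold_rank", np.nan)) else int(row["gold_rank"]),
                rmsd=None if pd.isna(row["rmsd"]) else float(row["rmsd"]),
            )
        ic50 = grp["ic50_nM"].iloc[0] if "ic50_nM" in grp else np.nan
        err = grp["ic50_err_nM"].iloc[0] if "ic50_err_nM" in grp else np.nan
        records.append(
            LigandRecord(
                ligand_id=str(lig),
                types=types,
                ic50_nM=None if pd.isna(ic50) else float(ic50),
                ic50_err_nM=None if pd.isna(err) else float(err),
            )
        )
    return records


def load_fixture_records(target: str) -> list[LigandRecord]:
    """Load the packaged per-ligand results for 'hAR', 'CDK2' or 'ERbeta'."""
    if target not in FIXTURE_FILES:
        raise KeyError(f"unknown target {target!r}; choose from {sorted(FIXTURE_FILES)}")
    path = files("kemlead") / "fixtures" / FIXTURE_FILES[target]
    with path.open() as fh:
        df = pd.read_csv(fh)
    return records_from_frame(df)
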