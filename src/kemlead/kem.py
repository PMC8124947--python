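"""Assemble total and interaction energies from kernel energy records.

The kernel energy method reconstructs the energy of an n-kernel system from
single-kernel energies E_i and double-kernel energies E_ij:

    E_total = sum_{i<j} E_ij - (n - 2) * sum_i E_i

For a strictly pairwise-additive potential this identity is exact:
sum_{i<j} (E_i + E_j + V_ij) - (n-2) sum_i E_i = sum_i E_i + sum_{i<j} V_ij.

The pairwise interaction energy is I_ij = E_ij - E_i - E_j, computed twice -
raw and counterpoise-corrected - and averaged; the protein-ligand
interaction energy is the sum of the averaged ligand-residue I_ij over the
active-site kernels.  More negative means stronger predicted binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

from .energy import ClassicalBackend, EnergyRecord
from .fragmentation import Kernel

PairKey = tuple[str, str]


def pair_key(a: str, b: str) -> PairKey:
    """Order-insensitive key for a kernel pair."""
    return (a, b) if a <= b else (b, a)


class InteractionEnergy(NamedTuple):
    raw: float
    cp: float
    averaged: float


@dataclass
class KEMResult:
    """Per-pair and total interaction energies of one ligand pose."""

    ie_pairwise: dict[PairKey, InteractionEnergy]
    ie_total: float
    n_kernels: int
    missing_pairs: list[PairKey] = field(default_factory=list)
    total_energy: float | None = None

    @property
    def incomplete(self) -> bool:
        return bool(self.missing_pairs)


def kem_total_energy(
    singles: list[EnergyRecord],
    pairs: Mapping[PairKey, EnergyRecord],
) -> float:
    """Total energy from all singles and all unordered pairs (raw energies)."""
    n = len(singles)
    if n < 2:
        raise ValueError("kernel energy reconstruction needs at least 2 kernels")
    for s in singles:
        if s.status != "ok":
            raise ValueError(f"single-kernel record {s.subject} failed")
    labels = [s.subject for s in singles]
    e_pairs = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            key = pair_key(labels[i], labels[j])
            rec = pairs.get(key)
            if rec is None or rec.status != "ok":
                raise ValueError(f"missing or failed pair record {key}")
            e_pairs += rec.e_raw
    e_singles = sum(s.e_raw for s in singles)
    return e_pairs - (n - 2) * e_singles


def pair_interaction_energy(
    e_pair: EnergyRecord,
    e_i: EnergyRecord,
    e_j: EnergyRecord,
) -> InteractionEnergy | None:
    """I_ij = E_ij - E_i - E_j, raw and CP, plus their average.

    Returns ``None`` when any record failed (the pair is then reported as
    missing rather than silently dropped).  Pair records that already hold
    complexation energies (parsed counterpoise logs) are used directly.
    """
    if any(r.status != "ok" for r in (e_pair, e_i, e_j)):
        return None
    if e_pair.is_complexation:
        raw = e_pair.e_raw
        cp = e_pair.e_cp if e_pair.e_cp is not None else raw
    else:
        raw = e_pair.e_raw - e_i.e_raw - e_j.e_raw
        cp_pair = e_pair.e_cp if e_pair.e_cp is not None else e_pair.e_raw
        cp = cp_pair - e_i.e_raw - e_j.e_raw
    return InteractionEnergy(raw=raw, cp=cp, averaged=0.5 * (raw + cp))


def protein_ligand_ie(
    ligand_kernel: Kernel,
    residue_kernels: list[Kernel],
    records: Mapping,
) -> KEMResult:
    """Sum averaged ligand-residue interaction energies over the site.

    ``records`` maps kernel labels to single records and order-insensitive
    ``(label_a, label_b)`` tuples to pair records.  Residue-residue pairs
    are not consulted: the protein-ligand interaction energy is the sum
    over ligand-vs-residue kernel pairs only.  Failed pairs are collected
    in ``missing_pairs`` and flag the result incomplete.
    """
    if not residue_kernels:
        raise ValueError("no residue kernels supplied")
    lig = ligand_kernel.label
    e_lig = records.get(lig)
    ie_pairwise: dict[PairKey, InteractionEnergy] = {}
    missing: list[PairKey] = []
    for rk in residue_kernels:
        key = pair_key(lig, rk.label)
        e_pair = records.get(key) or records.get((key[1], key[0]))
        e_res = records.get(rk.label)
        if e_pair is None or (not e_pair.is_complexation and (e_lig is None or e_res is None)):
            missing.append(key)
            continue
        ie = pair_interaction_energy(
            e_pair,
            e_lig or EnergyRecord(subject=lig, e_raw=0.0),
            e_res or EnergyRecord(subject=rk.label, e_raw=0.0),
        )
        if ie is None:
            missing.append(key)
        else:
            ie_pairwise[key] = ie
    if not ie_pairwise:
        raise ValueError("no ligand-residue pair records available")
    return KEMResult(
        ie_pairwise=ie_pairwise,
        ie_total=sum(ie.averaged for ie in ie_pairwise.values()),
        n_kernels=len(residue_kernels) + 1,
        missing_pairs=missing,
    )


def compute_protein_ligand_ie(
    ligand_kernel: Kernel,
    residue_kernels: list[Kernel],
    backend: ClassicalBackend | None = None,
) -> KEMResult:
    """Run a backend over the ligand-residue pairs and assemble the result."""
    backend = backend or ClassicalBackend()
    records: dict = {ligand_kernel.label: backend.single_energy(ligand_kernel)}
    for rk in residue_kernels:
        records[rk.label] = backend.single_energy(rk)
        records[pair_key(ligand_kernel.label, rk.label)] = backend.pair_energy(ligand_kernel, rk)
    return protein_ligand_ie(ligand_kernel, residue_kernels, records)


def compute_all_records(kernels: list[Kernel], backend: ClassicalBackend | None = None) -> dict:
    """Singles plus every unordered pair - the inputs to kem_total_energy."""
    backend = backend or ClassicalBackend()
    records: dict = {k.label: backend.single_energy(k) for k in kernels}
    for i in range(len(kernels)):
        for j in range(i + 1, len(kernels)):
            ka, kb = kernels[i], kernels[j]
            records[pair_key(ka.label, kb.label)] = backend.pair_energy(ka, kb)
    return records
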