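"""Kernel energies: a classical pairwise backend and a QM file interface.

Two backends satisfy one contract (deterministic energies per kernel and
kernel pair, in kcal/mol):

* ``ClassicalBackend`` evaluates an exact Coulomb + Lennard-Jones pairwise
  potential from per-atom parameters.  Because the potential is strictly
  pairwise-additive, the kernel-energy reconstruction of the total energy
  is algebraically exact, which makes this backend the testing oracle for
  the whole assembly layer.  Counterpoise correction is degenerate here
  (no basis sets), so the CP energy is reported identical to the raw one.

* The external-QM interface writes two-fragment counterpoise job files in
  the Gaussian input dialect and parses counterpoise summary lines from
  logs.  Running a QM program is out of scope; an aborted or truncated log
  becomes a ``failed`` record rather than an exception, so a single bad
  pose never kills a screening run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .fragmentation import Kernel

# Coulomb constant in kcal*A/(mol*e^2) and the Hartree -> kcal/mol factor.
COULOMB_K = 332.0636
HARTREE_TO_KCAL = 627.5095

# Caps default to a generic hydrogen type when they carry no parameters.
CAP_DEFAULT_PARAMS = {"partial_charge": 0.0, "lj_sigma": 2.5, "lj_epsilon": 0.03}


@dataclass
class EnergyRecord:
    """Raw and counterpoise-corrected energies for a kernel or kernel pair.

    ``is_complexation`` marks records whose energies are already interaction
    (complexation) energies, as parsed from a counterpoise log, rather than
    total energies of the subject system.
    """

    subject: str
    e_raw: float | None = None
    e_cp: float | None = None
    status: str = "ok"  # ok | failed
    is_complexation: bool = False

    def __post_init__(self) -> None:
        if self.status == "ok":
            if self.e_raw is None or not np.isfinite(self.e_raw):
                raise ValueError(f"record {self.subject}: ok status requires finite e_raw")
            if self.e_cp is not None and not np.isfinite(self.e_cp):
                raise ValueError(f"record {self.subject}: e_cp must be finite")
        elif self.status == "failed":
            if self.e_raw is not None or self.e_cp is not None:
                raise ValueError(f"record {self.subject}: failed records carry no energies")
        else:
            raise ValueError(f"record {self.subject}: unknown status {self.status!r}")


def _atom_params(kernel: Kernel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    coords, q, sig, eps = [], [], [], []
    for a in kernel.atoms:
        if a.partial_charge is None or a.lj_sigma is None or a.lj_epsilon is None:
            raise ValueError(f"kernel {kernel.label}: atom {a.name} lacks classical parameters")
        coords.append(a.coords)
        q.append(a.partial_charge)
        sig.append(a.lj_sigma)
        eps.append(a.lj_epsilon)
    for a in kernel.caps:
        coords.append(a.coords)
        q.append(a.partial_charge if a.partial_charge is not None else CAP_DEFAULT_PARAMS["partial_charge"])
        sig.append(a.lj_sigma if a.lj_sigma is not None else CAP_DEFAULT_PARAMS["lj_sigma"])
        eps.append(a.lj_epsilon if a.lj_epsilon is not None else CAP_DEFAULT_PARAMS["lj_epsilon"])
    return (np.array(coords), np.array(q), np.array(sig), np.array(eps))


def _pair_terms(r: np.ndarray, qq: np.ndarray, sig: np.ndarray, eps: np.ndarray) -> np.ndarray:
    sr6 = (sig / r) ** 6
    return COULOMB_K * qq / r + 4.0 * eps * (sr6 * sr6 - sr6)


def _intra_energy(coords: np.ndarray, q: np.ndarray, sig: np.ndarray, eps: np.ndarray, label: str) -> float:
    n = len(coords)
    if n < 2:
        return 0.0
    r = pdist(coords)
    if np.any(r == 0):
        raise ValueError(f"{label}: coincident atoms (r = 0)")
    iu, ju = np.triu_indices(n, k=1)
    qq = q[iu] * q[ju]
    s = 0.5 * (sig[iu] + sig[ju])  # Lorentz: arithmetic-mean sigma
    e = np.sqrt(eps[iu] * eps[ju])  # Berthelot: geometric-mean epsilon
    return float(np.sum(_pair_terms(r, qq, s, e)))


def classical_single_energy(kernel: Kernel) -> EnergyRecord:
    """Intra-kernel Coulomb + LJ energy; caps participate as real atoms."""
    coords, q, sig, eps = _atom_params(kernel)
    e = _intra_energy(coords, q, sig, eps, kernel.label)
    return EnergyRecord(subject=kernel.label, e_raw=e)


def cross_energy(ka: Kernel, kb: Kernel) -> float:
    """Sum of pair terms between atoms of two kernels (the interaction)."""
    ca, qa, sa, ea = _atom_params(ka)
    cb, qb, sb, eb = _atom_params(kb)
    r = cdist(ca, cb)
    if np.any(r == 0):
        raise ValueError(f"kernels {ka.label}/{kb.label}: overlapping atoms")
    qq = np.outer(qa, qb)
    s = 0.5 * (sa[:, None] + sb[None, :])
    e = np.sqrt(np.outer(ea, eb))
    return float(np.sum(_pair_terms(r, qq, s, e)))


def classical_pair_energy(ka: Kernel, kb: Kernel) -> EnergyRecord:
    """Energy of the union system of two kernels.

    With no basis sets there is no superposition error, so the counterpoise
    energy equals the raw energy by construction.
    """
    if ka.label == kb.label:
        raise ValueError(f"pair energy needs two distinct kernels, got {ka.label} twice")
    ea = classical_single_energy(ka).e_raw
    eb = classical_single_energy(kb).e_raw
    e = ea + eb + cross_energy(ka, kb)
    return EnergyRecord(subject=f"{ka.label}|{kb.label}", e_raw=e, e_cp=e)


class ClassicalBackend:
    """Deterministic pairwise Coulomb+LJ backend; CP supported (degenerate)."""

    name = "classical"
    supports_cp = True

    def single_energy(self, kernel: Kernel) -> EnergyRecord:
        return classical_single_energy(kernel)

    def pair_energy(self, ka: Kernel, kb: Kernel) -> EnergyRecord:
        return classical_pair_energy(ka, kb)


# --- external-QM interface ------------------------------------------------


def _format_fragment_atoms(kernel: Kernel, frag_idx: int) -> list[str]:
    lines = []
    for a in kernel.all_atoms:
        x, y, z = a.coords
        lines.append(f" {a.element}(Fragment={frag_idx})   {x:14.8f} {y:14.8f} {z:14.8f}")
    return lines


def write_counterpoise_job(
    ka: Kernel,
    kb: Kernel,
    level: str,
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Write a two-fragment counterpoise input in the Gaussian dialect.

    The route line carries the level of theory and ``Counterpoise=2``; the
    charge/multiplicity line lists the supermolecule first and then each
    fragment; atom lines are tagged with their fragment index, caps
    included in their kernel's fragment.  Byte-stable for identical input.
    """
    for k in (ka, kb):
        if k.formal_charge is None:
            raise ValueError(f"kernel {k.label}: formal charge unassigned (run assign_charge_multiplicity)")
    path = Path(path)
    total_charge = ka.formal_charge + kb.formal_charge
    # closed-shell fragments combine to a closed-shell supermolecule
    total_mult = 1 if ka.multiplicity == kb.multiplicity == 1 else max(ka.multiplicity, kb.multiplicity)
    lines = [
        f"%chk={path.stem}.chk",
        f"# {level} Counterpoise=2",
        "",
        title or f"kemlead counterpoise: {ka.label} + {kb.label}",
        "",
        f"{total_charge},{total_mult} {ka.formal_charge},{ka.multiplicity} {kb.formal_charge},{kb.multiplicity}",
    ]
    lines += _format_fragment_atoms(ka, 1)
    lines += _format_fragment_atoms(kb, 2)
    lines.append("")
    path.write_text("\n".join(lines) + "\n")
    return path


_RE_CP_CORRECTED = re.compile(r"corrected complexation energy\s*=\s*(-?\d+\.\d+)", re.IGNORECASE)
_RE_CP_RAW = re.compile(r"raw complexation energy\s*=\s*(-?\d+\.\d+)", re.IGNORECASE)
_RE_NORMAL_TERM = re.compile(r"Normal termination")


def parse_counterpoise_log(path: str | Path) -> EnergyRecord:
    """Extract complexation energies (Hartree) from a counterpoise log.

    Returns energies converted to kcal/mol with ``is_complexation=True``.
    A log without a normal-termination marker or without both complexation
    lines yields a ``failed`` record - never an exception - mirroring how a
    geometry that defeats the QM program is reported downstream.
    """
    path = Path(path)
    subject = path.stem
    try:
        text = path.read_text(errors="replace")
    except OSError:
        return EnergyRecord(subject=subject, status="failed")
    corrected = _RE_CP_CORRECTED.search(text)
    raw = _RE_CP_RAW.search(text)
    if corrected is None or raw is None or _RE_NORMAL_TERM.search(text) is None:
        return EnergyRecord(subject=subject, status="failed")
    return EnergyRecord(
        subject=subject,
        e_raw=float(raw.group(1)) * HARTREE_TO_KCAL,
        e_cp=float(corrected.group(1)) * HARTREE_TO_KCAL,
        is_complexation=True,
    )


def write_synthetic_counterpoise_log(
    path: str | Path,
    raw_hartree: float,
    corrected_hartree: float,
    terminated: bool = True,
) -> Path:
    """Emit a synthetic counterpoise log for round-trip testing.

    This is a stand-in log written by this package (no QM program is run);
    it uses the same summary-line vocabulary the parser recognizes.
    """
    path = Path(path)
    lines = [
        " Counterpoise: doing DCBS calculation, full system.",
        f" Counterpoise corrected energy = {corrected_hartree - 0.5:18.9f}",
        f" Counterpoise: BSSE energy = {abs(raw_hartree - corrected_hartree):18.9f}",
        f" Counterpoise: raw complexation energy = {raw_hartree:18.9f} Hartree",
        f" Counterpoise: corrected complexation energy = {corrected_hartree:18.9f} Hartree",
    ]
    if terminated:
        lines.append(" Normal termination of synthetic log.")
    path.write_text("\n".join(lines) + "\n")
    return path
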