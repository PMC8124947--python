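"""Shared fixtures and the independent brute-force energy oracle.

The oracle evaluates the Coulomb + Lennard-Jones potential by a plain
double loop over atom tuples, independently of the package's vectorized
backend, so kernel-energy reconstruction can be checked against an
implementation that shares no code with it.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from kemlead import Kernel, SyntheticSpec, make_complex, site_kernels

K_COULOMB = 332.0636
CAP_DEFAULTS = (0.0, 2.5, 0.03)  # q, sigma, epsilon for uncapped parameters


def atom_tuples(kernel: Kernel) -> list[tuple]:
    """(x, y, z, q, sigma, eps) per atom, caps with their default type."""
    out = []
    for a in kernel.atoms:
        out.append((*a.coords, a.partial_charge, a.lj_sigma, a.lj_epsilon))
    for a in kernel.caps:
        q = a.partial_charge if a.partial_charge is not None else CAP_DEFAULTS[0]
        s = a.lj_sigma if a.lj_sigma is not None else CAP_DEFAULTS[1]
        e = a.lj_epsilon if a.lj_epsilon is not None else CAP_DEFAULTS[2]
        out.append((*a.coords, q, s, e))
    return out


def _term(a: tuple, b: tuple) -> float:
    r = math.dist(a[:3], b[:3])
    sig = 0.5 * (a[4] + b[4])
    eps = math.sqrt(a[5] * b[5])
    sr6 = (sig / r) ** 6
    return K_COULOMB * a[3] * b[3] / r + 4.0 * eps * (sr6 * sr6 - sr6)


def brute_total(atoms: list[tuple]) -> float:
    """All-pairs energy of one atom set, plain double loop."""
    e = 0.0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            e += _term(atoms[i], atoms[j])
    return e


def brute_cross(a: list[tuple], b: list[tuple]) -> float:
    """Cross-term energy between two atom sets."""
    return sum(_term(x, y) for x in a for y in b)


@pytest.fixture(scope="session")
def toy_complex():
    """One seeded synthetic complex with its kernels (ligand first)."""
    sc = make_complex(SyntheticSpec(seed=42))
    kernels = site_kernels(sc.structure)
    return sc, kernels
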