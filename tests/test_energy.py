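"""Classical backend energies and the counterpoise file interface."""

import numpy as np
import pytest

from kemlead import (
    HARTREE_TO_KCAL,
    Atom,
    Kernel,
    classical_pair_energy,
    classical_single_energy,
    cross_energy,
    parse_counterpoise_log,
    write_counterpoise_job,
)
from kemlead.energy import write_synthetic_counterpoise_log

from conftest import atom_tuples, brute_cross


def _atom(x, y, z, q=0.0, sigma=3.0, eps=0.1, element="C", name="C1"):
    return Atom(
        element=element, name=name, coords=np.array([x, y, z], dtype=float),
        partial_charge=q, lj_sigma=sigma, lj_epsilon=eps,
    )


def _kernel(label, atoms, charge=0):
    return Kernel(label=label, atoms=atoms, formal_charge=charge)


class TestClassicalSingle:
    def test_single_atom_zero(self):
        rec = classical_single_energy(_kernel("k", [_atom(0, 0, 0)]))
        assert rec.e_raw == 0.0

    def test_unit_charges_hand_value(self):
        # 332.0636 * (+1)(-1) / 3.320636 = -100 kcal/mol exactly
        k = _kernel("k", [
            _atom(0, 0, 0, q=1.0, eps=0.0, name="A1"),
            _atom(3.320636, 0, 0, q=-1.0, eps=0.0, name="A2"),
        ])
        assert classical_single_energy(k).e_raw == pytest.approx(-100.0, abs=1e-10)

    def test_lj_zero_crossing_at_sigma(self):
        k = _kernel("k", [
            _atom(0, 0, 0, sigma=3.2, eps=0.2, name="A1"),
            _atom(3.2, 0, 0, sigma=3.2, eps=0.2, name="A2"),
        ])
        assert classical_single_energy(k).e_raw == pytest.approx(0.0, abs=1e-12)

    def test_missing_parameters_name_atom(self):
        bad = Atom(element="C", name="CX9", coords=np.zeros(3))
        with pytest.raises(ValueError, match="CX9"):
            classical_single_energy(Kernel(label="k", atoms=[bad]))

    def test_coincident_atoms_error(self):
        k = _kernel("k", [_atom(0, 0, 0, name="A1"), _atom(0, 0, 0, name="A2")])
        with pytest.raises(ValueError, match="r = 0"):
            classical_single_energy(k)


class TestClassicalPair:
    def test_far_separated_neutral_additivity(self):
        ka = _kernel("a", [_atom(0, 0, 0), _atom(1.5, 0, 0, name="C2")])
        kb = _kernel("b", [_atom(60, 0, 0), _atom(61.5, 0, 0, name="C2")])
        e_pair = classical_pair_energy(ka, kb).e_raw
        e_sum = classical_single_energy(ka).e_raw + classical_single_energy(kb).e_raw
        assert e_pair == pytest.approx(e_sum, abs=1e-6)

    def test_pair_minus_singles_equals_cross_sum(self, toy_complex):
        _, kernels = toy_complex
        lig, res = kernels[0], kernels[1]
        e_pair = classical_pair_energy(lig, res).e_raw
        e_sep = classical_single_energy(lig).e_raw + classical_single_energy(res).e_raw
        oracle = brute_cross(atom_tuples(lig), atom_tuples(res))
        assert e_pair - e_sep == pytest.approx(oracle, rel=1e-12, abs=1e-9)

    def test_symmetry(self, toy_complex):
        _, kernels = toy_complex
        a, b = kernels[0], kernels[2]
        assert classical_pair_energy(a, b).e_raw == classical_pair_energy(b, a).e_raw

    def test_identical_kernel_twice_errors(self):
        k = _kernel("k", [_atom(0, 0, 0)])
        with pytest.raises(ValueError):
            classical_pair_energy(k, k)

    def test_cp_degenerate_to_raw(self, toy_complex):
        _, kernels = toy_complex
        rec = classical_pair_energy(kernels[0], kernels[1])
        assert rec.e_cp == rec.e_raw

    def test_interaction_decays_with_distance(self):
        # neutral kernels: |pair - singles| -> 0 far away
        ka = _kernel("a", [_atom(0, 0, 0)])
        atoms = [_atom(100.0, 0, 0)]
        kb = _kernel("b", atoms)
        gap = classical_pair_energy(ka, kb).e_raw - (
            classical_single_energy(ka).e_raw + classical_single_energy(kb).e_raw
        )
        assert abs(gap) < 1e-6


class TestCounterpoiseFiles:
    def _kernels(self):
        ka = _kernel("ligand", [_atom(0, 0, 0), _atom(1.4, 0, 0, name="C2")], charge=-1)
        kb = _kernel("A:1", [_atom(5, 0, 0, element="N", name="N1")], charge=0)
        return ka, kb

    def test_job_contains_level_and_counterpoise(self, tmp_path):
        ka, kb = self._kernels()
        p = write_counterpoise_job(ka, kb, "MP2/6-311G(d,p)", tmp_path / "j.gjf")
        text = p.read_text()
        assert "MP2/6-311G(d,p)" in text
        assert "Counterpoise=2" in text
        assert "Fragment=1" in text and "Fragment=2" in text
        assert "-1,1 -1,1 0,1" in text  # combined then per-fragment charge/mult

    def test_byte_stable(self, tmp_path):
        ka, kb = self._kernels()
        p1 = write_counterpoise_job(ka, kb, "MP2/6-311G(d,p)", tmp_path / "a.gjf")
        p2 = write_counterpoise_job(ka, kb, "MP2/6-311G(d,p)", tmp_path / "b.gjf")
        assert p1.read_bytes().replace(b"a.chk", b"x.chk") == p2.read_bytes().replace(b"b.chk", b"x.chk")

    def test_caps_counted_in_atom_lines(self, tmp_path):
        ka, kb = self._kernels()
        capped = Kernel(
            label=ka.label, atoms=ka.atoms, formal_charge=-1,
            caps=[Atom(element="H", name="Hcap1", coords=np.array([0.0, 1.09, 0.0]))],
        )
        p = write_counterpoise_job(capped, kb, "HF/3-21G", tmp_path / "c.gjf")
        n_frag1 = sum("Fragment=1" in ln for ln in p.read_text().splitlines())
        assert n_frag1 == len(ka.atoms) + 1

    def test_unassigned_charge_errors(self, tmp_path):
        ka, kb = self._kernels()
        ka.formal_charge = None
        with pytest.raises(ValueError, match="charge"):
            write_counterpoise_job(ka, kb, "HF/3-21G", tmp_path / "d.gjf")


class TestCounterpoiseLogParsing:
    def test_hartree_conversion(self, tmp_path):
        p = write_synthetic_counterpoise_log(tmp_path / "ok.log", raw_hartree=-0.012, corrected_hartree=-0.01)
        rec = parse_counterpoise_log(p)
        assert rec.status == "ok"
        assert rec.e_cp == pytest.approx(-6.275095)
        assert rec.e_raw == pytest.approx(-0.012 * HARTREE_TO_KCAL)
        assert rec.is_complexation

    def test_truncated_log_fails_softly(self, tmp_path):
        p = write_synthetic_counterpoise_log(tmp_path / "t.log", -0.012, -0.01, terminated=False)
        rec = parse_counterpoise_log(p)
        assert rec.status == "failed"
        assert rec.e_raw is None and rec.e_cp is None

    def test_packaged_fixture_logs(self):
        from importlib.resources import files

        fx = files("kemlead") / "fixtures"
        ok = parse_counterpoise_log(fx / "counterpoise_ok.log")
        assert ok.e_cp == pytest.approx(-6.275095)
        assert parse_counterpoise_log(fx / "counterpoise_truncated.log").status == "failed"

    @pytest.mark.parametrize("raw,cp", [(-0.02, -0.015), (0.001, 0.0005), (-1.5, -1.4)])
    def test_round_trip_recovers_planted_energies(self, tmp_path, raw, cp):
        p = write_synthetic_counterpoise_log(tmp_path / "rt.log", raw, cp)
        rec = parse_counterpoise_log(p)
        assert rec.e_raw == pytest.approx(raw * HARTREE_TO_KCAL, rel=1e-9)
        assert rec.e_cp == pytest.approx(cp * HARTREE_TO_KCAL, rel=1e-9)
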