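"""Protocell formulas and event mechanics."""

import math

import pytest
import sympy

from rnaworld._rng import BufferedRNG
from rnaworld.chemistry import Compartment, MoleculePools
from rnaworld.params import ParameterSet
from rnaworld.protocell import (
    Protocell,
    amphiphile_leave_probability,
    cell_break,
    cell_fusion,
    cytophagy,
    divide_cell,
    division_probability,
    membrane_exchange,
    membrane_formation_probability,
    permeation,
    precursor_permeation_in_probability,
)
from rnaworld.sequences import Strand


class TestMembraneFormation:
    def test_at_lower_limit_equals_base_rate(self, params):
        assert membrane_formation_probability(params.l_am, params) == pytest.approx(0.01)

    def test_below_limit_zero(self, params):
        assert membrane_formation_probability(params.l_am - 1, params) == 0.0

    def test_one_above_limit(self, params):
        # 1 - 0.99^2
        assert membrane_formation_probability(501, params) == pytest.approx(0.0199)


class TestLeaveProbability:
    def test_no_ions_gives_base_rate(self, params):
        assert amphiphile_leave_probability(1000, 0, params) == params.p_alm

    def test_osmotic_suppression_value(self, params):
        # P_ALM / (1 + 10*500/500^1.5)
        got = amphiphile_leave_probability(1000, 500, params)
        assert got == pytest.approx(1.3820e-4, rel=1e-3)

    def test_strictly_decreasing_in_n(self, params):
        vals = [amphiphile_leave_probability(1000, n, params) for n in range(0, 2000, 50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestPermeationProbability:
    def test_unit_size_no_donnan(self, params):
        assert precursor_permeation_in_probability(params.l_am, 0, params) == params.p_npp

    def test_size_factor(self, params):
        assert precursor_permeation_in_probability(1000, 0, params) == pytest.approx(0.2)

    def test_donnan_suppression(self, params):
        base = precursor_permeation_in_probability(1000, 0, params)
        assert precursor_permeation_in_probability(1000, 800, params) < base

    def test_clamped_to_one(self):
        p = ParameterSet(p_npp=1.0)
        assert precursor_permeation_in_probability(50_000, 0, p) == 1.0


class TestDivisionProbability:
    def test_zero_at_twice_lower_limit(self, params):
        assert division_probability(2 * params.l_am, params) == 0.0

    def test_value_at_b_2000(self, params):
        assert division_probability(2000, params) == pytest.approx(5e-5)

    def test_monotone_increasing(self, params):
        vals = [division_probability(b, params) for b in range(1000, 10_000, 500)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))


def test_formula_lattice_matches_sympy(params):
    """All closed-form probabilities vs an arbitrary-precision evaluation."""
    psp = sympy.Rational(38, 100)
    pmf = sympy.Rational(1, 100)
    palm = sympy.Rational(2, 10_000)
    pnpp = sympy.Rational(1, 10)
    pcd = sympy.Rational(1, 10_000)
    lam, fop, fde = 500, 10, 10
    for b in (500, 800, 1000, 1500, 2500, 5000):
        for n in (0, 10, 250, 800, 3000):
            conc = sympy.Integer(n) / (sympy.Rational(b, 2) ** sympy.Rational(3, 2))
            want_leave = float(palm / (1 + fop * conc))
            assert amphiphile_leave_probability(b, n, params) == pytest.approx(
                want_leave, rel=1e-9)
            want_in = float(min(1, pnpp * sympy.Rational(b, lam) / (1 + fde * conc)))
            assert precursor_permeation_in_probability(b, n, params) == pytest.approx(
                want_in, rel=1e-9)
        want_div = float(max(0, pcd * (1 - sympy.Rational(2 * lam, b))))
        assert division_probability(b, params) == pytest.approx(want_div, rel=1e-9)
    for a in (500, 501, 520, 700):
        want_mf = float(1 - (1 - pmf) ** (a - lam + 1))
        assert membrane_formation_probability(a, params) == pytest.approx(
            want_mf, rel=1e-9)
    for r in (1, 2, 5, 18, 30):
        from rnaworld.replication import separation_probability
        want_sep = float(psp ** sympy.Rational(r + 1, 2))
        assert separation_probability(r, params) == pytest.approx(want_sep, rel=1e-9)


def _cell_with_inventory():
    cell = Protocell(b=1200)
    cell.interior.pools.np_ = 40
    cell.interior.pools.nt = [5, 6, 7, 8]
    cell.interior.pools.ap = 30
    cell.interior.pools.am = 20
    cell.interior.strands.append(Strand("ACGUCUCGACAGAUACGU"))
    cell.interior.strands.append(Strand("ACGUACGU"))
    cell.refresh_n()
    return cell


def test_ion_tally_counts_nucleotides_and_residues():
    cell = _cell_with_inventory()
    assert cell.n == (5 + 6 + 7 + 8) + (18 + 8)
    assert cell.n == cell.recompute_n()


class TestEventConservation:
    def test_break_conserves_ledgers(self, params, rng):
        p = ParameterSet(p_cb=1.0)
        cell = _cell_with_inventory()
        ext = Compartment(pools=MoleculePools(np_=3, am=7))
        nt_before = cell.interior.nucleotide_equivalents() + ext.nucleotide_equivalents()
        am_before = cell.b + cell.interior.pools.am + ext.pools.am + cell.interior.pools.ap + ext.pools.ap
        assert cell_break(cell, ext, p, rng)
        assert ext.nucleotide_equivalents() == nt_before
        assert ext.pools.am + ext.pools.ap == am_before

    def test_fusion_adds_membranes_and_contents(self):
        a, b = _cell_with_inventory(), _cell_with_inventory()
        a.b, b.b = 900, 1100
        survivor = cell_fusion(a, b)
        assert survivor is b  # larger membrane wins the room
        assert survivor.b == 2000
        assert survivor.recompute_n() == survivor.n
        assert len(survivor.interior.strands) == 4

    def test_cytophagy_engulfs_everything(self, rng):
        p = ParameterSet(p_cc=1.0)
        cell = _cell_with_inventory()
        n0 = cell.n
        neighbor = Compartment(pools=MoleculePools(np_=9, nt=[1, 1, 1, 1]))
        neighbor.strands.append(Strand(p.cs_tag + p.cs_nsr + p.cs_tag))
        assert cytophagy(cell, neighbor, p, rng)
        assert neighbor.pools.np_ == 0 and not neighbor.strands
        assert cell.n == n0 + 4 + 18  # engulfed ions join the tally

    def test_cytophagy_empty_neighbor_is_vacuous(self, rng):
        p = ParameterSet(p_cc=1.0)
        cell = _cell_with_inventory()
        n0 = cell.n
        assert cytophagy(cell, Compartment(), p, rng)
        assert cell.n == n0


class TestDivision:
    def test_partition_is_even_on_average(self):
        rng = BufferedRNG(5)
        lands = 0
        trials = 400
        for _ in range(trials):
            cell = Protocell(b=2000)
            cell.interior.pools.np_ = 100
            daughter = divide_cell(cell, rng)
            assert cell.b + daughter.b == 2000
            lands += daughter.interior.pools.np_
        frac = lands / (trials * 100)
        assert frac == pytest.approx(0.5, abs=0.013)  # ~99% binomial CI

    def test_complexes_travel_together(self, rng):
        from rnaworld.replication import rep_bind
        p = ParameterSet(p_rbt=1.0)
        found_split = False
        for _ in range(50):
            cell = Protocell(b=2000)
            rep = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
            t = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
            cell.interior.strands.extend([rep, t])
            assert rep_bind(rep, t, p, rng) is not None
            daughter = divide_cell(cell, rng)
            sides = {len(cell.interior.strands), len(daughter.interior.strands)}
            assert sides == {0, 2}  # the bound pair never separates
        assert not found_split

    def test_n_cache_consistent_after_division(self, rng):
        cell = _cell_with_inventory()
        cell.b = 3000
        daughter = divide_cell(cell, rng)
        assert cell.n == cell.recompute_n()
        assert daughter.n == daughter.recompute_n()


class TestClosedCell:
    def test_no_permeation_when_rates_zero(self, rng):
        p = ParameterSet(p_npp=0.0, p_app=0.0)
        cell = _cell_with_inventory()
        ext = Compartment(pools=MoleculePools(np_=1000, ap=1000))
        inner_before = cell.interior.nucleotide_equivalents()
        for _ in range(200):
            permeation(cell, ext, p, rng)
        assert cell.interior.nucleotide_equivalents() == inner_before
        assert ext.pools.np_ == 1000

    def test_membrane_exchange_conserves_amphiphile_equivalents(self, params, rng):
        cell = _cell_with_inventory()
        ext = Compartment(pools=MoleculePools(am=300, ap=50))
        total = (cell.b + cell.interior.pools.am + cell.interior.pools.ap
                 + ext.pools.am + ext.pools.ap)
        for _ in range(100):
            membrane_exchange(cell, ext, params, rng)
        after = (cell.b + cell.interior.pools.am + cell.interior.pools.ap
                 + ext.pools.am + ext.pools.ap)
        assert after == total
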