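"""Duplex mechanics and the tag-mediated REP copy cycle."""

import itertools

import pytest
import sympy

from rnaworld._rng import BufferedRNG
from rnaworld.chemistry import Compartment, MoleculePools
from rnaworld.params import ParameterSet
from rnaworld.replication import (
    attract_substrate,
    collision_round,
    rep_bind,
    rep_bindable,
    rep_extend,
    separation_probability,
    turn_to_template,
)
from rnaworld.sequences import Strand, reverse_complement


class TestSeparationProbability:
    def test_single_pair_reduces_to_base_rate(self, params):
        assert separation_probability(1, params) == pytest.approx(0.38)

    def test_three_pairs(self, params):
        # P_SP^((3+1)/2) = P_SP^2
        assert separation_probability(3, params) == pytest.approx(0.1444)

    def test_matches_arbitrary_precision_for_r_up_to_30(self, params):
        psp = sympy.Rational(38, 100)
        for r in range(1, 31):
            exact = float(psp ** sympy.Rational(r + 1, 2))
            assert separation_probability(r, params) == pytest.approx(exact, rel=1e-12)

    def test_strictly_decreasing(self, params):
        vals = [separation_probability(r, params) for r in range(1, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_rejects_zero_pairs(self, params):
        with pytest.raises(ValueError):
            separation_probability(0, params)


class TestTurnToTemplate:
    def test_rep_bound_is_deterministic(self, params, rng):
        s = Strand("ACGUA")
        assert turn_to_template(s, rep_bound=True, p=params, rng=rng)

    def test_never_without_rep_at_zero_rate(self, rng):
        p = ParameterSet(p_rtt=0.0)
        s = Strand("ACGUA")
        for _ in range(20):
            assert not turn_to_template(s, rep_bound=False, p=p, rng=rng)

    def test_frequency_near_default(self, params):
        rng = BufferedRNG(7)
        hits = sum(
            turn_to_template(Strand("ACGUA"), False, params, rng)
            for _ in range(100_000)
        )
        assert hits / 100_000 == pytest.approx(params.p_rtt, abs=0.005)


class TestAttractSubstrate:
    def test_short_template_rejected(self, params, rng):
        comp = Compartment()
        t = Strand("ACGU")  # below the 5-nt template minimum
        comp.strands.append(t)
        assert attract_substrate(t, "A", comp, params, rng) is None

    def test_perfect_complement_anneals_fully(self, rng):
        p = ParameterSet(p_at=1.0, p_rtt=1.0)
        comp = Compartment()
        t = Strand("ACGUCUCGACAGAUACGU")
        sub = Strand(reverse_complement(t.seq))
        comp.strands.extend([t, sub])
        seg = attract_substrate(t, sub, comp, p, rng)
        assert seg is not None and seg.offset == 0 and len(seg) == 18
        assert not seg.mismatches

    def test_no_false_pairs_when_pfp_zero(self, rng):
        p = ParameterSet(p_at=1.0, p_rtt=1.0, p_fp=0.0)
        comp = Compartment()
        t = Strand("AAAAAAAA")
        comp.strands.append(t)
        for _ in range(200):
            seg = attract_substrate(t, "C", comp, p, rng)  # C cannot pair A
            assert seg is None

    def test_mononucleotide_mismatch_rate_tracks_pfp(self):
        # a substrate with no complementary register anneals only by false
        # pairing, at rate ~ P_FP
        p = ParameterSet(p_at=1.0, p_rtt=1.0, p_fp=0.01)
        rng = BufferedRNG(3)
        hits = 0
        n = 200_000
        for _ in range(n):
            comp = Compartment()
            t = Strand("AAAAA")
            comp.strands.append(t)
            if attract_substrate(t, "C", comp, p, rng) is not None:
                hits += 1
        assert hits / n == pytest.approx(p.p_fp, rel=0.15)


class TestRepBind:
    def test_untagged_template_never_binds(self, params, rng):
        rep = Strand(params.cs_tag + params.cs_rep + params.cs_tag)
        t = Strand("AAAAAAAA")
        assert rep_bind(rep, t, params, rng) is None

    def test_binding_frequency_matches_p_rbt(self, params):
        rng = BufferedRNG(11)
        hits = 0
        n = 100_000
        for _ in range(n):
            rep = Strand(params.cs_tag + params.cs_rep + params.cs_tag)
            t = Strand(params.cs_tag + params.cs_rep + params.cs_tag)
            if rep_bind(rep, t, params, rng) is not None:
                hits += 1
        assert hits / n == pytest.approx(params.p_rbt, abs=0.005)

    def test_no_second_rep_on_a_bound_template(self, rng):
        p = ParameterSet(p_rbt=1.0)
        rep1 = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        rep2 = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        t = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        assert rep_bind(rep1, t, p, rng) is not None
        assert rep_bind(rep2, t, p, rng) is None

    def test_tag_must_not_be_duplexed(self, rng):
        # a stable (>= 2 nt) duplex over the 5' tag blocks recognition ...
        p = ParameterSet(p_rbt=1.0, p_at=1.0, p_rtt=1.0, p_fp=0.0)
        comp = Compartment()
        t = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        comp.strands.append(t)
        blocker = Strand(reverse_complement(t.seq[:6]))  # covers tag + 2 nt
        comp.strands.append(blocker)
        seg = attract_substrate(t, blocker, comp, p, rng)
        assert seg is not None and seg.offset == 0
        assert not rep_bindable(t, p)

    def test_stray_monomer_on_tag_does_not_block(self, rng):
        # ... but a transiently annealed mononucleotide does not
        p = ParameterSet(p_rbt=1.0)
        comp = Compartment()
        t = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        comp.strands.append(t)
        from rnaworld.replication import Duplex, Segment
        d = Duplex(template=t)
        t.as_template = d
        mono = Strand("U")  # pairs the 5'-terminal A
        comp.strands.append(mono)
        d.add_segment(Segment(strand=mono, offset=0))
        assert rep_bindable(t, p)
        rep = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        comp.strands.append(rep)
        binding = rep_bind(rep, t, p, rng, comp)
        assert binding is not None
        # the monomer was displaced back into the nucleotide pool
        assert comp.pools.nt_total() == 1 and mono not in comp.strands

    def test_bare_tag_below_template_minimum(self, params, rng):
        # a 4-nt bare-tag strand cannot serve as a REP template
        rep = Strand(params.cs_tag + params.cs_rep + params.cs_tag)
        assert rep_bind(rep, Strand("ACGU"), params, rng) is None


def _copy_with_rep(template_seq: str, p, rng):
    """Drive one full REP-catalysed copy; returns the product sequence."""
    comp = Compartment(pools=MoleculePools(nt=[10_000] * 4))
    rep = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
    t = Strand(template_seq)
    comp.strands.extend([rep, t])
    binding = rep_bind(rep, t, p, rng)
    assert binding is not None
    duplex = binding.duplex
    for _ in range(10 * len(template_seq)):
        if duplex.rep_binding is None:
            break
        rep_extend(binding, comp, p, rng)
    assert duplex.rep_binding is None, "copy did not complete"
    (seg,) = duplex.segments
    return seg.strand.seq


class TestRepExtend:
    FAITHFUL = ParameterSet(p_rbt=1.0, p_at=1.0, p_tlr=1.0, p_fp=0.0,
                            p_flr=0.0, p_rd=0.0, p_bb=0.0)

    def test_full_copy_is_reverse_complement(self, rng):
        p = self.FAITHFUL
        t_seq = p.cs_tag + p.cs_rep + p.cs_tag
        product = _copy_with_rep(t_seq, p, rng)
        assert product == reverse_complement(t_seq)
        # and, because the tag is palindromic, the copy is again tag-flanked
        assert product.startswith(p.cs_tag) and product.endswith(p.cs_tag)

    def test_exhaustive_faithful_copy_all_short_templates(self, rng):
        # every tagged template up to 8 nt copies to its exact reverse
        # complement when false pairing and false ligation are off
        p = self.FAITHFUL
        tag = p.cs_tag
        for extra_len in (1, 2, 3, 4):
            for extra in itertools.product("AUCG", repeat=extra_len):
                t_seq = tag + "".join(extra)
                product = _copy_with_rep(t_seq, p, rng)
                assert product == reverse_complement(t_seq)

    def test_stall_without_mononucleotides(self, rng):
        p = self.FAITHFUL
        comp = Compartment()  # no nucleotides at all
        rep = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        t = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        comp.strands.extend([rep, t])
        binding = rep_bind(rep, t, p, rng)
        for _ in range(50):
            rep_extend(binding, comp, p, rng)
        assert binding.product is None  # stalled, not erroring
        assert binding.duplex.rep_binding is binding

    def test_recognition_releases_at_tag_segment(self, rng):
        p = self.FAITHFUL
        comp = Compartment(pools=MoleculePools(nt=[1000] * 4))
        rep = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        t = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        comp.strands.extend([rep, t])
        binding = rep_bind(rep, t, p, rng)
        assert binding.recognition_paired
        while binding.copy_position >= len(p.cs_tag):
            rep_extend(binding, comp, p, rng)
        assert not binding.recognition_paired

    def test_catalysed_vs_nonenzymatic_speedup(self, params):
        # the catalysed junction rate dwarfs the non-enzymatic one
        assert params.p_tlr / params.p_tl == pytest.approx(9000)

    def test_residue_conservation_through_copy(self, rng):
        p = self.FAITHFUL
        comp = Compartment(pools=MoleculePools(nt=[100] * 4))
        rep = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        t = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        comp.strands.extend([rep, t])
        before = comp.nucleotide_equivalents()
        binding = rep_bind(rep, t, p, rng)
        for _ in range(100):
            if binding.duplex.rep_binding is None:
                break
            rep_extend(binding, comp, p, rng)
        assert comp.nucleotide_equivalents() == before


class TestCollisionRound:
    def test_single_entity_no_events(self, params, rng):
        comp = Compartment()
        comp.strands.append(Strand("ACGUA"))
        collision_round(comp, params, rng)
        assert len(comp.strands) == 1 and comp.strands[0].is_free

    def test_rep_binds_tagged_template_on_collision(self, rng):
        p = ParameterSet(p_rbt=1.0)
        comp = Compartment()
        rep = Strand(p.cs_tag + p.cs_rep + p.cs_tag)
        t = Strand(p.cs_tag + p.cs_nsr + p.cs_tag)
        comp.strands.extend([rep, t])
        collision_round(comp, p, rng)
        assert rep.rep_job is not None
        assert t.as_template is not None and t.as_template.rep_binding is rep.rep_job

    def test_nucleotide_pairs_random_ligation(self, rng):
        p = ParameterSet(p_rl=1.0)
        comp = Compartment(pools=MoleculePools(nt=[2, 0, 0, 0]))
        collision_round(comp, p, rng)
        assert [s.seq for s in comp.strands] == ["AA"]
        assert comp.pools.nt_total() == 0
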