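"""Small-molecule chemistry of one compartment.

A compartment (a grid room's free contents, or a protocell interior) holds
featureless nucleotide precursors, free nucleotides by letter, amphiphile
precursors, free amphiphiles, and a list of RNA strands.  The events here are
all per-molecule Bernoulli trials per Monte Carlo step, sampled as binomial
draws over the pools:

  precursor -> nucleotide     P_NF (or P_NFR if a free synthetase ribozyme,
                              NSR, shares the compartment; one NSR saturates)
  nucleotide -> precursor     P_ND (letter identity lost)
  chain-end residue decay     P_NDE per unpaired terminal residue
  bond breaking               P_BB single-chain, P_BB^(3/2) in a duplex
  random end-to-end ligation  P_RL on collision
  amphiphile formation/decay  P_AF / P_AD (free), P_ADM (in membrane)

Nucleotide-equivalents (precursors + free nucleotides + chain residues) and
amphiphile-equivalents (precursors + free + membrane) are conserved by every
event: matter converts, it is never created or destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import BASES, Strand, classify

__all__ = [
    "MoleculePools",
    "Compartment",
    "nucleotide_formation",
    "nucleotide_decay",
    "end_residue_decay",
    "bond_break_probability",
    "random_ligation",
    "amphiphile_events",
]

_UNIFORM4 = np.full(4, 0.25)


@dataclass
class MoleculePools:
    """Counts of the four small-molecule species (nt is per-letter A,U,C,G)."""

    np_: int = 0
    nt: list = field(default_factory=lambda: [0, 0, 0, 0])
    ap: int = 0
    am: int = 0

    def nt_total(self) -> int:
        n = self.nt
        return n[0] + n[1] + n[2] + n[3]

    def copy(self) -> "MoleculePools":
        return MoleculePools(self.np_, list(self.nt), self.ap, self.am)

    def add_nt(self, counts) -> None:
        for i in range(4):
            self.nt[i] += int(counts[i])

    def draw_letter(self, rng) -> int:
        """Remove and return one nucleotide letter index, pool-weighted."""
        u = rng.uniform() * self.nt_total()
        acc = 0
        for i in range(4):
            acc += self.nt[i]
            if u < acc:
                self.nt[i] -= 1
                return i
        self.nt[3] -= 1
        return 3


@dataclass
class Compartment:
    """Pools plus resident strands; the unit molecules interact within."""

    pools: MoleculePools = field(default_factory=MoleculePools)
    strands: list = field(default_factory=list)

    def residue_count(self) -> int:
        return sum(len(s.seq) for s in self.strands)

    def nucleotide_equivalents(self) -> int:
        return self.pools.np_ + self.pools.nt_total() + self.residue_count()

    def has_free_nsr(self, params) -> bool:
        """A free, unhybridised NSR-functional strand saturates catalysis."""
        from .replication import strand_roles  # cached classification

        return any(
            s.is_free and strand_roles(s, params).nsr_functional for s in self.strands
        )


def nucleotide_formation(pools: MoleculePools, nsr_present: bool, p, rng) -> MoleculePools:
    """Precursors convert independently; new letters are uniform over A,U,C,G."""
    rate = p.p_nfr if nsr_present else p.p_nf
    if pools.np_ > 0 and rate > 0.0:
        k = int(rng.binomial(pools.np_, rate))
        if k:
            pools.np_ -= k
            pools.add_nt(rng.multinomial(k, _UNIFORM4))
    return pools


def nucleotide_decay(pools: MoleculePools, p, rng) -> MoleculePools:
    """Free nucleotides revert to precursors with P_ND; letter identity lost."""
    if p.p_nd > 0.0:
        for i in range(4):
            n = int(pools.nt[i])
            if n:
                k = int(rng.binomial(n, p.p_nd))
                pools.nt[i] -= k
                pools.np_ += k
    return pools


def end_residue_decay(strand: Strand, pools: MoleculePools, p, rng) -> bool:
    """Unpaired terminal residues decay with P_NDE, crediting one precursor each.

    Returns True if the strand vanished (a 1-mer losing its residue).  Callers
    owning duplex bookkeeping (template overhangs) trim through the duplex
    API instead; this function handles free strands.
    """
    lost_5p = strand.end_unpaired("5p") and rng.bernoulli(p.p_nde)
    lost_3p = len(strand.seq) > 1 and strand.end_unpaired("3p") and rng.bernoulli(p.p_nde)
    if lost_5p:
        strand.seq = strand.seq[1:]
        pools.np_ += 1
    if lost_3p:
        strand.seq = strand.seq[:-1]
        pools.np_ += 1
    return len(strand.seq) == 0


def bond_break_probability(site_in_duplex: bool, p) -> float:
    """P_BB at a single-chain site; P_BB^(3/2) where two parallel bonds must break."""
    return p.p_bb ** 1.5 if site_in_duplex else p.p_bb


def random_ligation(a, b, p, rng):
    """End-to-end concatenation on collision, with P_RL.

    ``a``/``b`` are sequences (a mononucleotide is a length-1 sequence).
    Returns the joined sequence, or None.  Orientation is uniform between the
    two admissible joins (3' of one to 5' of the other).
    """
    if not rng.bernoulli(p.p_rl):
        return None
    return a + b if rng.bernoulli(0.5) else b + a


def amphiphile_events(pools: MoleculePools, membrane_b: int, p, rng) -> int:
    """Amphiphile formation and decay; returns the updated membrane count.

    Free precursors form amphiphiles with P_AF; free amphiphiles decay with
    P_AD; membrane amphiphiles decay with P_ADM (< P_AD: the membrane
    protects), each decayed one leaving the membrane as a precursor in the
    exterior pools.
    """
    if pools.ap > 0 and p.p_af > 0.0:
        k = int(rng.binomial(pools.ap, p.p_af))
        pools.ap -= k
        pools.am += k
    if pools.am > 0 and p.p_ad > 0.0:
        k = int(rng.binomial(pools.am, p.p_ad))
        pools.am -= k
        pools.ap += k
    if membrane_b > 0 and p.p_adm > 0.0:
        k = int(rng.binomial(membrane_b, p.p_adm))
        membrane_b -= k
        pools.ap += k
    return membrane_b
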