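"""Membrane assembly and protocell events.

A protocell is a bilayer membrane of ``b`` amphiphiles occupying one grid
room and enclosing an interior compartment.  ``b/2`` is a scale measure of
membrane surface, so ``(b/2)^(3/2)`` scales the enclosed volume, and
``n/(b/2)^(3/2)`` — with ``n`` the impermeable-ion tally (free nucleotides
plus RNA residues inside) — is an interior ion concentration.  Two corrections
derive from it:

  osmotic swelling   amphiphiles leave a swollen membrane less readily:
                     P_ALM / (1 + F_OP * n/(b/2)^(3/2))
  Donnan exclusion   like-charged precursors enter against the interior
                     charge: P_NPP * (b/L_AM) / (1 + F_DE * n/(b/2)^(3/2))

Membranes self-assemble once a room gathers at least L_AM free amphiphiles
(probability 1-(1-P_MF)^(a-L_AM+1)), grow by amphiphile joining, shed by
leaving/decay, and the cell may break, divide (only above b = 2*L_AM), fuse
with a neighbour, engulf an adjacent room's molecules (cytophagy), or move.
Nucleotides and RNA never cross an intact membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemistry import Compartment, MoleculePools

__all__ = [
    "Protocell",
    "membrane_formation_probability",
    "amphiphile_leave_probability",
    "precursor_permeation_in_probability",
    "division_probability",
    "membrane_exchange",
    "permeation",
    "cell_break",
    "cytophagy",
    "cell_fusion",
    "divide_cell",
]


@dataclass(eq=False)
class Protocell:
    """Membrane amphiphile count, interior inventory, cached ion tally."""

    b: int
    interior: Compartment = field(default_factory=Compartment)
    room: int = -1
    _n: int = 0

    def __post_init__(self):
        if self.b < 1:
            raise ValueError("a protocell needs b >= 1 membrane amphiphiles")
        self.refresh_n()

    @property
    def n(self) -> int:
        """Impermeable-ion quantity, in nucleotide-residue units (cached)."""
        return self._n

    def recompute_n(self) -> int:
        return self.interior.pools.nt_total() + self.interior.residue_count()

    def refresh_n(self) -> None:
        self._n = self.recompute_n()


def membrane_formation_probability(a: int, p) -> float:
    """1-(1-P_MF)^(a-L_AM+1) for a >= L_AM amphiphiles in a room, else 0."""
    if a < p.l_am:
        return 0.0
    return 1.0 - (1.0 - p.p_mf) ** (a - p.l_am + 1)


def _crowding(n: float, b: float, factor: float) -> float:
    return 1.0 + factor * n / (b / 2.0) ** 1.5


def amphiphile_leave_probability(b: int, n: int, p) -> float:
    """Osmotically corrected per-amphiphile leave rate: P_ALM/(1+F_OP*n/(b/2)^(3/2))."""
    return p.p_alm / _crowding(n, b, p.f_op)


def precursor_permeation_in_probability(b: int, n: int, p) -> float:
    """Per exterior nucleotide precursor: P_NPP*(b/L_AM)/(1+F_DE*n/(b/2)^(3/2)), clamped."""
    return min(1.0, p.p_npp * (b / p.l_am) / _crowding(n, b, p.f_de))


def division_probability(b: int, p) -> float:
    """max(0, P_CD*(1-2*L_AM/b)): no division at or below twice the lower limit."""
    return max(0.0, p.p_cd * (1.0 - 2.0 * p.l_am / b))


def membrane_exchange(cell: Protocell, exterior: Compartment, p, rng) -> None:
    """Joining, osmotically corrected leaving, and in-membrane decay.

    Free amphiphiles join from the cell's room and from the interior alike
    (symmetric joining); leavers and decayed precursors are deposited in the
    exterior room, so the interior ion tally is untouched.
    """
    if exterior.pools.am > 0:
        k = int(rng.binomial(exterior.pools.am, p.p_ajm))
        exterior.pools.am -= k
        cell.b += k
    if cell.interior.pools.am > 0:
        k = int(rng.binomial(cell.interior.pools.am, p.p_ajm))
        cell.interior.pools.am -= k
        cell.b += k
    if cell.b > 0:
        leave_p = amphiphile_leave_probability(cell.b, cell.n, p)
        k = int(rng.binomial(cell.b, leave_p))
        cell.b -= k
        exterior.pools.am += k
    if cell.b > 0 and p.p_adm > 0.0:
        k = int(rng.binomial(cell.b, p.p_adm))
        cell.b -= k
        exterior.pools.ap += k


def permeation(cell: Protocell, exterior: Compartment, p, rng) -> None:
    """Cross-membrane diffusion of the two permeable precursor classes.

    Nucleotide precursors enter with the size/Donnan-corrected rate and exit
    with flat P_NPP; amphiphile precursors cross with flat P_APP both ways.
    Nucleotides and RNA are impermeable.  The two directions are sampled
    simultaneously — each from the pre-exchange stock — so a permeability of
    1 equilibrates the compartments instead of emptying the interior.
    """
    p_in = precursor_permeation_in_probability(cell.b, cell.n, p)
    k_in = int(rng.binomial(exterior.pools.np_, p_in)) if exterior.pools.np_ else 0
    k_out = (int(rng.binomial(cell.interior.pools.np_, p.p_npp))
             if cell.interior.pools.np_ and p.p_npp > 0.0 else 0)
    exterior.pools.np_ += k_out - k_in
    cell.interior.pools.np_ += k_in - k_out
    if p.p_app > 0.0:
        a_in = int(rng.binomial(exterior.pools.ap, p.p_app)) if exterior.pools.ap else 0
        a_out = (int(rng.binomial(cell.interior.pools.ap, p.p_app))
                 if cell.interior.pools.ap else 0)
        exterior.pools.ap += a_out - a_in
        cell.interior.pools.ap += a_in - a_out


def _merge_compartments(dst: Compartment, src: Compartment) -> None:
    dst.pools.np_ += src.pools.np_
    dst.pools.add_nt(src.pools.nt)
    dst.pools.ap += src.pools.ap
    dst.pools.am += src.pools.am
    dst.strands.extend(src.strands)
    src.pools = MoleculePools()
    src.strands = []


def cell_break(cell: Protocell, exterior: Compartment, p, rng) -> bool:
    """With P_CB the membrane dissolves into free amphiphiles; the interior spills."""
    if not rng.bernoulli(p.p_cb):
        return False
    exterior.pools.am += cell.b
    cell.b = 0
    _merge_compartments(exterior, cell.interior)
    return True


def cytophagy(cell: Protocell, neighbor: Compartment, p, rng) -> bool:
    """With P_CC the cell engulfs every free molecule of an adjacent room."""
    if not rng.bernoulli(p.p_cc):
        return False
    _merge_compartments(cell.interior, neighbor)
    cell.refresh_n()
    return True


def cell_fusion(a: Protocell, b_cell: Protocell) -> Protocell:
    """Merge membranes and interiors; returns the surviving (larger-b) cell."""
    keep, gone = (a, b_cell) if a.b >= b_cell.b else (b_cell, a)
    keep.b += gone.b
    gone.b = 0
    _merge_compartments(keep.interior, gone.interior)
    keep.refresh_n()
    return keep


def divide_cell(cell: Protocell, rng) -> Protocell:
    """Split the membrane as evenly as possible and partition the interior.

    Every interior molecule lands in either daughter independently with
    probability 1/2; a strand engaged in a duplex or copy cycle travels with
    its whole complex.  The caller places the daughter in an adjacent room.
    """
    daughter = Protocell(b=max(1, cell.b // 2))
    cell.b -= daughter.b

    src, dst = cell.interior.pools, daughter.interior.pools
    k = int(rng.binomial(src.np_, 0.5)) if src.np_ else 0
    src.np_ -= k
    dst.np_ += k
    for i in range(4):
        if src.nt[i]:
            k = int(rng.binomial(src.nt[i], 0.5))
            src.nt[i] -= k
            dst.nt[i] += k
    for attr in ("ap", "am"):
        v = getattr(src, attr)
        if v:
            k = int(rng.binomial(v, 0.5))
            setattr(src, attr, v - k)
            setattr(dst, attr, getattr(dst, attr) + k)

    moved: set = set()
    for strand in list(cell.interior.strands):
        if id(strand) in moved or strand not in cell.interior.strands:
            continue
        group = _complex_members(strand)
        if rng.bernoulli(0.5):
            for member in group:
                if member in cell.interior.strands:
                    cell.interior.strands.remove(member)
                    daughter.interior.strands.append(member)
                moved.add(id(member))
        else:
            moved.update(id(m) for m in group)

    cell.refresh_n()
    daughter.refresh_n()
    return daughter


def _complex_members(strand) -> list:
    """The strand plus every partner bound to it through a duplex or REP job."""
    duplex = None
    if strand.as_template is not None:
        duplex = strand.as_template
    elif strand.in_segment is not None:
        duplex = strand.in_segment.duplex
    elif strand.rep_job is not None:
        duplex = strand.rep_job.duplex
    if duplex is None:
        return [strand]
    members = [duplex.template]
    members.extend(seg.strand for seg in duplex.segments)
    if duplex.rep_binding is not None:
        members.append(duplex.rep_binding.rep)
    return members
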