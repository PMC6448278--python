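"""The toroidal grid and the Monte Carlo step loop.

The world is an N x N square grid with toroidal adjacency (no edges).  Each
room holds an exterior compartment of free molecules and, optionally, one
protocell.  A Monte Carlo step executes a fixed phase order — the model only
says all entities update once per step, so a documented order is chosen for
reproducibility, with rooms processed in a freshly randomised order inside
each phase to avoid spatial sweep bias:

  1. small-molecule chemistry (formation/decay, amphiphile events)
  2. C_T collision rounds per room and per protocell interior
  3. REP extension, template-directed ligation, separations, bond
     breaking, chain-end decay
  4. protocell events (membrane exchange, formation, break, division,
     fusion, cytophagy, permeation)
  5. movement: molecules, then protocells (interface policy enforced at
     the moment of crossing)
  6. scheduled inoculations and parameter overrides
  7. observers (driven by the caller)

All randomness flows through one seeded PCG64 stream, so identical
(config, seed) pairs give bit-identical trajectories.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._rng import BufferedRNG
from .chemistry import (
    Compartment,
    MoleculePools,
    amphiphile_events,
    nucleotide_decay,
    nucleotide_formation,
)
from .params import ROCKY, SOLUTION, ParameterSet, RegionProfile, effective_params
from .protocell import (
    Protocell,
    cell_break,
    cell_fusion,
    cytophagy,
    divide_cell,
    division_probability,
    membrane_exchange,
    membrane_formation_probability,
    permeation,
)
from .replication import (
    bond_break_phase,
    collision_round,
    end_decay_phase,
    rep_extend,
    separation_phase,
    strand_roles,
    template_directed_ligation,
)
from .sequences import BASES, Strand

__all__ = [
    "GridRoom",
    "SimulationState",
    "Inoculation",
    "LedgerError",
    "new_state",
    "uniform_region_map",
    "core_region_map",
    "molecule_move_probability",
    "enforce_interface",
    "step",
    "run",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


class LedgerError(RuntimeError):
    """A conservation ledger was violated (always a bug, never physics)."""


@dataclass(eq=False)
class GridRoom:
    """One lattice cell: free contents, region label index, optional protocell."""

    index: int
    region: int  # index into SimulationState.profiles
    ext: Compartment = field(default_factory=Compartment)
    cell: Optional[Protocell] = None


@dataclass
class Inoculation:
    """A scheduled insertion of molecules or protocells."""

    step: int
    kind: str                    # "strands" | "cells"
    count: int = 0               # number of rooms / cells to seed
    per_room: int = 0            # strands per room (kind="strands")
    seqs: tuple = ()             # sequences inoculated into each room/cell
    placement: str = "center_block"
    # cell recipe (kind="cells")
    cell_b: int = 0


@dataclass
class Override:
    """A mid-run parameter change (step -> new value)."""

    step: int
    name: str
    value: float


def uniform_region_map(n: int, region: int = 0) -> np.ndarray:
    return np.full(n * n, region, dtype=np.int8)


def core_region_map(n: int, core: int) -> np.ndarray:
    """A core x core block of region 0 (rocky) centred in region 1 (solution)."""
    m = np.ones((n, n), dtype=np.int8)
    lo = (n - core) // 2
    m[lo:lo + core, lo:lo + core] = 0
    return m.ravel()


class SimulationState:
    """Full mutable world state plus the RNG stream and schedules."""

    def __init__(self, params: ParameterSet, region_map: np.ndarray,
                 profiles: list, seed: int):
        n = params.grid_size
        if region_map.shape != (n * n,):
            raise ValueError("region map must have N*N entries")
        self.params = params
        self.profiles = list(profiles)
        self.region_map = region_map.astype(np.int8)
        self.rng = BufferedRNG(seed)
        self.seed = int(seed)
        self.step_count = 0
        self.rooms = [GridRoom(index=i, region=int(region_map[i])) for i in range(n * n)]
        self.schedule: list = []
        self.overrides: list = []
        self.injected_nt_equiv = 0
        self.injected_am_equiv = 0
        self.check_every = 0  # ledger audit interval (0 = off)
        self._initial_nt_equiv = 0
        self._initial_am_equiv = 0
        self._build_neighbors()
        self._refresh_effective()

    # -- geometry ----------------------------------------------------------
    def _build_neighbors(self) -> None:
        n = self.params.grid_size
        idx = np.arange(n * n)
        y, x = idx // n, idx % n
        self.neighbors = np.stack([
            ((y - 1) % n) * n + x,       # up
            ((y + 1) % n) * n + x,       # down
            y * n + (x - 1) % n,         # left
            y * n + (x + 1) % n,         # right
        ], axis=1)

    # -- effective parameters ---------------------------------------------
    def _refresh_effective(self) -> None:
        p = self.params
        self.eff_out = [effective_params(p, prof, False) for prof in self.profiles]
        self.eff_in = [effective_params(p, prof, True) for prof in self.profiles]
        reg = self.region_map
        self._rate_nf = np.array([e.p_nf for e in self.eff_out])[reg]
        self._rate_nd = np.array([e.p_nd for e in self.eff_out])[reg]
        self._rate_ad = np.array([e.p_ad for e in self.eff_out])[reg]
        self._rate_mv = np.array([e.p_mv for e in self.eff_out])[reg]
        self._rate_rl = np.array([e.p_rl for e in self.eff_out])[reg]

    def set_param(self, name: str, value) -> None:
        self.params = self.params.replace(**{name: value})
        self._refresh_effective()

    # -- ledgers -----------------------------------------------------------
    def nucleotide_equivalents(self) -> int:
        total = 0
        for room in self.rooms:
            total += room.ext.nucleotide_equivalents()
            if room.cell is not None:
                total += room.cell.interior.nucleotide_equivalents()
        return total

    def amphiphile_equivalents(self) -> int:
        total = 0
        for room in self.rooms:
            total += room.ext.pools.ap + room.ext.pools.am
            if room.cell is not None:
                c = room.cell
                total += c.interior.pools.ap + c.interior.pools.am + c.b
        return total

    def seal_ledgers(self) -> None:
        """Record current totals as the conserved baselines."""
        self._initial_nt_equiv = self.nucleotide_equivalents()
        self._initial_am_equiv = self.amphiphile_equivalents()
        self.injected_nt_equiv = 0
        self.injected_am_equiv = 0

    def audit(self) -> None:
        nt = self.nucleotide_equivalents()
        am = self.amphiphile_equivalents()
        want_nt = self._initial_nt_equiv + self.injected_nt_equiv
        want_am = self._initial_am_equiv + self.injected_am_equiv
        if nt != want_nt or am != want_am:
            raise LedgerError(
                f"ledger violation at step {self.step_count}: "
                f"nucleotide-equivalents {nt} (expected {want_nt}), "
                f"amphiphile-equivalents {am} (expected {want_am})"
            )

    def cells(self):
        return [room.cell for room in self.rooms if room.cell is not None]


def new_state(params: ParameterSet = None, seed: int = 0,
              region_map: np.ndarray = None, profiles=None,
              distribute: bool = True) -> SimulationState:
    """Fresh world with the initial precursor totals scattered uniformly."""
    params = params if params is not None else ParameterSet()
    if region_map is None:
        region_map = uniform_region_map(params.grid_size)
    if profiles is None:
        profiles = [ROCKY, SOLUTION]
    state = SimulationState(params, region_map, profiles, seed)
    if distribute:
        r = len(state.rooms)
        if params.t_npb:
            counts = state.rng.multinomial(params.t_npb, np.full(r, 1.0 / r))
            for room, c in zip(state.rooms, counts):
                room.ext.pools.np_ = int(c)
        if params.t_apb:
            counts = state.rng.multinomial(params.t_apb, np.full(r, 1.0 / r))
            for room, c in zip(state.rooms, counts):
                room.ext.pools.ap = int(c)
    state.seal_ledgers()
    return state


def molecule_move_probability(m: int, p) -> float:
    """P_MV for monomers/precursors; P_MV/sqrt(m) for a chain of mass m."""
    if m < 1:
        raise ValueError("mass must be >= 1")
    return p.p_mv / (m ** 0.5)


def enforce_interface(entity_class: str, from_region: int, to_region: int,
                      state: SimulationState) -> bool:
    """May this entity cross between the two regions?

    Protocells may only ever be in regions that allow them.  For molecules a
    region-boundary crossing is vetoed unless the active policy admits the
    class: ``precursors_only`` admits nucleotide/amphiphile precursors,
    ``all_molecules`` admits everything.
    """
    if entity_class == "cell":
        return state.profiles[to_region].protocells_allowed
    if from_region == to_region:
        return True
    policies = (
        state.profiles[from_region].interface_policy,
        state.profiles[to_region].interface_policy,
    )
    if "precursors_only" in policies:
        return entity_class in ("np", "ap")
    return True


# ---------------------------------------------------------------------------
# phases

def _shuffled_indices(state, n: int) -> list:
    order = list(range(n))
    state.rng.shuffle(order)
    return order


def _chemistry_phase(state: SimulationState) -> None:
    rng, p = state.rng, state.params
    rooms = state.rooms
    r = len(rooms)

    np_arr = np.fromiter((rm.ext.pools.np_ for rm in rooms), dtype=np.int64, count=r)
    rate = state._rate_nf.copy()
    nsr_rooms = [
        i for i, rm in enumerate(rooms)
        if rm.ext.strands and rm.ext.has_free_nsr(p)
    ]
    if nsr_rooms:
        rate[nsr_rooms] = p.p_nfr
    formed = rng.gen.binomial(np_arr, rate)
    for i in np.nonzero(formed)[0]:
        k = int(formed[i])
        rooms[i].ext.pools.np_ -= k
        rooms[i].ext.pools.add_nt(rng.multinomial(k, np.full(4, 0.25)))

    nt_arr = np.array([rm.ext.pools.nt for rm in rooms], dtype=np.int64)
    decayed = rng.gen.binomial(nt_arr, state._rate_nd[:, None])
    tot = decayed.sum(axis=1)
    for i in np.nonzero(tot)[0]:
        nt = rooms[i].ext.pools.nt
        for j in range(4):
            nt[j] -= int(decayed[i, j])
        rooms[i].ext.pools.np_ += int(tot[i])

    ap_arr = np.fromiter((rm.ext.pools.ap for rm in rooms), dtype=np.int64, count=r)
    if ap_arr.any():
        k = rng.gen.binomial(ap_arr, p.p_af)
        for i in np.nonzero(k)[0]:
            rooms[i].ext.pools.ap -= int(k[i])
            rooms[i].ext.pools.am += int(k[i])
    am_arr = np.fromiter((rm.ext.pools.am for rm in rooms), dtype=np.int64, count=r)
    if am_arr.any():
        k = rng.gen.binomial(am_arr, state._rate_ad)
        for i in np.nonzero(k)[0]:
            rooms[i].ext.pools.am -= int(k[i])
            rooms[i].ext.pools.ap += int(k[i])

    # protocell interiors run the per-compartment operations directly
    for room in rooms:
        cell = room.cell
        if cell is None:
            continue
        eff = state.eff_in[room.region]
        interior = cell.interior
        nucleotide_formation(interior.pools, interior.has_free_nsr(p), eff, rng)
        nucleotide_decay(interior.pools, eff, rng)
        # membrane decay (P_ADM) is part of the membrane-exchange phase
        amphiphile_events(interior.pools, 0, eff, rng)


def _collision_phase(state: SimulationState) -> None:
    rng, p = state.rng, state.params
    for i in state._order:
        room = state.rooms[i]
        eff = state.eff_out[room.region]
        comp = room.ext
        if comp.strands:
            for _ in range(p.c_t):
                collision_round(comp, eff, rng)
        else:
            # nucleotide-only room: every pair can only random-ligate
            m = comp.pools.nt_total()
            pairs = p.c_t * (m // 2)
            if pairs and eff.p_rl > 0.0:
                n_lig = int(rng.binomial(pairs, eff.p_rl))
                for _ in range(n_lig):
                    if comp.pools.nt_total() < 2:
                        break
                    b1 = BASES[comp.pools.draw_letter(rng)]
                    b2 = BASES[comp.pools.draw_letter(rng)]
                    comp.strands.append(Strand(b1 + b2 if rng.bernoulli(0.5) else b2 + b1))
        cell = room.cell
        if cell is not None and (cell.interior.strands or cell.interior.pools.nt_total() > 1):
            eff_in = state.eff_in[room.region]
            for _ in range(p.c_t):
                collision_round(cell.interior, eff_in, rng)


def _strand_phase_compartment(comp: Compartment, eff, rng) -> None:
    # REP copy cycles
    for strand in list(comp.strands):
        if strand.rep_job is not None and strand in comp.strands:
            rep_extend(strand.rep_job, comp, eff, rng)
    # non-enzymatic template-directed ligation
    for strand in list(comp.strands):
        duplex = strand.as_template
        if duplex is not None and len(duplex.segments) > 1:
            template_directed_ligation(duplex, comp, eff, rng)
    separation_phase(comp, eff, rng)
    bond_break_phase(comp, eff, rng)
    end_decay_phase(comp, eff, rng)


def _strand_phase(state: SimulationState) -> None:
    rng = state.rng
    for i in state._order:
        room = state.rooms[i]
        if room.ext.strands:
            _strand_phase_compartment(room.ext, state.eff_out[room.region], rng)
        cell = room.cell
        if cell is not None and cell.interior.strands:
            _strand_phase_compartment(cell.interior, state.eff_in[room.region], rng)


def _protocell_phase(state: SimulationState) -> None:
    rng, p = state.rng, state.params
    rooms = state.rooms
    order = state._order

    # membrane exchange (join / leave / in-membrane decay)
    for i in order:
        room = rooms[i]
        if room.cell is not None:
            membrane_exchange(room.cell, room.ext, p, rng)
            if room.cell.b <= 0:
                _dissolve_cell(room)

    # membrane formation (only where protocells may exist)
    for i in order:
        room = rooms[i]
        if room.cell is not None or not state.profiles[room.region].protocells_allowed:
            continue
        a = room.ext.pools.am
        if a >= p.l_am and rng.bernoulli(membrane_formation_probability(a, p)):
            cell = Protocell(b=a, room=room.index)
            room.ext.pools.am = 0
            cell.interior, room.ext = room.ext, Compartment()
            cell.refresh_n()
            room.cell = cell

    # breaking
    for i in order:
        room = rooms[i]
        if room.cell is not None and cell_break(room.cell, room.ext, p, rng):
            room.cell = None

    # division
    for i in order:
        room = rooms[i]
        cell = room.cell
        if cell is None:
            continue
        if not rng.bernoulli(division_probability(cell.b, p)):
            continue
        targets = [
            int(j) for j in state.neighbors[room.index]
            if rooms[int(j)].cell is None
            and state.profiles[rooms[int(j)].region].protocells_allowed
        ]
        if not targets:
            continue  # boxed in: division aborts
        tgt = rooms[targets[rng.randbelow(len(targets))]]
        daughter = divide_cell(cell, rng)
        daughter.room = tgt.index
        # the daughter pushes the target room's free molecules into the
        # mother's surroundings (= the mother's room exterior)
        _merge_ext(room.ext, tgt.ext)
        tgt.cell = daughter

    # fusion: one trial per adjacent pair per step
    seen = set()
    for i in order:
        room = rooms[i]
        if room.cell is None:
            continue
        for j in state.neighbors[room.index]:
            j = int(j)
            key = (min(room.index, j), max(room.index, j))
            if key in seen:
                continue
            seen.add(key)
            other = rooms[j]
            if other.cell is None or room.cell is None:
                continue
            if rng.bernoulli(p.p_cf):
                survivor = cell_fusion(room.cell, other.cell)
                if survivor is room.cell:
                    other.cell = None
                else:
                    room.cell = None
                survivor.room = room.index if survivor is room.cell else other.index

    # cytophagy
    for i in order:
        room = rooms[i]
        cell = room.cell
        if cell is None:
            continue
        targets = [int(j) for j in state.neighbors[room.index] if rooms[int(j)].cell is None]
        if targets:
            tgt = rooms[targets[rng.randbelow(len(targets))]]
            cytophagy(cell, tgt.ext, p, rng)

    # permeation
    for i in order:
        room = rooms[i]
        if room.cell is not None:
            permeation(room.cell, room.ext, p, rng)
            room.cell.refresh_n()


def _dissolve_cell(room: GridRoom) -> None:
    cell = room.cell
    room.ext.pools.am += cell.b
    _merge_ext(room.ext, cell.interior)
    room.cell = None


def _merge_ext(dst: Compartment, src: Compartment) -> None:
    dst.pools.np_ += src.pools.np_
    dst.pools.add_nt(src.pools.nt)
    dst.pools.ap += src.pools.ap
    dst.pools.am += src.pools.am
    dst.strands.extend(src.strands)
    src.pools = MoleculePools()
    src.strands = []


_POOL_CLASSES = (("np_", "np"), ("ap", "ap"), ("am", "am"))


def _movement_phase(state: SimulationState) -> None:
    rng = state.rng
    rooms = state.rooms
    r = len(rooms)
    quarter = np.full(4, 0.25)

    # monomer/precursor pools: P_MV per molecule, 4-way uniform direction
    for attr, cls in _POOL_CLASSES:
        counts = np.fromiter((getattr(rm.ext.pools, attr) for rm in rooms),
                             dtype=np.int64, count=r)
        movers = rng.gen.binomial(counts, state._rate_mv)
        for i in np.nonzero(movers)[0]:
            split = rng.multinomial(int(movers[i]), quarter)
            src = rooms[i]
            for d in range(4):
                k = int(split[d])
                if k == 0:
                    continue
                tgt = rooms[int(state.neighbors[i, d])]
                if not enforce_interface(cls, src.region, tgt.region, state):
                    continue  # crossing vetoed: molecules stay put
                setattr(src.ext.pools, attr, getattr(src.ext.pools, attr) - k)
                setattr(tgt.ext.pools, attr, getattr(tgt.ext.pools, attr) + k)

    # free nucleotides (per letter)
    nt_arr = np.array([rm.ext.pools.nt for rm in rooms], dtype=np.int64)
    movers = rng.gen.binomial(nt_arr, state._rate_mv[:, None])
    for i in np.nonzero(movers.sum(axis=1))[0]:
        src = rooms[i]
        for letter in range(4):
            k = int(movers[i, letter])
            if k == 0:
                continue
            split = rng.multinomial(k, quarter)
            for d in range(4):
                kk = int(split[d])
                if kk == 0:
                    continue
                tgt = rooms[int(state.neighbors[i, d])]
                if not enforce_interface("nt", src.region, tgt.region, state):
                    continue
                src.ext.pools.nt[letter] -= kk
                tgt.ext.pools.nt[letter] += kk

    # strands and duplex complexes: P_MV / sqrt(m).  A hybridised strand
    # never moves independently; the whole complex (template + annealed
    # segments + bound REP) moves as one molecule with the summed mass.
    for i in state._order:
        room = rooms[i]
        if not room.ext.strands:
            continue
        eff_mv = state._rate_mv[i]
        for strand in list(room.ext.strands):
            if strand not in room.ext.strands:
                continue
            if strand.in_segment is not None or strand.rep_job is not None:
                continue  # moves with its template's complex
            members = [strand]
            mass = len(strand.seq)
            duplex = strand.as_template
            if duplex is not None:
                for seg in duplex.segments:
                    members.append(seg.strand)
                    mass += len(seg.strand.seq)
                if duplex.rep_binding is not None:
                    members.append(duplex.rep_binding.rep)
                    mass += len(duplex.rep_binding.rep.seq)
            if not rng.bernoulli(eff_mv / (mass ** 0.5)):
                continue
            d = rng.randbelow(4)
            tgt = rooms[int(state.neighbors[i, d])]
            if not enforce_interface("rna", room.region, tgt.region, state):
                continue
            for member in members:
                room.ext.strands.remove(member)
                tgt.ext.strands.append(member)

    # protocells: P_MC, pushing the target room's free molecules into the
    # vacated room
    p = state.params
    for i in state._order:
        room = rooms[i]
        cell = room.cell
        if cell is None or not state.rng.bernoulli(p.p_mc):
            continue
        d = rng.randbelow(4)
        tgt = rooms[int(state.neighbors[i, d])]
        if tgt.cell is not None:
            continue
        if not enforce_interface("cell", room.region, tgt.region, state):
            continue
        room.cell = None
        _merge_ext(room.ext, tgt.ext)  # pushed away into the vacated room
        tgt.cell = cell
        cell.room = tgt.index


def _apply_schedule(state: SimulationState) -> None:
    t = state.step_count
    for ov in state.overrides:
        if ov.step == t:
            state.set_param(ov.name, ov.value)
    for ino in state.schedule:
        if ino.step == t:
            _inoculate(state, ino)


def _inoculate(state: SimulationState, ino: Inoculation) -> None:
    rng = state.rng
    rooms = state.rooms
    n = state.params.grid_size

    if ino.kind == "strands":
        if ino.placement == "center_block":
            targets = _center_block(n, ino.count)
        elif ino.placement == "random_rep_rooms":
            candidates = [
                rm.index for rm in rooms
                if any(strand_roles(s, state.params).rep_functional
                       for s in rm.ext.strands)
            ]
            rng.shuffle(candidates)
            targets = candidates[:ino.count] or _center_block(n, ino.count)
        elif ino.placement == "rocky_rooms":
            candidates = [rm.index for rm in rooms if rm.region == 0]
            rng.shuffle(candidates)
            targets = candidates[:ino.count]
        else:
            raise ValueError(f"unknown placement {ino.placement!r}")
        per_room = max(1, ino.per_room)
        for idx in targets:
            for seq in ino.seqs:
                for _ in range(per_room):
                    rooms[idx].ext.strands.append(Strand(seq))
                    state.injected_nt_equiv += len(seq)
    elif ino.kind == "cells":
        candidates = [
            rm.index for rm in rooms
            if rm.cell is None and state.profiles[rm.region].protocells_allowed
        ]
        rng.shuffle(candidates)
        for idx in candidates[:ino.count]:
            cell = Protocell(b=ino.cell_b, room=idx)
            for seq in ino.seqs:
                cell.interior.strands.append(Strand(seq))
                state.injected_nt_equiv += len(seq)
            cell.refresh_n()
            rooms[idx].cell = cell
            state.injected_am_equiv += ino.cell_b
    elif ino.kind == "cell_strands":
        # distribute strands into existing cells containing ribozymes
        candidates = [
            rm.index for rm in rooms
            if rm.cell is not None and any(
                strand_roles(s, state.params).rep_functional
                for s in rm.cell.interior.strands)
        ] or [rm.index for rm in rooms if rm.cell is not None]
        rng.shuffle(candidates)
        for idx in candidates[:ino.count]:
            for seq in ino.seqs:
                rooms[idx].cell.interior.strands.append(Strand(seq))
                state.injected_nt_equiv += len(seq)
            rooms[idx].cell.refresh_n()
    else:
        raise ValueError(f"unknown inoculation kind {ino.kind!r}")


def _center_block(n: int, count: int) -> list:
    """`count` adjacent rooms centred on (n//2, n//2), rows of up to five."""
    cy, cx = n // 2, n // 2
    width = min(5, count)
    height = (count + width - 1) // width
    out = []
    for dy in range(height):
        for dx in range(width):
            if len(out) >= count:
                break
            y = (cy - height // 2 + dy) % n
            x = (cx - width // 2 + dx) % n
            out.append(y * n + x)
    return out


def step(state: SimulationState) -> SimulationState:
    """Advance the world by one Monte Carlo step (in place)."""
    # one freshly randomised room order per step, shared by all phases
    state._order = _shuffled_indices(state, len(state.rooms))
    _chemistry_phase(state)
    _collision_phase(state)
    _strand_phase(state)
    if state.params.t_apb or state.cells() or any(
        rm.ext.pools.am or rm.ext.pools.ap for rm in state.rooms
    ):
        _protocell_phase(state)
    _movement_phase(state)
    _apply_schedule(state)
    state.step_count += 1
    if state.check_every and state.step_count % state.check_every == 0:
        state.audit()
    return state


def run(state: SimulationState, steps: int, observer=None, observe_every: int = 1000):
    """Run ``steps`` Monte Carlo steps, calling ``observer(state)`` periodically."""
    if observer is not None and state.step_count == 0:
        observer(state)
    for _ in range(steps):
        step(state)
        if observer is not None and state.step_count % observe_every == 0:
            observer(state)
    return state


def save_checkpoint(state: SimulationState, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"version": CHECKPOINT_VERSION, "state": state}, fh)


def load_checkpoint(path) -> SimulationState:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != CHECKPOINT_VERSION:
        raise ValueError("unsupported checkpoint version")
    return payload["state"]
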