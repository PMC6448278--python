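"""Scenario presets, observers, and series/snapshot output.

Built-in reference set-ups: REP spread on a naked 20 x 20 grid,
REP+NSR co-spread, the two-region near-reality system (rocky core inside a
solution), protocell emergence by cytophagy, the fair-competition system,
and the parasite-pulse competition.  A ``tiny_*`` family scales the grid to
10 x 10 and molecule counts by the same area factor while keeping every
probability at its default, so per-capita dynamics are comparable at desk
scale; inoculation and stop steps are shortened accordingly.

A "REP count" in the series counts strands classified rep_functional
(bound or free) — molecule counts persist through replication intermediates;
pass ``count_mode="spreadable"`` to count fully tag-flanked strands only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .engine import (
    Inoculation,
    Override,
    SimulationState,
    core_region_map,
    new_state,
    run,
    uniform_region_map,
)
from .params import (
    ROCKY,
    SOLUTION,
    ParameterSet,
    RegionProfile,
    serialize_parameters,
)
from .replication import strand_roles

__all__ = [
    "Scenario",
    "ObservationRecord",
    "SCENARIO_NAMES",
    "build_scenario",
    "build_state",
    "record",
    "write_series",
    "read_series",
    "write_snapshot",
    "run_scenario",
]


@dataclass
class Scenario:
    """A named, fully resolved simulation set-up."""

    name: str
    params: ParameterSet
    core: int = 0                      # >0: rocky core side inside solution
    profiles: tuple = (ROCKY, SOLUTION)
    schedule: tuple = ()
    overrides: tuple = ()
    stop_step: int = 1_000_000

    def __post_init__(self):
        steps = [ino.step for ino in self.schedule]
        if steps != sorted(steps):
            raise ValueError("inoculation schedule steps must be non-decreasing")
        for ov in self.overrides:
            if not hasattr(self.params, ov.name):
                raise ValueError(f"override references unknown parameter {ov.name!r}")


def _rep_seq(p: ParameterSet) -> str:
    return p.cs_tag + p.cs_rep + p.cs_tag


def _nsr_seq(p: ParameterSet) -> str:
    return p.cs_tag + p.cs_nsr + p.cs_tag


def _parasite_seq(p: ParameterSet) -> str:
    return p.cs_tag + p.cs_tag


def build_scenario(name: str) -> Scenario:
    """One of the named presets (see SCENARIO_NAMES)."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(_PRESETS)}") from None
    return factory()


def _rep_spread() -> Scenario:
    p = ParameterSet(grid_size=20, t_npb=80_000, t_apb=0)
    return Scenario(
        name="rep_spread", params=p,
        schedule=(
            Inoculation(step=100_000, kind="strands", count=10, per_room=5,
                        seqs=(_rep_seq(p),), placement="center_block"),
        ),
        stop_step=10_000_000,
    )


def _nsr_into_rep() -> Scenario:
    base = _rep_spread()
    p = base.params
    return dataclasses.replace(
        base, name="nsr_into_rep",
        schedule=base.schedule + (
            Inoculation(step=2_000_000, kind="strands", count=10, per_room=5,
                        seqs=(_nsr_seq(p),), placement="random_rep_rooms"),
        ),
    )


def _co_spread() -> Scenario:
    p = ParameterSet(grid_size=20, t_npb=80_000, t_apb=0)
    return Scenario(
        name="co_spread", params=p,
        schedule=(
            Inoculation(step=100_000, kind="strands", count=10, per_room=5,
                        seqs=(_rep_seq(p), _nsr_seq(p)), placement="center_block"),
        ),
        stop_step=10_000_000,
    )


def _two_region() -> Scenario:
    p = ParameterSet(grid_size=40, t_npb=320_000, t_apb=240_000)
    cell_seqs = (_rep_seq(p),) * 5 + (_nsr_seq(p),) * 5
    return Scenario(
        name="two_region", params=p, core=20,
        profiles=(ROCKY, SOLUTION),
        schedule=(
            Inoculation(step=100_000, kind="strands", count=10, per_room=5,
                        seqs=(_rep_seq(p), _nsr_seq(p)), placement="rocky_rooms"),
            Inoculation(step=6_000_000, kind="cells", count=10, cell_b=p.l_am,
                        seqs=cell_seqs),
        ),
        stop_step=20_000_000,
    )


def _cytophagy() -> Scenario:
    base = _two_region()
    p = base.params.replace(p_cc=1e-5)  # cytophagy magnified 100-fold
    return dataclasses.replace(
        base, name="cytophagy_emergence", params=p,
        schedule=(
            base.schedule[0],
            Inoculation(step=6_000_000, kind="cells", count=10, cell_b=p.l_am,
                        seqs=()),  # empty protocells
        ),
    )


_FAIR_ROCKY = RegionProfile(label="rocky", interface_policy="precursors_only")
_FAIR_SOLUTION = RegionProfile(
    label="solution", protocells_allowed=True, interface_policy="precursors_only",
)


def _fair_competition() -> Scenario:
    # fair competition: no region rate differences, P_NPP = 1, only raw
    # materials cross the subsystem interface
    p = ParameterSet(grid_size=40, t_npb=320_000, t_apb=240_000, p_npp=1.0)
    cell_seqs = (_rep_seq(p),) * 5 + (_nsr_seq(p),) * 5
    return Scenario(
        name="fair_competition", params=p, core=20,
        profiles=(_FAIR_ROCKY, _FAIR_SOLUTION),
        schedule=(
            Inoculation(step=100_000, kind="strands", count=10, per_room=5,
                        seqs=(_rep_seq(p), _nsr_seq(p)), placement="rocky_rooms"),
            Inoculation(step=3_000_000, kind="cells", count=10, cell_b=p.l_am,
                        seqs=cell_seqs),
        ),
        stop_step=20_000_000,
    )


def _parasite_pulse() -> Scenario:
    base = _fair_competition()
    p = base.params.replace(p_nf=1e-4, p_mc=5e-6, p_fp=0.0)
    para = _parasite_seq(p)
    pulses = []
    for t in range(10_000_000, 30_000_001, 5_000_000):
        pulses.append(Inoculation(step=t, kind="strands", count=10, per_room=5,
                                  seqs=(para,), placement="random_rep_rooms"))
        pulses.append(Inoculation(step=t, kind="cell_strands", count=10,
                                  seqs=(para,) * 5))
    return dataclasses.replace(
        base, name="parasite_pulse", params=p,
        schedule=(base.schedule[0], base.schedule[1], *pulses),
        stop_step=30_000_000,
    )


def _tiny_rep_spread() -> Scenario:
    p = ParameterSet(grid_size=10, t_npb=20_000, t_apb=0)
    return Scenario(
        name="tiny_rep_spread", params=p,
        schedule=(
            Inoculation(step=5_000, kind="strands", count=4, per_room=3,
                        seqs=(_rep_seq(p),), placement="center_block"),
        ),
        stop_step=150_000,
    )


def _tiny_co_spread() -> Scenario:
    p = ParameterSet(grid_size=10, t_npb=20_000, t_apb=0)
    return Scenario(
        name="tiny_co_spread", params=p,
        schedule=(
            Inoculation(step=5_000, kind="strands", count=4, per_room=3,
                        seqs=(_rep_seq(p), _nsr_seq(p)), placement="center_block"),
        ),
        stop_step=150_000,
    )


def _tiny_competition() -> Scenario:
    p = ParameterSet(grid_size=10, t_npb=20_000, t_apb=15_000, p_npp=1.0)
    cell_seqs = (_rep_seq(p),) * 3 + (_nsr_seq(p),) * 3
    return Scenario(
        name="tiny_competition", params=p, core=5,
        profiles=(_FAIR_ROCKY, _FAIR_SOLUTION),
        schedule=(
            Inoculation(step=2_000, kind="strands", count=4, per_room=3,
                        seqs=(_rep_seq(p), _nsr_seq(p)), placement="rocky_rooms"),
            Inoculation(step=10_000, kind="cells", count=5, cell_b=p.l_am,
                        seqs=cell_seqs),
        ),
        stop_step=40_000,
    )


_PRESETS = {
    "rep_spread": _rep_spread,
    "nsr_into_rep": _nsr_into_rep,
    "co_spread": _co_spread,
    "two_region": _two_region,
    "cytophagy_emergence": _cytophagy,
    "fair_competition": _fair_competition,
    "parasite_pulse": _parasite_pulse,
    "tiny_rep_spread": _tiny_rep_spread,
    "tiny_co_spread": _tiny_co_spread,
    "tiny_competition": _tiny_competition,
}
SCENARIO_NAMES = tuple(sorted(_PRESETS))


def build_state(scenario: Scenario, seed: int) -> SimulationState:
    """Instantiate the world for a scenario with its schedule attached."""
    p = scenario.params
    if scenario.core:
        region_map = core_region_map(p.grid_size, scenario.core)
    else:
        region_map = uniform_region_map(p.grid_size, 0)
    state = new_state(p, seed=seed, region_map=region_map,
                      profiles=list(scenario.profiles))
    state.schedule = list(scenario.schedule)
    state.overrides = list(scenario.overrides)
    return state


# ---------------------------------------------------------------------------
# observation

_COLUMNS = [
    "step", "np", "nt", "ap", "am", "protocells",
    "rep_naked", "rep_in_cell", "nsr_naked", "nsr_in_cell",
    "parasites_naked", "parasites_in_cell",
    "np_rocky", "np_solution", "rep_rocky", "rep_solution",
    "nsr_rocky", "nsr_solution",
]


@dataclass
class ObservationRecord:
    """One sampled row of system-wide and per-region molecule counts."""

    values: dict

    def as_row(self) -> list:
        return [self.values[c] for c in _COLUMNS]


def _count_comp(comp, params, count_mode):
    rep = nsr = para = 0
    for s in comp.strands:
        roles = strand_roles(s, params)
        if count_mode == "spreadable":
            rep += roles.rep_spreadable
            nsr += roles.nsr_spreadable
        else:
            rep += roles.rep_functional
            nsr += roles.nsr_functional
        para += roles.parasite
    return rep, nsr, para


def record(state: SimulationState, count_mode: str = "functional") -> ObservationRecord:
    """Count molecules by class, overall and split by region and by naked/in-cell."""
    v = {c: 0 for c in _COLUMNS}
    v["step"] = state.step_count
    p = state.params
    for room in state.rooms:
        reg = "rocky" if room.region == 0 else "solution"
        pools = room.ext.pools
        v["np"] += pools.np_
        v["nt"] += pools.nt_total()
        v["ap"] += pools.ap
        v["am"] += pools.am
        v[f"np_{reg}"] += pools.np_
        rep, nsr, para = _count_comp(room.ext, p, count_mode)
        v["rep_naked"] += rep
        v["nsr_naked"] += nsr
        v["parasites_naked"] += para
        v[f"rep_{reg}"] += rep
        v[f"nsr_{reg}"] += nsr
        cell = room.cell
        if cell is not None:
            v["protocells"] += 1
            ip = cell.interior.pools
            v["np"] += ip.np_
            v["nt"] += ip.nt_total()
            v["ap"] += ip.ap
            v["am"] += ip.am
            v[f"np_{reg}"] += ip.np_
            rep, nsr, para = _count_comp(cell.interior, p, count_mode)
            v["rep_in_cell"] += rep
            v["nsr_in_cell"] += nsr
            v["parasites_in_cell"] += para
            v[f"rep_{reg}"] += rep
            v[f"nsr_{reg}"] += nsr
    return ObservationRecord(values=v)


def write_series(records, path) -> None:
    """Write sampled records as CSV (one row per sampling interval)."""
    df = pd.DataFrame([r.as_row() for r in records], columns=_COLUMNS)
    df.to_csv(path, index=False)


def read_series(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_snapshot(state: SimulationState, path) -> None:
    """Per-room table (coordinates, region, pools, roles, protocell presence)."""
    n = state.params.grid_size
    rows = []
    for room in state.rooms:
        pools = room.ext.pools
        rep, nsr, para = _count_comp(room.ext, state.params, "functional")
        row = {
            "room": room.index, "x": room.index % n, "y": room.index // n,
            "region": state.profiles[room.region].label,
            "np": pools.np_, "nt": pools.nt_total(),
            "ap": pools.ap, "am": pools.am,
            "rep": rep, "nsr": nsr, "parasites": para,
            "strands": len(room.ext.strands),
            "cell_b": room.cell.b if room.cell else 0,
            "cell_rep": 0, "cell_nsr": 0,
        }
        if room.cell is not None:
            crep, cnsr, _ = _count_comp(room.cell.interior, state.params, "functional")
            row["cell_rep"], row["cell_nsr"] = crep, cnsr
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def run_scenario(scenario, seed: int, steps: int = None, out_dir=None,
                 sample_every: int = 1000, snapshot_every: int = 0):
    """Run a scenario and return ``(state, series_dataframe)``.

    With ``out_dir`` set, writes ``series.csv``, optional periodic
    ``snapshot_<step>.csv`` files, and a ``manifest.txt`` holding the fully
    resolved configuration, the seed, and the package version.
    """
    import pathlib

    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    state = build_state(scenario, seed)
    total = steps if steps is not None else scenario.stop_step
    records = []
    out = pathlib.Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def observer(st):
        records.append(record(st))
        if out is not None and snapshot_every and st.step_count % snapshot_every == 0:
            write_snapshot(st, out / f"snapshot_{st.step_count:09d}.csv")

    run(state, total, observer=observer, observe_every=sample_every)
    if state.step_count % sample_every != 0:
        records.append(record(state))
    df = pd.DataFrame([r.as_row() for r in records], columns=_COLUMNS)
    if out is not None:
        df.to_csv(out / "series.csv", index=False)
        manifest = (
            f"scenario = {scenario.name}\nseed = {seed}\nsteps = {total}\n"
            f"rnaworld_version = {__version__}\n\n"
            + serialize_parameters(state.params)
        )
        (out / "manifest.txt").write_text(manifest)
    return state, df
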