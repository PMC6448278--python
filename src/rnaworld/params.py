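"""Parameter system of the simulator.

Every stochastic event in the model is governed by a named per-step
probability (``P_*``), and the scene is shaped by a handful of counts and
factors (grid side ``N``, initial precursor totals, the osmotic and Donnan
factors, the membrane lower limit, the catalytic-domain and tag sequences).
:class:`ParameterSet` is the single source of those rates; everything else
in the package reads rates from it and never hard-codes a number.

A two-phase environment (porous-rock core inside a surrounding water body)
is expressed with :class:`RegionProfile` multipliers: in solution, movement
is faster, degradation is faster (outside protocells, which are not a
free-water environment), and surface-catalysed synthesis is slower.
"""

from __future__ import annotations

import configparser
import dataclasses
import io
import warnings
from dataclasses import dataclass, field, fields

__all__ = [
    "ParameterSet",
    "RegionProfile",
    "ParameterError",
    "DEFAULTS",
    "MAGNITUDES",
    "ROCKY",
    "SOLUTION",
    "load_parameters",
    "effective_params",
    "serialize_parameters",
    "read_config",
]


class ParameterError(ValueError):
    """Raised for out-of-range or malformed parameter values."""


# probability fields, attribute name -> config/Table key
_PROB_KEYS = {
    "p_at": "P_AT", "p_bb": "P_BB", "p_flr": "P_FLR", "p_fp": "P_FP",
    "p_mv": "P_MV", "p_nd": "P_ND", "p_nde": "P_NDE", "p_nf": "P_NF",
    "p_nfr": "P_NFR", "p_rbt": "P_RBT", "p_rd": "P_RD", "p_rl": "P_RL",
    "p_rtt": "P_RTT", "p_sp": "P_SP", "p_tl": "P_TL", "p_tlr": "P_TLR",
    "p_ad": "P_AD", "p_adm": "P_ADM", "p_af": "P_AF", "p_ajm": "P_AJM",
    "p_alm": "P_ALM", "p_app": "P_APP", "p_cb": "P_CB", "p_cc": "P_CC",
    "p_cd": "P_CD", "p_cf": "P_CF", "p_mc": "P_MC", "p_mf": "P_MF",
    "p_npp": "P_NPP",
}
_OTHER_KEYS = {
    "grid_size": "N", "t_npb": "T_NPB", "t_apb": "T_APB",
    "f_op": "F_OP", "f_de": "F_DE", "c_t": "C_T", "l_am": "L_AM",
    "cs_rep": "CS_REP", "cs_nsr": "CS_NSR", "cs_tag": "CS_Tag",
}
CONFIG_KEYS = {**_PROB_KEYS, **_OTHER_KEYS}
_KEY_TO_ATTR = {v: k for k, v in CONFIG_KEYS.items()}

#: documented "magnitude" ranges, kept as metadata only (no sampling scheme
#: over them is defined; sweeps pick explicit values).
MAGNITUDES = {
    "p_at": (0.3, 0.5), "p_bb": (1e-6, 5e-6), "p_flr": (0.05, 0.2),
    "p_fp": (5e-5, 2e-4), "p_mv": (5e-5, 2e-4), "p_nd": (0.002, 0.01),
    "p_nde": (1e-4, 5e-4), "p_nf": (1e-4, 5e-4), "p_nfr": (0.5, 0.9),
    "p_rbt": (0.3, 0.5), "p_rd": (5e-5, 2e-4), "p_rl": (5e-7, 2e-6),
    "p_rtt": (0.4, 0.6), "p_sp": (0.3, 0.4), "p_tl": (5e-5, 2e-4),
    "p_tlr": (0.5, 0.9), "p_ad": (1e-4, 5e-4), "p_adm": (1e-5, 5e-5),
    "p_af": (5e-4, 2e-3), "p_ajm": (0.7, 0.9), "p_alm": (1e-4, 5e-4),
    "p_app": (0.5, 1.0), "p_cb": (5e-6, 2e-5), "p_cc": (1e-7, 5e-7),
    "p_cd": (5e-5, 2e-4), "p_cf": (0.002, 0.01), "p_mc": (5e-6, 2e-5),
    "p_mf": (0.005, 0.02), "p_npp": (0.05, 0.2),
    "grid_size": (20, 40), "t_npb": (80_000, 320_000),
    "t_apb": (60_000, 240_000), "f_op": (5, 10), "f_de": (5, 10),
    "c_t": (5, 10), "l_am": (400, 600),
}

_RNA_ALPHABET = set("AUCG")
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ParameterSet:
    """All event probabilities and scene constants (default values below)."""

    # substrate attraction, chain chemistry, replication
    p_at: float = 0.4        # template attracting a substrate
    p_bb: float = 2e-6       # phosphodiester bond breaking (single chain)
    p_flr: float = 0.1       # false (mismatch-involving) REP-catalysed ligation
    p_fp: float = 1e-4       # false base-pairing on substrate attraction
    p_mv: float = 1e-4       # movement of monomers/precursors per step
    p_nd: float = 0.005      # nucleotide -> precursor decay
    p_nde: float = 2e-4      # chain-end residue decay
    p_nf: float = 2e-4       # precursor -> nucleotide, non-enzymatic
    p_nfr: float = 0.9       # precursor -> nucleotide, NSR-catalysed
    p_rbt: float = 0.4       # REP binding a tagged template
    p_rd: float = 1e-4       # REP dropping mid-copy
    p_rl: float = 1e-6       # random end-to-end ligation
    p_rtt: float = 0.5       # strand turning template on first attraction
    p_sp: float = 0.38       # separation of a single base pair
    p_tl: float = 1e-4       # template-directed ligation, non-enzymatic
    p_tlr: float = 0.9       # template-directed ligation, REP-catalysed
    # amphiphiles and protocells
    p_ad: float = 2e-4       # free amphiphile decay
    p_adm: float = 2e-5      # membrane amphiphile decay
    p_af: float = 1e-3       # amphiphile formation from precursor
    p_ajm: float = 0.8       # amphiphile joining a membrane
    p_alm: float = 2e-4      # amphiphile leaving a membrane (base rate)
    p_app: float = 1.0       # amphiphile-precursor permeation
    p_cb: float = 1e-5       # protocell breaking
    p_cc: float = 1e-7       # cytophagy (engulfing an adjacent room)
    p_cd: float = 1e-4       # division (base rate)
    p_cf: float = 0.005      # fusion of adjacent protocells
    p_mc: float = 1e-5       # protocell movement
    p_mf: float = 0.01       # membrane formation (base rate)
    p_npp: float = 0.1       # nucleotide-precursor permeation (base rate)
    # scene constants
    grid_size: int = 40      # N (grid is N x N, toroidal)
    t_npb: int = 320_000     # initial nucleotide precursors
    t_apb: int = 240_000     # initial amphiphile precursors
    f_op: float = 10.0       # osmotic-pressure factor
    f_de: float = 10.0       # Donnan-equilibrium factor
    c_t: int = 8             # collision rounds per step
    l_am: int = 500          # membrane lower limit (amphiphiles)
    cs_rep: str = "CUCGACAGAU"   # REP catalytic domain
    cs_nsr: str = "ACUGGCAUCU"   # NSR catalytic domain
    cs_tag: str = "ACGU"         # tag (must be its own reverse complement)

    def __post_init__(self):
        validate(self)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ordering constraints of the model; violations are plausible in sweeps,
# so the validator warns instead of refusing.
_ORDERINGS = [
    ("p_tlr", ">>", "p_tl"), ("p_nfr", ">>", "p_nf"), ("p_tl", ">>", "p_rl"),
    ("p_nde", "<", "p_nd"), ("p_adm", "<", "p_ad"), ("p_mf", ">>", "p_cb"),
    ("p_ajm", ">>", "p_alm"), ("p_mv", ">", "p_mc"), ("p_app", ">", "p_npp"),
]


def validate(p: ParameterSet) -> None:
    """Hard checks (ranges, alphabets, tag palindromy) and soft ordering warnings."""
    for attr in _PROB_KEYS:
        v = getattr(p, attr)
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{CONFIG_KEYS[attr]} out of [0,1]: {v!r}")
    for attr in ("grid_size", "c_t", "l_am"):
        if getattr(p, attr) < 1:
            raise ParameterError(f"{CONFIG_KEYS[attr]} must be >= 1")
    for attr in ("t_npb", "t_apb"):
        if getattr(p, attr) < 0:
            raise ParameterError(f"{CONFIG_KEYS[attr]} must be >= 0")
    for attr in ("f_op", "f_de"):
        if getattr(p, attr) <= 0:
            raise ParameterError(f"{CONFIG_KEYS[attr]} must be > 0")
    for attr in ("cs_rep", "cs_nsr", "cs_tag"):
        s = getattr(p, attr)
        if not s or set(s) - _RNA_ALPHABET:
            raise ParameterError(f"{CONFIG_KEYS[attr]} must be a non-empty A/U/C/G sequence")
    if _revcomp(p.cs_tag) != p.cs_tag:
        raise ParameterError("tag not palindromic: CS_Tag must equal its reverse complement")
    for a, op, b in _ORDERINGS:
        va, vb = getattr(p, a), getattr(p, b)
        ok = va > vb if op in (">", ">>") else va < vb
        if not ok:
            warnings.warn(
                f"ordering constraint violated: {CONFIG_KEYS[a]} {op} {CONFIG_KEYS[b]} "
                f"({va!r} vs {vb!r})",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class RegionProfile:
    """Per-region multipliers on the base rates.

    ``degradation_mult`` scales P_BB, P_ND, P_NDE, P_AD (never inside a
    protocell); ``synthesis_mult`` scales P_RL, P_NF; ``mv_mult`` scales
    P_MV.  ``interface_policy`` says which molecule classes may cross the
    rocky/solution boundary when this region is part of a two-phase layout.
    """

    label: str = "rocky"
    mv_mult: float = 1.0
    degradation_mult: float = 1.0
    synthesis_mult: float = 1.0
    protocells_allowed: bool = False
    interface_policy: str = "all_molecules"  # or "precursors_only"

    def __post_init__(self):
        for attr in ("mv_mult", "degradation_mult", "synthesis_mult"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"RegionProfile.{attr} must be > 0")
        if self.interface_policy not in ("all_molecules", "precursors_only"):
            raise ParameterError(f"unknown interface policy {self.interface_policy!r}")


#: the default two-phase profiles: rocky core is the reference environment;
#: solution has 10x movement, 2x degradation (outside cells), 1/20 synthesis.
ROCKY = RegionProfile(label="rocky")
SOLUTION = RegionProfile(
    label="solution", mv_mult=10.0, degradation_mult=2.0,
    synthesis_mult=1.0 / 20.0, protocells_allowed=True,
)

_DEGRADATION = ("p_bb", "p_nd", "p_nde", "p_ad")
_SYNTHESIS = ("p_rl", "p_nf")


def effective_params(base: ParameterSet, region: RegionProfile,
                     inside_protocell: bool = False) -> ParameterSet:
    """Apply region multipliers; results clamped to [0,1].

    Degradation multipliers are skipped inside a protocell (a membrane-bounded
    interior is not a free-water environment).  Identity multipliers return a
    field-wise identical set, so the operation is idempotent for the rocky
    profile.
    """
    changes: dict = {}
    if region.mv_mult != 1.0:
        changes["p_mv"] = min(1.0, base.p_mv * region.mv_mult)
    if region.degradation_mult != 1.0 and not inside_protocell:
        for attr in _DEGRADATION:
            changes[attr] = min(1.0, getattr(base, attr) * region.degradation_mult)
    if region.synthesis_mult != 1.0:
        for attr in _SYNTHESIS:
            changes[attr] = min(1.0, getattr(base, attr) * region.synthesis_mult)
    return base.replace(**changes) if changes else base


DEFAULTS = ParameterSet()


def _coerce(attr: str, raw):
    if attr in ("cs_rep", "cs_nsr", "cs_tag"):
        return str(raw).strip().upper().replace("T", "U")
    if attr in ("grid_size", "t_npb", "t_apb", "c_t", "l_am"):
        return int(float(raw))
    return float(raw)


def load_parameters(config=None) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    ``config`` may be None (all defaults), a mapping of Table keys
    (``{"P_SP": 0.35}``) or attribute names, or a path / file text in the
    ``key = value`` config format (section ``[parameters]``).  Omitted fields
    take their defaults; unknown keys are an error (catches typos in sweep
    scripts).
    """
    if config is None:
        return ParameterSet()
    if isinstance(config, ParameterSet):
        return config
    if isinstance(config, (str, io.IOBase)) or hasattr(config, "read_text"):
        cfg, _, _ = read_config(config)
        return cfg
    changes = {}
    for key, raw in dict(config).items():
        attr = _KEY_TO_ATTR.get(key, key.lower() if key.lower() in CONFIG_KEYS else None)
        if attr is None:
            raise ParameterError(f"unknown parameter {key!r}")
        changes[attr] = _coerce(attr, raw)
    return ParameterSet(**changes)


def serialize_parameters(p: ParameterSet, include_defaults: bool = True) -> str:
    """Dump as ``[parameters]`` config text; round-trips through load_parameters."""
    lines = ["[parameters]"]
    for attr, key in CONFIG_KEYS.items():
        v = getattr(p, attr)
        if not include_defaults and v == getattr(DEFAULTS, attr):
            continue
        lines.append(f"{key} = {v!r}" if isinstance(v, float) else f"{key} = {v}")
    return "\n".join(lines) + "\n"


def _region_from_section(label: str, sec) -> RegionProfile:
    kwargs = {"label": label}
    known = {"mv_mult", "degradation_mult", "synthesis_mult",
             "protocells_allowed", "interface_policy"}
    for key, raw in sec.items():
        if key not in known:
            raise ParameterError(f"unknown region key {key!r}")
        if key == "protocells_allowed":
            kwargs[key] = raw.strip().lower() in ("1", "true", "yes")
        elif key == "interface_policy":
            kwargs[key] = raw.strip()
        else:
            kwargs[key] = float(raw)
    return RegionProfile(**kwargs)


def read_config(source):
    """Parse a full config file.

    Returns ``(ParameterSet, {label: RegionProfile}, scenario_dict)``.
    Sections: ``[parameters]``, ``[regions.rocky]``, ``[regions.solution]``,
    ``[scenario]`` (the scenario block is returned raw for scenarios_io).
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keys are case-sensitive (P_NF vs N)
    if hasattr(source, "read_text"):
        text = source.read_text()
    elif isinstance(source, str) and "=" not in source and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    cp.read_string(text)

    for section in cp.sections():
        if section not in ("parameters", "scenario") and not section.startswith("regions."):
            raise ParameterError(f"unknown config section [{section}]")

    changes = {}
    if cp.has_section("parameters"):
        for key, raw in cp.items("parameters"):
            attr = _KEY_TO_ATTR.get(key)
            if attr is None:
                raise ParameterError(f"unknown parameter {key!r}")
            changes[attr] = _coerce(attr, raw)
    params = ParameterSet(**changes)

    regions = {"rocky": ROCKY, "solution": SOLUTION}
    for section in cp.sections():
        if section.startswith("regions."):
            label = section.split(".", 1)[1]
            regions[label] = _region_from_section(label, cp[section])

    scenario = dict(cp.items("scenario")) if cp.has_section("scenario") else {}
    return params, regions, scenario
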