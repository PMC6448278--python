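# rnaworld

A grid-based Monte Carlo simulator of the RNA world: the spread of naked
ribozymes, the parasites that exploit them, and the emergence and
competition of membrane-bounded protocells.

## The problem

How could Darwinian evolution move from free replicating molecules to
cell-like entities?  `rnaworld` models a concrete version of that
transition.  Molecules live on an N x N toroidal lattice of "grid rooms";
nucleotide precursors convert to nucleotides (probability `P_NF` per step,
or `P_NFR` under a nucleotide-synthetase ribozyme, NSR), nucleotides ligate
into RNA chains, and chains act as templates.  A polymerase ribozyme (REP)
recognises templates through a short palindromic tag (`ACGU`) at the
template's 5' end and copies them one mononucleotide at a time; because the
tag is its own reverse complement, a tag-flanked strand is replicable
("spreadable") — and so is any tag-flanked freeloader, which is what makes
parasites a structural problem rather than an accident.  Amphiphiles
self-assemble into membranes once a room gathers `L_AM` of them, producing
protocells that grow, divide (only above `b = 2 L_AM` membrane molecules),
fuse, break, engulf the contents of neighbouring rooms (cytophagy), and
exchange material through osmotically and Donnan-corrected permeation:

- strand separation: `P_SP^((r+1)/2)` for a duplex of `r` base pairs
- membrane formation: `1 - (1 - P_MF)^(a - L_AM + 1)`
- amphiphile leaving: `P_ALM / (1 + F_OP * n / (b/2)^(3/2))`
- precursor influx: `P_NPP * (b / L_AM) / (1 + F_DE * n / (b/2)^(3/2))`
- division: `P_CD * (1 - 2 L_AM / b)`
- RNA movement: `P_MV / sqrt(m)` for a chain of mass `m`

where `n` counts the impermeable interior ions (free nucleotides plus RNA
residues).  A two-phase layout — a rocky core with reference rates inside a
solution region with faster movement, faster degradation and slower
synthesis — hosts the headline experiment: naked REP + NSR thriving in the
rock versus ribozyme-carrying protocells spreading in the water around it.

Every event probability comes from a single validated parameter table with
documented defaults and ranges; all randomness flows through one seeded
PCG64 stream, so a (config, seed) pair reproduces a run bit-for-bit.

## A worked example

```python
from rnaworld import run_scenario

state, series = run_scenario("tiny_rep_spread", seed=1, steps=20_000, sample_every=5_000)
print(series[["step", "np", "nt", "rep_naked", "parasites_naked"]].to_string(index=False))
```

prints

```
 step    np  nt  rep_naked  parasites_naked
    0 20000   0          0                0
 5000 19240 748          0                0
10000 19097 776          8                7
15000 19089 744          9                8
20000 19045 774          9                8
```

`tiny_rep_spread` is a desk-scale naked scene: a 10 x 10 grid seeded with 20,000
nucleotide precursors.  The pool first equilibrates (`np`/`nt` settle near
the `P_NF`/`P_ND` balance, here ~750 free nucleotides).  At step 5,000,
twelve 18-nt spreadable REP molecules (`ACGU + CUCGACAGAU + ACGU`) are
inoculated into four central rooms; most of them immediately pair off into
copying complexes, so the count of free-or-bound functional replicases
(here 9 at step 20,000) hovers near the inoculum early on and climbs only
over ~10^5-step horizons, because a finished copy stays locked in its
18-base-pair duplex for ~1/P_SP^9.5 ~ 10^4 steps before the strands
separate.  The "parasite" count tracking just below it is mostly the
obligatory tag-flanked complement intermediates, plus the occasional true
freeloader.  Precursors deplete only slightly: raw material is not what
limits the spread at this stage.

The same machinery runs from the shell:

```bash
rnaworld run --scenario tiny_rep_spread --seed 1 --steps 20000 --out out/
rnaworld print-defaults        # the full parameter table in config format
rnaworld scenarios             # list the built-in presets
```

writing `series.csv`, optional per-room snapshots, and a `manifest.txt` with
the fully resolved configuration and seed.

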