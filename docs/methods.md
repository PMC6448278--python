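# Methods

## The model

`rnaworld` simulates an RNA-world scenario on an N x N toroidal lattice of
"grid rooms".  Matter exists in five forms: nucleotide precursors (Np),
free nucleotides (Nt, with letter identity A/U/C/G), RNA strands, amphiphile
precursors (Ap), and amphiphiles (Am).  Only entities in the same room (or
the same protocell interior) interact within one Monte Carlo step; in one
step every entity samples each of its applicable events with the per-step
probabilities of the parameter table (`rnaworld.params.ParameterSet`).

Two ribozymes are defined by characteristic catalytic-domain sequences: a
template-directed RNA polymerase (REP, domain `CUCGACAGAU`) and a nucleotide
synthetase (NSR, domain `ACUGGCAUCU`).  Template recognition by REP works
through a 4-nt palindromic tag (`ACGU`): the REP's 5' tag-recognising domain
base-pairs the template's 5' tag, and because the tag equals its own reverse
complement, a strand flanked by tags at both ends has complements that are
again 5'-tagged — such strands are replicable ("spreadable").  A functional
REP is therefore at least 14 nt (tag + domain), a spreadable REP 18 nt;
a functional NSR is 10 nt (bare domain), a spreadable NSR 18 nt.  Tag-flanked
strands without a catalytic domain are parasites: they consume REP activity
and contribute nothing.  The obligatory replication intermediate — the
complement of a spreadable REP or NSR — also classifies as a parasite, which
is deliberate: it carries tags but no domain, and the model's molecule
counts treat it the same way.

## Event mechanics and numerical choices

**Chemistry.**  Np->Nt conversion is a per-precursor Bernoulli event at
P_NF, switched to P_NFR when at least one free (unhybridised) NSR-functional
strand shares the compartment; catalysis saturates — multiple NSRs do not
stack.  New letters are uniform.  All small-molecule events are sampled as
binomial draws over pools, which is exact for independent per-molecule
Bernoulli trials.

**Collisions.**  Per step each room runs C_T collision rounds.  In a round
the free RNA entities (strands plus mononucleotides; also "open" templates —
strands carrying annealed substrates but no bound REP) are grouped into
uniformly random disjoint pairs (sequential uniform matching; the odd entity
idles).  Each pair attempts exactly one candidate event with priority
REP binding > substrate attraction > random ligation.  The priority is a
design choice (the model itself gives the three events no order);
binding first reflects that tag recognition is the defining event and
prevents a replicase from being consumed as a mere substrate whenever a
tagged template is present.  Pairs of mononucleotides can only random-ligate
and are handled in bulk as one binomial draw over the pair count.

**Templates and substrates.**  Only chains of >= 5 nt can act as templates
(this also bounds REP templates, which keeps the bare 4-nt tag from being a
self-replicator).  A strand without a REP turns template with P_RTT, rolled
once at its first substrate attraction and sticky for the strand's lifetime
(a molecule either is the kind that folds open as a template or it is not;
REP binding forces the template state).  The frozen fate keeps roughly half
the strands naked and available to the replicase — with a fresh roll at
every attraction, all strands accrete transient substrates within a step or
two and the copy cycle starves.  A substrate anneals at a
maximal-complementarity register among uncovered registers (uniform
tie-break); each mismatched position must independently pass P_FP, which
makes the per-copied-residue mutation rate ~ P_FP.  Adjacent, gap-free
substrates ligate with P_TL per junction and step.

**The REP cycle.**  A catalysis-capable REP (one whose functional head —
tag-recognising plus catalytic domain — is not hybridised; loosely annealed
substrates elsewhere do not abolish function, and are shed when the ribozyme
folds to act) binds a recognisable template with P_RBT.  Recognition needs
the template's 5' tag single-stranded; substrates annealed elsewhere do not
block it.  Copying proceeds from the template's 3' end (products grow
5'->3') with up to C_T incorporation attempts per step — the working complex
meets candidate mononucleotides through the same collision schedule as every
other entity, and one attempt per step would let the spontaneous drop rate
P_RD abort most supply-limited copies.  Per attempt the complementary letter
is drawn (a mismatch with P_FP), a missing letter stalls that attempt, the
first residue is placed with P_AT and every later junction ligates with
P_TLR — or P_FLR when the junction involves a falsely paired residue.  When
copying reaches the
template's tag segment the recognition pairing separates.  The REP drops on
completion, spontaneously with P_RD, or when its own chain breaks (P_BB).
While a REP works, its product accepts no oligomer junctions — only the
catalysed mononucleotide additions.

**Separation and degradation.**  An annealed segment of r base pairs
dissociates with P_SP^((r+1)/2); full-length 18-bp replication intermediates
therefore persist ~10^4 steps, which is the generation-time bottleneck of
the whole system.  Bond breaking is P_BB per single-chain site and
P_BB^(3/2) where two parallel bonds must fail together; because a break in
an engaged strand is ~10^-9 per site at defaults, the implementation
dissolves the affected duplex before splitting rather than re-anchoring
segments across the break.  Only unpaired terminal residues decay (P_NDE),
crediting one precursor; paired residues — including whole strands locked in
duplexes and the catalyst while bound — are protected.

**Protocells.**  A room in a protocell-permitting region whose free
amphiphiles reach L_AM forms a membrane with 1-(1-P_MF)^(a-L_AM+1),
enclosing the room's contents.  The membrane count b sets a surface scale
b/2 and volume scale (b/2)^(3/2); the interior impermeable-ion tally n (free
nucleotides + RNA residues) enters an osmotic correction of amphiphile
leaving and a Donnan correction of precursor influx.  Precursor efflux uses
flat P_NPP (only the influx has a closed-form correction; Donnan exclusion
suppresses influx of like charge, and the efflux is left uncorrected);
influx and efflux are sampled simultaneously from the pre-exchange stocks,
so a permeability of 1 equilibrates the compartments rather than emptying
the interior each step;
amphiphile precursors cross with flat P_APP both ways; nucleotides and RNA
never cross an intact membrane.  Division requires b > 2*L_AM, splits the
membrane evenly and partitions every interior molecule binomially — a strand
engaged in a duplex travels with its whole complex.  Fusion merges two
adjacent cells into the larger-b partner's room (ties resolve toward the
first cell in the randomised processing order).  Cytophagy moves every free
molecule of one adjacent cell-free room into the interior.  A room holds at
most one protocell plus an exterior compartment of free molecules; membrane
exchange and permeation couple the two, and a moving or dividing cell pushes
the target room's free molecules into the vacated room (a mass-conserving
swap).

**Regions.**  A two-phase layout places a rocky core (reference rates)
inside a solution region where movement is 10x, degradation (P_BB, P_ND,
P_NDE, P_AD) 2x — never inside protocells — and surface-mediated synthesis
(P_RL, P_NF) 1/20.  Boundary crossings are vetoed per the interface policy
(`all_molecules` or `precursors_only`); protocells never enter rock.
Multiplied probabilities clamp to [0,1].

**Step order and RNG.**  The model only states that all entities update once
per step, so a fixed phase order is used for reproducibility — chemistry,
collisions, synthesis/separation/degradation, protocell events, movement,
scheduled inoculations — with rooms processed in a freshly randomised order
each step (one shared shuffle per step) to avoid spatial sweep bias.
Entities see the running state, a deliberate choice, not a statement of the
source model.  All randomness flows through one seeded PCG64 stream, so a
(config, seed) pair reproduces a trajectory bit-for-bit.

## Conservation ledgers

Every event converts matter, never creates or destroys it:
nucleotide-equivalents (precursors + free nucleotides + chain residues) and
amphiphile-equivalents (precursors + free + membrane amphiphiles) are exact
invariants, tracked system-wide across rooms, interiors and membranes.
`SimulationState.audit()` recomputes both from scratch and raises on any
discrepancy; the test suite runs audited simulations covering membrane
formation, division, fusion, breaking and cytophagy.

## The scenario presets and what the synthetic conditions do not show

The presets define the model's reference set-ups (naked REP spread on a 20 x 20 grid
with 80,000 initial precursors and 50 inoculated REP; REP+NSR co-spread; the
40 x 40 two-region system with 320,000/240,000 initial precursors; protocell
emergence with cytophagy magnified 100-fold; fair competition with P_NPP = 1
and a precursors-only interface; periodic parasite pulses of 50 molecules).
The `tiny_*` family scales the grid to 10 x 10 and molecule totals by the
same area factor (1/4 of the 20 x 20 naked scene: 20,000 precursors),
keeping every probability at its default so per-room densities and
per-capita dynamics are comparable; inoculation steps are shortened to just
after pool equilibration (a few thousand steps, against an equilibration
time of ~1/(P_NF+P_ND) ~ 200 steps).  Desk-scale runs use 10^4-10^5 steps —
problem sizes chosen so the whole suite completes on one CPU — where the
full-scale reference scenarios run to 10^7.

Two timescales bound what such runs can show.  A finished copy stays locked
to its template for ~1/P_SP^((r+1)/2) ~ 10^4 steps (r = 18), so the
replicase's generation time is ~10^4 steps and its net per-capita growth
margin — one copy per lock, against chain-end erosion of waiting strands,
P_RD-aborted copies, and tagged junk competing for catalyst attention — is
a few 10^-6 per step.  Multi-fold population growth therefore needs several
10^5 steps, and with only ~10-20 replicators in play a single tiny run
drifts: persistence near or above the inoculum is the expected desk-scale
signature, while stochastic extinction remains possible at settings where a
400-room system would thrive.  Slower still is competitive exclusion: the
naked-versus-protocell balance turns on which subsystem's ribozyme economy
outgrows the other, a differential of order 10^-6 per step that the
full-scale scenarios integrate over 10^6-10^7 steps (their protocells are
inoculated only at step 3x10^6); at 10^4-step horizons both
subsystems still reflect their inocula, so tiny competition runs measure
early-transient direction, not the full-scale outcome.  No real biological
data enters anywhere; all inputs are synthesized from the parameter table.

## Known limitations

- No secondary structure, folding thermodynamics, or strand displacement;
  hybridisation is register-based complementarity only.
- Bond breaks inside engaged duplexes dissolve the complex rather than
  splitting it in place (second-order rare at default rates).
- A REP whose chain is bound by another REP as template cannot
  simultaneously catalyse; end decay of the bound catalyst's free 3' tail is
  neglected.
- The chromosome extension and the amphiphile-synthetase ribozyme of the
  wider model family are out of scope; de novo NSR emergence by single-point
  mutation is supported through configuration but has no quantitative test.
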