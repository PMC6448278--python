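"""Collisions, hybridisation, and template-directed RNA synthesis.

Two synthesis routes exist.  Non-enzymatically, a strand of at least 5 nt may
act as a template (turning template with P_RTT on its first substrate
attraction), attract complementary substrates — mononucleotides or oligomers
— with P_AT, and adjacent substrates ligate with P_TL.  Enzymatically, a
replicase ribozyme (REP) binds a template by base-pairing its 5'
tag-recognising domain to the template's 5' tag (P_RBT on collision) and then
copies the template one mononucleotide per step, 3'->5' along the template so
the product grows 5'->3'; each junction ligates with P_TLR, or with P_FLR
when a falsely paired residue is involved.  False pairing (P_FP) is the
mutation mechanism: a mismatched letter is fixed into the product.

Strand separation is cooperative: a duplex of r base pairs dissociates with
P_SP^((r+1)/2), so long duplexes are nearly inseparable while short annealed
substrates fall off readily.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .sequences import BASE_INDEX, BASES, COMPLEMENT, Strand, classify, reverse_complement

__all__ = [
    "Segment",
    "Duplex",
    "RepBinding",
    "separation_probability",
    "turn_to_template",
    "rep_bind",
    "rep_extend",
    "attract_substrate",
    "template_directed_ligation",
    "collision_round",
    "separation_phase",
    "bond_break_phase",
    "end_decay_phase",
    "release_strand",
    "dissolve_duplex",
    "strand_roles",
]

MIN_TEMPLATE_LEN = 5  # below this a chain cannot act as a template


@dataclass(eq=False)
class Segment:
    """A substrate/product annealed on a template.

    Covers template positions [offset, offset+len-1]; substrate index ``s``
    (5'->3') pairs template position ``offset + len - 1 - s`` (antiparallel).
    ``mismatches`` holds template positions that are falsely paired.
    """

    strand: Strand
    offset: int
    mismatches: set = field(default_factory=set)
    duplex: Optional["Duplex"] = None

    def __len__(self) -> int:
        return len(self.strand.seq)

    @property
    def end(self) -> int:
        return self.offset + len(self.strand.seq) - 1

    def pairs(self) -> int:
        """Number of formed base pairs (every aligned position is paired)."""
        return len(self.strand.seq)


@dataclass(eq=False)
class RepBinding:
    """A REP engaged in copying one template."""

    rep: Strand
    duplex: "Duplex"
    tag_len: int
    copy_position: int            # next template index to copy (3'->5'); -1 = done
    recognition_paired: bool = True
    product: Optional[Segment] = None
    last_was_mismatch: bool = False


@dataclass(eq=False)
class Duplex:
    """A template with its annealed segments and (optionally) a bound REP.

    ``seg_mask`` is a bitmask of template positions covered by segments
    (bit i set = position i paired), maintained incrementally.
    """

    template: Strand
    segments: list = field(default_factory=list)  # kept sorted by offset
    rep_binding: Optional[RepBinding] = None
    seg_mask: int = 0

    def _mask(self) -> int:
        rb = self.rep_binding
        if rb is not None and rb.recognition_paired:
            return self.seg_mask | ((1 << rb.tag_len) - 1)
        return self.seg_mask

    def covers(self, pos: int) -> bool:
        return bool((self._mask() >> pos) & 1)

    def interval_free(self, lo: int, hi: int) -> bool:
        span = ((1 << (hi - lo + 1)) - 1) << lo
        return not (self._mask() & span)

    def recompute_mask(self) -> None:
        m = 0
        for seg in self.segments:
            m |= ((1 << len(seg.strand.seq)) - 1) << seg.offset
        self.seg_mask = m

    def add_segment(self, seg: Segment) -> None:
        seg.duplex = self
        self.segments.append(seg)
        self.segments.sort(key=lambda s: s.offset)
        seg.strand.in_segment = seg
        self.seg_mask |= ((1 << len(seg.strand.seq)) - 1) << seg.offset


def separation_probability(r: int, p) -> float:
    """Dissociation probability of a duplex with r base pairs: P_SP^((r+1)/2)."""
    if r < 1:
        raise ValueError("r must be >= 1")
    return p.p_sp ** ((r + 1) / 2.0)


def turn_to_template(strand: Strand, rep_bound: bool, p, rng) -> bool:
    """A strand becomes a template deterministically under a REP, else with P_RTT.

    Without a REP the roll happens once, at the strand's first substrate
    attraction, and the outcome is sticky for the strand's lifetime: a
    molecule either is the kind that folds open as a template or it is not.
    A declining strand stays naked — available as a ribozyme or for REP
    recognition — instead of accreting substrates.
    """
    if rep_bound:
        strand.template_fate = True
        return True
    if strand.template_fate is None:
        strand.template_fate = rng.bernoulli(p.p_rtt)
    return strand.template_fate


def strand_roles(strand: Strand, params):
    """Role classification, cached per (sequence, characteristic sequences).

    Identity comparison suffices for invalidation: mutating a strand's
    sequence always rebinds ``seq`` to a new string object.
    """
    cached = getattr(strand, "_roles_cache", None)
    if (
        cached is not None
        and cached[0] is strand.seq
        and cached[1] is params.cs_tag
        and cached[2] is params.cs_rep
        and cached[3] is params.cs_nsr
    ):
        return cached[4]
    roles = classify(strand.seq, params)
    strand._roles_cache = (strand.seq, params.cs_tag, params.cs_rep,
                           params.cs_nsr, roles)
    return roles


def release_strand(comp, strand: Strand) -> None:
    """Return a freed strand to the compartment; free 1-mers rejoin the nt pool."""
    strand.in_segment = None
    strand.as_template = None
    strand.rep_job = None
    if len(strand.seq) == 1:
        comp.pools.nt[BASE_INDEX[strand.seq]] += 1
        if strand in comp.strands:
            comp.strands.remove(strand)


def _detach_segment(comp, duplex: Duplex, seg: Segment) -> None:
    duplex.segments.remove(seg)
    duplex.recompute_mask()
    release_strand(comp, seg.strand)


def dissolve_duplex(comp, duplex: Duplex) -> None:
    """Free every participant (the template keeps its template fate)."""
    for seg in list(duplex.segments):
        _detach_segment(comp, duplex, seg)
    rb = duplex.rep_binding
    if rb is not None:
        rb.rep.rep_job = None
        duplex.rep_binding = None
    duplex.template.as_template = None


def _maybe_dissolve(comp, duplex: Duplex) -> None:
    if not duplex.segments and duplex.rep_binding is None:
        dissolve_duplex(comp, duplex)


def _region_hybridised(duplex, lo: int, hi: int) -> bool:
    """Is [lo, hi] overlapped by a real duplex segment (>= 2 nt)?

    Transiently annealed mononucleotides (r = 1, lifetime ~1/P_SP steps) do
    not constitute hybridisation of a domain and are displaced when a
    ribozyme folds or binds.
    """
    if duplex is None:
        return False
    for seg in duplex.segments:
        if len(seg.strand.seq) >= 2 and seg.offset <= hi and seg.end >= lo:
            return True
    return False


def rep_bindable(template: Strand, p) -> bool:
    """Can a REP recognise this strand right now?

    Needs template length (>= 5 nt), a 5' tag not engaged in a stable duplex,
    and no REP already bound; the strand must not itself be busy as a
    substrate or catalyst.  Substrates annealed elsewhere on the strand do
    not block recognition, and stray mononucleotides sitting on the tag are
    displaced at binding.
    """
    if template.in_segment is not None or template.rep_job is not None:
        return False
    if len(template.seq) < MIN_TEMPLATE_LEN or not template.seq.startswith(p.cs_tag):
        return False
    duplex = template.as_template
    if duplex is not None:
        if duplex.rep_binding is not None:
            return False
        if _region_hybridised(duplex, 0, len(p.cs_tag) - 1):
            return False
    return True


def rep_can_catalyse(rep: Strand, p) -> bool:
    """May this strand act as a replicase right now?

    The functional head (5' tag-recognising domain plus catalytic domain)
    must not be engaged in a stable duplex; transiently annealed
    mononucleotides do not abolish function.  A strand serving as a
    substrate or already running a copy cannot simultaneously catalyse.
    """
    if rep.in_segment is not None or rep.rep_job is not None:
        return False
    head = len(p.cs_tag) + len(p.cs_rep)
    return not _region_hybridised(rep.as_template, 0, min(head, len(rep.seq)) - 1)


def rep_bind(rep: Strand, template: Strand, p, rng, comp=None) -> Optional[RepBinding]:
    """A catalysis-capable REP binds a 5'-tagged template with P_RBT.

    Copying starts at the template's 3' end; the tag-recognising domain pairs
    the template's 5' tag (so the tag region counts as double-stranded until
    copying reaches it and the recognition separates).  A REP that was itself
    carrying loosely annealed substrates sheds them as it folds to act.
    """
    if not rep_can_catalyse(rep, p) or not rep_bindable(template, p):
        return None
    if not rng.bernoulli(p.p_rbt):
        return None
    if rep.as_template is not None and comp is not None:
        dissolve_duplex(comp, rep.as_template)
    elif rep.as_template is not None:
        return None  # cannot shed substrates without compartment bookkeeping
    duplex = template.as_template
    if duplex is None:
        duplex = Duplex(template=template)
        template.as_template = duplex
    else:
        # displace stray mononucleotides from the tag so recognition can pair
        tag_monomers = [
            seg for seg in duplex.segments
            if len(seg.strand.seq) == 1 and seg.offset < len(p.cs_tag)
        ]
        if tag_monomers and comp is None:
            return None
        for seg in tag_monomers:
            _detach_segment(comp, duplex, seg)
    template.template_fate = True
    binding = RepBinding(
        rep=rep, duplex=duplex, tag_len=len(p.cs_tag),
        copy_position=len(template.seq) - 1,
    )
    duplex.rep_binding = binding
    rep.rep_job = binding
    return binding


def _draw_copy_letter(template_base: str, p, rng):
    """The letter to incorporate opposite ``template_base``; returns (letter, is_mismatch)."""
    correct = COMPLEMENT[template_base]
    if p.p_fp > 0.0 and rng.bernoulli(p.p_fp):
        others = [b for b in BASES if b != correct]
        return rng.choice(others), True
    return correct, False


def rep_extend(binding: RepBinding, comp, p, rng) -> None:
    """One step of the bound-REP copy cycle.

    The working complex meets candidate mononucleotides through the same
    collision schedule as everything else, so it makes up to C_T
    incorporation attempts per step; each drawn letter that is present in
    the compartment pool is ligated on (a missing letter stalls that
    attempt — oligomers are never accepted while a REP is at work).  The
    completion / spontaneous-drop (P_RD) / chain-breaking (P_BB) exits are
    evaluated once per step.
    """
    duplex = binding.duplex
    template = duplex.template

    for _ in range(p.c_t):
        if binding.copy_position < 0:
            break
        # a foreign substrate annealed over the next position stalls the
        # cycle until it separates (the product only covers later positions)
        if (duplex.seg_mask >> binding.copy_position) & 1:
            break
        letter, mism = _draw_copy_letter(template.seq[binding.copy_position], p, rng)
        li = BASE_INDEX[letter]
        if comp.pools.nt[li] <= 0:
            continue  # no suitable mononucleotide met in this collision
        if binding.product is None:
            ok = rng.bernoulli(p.p_at)  # initial attraction, no junction yet
        else:
            junction_false = mism or binding.last_was_mismatch
            ok = rng.bernoulli(p.p_flr if junction_false else p.p_tlr)
        if not ok:
            continue
        comp.pools.nt[li] -= 1
        cp = binding.copy_position
        if binding.product is None:
            prod = Strand(letter)
            comp.strands.append(prod)
            binding.product = Segment(strand=prod, offset=cp)
            duplex.add_segment(binding.product)
        else:
            seg = binding.product
            seg.strand.seq = seg.strand.seq + letter
            seg.offset = cp
            duplex.seg_mask |= 1 << cp
        if mism:
            binding.product.mismatches.add(cp)
        binding.last_was_mismatch = mism
        binding.copy_position = cp - 1
        if binding.copy_position < binding.tag_len:
            # copying has reached the tag segment: the recognition pairing
            # separates and synthesis continues over the tag
            binding.recognition_paired = False

    # exits: completion, spontaneous drop, chain breaking of the passive REP
    if binding.copy_position < 0:
        _drop_rep(binding)
        return
    if rng.bernoulli(p.p_rd):
        _drop_rep(binding)
        return
    L = len(binding.rep.seq)
    if L > 1 and rng.bernoulli(1.0 - (1.0 - p.p_bb) ** (L - 1)):
        site = rng.randbelow(L - 1)
        rep = binding.rep
        _drop_rep(binding)
        _split_strand(comp, rep, site)


def _drop_rep(binding: RepBinding) -> None:
    binding.rep.rep_job = None
    binding.duplex.rep_binding = None
    binding.recognition_paired = False
    # the duplex (template + product segment, if any) persists until it
    # separates or, with no segments, dissolves at the next separation phase


def attract_substrate(template: Strand, substrate, comp, p, rng) -> Optional[Segment]:
    """A template attracts a substrate by base-pairing, with P_AT.

    ``substrate`` is a free Strand or a single-letter string (a mononucleotide
    already withdrawn from the pool by the caller).  The substrate anneals at
    a maximal-complementarity free register (uniform tie-break); every
    mismatched position must be accepted with P_FP or the attempt fails.
    Returns the new segment or None.
    """
    L = len(template.seq)
    if L < MIN_TEMPLATE_LEN:
        return None
    rep_bound = template.as_template is not None and template.as_template.rep_binding is not None
    if not turn_to_template(template, rep_bound, p, rng):
        return None
    if not rng.bernoulli(p.p_at):
        return None

    sub_seq = substrate.seq if isinstance(substrate, Strand) else substrate
    ell = len(sub_seq)
    if ell > L:
        return None
    duplex = template.as_template

    if ell == 1:
        return _attract_mononucleotide(template, sub_seq, duplex, comp, p, rng)

    # fast path: a fully complementary register is always maximal-score, and
    # registers with mismatches survive only through P_FP rolls — so search
    # perfect registers with C-level substring matching first
    rc_sub = reverse_complement(sub_seq)
    perfect: list = []
    start = template.seq.find(rc_sub)
    while start != -1:
        if duplex is None or duplex.interval_free(start, start + ell - 1):
            perfect.append(start)
        start = template.seq.find(rc_sub, start + 1)
    mismatches: set = set()
    if perfect:
        o = perfect[rng.randbelow(len(perfect))] if len(perfect) > 1 else perfect[0]
    else:
        # best free register carries >= 1 mismatch; one P_FP factor is
        # consumed here, the remaining k-1 in the exact scoring below
        if not rng.bernoulli(p.p_fp):
            return None
        best_score = -1
        best: list = []
        for o in range(0, L - ell + 1):
            if duplex is not None and not duplex.interval_free(o, o + ell - 1):
                continue
            score = 0
            for s in range(ell):
                if sub_seq[s] == COMPLEMENT[template.seq[o + ell - 1 - s]]:
                    score += 1
            if score > best_score:
                best_score, best = score, [o]
            elif score == best_score:
                best.append(o)
        if not best or best_score < 0:
            return None
        o = best[rng.randbelow(len(best))] if len(best) > 1 else best[0]
        mismatches = {
            o + ell - 1 - s
            for s in range(ell)
            if sub_seq[s] != COMPLEMENT[template.seq[o + ell - 1 - s]]
        }
        for _ in range(len(mismatches) - 1):
            if not rng.bernoulli(p.p_fp):
                return None

    if duplex is None:
        duplex = Duplex(template=template)
        template.as_template = duplex
    if isinstance(substrate, Strand):
        sub = substrate
    else:
        sub = Strand(sub_seq)
        comp.strands.append(sub)
    seg = Segment(strand=sub, offset=o, mismatches=mismatches)
    duplex.add_segment(seg)
    return seg


def _letter_positions(strand: Strand) -> dict:
    """Positions of each letter in the strand, cached per sequence object."""
    cached = getattr(strand, "_letpos_cache", None)
    if cached is not None and cached[0] is strand.seq:
        return cached[1]
    pos: dict = {"A": [], "U": [], "C": [], "G": []}
    for i, b in enumerate(strand.seq):
        pos[b].append(i)
    strand._letpos_cache = (strand.seq, pos)
    return pos


def _attract_mononucleotide(template: Strand, base: str, duplex, comp, p, rng):
    """Fast path of attract_substrate for a single-nucleotide substrate."""
    mask = duplex._mask() if duplex is not None else 0
    tseq = template.seq
    pair_base = COMPLEMENT[base]  # template letter this base pairs correctly with
    candidates = _letter_positions(template)[pair_base]
    if mask:
        wc = [i for i in candidates if not (mask >> i) & 1]
    else:
        wc = candidates
    if wc:
        o = wc[rng.randbelow(len(wc))] if len(wc) > 1 else wc[0]
        mismatches = set()
    else:
        # only mismatched registers remain: the false pairing needs P_FP
        if not rng.bernoulli(p.p_fp):
            return None
        free = [i for i in range(len(tseq)) if not (mask >> i) & 1]
        if not free:
            return None
        o = free[rng.randbelow(len(free))]
        mismatches = {o}
    if duplex is None:
        duplex = Duplex(template=template)
        template.as_template = duplex
    sub = Strand(base)
    comp.strands.append(sub)
    seg = Segment(strand=sub, offset=o, mismatches=mismatches)
    duplex.add_segment(seg)
    return seg


def template_directed_ligation(duplex: Duplex, comp, p, rng) -> None:
    """Adjacent (gap-free) substrates on a template join with P_TL per junction.

    The product of the join spans both registers; because the template is
    read 3'->5' for a 5'->3' product, the higher-offset segment contributes
    the 5' part of the merged strand.
    """
    rb = duplex.rep_binding
    held = rb.product if rb is not None else None
    i = 0
    while i < len(duplex.segments) - 1:
        low, high = duplex.segments[i], duplex.segments[i + 1]
        if held is not None and (low is held or high is held):
            # a product held by a working REP only accepts mononucleotides
            # through the catalysed cycle, never an oligomer junction
            i += 1
            continue
        if high.offset == low.end + 1 and rng.bernoulli(p.p_tl):
            merged = high.strand.seq + low.strand.seq
            low.strand.seq = merged
            low.mismatches |= high.mismatches
            # the high strand object is consumed by the join
            high.strand.in_segment = None
            if high.strand in comp.strands:
                comp.strands.remove(high.strand)
            duplex.segments.pop(i + 1)  # span is now [low.offset, high.end]
        else:
            i += 1


def separation_phase(comp, p, rng) -> None:
    """Per-segment dissociation trials; empty duplexes dissolve."""
    for strand in list(comp.strands):
        duplex = strand.as_template
        if duplex is None:
            continue
        rb = duplex.rep_binding
        for seg in list(duplex.segments):
            if rb is not None and seg is rb.product:
                continue  # the growing product is held by the REP
            if rng.bernoulli(separation_probability(seg.pairs(), p)):
                _detach_segment(comp, duplex, seg)
        _maybe_dissolve(comp, duplex)


def _split_strand(comp, strand: Strand, site: int) -> None:
    """Break the bond after residue ``site``; both pieces end up free."""
    if strand.as_template is not None:
        dissolve_duplex(comp, strand.as_template)
    if strand.in_segment is not None and strand.in_segment.duplex is not None:
        dissolve_duplex(comp, strand.in_segment.duplex)
    if strand.rep_job is not None:
        _drop_rep(strand.rep_job)
    left, right = strand.seq[: site + 1], strand.seq[site + 1:]
    strand.seq = left
    release_strand(comp, strand)
    new = Strand(right)
    comp.strands.append(new)
    release_strand(comp, new)


def bond_break_phase(comp, p, rng) -> None:
    """Phosphodiester bond breaking: P_BB per single-chain site and step.

    At a double-chain site the two parallel bonds must break together
    (P_BB^(3/2)); the extra factor P_BB^(1/2) is applied after site choice.
    Multiple breaks of one strand in one step are neglected (second order in
    P_BB).
    """
    if p.p_bb <= 0.0:
        return
    for strand in list(comp.strands):
        L = len(strand.seq)
        if L < 2 or strand not in comp.strands:
            continue
        if not rng.bernoulli(1.0 - (1.0 - p.p_bb) ** (L - 1)):
            continue
        site = rng.randbelow(L - 1)
        if _site_double_chain(comp, strand, site) and not rng.bernoulli(p.p_bb ** 0.5):
            continue
        _split_strand(comp, strand, site)


def _site_double_chain(comp, strand: Strand, site: int) -> bool:
    if strand.as_template is not None:
        d = strand.as_template
        return d.covers(site) and d.covers(site + 1)
    if strand.in_segment is not None:
        return True  # segments are paired over their full length
    if strand.rep_job is not None:
        rb = strand.rep_job
        # the REP's 5' tag-recognising domain is paired while recognition holds
        return rb.recognition_paired and site + 1 < rb.tag_len
    return False


def end_decay_phase(comp, p, rng) -> None:
    """Chain-end residue decay for free strands and template overhangs."""
    from .chemistry import end_residue_decay  # local to avoid cycle at import

    if p.p_nde <= 0.0:
        return
    for strand in list(comp.strands):
        if strand not in comp.strands:
            continue
        if strand.is_free:
            if end_residue_decay(strand, comp.pools, p, rng):
                comp.strands.remove(strand)
            elif len(strand.seq) == 1:
                release_strand(comp, strand)
        elif strand.as_template is not None:
            _template_end_decay(comp, strand.as_template, p, rng)


def _template_end_decay(comp, duplex: Duplex, p, rng) -> None:
    t = duplex.template
    L = len(t.seq)
    span_lo = min((s.offset for s in duplex.segments), default=L)
    span_hi = max((s.end for s in duplex.segments), default=-1)
    rb = duplex.rep_binding
    if rb is not None:
        if rb.recognition_paired:
            span_lo = min(span_lo, 0)
        span_hi = max(span_hi, rb.copy_position + 1 if rb.product else L - 1)
    # 3' overhang
    if L - 1 > span_hi and L > 1 and rng.bernoulli(p.p_nde):
        t.seq = t.seq[:-1]
        comp.pools.np_ += 1
        if rb is not None:
            rb.copy_position = min(rb.copy_position, len(t.seq) - 1)
        L -= 1
    # 5' overhang: trimming shifts every template coordinate by -1
    if span_lo > 0 and L > 1 and rng.bernoulli(p.p_nde):
        t.seq = t.seq[1:]
        comp.pools.np_ += 1
        for seg in duplex.segments:
            seg.offset -= 1
            seg.mismatches = {m - 1 for m in seg.mismatches}
        duplex.recompute_mask()
        if rb is not None:
            rb.copy_position -= 1


# ---------------------------------------------------------------------------
# collisions

def _collision_eligible(comp):
    """Strands that can take part in a collision this round.

    Free strands always can; so can open templates (no bound REP) — they keep
    attracting substrates onto their uncovered registers.
    """
    return [
        s for s in comp.strands
        if s.in_segment is None and s.rep_job is None
        and (s.as_template is None or s.as_template.rep_binding is None)
    ]


def _pair_strand_nt(comp, strand: Strand, p, rng) -> None:
    if len(strand.seq) >= MIN_TEMPLATE_LEN and (strand.is_free or strand.as_template is not None):
        # cheap gates first: template fate, then the P_AT roll, and only
        # then withdraw a nucleotide from the pool for register matching
        rep_bound = (strand.as_template is not None
                     and strand.as_template.rep_binding is not None)
        if not turn_to_template(strand, rep_bound, p, rng):
            return
        if not rng.bernoulli(p.p_at):
            return
        letter = BASES[comp.pools.draw_letter(rng)]
        seg = _attract_mononucleotide(strand, letter, strand.as_template, comp, p, rng)
        if seg is None:
            comp.pools.nt[BASE_INDEX[letter]] += 1  # back to the pool
    elif strand.is_free:
        letter = BASES[comp.pools.draw_letter(rng)]
        joined = None
        if rng.bernoulli(p.p_rl):
            joined = strand.seq + letter if rng.bernoulli(0.5) else letter + strand.seq
        if joined is None:
            comp.pools.nt[BASE_INDEX[letter]] += 1
        else:
            strand.seq = joined


def _pair_strands(comp, a: Strand, b: Strand, p, rng) -> None:
    a_free, b_free = a.is_free, b.is_free

    # (ii) REP binding, the defining tag-mechanism event, takes priority
    a_cat = (strand_roles(a, p).rep_functional and rep_can_catalyse(a, p)
             and rep_bindable(b, p))
    b_cat = (strand_roles(b, p).rep_functional and rep_can_catalyse(b, p)
             and rep_bindable(a, p))
    if a_cat and b_cat:
        if rng.bernoulli(0.5):
            a_cat = False
        else:
            b_cat = False
    if a_cat:
        rep_bind(a, b, p, rng, comp)
        return
    if b_cat:
        rep_bind(b, a, p, rng, comp)
        return

    # (iii) the longer strand attracts the shorter as a substrate
    if a_free and b_free:
        if len(a.seq) == len(b.seq):
            template, substrate = (a, b) if rng.bernoulli(0.5) else (b, a)
        else:
            template, substrate = (a, b) if len(a.seq) > len(b.seq) else (b, a)
    elif a_free:  # b is an open template
        template, substrate = b, a
    elif b_free:
        template, substrate = a, b
    else:
        return  # two busy templates: no admissible event
    if len(template.seq) >= MIN_TEMPLATE_LEN and len(substrate.seq) <= len(template.seq):
        attract_substrate(template, substrate, comp, p, rng)
        return

    # (i) random end-to-end ligation
    if a_free and b_free:
        joined = random_ligation(a.seq, b.seq, p, rng)
        if joined is not None:
            a.seq = joined
            comp.strands.remove(b)


def random_ligation(a_seq: str, b_seq: str, p, rng):
    from .chemistry import random_ligation as _rl

    return _rl(a_seq, b_seq, p, rng)


def collision_round(comp, p, rng) -> None:
    """One pairwise grouping of the compartment's free RNA entities.

    Strands and mononucleotides are matched uniformly at random (the odd one
    idles); each pair attempts exactly one candidate event with priority
    REP-binding > substrate attraction > random ligation.  Pairs of
    mononucleotides can only random-ligate, so they are handled in bulk as a
    binomial draw over the pair count.
    """
    pool = _collision_eligible(comp)
    nt_rem = comp.pools.nt_total()
    if len(pool) + nt_rem < 2:
        return
    # sequential uniform matching: repeatedly take the next unmatched strand
    # and pair it with a uniformly random remaining entity — this samples a
    # uniform perfect matching without shuffling the whole room
    idx = 0
    n_str = len(pool)
    while idx < n_str:
        a = pool[idx]
        idx += 1
        remaining = (n_str - idx) + nt_rem
        if remaining <= 0:
            break
        pick = rng.randbelow(remaining)
        if pick < n_str - idx:
            # partner is another strand: swap it next to us and consume it
            j = idx + pick
            pool[idx], pool[j] = pool[j], pool[idx]
            b = pool[idx]
            idx += 1
            _pair_strands(comp, a, b, p, rng)
        else:
            nt_rem -= 1
            _pair_strand_nt(comp, a, p, rng)

    # leftover mononucleotides pair among themselves; only random ligation applies
    k = nt_rem // 2
    if k > 0 and p.p_rl > 0.0:
        n_lig = int(rng.binomial(k, p.p_rl))
        for _ in range(n_lig):
            if comp.pools.nt_total() < 2:
                break
            b1 = BASES[comp.pools.draw_letter(rng)]
            b2 = BASES[comp.pools.draw_letter(rng)]
            seq = b1 + b2 if rng.bernoulli(0.5) else b2 + b1
            comp.strands.append(Strand(seq))
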