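"""RNA sequence logic: complementarity, the tag mechanism, role classification.

The replicase (REP) recognises its templates through a short palindromic tag
at the template's 5' end.  Because the tag equals its own reverse complement,
the REP's 5' tag-recognising domain, the template's 5' tag and the 3'
"reverse tag" are all one sequence, and a strand that carries the tag at both
ends is replicable ("spreadable"): its complement again starts with the tag.

Role rules (with tag T, REP domain R, NSR domain S):
  rep_functional   seq starts with T + R          (catalyst: recogniser + domain)
  rep_spreadable   T + R prefix and a T suffix    (both ends tagged -> replicable)
  nsr_functional   S occurs anywhere in seq       (the synthetase needs no tag to act)
  nsr_spreadable   seq == T + S + T
  parasite         tagged at both ends, no R and no S anywhere
  plain            none of the above
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "COMPLEMENT",
    "Strand",
    "RoleSet",
    "reverse_complement",
    "complement_base",
    "classify",
    "write_fasta",
    "read_fasta",
]

COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
BASES = "AUCG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def complement_base(b: str) -> str:
    try:
        return COMPLEMENT[b]
    except KeyError:
        raise ValueError(f"invalid RNA base {b!r}") from None


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement (A<->U, C<->G), reversed; 5'->3' in, 5'->3' out."""
    return "".join(complement_base(b) for b in reversed(seq))


@dataclass(eq=False)
class Strand:
    """One RNA molecule, sequence stored 5'->3'.

    A strand participates in at most one duplex role at a time: as the
    template of a duplex (``as_template``), as an annealed substrate/product
    segment (``in_segment``), or as the REP catalyst of a copy in progress
    (``rep_job``).  Mass ``m`` equals chain length in nucleotide residues.
    """

    seq: str
    as_template: Optional[object] = None   # replication.Duplex
    in_segment: Optional[object] = None    # replication.Segment
    rep_job: Optional[object] = None       # replication.RepBinding
    # non-enzymatic template fate: undecided (None) until the first substrate
    # attraction, then rolled once with P_RTT and sticky for the strand's
    # lifetime; a REP binding forces it True.
    template_fate: Optional[bool] = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError("strand must have length >= 1")
        for b in self.seq:
            if b not in COMPLEMENT:
                raise ValueError(f"invalid RNA base {b!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mass(self) -> int:
        return len(self.seq)

    @property
    def is_free(self) -> bool:
        """Free to move, collide, and act: engaged in no duplex or copy job."""
        return self.as_template is None and self.in_segment is None and self.rep_job is None

    def end_unpaired(self, which: str) -> bool:
        """Is the terminal residue at the 5' or 3' end unpaired?

        Substrate/product segments are fully paired over their length; a
        template's end is paired when a segment covers it.
        """
        if self.in_segment is not None:
            return False
        if self.as_template is not None:
            pos = 0 if which == "5p" else len(self.seq) - 1
            return not self.as_template.covers(pos)
        return True


@dataclass(frozen=True)
class RoleSet:
    """Classification flags of one strand; several may hold at once."""

    rep_functional: bool = False
    rep_spreadable: bool = False
    nsr_functional: bool = False
    nsr_spreadable: bool = False
    parasite: bool = False
    plain: bool = False

    @property
    def roles(self) -> frozenset:
        return frozenset(
            name for name in (
                "rep_functional", "rep_spreadable", "nsr_functional",
                "nsr_spreadable", "parasite", "plain",
            ) if getattr(self, name)
        )


def classify(strand, params) -> RoleSet:
    """Classify a strand (or bare sequence) under the tag mechanism."""
    seq = strand.seq if isinstance(strand, Strand) else str(strand)
    tag, rep, nsr = params.cs_tag, params.cs_rep, params.cs_nsr

    rep_functional = seq.startswith(tag + rep)
    rep_spreadable = (
        rep_functional
        and len(seq) >= len(tag) + len(rep) + len(tag)
        and seq.endswith(tag)
    )
    nsr_functional = nsr in seq
    nsr_spreadable = seq == tag + nsr + tag
    parasite = (
        len(seq) >= 2 * len(tag)
        and seq.startswith(tag)
        and seq.endswith(tag)
        and rep not in seq
        and nsr not in seq
    )
    plain = not (rep_functional or nsr_functional or parasite)
    return RoleSet(
        rep_functional=rep_functional,
        rep_spreadable=rep_spreadable,
        nsr_functional=nsr_functional,
        nsr_spreadable=nsr_spreadable,
        parasite=parasite,
        plain=plain,
    )


def has_5p_tag(seq: str, params) -> bool:
    """Can a REP recognise this strand as a template (5' tag present)?"""
    return seq.startswith(params.cs_tag)


def write_fasta(strands, path) -> None:
    """Debug fixture export (U alphabet, one record per strand)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, s in enumerate(strands):
        seq = s.seq if isinstance(s, Strand) else str(s)
        records.append(SeqRecord(Seq(seq), id=f"strand_{i}", description=f"len={len(seq)}"))
    write(records, str(path), "fasta")


def read_fasta(path) -> list:
    from Bio.SeqIO import parse

    return [Strand(str(rec.seq).upper().replace("T", "U")) for rec in parse(str(path), "fasta")]
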