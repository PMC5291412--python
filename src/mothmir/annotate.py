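"""Assignment of unique reads to known mature miRNAs.

A read is annotated against a mature reference if, after shifting its ends by
at most a configurable number of nucleotides on each side, it carries at most
one internal substitution in the overlap.  Variant names follow the
``<ref>_L±n R±n _1ss<pos><refBase><readBase>`` grammar (e.g. ``miR-10-5p_L+1``
for a read one nucleotide longer at the 5' end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ._seq import normalize


@dataclass(frozen=True)
class ReferenceMature:
    """A known mature miRNA (miRBase-style id with a 3-letter species prefix)."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize(self.sequence))

    @property
    def species(self) -> str:
        return self.id.split("-", 1)[0]


@dataclass(frozen=True)
class MatchAllowance:
    max_end_shift_5p: int = 3
    max_end_shift_3p: int = 3
    max_internal_mismatches: int = 1

    def __post_init__(self):
        if min(self.max_end_shift_5p, self.max_end_shift_3p,
               self.max_internal_mismatches) < 0:
            raise ValueError("match allowances must be non-negative")


@dataclass(frozen=True)
class Alignment:
    """End-anchored alignment of a read against a mature reference.

    ``shift5`` > 0 means the read extends beyond the reference 5' end;
    ``shift3`` > 0 means it extends beyond the 3' end.  ``mismatches`` holds
    (read_pos0, ref_base, read_base) for internal substitutions.
    """

    ref: ReferenceMature
    shift5: int
    shift3: int
    mismatches: tuple

    @property
    def total_shift(self) -> int:
        return abs(self.shift5) + abs(self.shift3)


@dataclass(frozen=True)
class ConservedAnnotation:
    reference_id: str
    suffix: str
    name: str
    seed: str
    count: float
    abundance: str
    sequence: str


def _align(read: str, ref: ReferenceMature, allow: MatchAllowance):
    """All admissible end alignments of *read* on *ref*."""
    len_r, len_m = len(read), len(ref.sequence)
    for s in range(-allow.max_end_shift_5p, allow.max_end_shift_5p + 1):
        t = len_r - len_m - s
        if abs(t) > allow.max_end_shift_3p:
            continue
        lo = max(0, s)
        hi = min(len_r, len_m + s)
        if hi - lo <= 0:
            continue
        mismatches = tuple(
            (i, ref.sequence[i - s], read[i])
            for i in range(lo, hi)
            if read[i] != ref.sequence[i - s]
        )
        if len(mismatches) <= allow.max_internal_mismatches:
            yield Alignment(ref, s, t, mismatches)


def match_known(read_seq: str, refs, allow: MatchAllowance | None = None,
                return_ties: bool = False):
    """Best reference match for a read, or ``None``.

    Best = fewest internal mismatches, then smallest total end shift, then
    lexicographically smallest reference id.  With ``return_ties`` the full
    list of equally-best alignments (distinct references) is returned, which
    supports fractional count assignment.
    """
    allow = allow or MatchAllowance()
    read_seq = normalize(read_seq)
    candidates = []
    for ref in refs:
        best_for_ref = None
        for aln in _align(read_seq, ref, allow):
            key = (len(aln.mismatches), aln.total_shift)
            if best_for_ref is None or key < (len(best_for_ref.mismatches),
                                              best_for_ref.total_shift):
                best_for_ref = aln
        if best_for_ref is not None:
            candidates.append(best_for_ref)
    if not candidates:
        return [] if return_ties else None
    candidates.sort(key=lambda a: (len(a.mismatches), a.total_shift, a.ref.id))
    if not return_ties:
        return candidates[0]
    best_key = (len(candidates[0].mismatches), candidates[0].total_shift)
    return [a for a in candidates
            if (len(a.mismatches), a.total_shift) == best_key]


def name_variant(read_seq: str, aln: Alignment) -> str:
    """Variant-name suffix for a matched read ('' when identical)."""
    if len(aln.mismatches) > 1:
        raise ValueError("more than one substitution; match should have been rejected")
    parts = ""
    if aln.shift5:
        parts += f"L{aln.shift5:+d}"
    if aln.shift3:
        parts += f"R{aln.shift3:+d}"
    if aln.mismatches:
        i, ref_base, read_base = aln.mismatches[0]
        ss = f"1ss{i + 1}{ref_base}{read_base}"
        parts = f"{parts}_{ss}" if parts else ss
    return parts


def full_name(aln: Alignment, read_seq: str) -> str:
    suffix = name_variant(read_seq, aln)
    return f"{aln.ref.id}_{suffix}" if suffix else aln.ref.id


_SUFFIX_RE = re.compile(
    r"^(?:L(?P<l>[+-]\d+))?(?:R(?P<r>[+-]\d+))?"
    r"(?:_?1ss(?P<pos>\d+)(?P<refb>[ACGTN])(?P<readb>[ACGTN]))?$"
)


def apply_variant(ref_seq: str, suffix: str, ext5: str = "", ext3: str = "") -> str:
    """Reconstruct a read from a reference sequence and a variant suffix.

    5'/3' extensions (L+n / R+n) add bases that are not present in the mature
    reference; they must be supplied via ``ext5`` / ``ext3`` (as recorded in
    the annotation).  Shortenings and substitutions are fully determined.
    """
    m = _SUFFIX_RE.match(suffix)
    if not m:
        raise ValueError(f"unparseable variant suffix: {suffix!r}")
    ref_seq = normalize(ref_seq)
    l = int(m.group("l") or 0)
    r = int(m.group("r") or 0)
    if l > 0 and len(ext5) != l:
        raise ValueError(f"L{l:+d} requires {l} recorded 5' extension bases")
    if r > 0 and len(ext3) != r:
        raise ValueError(f"R{r:+d} requires {r} recorded 3' extension bases")
    core = ref_seq[max(0, -l): len(ref_seq) + min(0, r)]
    read = (ext5 if l > 0 else "") + core + (ext3 if r > 0 else "")
    if m.group("pos"):
        pos = int(m.group("pos")) - 1
        read = read[:pos] + m.group("readb") + read[pos + 1:]
    return read


def extract_seed(mature: str) -> str:
    """Seed region: nucleotides 2-8 (1-based, inclusive) of a mature sequence."""
    mature = normalize(mature)
    if len(mature) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature!r}")
    return mature[1:8]


def classify_abundance(count: float) -> str:
    """Abundance class: low (<10 reads), middle (10-1999), high (>=2000)."""
    if count < 0:
        raise ValueError(f"negative read count: {count}")
    if count < 10:
        return "low"
    if count < 2000:
        return "middle"
    return "high"


def annotate_reads(unique_reads, refs, allow: MatchAllowance | None = None):
    """Annotate collapsed reads against the mature reference set.

    Returns ``(annotations, unannotated)``.  A read matching k references
    equally contributes 1/k of its count to each (half-integer totals arise
    exactly this way).
    """
    allow = allow or MatchAllowance()
    annotations = []
    unannotated = []
    for ur in unique_reads:
        ties = match_known(ur.sequence, refs, allow, return_ties=True)
        if not ties:
            unannotated.append(ur)
            continue
        share = ur.count / len(ties)
        for aln in ties:
            annotations.append(ConservedAnnotation(
                reference_id=aln.ref.id,
                suffix=name_variant(ur.sequence, aln),
                name=full_name(aln, ur.sequence),
                seed=extract_seed(ur.sequence),
                count=share,
                abundance=classify_abundance(share),
                sequence=ur.sequence,
            ))
    return annotations, unannotated


def load_mature_fasta(path):
    """Mature reference FASTA (miRBase-style ids; U converted to T)."""
    from Bio import SeqIO

    return [ReferenceMature(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def annotations_to_frame(annotations):
    import pandas as pd

    return pd.DataFrame([{
        "miRNA": a.name,
        "Sequence": a.sequence,
        "Length": len(a.sequence),
        "Seed": a.seed,
        "Reads": a.count,
        "Abundance": a.abundance,
    } for a in annotations])
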