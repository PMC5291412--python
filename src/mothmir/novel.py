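"""Novel miRNA discovery from unannotated reads.

Pipeline: map reads exactly to a genome/transcriptome, cut the two
candidate precursor windows around each locus (20 nt up / 60 nt down and
60 nt up / 20 nt down), fold each window, apply the 11 structural criteria
to the hairpin that carries the mature read, and name the survivors
``<prefix>-miR-PC-<arm>-<rank>_<count>``.

The folder is a self-contained dynamic program over a simple pair-energy
model (GC -3, AU -2, GU -1 kcal/mol; hairpin loops shorter than 3 nt
forbidden).  It exists so the criteria are exercisable without an external
binary; the criteria themselves operate on (structure, energy) and accept
external Vienna-format folds via :func:`read_vienna`.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import can_pair, check_dna, normalize, pair_energy, revcomp, round_half_up

MIN_HAIRPIN_LOOP = 3  # smallest number of unpaired nt enclosed by a pair


class ArmAssignmentError(ValueError):
    """Mature read straddles the hairpin loop midpoint."""


@dataclass(frozen=True)
class GenomicLocus:
    seq_id: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid locus coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class PrecursorCandidate:
    """A candidate precursor window with its fold and mature placement."""

    sequence: str
    structure: str
    energy: float
    mature_offset: int
    mature_length: int
    locus: GenomicLocus | None = None
    window_locus: GenomicLocus | None = None

    def __post_init__(self):
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure and sequence lengths differ")
        depth = 0
        for c in self.structure:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket structure")
            elif c != ".":
                raise ValueError(f"invalid structure character {c!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket structure")
        if not (0 <= self.mature_offset
                and self.mature_offset + self.mature_length <= len(self.sequence)):
            raise ValueError("mature read lies outside the precursor window")


@dataclass(frozen=True)
class HairpinCriteria:
    """The 11 structural thresholds applied jointly (AND)."""

    max_stem_bulge_nt: int = 12        # (1)  <=
    min_stem_pairs: int = 16           # (2)  >=
    max_free_energy: float = -15.0     # (3)  <= kcal/mol
    min_hairpin_len: int = 50          # (4)  >=
    max_loop_len: int = 20             # (5)  <=
    max_mature_bulge_nt: int = 8       # (6)  <=
    max_biased_errors_mature: int = 4  # (7)  <=
    max_biased_bulges_mature: int = 2  # (8)  <=
    max_mature_errors: int = 7         # (9)  <=
    min_mature_pairs: int = 12         # (10) >=
    min_pct_mature_in_stem: float = 80.0  # (11) >=


#: criterion index -> (report key, direction); 'le' means measured <= threshold passes
CRITERION_FIELDS = {
    1: ("max_stem_bulge_nt", "le"),
    2: ("min_stem_pairs", "ge"),
    3: ("max_free_energy", "le"),
    4: ("min_hairpin_len", "ge"),
    5: ("max_loop_len", "le"),
    6: ("max_mature_bulge_nt", "le"),
    7: ("max_biased_errors_mature", "le"),
    8: ("max_biased_bulges_mature", "le"),
    9: ("max_mature_errors", "le"),
    10: ("min_mature_pairs", "ge"),
    11: ("min_pct_mature_in_stem", "ge"),
}


@dataclass
class CriteriaReport:
    measured: dict        # criterion index -> measured value (None when unmeasurable)
    passed: dict          # criterion index -> bool
    overall: bool
    note: str = ""


# ---------------------------------------------------------------------------
# folding

def fold(sequence: str) -> tuple[str, float]:
    """Maximum-stability nested structure under the simple pair-energy model.

    Dynamic program minimising total energy; ties broken by maximal pair
    count, then by pairing the 5'-most base with its closest admissible
    partner.  Returns (dot-bracket, free energy in kcal/mol).
    """
    seq = check_dna(sequence)
    n = len(seq)
    if n < 10:
        raise ValueError("sequences shorter than 10 nt are not folded")
    # best[i][j] over inclusive span, as (energy, -npairs); choice[i][j] is the
    # partner of i (or None when i is left unpaired)
    best = [[(0.0, 0)] * n for _ in range(n)]
    choice = [[None] * n for _ in range(n)]

    def val(i, j):
        return best[i][j] if i <= j else (0.0, 0)

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best_v = None
            best_c = None
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if not can_pair(seq[i], seq[k]):
                    continue
                inner = val(i + 1, k - 1)
                rest = val(k + 1, j)
                v = (pair_energy(seq[i], seq[k]) + inner[0] + rest[0],
                     inner[1] + rest[1] - 1)
                if best_v is None or v < best_v:
                    best_v, best_c = v, k
            skip = val(i + 1, j)
            if best_v is None or skip < best_v:
                best_v, best_c = skip, None
            best[i][j] = best_v
            choice[i][j] = best_c

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        k = choice[i][j]
        if k is None:
            stack.append((i + 1, j))
        else:
            structure[i], structure[k] = "(", ")"
            stack.append((i + 1, k - 1))
            stack.append((k + 1, j))
    return "".join(structure), best[0][n - 1][0]


def pair_table(structure: str) -> list:
    """Partner index per position (None when unpaired)."""
    partner = [None] * len(structure)
    stack = []
    for idx, c in enumerate(structure):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            i = stack.pop()
            partner[i], partner[idx] = idx, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partner


@dataclass
class Hairpin:
    """A stem-loop: the pair chain from the hairpin loop outward."""

    chain: list  # pairs (i, j), ordered innermost -> outermost

    @property
    def inner(self):
        return self.chain[0]

    @property
    def outer(self):
        return self.chain[-1]

    @property
    def loop_len(self) -> int:
        i, j = self.inner
        return j - i - 1

    @property
    def span(self) -> int:
        i, j = self.outer
        return j - i + 1

    @property
    def n_pairs(self) -> int:
        return len(self.chain)

    def stem_positions(self) -> set:
        i_out, j_out = self.outer
        i_in, j_in = self.inner
        return set(range(i_out, i_in + 1)) | set(range(j_in, j_out + 1))

    def gap_regions(self):
        """(5'-gap positions, 3'-gap positions) between consecutive pairs,
        walked from the outside in."""
        regions = []
        for (i_o, j_o), (i_i, j_i) in zip(self.chain[::-1][:-1], self.chain[::-1][1:]):
            regions.append((list(range(i_o + 1, i_i)), list(range(j_i + 1, j_o))))
        return regions


def hairpins(structure: str, trim_gap: int | None = 12) -> list:
    """Stem-loop components of a nested structure.

    Each hairpin loop (innermost pair) is extended outward through its chain
    of singly-nested enclosing pairs; the chain stops at a multiloop.  With
    ``trim_gap`` set, a one-sided gap larger than ``trim_gap`` is crossed
    only when the enclosing pairs beyond it outnumber the gap (a helix that
    more than pays for the bulge).  Under a pair-energy model without loop
    penalties, isolated long-range pairs form freely around a stem; this
    rule keeps a genuine far stem arm while shedding such opportunistic
    enclosures, which would otherwise read as giant stem bulges.
    """
    partner = pair_table(structure)
    pairs = sorted((i, j) for i, j in enumerate(partner) if j is not None and i < j)
    children: dict = {p: [] for p in pairs}
    roots = []
    stack = []
    for p in pairs:
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        else:
            roots.append(p)
        stack.append(p)
    parent = {}
    for p, kids in children.items():
        for k in kids:
            parent[k] = p
    result = []
    for p in pairs:
        if children[p]:
            continue  # not a hairpin loop
        chain = [p]
        cur = p
        while cur in parent and len(children[parent[cur]]) == 1:
            cur = parent[cur]
            chain.append(cur)
        if trim_gap is not None and len(chain) > 1:
            kept = 1
            while kept < len(chain):
                i_i, j_i = chain[kept - 1]
                i_o, j_o = chain[kept]
                gap = max(i_i - i_o - 1, j_o - j_i - 1)
                if gap > trim_gap and len(chain) - kept <= gap:
                    break
                kept += 1
            chain = chain[:kept]
        result.append(Hairpin(chain))
    return result


# ---------------------------------------------------------------------------
# criteria

def evaluate_criteria(candidate: PrecursorCandidate,
                      crit: HairpinCriteria | None = None) -> CriteriaReport:
    """Measure the 11 hairpin criteria for a folded candidate.

    The hairpin used is the stem-loop whose stem covers the most mature
    positions; a candidate whose mature overlaps no stem fails outright.
    """
    crit = crit or HairpinCriteria()
    m0 = candidate.mature_offset
    m1 = m0 + candidate.mature_length
    mature = set(range(m0, m1))
    partner = pair_table(candidate.structure)

    comps = hairpins(candidate.structure, trim_gap=crit.max_stem_bulge_nt)
    best = None
    best_cover = -1
    for hp in comps:
        cover = len(mature & hp.stem_positions())
        if cover > best_cover:
            best, best_cover = hp, cover
    if best is None or best_cover == 0:
        measured = {idx: None for idx in CRITERION_FIELDS}
        measured[3] = candidate.energy
        passed = {idx: False for idx in CRITERION_FIELDS}
        passed[3] = candidate.energy <= crit.max_free_energy
        return CriteriaReport(measured, passed, overall=False,
                              note="mature read overlaps no hairpin stem")

    gaps = best.gap_regions()
    one_sided_runs = []
    max_stem_gap = 0
    for g5, g3 in gaps:
        max_stem_gap = max(max_stem_gap, len(g5), len(g3))
        if g5 and not g3:
            one_sided_runs.append(g5)
        elif g3 and not g5:
            one_sided_runs.append(g3)

    # longest contiguous run of unpaired mature positions
    longest_mature_run = run = 0
    for p in range(m0, m1):
        run = run + 1 if partner[p] is None else 0
        longest_mature_run = max(longest_mature_run, run)

    biased_positions = [p for r in one_sided_runs for p in r if p in mature]
    biased_bulges = sum(1 for r in one_sided_runs if mature.intersection(r))
    unpaired_mature = sum(1 for p in range(m0, m1) if partner[p] is None)
    paired_mature = candidate.mature_length - unpaired_mature
    pct_in_stem = 100.0 * best_cover / candidate.mature_length

    measured = {
        1: max_stem_gap,
        2: best.n_pairs,
        3: candidate.energy,
        4: best.span,
        5: best.loop_len,
        6: longest_mature_run,
        7: len(biased_positions),
        8: biased_bulges,
        9: unpaired_mature,
        10: paired_mature,
        11: pct_in_stem,
    }
    passed = {}
    for idx, (fname, direction) in CRITERION_FIELDS.items():
        threshold = getattr(crit, fname)
        v = measured[idx]
        passed[idx] = (v <= threshold) if direction == "le" else (v >= threshold)
    return CriteriaReport(measured, passed, overall=all(passed.values()))


# ---------------------------------------------------------------------------
# mapping and windows

def map_exact(read_seq: str, references: dict) -> list:
    """All exact occurrences of a read on both strands of the references."""
    read_seq = normalize(read_seq)
    rc = revcomp(read_seq)
    loci = []
    for seq_id, ref in references.items():
        ref = normalize(ref)
        for probe, strand in ((read_seq, "+"), (rc, "-")):
            pos = ref.find(probe)
            while pos != -1:
                loci.append(GenomicLocus(seq_id, pos, pos + len(probe), strand))
                pos = ref.find(probe, pos + 1)
    return loci


def extract_windows(locus: GenomicLocus, references: dict,
                    upstream: int = 20, downstream: int = 60) -> list:
    """The two precursor windows around a mapped read (strand-resolved).

    Window A puts the read near the window 5' end (20 nt up / 60 nt down),
    window B near the 3' end (60 nt up / 20 nt down); both are clipped at the
    sequence bounds.  Returned candidates are unfolded (empty structure/zero
    energy placeholders replaced by :func:`fold` downstream).
    """
    ref = normalize(references[locus.seq_id])
    out = []
    for up, down in ((upstream, downstream), (downstream, upstream)):
        if locus.strand == "+":
            ws = max(0, locus.start - up)
            we = min(len(ref), locus.end + down)
            seq = ref[ws:we]
            offset = locus.start - ws
        else:
            ws = max(0, locus.start - down)
            we = min(len(ref), locus.end + up)
            seq = revcomp(ref[ws:we])
            offset = we - locus.end
        out.append(PrecursorCandidate(
            sequence=seq,
            structure="." * len(seq),
            energy=0.0,
            mature_offset=offset,
            mature_length=locus.end - locus.start,
            locus=locus,
            window_locus=GenomicLocus(locus.seq_id, ws, we, locus.strand),
        ))
    return out


def fold_candidate(candidate: PrecursorCandidate) -> PrecursorCandidate:
    structure, energy = fold(candidate.sequence)
    candidate.structure = structure
    candidate.energy = energy
    return candidate


# ---------------------------------------------------------------------------
# calling

@dataclass
class NovelMiRNA:
    name: str
    arm: str
    sequence: str
    count: float
    candidate: PrecursorCandidate
    report: CriteriaReport
    both_arms: bool = False


def assign_arm(candidate: PrecursorCandidate,
               crit: HairpinCriteria | None = None) -> str:
    """5p/3p arm of the mature read relative to the hairpin loop midpoint."""
    crit = crit or HairpinCriteria()
    comps = hairpins(candidate.structure, trim_gap=crit.max_stem_bulge_nt)
    mature = set(range(candidate.mature_offset,
                       candidate.mature_offset + candidate.mature_length))
    best = max(comps, key=lambda hp: len(mature & hp.stem_positions()),
               default=None)
    if best is None:
        raise ArmAssignmentError("no hairpin in candidate structure")
    i_in, j_in = best.inner
    mid = (i_in + j_in) / 2.0
    if all(p < mid for p in mature):
        return "5p"
    if all(p > mid for p in mature):
        return "3p"
    raise ArmAssignmentError("mature read straddles the loop midpoint")


def call_novel(reads, references: dict, crit: HairpinCriteria | None = None,
               min_novel_count: float = 10, species_prefix: str = "gmo"):
    """Call novel miRNAs from unannotated collapsed reads.

    ``reads`` is an iterable of objects with ``sequence`` and ``count``
    (e.g. :class:`mothmir.readqc.UniqueRead`).  A read is called when it has
    at least ``min_novel_count`` reads, maps exactly to the references, and
    at least one of its precursor windows passes all 11 criteria; among
    passing windows the lowest-energy one is kept.  Candidates are ranked by
    descending count and named ``<prefix>-miR-PC-<arm>-<rank>_<count>``.
    """
    crit = crit or HairpinCriteria()
    called = []
    skipped = []
    for read in reads:
        if read.count < min_novel_count:
            continue
        passing = []
        for locus in map_exact(read.sequence, references):
            for cand in extract_windows(locus, references):
                fold_candidate(cand)
                report = evaluate_criteria(cand, crit)
                if report.overall:
                    passing.append((cand, report))
        if not passing:
            continue
        cand, report = min(passing, key=lambda cr: cr[0].energy)
        try:
            arm = assign_arm(cand, crit)
        except ArmAssignmentError as exc:
            skipped.append((read.sequence, str(exc)))
            continue
        called.append(NovelMiRNA("", arm, read.sequence, read.count, cand, report))

    called.sort(key=lambda nv: (-nv.count, nv.sequence))
    for rank, nv in enumerate(called, start=1):
        nv.name = f"{species_prefix}-miR-PC-{nv.arm}-{rank}_{int(round(nv.count))}"
    _mark_both_arms(called)
    return called, skipped


def _precursor_key(nv: NovelMiRNA):
    wl = nv.candidate.window_locus
    if wl is None:
        return None
    return (wl.seq_id, wl.start, wl.end)


def _mark_both_arms(called) -> None:
    """Flag precursors whose two arms each yielded a called mature."""
    spans: dict = {}
    for nv in called:
        wl = nv.candidate.window_locus
        if wl is None:
            continue
        spans.setdefault(wl.seq_id, []).append(nv)
    for seq_id, group in spans.items():
        for a in group:
            for b in group:
                if a is b or a.arm == b.arm:
                    continue
                wa, wb = a.candidate.window_locus, b.candidate.window_locus
                if wa.start < wb.end and wb.start < wa.end:  # windows overlap
                    a.both_arms = b.both_arms = True


def arm_ratio(novel_set) -> float | None:
    """5p-only / 3p-only count (2 dp); None when undefined.

    Accepts NovelMiRNA objects or plain names containing ``-5p-``/``-3p-``.
    """
    n5 = n3 = 0
    for nv in novel_set:
        if isinstance(nv, NovelMiRNA):
            if nv.both_arms:
                continue
            arm = nv.arm
        else:
            name = str(nv)
            arm = "5p" if "-5p-" in name else "3p" if "-3p-" in name else None
        if arm == "5p":
            n5 += 1
        elif arm == "3p":
            n3 += 1
    if n3 == 0:
        return None
    return round_half_up(n5 / n3, 2)


# ---------------------------------------------------------------------------
# Vienna I/O

def read_vienna(path):
    """Parse a Vienna-format file: ``>name`` / sequence / structure (energy)."""
    entries = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected a '>' header at line {i + 1}")
        name = lines[i][1:].strip()
        seq = normalize(lines[i + 1].strip())
        struct_line = lines[i + 2].strip()
        energy = 0.0
        if "(" in struct_line and struct_line.rsplit(" ", 1)[-1].startswith("("):
            struct, _, tail = struct_line.rpartition(" ")
            energy = float(tail.strip("()"))
            struct_line = struct.strip()
        entries.append((name, seq, struct_line, energy))
        i += 3
    return entries


def write_gff3(novel_list, path) -> None:
    """GFF3 of called loci (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for nv in novel_list:
            loc = nv.candidate.locus
            if loc is None:
                continue
            fh.write("\t".join([
                loc.seq_id, "mothmir", "miRNA",
                str(loc.start + 1), str(loc.end), ".",
                loc.strand, ".", f"ID={nv.name};arm={nv.arm}",
            ]) + "\n")
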