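"""Small-RNA read cleaning: adapter trimming, length/junk/Rfam/repeat filters,
collapse to unique reads and a sequencing-audit summary.

The cascade mirrors a standard sRNA-seq preprocessing protocol: 3' adapter
removal (adapter-only reads are "adapter dimers"), an 18-26 nt length window,
composition-based junk rules (excess N, homopolymer runs, short tandem
repeats), removal of common non-miRNA non-coding RNA classes by containment
in a labelled reference, optional repeat removal, and finally collapsing of
identical inserts into unique reads carrying their total count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._seq import check_dna, normalize, round_half_up

RFAM_CATEGORIES = ("rRNA", "tRNA", "snoRNA", "snRNA", "other_rfam")

#: Sentinel returned by :func:`trim_adapter` for adapter-only reads.
ADAPTER_DIMER = "adapter_dimer"


@dataclass(frozen=True)
class JunkRules:
    """Composition thresholds that flag a read as junk.

    A read is junk when it contains at least ``min_N`` ambiguous bases
    (anywhere), a contiguous homopolymer run reaching the per-base threshold,
    or a contiguous tandem repeat of a single 2/3/4-mer motif reaching the
    per-k copy number.  Rules are evaluated in the order
    N, A, C, G, T, dimer, trimer, tetramer and the first rule fired is
    reported.
    """

    min_N: int = 2
    min_runA: int = 7
    min_runC: int = 8
    min_runG: int = 6
    min_runT: int = 7
    min_dimer_copies: int = 10
    min_trimer_copies: int = 6
    min_tetramer_copies: int = 5

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 1:
                raise ValueError(f"JunkRules.{name} must be >= 1, got {value}")


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed read sequence with its total count."""

    sequence: str
    count: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FilterStageTallies:
    """Running total/unique tallies per removal category."""

    total: Counter = field(default_factory=Counter)
    unique_seqs: dict = field(default_factory=dict)  # category -> set of sequences

    def add(self, category: str, sequence: str, n: int = 1) -> None:
        self.total[category] += n
        self.unique_seqs.setdefault(category, set()).add(sequence)

    def unique_counts(self) -> dict:
        return {cat: len(seqs) for cat, seqs in self.unique_seqs.items()}


ROW_ORDER = (
    "raw", "adaptor_length", "junk",
    "rfam", "rRNA", "tRNA", "snoRNA", "snRNA", "other_rfam",
    "repeats", "unique_reads",
)


@dataclass
class FilterSummary:
    """Audit table: per category the read totals, unique-sequence totals and
    their percentages of the raw library (2 dp, half-up)."""

    table: pd.DataFrame

    @classmethod
    def from_counts(cls, total: dict, unique: dict) -> "FilterSummary":
        """Build the audit from externally supplied per-category counts.

        ``total`` / ``unique`` map category names (see ``ROW_ORDER``) to read
        and distinct-sequence counts.  The ``rfam`` row, if absent, is filled
        from its five subcategories.  Percentages are recomputed here; the
        counts themselves are taken as given.
        """
        total = dict(total)
        unique = dict(unique)
        for d in (total, unique):
            if "rfam" not in d:
                d["rfam"] = sum(d.get(c, 0) for c in RFAM_CATEGORIES)
        if "raw" not in total or "raw" not in unique:
            raise ValueError("raw totals are required to compute percentages")
        raw_t, raw_u = total["raw"], unique["raw"]
        rows = []
        for cat in ROW_ORDER:
            t = total.get(cat, 0)
            u = unique.get(cat, 0)
            rows.append({
                "category": cat,
                "total_reads": t,
                "pct_total_reads": round_half_up(100.0 * t / raw_t if raw_t else 0.0),
                "unique_sequences": u,
                "pct_unique_sequences": round_half_up(100.0 * u / raw_u if raw_u else 0.0),
            })
        return cls(pd.DataFrame(rows))

    def pct_total(self, category: str) -> float:
        return float(self.table.set_index("category").loc[category, "pct_total_reads"])

    def pct_unique(self, category: str) -> float:
        return float(self.table.set_index("category").loc[category, "pct_unique_sequences"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def trim_adapter(read: str, adapter: str, min_prefix: int = 5) -> str:
    """Remove the 3' adapter at its leftmost occurrence.

    A full-adapter match anywhere is preferred; failing that, a prefix of the
    adapter (>= ``min_prefix`` nt) terminating the read is trimmed, which
    handles adapters truncated by the sequencer's read length.  Returns the
    insert, :data:`ADAPTER_DIMER` when the insert is empty, or the read
    unchanged when no adapter is found (the length filter catches those).
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    read = normalize(read)
    adapter = normalize(adapter)
    pos = read.find(adapter)
    if pos == -1:
        # prefix-only match at the very end of the read
        max_k = min(len(adapter) - 1, len(read))
        for k in range(max_k, min_prefix - 1, -1):
            if read.endswith(adapter[:k]):
                pos = len(read) - k
                break
    if pos == -1:
        return read
    if pos == 0:
        return ADAPTER_DIMER
    return read[:pos]


def filter_length(seq: str, min_len: int = 18, max_len: int = 26) -> bool:
    """Keep a read iff ``min_len <= len <= max_len``."""
    return min_len <= len(seq) <= max_len


def _max_homopolymer_run(seq: str, base: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == base else 0
        best = max(best, run)
    return best


def _max_tandem_copies(seq: str, k: int) -> int:
    """Maximal number of contiguous full copies of any k-mer motif.

    Partial trailing copies do not count.
    """
    n = len(seq)
    best = 0
    for start in range(n - k + 1):
        motif = seq[start:start + k]
        copies = 1
        pos = start + k
        while pos + k <= n and seq[pos:pos + k] == motif:
            copies += 1
            pos += k
        best = max(best, copies)
    return best


def is_junk(seq: str, rules: JunkRules | None = None) -> tuple[bool, str | None]:
    """Flag composition-junk reads; returns (flag, first rule fired)."""
    rules = rules or JunkRules()
    seq = check_dna(seq)
    checks = (
        ("N", seq.count("N") >= rules.min_N),
        ("A", _max_homopolymer_run(seq, "A") >= rules.min_runA),
        ("C", _max_homopolymer_run(seq, "C") >= rules.min_runC),
        ("G", _max_homopolymer_run(seq, "G") >= rules.min_runG),
        ("T", _max_homopolymer_run(seq, "T") >= rules.min_runT),
        ("dimer", _max_tandem_copies(seq, 2) >= rules.min_dimer_copies),
        ("trimer", _max_tandem_copies(seq, 3) >= rules.min_trimer_copies),
        ("tetramer", _max_tandem_copies(seq, 4) >= rules.min_tetramer_copies),
    )
    for name, fired in checks:
        if fired:
            return True, name
    return False, None


def _contains(haystack: str, needle: str, max_mismatches: int = 0) -> bool:
    if max_mismatches == 0:
        return needle in haystack
    n, m = len(haystack), len(needle)
    for start in range(n - m + 1):
        mm = 0
        for a, b in zip(haystack[start:start + m], needle):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return True
    return False


def classify_rfam(seq: str, rfam_reference, max_mismatches: int = 0) -> str:
    """Category of the first reference record containing the read (sense strand).

    ``rfam_reference`` is a sequence of ``(record_id, category, sequence)``
    tuples; returns one of rRNA/tRNA/snoRNA/snRNA/other_rfam or ``"none"``.
    """
    seq = normalize(seq)
    for rec_id, category, ref_seq in rfam_reference:
        if not category:
            raise ValueError(f"reference record {rec_id!r} carries no category label")
        if _contains(normalize(ref_seq), seq, max_mismatches):
            if category in RFAM_CATEGORIES[:4]:
                return category
            return "other_rfam"
    return "none"


def load_labelled_fasta(path):
    """Read a labelled FASTA: ``>id category`` headers -> (id, category, seq)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        category = parts[1] if len(parts) > 1 else None
        if category is None:
            raise ValueError(f"reference record {rec.id!r} carries no category label")
        records.append((rec.id, category, normalize(str(rec.seq))))
    return records


def collapse_and_summarize(surviving, tallies: FilterStageTallies,
                           raw_total: int, raw_unique: int):
    """Collapse surviving read sequences and assemble the audit table.

    ``surviving`` is an iterable of insert sequences (one entry per read).
    Unique reads are sorted by descending count, then lexicographically.
    """
    counts = Counter(surviving)
    uniques = [UniqueRead(seq, c) for seq, c in
               sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    total = dict(tallies.total)
    unique = tallies.unique_counts()
    total["raw"] = raw_total
    unique["raw"] = raw_unique
    total["unique_reads"] = sum(counts.values())
    unique["unique_reads"] = len(counts)
    summary = FilterSummary.from_counts(total, unique)
    return uniques, summary


def run_readqc(reads, adapter: str, rules: JunkRules | None = None,
               rfam_reference=None, repeat_reference=None,
               min_len: int = 18, max_len: int = 26):
    """Run the full cascade on raw read sequences.

    ``reads`` is an iterable of raw sequences (FASTQ order).  Returns
    ``(unique_reads, summary, dispositions)`` where ``dispositions`` maps each
    raw sequence to the category that removed it (or ``"kept"``).  Filter
    order: adapter -> length -> junk -> Rfam -> repeats.
    """
    rules = rules or JunkRules()
    tallies = FilterStageTallies()
    surviving = []
    dispositions = {}
    raw_seqs = set()
    n_raw = 0
    decided: dict[str, tuple[str, str | None]] = {}  # raw seq -> (category, insert)

    for raw in reads:
        raw = normalize(raw)
        n_raw += 1
        raw_seqs.add(raw)
        if raw in decided:
            category, insert = decided[raw]
        else:
            insert = trim_adapter(raw, adapter)
            if insert == ADAPTER_DIMER or not filter_length(insert, min_len, max_len):
                category = "adaptor_length"
            elif is_junk(insert, rules)[0]:
                category = "junk"
            else:
                category = "kept"
                if rfam_reference is not None:
                    rf = classify_rfam(insert, rfam_reference)
                    if rf != "none":
                        category = rf
                if category == "kept" and repeat_reference is not None:
                    for rec in repeat_reference:
                        ref_seq = rec[-1]
                        if insert in normalize(ref_seq):
                            category = "repeats"
                            break
            decided[raw] = (category, insert)
        dispositions[raw] = category
        if category == "kept":
            surviving.append(insert)
        elif category in RFAM_CATEGORIES:
            tallies.add(category, raw)
            tallies.total["rfam"] += 1
            tallies.unique_seqs.setdefault("rfam", set()).add(raw)
        else:
            tallies.add(category, raw)

    return collapse_and_summarize(surviving, tallies, n_raw, len(raw_seqs)) + (dispositions,)


def write_collapsed_fasta(uniques, path) -> None:
    """Write unique reads as FASTA with ``>u<i>_<count>`` headers."""
    with open(path, "w") as fh:
        for i, ur in enumerate(uniques, start=1):
            count = int(ur.count) if float(ur.count).is_integer() else ur.count
            fh.write(f">u{i}_{count}\n{ur.sequence}\n")
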