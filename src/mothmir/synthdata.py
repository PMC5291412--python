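"""Synthetic data with planted ground truth.

Emulates the inputs of a pooled insect small-RNA study: a genome carrying
perfect inverted-repeat miRNA hairpins (optionally clustered), a raw sRNA
read set with the realistic contaminant mix (adapter dimers, junk reads,
Rfam-class non-coding RNA fragments, out-of-range lengths) and qPCR Cq
matrices containing stable and condition-driven candidate reference genes
plus a validation target with known fold changes.  Everything is
deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .novel import GenomicLocus
from .readqc import is_junk, classify_rfam, JunkRules

_BASES = np.array(list("ACGT"))
#: planted 5' arms are purine-only (G/A) and 3' arms their complement (C/T),
#: with an all-A loop: the planted register then attains every arm base's
#: best possible pair energy simultaneously, the arms and the loop cannot
#: pair internally, and the folder always recovers the full planted stem
_ARM_BASES = np.array(list("GA"))

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter

JUNK_RULE_CYCLE = ("N", "A", "C", "G", "T", "dimer", "trimer", "tetramer")
RFAM_LABELS = ("rRNA", "tRNA", "snoRNA", "snRNA", "other_rfam")


@dataclass(frozen=True)
class SynthConfig:
    rng_seed: int = 20170203
    genome_length: int = 150_000
    n_hairpins: int = 10
    cluster_spec: tuple = ((3, 2000), (2, 4000))
    stem_length: int = 30
    loop_length: int = 10
    mature_length: int = 22
    read_depth: float = 100.0
    end_shift_max: int = 0
    substitution_rate: float = 0.0
    junk_fraction: float = 0.0015
    adapter_dimer_fraction: float = 0.30
    rfam_fraction: float = 0.03
    length_outlier_fraction: float = 0.30
    adapter: str = DEFAULT_ADAPTER
    arm_fractions: tuple = (0.5, 0.4, 0.1)  # P(5p), P(3p), P(both)
    minus_strand_fraction: float = 0.25
    intercluster_gap: int = 15_000
    margin: int = 200
    n_cq_genes: int = 12
    n_cq_stable: int = 6
    n_cq_samples: int = 8
    n_cq_replicates: int = 3
    cq_stable_sd: float = 0.1
    cq_unstable_sd: float = 1.5
    true_efficiency: float = 1.0  # 1.0 == 100 % amplification efficiency

    def __post_init__(self):
        fracs = (self.junk_fraction, self.adapter_dimer_fraction,
                 self.rfam_fraction, self.length_outlier_fraction)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("contaminant fractions must lie in [0, 1]")
        # a sum of exactly 1 is the degenerate all-contaminant library
        if sum(fracs) > 1.0:
            raise ValueError("contaminant fractions must sum to <= 1")
        if self.stem_length < 16:
            raise ValueError("stem_length must be >= 16 so planted hairpins "
                             "satisfy the stem-pair criterion")
        if not (8 <= self.mature_length <= self.stem_length):
            raise ValueError("mature_length must be in [8, stem_length]")
        if self.n_hairpins and sum(n for n, _ in self.cluster_spec) > self.n_hairpins:
            raise ValueError("cluster_spec assigns more members than n_hairpins")
        if abs(sum(self.arm_fractions) - 1.0) > 1e-9:
            raise ValueError("arm_fractions must sum to 1")


@dataclass
class PlantedMature:
    hairpin_id: str
    arm: str  # 5p | 3p
    sequence: str
    locus: GenomicLocus


@dataclass
class PlantedHairpin:
    hairpin_id: str
    locus: GenomicLocus
    precursor: str
    arm_mode: str  # 5p | 3p | both
    cluster_id: int | None


@dataclass
class GroundTruth:
    hairpins: list = field(default_factory=list)
    matures: list = field(default_factory=list)
    true_counts: dict = field(default_factory=dict)  # mature sequence -> reads


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_nonjunk(rng, n: int, rules: JunkRules) -> str:
    for _ in range(1000):
        s = _random_seq(rng, n)
        if not is_junk(s, rules)[0]:
            return s
    raise RuntimeError("could not draw a junk-free sequence")


def _build_precursor(rng, config: SynthConfig, rules: JunkRules) -> str:
    ml = config.mature_length
    for _ in range(5000):
        arm5 = "".join(_ARM_BASES[rng.integers(0, 2, config.stem_length)])
        loop = "A" * config.loop_length
        precursor = arm5 + loop + revcomp(arm5)
        m5 = precursor[:ml]
        m3 = precursor[-ml:]
        # matures must survive the junk filter; the loop itself never becomes
        # part of a read (matures sit at the arm ends)
        if not is_junk(m5, rules)[0] and not is_junk(m3, rules)[0]:
            return precursor
    raise RuntimeError("could not build a junk-free precursor")


def generate_genome(config: SynthConfig):
    """Plant hairpin precursors in a random genome.

    Returns ``({seq_id: sequence}, GroundTruth)``.  Hairpins listed in
    ``cluster_spec`` are placed with end-to-start gaps <= the cluster's
    maximum gap; groups are separated by ``intercluster_gap``.
    """
    rng = np.random.default_rng([config.rng_seed, 0])
    rules = JunkRules()

    n_clustered = sum(n for n, _ in config.cluster_spec) if config.n_hairpins else 0
    groups = []
    if config.n_hairpins:
        groups = [spec for spec in config.cluster_spec]
        groups += [(1, 0)] * (config.n_hairpins - n_clustered)

    hp_len = 2 * config.stem_length + config.loop_length
    worst = 2 * config.margin
    worst += config.n_hairpins * hp_len
    worst += sum((n - 1) * g for n, g in groups)
    worst += max(0, len(groups) - 1) * config.intercluster_gap
    if worst > config.genome_length:
        raise ValueError(
            f"genome_length={config.genome_length} cannot hold {config.n_hairpins} "
            f"hairpins with the requested spacing (needs up to {worst} bp)")

    genome = list(_random_seq(rng, config.genome_length))
    truth = GroundTruth()
    seq_id = "synth1"
    cursor = config.margin
    matures_seen = set()
    hp_index = 0
    for cluster_idx, (n_members, max_gap) in enumerate(groups):
        cluster_id = cluster_idx + 1 if n_members > 1 else None
        for member in range(n_members):
            precursor = _build_precursor(rng, config, rules)
            m5 = precursor[:config.mature_length]
            m3 = precursor[-config.mature_length:]
            while m5 in matures_seen or m3 in matures_seen or m5 == m3:
                precursor = _build_precursor(rng, config, rules)
                m5 = precursor[:config.mature_length]
                m3 = precursor[-config.mature_length:]
            matures_seen.update((m5, m3))

            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            u = rng.random()
            p5, p3, _ = config.arm_fractions
            arm_mode = "5p" if u < p5 else ("3p" if u < p5 + p3 else "both")

            start = cursor
            end = start + hp_len
            planted = precursor if strand == "+" else revcomp(precursor)
            genome[start:end] = list(planted)
            hp_index += 1
            hp_id = f"hp{hp_index:03d}"
            locus = GenomicLocus(seq_id, start, end, strand)
            truth.hairpins.append(PlantedHairpin(hp_id, locus, precursor,
                                                 arm_mode, cluster_id))
            ml = config.mature_length
            if strand == "+":
                loc5 = GenomicLocus(seq_id, start, start + ml, "+")
                loc3 = GenomicLocus(seq_id, end - ml, end, "+")
            else:
                loc5 = GenomicLocus(seq_id, end - ml, end, "-")
                loc3 = GenomicLocus(seq_id, start, start + ml, "-")
            if arm_mode in ("5p", "both"):
                truth.matures.append(PlantedMature(hp_id, "5p", m5, loc5))
            if arm_mode in ("3p", "both"):
                truth.matures.append(PlantedMature(hp_id, "3p", m3, loc3))

            cursor = end
            if member < n_members - 1:
                gap = int(rng.integers(10, max_gap + 1)) if max_gap >= 10 else max_gap
                cursor += gap
        cursor += config.intercluster_gap
    return {seq_id: "".join(genome)}, truth


def generate_rfam_reference(config: SynthConfig, n_records: int = 15):
    """A labelled mock reference of common non-miRNA non-coding RNA classes."""
    rng = np.random.default_rng([config.rng_seed, 3])
    rules = JunkRules()
    records = []
    for i in range(n_records):
        label = RFAM_LABELS[i % len(RFAM_LABELS)]
        length = int(rng.integers(80, 300))
        records.append((f"ncrna{i + 1:03d}", label, _random_nonjunk(rng, length, rules)))
    return records


def _make_junk_insert(rng, rule: str, rules: JunkRules) -> str:
    for _ in range(200):
        if rule == "N":
            base = list(_random_nonjunk(rng, 22, rules))
            i, j = rng.choice(22, size=2, replace=False)
            base[i] = base[j] = "N"
            insert = "".join(base)
        elif rule in "ACGT":
            run_len = {"A": rules.min_runA, "C": rules.min_runC,
                       "G": rules.min_runG, "T": rules.min_runT}[rule]
            pad = _random_nonjunk(rng, 22 - run_len, rules)
            pos = int(rng.integers(0, len(pad) + 1))
            insert = pad[:pos] + rule * run_len + pad[pos:]
        else:
            k, copies = {"dimer": (2, rules.min_dimer_copies),
                         "trimer": (3, rules.min_trimer_copies),
                         "tetramer": (4, rules.min_tetramer_copies)}[rule]
            motif = _random_seq(rng, k)
            insert = motif * copies
        flag, fired = is_junk(insert, rules)
        if flag and fired == rule and 18 <= len(insert) <= 26:
            return insert
    raise RuntimeError(f"could not build a junk read for rule {rule!r}")


def generate_reads(truth: GroundTruth, config: SynthConfig, genome=None,
                   rfam_reference=None):
    """Raw reads (insert + 3' adapter) with per-read truth labels.

    Mature-derived reads are drawn per planted mature with Poisson depth,
    end shifts up to ``end_shift_max`` (sequence taken from the genomic
    context, so shifted reads still map exactly) and at most one
    substitution.  Contaminants are emitted so that each category is the
    configured fraction of the total.  Returns ``(reads, labels)`` where
    ``reads`` is a list of (read_id, raw_sequence) in shuffled order and
    ``labels`` a DataFrame with read_id, label, mature_id, insert.
    """
    if config.rfam_fraction > 0 and rfam_reference is None:
        raise ValueError("rfam_fraction > 0 requires an rfam reference")
    if config.end_shift_max > 0 and genome is None:
        raise ValueError("end shifts require the genome for flanking context")
    rng = np.random.default_rng([config.rng_seed, 1])

    rules = JunkRules()
    entries = []  # (label, mature_id, insert, raw)

    def emit(label, mature_id, insert, raw=None):
        entries.append((label, mature_id, insert, insert + config.adapter if raw is None else raw))

    frac = (config.junk_fraction + config.adapter_dimer_fraction
            + config.rfam_fraction + config.length_outlier_fraction)
    all_contaminant = frac >= 1.0 - 1e-12

    n_mature_total = 0
    for mature in truth.matures:
        if all_contaminant:
            truth.true_counts[mature.sequence] = 0
            continue
        n = int(rng.poisson(config.read_depth))
        truth.true_counts[mature.sequence] = n
        n_mature_total += n
        mid = f"{mature.hairpin_id}-{mature.arm}"
        for _ in range(n):
            seq = mature.sequence
            if config.end_shift_max > 0:
                e = config.end_shift_max
                for _attempt in range(50):
                    s5 = int(rng.integers(-e, e + 1))
                    s3 = int(rng.integers(-e, e + 1))
                    loc = mature.locus
                    if loc.strand == "+":
                        a, b = loc.start - s5, loc.end + s3
                    else:
                        a, b = loc.start - s3, loc.end + s5
                    ref = genome[loc.seq_id]
                    if 0 <= a < b <= len(ref) and 18 <= b - a <= 26:
                        span = ref[a:b]
                        seq = span if loc.strand == "+" else revcomp(span)
                        break
            if config.substitution_rate > 0 and rng.random() < config.substitution_rate:
                pos = int(rng.integers(len(seq)))
                options = [b for b in "ACGT" if b != seq[pos]]
                seq = seq[:pos] + options[int(rng.integers(3))] + seq[pos + 1:]
            emit("mature", mid, seq)

    if all_contaminant:
        n_total = int(round(config.read_depth * max(1, len(truth.matures))))
    else:
        n_total = int(round(n_mature_total / (1.0 - frac))) if n_mature_total else 0
    n_junk = int(round(config.junk_fraction * n_total))
    n_dimer = int(round(config.adapter_dimer_fraction * n_total))
    n_rfam = int(round(config.rfam_fraction * n_total))
    n_outlier = int(round(config.length_outlier_fraction * n_total))

    for i in range(n_junk):
        rule = JUNK_RULE_CYCLE[i % len(JUNK_RULE_CYCLE)]
        emit("junk", None, _make_junk_insert(rng, rule, rules))
    for _ in range(n_dimer):
        emit("adapter_dimer", None, "", raw=config.adapter)
    for _ in range(n_rfam):
        for _attempt in range(200):
            rec_id, label, ref_seq = rfam_reference[int(rng.integers(len(rfam_reference)))]
            length = int(rng.integers(18, 27))
            if length > len(ref_seq):
                continue
            start = int(rng.integers(0, len(ref_seq) - length + 1))
            insert = ref_seq[start:start + length]
            if is_junk(insert, rules)[0]:
                continue
            if classify_rfam(insert, rfam_reference) == label:
                emit("rfam", None, insert)
                break
        else:
            raise RuntimeError("could not draw an rfam contaminant read")
    outlier_lengths = (15, 16, 17, 27, 28, 29, 30)
    for i in range(n_outlier):
        emit("length_outlier", None,
             _random_seq(rng, outlier_lengths[i % len(outlier_lengths)]))

    order = rng.permutation(len(entries))
    reads = []
    rows = []
    for new_idx, old_idx in enumerate(order, start=1):
        label, mature_id, insert, raw = entries[old_idx]
        read_id = f"r{new_idx:07d}"
        reads.append((read_id, raw))
        rows.append({"read_id": read_id, "label": label,
                     "mature_id": mature_id, "insert": insert})
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR data

@dataclass
class DilutionSeries:
    """Relative template amounts (strictly decreasing) and their mean Cq."""

    amounts: np.ndarray
    cq: np.ndarray

    def __post_init__(self):
        self.amounts = np.asarray(self.amounts, dtype=float)
        self.cq = np.asarray(self.cq, dtype=float)
        if len(self.amounts) < 3:
            raise ValueError("a dilution series needs at least 3 points")
        if not np.all(np.diff(self.amounts) < 0):
            raise ValueError("amounts must be strictly decreasing")


@dataclass
class CqTruth:
    stability: dict            # gene -> "stable" | "unstable"
    target_folds: dict         # sample -> true fold change vs calibrator
    true_efficiency: float
    calibrator: str


def generate_cq(config: SynthConfig):
    """Cq matrices with planted stable/unstable genes and a known-fold target.

    Returns ``(cq, target_cq, dilutions, truth)``: ``cq`` is genes x samples,
    ``target_cq`` replicates x samples for the validation target,
    ``dilutions`` maps each candidate gene to a five-point 5-fold
    :class:`DilutionSeries` generated at ``true_efficiency``.
    """
    if config.n_cq_genes < 3:
        raise ValueError("at least 3 candidate genes are required")
    if config.n_cq_samples < 2:
        raise ValueError("at least 2 samples are required")
    rng = np.random.default_rng([config.rng_seed, 2])
    genes = [f"ref{i + 1:02d}" for i in range(config.n_cq_genes)]
    samples = [f"s{i + 1:02d}" for i in range(config.n_cq_samples)]
    stability = {g: ("stable" if i < config.n_cq_stable else "unstable")
                 for i, g in enumerate(genes)}

    base = rng.uniform(18.0, 28.0, size=config.n_cq_genes)
    cq = np.empty((config.n_cq_genes, config.n_cq_samples))
    for gi, gene in enumerate(genes):
        noise = rng.normal(0.0, config.cq_stable_sd, size=config.n_cq_samples)
        shift = 0.0
        if stability[gene] == "unstable":
            # condition-linked: every sample is a distinct condition
            shift = rng.normal(0.0, config.cq_unstable_sd, size=config.n_cq_samples)
        cq[gi] = base[gi] + shift + noise
    cq_df = pd.DataFrame(cq, index=genes, columns=samples)

    folds = {samples[0]: 1.0}
    for si in range(1, config.n_cq_samples):
        folds[samples[si]] = float(2.0 ** (((si - 1) % 5) - 2))
    base_t = float(rng.uniform(20.0, 26.0))
    target = np.empty((config.n_cq_replicates, config.n_cq_samples))
    for si, s in enumerate(samples):
        target[:, si] = (base_t - np.log2(folds[s])
                         + rng.normal(0.0, config.cq_stable_sd,
                                      size=config.n_cq_replicates))
    target_df = pd.DataFrame(target, columns=samples,
                             index=[f"rep{r + 1}" for r in range(config.n_cq_replicates)])

    amounts = np.array([1.0, 1 / 5, 1 / 25, 1 / 125, 1 / 625])
    slope = -1.0 / np.log10(1.0 + config.true_efficiency)
    dilutions = {}
    for gi, gene in enumerate(genes):
        cq_points = (base[gi] + slope * np.log10(amounts)
                     + rng.normal(0.0, config.cq_stable_sd, size=len(amounts)))
        dilutions[gene] = DilutionSeries(amounts, cq_points)

    truth = CqTruth(stability, folds, config.true_efficiency, samples[0])
    return cq_df, target_df, dilutions, truth


# ---------------------------------------------------------------------------
# writers (plain-text formats only)

def write_fasta(records: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def write_labelled_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec_id, label, seq in records:
            fh.write(f">{rec_id} {label}\n{seq}\n")


def write_fastq(reads, path) -> None:
    """Phred+33 FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_gff3(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for hp in truth.hairpins:
            loc = hp.locus
            fh.write("\t".join([
                loc.seq_id, "mothmir_synth", "pre_miRNA",
                str(loc.start + 1), str(loc.end), ".", loc.strand, ".",
                f"ID={hp.hairpin_id};arm_mode={hp.arm_mode}",
            ]) + "\n")
        for m in truth.matures:
            loc = m.locus
            fh.write("\t".join([
                loc.seq_id, "mothmir_synth", "miRNA",
                str(loc.start + 1), str(loc.end), ".", loc.strand, ".",
                f"ID={m.hairpin_id}-{m.arm};Parent={m.hairpin_id}",
            ]) + "\n")
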