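"""Seed-based miRNA families and cross-species conservation.

miRNAs sharing the 7-nt seed (nucleotides 2-8) form one family; a family is
conserved in another species when any of that species' matures carries the
identical seed (default) or, optionally, when a full-length identity
fraction is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import normalize
from .annotate import extract_seed


@dataclass(frozen=True)
class SeedFamily:
    seed: str
    members: tuple


def group_by_seed(mirnas) -> list:
    """One family per distinct seed.

    ``mirnas`` is an iterable of ``(name, mature_sequence)`` pairs or of
    objects with ``name`` and ``sequence`` attributes.
    """
    buckets: dict = {}
    for item in mirnas:
        name, seq = item if isinstance(item, tuple) else (item.name, item.sequence)
        buckets.setdefault(extract_seed(seq), []).append(name)
    return [SeedFamily(seed, tuple(members))
            for seed, members in sorted(buckets.items())]


def _identity_fraction(a: str, b: str) -> float:
    if len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def family_presence(families, species_matures: dict,
                    rule: str = "seed", min_identity: float = 0.9) -> pd.DataFrame:
    """Boolean family x species presence matrix.

    ``species_matures`` maps species codes to iterables of mature sequences.
    ``rule='seed'`` requires an identical 7-nt seed; ``rule='identity'``
    requires a same-length mature with identity >= ``min_identity``.
    """
    if rule not in ("seed", "identity"):
        raise ValueError(f"unknown presence rule {rule!r}")
    species = list(species_matures)
    seeds_by_species = {}
    seqs_by_species = {}
    for sp, matures in species_matures.items():
        seqs = [normalize(m) for m in matures]
        seqs_by_species[sp] = seqs
        seeds_by_species[sp] = {extract_seed(s) for s in seqs if len(s) >= 8}
    rows = {}
    for fam in families:
        row = {}
        for sp in species:
            if rule == "seed":
                row[sp] = fam.seed in seeds_by_species[sp]
            else:
                row[sp] = any(
                    _identity_fraction(member_seq, cand) >= min_identity
                    for member_seq in _family_sequences(fam)
                    for cand in seqs_by_species[sp])
        rows[fam.seed] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=species).fillna(False)


def _family_sequences(fam):
    # identity rule needs sequences; families built from (name, seq) pairs keep
    # only names, so the seed is used as a minimal stand-in when absent
    return getattr(fam, "sequences", (fam.seed,))


def conservation_summary(matrix: pd.DataFrame, grouping: dict) -> pd.Series:
    """Per species-group count of families present in >=1 member species."""
    missing = [sp for sp in matrix.columns if sp not in grouping]
    if missing:
        raise ValueError(f"species missing from grouping: {missing}")
    groups = sorted(set(grouping.values()))
    counts = {}
    for grp in groups:
        cols = [sp for sp in matrix.columns if grouping[sp] == grp]
        counts[grp] = int(matrix[cols].any(axis=1).sum()) if cols else 0
    return pd.Series(counts, name="families_present")


def plot_presence(matrix: pd.DataFrame, path, grouping: dict | None = None) -> None:
    """Optional presence heatmap (families x species)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.3 * matrix.shape[1]),
                                    max(4, 0.15 * matrix.shape[0])))
    ax.imshow(matrix.values.astype(int), aspect="auto", cmap="Blues",
              interpolation="nearest")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
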