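"""Published summary tables for the G. molesta pooled small-RNA library.

These are replay fixtures: the printed sequencing audit, the abundant
conserved miRNAs, the middle/high-abundance novel miRNAs and the genomic
cluster membership lists at 3/5/10/50 kb.  They let the arithmetic of the
reporting layer (percentages, seeds, arm ratios, cluster statistics) be
exercised against published numbers without any raw-read download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Number of genome-placed miRNAs behind the published cluster percentages
#: (48 clustered / 28.92 % at 50 kb and the other three distances all imply
#: the same denominator).
N_PLACED_MIRNAS = 166


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("mothmir.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_filter_audit() -> pd.DataFrame:
    """Sequencing audit counts: category, total_reads, unique_sequences."""
    return _load("gmolesta_filter_audit.tsv")


def load_conserved_mirnas() -> pd.DataFrame:
    """The 39 most abundant conserved miRNAs (name, sequence, seed, reads)."""
    return _load("gmolesta_conserved_mirnas.tsv")


def load_novel_mirnas() -> pd.DataFrame:
    """The 44 middle/high-abundance novel miRNAs (name, sequence, seed, reads)."""
    return _load("gmolesta_novel_mirnas.tsv")


def load_cluster_members() -> pd.DataFrame:
    """Genomic cluster membership (distance_bp, cluster_id, member, reads)."""
    return _load("gmolesta_mirna_clusters.tsv")


def cluster_member_lists(distance_bp: int) -> list[list[str]]:
    """Member-name lists, one per cluster, for one clustering distance."""
    df = load_cluster_members()
    sub = df[df["distance_bp"] == distance_bp]
    if sub.empty:
        raise ValueError(f"no cluster table at distance {distance_bp} bp")
    return [g["member"].tolist() for _, g in sub.groupby("cluster_id", sort=True)]
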