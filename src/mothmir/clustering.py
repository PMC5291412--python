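"""Genomic clustering of miRNA loci at fixed distance thresholds.

Loci on the same reference sequence are chained by single linkage: sorted by
start, neighbours whose end-to-start gap (floor 0 for overlaps) is within
the distance join one cluster; only chains of two or more loci are reported.
Strand is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from ._seq import round_half_up
from .novel import GenomicLocus


@dataclass(frozen=True)
class PlacedMiRNA:
    name: str
    locus: GenomicLocus
    count: float = 0.0


@dataclass
class MiRNACluster:
    cluster_id: int
    distance: int
    members: list  # PlacedMiRNA, sorted by position

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def member_names(self) -> list:
        return [m.name for m in self.members]


def cluster_loci(placed, distance: int) -> list:
    """Single-linkage clusters of loci within ``distance`` bp.

    Cluster ids are 1-based in genomic order (reference id, then start).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    by_ref: dict = {}
    for p in placed:
        by_ref.setdefault(p.locus.seq_id, []).append(p)
    clusters = []
    for seq_id in sorted(by_ref):
        group = sorted(by_ref[seq_id], key=lambda p: (p.locus.start, p.locus.end))
        chain = [group[0]]
        for p in group[1:]:
            gap = max(0, p.locus.start - chain[-1].locus.end)
            if gap <= distance:
                chain.append(p)
            else:
                if len(chain) >= 2:
                    clusters.append(chain)
                chain = [p]
        if len(chain) >= 2:
            clusters.append(chain)
    return [MiRNACluster(i + 1, distance, members)
            for i, members in enumerate(clusters)]


def cluster_stats(clusters, n_placed: int):
    """(mean cluster size, percent of placed miRNAs clustered).

    ``clusters`` may be MiRNACluster objects or plain member lists.  Mean is
    reported at 1 dp and the percentage at 2 dp (half-up); with no clusters
    the mean is None.
    """
    sizes = [c.size if isinstance(c, MiRNACluster) else len(c) for c in clusters]
    n_clustered = sum(sizes)
    if n_placed < n_clustered:
        raise ValueError("n_placed smaller than the number of clustered miRNAs")
    mean_size = round_half_up(n_clustered / len(sizes), 1) if sizes else None
    pct = round_half_up(100.0 * n_clustered / n_placed, 2) if n_placed else 0.0
    return mean_size, pct


def clusters_nested(small_clusters, big_clusters) -> bool:
    """True when every small-distance cluster lies inside a larger-distance one."""
    big_sets = [set(c.member_names if isinstance(c, MiRNACluster) else c)
                for c in big_clusters]
    for c in small_clusters:
        members = set(c.member_names if isinstance(c, MiRNACluster) else c)
        if not any(members <= b for b in big_sets):
            return False
    return True


def cluster_coexpression(cluster, profiles=None):
    """Within-cluster expression concordance.

    With ``profiles`` (mapping member name -> per-condition expression
    vector), returns the list of pairwise Spearman rank correlations
    (None for constant profiles).  Without profiles, returns the max/min
    ratio of the members' library counts (library mode).
    """
    members = cluster.members if isinstance(cluster, MiRNACluster) else cluster
    if profiles is None:
        counts = [m.count for m in members]
        if len(counts) < 2 or min(counts) <= 0:
            raise ValueError("library mode needs >=2 members with positive counts")
        return max(counts) / min(counts)
    names = [m.name if isinstance(m, PlacedMiRNA) else m for m in members]
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = profiles[names[i]], profiles[names[j]]
            if len(set(a)) == 1 or len(set(b)) == 1:
                out.append((names[i], names[j], None))
            else:
                rs = stats.spearmanr(a, b).statistic
                out.append((names[i], names[j], float(rs)))
    return out


def clusters_to_frame(clusters):
    import pandas as pd

    rows = []
    for c in clusters:
        for m in c.members:
            rows.append({"cluster_id": c.cluster_id, "distance": c.distance,
                         "member": m.name, "reads": m.count,
                         "seq_id": m.locus.seq_id, "start": m.locus.start,
                         "end": m.locus.end})
    return pd.DataFrame(rows)
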