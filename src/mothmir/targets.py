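"""miRNA target prediction in 3'UTRs and pathway enrichment.

Two independent filters emulate the classic dual-algorithm protocol: a
seed-site context-like score kept at percentile >= 50 within each miRNA's
site pool, and a gapless duplex energy kept at <= -10 kcal/mol; the final
prediction is the gene-level intersection.  The scoring functions are
deliberately simple stand-ins (site-type weight + local AU content; pair-sum
duplex energy): they preserve the decision logic, not the trained models.
Pathway over-representation uses the one-sided hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from ._seq import normalize, pair_energy, revcomp

SITE_TYPE_WEIGHTS = {"8mer": 3.0, "7mer-m8": 2.0, "7mer-A1": 1.5, "6mer": 1.0}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TargetSite:
    mirna: str
    transcript: str
    start: int            # 0-based start of the 6mer core in the UTR
    site_type: str
    energy: float = 0.0
    score: float = 0.0
    percentile: float = 0.0


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    significant: bool


def find_seed_sites(mirna_name: str, mature: str, transcript: str, utr: str) -> list:
    """All seed-complementary sites of a miRNA in one 3'UTR.

    The 6mer core is the reverse complement of miRNA nucleotides 2-7;
    sites are typed 8mer / 7mer-m8 / 7mer-A1 / 6mer by pairing of miRNA
    position 8 and by an A opposite position 1.
    """
    mature = normalize(mature)
    utr = normalize(utr)
    if len(mature) < 8 or len(utr) < 7:
        return []
    core = revcomp(mature[1:7])
    sites = []
    pos = utr.find(core)
    while pos != -1:
        m8 = pos >= 1 and utr[pos - 1] == _COMP.get(mature[7], "?")
        a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        site_type = ("8mer" if m8 and a1 else
                     "7mer-m8" if m8 else
                     "7mer-A1" if a1 else "6mer")
        sites.append(TargetSite(mirna_name, transcript, pos, site_type))
        pos = utr.find(core, pos + 1)
    return sites


def duplex_energy(mature: str, window: str) -> float:
    """Energy of the best gapless antiparallel duplex (kcal/mol).

    At each offset, complementary (and GU) positions contribute their pair
    energies; the minimum over offsets is returned.
    """
    mature = normalize(mature)
    window = normalize(window)
    lm, lw = len(mature), len(window)
    best = 0.0
    for shift in range(-lm + 1, lw):
        total = 0.0
        for k in range(lm):
            w = shift + k
            if 0 <= w < lw:
                total += pair_energy(mature[lm - 1 - k], window[w])
        best = min(best, total)
    return best


def site_window(site: TargetSite, utr: str, mature_len: int) -> str:
    """UTR segment covering the site plus one miRNA length on each side."""
    lo = max(0, site.start - mature_len)
    hi = min(len(utr), site.start + 6 + mature_len)
    return utr[lo:hi]


def context_like_score(site: TargetSite, utr: str, flank: int = 30) -> float:
    """Type weight plus local AU fraction in +/-``flank`` nt around the site."""
    lo = max(0, site.start - flank)
    hi = min(len(utr), site.start + 6 + flank)
    local = utr[lo:hi]
    au = (local.count("A") + local.count("T")) / len(local) if local else 0.0
    return SITE_TYPE_WEIGHTS[site.site_type] + au


def assign_percentiles(sites) -> None:
    """Percentile of each site's score within its miRNA's site pool (0-100).

    The percentile of a site is 100 x (number of pool sites with score <=
    its score) / pool size, so a single site scores 100 and the lower of two
    distinct scores 50.
    """
    pools: dict = {}
    for s in sites:
        pools.setdefault(s.mirna, []).append(s)
    for pool in pools.values():
        scores = sorted(s.score for s in pool)
        n = len(pool)
        for s in pool:
            rank = sum(1 for x in scores if x <= s.score)
            s.percentile = 100.0 * rank / n


def predict_targets(mirnas: dict, utrs: dict,
                    min_percentile: float = 50.0,
                    max_energy: float = -10.0):
    """Run the dual-filter-and-intersect prediction.

    ``mirnas`` maps miRNA name -> mature sequence; ``utrs`` maps transcript
    id -> 3'UTR sequence.  Returns ``(sites, final_edges)`` where ``sites``
    is the fully annotated site list and ``final_edges`` the set of
    (mirna, transcript) pairs recommended by both filters.
    """
    sites = []
    for name, mature in mirnas.items():
        for tid, utr in utrs.items():
            for site in find_seed_sites(name, mature, tid, utr):
                site.score = context_like_score(site, normalize(utr))
                site.energy = duplex_energy(mature, site_window(site, normalize(utr),
                                                                len(mature)))
                sites.append(site)
    assign_percentiles(sites)
    survivors_a = {(s.mirna, s.transcript) for s in sites
                   if s.percentile >= min_percentile}
    survivors_b = {(s.mirna, s.transcript) for s in sites
                   if s.energy <= max_energy}
    return sites, intersect_predictions(survivors_a, survivors_b)


def intersect_predictions(filter_a, filter_b) -> set:
    """Gene-level intersection of the two filters' survivor sets."""
    return set(filter_a) & set(filter_b)


def fisher_enrichment(target_genes, pathway_map: dict, universe,
                      alpha: float = 0.05, fdr: bool = False) -> list:
    """One-sided over-representation test per pathway.

    ``pathway_map`` maps pathway id -> gene collection.  p is the upper
    hypergeometric tail P(X >= k) drawing ``n`` query genes from a universe
    of ``N`` containing ``K`` pathway genes.  Significance at p <= ``alpha``
    (no multiple-testing correction by default; ``fdr=True`` applies
    Benjamini-Hochberg).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    targets_in = set(target_genes) & universe
    n = len(targets_in)
    N = len(universe)
    results = []
    for pathway, genes in pathway_map.items():
        pw = set(genes) & universe
        K = len(pw)
        k = len(pw & targets_in)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(0.0, p))
        results.append([pathway, k, K, n, N, p])
    results.sort(key=lambda r: (r[5], r[0]))
    if fdr:
        m = len(results)
        adjusted = []
        running = 1.0
        for rank_from_last, row in enumerate(reversed(results)):
            rank = m - rank_from_last
            running = min(running, row[5] * m / rank)
            adjusted.append(running)
        for row, q in zip(results, reversed(adjusted)):
            row[5] = q
    return [EnrichmentResult(p_id, k, K, n, N, p, p <= alpha)
            for p_id, k, K, n, N, p in results]


def load_pathway_map(path) -> dict:
    """Two-column TSV (gene, pathway) -> {pathway: set of genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "pathway"])
    out: dict = {}
    for gene, pathway in df.itertuples(index=False):
        out.setdefault(pathway, set()).add(gene)
    return out


def enrichment_to_frame(results):
    return pd.DataFrame([{
        "pathway": r.pathway, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
        "p_value": r.p_value, "significant": r.significant,
    } for r in results])
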