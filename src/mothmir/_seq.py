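"""Shared sequence and numeric helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

DNA_ALPHABET = set("ACGTN")

#: Stacking-free pair energies (kcal/mol) used by the folder and the duplex
#: scorer.  GU wobble pairs are allowed.  Sequences are stored as DNA, so T
#: plays the role of U.
PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to the DNA alphabet."""
    return seq.upper().replace("U", "T")


def check_dna(seq: str, allow_n: bool = True) -> str:
    seq = normalize(seq)
    allowed = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    return normalize(seq).translate(_COMPLEMENT)[::-1]


def pair_energy(a: str, b: str) -> float:
    """Energy of pairing bases *a* and *b*; 0.0 when they cannot pair."""
    return PAIR_ENERGY.get((a, b), 0.0)


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIR_ENERGY


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention used in the printed summary tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def gc_fraction(seq: str) -> float:
    seq = normalize(seq)
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
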