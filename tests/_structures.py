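"""Hand-built precursor candidates that violate exactly one hairpin criterion.

Structures are written directly in dot-bracket form (the criteria are
folder-agnostic and accept external folds), with energies summed from the
same pair-energy model the package uses.  Under that model two criteria have
no single-violation witness among foldable structures: a free energy above
-15 kcal/mol requires fewer than 16 stem pairs (every pair contributes at
least -1), and a one-sided mature bulge above 8 nt necessarily carries more
than 4 biased and more than 7 total mature errors.  Criterion 3 is therefore
exercised with an externally supplied energy and criterion 6 jointly with
criteria 7 and 9.
"""

from mothmir.novel import PrecursorCandidate, pair_table
from mothmir._seq import pair_energy


def _energy(seq, structure):
    partner = pair_table(structure)
    return sum(pair_energy(seq[i], seq[j])
               for i, j in enumerate(partner) if j is not None and i < j)


def make(seq, structure, mature_offset, mature_length, energy=None):
    return PrecursorCandidate(
        sequence=seq, structure=structure,
        energy=_energy(seq, structure) if energy is None else energy,
        mature_offset=mature_offset, mature_length=mature_length)


def perfect_hairpin(stem=30, loop=10, mature_len=22):
    seq = "G" * stem + "A" * loop + "C" * stem
    structure = "(" * stem + "." * loop + ")" * stem
    return make(seq, structure, 0, mature_len)


def violating_candidates():
    """{criterion index: candidate violating that criterion and only it}.

    Criterion 6 is absent (see module docstring); :func:`bulge9_candidate`
    returns its joint witness.
    """
    cases = {}

    # (1) 13-nt one-sided stem bulge outside the mature span
    seq = "G" * 30 + "A" * 10 + "C" * 10 + "A" * 13 + "C" * 20
    st = "(" * 30 + "." * 10 + ")" * 10 + "." * 13 + ")" * 20
    cases[1] = make(seq, st, 0, 22)

    # (2) 15 stem pairs (loop widened so the span still reaches 50)
    seq = "G" * 15 + "A" * 20 + "C" * 15
    st = "(" * 15 + "." * 20 + ")" * 15
    cases[2] = make(seq, st, 0, 18)

    # (3) energy above -15, structure otherwise conforming (external fold)
    good = perfect_hairpin()
    cases[3] = make(good.sequence, good.structure, 0, 22, energy=-10.0)

    # (4) span 42 < 50 with 16 pairs and a legal loop
    seq = "G" * 16 + "A" * 10 + "C" * 16
    st = "(" * 16 + "." * 10 + ")" * 16
    cases[4] = make(seq, st, 0, 18)

    # (5) 21-nt terminal loop
    seq = "G" * 30 + "A" * 21 + "C" * 30
    st = "(" * 30 + "." * 21 + ")" * 30
    cases[5] = make(seq, st, 0, 22)

    # (7) one 5-nt one-sided bulge inside the mature (5 biased errors > 4)
    seq = "G" * 10 + "A" * 5 + "G" * 20 + "A" * 10 + "C" * 30
    st = "(" * 10 + "." * 5 + "(" * 20 + "." * 10 + ")" * 30
    cases[7] = make(seq, st, 0, 22)

    # (8) three 1-nt one-sided bulges inside the mature
    seq = ("G" * 5 + "A") * 3 + "G" * 15 + "A" * 10 + "C" * 30
    st = ("(" * 5 + ".") * 3 + "(" * 15 + "." * 10 + ")" * 30
    cases[8] = make(seq, st, 0, 22)

    # (9) 8 unpaired mature positions via two symmetric 4-nt internal loops
    seq = ("G" * 6 + "A" * 4 + "G" * 6 + "A" * 4 + "G" * 8
           + "A" * 10 + "C" * 8 + "A" * 4 + "C" * 6 + "A" * 4 + "C" * 6)
    st = ("(" * 6 + "." * 4 + "(" * 6 + "." * 4 + "(" * 8
          + "." * 10 + ")" * 8 + "." * 4 + ")" * 6 + "." * 4 + ")" * 6)
    cases[9] = make(seq, st, 0, 22)

    # (10) 11 paired mature positions (7 unpaired, all two-sided)
    seq = ("G" * 4 + "A" * 4 + "G" * 4 + "A" * 3 + "G" * 3 + "G" * 10
           + "A" * 10
           + "C" * 10 + "C" * 3 + "A" * 3 + "C" * 4 + "A" * 4 + "C" * 4)
    st = ("(" * 4 + "." * 4 + "(" * 4 + "." * 3 + "(" * 3 + "(" * 10
          + "." * 10
          + ")" * 10 + ")" * 3 + "." * 3 + ")" * 4 + "." * 4 + ")" * 4)
    cases[10] = make(seq, st, 0, 18)

    # (11) 5 of 20 mature nt dangle outside the stem (75 % < 80 %)
    seq = "A" * 5 + "G" * 25 + "A" * 10 + "C" * 25
    st = "." * 5 + "(" * 25 + "." * 10 + ")" * 25
    cases[11] = make(seq, st, 0, 20)

    return cases


def bulge9_candidate():
    """9-nt one-sided mature bulge: violates criteria 6, 7 and 9 jointly."""
    seq = "G" * 8 + "A" * 9 + "G" * 22 + "A" * 10 + "C" * 30
    st = "(" * 8 + "." * 9 + "(" * 22 + "." * 10 + ")" * 30
    return make(seq, st, 0, 22)
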