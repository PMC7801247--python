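"""Universal genetic-code tables used by the divergence estimator and the simulator.

Everything here is derived once, at import time, from Biopython's standard
codon table: per-codon synonymous site fractions (Nei-Gojobori site counting),
synonymous/nonsynonymous single-nucleotide neighbor sets, fourfold-degenerate
family membership, and path-averaged difference counts for codon pairs.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")

CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_AA))


def is_transversion(a: str, b: str) -> bool:
    return (a in PURINES) != (b in PURINES)


def _neighbors(codon: str, pos: int):
    """All single-nucleotide variants of ``codon`` at ``pos``."""
    for nt in NUCLEOTIDES:
        if nt != codon[pos]:
            yield codon[:pos] + nt + codon[pos + 1 :]


def _build_site_tables():
    syn_sites = {}          # codon -> S contribution (sum over 3 positions of m/3)
    syn_alt = {}            # (codon, pos) -> tuple of synonymous alternative codons
    nonsyn_alt = {}         # (codon, pos) -> tuple of nonsynonymous sense alternatives
    for codon in SENSE_CODONS:
        aa = CODON_AA[codon]
        total = 0.0
        for pos in range(3):
            syn = tuple(
                n for n in _neighbors(codon, pos)
                if n not in STOP_CODONS and CODON_AA[n] == aa
            )
            non = tuple(
                n for n in _neighbors(codon, pos)
                if n not in STOP_CODONS and CODON_AA[n] != aa
            )
            syn_alt[(codon, pos)] = syn
            nonsyn_alt[(codon, pos)] = non
            total += len(syn) / 3.0
        syn_sites[codon] = total
    return syn_sites, syn_alt, nonsyn_alt


SYN_SITES, SYN_ALTERNATIVES, NONSYN_ALTERNATIVES = _build_site_tables()

# A codon sits in a fourfold-degenerate family when every third-position
# variant of its first two nucleotides encodes the same amino acid.
FOURFOLD_CODONS: frozenset[str] = frozenset(
    c for c in SENSE_CODONS
    if len({CODON_AA.get(c[:2] + nt) for nt in NUCLEOTIDES}) == 1
    and all(c[:2] + nt not in STOP_CODONS for nt in NUCLEOTIDES)
)


@lru_cache(maxsize=None)
def pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts (Sd, Nd) for one codon pair.

    Codons differing at d positions are resolved by averaging over all d!
    orderings of the single-nucleotide steps; orderings passing through a stop
    codon are discarded (if every ordering is blocked, all are used).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_AA[current] == CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every route crosses a stop codon; fall back to all routes
        for order in itertools.permutations(diff_pos):
            current = codon_a
            sd = nd = 0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                aa_cur = CODON_AA.get(current)
                aa_nxt = CODON_AA.get(nxt)
                if aa_cur is not None and aa_cur == aa_nxt:
                    sd += 1
                else:
                    nd += 1
                current = nxt
            paths.append((sd, nd))
    n = len(paths)
    return sum(p[0] for p in paths) / n, sum(p[1] for p in paths) / n
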