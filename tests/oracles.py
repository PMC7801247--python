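"""Independent brute-force oracles used to validate the fast implementations.

These are written from first principles against Biopython's translation
machinery (never against the package's own codon tables): literal site-
fraction sums for synonymous site counting, explicit enumeration of every
substitution path for difference counting, and exhaustive chain enumeration
for colinearity.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from Bio.Seq import Seq

NTS = "ACGT"


@lru_cache(maxsize=None)
def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_stop(codon: str) -> bool:
    return _translate(codon) == "*"


def syn_site_fraction(codon: str) -> float:
    """Sum over the 3 positions of (synonymous neighbor changes) / 3."""
    aa = _translate(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for nt in NTS:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if not _is_stop(mutant) and _translate(mutant) == aa:
                syn += 1
        total += syn / 3.0
    return total


def codon_pair_differences(a: str, b: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over all stop-free substitution orderings."""
    positions = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(positions):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _is_stop(nxt):
                ok = False
                break
            if _translate(cur) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        for order in itertools.permutations(positions):
            cur = a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if _translate(cur) == _translate(nxt) and not _is_stop(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    n = len(results)
    return (sum(r[0] for r in results) / n, sum(r[1] for r in results) / n)


def ng86_oracle(codons_a: list[str], codons_b: list[str]) -> dict:
    """Brute-force Nei-Gojobori quantities for a gap-free codon alignment."""
    S = 0.0
    Sd = 0.0
    Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        S += (syn_site_fraction(ca) + syn_site_fraction(cb)) / 2.0
        if ca != cb:
            sd, nd = codon_pair_differences(ca, cb)
            Sd += sd
            Nd += nd
    N = 3.0 * len(codons_a) - S
    pS = Sd / S if S else float("nan")
    pN = Nd / N if N else float("nan")

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3)

    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "ks": jc(pS) if S else None, "ka": jc(pN) if N else None}


def max_chain_oracle(points: list[tuple[int, int]], max_gap: int) -> int:
    """Exhaustive longest gap-capped monotone chain, both orientations.

    Recursively extends every chain; feasible for ~a dozen points.
    """

    def ok_step(p, q, sign):
        dx = q[0] - p[0]
        dy = sign * (q[1] - p[1])
        return 0 < dx <= max_gap + 1 and 0 < dy <= max_gap + 1

    def extend(last, remaining, sign):
        best = 0
        for i, q in enumerate(remaining):
            if last is None or ok_step(last, q, sign):
                best = max(best, 1 + extend(q, remaining[i + 1 :], sign))
        return best

    best = 0
    for sign in (1, -1):
        pts = sorted(points, key=lambda p: (p[0], sign * p[1]))
        best = max(best, extend(None, pts, sign))
    return best
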