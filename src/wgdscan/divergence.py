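"""Codon-aware divergence between homologous coding sequences.

The estimator is the Nei-Gojobori (1986) counting method: synonymous site
opportunities counted as fractions of immediate-neighbor changes, differences
between multi-hit codons averaged over all shortest substitution paths that
avoid stop codons, and a Jukes-Cantor correction for multiple hits:

    Ks = -(3/4) * ln(1 - (4/3) * pS),   pS = Sd / S

with the same form for Ka. 4Dtv — the transversion rate at fourfold-degenerate
third codon positions — is reported uncorrected as an independent divergence
proxy. Pairs whose pS reaches the Jukes-Cantor singularity (pS >= 3/4) are
flagged saturated and excluded from peak fitting downstream.

Codon alignments are obtained by global protein alignment (BLOSUM62, affine
gaps) back-translated onto the CDS; columns with a gap, ambiguity, or stop in
either sequence are masked out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from statistics import median

from Bio import Align
from Bio.Align import substitution_matrices

from ._codon import (
    CODON_AA,
    FOURFOLD_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_SITES,
    is_transversion,
    pair_differences,
)
from .genome import SequenceStore

__all__ = [
    "CodonAlignment",
    "DivergenceEstimate",
    "align_codons",
    "ng86",
    "four_dtv",
    "block_divergence",
    "pair_divergence",
]

#: minimum retained codon columns for a pair to be considered alignable
MIN_CODONS = 30

_SENSE = frozenset(SENSE_CODONS)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free paired codon columns retained after masking."""

    gene_a: str
    gene_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]
    n_masked: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    @property
    def unalignable(self) -> bool:
        return self.n_codons < MIN_CODONS


@dataclass(frozen=True)
class DivergenceEstimate:
    """Per-pair NG86 quantities plus the 4Dtv proxy.

    ``S``/``N`` are site counts averaged over both sequences; ``Sd``/``Nd``
    are path-averaged difference counts. ``ks``/``ka`` are None when undefined
    (saturation or zero opportunity).
    """

    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float | None
    ka: float | None
    fourdtv: float | None
    n_4d_sites: int
    n_codons: int
    saturated: bool


def _protein_of(cds: str) -> str:
    return "".join(CODON_AA.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3))


def align_codons(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b") -> CodonAlignment:
    """Protein-guided codon alignment of two CDS.

    Proteins are globally aligned and the alignment is back-translated; any
    column with a gap, an ambiguous codon, or a stop in either sequence is
    masked. Alignments retaining fewer than ``MIN_CODONS`` columns are flagged
    via :attr:`CodonAlignment.unalignable`.
    """
    prot_a = _protein_of(cds_a)
    prot_b = _protein_of(cds_b)
    alignment = _ALIGNER.align(prot_a, prot_b)[0]
    idx_a, idx_b = alignment.indices  # -1 marks a gap
    cod_a: list[str] = []
    cod_b: list[str] = []
    masked = 0
    for ia, ib in zip(idx_a, idx_b):
        if ia < 0 or ib < 0:
            masked += 1
            continue
        ca = cds_a[3 * ia : 3 * ia + 3]
        cb = cds_b[3 * ib : 3 * ib + 3]
        if ca not in _SENSE or cb not in _SENSE:
            masked += 1
            continue
        cod_a.append(ca)
        cod_b.append(cb)
    return CodonAlignment(gene_a, gene_b, tuple(cod_a), tuple(cod_b), n_masked=masked)


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86(alignment: CodonAlignment) -> DivergenceEstimate:
    """Nei-Gojobori Ka/Ks over a gap-free codon alignment."""
    S = 0.0
    Sd = 0.0
    Nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        S += 0.5 * (SYN_SITES[ca] + SYN_SITES[cb])
        if ca != cb:
            sd, nd = pair_differences(ca, cb)
            Sd += sd
            Nd += nd
    total_sites = 3.0 * alignment.n_codons
    N = total_sites - S
    pS = Sd / S if S > 0 else float("nan")
    pN = Nd / N if N > 0 else float("nan")
    ks = _jc_correct(pS) if S > 0 else None
    ka = _jc_correct(pN) if N > 0 else None
    saturated = bool(S > 0 and pS >= 0.75) or S == 0
    fourdtv, n4d = four_dtv(alignment)
    return DivergenceEstimate(
        gene_a=alignment.gene_a,
        gene_b=alignment.gene_b,
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, ks=ks, ka=ka,
        fourdtv=fourdtv, n_4d_sites=n4d,
        n_codons=alignment.n_codons, saturated=saturated,
    )


def four_dtv(alignment: CodonAlignment) -> tuple[float | None, int]:
    """Transversion rate at shared fourfold-degenerate third positions.

    A column counts as a 4D site only when both codons lie in fourfold
    families and encode the same amino acid. Returns (rate, n_sites);
    rate is None when no 4D site is shared.
    """
    n4d = 0
    tv = 0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        if ca in FOURFOLD_CODONS and cb in FOURFOLD_CODONS and CODON_AA[ca] == CODON_AA[cb]:
            n4d += 1
            if ca[2] != cb[2] and is_transversion(ca[2], cb[2]):
                tv += 1
    if n4d == 0:
        return None, 0
    return tv / n4d, n4d


def pair_divergence(gene_a: str, gene_b: str, store: SequenceStore) -> DivergenceEstimate | None:
    """Align and estimate divergence for one gene pair; None if unalignable."""
    if gene_a not in store or gene_b not in store:
        return None
    aln = align_codons(store.cds(gene_a), store.cds(gene_b), gene_a, gene_b)
    if aln.unalignable:
        return None
    return ng86(aln)


def block_divergence(block, store: SequenceStore, cache: dict | None = None):
    """Attach median Ks and median 4Dtv over a block's usable pairs.

    Saturated or unalignable pairs are excluded; with zero usable pairs the
    medians stay undefined. Returns a new block (blocks are immutable).
    A ``cache`` dict keyed by (gene_a, gene_b) avoids re-aligning pairs shared
    across calls.
    """
    ks_values: list[float] = []
    tv_values: list[float] = []
    for pair in block.pairs:
        key = (pair.gene_a, pair.gene_b)
        if cache is not None and key in cache:
            est = cache[key]
        else:
            est = pair_divergence(pair.gene_a, pair.gene_b, store)
            if cache is not None:
                cache[key] = est
        if est is None or est.saturated or est.ks is None:
            continue
        ks_values.append(est.ks)
        if est.fourdtv is not None:
            tv_values.append(est.fourdtv)
    return replace(
        block,
        median_ks=median(ks_values) if ks_values else None,
        median_4dtv=median(tv_values) if tv_values else None,
    )
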