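"""Homologous gene pairs: internal protein search, tabular import, ranking.

Hits seed both the dot plot (colored best / second-best / other, matching the
classic homologous-dot-plot convention) and colinearity inference. Two entry
points produce identical ``HitTable`` semantics: an internal protein aligner
(shared-k-mer prefilter then global BLOSUM62 alignment) for synthetic or
desk-scale runs, and a 12-column outfmt-6 tabular reader for precomputed
searches. High-copy gene families (> ``max_copies`` distinct partners) are
removed before colinearity, as repetitive families fake synteny signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome import SequenceStore

__all__ = [
    "HomologyHit",
    "HitTable",
    "score_pairs",
    "read_hits_tabular",
    "rank_hits",
    "filter_high_copy",
]

OUTFMT6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

# Karlin-Altschul parameters for gapped BLOSUM62 (open 10 / extend 0.5),
# used only to attach an E-value-like significance to internal scores.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    score: float
    identity: float
    significance: float
    rank_label: str = "other"  # best | second | other


@dataclass
class HitTable:
    """Deduplicated homology hits (one record per ordered query/subject pair)."""

    hits: list[HomologyHit] = field(default_factory=list)
    provenance: str = "internal"

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for h in self.hits:
            out.add(h.query)
            out.add(h.subject)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(h.query, h.subject, h.score, h.identity, h.significance, h.rank_label)
             for h in self.hits],
            columns=["query", "subject", "score", "identity", "significance", "rank_label"],
        )


def _dedup(hits: list[HomologyHit], provenance: str) -> HitTable:
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        if h.query == h.subject:
            continue
        key = (h.query, h.subject)
        if key not in best or h.score > best[key].score:
            best[key] = h
    return HitTable(hits=list(best.values()), provenance=provenance)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def _evalue(score: float, len_a: int, len_b: int) -> float:
    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
    return len_a * len_b * 2.0 ** (-min(bits, 1000.0))


def _kmer_index(store: SequenceStore, k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for gid in store.ids():
        prot = store.protein(gid)
        for i in range(len(prot) - k + 1):
            index.setdefault(prot[i : i + k], set()).add(gid)
    return index


def score_pairs(
    store_a: SequenceStore,
    store_b: SequenceStore,
    kmer_prefilter_len: int = 6,
    min_score: float = 50.0,
    max_hits_per_query: int = 5,
) -> HitTable:
    """Protein-level homology search between (or within) sequence stores.

    Candidates must share at least one k-mer; survivors are scored by global
    BLOSUM62 alignment with affine gaps, and the top ``max_hits_per_query``
    per query are retained. For self-comparison (``store_a is store_b``) the
    table is symmetric: hit (a, b) implies (b, a).
    """
    if len(store_a) == 0 or len(store_b) == 0:
        raise ValueError("sequence stores must be non-empty")
    aligner = _make_aligner()
    self_mode = store_a is store_b
    index = _kmer_index(store_b, kmer_prefilter_len)

    scored: dict[tuple[str, str], float] = {}
    for query in store_a.ids():
        prot_q = store_a.protein(query)
        candidates: set[str] = set()
        for i in range(len(prot_q) - kmer_prefilter_len + 1):
            candidates |= index.get(prot_q[i : i + kmer_prefilter_len], set())
        candidates.discard(query)
        for subject in candidates:
            key = (min(query, subject), max(query, subject)) if self_mode else (query, subject)
            if key in scored:
                continue
            score = aligner.score(prot_q, store_b.protein(subject))
            if score >= min_score:
                scored[key] = score

    per_query: dict[str, list[tuple[str, float]]] = {}
    for (a, b), score in scored.items():
        per_query.setdefault(a, []).append((b, score))
        if self_mode:
            per_query.setdefault(b, []).append((a, score))
    identity_cache: dict[tuple[str, str], float] = {}

    def identity_of(query: str, subject: str) -> float:
        key = (min(query, subject), max(query, subject))
        if key not in identity_cache:
            prot_q = store_a.protein(query)
            prot_s = (store_a if self_mode else store_b).protein(subject)
            counts = aligner.align(prot_q, prot_s)[0].counts()
            aligned = counts.identities + counts.mismatches
            identity_cache[key] = counts.identities / aligned if aligned else 0.0
        return identity_cache[key]

    hits: list[HomologyHit] = []
    for query, subs in per_query.items():
        subs.sort(key=lambda t: (-t[1], t[0]))
        for subject, score in subs[:max_hits_per_query]:
            hits.append(HomologyHit(
                query=query, subject=subject, score=score,
                identity=identity_of(query, subject),
                significance=_evalue(
                    score, len(store_a.protein(query)),
                    len((store_a if self_mode else store_b).protein(subject))),
            ))
    return _dedup(hits, provenance="internal")


def read_hits_tabular(path) -> HitTable:
    """Read a 12-column outfmt-6 tabular hit file.

    Duplicate (query, subject) rows keep the highest bitscore; self-hits are
    dropped. A malformed row is a hard error naming its line number.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{line_no}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: malformed numeric field: {exc}") from None
            hits.append(HomologyHit(
                query=fields[0], subject=fields[1], score=bitscore,
                identity=pident / 100.0, significance=evalue,
            ))
    return _dedup(hits, provenance="tabular")


def rank_hits(hits: HitTable) -> HitTable:
    """Label each query's hits best / second / other by descending score.

    Ties break by smaller significance, then lexicographic subject id. The
    operation is idempotent.
    """
    per_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        per_query.setdefault(h.query, []).append(h)
    out: list[HomologyHit] = []
    for query in per_query:
        ordered = sorted(per_query[query],
                         key=lambda h: (-h.score, h.significance, h.subject))
        for i, h in enumerate(ordered):
            label = "best" if i == 0 else ("second" if i == 1 else "other")
            out.append(replace(h, rank_label=label))
    return HitTable(hits=out, provenance=hits.provenance)


def filter_high_copy(
    hits: HitTable,
    max_copies: int = 30,
    significance_cutoff: float = 1e-5,
) -> HitTable:
    """Remove hits touching genes from families with more than ``max_copies`` members.

    A gene's copy number is the number of distinct partners it hits at or
    below the significance cutoff — family size, not alignment-row count.
    """
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    partners: dict[str, set[str]] = {}
    for h in hits:
        if h.significance <= significance_cutoff:
            partners.setdefault(h.query, set()).add(h.subject)
            partners.setdefault(h.subject, set()).add(h.query)
    high = {g for g, p in partners.items() if len(p) > max_copies}
    kept = [h for h in hits if h.query not in high and h.subject not in high]
    return HitTable(hits=kept, provenance=hits.provenance)
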