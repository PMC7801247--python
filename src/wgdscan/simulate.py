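"""Gene-order and sequence evolution simulator with known polyploidy truth.

The generator produces a genome that has lived through a specified history of
whole-genome duplications (WGDs): an ancestral gene order on several
scaffolds, one or more WGD events at chosen synonymous divergences (target
Ks), gene-wise independent fractionation of the extra copies, inversions and
translocations, and scaffold fragmentation. Alongside the genome it returns
the full ground truth (true paralog pairs per event, their target Ks, the
ancestral-gene map, and the rearrangement log) so every downstream stage can
be tested for parameter recovery.

Divergence model
----------------
Divergence is parameterized directly in Ks units. Events are laid out on a
per-lineage timeline: a pair duplicated at an event with target Ks ``K``
accumulates ``K/2`` on each side after the split, so its expected pairwise
divergence is ``K``. Substitutions are placed per site as a Poisson process
with multiple hits allowed: each codon position with ``m`` synonymous
single-nucleotide alternatives performs a uniform-jump walk over its ``m+1``
synonymous states, with the Poisson rate chosen so the expected
Nei-Gojobori/Jukes-Cantor *corrected* Ks of a pair equals its target (for a
fourfold-degenerate site this is exactly the Jukes-Cantor process at rate Ks
per synonymous site). Nonsynonymous noise is added the same way at rate
``omega * Ks`` per nonsynonymous site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._codon import NONSYN_ALTERNATIVES, SENSE_CODONS, SYN_ALTERNATIVES
from .genome import Gene, GenomeAnnotation, SequenceStore

__all__ = [
    "WGDSpec",
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_species_pair",
    "apply_rearrangements",
    "fragment_scaffolds",
    "shuffle_annotation",
]

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

# per (codon index, position): synonymous / nonsynonymous alternative codon indices
_SYN_ALT_IDX: dict[tuple[int, int], tuple[int, ...]] = {}
_NON_ALT_IDX: dict[tuple[int, int], tuple[int, ...]] = {}
_M_SYN = np.zeros((len(SENSE_CODONS), 3), dtype=np.int64)
_M_NON = np.zeros((len(SENSE_CODONS), 3), dtype=np.int64)
for _c, _i in _CODON_INDEX.items():
    for _pos in range(3):
        _syn = tuple(_CODON_INDEX[a] for a in SYN_ALTERNATIVES[(_c, _pos)])
        _non = tuple(_CODON_INDEX[a] for a in NONSYN_ALTERNATIVES[(_c, _pos)])
        _SYN_ALT_IDX[(_i, _pos)] = _syn
        _NON_ALT_IDX[(_i, _pos)] = _non
        _M_SYN[_i, _pos] = len(_syn)
        _M_NON[_i, _pos] = len(_non)


@dataclass(frozen=True)
class WGDSpec:
    """One whole-genome duplication: ploidy multiplier, divergence, retention."""

    target_ks: float
    retention: float
    ploidy: int = 2

    def __post_init__(self):
        if self.target_ks < 0:
            raise ValueError("target_ks must be >= 0")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must lie in (0, 1]")
        if self.ploidy not in (2, 3):
            raise ValueError("ploidy must be 2 or 3")


@dataclass
class SimConfig:
    """Configuration of a simulated genome history.

    ``events`` are ordered oldest-first with strictly decreasing target Ks.
    ``terminal_ks`` is the per-lineage divergence applied after the youngest
    event; by default it is half the youngest target, which is exactly the
    amount that realizes that event's pairwise Ks target.
    """

    n_ancestral_genes: int = 1000
    n_scaffolds: int = 5
    events: tuple[WGDSpec, ...] = ()
    n_inversions: int = 0
    n_translocations: int = 0
    n_fragments: int | None = None
    omega: float = 0.1
    terminal_ks: float | None = None
    min_codons: int = 150
    max_codons: int = 450
    seed: int = 0

    def __post_init__(self):
        self.events = tuple(self.events)
        ks = [e.target_ks for e in self.events]
        if any(a <= b for a, b in zip(ks, ks[1:])):
            raise ValueError("events must be ordered oldest-first with strictly decreasing target_ks")
        if self.n_ancestral_genes < 1 or self.n_scaffolds < 1:
            raise ValueError("need at least one gene and one scaffold")
        if self.n_scaffolds > self.n_ancestral_genes:
            raise ValueError("more scaffolds than genes")


@dataclass
class SimTruth:
    """Ground truth of a simulated genome."""

    event_pairs: list[list[tuple[str, str]]]  # oldest-first, per event
    pair_target_ks: dict[tuple[str, str], float]
    ancestor_map: dict[str, list[str]]  # ancestral id -> extant copies
    rearrangements: list[tuple] = field(default_factory=list)
    seed: int = 0

    def pairs_for_event(self, index: int) -> list[tuple[str, str]]:
        return self.event_pairs[index]


# ---------------------------------------------------------------------------
# calibrated mutation machinery


def _walk_rate(m: int, ks: float) -> float:
    """Poisson rate for a site with ``m`` alternatives realizing divergence ``ks``.

    The site's uniform-jump walk over m+1 states must show difference
    probability p_jc(ks) * m/3 so that path-averaged difference counts over
    fractional site counts reproduce the Jukes-Cantor expectation.
    """
    if m == 0 or ks <= 0:
        return 0.0
    p_target = 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0)) * m / 3.0
    arg = 1.0 - p_target * (m + 1) / m
    if arg <= 0:  # unreachable for finite ks with m <= 3
        return float("inf")
    return -m / (m + 1) * math.log(arg)


def _rate_tables(ks: float) -> np.ndarray:
    return np.array([_walk_rate(m, ks) for m in range(4)])


def _apply_walk(seq: np.ndarray, i: int, pos: int, n: int,
                alt_table: dict, rng: np.random.Generator) -> None:
    alts = alt_table.get((int(seq[i]), pos))
    if not alts:
        return
    states = (int(seq[i]),) + alts
    k = len(states)
    idx = 0
    for _ in range(n):
        j = int(rng.integers(k - 1))
        if j >= idx:
            j += 1
        idx = j
    seq[i] = states[idx]


def _mutate(seq: np.ndarray, ks: float, omega: float, rng: np.random.Generator) -> None:
    """Evolve one coding sequence in place by ``ks`` synonymous units."""
    if ks <= 0:
        return
    lam_syn = _rate_tables(ks)
    lam_non = _rate_tables(omega * ks)
    n_syn = rng.poisson(lam_syn[_M_SYN[seq]])
    n_non = rng.poisson(lam_non[_M_NON[seq]])
    for i, pos in zip(*np.nonzero(n_syn)):
        _apply_walk(seq, int(i), int(pos), int(n_syn[i, pos]), _SYN_ALT_IDX, rng)
    for i, pos in zip(*np.nonzero(n_non)):
        _apply_walk(seq, int(i), int(pos), int(n_non[i, pos]), _NON_ALT_IDX, rng)


def _decode(seq: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in seq)


# ---------------------------------------------------------------------------
# genome history


@dataclass
class _Copy:
    anc: int
    branch: tuple[int, ...]
    seq: np.ndarray
    strand: str

    @property
    def gid(self) -> str:
        suffix = "".join(f"_{b}" for b in self.branch)
        return f"g{self.anc:05d}{suffix}"


def _ancestral_copies(config: SimConfig, rng: np.random.Generator) -> list[list[_Copy]]:
    lengths = rng.integers(config.min_codons, config.max_codons + 1,
                           size=config.n_ancestral_genes)
    strands = rng.integers(0, 2, size=config.n_ancestral_genes)
    sizes = np.full(config.n_scaffolds, config.n_ancestral_genes // config.n_scaffolds)
    sizes[: config.n_ancestral_genes % config.n_scaffolds] += 1
    scaffolds: list[list[_Copy]] = []
    gi = 0
    for size in sizes:
        scaffold: list[_Copy] = []
        for _ in range(size):
            seq = rng.integers(0, len(SENSE_CODONS), size=lengths[gi]).astype(np.int64)
            scaffold.append(_Copy(gi, (), seq, "+-"[strands[gi]]))
            gi += 1
        scaffolds.append(scaffold)
    return scaffolds


def _epoch_schedule(events: tuple[WGDSpec, ...], terminal_ks: float | None) -> list[float]:
    """Per-lineage divergence applied after each event (last entry = terminal)."""
    ks = [e.target_ks for e in events]
    deltas = [(a - b) / 2.0 for a, b in zip(ks, ks[1:])]
    if terminal_ks is None:
        terminal_ks = ks[-1] / 2.0 if ks else 0.0
    deltas.append(terminal_ks)
    return deltas


def simulate_genome(config: SimConfig) -> tuple[GenomeAnnotation, SequenceStore, SimTruth]:
    """Run the configured history; deterministic for a fixed seed."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    anc_rng, event_rng, mut_rng, rearr_rng, frag_rng = map(np.random.default_rng, streams)

    scaffolds = _ancestral_copies(config, anc_rng)
    scaffold_names = [f"sc{j:03d}" for j in range(len(scaffolds))]
    deltas = _epoch_schedule(config.events, config.terminal_ks)

    for ev_idx, event in enumerate(config.events):
        # duplicate every scaffold; drop each duplicated gene independently
        new_scaffolds: list[list[_Copy]] = []
        new_names: list[str] = []
        for name, scaffold in zip(scaffold_names, scaffolds):
            for c in scaffold:
                c.branch = c.branch + (0,)
            for extra in range(1, event.ploidy):
                dup = [
                    _Copy(c.anc, c.branch[:-1] + (extra,), c.seq.copy(), c.strand)
                    for c in scaffold
                    if event_rng.random() < event.retention
                ]
                if dup:
                    new_scaffolds.append(dup)
                    new_names.append(f"{name}w{ev_idx}{extra}")
        scaffolds.extend(new_scaffolds)
        scaffold_names.extend(new_names)
        delta = deltas[ev_idx]
        if delta > 0:
            for scaffold in scaffolds:
                for c in scaffold:
                    _mutate(c.seq, delta, config.omega, mut_rng)

    annot, store, truth = _finalize(config, scaffolds, scaffold_names)

    if config.n_inversions or config.n_translocations:
        annot = apply_rearrangements(
            annot, config.n_inversions, config.n_translocations,
            rng=rearr_rng, log=truth.rearrangements,
        )
    if config.n_fragments is not None:
        annot = fragment_scaffolds(annot, config.n_fragments, rng=frag_rng)
    return annot, store, truth


def _finalize(config, scaffolds, scaffold_names):
    genes: dict[str, list[Gene]] = {}
    store = SequenceStore()
    by_anc: dict[int, list[_Copy]] = {}
    for name, scaffold in zip(scaffold_names, scaffolds):
        ranked = []
        for rank, c in enumerate(scaffold, start=1):
            ranked.append(Gene(id=c.gid, scaffold=name, rank=rank, strand=c.strand,
                               cds_id=c.gid))
            store.add(c.gid, _decode(c.seq))
            by_anc.setdefault(c.anc, []).append(c)
        genes[name] = ranked
    annot = GenomeAnnotation(name=f"sim{config.seed}", genes=genes)

    n_events = len(config.events)
    event_pairs: list[list[tuple[str, str]]] = [[] for _ in range(n_events)]
    pair_target: dict[tuple[str, str], float] = {}
    ancestor_map: dict[str, list[str]] = {}
    for anc, copies in sorted(by_anc.items()):
        ancestor_map[f"g{anc:05d}"] = [c.gid for c in copies]
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                a, b = copies[i], copies[j]
                split = next(k for k in range(n_events) if a.branch[k] != b.branch[k])
                pair = tuple(sorted((a.gid, b.gid)))
                event_pairs[split].append(pair)
                pair_target[pair] = config.events[split].target_ks
    return annot, store, SimTruth(
        event_pairs=event_pairs, pair_target_ks=pair_target,
        ancestor_map=ancestor_map, rearrangements=[], seed=config.seed,
    )


# ---------------------------------------------------------------------------
# rearrangement operators


def _rebuild(name: str, order: dict[str, list[Gene]]) -> GenomeAnnotation:
    genes = {
        sc: [replace(g, scaffold=sc, rank=i) for i, g in enumerate(gl, start=1)]
        for sc, gl in order.items()
        if gl
    }
    return GenomeAnnotation(name=name, genes=genes)


def _flip(g: Gene) -> Gene:
    return replace(g, strand="-" if g.strand == "+" else "+")


def apply_rearrangements(
    annot: GenomeAnnotation,
    n_inversions: int,
    n_translocations: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    log: list | None = None,
) -> GenomeAnnotation:
    """Apply random inversions and translocations in gene-rank space.

    Inversions reverse a contiguous rank interval and flip its strands;
    translocations move a contiguous interval to a position on another
    scaffold. The gene content multiset is invariant.
    """
    if n_inversions < 0 or n_translocations < 0:
        raise ValueError("rearrangement counts must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    order = {sc: list(gl) for sc, gl in annot.genes.items()}

    def pick_scaffold(min_size: int) -> str | None:
        eligible = [sc for sc, gl in order.items() if len(gl) >= min_size]
        if not eligible:
            return None
        weights = np.array([len(order[sc]) for sc in eligible], dtype=float)
        return eligible[rng.choice(len(eligible), p=weights / weights.sum())]

    for _ in range(n_inversions):
        sc = pick_scaffold(2)
        if sc is None:
            break
        n = len(order[sc])
        lo, hi = sorted(rng.choice(n, size=2, replace=False))
        order[sc][lo : hi + 1] = [_flip(g) for g in reversed(order[sc][lo : hi + 1])]
        if log is not None:
            log.append(("inversion", sc, lo + 1, hi + 1))

    for _ in range(n_translocations):
        src = pick_scaffold(2)
        if src is None:
            break
        n = len(order[src])
        lo, hi = sorted(rng.choice(n, size=2, replace=False))
        segment = order[src][lo : hi + 1]
        del order[src][lo : hi + 1]
        others = [sc for sc in order if sc != src and order[sc]] or [src]
        dst = others[int(rng.integers(len(others)))]
        at = int(rng.integers(len(order[dst]) + 1))
        order[dst][at:at] = segment
        if log is not None:
            log.append(("translocation", src, lo + 1, hi + 1, dst, at + 1))

    return _rebuild(annot.name, order)


def fragment_scaffolds(
    annot: GenomeAnnotation,
    n_pieces: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenomeAnnotation:
    """Split scaffolds at random rank boundaries into ``n_pieces`` total."""
    current = annot.n_scaffolds
    if n_pieces < current:
        raise ValueError("n_pieces must be >= current scaffold count")
    if n_pieces > annot.n_genes:
        raise ValueError("cannot make more pieces than genes")
    if rng is None:
        rng = np.random.default_rng(seed)
    boundaries = [
        (sc, cut)
        for sc, gl in annot.genes.items()
        for cut in range(1, len(gl))
    ]
    n_cuts = n_pieces - current
    chosen = rng.choice(len(boundaries), size=n_cuts, replace=False) if n_cuts else []
    cuts: dict[str, list[int]] = {}
    for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
        sc, cut = boundaries[idx]
        cuts.setdefault(sc, []).append(cut)
    order: dict[str, list[Gene]] = {}
    for sc, gl in annot.genes.items():
        edges = [0] + sorted(cuts.get(sc, [])) + [len(gl)]
        if len(edges) == 2:
            order[sc] = list(gl)
            continue
        for piece, (a, b) in enumerate(zip(edges, edges[1:])):
            order[f"{sc}.{piece}"] = gl[a:b]
    return _rebuild(annot.name, order)


def shuffle_annotation(annot: GenomeAnnotation, seed: int = 0) -> GenomeAnnotation:
    """Permute gene order genome-wide, keeping scaffold sizes.

    The null model for colinearity: homology structure is untouched while all
    positional signal is destroyed, so any block found afterwards is chance.
    """
    rng = np.random.default_rng(seed)
    genes = annot.all_genes()
    perm = rng.permutation(len(genes))
    shuffled = [genes[i] for i in perm]
    order: dict[str, list[Gene]] = {}
    at = 0
    for sc in annot.scaffolds:
        size = annot.scaffold_size(sc)
        order[sc] = shuffled[at : at + size]
        at += size
    return _rebuild(annot.name + "_shuffled", order)


# ---------------------------------------------------------------------------
# two-species histories (ortholog divergence)


def simulate_species_pair(
    n_genes: int,
    n_scaffolds: int,
    split_ks: float,
    seed: int = 0,
    omega: float = 0.1,
    wgd_after_split: WGDSpec | None = None,
) -> tuple[GenomeAnnotation, GenomeAnnotation, SequenceStore, list[tuple[str, str]]]:
    """Two genomes descending from one ancestor split at pairwise Ks ``split_ks``.

    An optional WGD (``wgd_after_split``, target_ks < split_ks) is applied to
    lineage A after the split. Returns both annotations, a shared sequence
    store, and the true ortholog pairs (copies of the same ancestral gene
    across the two species).
    """
    if wgd_after_split is not None and wgd_after_split.target_ks >= split_ks:
        raise ValueError("post-split WGD must be younger than the split")
    streams = np.random.SeedSequence(seed).spawn(3)
    anc_rng, mut_rng, event_rng = map(np.random.default_rng, streams)
    base = SimConfig(n_ancestral_genes=n_genes, n_scaffolds=n_scaffolds, seed=seed)
    scaffolds_a = _ancestral_copies(base, anc_rng)
    scaffolds_b = [[_Copy(c.anc, c.branch, c.seq.copy(), c.strand) for c in sc]
                   for sc in scaffolds_a]

    wgd_ks = wgd_after_split.target_ks if wgd_after_split else 0.0
    for sc in scaffolds_b:
        for c in sc:
            _mutate(c.seq, split_ks / 2.0, omega, mut_rng)
    for sc in scaffolds_a:
        for c in sc:
            _mutate(c.seq, (split_ks - wgd_ks) / 2.0, omega, mut_rng)
            c.branch = (0,)
    if wgd_after_split is not None:
        extra = []
        for name_idx, sc in enumerate(list(scaffolds_a)):
            dup = [_Copy(c.anc, (1,), c.seq.copy(), c.strand) for c in sc
                   if event_rng.random() < wgd_after_split.retention]
            if dup:
                extra.append(dup)
        scaffolds_a.extend(extra)
        for sc in scaffolds_a:
            for c in sc:
                _mutate(c.seq, wgd_ks / 2.0, omega, mut_rng)

    store = SequenceStore()

    def build(tag: str, scaffolds: list[list[_Copy]]) -> GenomeAnnotation:
        genes: dict[str, list[Gene]] = {}
        for j, sc in enumerate(scaffolds):
            name = f"{tag}{j:03d}"
            ranked = []
            for rank, c in enumerate(sc, start=1):
                gid = f"{tag}_g{c.anc:05d}" + "".join(f"_{b}" for b in c.branch)
                ranked.append(Gene(id=gid, scaffold=name, rank=rank, strand=c.strand,
                                   cds_id=gid))
                store.add(gid, _decode(c.seq))
            genes[name] = ranked
        return GenomeAnnotation(name=tag, genes=genes)

    annot_a = build("A", scaffolds_a)
    annot_b = build("B", scaffolds_b)
    id_a: dict[int, list[str]] = {}
    for g in annot_a.all_genes():
        anc = int(g.id.split("_")[1][1:])
        id_a.setdefault(anc, []).append(g.id)
    orthologs = []
    for g in annot_b.all_genes():
        anc = int(g.id.split("_")[1][1:])
        for a_id in id_a.get(anc, []):
            orthologs.append((a_id, g.id))
    return annot_a, annot_b, store, orthologs
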