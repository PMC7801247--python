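"""Colinear (syntenic) block inference by recursive longest-path chaining.

Homologous gene pairs are points in the rank grid of a scaffold pair. A
colinear block is a chain of points strictly increasing along the x scaffold
and strictly monotone along the y scaffold (increasing = parallel,
decreasing = antiparallel), with at most ``max_gap`` intervening genes
between neighbors on either axis. The longest such chain (node count) is
extracted by dynamic programming, its pairs are removed, and the search
recurses until no chain of ``min_len`` nodes remains — so each gene pair
belongs to at most one block.

Block significance is assessed empirically: the same number of pairs is
re-scattered uniformly over the scaffold pair's rank grid and the best chain
length recomputed; the p-value is the fraction of permutations reaching the
observed length, with the +1/(n+1) correction (p is never exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeAnnotation
from .homology import HitTable

__all__ = [
    "GenePair",
    "ColinearBlock",
    "build_pairs",
    "infer_blocks",
    "block_significance",
    "null_chain_lengths",
    "blocks_self",
    "blocks_cross",
    "write_blocks_tsv",
    "read_blocks_tsv",
    "write_collinearity",
]

#: pairs closer than this to the self-comparison diagonal are tandem shadow
DEFAULT_DIAGONAL_WINDOW = 5


@dataclass(frozen=True)
class GenePair:
    gene_a: str
    gene_b: str
    x: int
    y: int
    score: float = 0.0


@dataclass(frozen=True)
class ColinearBlock:
    scaffold_a: str
    scaffold_b: str
    pairs: tuple[GenePair, ...]
    orientation: str  # parallel | antiparallel
    p_value: float | None = None
    median_ks: float | None = None
    median_4dtv: float | None = None
    event_label: str | None = None

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def span_a(self) -> tuple[int, int]:
        xs = [p.x for p in self.pairs]
        return min(xs), max(xs)

    @property
    def span_b(self) -> tuple[int, int]:
        ys = [p.y for p in self.pairs]
        return min(ys), max(ys)


def build_pairs(
    hits: HitTable,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    self_mode: bool = False,
) -> dict[tuple[str, str], list[GenePair]]:
    """Map hits to rank coordinates, grouped by scaffold pair.

    In self mode the gene-vs-itself diagonal is dropped and each unordered
    pair is kept once, oriented so scaffold_a <= scaffold_b (and x <= y on a
    shared scaffold).
    """
    genes_a = annot_a.by_id()
    genes_b = annot_b.by_id()
    groups: dict[tuple[str, str], dict[tuple[str, str], GenePair]] = {}
    for hit in hits:
        if self_mode and hit.query == hit.subject:
            continue
        ga = genes_a.get(hit.query)
        gb = genes_b.get(hit.subject)
        if ga is None or gb is None:
            raise KeyError(
                f"hit references unknown gene: {hit.query if ga is None else hit.subject}"
            )
        a_id, b_id = hit.query, hit.subject
        x, y = ga.rank, gb.rank
        sc_a, sc_b = ga.scaffold, gb.scaffold
        if self_mode and (sc_a, x) > (sc_b, y):
            sc_a, sc_b, x, y, a_id, b_id = sc_b, sc_a, y, x, b_id, a_id
        key = (sc_a, sc_b)
        pkey = (a_id, b_id)
        group = groups.setdefault(key, {})
        existing = group.get(pkey)
        if existing is None or hit.score > existing.score:
            group[pkey] = GenePair(a_id, b_id, x, y, hit.score)
    return {
        key: sorted(group.values(), key=lambda p: (p.x, p.y, p.gene_a, p.gene_b))
        for key, group in sorted(groups.items())
    }


# ---------------------------------------------------------------------------
# chain dynamic programming


def _best_chain(pairs: list[GenePair], max_gap: int, antiparallel: bool) -> list[int]:
    """Indices (into ``pairs``) of the best gap-capped monotone chain.

    Best = longest; ties broken by smaller total gap sum, then smaller
    starting x, then smaller starting y (original coordinates).
    """
    n = len(pairs)
    if n == 0:
        return []
    sign = -1 if antiparallel else 1
    order = sorted(range(n), key=lambda i: (pairs[i].x, sign * pairs[i].y))
    xs = [pairs[i].x for i in order]
    ys = [sign * pairs[i].y for i in order]
    # dp state: (length, -gap_sum is worse; store (length, gap_sum, start_x, start_y))
    length = [1] * n
    gap_sum = [0] * n
    start = [(xs[i], pairs[order[i]].y) for i in range(n)]
    prev = [-1] * n
    for i in range(n):
        best_key = None
        for j in range(i - 1, -1, -1):
            dx = xs[i] - xs[j]
            if dx > max_gap + 1:
                break  # xs sorted ascending: earlier j only farther in x
            if dx <= 0:
                continue
            dy = ys[i] - ys[j]
            if dy <= 0 or dy > max_gap + 1:
                continue
            g = gap_sum[j] + (dx - 1) + (dy - 1)
            key = (-(length[j] + 1), g, start[j][0], start[j][1], j)
            if best_key is None or key < best_key:
                best_key = key
        if best_key is not None:
            j = best_key[4]
            length[i] = length[j] + 1
            gap_sum[i] = best_key[1]
            start[i] = start[j]
            prev[i] = j
    best_i = min(range(n), key=lambda i: (-length[i], gap_sum[i], start[i][0], start[i][1]))
    chain = []
    i = best_i
    while i != -1:
        chain.append(order[i])
        i = prev[i]
    chain.reverse()
    return chain


def infer_blocks(
    pairs: list[GenePair],
    max_gap: int = 50,
    min_len: int = 5,
    scaffold_a: str = "",
    scaffold_b: str = "",
) -> list[ColinearBlock]:
    """Recursively extract colinear blocks from one scaffold pair's gene pairs."""
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    remaining = list(pairs)
    blocks: list[ColinearBlock] = []
    while remaining:
        par = _best_chain(remaining, max_gap, antiparallel=False)
        anti = _best_chain(remaining, max_gap, antiparallel=True)

        def chain_key(chain: list[int]) -> tuple:
            if not chain:
                return (0, 0, 0, 0)
            first = remaining[chain[0]]
            g = sum(
                (remaining[b].x - remaining[a].x - 1) + (abs(remaining[b].y - remaining[a].y) - 1)
                for a, b in zip(chain, chain[1:])
            )
            return (-len(chain), g, first.x, first.y)

        if chain_key(par) <= chain_key(anti):
            chain, orientation = par, "parallel"
        else:
            chain, orientation = anti, "antiparallel"
        if len(chain) < min_len:
            break
        chosen = tuple(remaining[i] for i in chain)
        blocks.append(ColinearBlock(
            scaffold_a=scaffold_a, scaffold_b=scaffold_b,
            pairs=chosen, orientation=orientation,
        ))
        used = set(chain)
        remaining = [p for i, p in enumerate(remaining) if i not in used]
    return blocks


def _best_length_arrays(x: np.ndarray, y: np.ndarray, max_gap: int) -> int:
    """Best chain length over both orientations for permutation nulls."""
    best = 0
    for yy in (y, -y):
        order = np.lexsort((yy, x))
        xs = x[order]
        ys = yy[order]
        n = len(xs)
        dp = np.ones(n, dtype=np.int64)
        for i in range(1, n):
            ok = (
                (xs[:i] < xs[i]) & (xs[i] - xs[:i] <= max_gap + 1)
                & (ys[:i] < ys[i]) & (ys[i] - ys[:i] <= max_gap + 1)
            )
            if ok.any():
                dp[i] = 1 + dp[:i][ok].max()
        if n:
            best = max(best, int(dp.max()))
    return best


def null_chain_lengths(
    n_pairs: int,
    len_a: int,
    len_b: int,
    max_gap: int = 50,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Best chain lengths of ``n_perm`` uniform re-scatters of ``n_pairs`` points."""
    if rng is None:
        rng = np.random.default_rng(seed)
    cells = len_a * len_b
    out = np.zeros(n_perm, dtype=np.int64)
    for k in range(n_perm):
        if n_pairs <= cells:
            flat = rng.choice(cells, size=n_pairs, replace=False)
        else:
            flat = rng.integers(0, cells, size=n_pairs)
        x = (flat // len_b + 1).astype(np.int64)
        y = (flat % len_b + 1).astype(np.int64)
        out[k] = _best_length_arrays(x, y, max_gap)
    return out


def block_significance(
    block: ColinearBlock,
    n_pairs_on_scaffold_pair: int,
    len_a: int,
    len_b: int,
    max_gap: int = 50,
    n_perm: int = 1000,
    seed: int | None = None,
    null_sample: np.ndarray | None = None,
) -> float:
    """Empirical p-value of a block's length against uniform re-scatter.

    A precomputed ``null_sample`` (from :func:`null_chain_lengths` with the
    same context) may be supplied so several blocks on one scaffold pair share
    one permutation run.
    """
    if n_pairs_on_scaffold_pair < block.length:
        raise ValueError("context pair count smaller than observed block")
    if null_sample is None:
        null_sample = null_chain_lengths(
            n_pairs_on_scaffold_pair, len_a, len_b, max_gap, n_perm, seed=seed
        )
    n = len(null_sample)
    return (1 + int((null_sample >= block.length).sum())) / (n + 1)


# ---------------------------------------------------------------------------
# orchestration


def _significant_blocks(
    grouped: dict[tuple[str, str], list[GenePair]],
    size_a,
    size_b,
    max_gap: int,
    min_len: int,
    alpha: float,
    n_perm: int,
    seed: int,
) -> list[ColinearBlock]:
    rng = np.random.default_rng(seed)
    out: list[ColinearBlock] = []
    for (sc_a, sc_b), pairs in grouped.items():
        blocks = infer_blocks(pairs, max_gap=max_gap, min_len=min_len,
                              scaffold_a=sc_a, scaffold_b=sc_b)
        if not blocks:
            continue
        null = null_chain_lengths(
            len(pairs), size_a(sc_a), size_b(sc_b), max_gap, n_perm, rng=rng
        )
        for b in blocks:
            p = block_significance(
                b, len(pairs), size_a(sc_a), size_b(sc_b), max_gap,
                null_sample=null,
            )
            if p <= alpha:
                out.append(replace(b, p_value=p))
    return out


def blocks_self(
    annot: GenomeAnnotation,
    hits: HitTable,
    max_gap: int = 50,
    min_len: int = 5,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    diagonal_window: int = DEFAULT_DIAGONAL_WINDOW,
) -> list[ColinearBlock]:
    """Significant colinear blocks from a genome's self-comparison.

    Pairs within ``diagonal_window`` of the same-scaffold diagonal (tandem
    shadow) are excluded from seeding blocks.
    """
    grouped = build_pairs(hits, annot, annot, self_mode=True)
    grouped = {
        key: [p for p in pairs if key[0] != key[1] or abs(p.x - p.y) > diagonal_window]
        for key, pairs in grouped.items()
    }
    grouped = {k: v for k, v in grouped.items() if v}
    return _significant_blocks(
        grouped, annot.scaffold_size, annot.scaffold_size,
        max_gap, min_len, alpha, n_perm, seed,
    )


def blocks_cross(
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    hits: HitTable,
    max_gap: int = 50,
    min_len: int = 4,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[ColinearBlock]:
    """Significant colinear blocks between two genomes."""
    grouped = build_pairs(hits, annot_a, annot_b, self_mode=False)
    return _significant_blocks(
        grouped, annot_a.scaffold_size, annot_b.scaffold_size,
        max_gap, min_len, alpha, n_perm, seed,
    )


# ---------------------------------------------------------------------------
# output formats


def write_blocks_tsv(blocks: list[ColinearBlock], path) -> None:
    """Block table: one header row per block, then one row per gene pair."""
    with open(path, "w") as fh:
        fh.write("#block\tscaffold_a\tscaffold_b\torientation\tlength\tp_value\t"
                 "median_ks\tmedian_4dtv\tevent\n")
        for i, b in enumerate(blocks):
            fmt = lambda v: "NA" if v is None else f"{v:.6g}"
            fh.write(f"B{i:04d}\t{b.scaffold_a}\t{b.scaffold_b}\t{b.orientation}\t"
                     f"{b.length}\t{fmt(b.p_value)}\t{fmt(b.median_ks)}\t"
                     f"{fmt(b.median_4dtv)}\t{b.event_label or 'NA'}\n")
            for p in b.pairs:
                fh.write(f"B{i:04d}.pair\t{p.gene_a}\t{p.gene_b}\t{p.x}\t{p.y}\n")


def read_blocks_tsv(path) -> list[ColinearBlock]:
    """Read a block table written by :func:`write_blocks_tsv`."""

    def parse(v: str) -> float | None:
        return None if v == "NA" else float(v)

    headers: dict[str, dict] = {}
    pairs: dict[str, list[GenePair]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#block"):
                continue
            fields = line.split("\t")
            if fields[0].endswith(".pair"):
                bid = fields[0][: -len(".pair")]
                pairs.setdefault(bid, []).append(
                    GenePair(fields[1], fields[2], int(fields[3]), int(fields[4]))
                )
            else:
                bid = fields[0]
                order.append(bid)
                headers[bid] = dict(
                    scaffold_a=fields[1], scaffold_b=fields[2], orientation=fields[3],
                    p_value=parse(fields[5]), median_ks=parse(fields[6]),
                    median_4dtv=parse(fields[7]),
                    event_label=None if fields[8] == "NA" else fields[8],
                )
    return [
        ColinearBlock(pairs=tuple(pairs.get(bid, [])), **headers[bid])
        for bid in order
    ]


def write_collinearity(blocks: list[ColinearBlock], path) -> None:
    """MCScanX-like .collinearity text file for interoperability."""
    with open(path, "w") as fh:
        fh.write("############### Collinearity ###############\n")
        for i, b in enumerate(blocks):
            strand = "plus" if b.orientation == "parallel" else "minus"
            pv = b.p_value if b.p_value is not None else float("nan")
            fh.write(f"## Alignment {i}: score={b.length * 50:.1f} e_value={pv:.3g} "
                     f"N={b.length} {b.scaffold_a}&{b.scaffold_b} {strand}\n")
            for j, p in enumerate(b.pairs):
                fh.write(f"{i:3d}-{j:3d}:\t{p.gene_a}\t{p.gene_b}\t{pv:.3g}\n")
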