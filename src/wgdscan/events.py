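"""From per-pair divergences to inferred polyploidy events.

Peak detection fits Gaussian mixtures to log-Ks with BIC model selection
(polyploidy events appear as approximately lognormal components of the
paralog Ks distribution). Detected peaks are dated under a synonymous
molecular clock, T = Ks / (2r), with the substitution rate given as an
interval (default 6.0-7.0 x 1e-9 synonymous substitutions/site/year, the
angiosperm range). Homologous depth profiling counts, per gene, the number
of significant blocks covering it — depth >= ploidy-1 within a genome is the
positional signature of polyploidy rounds. Ancestral genome reconstruction
collapses the duplicated regions of one event back to single ancestral
copies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .colinearity import ColinearBlock
from .genome import GenomeAnnotation, SequenceStore

logger = logging.getLogger(__name__)

__all__ = [
    "PeakEstimate",
    "WGDEvent",
    "DepthProfile",
    "AncestralGene",
    "AncestralGenome",
    "find_peaks",
    "assign_events",
    "date_event",
    "make_event",
    "depth_profile",
    "reconstruct_ancestral",
    "ortholog_peak",
]

DEFAULT_RATE_LO = 6.0e-9
DEFAULT_RATE_HI = 7.0e-9
#: blocks with median Ks below this are treated as residual heterozygosity
DEFAULT_HETEROZYGOSITY_GUARD = 0.07


@dataclass(frozen=True)
class PeakEstimate:
    """One mixture component of the Ks distribution, on the Ks scale."""

    mode_ks: float
    weight: float
    interval: tuple[float, float]
    n_pairs: int
    sigma_log: float = float("nan")


@dataclass(frozen=True)
class WGDEvent:
    """A dated polyploidy event: a Ks peak plus its age under a rate interval."""

    label: str
    peak: PeakEstimate
    rate_lo: float
    rate_hi: float
    age_lo: float  # million years
    age_hi: float


@dataclass(frozen=True)
class DepthProfile:
    """Per-gene homologous coverage depth and its genome-wide distribution."""

    depth: dict[str, int]
    fraction_at_depth: dict[int, float]
    max_depth: int

    def fraction_at_least(self, d: int) -> float:
        return sum(f for k, f in self.fraction_at_depth.items() if k >= d)


@dataclass(frozen=True)
class AncestralGene:
    id: str
    region: str
    rank: int
    copies: tuple[str, ...]


@dataclass
class AncestralGenome:
    """Reconstructed pre-event gene order: one copy per collapsed region group."""

    regions: dict[str, list[AncestralGene]] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def copy_map(self) -> dict[str, tuple[str, ...]]:
        return {g.id: g.copies for gl in self.regions.values() for g in gl}

    def all_genes(self) -> list[AncestralGene]:
        return [g for gl in self.regions.values() for g in gl]


# ---------------------------------------------------------------------------
# peak detection and dating


def find_peaks(
    ks_values,
    k_max: int = 4,
    ks_range: tuple[float, float] = (0.02, 3.0),
    seed: int = 0,
    weight_floor: float = 0.05,
) -> list[PeakEstimate]:
    """Detect Ks peaks by Gaussian-mixture fitting on log-Ks.

    The number of components (1..k_max) is chosen by the integrated completed
    likelihood (ICL): BIC plus twice the classification entropy. Unlike raw
    BIC — which at large sample sizes splits a single skewed peak into
    overlapping Gaussians — ICL counts well-separated clusters, which is what
    a duplication *event* is. Components with weight below ``weight_floor``
    are dropped as noise. Values outside ``ks_range`` are ignored (saturation
    guard). Peaks are returned sorted by mode, with assignment intervals at
    the posterior crossing points of adjacent components.
    """
    lo, hi = ks_range
    values = np.asarray([v for v in ks_values if v is not None and np.isfinite(v)])
    values = values[(values >= lo) & (values <= hi)]
    if len(values) < 50:
        raise ValueError(
            f"only {len(values)} usable Ks values in range; too few for mixture "
            "fitting — inspect the histogram instead"
        )
    logv = np.log(values).reshape(-1, 1)
    best = None
    best_icl = np.inf
    for k in range(1, k_max + 1):
        gmm = GaussianMixture(n_components=k, n_init=5, random_state=seed,
                              covariance_type="full", reg_covar=1e-4)
        gmm.fit(logv)
        resp = gmm.predict_proba(logv)
        entropy = -np.sum(resp * np.log(np.clip(resp, 1e-12, None)))
        icl = gmm.bic(logv) + 2.0 * entropy
        if icl < best_icl:
            best_icl = icl
            best = gmm
    means = best.means_.ravel()
    sigmas = np.sqrt(best.covariances_.reshape(-1))
    weights = best.weights_.ravel()
    order = np.argsort(means)
    means, sigmas, weights = means[order], sigmas[order], weights[order]
    keep = weights >= weight_floor
    means, sigmas, weights = means[keep], sigmas[keep], weights[keep]

    # posterior boundaries between adjacent components, on the log scale
    bounds = [math.log(lo)]
    for i in range(len(means) - 1):
        f = lambda x: (
            math.log(weights[i]) + norm.logpdf(x, means[i], sigmas[i])
            - math.log(weights[i + 1]) - norm.logpdf(x, means[i + 1], sigmas[i + 1])
        )
        a, b = means[i], means[i + 1]
        try:
            bounds.append(brentq(f, a, b))
        except ValueError:
            bounds.append((a + b) / 2.0)
    bounds.append(math.log(hi))

    peaks = []
    logs = logv.ravel()
    for i in range(len(means)):
        blo, bhi = bounds[i], bounds[i + 1]
        n = int(((logs >= blo) & (logs < bhi)).sum())
        peaks.append(PeakEstimate(
            mode_ks=float(np.exp(means[i])),
            weight=float(weights[i]),
            interval=(float(np.exp(blo)), float(np.exp(bhi))),
            n_pairs=n,
            sigma_log=float(sigmas[i]),
        ))
    return peaks


def date_event(
    mode_ks: float,
    rate_lo: float = DEFAULT_RATE_LO,
    rate_hi: float = DEFAULT_RATE_HI,
) -> tuple[float, float]:
    """Age interval in million years under T = Ks / (2r)."""
    if mode_ks <= 0:
        raise ValueError("mode_ks must be > 0")
    if not (0 < rate_lo <= rate_hi):
        raise ValueError("need 0 < rate_lo <= rate_hi")
    age_lo = mode_ks / (2.0 * rate_hi) / 1e6
    age_hi = mode_ks / (2.0 * rate_lo) / 1e6
    return age_lo, age_hi


def make_event(
    label: str,
    peak: PeakEstimate,
    rate_lo: float = DEFAULT_RATE_LO,
    rate_hi: float = DEFAULT_RATE_HI,
) -> WGDEvent:
    age_lo, age_hi = date_event(peak.mode_ks, rate_lo, rate_hi)
    return WGDEvent(label=label, peak=peak, rate_lo=rate_lo, rate_hi=rate_hi,
                    age_lo=age_lo, age_hi=age_hi)


def assign_events(
    blocks: list[ColinearBlock],
    young_max: float = 0.5,
    old_range: tuple[float, float] = (1.0, 1.7),
    heterozygosity_guard: float | None = DEFAULT_HETEROZYGOSITY_GUARD,
) -> list[ColinearBlock]:
    """Label blocks by median Ks: "xi" (young) below ``young_max``, "eta" (old)
    inside ``old_range``; anything else stays unlabeled.

    Blocks below the heterozygosity guard are left unlabeled too: divergence
    that low is indistinguishable from residual haplotype divergence in a
    partially phased assembly. Pass ``heterozygosity_guard=None`` for
    cross-species runs.
    """
    out = []
    for b in blocks:
        label = None
        ks = b.median_ks
        if ks is not None:
            if heterozygosity_guard is not None and ks < heterozygosity_guard:
                label = None
            elif ks < young_max:
                label = "xi"
            elif old_range[0] < ks < old_range[1]:
                label = "eta"
        out.append(replace(b, event_label=label))
    return out


# ---------------------------------------------------------------------------
# homologous depth


def depth_profile(
    blocks: list[ColinearBlock],
    annot: GenomeAnnotation,
    axis: str = "a",
    min_len: int = 4,
) -> DepthProfile:
    """Per-gene homologous coverage depth.

    A gene's depth is the number of blocks (length >= ``min_len``) whose rank
    span on the chosen axis contains it. ``axis="both"`` counts both of a
    block's regions, which is the natural choice for self-comparison where
    both sides live on the same genome.
    """
    if axis not in ("a", "b", "both"):
        raise ValueError("axis must be 'a', 'b', or 'both'")
    depth = {g.id: 0 for g in annot.all_genes()}
    per_scaffold = annot.genes
    for b in blocks:
        if b.length < min_len:
            continue
        spans = []
        if axis in ("a", "both"):
            spans.append((b.scaffold_a, b.span_a))
        if axis in ("b", "both"):
            spans.append((b.scaffold_b, b.span_b))
        for scaffold, (lo, hi) in spans:
            for g in per_scaffold.get(scaffold, ())[lo - 1 : hi]:
                depth[g.id] += 1
    n = len(depth)
    if n == 0:
        return DepthProfile(depth={}, fraction_at_depth={0: 1.0}, max_depth=0)
    counts: dict[int, int] = {}
    for d in depth.values():
        counts[d] = counts.get(d, 0) + 1
    fractions = {d: c / n for d, c in sorted(counts.items())}
    return DepthProfile(depth=depth, fraction_at_depth=fractions,
                        max_depth=max(depth.values()))


# ---------------------------------------------------------------------------
# ancestral genome reconstruction


def reconstruct_ancestral(
    blocks: list[ColinearBlock],
    annot: GenomeAnnotation,
    ploidy: int = 2,
) -> AncestralGenome:
    """Collapse one event's duplicated regions into a single ancestral copy.

    For each block the copy on the longer scaffold anchors ancestral gene
    order; its colinear partner collapses onto it. Unpaired genes lying
    inside an anchored span are retained as single-copy ancestral genes.
    When a gene is claimed by two region groups the block with the worse
    (higher) p-value loses; conflicts are logged.
    """
    if ploidy not in (2, 3):
        raise ValueError("ploidy must be 2 or 3")
    by_id = annot.by_id()
    ordered = sorted(
        blocks,
        key=lambda b: (b.p_value if b.p_value is not None else 1.0, -b.length,
                       b.scaffold_a, b.scaffold_b),
    )
    claimed: dict[str, str] = {}  # extant gene id -> ancestral id
    entries: list[tuple[str, int, str, tuple[str, ...]]] = []  # region, rank, anc id, copies
    conflicts = 0
    anchored_spans: list[tuple[str, int, int]] = []
    for b in ordered:
        size_a = annot.scaffold_size(b.scaffold_a)
        size_b = annot.scaffold_size(b.scaffold_b)
        anchor_is_a = size_a > size_b or (size_a == size_b and b.scaffold_a <= b.scaffold_b)
        for p in b.pairs:
            anchor_gene, other_gene = (p.gene_a, p.gene_b) if anchor_is_a else (p.gene_b, p.gene_a)
            if anchor_gene in claimed or other_gene in claimed:
                conflicts += 1
                continue
            anchor = by_id[anchor_gene]
            anc_id = f"anc_{anchor_gene}"
            claimed[anchor_gene] = anc_id
            claimed[other_gene] = anc_id
            entries.append((anchor.scaffold, anchor.rank, anc_id,
                            (anchor_gene, other_gene)))
        scaffold = b.scaffold_a if anchor_is_a else b.scaffold_b
        lo, hi = b.span_a if anchor_is_a else b.span_b
        anchored_spans.append((scaffold, lo, hi))
    if conflicts:
        logger.info("ancestral reconstruction: %d pair(s) lost to overlap conflicts",
                    conflicts)

    # single-copy ancestral genes: unpaired genes inside anchored spans
    for scaffold, lo, hi in anchored_spans:
        for g in annot.genes.get(scaffold, ())[lo - 1 : hi]:
            if g.id not in claimed:
                anc_id = f"anc_{g.id}"
                claimed[g.id] = anc_id
                entries.append((scaffold, g.rank, anc_id, (g.id,)))

    regions: dict[str, list[AncestralGene]] = {}
    for scaffold in annot.scaffolds:
        rows = sorted((e for e in entries if e[0] == scaffold), key=lambda e: e[1])
        if not rows:
            continue
        regions[scaffold] = [
            AncestralGene(id=anc_id, region=scaffold, rank=i, copies=copies)
            for i, (_sc, _rk, anc_id, copies) in enumerate(rows, start=1)
        ]
    return AncestralGenome(regions=regions)


# ---------------------------------------------------------------------------
# ortholog divergence


def ortholog_peak(
    cross_blocks: list[ColinearBlock],
    store_a: SequenceStore,
    store_b: SequenceStore | None = None,
    seed: int = 0,
    ks_range: tuple[float, float] = (0.02, 3.0),
) -> PeakEstimate:
    """Dominant Ks peak of cross-species colinear pairs (the species split).

    A post-split WGD in one lineage adds a paralog peak; the heaviest
    component still tracks the split.
    """
    from .divergence import align_codons, ng86

    if store_b is None:
        store_b = store_a

    def cds_of(gid: str) -> str | None:
        if gid in store_a:
            return store_a.cds(gid)
        if gid in store_b:
            return store_b.cds(gid)
        return None

    ks = []
    for b in cross_blocks:
        for p in b.pairs:
            ca, cb = cds_of(p.gene_a), cds_of(p.gene_b)
            if ca is None or cb is None:
                continue
            aln = align_codons(ca, cb, p.gene_a, p.gene_b)
            if aln.unalignable:
                continue
            est = ng86(aln)
            if not est.saturated and est.ks is not None:
                ks.append(est.ks)
    peaks = find_peaks(ks, k_max=2, ks_range=ks_range, seed=seed)
    return max(peaks, key=lambda p: p.weight)
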