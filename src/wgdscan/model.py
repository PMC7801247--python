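"""Model/results interface over the paleo-polyploidy detection pipeline.

:class:`PolyploidyScan` is built from a genome (annotation + coding
sequences, optionally precomputed homology hits) and a set of scan
parameters; :meth:`PolyploidyScan.fit` runs homology search, colinear-block
inference with permutation significance, per-pair Ks/4Dtv estimation,
mixture-based peak detection, event dating, and depth profiling, returning a
:class:`ScanResults` carrying the estimates, their uncertainties, and
diagnostics, with a ``summary()`` table, plotting, and ancestral-genome
reconstruction hanging off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colinearity import ColinearBlock, blocks_self, write_blocks_tsv, write_collinearity
from .divergence import DivergenceEstimate, block_divergence, pair_divergence
from .events import (
    DEFAULT_HETEROZYGOSITY_GUARD,
    DEFAULT_RATE_HI,
    DEFAULT_RATE_LO,
    AncestralGenome,
    DepthProfile,
    PeakEstimate,
    WGDEvent,
    assign_events,
    depth_profile,
    find_peaks,
    make_event,
    reconstruct_ancestral,
)
from .genome import GenomeAnnotation, SequenceStore, filter_small_scaffolds
from .homology import HitTable, filter_high_copy, rank_hits, score_pairs
from .report import RunSummary, coverage_percent, dotplot, genes_in_blocks

__all__ = ["PolyploidyScan", "ScanResults"]

_EVENT_LABELS = ("xi", "eta", "event3", "event4")


class PolyploidyScan:
    """Scan a genome's self-comparison for whole-genome duplication events.

    Parameters
    ----------
    annotation
        Gene order in rank coordinates.
    sequences
        Coding sequences for the annotated genes.
    hits
        Optional precomputed homology table (e.g. read from an outfmt-6
        file). When absent, the internal protein search is used.
    max_gap
        Maximum intervening genes between colinear neighbors (default 50).
    min_len
        Minimum colinear genes per block (default 5 for self-comparison).
    max_copies
        Gene-family size cutoff; larger families are removed (default 30).
    alpha, n_perm
        Block significance level and permutation count.
    min_scaffold_genes
        Scaffolds with fewer genes are dropped before scanning (1 = keep all).
    rate_lo, rate_hi
        Synonymous substitution rate interval (per site per year) for dating.
    """

    def __init__(
        self,
        annotation: GenomeAnnotation,
        sequences: SequenceStore,
        hits: HitTable | None = None,
        *,
        max_gap: int = 50,
        min_len: int = 5,
        max_copies: int = 30,
        alpha: float = 0.05,
        n_perm: int = 1000,
        min_scaffold_genes: int = 1,
        diagonal_window: int = 5,
        ks_range: tuple[float, float] = (0.02, 3.0),
        k_max: int = 4,
        young_max: float = 0.5,
        old_range: tuple[float, float] = (1.0, 1.7),
        heterozygosity_guard: float | None = DEFAULT_HETEROZYGOSITY_GUARD,
        rate_lo: float = DEFAULT_RATE_LO,
        rate_hi: float = DEFAULT_RATE_HI,
    ):
        self.annotation_raw = annotation
        self.annotation = (
            filter_small_scaffolds(annotation, min_scaffold_genes)
            if min_scaffold_genes > 1 else annotation
        )
        self.sequences = sequences
        self.hits = hits
        self.params = dict(
            max_gap=max_gap, min_len=min_len, max_copies=max_copies,
            alpha=alpha, n_perm=n_perm, min_scaffold_genes=min_scaffold_genes,
            diagonal_window=diagonal_window, ks_range=ks_range, k_max=k_max,
            young_max=young_max, old_range=old_range,
            heterozygosity_guard=heterozygosity_guard,
            rate_lo=rate_lo, rate_hi=rate_hi,
        )

    @classmethod
    def from_simulation(cls, config, **kwargs):
        """Build a scan from a simulated history; returns (model, truth)."""
        from .simulate import simulate_genome

        annot, store, truth = simulate_genome(config)
        return cls(annot, store, **kwargs), truth

    def fit(self, seed: int = 0) -> "ScanResults":
        p = self.params
        hits = self.hits
        if hits is None:
            hits = score_pairs(self.sequences, self.sequences)
        hits = rank_hits(hits)
        hits = filter_high_copy(hits, max_copies=p["max_copies"])

        blocks = blocks_self(
            self.annotation, hits,
            max_gap=p["max_gap"], min_len=p["min_len"], alpha=p["alpha"],
            n_perm=p["n_perm"], seed=seed, diagonal_window=p["diagonal_window"],
        )

        cache: dict[tuple[str, str], DivergenceEstimate | None] = {}
        blocks = [block_divergence(b, self.sequences, cache=cache) for b in blocks]
        blocks = assign_events(
            blocks, young_max=p["young_max"], old_range=p["old_range"],
            heterozygosity_guard=p["heterozygosity_guard"],
        )

        estimates = [e for e in cache.values() if e is not None]
        ks_values = [e.ks for e in estimates if e.ks is not None and not e.saturated]
        peaks: list[PeakEstimate] = []
        if len(ks_values) >= 50:
            try:
                peaks = find_peaks(
                    ks_values, k_max=p["k_max"], ks_range=p["ks_range"], seed=seed,
                )
            except ValueError:
                peaks = []
        events = [
            make_event(_EVENT_LABELS[i] if i < len(_EVENT_LABELS) else f"event{i + 1}",
                       peak, p["rate_lo"], p["rate_hi"])
            for i, peak in enumerate(peaks)
        ]
        depth = depth_profile(blocks, self.annotation, axis="both", min_len=p["min_len"])
        return ScanResults(
            model=self, hits=hits, blocks=blocks, pair_estimates=estimates,
            ks_values=ks_values, peaks=peaks, events=events, depth=depth,
            seed=seed,
        )


@dataclass
class ScanResults:
    """Fitted scan: detected blocks, divergences, peaks, events, depth."""

    model: PolyploidyScan
    hits: HitTable
    blocks: list[ColinearBlock]
    pair_estimates: list[DivergenceEstimate]
    ks_values: list[float]
    peaks: list[PeakEstimate]
    events: list[WGDEvent]
    depth: DepthProfile
    seed: int = 0

    # -- derived quantities -------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_colinear_pairs(self) -> int:
        return sum(b.length for b in self.blocks)

    def coverage(self) -> tuple[int, int, float]:
        """(covered genes, total genes, percent) on the scanned annotation."""
        covered, total = genes_in_blocks(self.blocks, self.model.annotation, axis="both")
        return covered, total, coverage_percent(covered, total)

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_a, e.gene_b, e.n_codons, e.S, e.N, e.Sd, e.Nd,
              e.ks, e.ka, e.fourdtv, e.saturated)
             for e in self.pair_estimates],
            columns=["gene_a", "gene_b", "n_codons", "S", "N", "Sd", "Nd",
                     "ks", "ka", "fourdtv", "saturated"],
        )

    def blocks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.scaffold_a, b.scaffold_b, b.orientation, b.length, b.p_value,
              b.median_ks, b.median_4dtv, b.event_label)
             for b in self.blocks],
            columns=["scaffold_a", "scaffold_b", "orientation", "length",
                     "p_value", "median_ks", "median_4dtv", "event"],
        )

    # -- downstream operations ---------------------------------------------

    def reconstruct_ancestral(self, label: str = "xi", ploidy: int = 2) -> AncestralGenome:
        """Collapse the blocks of one labeled event to the pre-event genome."""
        chosen = [b for b in self.blocks if b.event_label == label]
        return reconstruct_ancestral(chosen, self.model.annotation, ploidy=ploidy)

    def dotplot(self, out="dotplot.png", **kwargs) -> Path:
        return dotplot(self.hits, self.model.annotation, self.model.annotation,
                       blocks=self.blocks, out=out, **kwargs)

    def run_summary(self) -> RunSummary:
        covered, total, pct = self.coverage()
        return RunSummary(
            genome=self.model.annotation.name,
            n_genes=total,
            n_scaffolds=self.model.annotation.n_scaffolds,
            n_blocks=self.n_blocks,
            n_colinear_pairs=self.n_colinear_pairs,
            covered_genes=covered,
            coverage_pct=pct,
            depth_fractions=dict(self.depth.fraction_at_depth),
            peaks=[{"mode_ks": p.mode_ks, "weight": p.weight,
                    "interval": list(p.interval), "n_pairs": p.n_pairs}
                   for p in self.peaks],
            events=[{"label": e.label, "mode_ks": e.peak.mode_ks,
                     "weight": e.peak.weight, "n_pairs": e.peak.n_pairs,
                     "age_lo": e.age_lo, "age_hi": e.age_hi}
                    for e in self.events],
            config={k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in self.model.params.items()},
            seed=self.seed,
            version=__version__,
        )

    def write(self, out_dir) -> None:
        """Write block TSV, .collinearity, and summary reports."""
        from .report import write_summary

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_blocks_tsv(self.blocks, out_dir / "blocks.tsv")
        write_collinearity(self.blocks, out_dir / "blocks.collinearity")
        write_summary(self.run_summary(), out_dir)

    def summary(self) -> str:
        """Human-readable report in the style of a model-fit summary."""
        covered, total, pct = self.coverage()
        lines = [
            "Paleo-polyploidy scan results",
            "=" * 64,
            f"Genome: {self.model.annotation.name}"
            f"  ({total} genes on {self.model.annotation.n_scaffolds} scaffolds)",
            f"Significant colinear blocks: {self.n_blocks}"
            f"  (colinear gene pairs: {self.n_colinear_pairs})",
            f"Gene coverage by blocks: {pct:.2f}% ({covered}/{total})",
            "",
            "Ks peaks (Gaussian mixture on log-Ks, ICL-selected):",
            f"{'label':>8} {'mode Ks':>9} {'weight':>7} {'n pairs':>8} "
            f"{'sigma(log)':>10} {'age lo-hi (MY)':>16}",
        ]
        for e in self.events:
            p = e.peak
            lines.append(
                f"{e.label:>8} {p.mode_ks:>9.3f} {p.weight:>7.2f} {p.n_pairs:>8d} "
                f"{p.sigma_log:>10.3f} {e.age_lo:>7.1f}-{e.age_hi:.1f}"
            )
        if not self.events:
            lines.append("    (no peaks detected)")
        lines += [
            "",
            "Homologous depth (fractions of genes):",
        ]
        ge4 = self.depth.fraction_at_least(4)
        for d in range(0, 4):
            frac = self.depth.fraction_at_depth.get(d, 0.0)
            lines.append(f"    depth {d}: {100 * frac:6.2f}%")
        lines.append(f"    depth >=4: {100 * ge4:6.2f}%   (max depth {self.depth.max_depth})")
        lines.append("")
        lines.append(f"Dating rate interval: {self.model.params['rate_lo']:.1e}"
                     f"-{self.model.params['rate_hi']:.1e} syn subs/site/year; T = Ks/(2r)")
        return "\n".join(lines)
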