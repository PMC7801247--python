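"""Dot plots, coverage arithmetic, and run summaries.

Percentages follow the printed-report convention: 2 decimals, half-up
rounding (19391/22285 -> 87.01). Depth tables are reported as *gene*
fractions — depth is computed at gene-rank resolution, so "fraction of the
genome at depth d" here means fraction of genes, stated in every output
header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .colinearity import ColinearBlock
from .genome import GenomeAnnotation
from .homology import HitTable

__all__ = [
    "RunSummary",
    "coverage_percent",
    "genes_in_blocks",
    "dotplot",
    "write_summary",
    "load_summary",
]

_LABEL_COLORS = {"best": "red", "second": "blue", "other": "0.6"}


def coverage_percent(numerator: int, denominator: int) -> float:
    """Percentage at 2 decimals with half-up ties."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not (0 <= numerator <= denominator):
        raise ValueError("need 0 <= numerator <= denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def genes_in_blocks(
    blocks: list[ColinearBlock],
    annot: GenomeAnnotation,
    axis: str = "both",
) -> tuple[int, int]:
    """(distinct genes inside any block's rank span on the mapped axis, total)."""
    covered: set[str] = set()
    for b in blocks:
        spans = []
        if axis in ("a", "both"):
            spans.append((b.scaffold_a, b.span_a))
        if axis in ("b", "both"):
            spans.append((b.scaffold_b, b.span_b))
        for scaffold, (lo, hi) in spans:
            for g in annot.genes.get(scaffold, ())[lo - 1 : hi]:
                covered.add(g.id)
    return len(covered), annot.n_genes


@dataclass
class RunSummary:
    """Machine-readable account of one pipeline run."""

    genome: str
    n_genes: int
    n_scaffolds: int
    n_blocks: int
    n_colinear_pairs: int
    covered_genes: int
    coverage_pct: float
    depth_fractions: dict[int, float] = field(default_factory=dict)
    peaks: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0
    version: str = ""

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _scaffold_offsets(annot: GenomeAnnotation, by_size: bool = True):
    """Cumulative rank offsets of concatenated scaffolds along one axis."""
    names = sorted(annot.scaffolds, key=lambda s: -annot.scaffold_size(s)) \
        if by_size else annot.scaffolds
    offsets = {}
    total = 0
    for name in names:
        offsets[name] = total
        total += annot.scaffold_size(name)
    return offsets, total, names


def dotplot(
    hits: HitTable,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    blocks: list[ColinearBlock] | None = None,
    out: str | Path = "dotplot.png",
    order_by_size: bool = True,
    young_max: float = 0.5,
    old_range: tuple[float, float] = (1.0, 1.7),
) -> Path:
    """Homologous-gene dot plot with block boxes and median-Ks labels.

    Dots are colored by hit rank (best = red, second = blue, other = gray);
    block bounding boxes are highlighted in yellow, with the block's median
    Ks printed in red when Ks < ``young_max`` and black when inside
    ``old_range``. Axes are sequentially linked scaffolds separated by thin
    lines.
    """
    blocks = blocks or []
    off_a, total_a, _ = _scaffold_offsets(annot_a, order_by_size)
    off_b, total_b, _ = _scaffold_offsets(annot_b, order_by_size)
    genes_a = annot_a.by_id()
    genes_b = annot_b.by_id()

    fig, ax = plt.subplots(figsize=(8, 8))
    for label in ("other", "second", "best"):  # best drawn on top
        xs, ys = [], []
        for h in sorted(hits, key=lambda h: (h.query, h.subject)):
            if h.rank_label != label:
                continue
            ga = genes_a.get(h.query)
            gb = genes_b.get(h.subject)
            if ga is None or gb is None:
                continue
            xs.append(off_a[ga.scaffold] + ga.rank)
            ys.append(off_b[gb.scaffold] + gb.rank)
        if xs:
            ax.scatter(xs, ys, s=2, c=_LABEL_COLORS[label], label=label, linewidths=0)
    for b in blocks:
        (x0, x1), (y0, y1) = b.span_a, b.span_b
        x0 += off_a.get(b.scaffold_a, 0)
        x1 += off_a.get(b.scaffold_a, 0)
        y0 += off_b.get(b.scaffold_b, 0)
        y1 += off_b.get(b.scaffold_b, 0)
        ax.add_patch(Rectangle((x0, y0), x1 - x0, y1 - y0, fill=False,
                               edgecolor="gold", linewidth=1.2))
        ks = b.median_ks
        if ks is not None:
            color = "red" if ks < young_max else (
                "black" if old_range[0] < ks < old_range[1] else "0.5")
            ax.text(x1, y1, f"{ks:.2f}", fontsize=6, color=color,
                    ha="left", va="bottom")
    for off in sorted(set(off_a.values())):
        if off:
            ax.axvline(off + 0.5, color="0.85", linewidth=0.4, zorder=0)
    for off in sorted(set(off_b.values())):
        if off:
            ax.axhline(off + 0.5, color="0.85", linewidth=0.4, zorder=0)
    ax.set_xlim(0, total_a + 1)
    ax.set_ylim(0, total_b + 1)
    ax.set_xlabel(f"{annot_a.name} (gene rank, scaffolds linked)")
    ax.set_ylabel(f"{annot_b.name} (gene rank, scaffolds linked)")
    ax.legend(loc="upper right", markerscale=4, fontsize=8)
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def write_summary(summary: RunSummary, out_dir: str | Path) -> dict[str, Path]:
    """Write JSON + TSV reports; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = asdict(summary)
    payload["config_hash"] = summary.config_hash
    # JSON keys must be strings; keep depth keys convertible
    payload["depth_fractions"] = {str(k): v for k, v in summary.depth_fractions.items()}
    json_path = out_dir / "summary.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    depth_path = out_dir / "depth_table.tsv"
    with open(depth_path, "w") as fh:
        fh.write("# homologous depth distribution (fractions are of GENES;\n")
        fh.write("# depth is counted at gene-rank resolution)\n")
        fh.write("depth\tpercent\n")
        total = 0.0
        ge4 = sum(f for d, f in summary.depth_fractions.items() if d >= 4)
        for d in sorted(summary.depth_fractions, reverse=True):
            if d >= 4:
                continue
            pct = round(100 * summary.depth_fractions[d], 2)
            total += summary.depth_fractions[d]
            fh.write(f"{d}\t{pct:.2f}\n")
        fh.write(f">=4\t{round(100 * ge4, 2):.2f}\n")
        fh.write(f"sum\t{round(100 * (total + ge4), 2):.2f}\n")

    events_path = out_dir / "events.tsv"
    with open(events_path, "w") as fh:
        fh.write("label\tmode_ks\tweight\tn_pairs\tage_lo_my\tage_hi_my\n")
        for e in summary.events:
            fh.write(f"{e['label']}\t{e['mode_ks']:.4g}\t{e['weight']:.3f}\t"
                     f"{e['n_pairs']}\t{e['age_lo']:.1f}\t{e['age_hi']:.1f}\n")
    return {"json": json_path, "depth": depth_path, "events": events_path}


def load_summary(path: str | Path) -> RunSummary:
    """Reload a summary.json written by :func:`write_summary`."""
    with open(path) as fh:
        payload = json.load(fh)
    payload.pop("config_hash", None)
    payload["depth_fractions"] = {int(k): v for k, v in payload["depth_fractions"].items()}
    return RunSummary(**payload)
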