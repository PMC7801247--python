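"""Gene-order domain model and I/O.

All colinearity analysis in this package runs in *gene-rank* coordinates:
genes on a scaffold are numbered 1..n by position, and block gaps are counted
in intervening genes, not base pairs. This module converts physical
annotations (GFF3 or bed-like tables) into that coordinate system and holds
the coding/protein sequence store.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "SequenceStore",
    "read_annotation",
    "read_sequences",
    "write_annotation",
    "filter_small_scaffolds",
]


@dataclass(frozen=True)
class Gene:
    """A gene placed on a scaffold at 1-based gene-order rank ``rank``.

    ``start``/``end`` are optional 1-based closed base-pair coordinates kept
    for reporting; they never enter colinearity computations.
    """

    id: str
    scaffold: str
    rank: int
    strand: str = "+"
    start: int | None = None
    end: int | None = None
    cds_id: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for gene {self.id}")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"start > end for gene {self.id}")


@dataclass
class GenomeAnnotation:
    """Ordered genes on ordered scaffolds; the coordinate frame for all blocks."""

    name: str
    genes: dict[str, list[Gene]] = field(default_factory=dict)

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for scaffold, gene_list in self.genes.items():
            for i, g in enumerate(gene_list, start=1):
                if g.rank != i:
                    raise ValueError(
                        f"ranks on scaffold {scaffold} are not 1..n "
                        f"(gene {g.id} has rank {g.rank}, expected {i})"
                    )
                if g.scaffold != scaffold:
                    raise ValueError(f"gene {g.id} filed under wrong scaffold")
                if g.id in seen:
                    raise ValueError(f"duplicate gene id: {g.id}")
                seen.add(g.id)

    @property
    def scaffolds(self) -> list[str]:
        return list(self.genes)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes.values())

    @property
    def n_scaffolds(self) -> int:
        return len(self.genes)

    def all_genes(self) -> list[Gene]:
        return [g for gl in self.genes.values() for g in gl]

    def by_id(self) -> dict[str, Gene]:
        return {g.id: g for g in self.all_genes()}

    def scaffold_size(self, scaffold: str) -> int:
        return len(self.genes[scaffold])


def _rank_scaffold(scaffold: str, rows: list[tuple]) -> list[Gene]:
    """Sort raw (start, end, id, strand) rows by start and assign ranks 1..n."""
    rows = sorted(rows, key=lambda r: (r[0] if r[0] is not None else 0, r[2]))
    return [
        Gene(id=gid, scaffold=scaffold, rank=i, strand=strand, start=start, end=end,
             cds_id=gid)
        for i, (start, end, gid, strand) in enumerate(rows, start=1)
    ]


def _read_bed_like(path: Path) -> dict[str, list[tuple]]:
    per_scaffold: dict[str, list[tuple]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{line_no}: bed-like row needs >= 4 columns "
                    "(scaffold, start, end, id[, strand])"
                )
            scaffold, start, end, gid = fields[:4]
            strand = fields[4] if len(fields) > 4 and fields[4] in ("+", "-") else "+"
            per_scaffold.setdefault(scaffold, []).append(
                (int(start), int(end), gid, strand)
            )
    return per_scaffold


def _read_gff3(path: Path) -> dict[str, list[tuple]]:
    """Extract one point per gene from GFF3.

    ``gene`` features are preferred; where a file carries only mRNA features,
    the first mRNA per gene (by its Parent or its own ID) stands in. Extra
    isoforms are ignored: one gene is one point in the dot plot.
    """
    per_scaffold: dict[str, list[tuple]] = {}
    seen_genes: set[str] = set()
    mrna_rows: list[tuple[str, tuple]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            scaffold, _src, ftype, start, end, _score, strand, _frame, attrs = fields[:9]
            if ftype not in ("gene", "mRNA"):
                continue
            attr = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr[k.strip()] = v.strip()
            strand = strand if strand in ("+", "-") else "+"
            row = (int(start), int(end), None, strand)
            if ftype == "gene":
                gid = attr.get("ID") or attr.get("Name")
                if gid is None:
                    raise ValueError(f"gene feature without ID in {path}")
                per_scaffold.setdefault(scaffold, []).append(
                    (row[0], row[1], gid, strand)
                )
                seen_genes.add(gid)
            else:
                parent = attr.get("Parent") or attr.get("ID")
                mrna_rows.append((scaffold, (row[0], row[1], parent, strand)))
    # mRNAs whose parent gene never appeared as a gene feature
    claimed: set[str] = set(seen_genes)
    for scaffold, (start, end, gid, strand) in mrna_rows:
        if gid is None or gid in claimed:
            continue
        claimed.add(gid)
        per_scaffold.setdefault(scaffold, []).append((start, end, gid, strand))
    return per_scaffold


def read_annotation(path, format: str = "bed-like", name: str | None = None) -> GenomeAnnotation:
    """Read a GFF3 or bed-like gene table into rank coordinates.

    Genes are sorted by start coordinate per scaffold (unsorted input is
    sorted, not rejected) and assigned ranks 1..n. A duplicate gene id is a
    hard error.
    """
    path = Path(path)
    if format == "gff3":
        per_scaffold = _read_gff3(path)
    elif format in ("bed-like", "bed"):
        per_scaffold = _read_bed_like(path)
    else:
        raise ValueError(f"unknown annotation format: {format}")
    seen: set[str] = set()
    for rows in per_scaffold.values():
        for _s, _e, gid, _st in rows:
            if gid in seen:
                raise ValueError(f"duplicate gene id: {gid}")
            seen.add(gid)
    genes = {sc: _rank_scaffold(sc, rows) for sc, rows in sorted(per_scaffold.items())}
    return GenomeAnnotation(name=name or path.stem, genes=genes)


def write_annotation(annot: GenomeAnnotation, path) -> None:
    """Write the canonical gene-order table (bed-like 5-column TSV).

    Genes without physical coordinates get their rank as a stand-in start/end
    so the table round-trips ranks, ids, and strands exactly.
    """
    with open(path, "w") as fh:
        for scaffold in annot.scaffolds:
            for g in annot.genes[scaffold]:
                start = g.start if g.start is not None else g.rank
                end = g.end if g.end is not None else start
                fh.write(f"{scaffold}\t{start}\t{end}\t{g.id}\t{g.strand}\n")


def filter_small_scaffolds(annot: GenomeAnnotation, min_genes: int) -> GenomeAnnotation:
    """Drop scaffolds carrying fewer than ``min_genes`` genes."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    kept = {sc: gl for sc, gl in annot.genes.items() if len(gl) >= min_genes}
    return GenomeAnnotation(name=annot.name, genes=kept)


class SequenceStore:
    """Validated CDS sequences and their translations.

    Every stored CDS has length divisible by 3 and no internal stop codon;
    a terminal stop is stripped. Records violating either rule are excluded
    with a logged warning rather than raising.
    """

    def __init__(self, cds: dict[str, str] | None = None):
        self._cds: dict[str, str] = {}
        self._protein: dict[str, str] = {}
        if cds:
            for gid, seq in cds.items():
                self.add(gid, seq)

    def add(self, gid: str, seq: str) -> bool:
        """Validate and store one CDS; returns False (and logs) on rejection."""
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            logger.warning("CDS %s length %d not divisible by 3; excluded", gid, len(seq))
            return False
        if seq.endswith(("TAA", "TAG", "TGA")):
            seq = seq[:-3]
        if not seq:
            logger.warning("CDS %s empty after stop stripping; excluded", gid)
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            protein = str(Seq(seq).translate())
        if "*" in protein:
            logger.warning("CDS %s contains an internal stop codon; excluded", gid)
            return False
        self._cds[gid] = seq
        self._protein[gid] = protein
        return True

    def cds(self, gid: str) -> str:
        return self._cds[gid]

    def protein(self, gid: str) -> str:
        return self._protein[gid]

    def __contains__(self, gid: str) -> bool:
        return gid in self._cds

    def __len__(self) -> int:
        return len(self._cds)

    def ids(self) -> list[str]:
        return list(self._cds)

    def write_fasta(self, path, what: str = "cds") -> None:
        source = self._cds if what == "cds" else self._protein
        with open(path, "w") as fh:
            for gid, seq in source.items():
                fh.write(f">{gid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def read_sequences(path) -> SequenceStore:
    """Read a CDS FASTA into a validated SequenceStore."""
    store = SequenceStore()
    for record in SeqIO.parse(str(path), "fasta"):
        store.add(record.id, str(record.seq))
    return store
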