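"""Domain types, standard-format readers/writers, and an interval index.

Coordinates are 0-based half-open throughout (BED convention). A TSS is a
single base position. Comment lines starting with ``#`` are skipped in every
reader; all files are tab-separated UTF-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "DifferentialResult",
    "Loop",
    "SampleDesign",
    "Gene",
    "Peak",
    "PeakSet",
    "GeneSetCollection",
    "IntervalIndex",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_bedpe_loops",
    "write_bedpe_loops",
    "read_gene_table",
    "write_gene_table",
    "read_gmt",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to_point(self, pos: int) -> int:
        """Gap from a single base position to the nearest interval edge.

        0 when the position lies inside the (half-open) interval.
        """
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


@dataclass(frozen=True)
class DifferentialResult:
    """Outcome of the NB Wald test for one loop (treated over vehicle)."""

    log2fc: float
    pvalue: float
    qvalue: float
    direction: str  # increased | decreased | ns

    def __post_init__(self) -> None:
        for name in ("pvalue", "qvalue"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.direction not in ("increased", "decreased", "ns"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class Loop:
    """An intra-chromosomal chromatin loop with per-sample PET counts.

    Anchors are canonicalized so ``anchor_a.start <= anchor_b.start``.
    ``loop_class`` is PP/PE/EE once classified; ``er_class`` is
    primary/secondary/unrelated once TF-binding connectivity is computed.
    """

    loop_id: str
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    counts: dict[str, int] = field(default_factory=dict)
    loop_class: str = "unset"
    diff: Optional[DifferentialResult] = None
    er_class: str = "unset"

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError(
                f"inter-chromosomal loop {self.loop_id}: "
                f"{self.anchor_a.chrom} vs {self.anchor_b.chrom}"
            )
        if self.anchor_a.start > self.anchor_b.start:
            self.anchor_a, self.anchor_b = self.anchor_b, self.anchor_a
        for sample, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for sample {sample!r}")

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom

    @property
    def anchor_distance_bp(self) -> float:
        """Midpoint-to-midpoint distance between the two anchors."""
        return self.anchor_b.midpoint - self.anchor_a.midpoint

    @property
    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.anchor_a, self.anchor_b)


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample names to condition (treated/vehicle) and replicate index.

    ``samples`` preserves the column order of the count file.
    """

    samples: tuple[str, ...]
    condition: Mapping[str, str]  # sample -> treated | vehicle
    replicate: Mapping[str, int]  # sample -> 1-based replicate index

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample names must be unique")
        for s in self.samples:
            if self.condition[s] not in ("treated", "vehicle"):
                raise ValueError(f"bad condition for {s!r}")
        for cond in ("treated", "vehicle"):
            if not self.samples_for(cond):
                raise ValueError(f"need >=1 replicate for condition {cond!r}")

    @classmethod
    def two_by_two(
        cls,
        treated: Sequence[str] = ("treated_1", "treated_2"),
        vehicle: Sequence[str] = ("vehicle_1", "vehicle_2"),
    ) -> "SampleDesign":
        samples = tuple(vehicle) + tuple(treated)
        condition = {s: "vehicle" for s in vehicle}
        condition.update({s: "treated" for s in treated})
        replicate = {s: i + 1 for i, s in enumerate(vehicle)}
        replicate.update({s: i + 1 for i, s in enumerate(treated)})
        return cls(samples=samples, condition=condition, replicate=replicate)

    def samples_for(self, condition: str) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.condition[s] == condition)

    @property
    def conditions(self) -> tuple[str, ...]:
        return ("vehicle", "treated")


@dataclass(frozen=True)
class Gene:
    """A gene anchored at its TSS, with optional hormone-response labels."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str
    regulation: str = "unknown"  # up | down | ns | unknown
    expr_log2fc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.regulation not in ("up", "down", "ns", "unknown"):
            raise ValueError(f"bad regulation {self.regulation!r}")


@dataclass(frozen=True)
class Peak:
    """A TF binding site (ChIP-seq peak) interval."""

    interval: GenomicInterval
    peak_id: str
    score: Optional[float] = None


class PeakSet:
    """An ordered collection of peaks, sorted by (chrom, start)."""

    def __init__(self, peaks: Iterable[Peak]):
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]


class GeneSetCollection:
    """Named gene sets (e.g. hallmark collections) keyed by set name."""

    def __init__(self, sets: Mapping[str, set[str]]):
        for name, members in sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets: dict[str, set[str]] = {k: set(v) for k, v in sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def items(self):
        return self.sets.items()


class IntervalIndex:
    """Overlap-query index over a set of intervals, per chromosome.

    Backed by an interval tree; query results are defined to equal a
    brute-force scan of all indexed intervals.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )
            self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(
        self, interval: GenomicInterval, min_overlap_bp: int = 1
    ) -> list[GenomicInterval]:
        """All indexed intervals overlapping ``interval`` by >= min_overlap_bp."""
        if min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [
            node.data
            for node in tree.overlap(interval.start, interval.end)
            if node.data.overlap_bp(interval) >= min_overlap_bp
        ]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits


def build_index(intervals: Iterable[GenomicInterval]) -> IntervalIndex:
    return IntervalIndex(intervals)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping comments/blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_bed(path: str | Path) -> PeakSet:
    """Read a BED3+ file of peaks; column 4 (if present) is the peak id,
    column 5 the score. Missing ids default to ``peak_<row>``."""
    peaks: list[Peak] = []
    for i, (lineno, line) in enumerate(_data_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"need >=3 tab-separated columns at line {lineno}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate at line {lineno}") from exc
        if start >= end:
            raise ParseError(f"start >= end at line {lineno}")
        peak_id = fields[3] if len(fields) > 3 and fields[3] else f"peak_{i}"
        score = None
        if len(fields) > 4 and fields[4] not in ("", "."):
            score = float(fields[4])
        peaks.append(Peak(GenomicInterval(chrom, start, end), peak_id, score))
    return PeakSet(peaks)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            score = "." if p.score is None else repr(p.score)
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.peak_id}\t{score}\n"
            )


_BEDPE_FIXED = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "loop_id"]


def read_bedpe_loops(path: str | Path, design: SampleDesign) -> list[Loop]:
    """Read the BEDPE+counts dialect: 6 coordinate columns, loop id, then one
    count column per sample. The header row must name the count columns and
    they must match the design's sample names (any order)."""
    lines = _data_lines(path)
    try:
        header_lineno, header = next(lines)
    except StopIteration:
        raise ParseError("empty loop file (missing header)") from None
    cols = header.split("\t")
    if cols[: len(_BEDPE_FIXED)] != _BEDPE_FIXED:
        raise ParseError(
            f"header at line {header_lineno} must start with "
            f"{' '.join(_BEDPE_FIXED)}"
        )
    count_cols = cols[len(_BEDPE_FIXED) :]
    missing = set(design.samples) - set(count_cols)
    if missing:
        raise ParseError(f"missing sample columns: {sorted(missing)}")
    extra = set(count_cols) - set(design.samples)
    if extra:
        raise ParseError(f"unknown sample columns: {sorted(extra)}")

    loops: list[Loop] = []
    seen_ids: set[str] = set()
    for lineno, line in lines:
        f = line.split("\t")
        if len(f) != len(cols):
            raise ParseError(
                f"expected {len(cols)} columns at line {lineno}, got {len(f)}"
            )
        chrom_a, chrom_b = f[0], f[3]
        if chrom_a != chrom_b:
            raise ParseError(f"inter-chromosomal loop at line {lineno}")
        try:
            sa, ea, sb, eb = int(f[1]), int(f[2]), int(f[4]), int(f[5])
            counts_raw = [int(x) for x in f[7:]]
        except ValueError as exc:
            raise ParseError(f"non-integer field at line {lineno}") from exc
        if sa >= ea or sb >= eb:
            raise ParseError(f"start >= end at line {lineno}")
        if any(c < 0 for c in counts_raw):
            raise ParseError(f"negative count at line {lineno}")
        loop_id = f[6]
        if loop_id in seen_ids:
            raise ParseError(f"duplicate loop_id {loop_id!r} at line {lineno}")
        seen_ids.add(loop_id)
        counts = dict(zip(count_cols, counts_raw))
        loops.append(
            Loop(
                loop_id=loop_id,
                anchor_a=GenomicInterval(chrom_a, sa, ea),
                anchor_b=GenomicInterval(chrom_b, sb, eb),
                counts=counts,
            )
        )
    return loops


def write_bedpe_loops(
    loops: Sequence[Loop], design: SampleDesign, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_BEDPE_FIXED + list(design.samples)) + "\n")
        for lp in loops:
            row = [
                lp.anchor_a.chrom,
                str(lp.anchor_a.start),
                str(lp.anchor_a.end),
                lp.anchor_b.chrom,
                str(lp.anchor_b.start),
                str(lp.anchor_b.end),
                lp.loop_id,
            ] + [str(lp.counts[s]) for s in design.samples]
            fh.write("\t".join(row) + "\n")


_GENE_COLS = ["gene_id", "symbol", "chrom", "tss", "strand", "regulation", "expr_log2fc"]


def read_gene_table(path: str | Path) -> list[Gene]:
    """Read the gene TSV. The regulation and expr_log2fc columns are optional;
    regulation defaults to "unknown" when absent. Genes come back sorted by
    (chrom, tss)."""
    lines = _data_lines(path)
    try:
        header_lineno, header = next(lines)
    except StopIteration:
        raise ParseError("empty gene table (missing header)") from None
    cols = header.split("\t")
    if cols[:5] != _GENE_COLS[:5]:
        raise ParseError(
            f"header at line {header_lineno} must start with {' '.join(_GENE_COLS[:5])}"
        )
    has_reg = "regulation" in cols
    has_fc = "expr_log2fc" in cols
    idx = {c: i for i, c in enumerate(cols)}

    genes: list[Gene] = []
    seen: set[str] = set()
    for lineno, line in lines:
        f = line.split("\t")
        if len(f) != len(cols):
            raise ParseError(
                f"expected {len(cols)} columns at line {lineno}, got {len(f)}"
            )
        gene_id = f[idx["gene_id"]]
        if gene_id in seen:
            raise ParseError(f"duplicate gene_id {gene_id!r} at line {lineno}")
        seen.add(gene_id)
        try:
            tss = int(f[idx["tss"]])
        except ValueError as exc:
            raise ParseError(f"non-integer tss at line {lineno}") from exc
        regulation = f[idx["regulation"]] if has_reg else "unknown"
        expr = None
        if has_fc and f[idx["expr_log2fc"]] not in ("", "NA", "."):
            expr = float(f[idx["expr_log2fc"]])
        genes.append(
            Gene(
                gene_id=gene_id,
                symbol=f[idx["symbol"]],
                chrom=f[idx["chrom"]],
                tss=tss,
                strand=f[idx["strand"]],
                regulation=regulation,
                expr_log2fc=expr,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def write_gene_table(genes: Sequence[Gene], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            fc = "NA" if g.expr_log2fc is None else repr(g.expr_log2fc)
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.tss}\t{g.strand}"
                f"\t{g.regulation}\t{fc}\n"
            )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member symbols. Duplicate
    members within a line collapse; duplicate set names are an error."""
    sets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"need >=3 tab-separated fields at line {lineno}")
        name = fields[0]
        if name in sets:
            raise ParseError(f"duplicate set name {name!r} at line {lineno}")
        members = {m for m in fields[2:] if m}
        if not members:
            raise ParseError(f"gene set {name!r} at line {lineno} has no members")
        sets[name] = members
    return GeneSetCollection(sets)
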