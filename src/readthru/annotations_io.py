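"""Gene models and stranded tag coverage: internal containers and standard-format I/O.

All coordinates are 0-based, half-open (BED convention). GTF input is
converted on read. A sequenced fragment is represented by the single
genomic position of its strand-aware 5' end, so every fragment falls in
exactly one counting window or bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class ParseError(ValueError):
    """Raised for malformed annotation or tag records; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """One gene's exon structure with strand-aware TSS/TTS.

    For a + strand gene tss == span.start and tts == span.end; on the
    - strand the two are reflected. ``body_length`` is the summed exon
    length (the FPKM denominator).
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    tss: int
    tts: int
    body_length: int

    @classmethod
    def from_exons(
        cls, gene_id: str, chrom: str, strand: str, exons: list[tuple[int, int]]
    ) -> "GeneModel":
        exons = sorted(exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(f"gene {gene_id}: overlapping exons {e1} > {s2}")
        span = GenomicInterval(chrom, exons[0][0], exons[-1][1], strand)
        tss, tts = (span.start, span.end) if strand == "+" else (span.end, span.start)
        body = sum(e - s for s, e in exons)
        return cls(
            gene_id=gene_id,
            span=span,
            exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
            tss=tss,
            tts=tts,
            body_length=body,
        )


def downstream_window(
    gene: GeneModel, length_bp: int, chrom_length: int | None = None
) -> GenomicInterval | None:
    """The read-through counting window immediately 3' of the TTS.

    Clipped at the chromosome start (and end, when the length is known);
    returns None if clipping empties the window.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    if gene.span.strand == "+":
        start, end = gene.tts, gene.tts + length_bp
    else:
        start, end = gene.tts - length_bp, gene.tts
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        logger.warning("gene %s: downstream window clipped to empty", gene.gene_id)
        return None
    return GenomicInterval(gene.span.chrom, start, end, gene.span.strand)


@dataclass
class StrandedCoverage:
    """Strand-specific fragment 5'-end positions for one library.

    ``tags`` maps (chrom, strand) to a sorted int64 array of positions.
    ``library_size`` is the total mapped fragments used for per-million
    normalisation; it may exceed the number of stored tags when the
    stored region is a subset of the full library.
    """

    condition: str
    replicate: int
    library_size: int
    tags: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for key, arr in self.tags.items():
            a = np.asarray(arr, dtype=np.int64)
            if a.size and a.min() < 0:
                raise ValueError(f"negative tag position on {key}")
            self.tags[key] = np.sort(a)
        if self.library_size < self.n_tags:
            raise ValueError("library_size smaller than number of stored tags")

    @property
    def n_tags(self) -> int:
        return int(sum(a.size for a in self.tags.values()))

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        return self.tags.get((chrom, strand), np.empty(0, dtype=np.int64))

    def count(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Number of tag positions p with start <= p < end."""
        pos = self.positions(chrom, strand)
        if pos.size == 0:
            return 0
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(hi - lo)


# ---------------------------------------------------------------------------
# gene model readers


def _parse_bed12_line(line: str, lineno: int) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) == 1:
        f = line.split()
    if len(f) < 12:
        raise ParseError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    try:
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed BED12 record: {exc}") from None
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"line {lineno}: blockCount disagrees with block lists")
    exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
    for s, e in exons:
        if s < start or e > end:
            raise ParseError(f"line {lineno}: exon block [{s},{e}) outside span [{start},{end})")
    try:
        return GeneModel.from_exons(name, chrom, strand, exons)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


_GTF_ATTR_KEYS = ("gene_id", "transcript_id")


def _gtf_attr(attrs: str, key: str) -> str | None:
    # ensembl-style: key "value"; tolerate unquoted values
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            val = part[len(key):].strip(" =")
            return val.strip('"')
    return None


def read_gene_models(
    path: str, dialect: str = "bed12", transcript_policy: str = "longest"
) -> list[GeneModel]:
    """Read gene models from BED12 or GTF.

    GTF exon records are grouped by gene; either the longest transcript
    (default) or the union of all exons defines the model.
    """
    dialect = dialect.lower()
    if dialect == "bed12":
        models = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                models.append(_parse_bed12_line(line, lineno))
        _check_unique_ids(models)
        return models
    if dialect != "gtf":
        raise ValueError(f"unknown dialect {dialect!r}; use 'bed12' or 'gtf'")
    if transcript_policy not in ("longest", "union"):
        raise ValueError("transcript_policy must be 'longest' or 'union'")

    # gene_id -> transcript_id -> (chrom, strand, [exons])
    genes: dict[str, dict[str, tuple[str, str, list[tuple[int, int]]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"line {lineno}: GTF needs 9 fields, got {len(f)}")
            if f[2] != "exon":
                continue
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer GTF coordinates") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"line {lineno}: invalid GTF coordinates {start1}-{end1}")
            strand = f[6]
            if strand not in STRANDS:
                raise ParseError(f"line {lineno}: missing strand in GTF exon record")
            gid = _gtf_attr(f[8], "gene_id")
            if gid is None:
                raise ParseError(f"line {lineno}: GTF record lacks gene_id attribute")
            tid = _gtf_attr(f[8], "transcript_id") or gid
            tx = genes.setdefault(gid, {})
            if gid not in order:
                order.append(gid)
            # 1-based closed -> 0-based half-open
            tx.setdefault(tid, (f[0], strand, []))[2].append((start1 - 1, end1))

    models = []
    for gid in order:
        transcripts = genes[gid]
        if transcript_policy == "longest":
            tid = max(
                sorted(transcripts),
                key=lambda t: sum(e - s for s, e in transcripts[t][2]),
            )
            chrom, strand, exons = transcripts[tid]
            exons = sorted(exons)
        else:
            chrom, strand, _ = next(iter(transcripts.values()))
            exons = _union_intervals(
                [iv for _, _, ivs in transcripts.values() for iv in ivs]
            )
        models.append(GeneModel.from_exons(gid, chrom, strand, exons))
    _check_unique_ids(models)
    return models


def _union_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _check_unique_ids(models: list[GeneModel]) -> None:
    seen: set[str] = set()
    for m in models:
        if m.gene_id in seen:
            raise ValueError(f"duplicate gene_id {m.gene_id!r} in annotation")
        seen.add(m.gene_id)


def write_gene_models_bed12(models: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e.length) for e in m.exons) + ","
            offsets = ",".join(str(e.start - m.span.start) for e in m.exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.span.chrom, m.span.start, m.span.end, m.gene_id, 0,
                        m.span.strand, m.span.start, m.span.end, 0,
                        len(m.exons), sizes, offsets,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# stranded tag I/O


def load_stranded_tags(
    path: str,
    condition: str,
    replicate: int,
    library_size: int | None = None,
) -> StrandedCoverage:
    """Load BED6 aligned-fragment records as strand-aware 5'-end tags.

    A + record contributes one tag at its start, a - record at end-1.
    ``library_size`` defaults to the record count.
    """
    tags: dict[tuple[str, str], list[int]] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 6:
                raise ParseError(f"line {lineno}: BED6 needs 6 fields (strand required)")
            strand = f[5]
            if strand not in STRANDS:
                raise ParseError(f"line {lineno}: record is unstranded ({strand!r})")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if start < 0 or end <= start:
                raise ParseError(f"line {lineno}: invalid coordinates {start}-{end}")
            pos = start if strand == "+" else end - 1
            tags.setdefault((f[0], strand), []).append(pos)
            n += 1
    return StrandedCoverage(
        condition=condition,
        replicate=replicate,
        library_size=library_size if library_size is not None else max(n, 1),
        tags={k: np.asarray(v, dtype=np.int64) for k, v in tags.items()},
    )


def write_tags_bed6(cov: StrandedCoverage, path: str) -> None:
    """Write stored tags back out as 1-bp BED6 records (one per fragment)."""
    with open(path, "w") as fh:
        for (chrom, strand), pos in sorted(cov.tags.items()):
            for i, p in enumerate(pos):
                fh.write(f"{chrom}\t{p}\t{p + 1}\tt{i}\t0\t{strand}\n")


def load_stranded_bedgraph(
    plus_path: str | None,
    minus_path: str | None,
    condition: str,
    replicate: int,
    library_size: int | None = None,
) -> StrandedCoverage:
    """Load a per-strand bedGraph pair as per-base tag counts (lossless)."""
    tags: dict[tuple[str, str], np.ndarray] = {}
    total = 0
    for strand, p in (("+", plus_path), ("-", minus_path)):
        if p is None:
            continue
        per_chrom: dict[str, list[np.ndarray]] = {}
        with open(p) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split()
                if len(f) < 4:
                    raise ParseError(f"line {lineno}: bedGraph needs 4 fields")
                chrom, start, end, val = f[0], int(f[1]), int(f[2]), float(f[3])
                if start < 0 or end <= start:
                    raise ParseError(f"line {lineno}: invalid interval {start}-{end}")
                c = int(round(val))
                if c < 0:
                    raise ParseError(f"line {lineno}: negative count")
                if c:
                    block = np.repeat(np.arange(start, end, dtype=np.int64), c)
                    per_chrom.setdefault(chrom, []).append(block)
        for chrom, blocks in per_chrom.items():
            arr = np.sort(np.concatenate(blocks))
            tags[(chrom, strand)] = arr
            total += arr.size
    return StrandedCoverage(
        condition=condition,
        replicate=replicate,
        library_size=library_size if library_size is not None else max(total, 1),
        tags=tags,
    )


def write_bedgraph(cov: StrandedCoverage, strand: str, path: str) -> None:
    """Write one strand's per-base tag counts as a sorted, run-length-merged bedGraph."""
    if strand not in STRANDS:
        raise ValueError(f"strand must be one of {STRANDS}")
    try:
        with open(path, "w") as fh:
            for (chrom, s), pos in sorted(cov.tags.items()):
                if s != strand or pos.size == 0:
                    continue
                uniq, counts = np.unique(pos, return_counts=True)
                # merge adjacent runs of equal count
                run_start = uniq[0]
                prev_pos, prev_cnt = uniq[0], counts[0]
                for p, c in zip(uniq[1:], counts[1:]):
                    if p == prev_pos + 1 and c == prev_cnt:
                        prev_pos = p
                        continue
                    fh.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_cnt}\n")
                    run_start, prev_pos, prev_cnt = p, p, c
                fh.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_cnt}\n")
    except OSError as exc:
        raise OSError(f"failed writing bedGraph to {path}: {exc}") from exc
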