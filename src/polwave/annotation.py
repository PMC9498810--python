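"""Gene models and genomic windows.

All coordinates are 0-based half-open throughout the package; BED input is
native, GTF (1-based closed) is converted on read.  A :class:`GeneModel`
stores the transcription start site (TSS) and transcription termination site
(TTS) strand-aware: ``tss`` is always the 5' end with respect to the strand,
so for minus-strand genes ``tss > tts``.  Every genomic window used downstream
(promoter TSS+/-500 bp, metagene TSS-2kb..+50kb, m6A extent TSS-2kb..TTS+2kb)
is derived through :func:`window`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Fatal annotation problem (unreadable file, zero valid records)."""


@dataclass(frozen=True)
class GeneModel:
    """One curated gene/transcript model.

    ``tss`` is the 5' end in transcription direction; for a minus-strand gene
    it is the larger genomic coordinate.  ``exons`` are genomic 0-based
    half-open intervals, sorted by start, non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.tss == self.tts:
            raise AnnotationError(f"zero-length gene {self.gene_id}")
        if self.strand == "+" and self.tss > self.tts:
            raise AnnotationError(f"+ strand gene {self.gene_id} has tss > tts")
        if self.strand == "-" and self.tss < self.tts:
            raise AnnotationError(f"- strand gene {self.gene_id} has tss < tts")
        lo, hi = self.span
        last = lo
        for s, e in self.exons:
            if s < last or e <= s or e > hi:
                raise AnnotationError(
                    f"exons of {self.gene_id} not sorted/non-overlapping/contained"
                )
            last = e

    @property
    def length(self) -> int:
        """Gene length in bp, |tts - tss|."""
        return abs(self.tts - self.tss)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval [start, end) covered by the gene body."""
        return (min(self.tss, self.tts), max(self.tss, self.tts))

    def to_transcript_coord(self, pos: int) -> int:
        """Distance of genomic position ``pos`` from the TSS, measured 5'->3'.

        0 at the TSS, increasing into the gene body regardless of strand.
        """
        if self.strand == "+":
            return pos - self.tss
        return self.tss - 1 - pos


@dataclass
class GeneSet:
    """A keyed collection of gene models with free-text provenance."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def add(self, g: GeneModel) -> None:
        if g.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene_id {g.gene_id}")
        self.genes[g.gene_id] = g


def _bed12_to_gene(fields: list[str]) -> GeneModel:
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    name = fields[3]
    strand = fields[5] if len(fields) > 5 else "+"
    if len(fields) >= 12:
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    else:
        exons = ((start, end),)
    if strand == "+":
        tss, tts = start, end
    else:
        tss, tts = end, start
    return GeneModel(name, chrom, strand, tss, tts, exons)


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_annotation(path: str | Path) -> GeneSet:
    """Read a BED(12) or minimal GTF file into a :class:`GeneSet`.

    BED is taken as 0-based half-open; GTF ``transcript``/``exon`` features
    (1-based closed) are converted internally.  Malformed records are skipped
    with a logged count; zero valid records is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    text = path.read_text().splitlines()
    is_gtf = path.suffix.lower() in (".gtf", ".gff")
    gs = GeneSet(provenance=f"read from {path.name}")
    skipped = 0
    if is_gtf:
        # gather transcript spans and exon lists keyed by transcript_id
        spans: dict[str, tuple[str, str, int, int]] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        for line in text:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                skipped += 1
                continue
            chrom, _, feat, start1, end1, _, strand, _, attr = f[:9]
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError:
                skipped += 1
                continue
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id") or attrs.get("gene_id")
            if tid is None:
                skipped += 1
                continue
            if feat == "transcript":
                spans[tid] = (chrom, strand, start, end)
            elif feat == "exon":
                exons.setdefault(tid, []).append((start, end))
                if tid not in spans:
                    c, s, lo, hi = spans.get(tid, (chrom, strand, start, end))
                    spans[tid] = (chrom, strand, min(lo, start), max(hi, end))
        for tid, (chrom, strand, start, end) in spans.items():
            ex = tuple(sorted(exons.get(tid, [(start, end)])))
            try:
                if strand == "+":
                    gs.add(GeneModel(tid, chrom, strand, start, end, ex))
                else:
                    gs.add(GeneModel(tid, chrom, strand, end, start, ex))
            except AnnotationError:
                skipped += 1
    else:
        for line in text:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                skipped += 1
                continue
            try:
                gs.add(_bed12_to_gene(f))
            except (ValueError, IndexError, AnnotationError):
                skipped += 1
    if skipped:
        logger.warning("skipped %d malformed records in %s", skipped, path.name)
    if len(gs) == 0:
        raise AnnotationError(f"no valid records in {path}")
    return gs


def write_annotation(gs: GeneSet, path: str | Path) -> None:
    """Write a curated GeneSet as BED12 (round-trips bit-exactly)."""
    with open(path, "w") as fh:
        for g in gs:
            lo, hi = g.span
            ex = g.exons or ((lo, hi),)
            sizes = ",".join(str(e - s) for s, e in ex) + ","
            offsets = ",".join(str(s - lo) for s, e in ex) + ","
            fh.write(
                f"{g.chrom}\t{lo}\t{hi}\t{g.gene_id}\t0\t{g.strand}\t{lo}\t{hi}"
                f"\t0\t{len(ex)}\t{sizes}\t{offsets}\n"
            )


def write_gene_table(gs: GeneSet, path: str | Path) -> None:
    """TSV summary: gene_id, chrom, strand, tss, tts, length, n_exons."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\ttts\tlength\tn_exons\n")
        for g in gs:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tts}"
                f"\t{g.length}\t{len(g.exons)}\n"
            )


def keep_longest_transcript(gs: GeneSet, gene_key: Mapping[str, str]) -> GeneSet:
    """Keep one model per gene: the longest transcript.

    ``gene_key`` maps transcript id -> gene id.  Ties in length are broken by
    the lexicographically smallest transcript id, so the result is
    deterministic and the operation idempotent.
    """
    if not gene_key:
        raise AnnotationError("empty transcript->gene mapping")
    best: dict[str, GeneModel] = {}
    for tid, g in gs.genes.items():
        try:
            gid = gene_key[tid]
        except KeyError:
            raise AnnotationError(f"transcript {tid} missing from gene_key") from None
        cur = best.get(gid)
        if cur is None or g.length > cur.length or (
            g.length == cur.length and g.gene_id < cur.gene_id
        ):
            best[gid] = g
    out = GeneSet(provenance=gs.provenance + " | longest transcript per gene")
    for g in sorted(best.values(), key=lambda x: x.gene_id):
        out.add(g)
    return out


def window(
    g: GeneModel,
    anchor: str,
    upstream: int,
    downstream: int,
) -> tuple[int, int, bool]:
    """Half-open genomic interval around the TSS or TTS, strand-aware.

    ``upstream``/``downstream`` are measured in transcription direction: for a
    minus-strand gene upstream extends toward larger genomic coordinates.
    Returns ``(start, end, clipped)``; intervals extending below position 0
    are clipped at 0 and flagged.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if anchor not in ("TSS", "TTS"):
        raise ValueError(f"anchor must be TSS or TTS, got {anchor!r}")
    pos = g.tss if anchor == "TSS" else g.tts
    if g.strand == "+":
        start, end = pos - upstream, pos + downstream
    else:
        start, end = pos - downstream, pos + upstream
    clipped = start < 0
    return (max(0, start), max(0, end), clipped)


def gene_body(g: GeneModel) -> tuple[int, int]:
    """The gene body interval, identical to window(TSS, 0, length)."""
    s, e, _ = window(g, "TSS", 0, g.length)
    return (s, e)
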