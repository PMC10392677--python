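"""Genomic-interval site selection: promoters with overlapping ChIP-seq
peaks near a TSS, intersected with CpG methylation tracks, and assembly of
the simulated model region.

Coordinates are 1-based inclusive internally (a 49-bp region spans
start..end with end - start + 1 = 49); BED I/O converts to and from the
0-based half-open convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .core_io import FormatError


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, inclusive genomic interval with optional strand/score."""

    chromosome: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None   # e.g. methylation rate in percent
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chromosome == other.chromosome
                and self.start <= other.end and other.start <= self.end)

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open on disk <-> 1-based inclusive in memory)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: BED line needs >= 3 columns")
        try:
            start0, end0 = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
        if end0 <= start0:
            raise FormatError(f"{path}:{ln}: empty or inverted interval")
        name = parts[3] if len(parts) > 3 else ""
        score = None
        if len(parts) > 4 and parts[4] not in (".", ""):
            try:
                score = float(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric score") from exc
        strand = parts[5] if len(parts) > 5 else "."
        intervals.append(GenomicInterval(parts[0], start0 + 1, end0,
                                         strand=strand, score=score, name=name))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              scores: bool = False) -> None:
    lines = []
    for iv in intervals:
        cols = [iv.chromosome, str(iv.start - 1), str(iv.end)]
        if scores or iv.strand != ".":
            cols.append(iv.name or ".")
            cols.append(str(iv.score) if iv.score is not None else ".")
            cols.append(iv.strand)
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Site-selection filters
# ---------------------------------------------------------------------------

@dataclass
class Promoter:
    """A TSS-centred window together with its supporting evidence."""

    tss: GenomicInterval
    window: GenomicInterval
    peak_tracks_hit: int = 0
    cpg_count: int = 0
    mean_methylation: float | None = None
    cpg_sites: list[GenomicInterval] = field(default_factory=list)


def promoters_with_peaks(
    tss: Sequence[GenomicInterval],
    peak_tracks: Sequence[Sequence[GenomicInterval]],
    window: int = 200,
    min_tracks: int = 2,
) -> list[Promoter]:
    """Promoters (TSS +/- ``window``) overlapped by >= ``min_tracks`` distinct
    ChIP-seq peak tracks.

    Overlap is inclusive on both boundaries.  The window is symmetric
    around the TSS.
    """
    trees: dict[tuple[int, str], IntervalTree] = {}
    for k, track in enumerate(peak_tracks):
        for peak in track:
            # IntervalTree is half-open; shift end by +1 for inclusive ends
            trees.setdefault((k, peak.chromosome), IntervalTree()) \
                .addi(peak.start, peak.end + 1, peak)
    out = []
    for t in tss:
        w = GenomicInterval(t.chromosome, max(1, t.start - window),
                            t.end + window, strand=t.strand)
        hits = sum(
            1 for k in range(len(peak_tracks))
            if (k, t.chromosome) in trees
            and trees[(k, t.chromosome)].overlap(w.start, w.end + 1))
        if hits >= min_tracks:
            out.append(Promoter(tss=t, window=w, peak_tracks_hit=hits))
    return out


def intersect_methylation(
    promoters: Sequence[Promoter],
    cpg_sites: Sequence[GenomicInterval],
    window: int | None = None,
) -> list[Promoter]:
    """Annotate promoters with CpG-site counts and mean methylation rate.

    Sites are counted inside the promoter window (inclusive boundaries); a
    different ``window`` around the TSS may be given, e.g. 500 bp for the
    promoter-wide methylation census.
    """
    tree: dict[str, IntervalTree] = {}
    for s in cpg_sites:
        tree.setdefault(s.chromosome, IntervalTree()) \
            .addi(s.start, s.end + 1, s)
    out = []
    for p in promoters:
        if window is None:
            w = p.window
        else:
            w = GenomicInterval(p.tss.chromosome,
                                max(1, p.tss.start - window),
                                p.tss.end + window)
        found = ([iv.data for iv in tree[w.chromosome].overlap(w.start, w.end + 1)]
                 if w.chromosome in tree else [])
        found.sort(key=lambda s: s.start)
        rates = [s.score for s in found if s.score is not None]
        q = Promoter(tss=p.tss, window=p.window,
                     peak_tracks_hit=p.peak_tracks_hit,
                     cpg_count=len(found),
                     mean_methylation=(sum(rates) / len(rates)) if rates else None,
                     cpg_sites=found)
        out.append(q)
    return out


# ---------------------------------------------------------------------------
# Model-region assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelRegion:
    """The simulated duplex: 1..L bp numbering with RE and ME annotation."""

    interval: GenomicInterval
    re_positions: dict[str, tuple[int, int]]          # name -> (bp_start, bp_end)
    methylation: tuple[tuple[int, str], ...] = ()     # (bp, "single"|"double")
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def n_methylcytosines(self) -> int:
        return sum(2 if kind == "double" else 1 for _, kind in self.methylation)

    def to_fasta(self, path: str | Path, name: str = "model_region") -> None:
        if self.sequence is None:
            raise ValueError("model region carries no sequence")
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO
        SeqIO.write([SeqRecord(Seq(self.sequence), id=name, description="")],
                    str(path), "fasta")


def assemble_model_region(
    interval: GenomicInterval,
    re_annotations: Sequence[tuple[str, int, int]],
    flank: int = 0,
    methylation_sites: Sequence[int] = (),
    sequence: str | None = None,
) -> ModelRegion:
    """Build the bp-numbered model duplex from a genomic interval.

    ``re_annotations`` are (name, absolute start, absolute end) response
    elements that must lie inside ``interval``; the model region is the
    interval extended by ``flank`` bp on both sides, renumbered 1..L.
    Adjacent methylation sites (positions p, p+1 — the two cytosines of a
    CpG) merge into one "double" mark; isolated sites are "single" marks.
    """
    for name, s, e in re_annotations:
        if s < interval.start or e > interval.end:
            raise ValueError(f"RE {name!r} ({s}-{e}) outside interval "
                             f"{interval.start}-{interval.end}")
    start = interval.start - flank
    end = interval.end + flank
    model = GenomicInterval(interval.chromosome, start, end,
                            strand=interval.strand)
    res = {name: (s - start + 1, e - start + 1) for name, s, e in re_annotations}

    marks: list[tuple[int, str]] = []
    sites = sorted(set(methylation_sites))
    i = 0
    while i < len(sites):
        p = sites[i]
        if not model.contains_point(p):
            i += 1
            continue
        if i + 1 < len(sites) and sites[i + 1] == p + 1:
            marks.append((p - start + 1, "double"))
            i += 2
        else:
            marks.append((p - start + 1, "single"))
            i += 1

    if sequence is not None and len(sequence) != model.length:
        raise ValueError("sequence length does not match model region")
    return ModelRegion(interval=model, re_positions=res,
                       methylation=tuple(marks), sequence=sequence)
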