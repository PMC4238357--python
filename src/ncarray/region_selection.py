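"""Selection of oligo target regions from RNA-Seq coverage contigs.

A *coverage contig* is an assembled stack of sequencing reads defining a
candidate ncRNA locus together with a per-base read-coverage profile.  Probe
regions are chosen from these profiles:

* short contigs (< 70 nt) receive exactly one signal region of 18-30 nt,
  placed where mean coverage is highest;
* longer contigs are tiled with non-overlapping 30-nt windows anchored at
  offset 0, and every window whose mean coverage exceeds the contig-wide
  mean ("elevated" coverage) becomes a signal region (falling back to the
  single best window when coverage is flat);
* per contig, one low-coverage window (mean below one-third of the single-base
  maximum) may additionally be selected as a control/precursor region --
  high coverage flanked by low coverage is the signature of a processed
  ncRNA excised from a longer precursor.

Candidate loci must be supported by a minimum number of reads (default 5)
to be considered at all.

Coordinates are 0-based half-open throughout.  Offsets within a contig are
transcript-sense (5'->3' of the RNA): minus-strand inputs have their sequence
reverse-complemented and their coverage vector reversed on read, so
``coverage[0]`` always refers to the transcript 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from pyfaidx import Fasta

from ._seq import revcomp_dna

__all__ = [
    "CoverageContig",
    "ProbeRegion",
    "SelectionConfig",
    "read_contigs",
    "filter_min_reads",
    "filter_candidate_ids",
    "select_signal_regions",
    "select_control_region",
    "select_regions",
    "write_region_table",
]

BIOTYPES = ("snoRNA", "miRNA", "tRF", "other", "unknown", "prediction")


@dataclass
class CoverageContig:
    """A genomic interval with strand, sequence and per-base read coverage."""

    contig_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    coverage: np.ndarray
    read_count: int = 0
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.end - self.start <= 0:
            raise ValueError(f"contig {self.contig_id}: empty interval")
        if len(self.coverage) != self.end - self.start:
            raise ValueError(
                f"contig {self.contig_id}: coverage length {len(self.coverage)} "
                f"!= interval length {self.end - self.start}"
            )
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"contig {self.contig_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start}"
            )
        if self.strand not in "+-":
            raise ValueError(f"contig {self.contig_id}: strand must be '+' or '-'")
        if self.read_count < 0:
            raise ValueError(f"contig {self.contig_id}: negative read_count")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProbeRegion:
    """A window within a contig earmarked for oligo design.

    ``kind`` is ``"signal"`` for expression probes, ``"control"`` for the
    low-coverage control/precursor region.  ``coverage_ratio`` is the window
    mean divided by the contig's single-base maximum coverage.
    """

    contig_id: str
    offset: int
    length: int
    kind: str
    mean_coverage: float
    coverage_ratio: float

    def overlaps(self, other: "ProbeRegion") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.offset < other.offset + other.length
            and other.offset < self.offset + self.length
        )


@dataclass
class SelectionConfig:
    """Tunable thresholds for region selection (defaults are the platform's)."""

    min_reads: int = 5
    short_contig_cutoff: int = 70
    tiling_interval: int = 30
    control_ratio: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.min_reads, self.short_contig_cutoff, self.tiling_interval) < 0:
            raise ValueError("SelectionConfig fields must be non-negative")
        if not (0.0 < self.control_ratio < 1.0):
            raise ValueError("control_ratio must lie in (0, 1)")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_bed6(path: str | Path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED line {lineno}: expected 6 columns, got {len(fields)}")
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
                score_i = 0 if score in (".", "") else int(float(score))
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: {exc}") from exc
            rows.append((chrom, start_i, end_i, name, score_i, strand))
    return rows


def _parse_bedgraph(path: str | Path):
    """chrom -> (starts, ends, values) arrays, sorted by start."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"malformed bedGraph line {lineno}: expected 4 columns, got {len(fields)}"
                )
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"malformed bedGraph line {lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"malformed bedGraph line {lineno}: end <= start")
            per_chrom.setdefault(fields[0], []).append((start, end, value))
    out = {}
    for chrom, entries in per_chrom.items():
        entries.sort()
        starts = np.array([e[0] for e in entries])
        ends = np.array([e[1] for e in entries])
        values = np.array([e[2] for e in entries])
        out[chrom] = (starts, ends, values)
    return out


def read_contigs(
    bed_path: str | Path,
    bedgraph_path: str | Path,
    fasta_path: str | Path,
) -> list[CoverageContig]:
    """Assemble :class:`CoverageContig` objects from BED6 + bedGraph + FASTA.

    The BED ``name`` field is the contig ID, optionally suffixed with
    ``|<biotype>``; the ``score`` field carries the supporting read count.
    FASTA records are genome-strand sequences keyed by contig ID.  Bases not
    covered by any bedGraph interval get coverage 0.  Minus-strand contigs
    are flipped to transcript sense (sequence reverse-complemented, coverage
    reversed).
    """
    bed = _parse_bed6(bed_path)
    cov = _parse_bedgraph(bedgraph_path)
    fasta = Fasta(str(fasta_path), as_raw=True, rebuild=False)

    contigs = []
    for chrom, start, end, name, score, strand in bed:
        contig_id, _, biotype = name.partition("|")
        biotype = biotype or "unknown"
        if contig_id not in fasta:
            raise ValueError(f"contig {contig_id}: no FASTA record")
        seq = str(fasta[contig_id][:]).upper()
        if len(seq) != end - start:
            raise ValueError(
                f"contig {contig_id}: FASTA length {len(seq)} != BED length {end - start}"
            )
        coverage = np.zeros(end - start)
        if chrom in cov:
            starts, ends, values = cov[chrom]
            lo = np.searchsorted(ends, start, side="right")
            hi = np.searchsorted(starts, end, side="left")
            for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
                a, b = max(s, start), min(e, end)
                if a < b:
                    coverage[a - start : b - start] = v
        if strand == "-":
            seq = revcomp_dna(seq)
            coverage = coverage[::-1].copy()
        contigs.append(
            CoverageContig(
                contig_id=contig_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                sequence=seq,
                coverage=coverage,
                read_count=score,
                biotype=biotype,
            )
        )
    return contigs


# ---------------------------------------------------------------------------
# Filtering & selection
# ---------------------------------------------------------------------------

def filter_min_reads(
    contigs: Iterable[CoverageContig], config: SelectionConfig | None = None
) -> list[CoverageContig]:
    """Keep contigs supported by at least ``config.min_reads`` reads (order preserved)."""
    config = config or SelectionConfig()
    return [c for c in contigs if c.read_count >= config.min_reads]


def filter_candidate_ids(
    contigs: Iterable[CoverageContig], keep_ids: Iterable[str]
) -> list[CoverageContig]:
    """Optional pre-filter hook: restrict to an externally supplied candidate list.

    Used when an additional selection criterion (e.g. expression changes during
    stem-cell differentiation) has been evaluated outside this package and is
    available as a plain list of contig IDs.
    """
    keep = set(keep_ids)
    return [c for c in contigs if c.contig_id in keep]


def _window_means(coverage: np.ndarray, length: int) -> np.ndarray:
    """Mean coverage of every sliding window of the given length."""
    csum = np.concatenate([[0.0], np.cumsum(coverage)])
    return (csum[length:] - csum[:-length]) / length


def _grid_windows(contig_len: int, interval: int, min_len: int = 18):
    """(offset, length) of tiling windows at offsets 0, interval, 2*interval, ...

    The last partial window is dropped when shorter than ``min_len``.
    """
    windows = []
    for offset in range(0, contig_len, interval):
        length = min(interval, contig_len - offset)
        if length >= min_len:
            windows.append((offset, length))
    return windows


def _region(contig: CoverageContig, offset: int, length: int, kind: str) -> ProbeRegion:
    mean_cov = float(np.mean(contig.coverage[offset : offset + length]))
    max_cov = float(np.max(contig.coverage)) if contig.length else 0.0
    ratio = mean_cov / max_cov if max_cov > 0 else 0.0
    return ProbeRegion(contig.contig_id, offset, length, kind, mean_cov, ratio)


def select_signal_regions(
    contig: CoverageContig, config: SelectionConfig | None = None
) -> list[ProbeRegion]:
    """Pick the signal (expression-probe) regions of one contig.

    Short contigs yield the single best window; long contigs yield every
    tiling window with above-average coverage (or the best window if none
    is elevated).  Ties break leftmost.  Returned regions never overlap.
    """
    config = config or SelectionConfig()
    if contig.length < 18:
        raise ValueError(f"contig {contig.contig_id} too short for probe design")

    if contig.length < config.short_contig_cutoff:
        wlen = min(25, contig.length)  # already >= 18, <= 30 by construction
        means = _window_means(contig.coverage, wlen)
        best = int(np.argmax(means))  # argmax returns the first (leftmost) maximum
        return [_region(contig, best, wlen, "signal")]

    windows = _grid_windows(contig.length, config.tiling_interval)
    overall_mean = float(np.mean(contig.coverage))
    scored = [(off, ln, float(np.mean(contig.coverage[off : off + ln]))) for off, ln in windows]
    elevated = [(off, ln) for off, ln, m in scored if m > overall_mean]
    if not elevated:
        best_off, best_ln, _ = max(scored, key=lambda t: (t[2], -t[0]))
        elevated = [(best_off, best_ln)]
    return [_region(contig, off, ln, "signal") for off, ln in elevated]


def select_control_region(
    contig: CoverageContig,
    config: SelectionConfig | None = None,
    signal_regions: Sequence[ProbeRegion] = (),
) -> Optional[ProbeRegion]:
    """Pick the low-coverage control/precursor region of one contig, if any.

    Among tiling-grid windows, the one with lowest mean coverage qualifies
    when its mean is strictly below ``control_ratio`` times the contig's
    single-base maximum coverage and it does not overlap any signal region;
    otherwise no control region is returned.
    """
    config = config or SelectionConfig()
    if contig.length < config.tiling_interval:
        return None
    windows = _grid_windows(contig.length, config.tiling_interval)
    if not windows:
        return None
    scored = [(float(np.mean(contig.coverage[off : off + ln])), off, ln) for off, ln in windows]
    mean_cov, offset, length = min(scored, key=lambda t: (t[0], t[1]))
    if mean_cov >= config.control_ratio * float(np.max(contig.coverage)):
        return None
    candidate = _region(contig, offset, length, "control")
    if any(candidate.overlaps(r) for r in signal_regions):
        return None
    return candidate


def select_regions(
    contig: CoverageContig, config: SelectionConfig | None = None
) -> list[ProbeRegion]:
    """Signal regions plus the control region (when one qualifies)."""
    config = config or SelectionConfig()
    signal = select_signal_regions(contig, config)
    control = select_control_region(contig, config, signal)
    return signal + ([control] if control else [])


def write_region_table(regions: Iterable[ProbeRegion], path: str | Path) -> None:
    """Tab-separated region table (one row per region)."""
    with open(path, "w") as fh:
        fh.write("contig_id\toffset\tlength\tkind\tmean_coverage\tcoverage_ratio\n")
        for r in regions:
            fh.write(
                f"{r.contig_id}\t{r.offset}\t{r.length}\t{r.kind}\t"
                f"{r.mean_coverage:.6g}\t{r.coverage_ratio:.6g}\n"
            )
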