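"""Genomic-region classification and conservation-based filtering.

Binding-site statistics are calibrated separately for six classes of
regulatory sequence: intronic regions flanking splice sites, internal exons,
5' and 3' UTR exons, non-coding RNAs, and mid-intron/intergenic sequence.
A :class:`RegionAnnotation` holds the interval sets needed to place any
genomic position into exactly one class; a :class:`ConservationTrack` holds
per-base conservation values (phyloP/phastCons semantics) used to discard
mid-intron/intergenic sites that fall in non-conserved sequence.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

REGION_CLASSES = (
    "splice_flank",
    "internal_exon",
    "utr5_exon",
    "utr3_exon",
    "ncRNA",
    "mid_intron_intergenic",
)

MAX_QUERY_INTERVAL = 10_000
DEFAULT_FLANK_NT = 100
DEFAULT_ENVIRONMENT_NT = 50


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


class _IntervalSet:
    """Sorted, merged intervals per chromosome with fast point queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self.ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self.starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < self.ends[chrom][i]

    def edge_distance(self, chrom: str, pos: int) -> float:
        """Distance from pos to the nearest interval boundary base.

        For a position just past an interval end the distance is 1; inside an
        interval the distance is 0.
        """
        starts = self.starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.inf
        ends = self.ends[chrom]
        if self.contains(chrom, pos):
            return 0.0
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        d_prev = pos - (ends[i] - 1) if i >= 0 else np.inf
        d_next = starts[i + 1] - pos if i + 1 < len(starts) else np.inf
        return float(min(d_prev, d_next))

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        if chrom not in self.starts:
            return []
        return list(zip(self.starts[chrom].tolist(), self.ends[chrom].tolist()))

    def chroms(self) -> list[str]:
        return sorted(self.starts)


@dataclass
class RegionAnnotation:
    """Interval sets classifying genomic positions into region classes.

    ``exons`` holds internal (coding) exons; UTR exons and ncRNA transcripts
    are separate sets; ``gene_bounds`` spans whole gene loci (introns are the
    in-gene complement of the exon sets).
    """

    exons: _IntervalSet = field(default_factory=_IntervalSet)
    utr5_exons: _IntervalSet = field(default_factory=_IntervalSet)
    utr3_exons: _IntervalSet = field(default_factory=_IntervalSet)
    ncRNA_intervals: _IntervalSet = field(default_factory=_IntervalSet)
    gene_bounds: _IntervalSet = field(default_factory=_IntervalSet)

    @classmethod
    def from_interval_lists(
        cls,
        exons=(),
        utr5_exons=(),
        utr3_exons=(),
        ncRNA=(),
        gene_bounds=(),
    ) -> "RegionAnnotation":
        return cls(
            exons=_IntervalSet(exons),
            utr5_exons=_IntervalSet(utr5_exons),
            utr3_exons=_IntervalSet(utr3_exons),
            ncRNA_intervals=_IntervalSet(ncRNA),
            gene_bounds=_IntervalSet(gene_bounds),
        )

    def all_exon_set(self) -> _IntervalSet:
        cached = getattr(self, "_all_exon_cache", None)
        if cached is None:
            ivs = []
            for s in (self.exons, self.utr5_exons, self.utr3_exons):
                for chrom in s.chroms():
                    ivs.extend((chrom, a, b) for a, b in s.intervals(chrom))
            cached = _IntervalSet(ivs)
            object.__setattr__(self, "_all_exon_cache", cached)
        return cached

    @classmethod
    def from_bed(cls, stream) -> "RegionAnnotation":
        """Read a labeled BED file: chrom, start, end, class-label[, ...].

        Labels: exon | utr5 | utr3 | ncRNA | gene.
        """
        buckets: dict[str, list[tuple[str, int, int]]] = {
            "exon": [], "utr5": [], "utr3": [], "ncRNA": [], "gene": [],
        }
        for ln in stream:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 4:
                raise ValueError(f"annotation BED line needs 4 fields: {ln!r}")
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if label not in buckets:
                raise ValueError(f"unknown region label {label!r}")
            buckets[label].append((chrom, start, end))
        return cls.from_interval_lists(
            exons=buckets["exon"],
            utr5_exons=buckets["utr5"],
            utr3_exons=buckets["utr3"],
            ncRNA=buckets["ncRNA"],
            gene_bounds=buckets["gene"],
        )


def classify(
    annotation: RegionAnnotation,
    site_interval: GenomicInterval,
    flank_nt: int = DEFAULT_FLANK_NT,
) -> str:
    """Region class of a site, judged at its midpoint.

    Priority when several annotations overlap: ncRNA > 5'UTR exon > 3'UTR
    exon > internal exon > splice flank > mid-intron/intergenic.  A splice
    flank is an intronic midpoint within ``flank_nt`` of an annotated exon
    edge; positions outside any gene are mid-intron/intergenic.  An
    unannotated chromosome classifies as mid-intron/intergenic with a
    warning.
    """
    chrom, mid = site_interval.chrom, site_interval.midpoint
    known = set()
    for s in (annotation.exons, annotation.utr5_exons, annotation.utr3_exons,
              annotation.ncRNA_intervals, annotation.gene_bounds):
        known.update(s.chroms())
    if chrom not in known:
        warnings.warn(f"chromosome {chrom!r} absent from annotation", stacklevel=2)
        return "mid_intron_intergenic"
    if annotation.ncRNA_intervals.contains(chrom, mid):
        return "ncRNA"
    if annotation.utr5_exons.contains(chrom, mid):
        return "utr5_exon"
    if annotation.utr3_exons.contains(chrom, mid):
        return "utr3_exon"
    if annotation.exons.contains(chrom, mid):
        return "internal_exon"
    if annotation.gene_bounds.contains(chrom, mid):
        if annotation.all_exon_set().edge_distance(chrom, mid) <= flank_nt:
            return "splice_flank"
        return "mid_intron_intergenic"
    return "mid_intron_intergenic"


class ConservationTrack:
    """Sparse per-base conservation scores stored as value intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]] = ()):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if end <= start:
                raise ValueError("empty track interval")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping track intervals on {chrom}")
            self._starts[chrom] = np.array([iv[0] for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv[1] for iv in ivs], dtype=np.int64)
            self._values[chrom] = np.array([iv[2] for iv in ivs])

    @classmethod
    def from_bedgraph(cls, stream) -> "ConservationTrack":
        ivs = []
        for ln in stream:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = ln.split()[:4]
            ivs.append((chrom, int(start), int(end), float(value)))
        return cls(ivs)

    @classmethod
    def from_wiggle(cls, stream) -> "ConservationTrack":
        """Read fixedStep wiggle (the UCSC conservation-table dump format)."""
        ivs = []
        chrom, pos, step, span = None, 0, 1, 1
        for ln in stream:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            if ln.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in ln.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                continue
            if chrom is None:
                raise ValueError("wiggle data before any fixedStep header")
            ivs.append((chrom, pos, pos + span, float(ln)))
            pos += step
        return cls(ivs)

    def coverage_sum(self, chrom: str, start: int, end: int) -> tuple[int, float]:
        """(covered position count, value sum) over [start, end)."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0, 0.0
        ends, values = self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        count, total = 0, 0.0
        for i in range(lo, hi):
            ov = min(end, ends[i]) - max(start, starts[i])
            if ov > 0:
                count += ov
                total += ov * values[i]
        return count, total


def mean_conservation(
    track: ConservationTrack,
    site_interval: GenomicInterval,
    environment_nt: int = DEFAULT_ENVIRONMENT_NT,
) -> float | None:
    """Mean conservation over the site's environment, or None if undercovered.

    The environment is the site interval extended symmetrically to a total
    width of ``environment_nt`` (sites already wider keep their own width).
    Positions without track data are ignored; if fewer than half the
    environment positions are covered, no-data (None) is returned.
    """
    width = len(site_interval)
    ext = max(0, environment_nt - width)
    start = site_interval.start - ext // 2
    end = start + max(environment_nt, width)
    count, total = track.coverage_sum(site_interval.chrom, start, end)
    if count < 0.5 * (end - start):
        return None
    return total / count


def splice_flank_intervals(
    annotation: RegionAnnotation, flank_nt: int = DEFAULT_FLANK_NT
) -> list[tuple[str, int, int]]:
    """Intronic intervals within ``flank_nt`` of annotated exon edges."""
    exon_set = annotation.all_exon_set()
    out = []
    for chrom in exon_set.chroms():
        exons = exon_set.intervals(chrom)
        genes = annotation.gene_bounds
        for s, e in exons:
            for a, b in ((s - flank_nt, s), (e, e + flank_nt)):
                # clip to intronic sequence: inside a gene, outside all exons
                for p, q in _subtract(chrom, a, b, exon_set):
                    clipped = _intersect_gene(chrom, p, q, genes)
                    out.extend((chrom, x, y) for x, y in clipped)
    merged = _IntervalSet(out)
    return [(c, a, b) for c in merged.chroms() for a, b in merged.intervals(c)]


def _subtract(chrom, start, end, iset: _IntervalSet):
    """Yield sub-intervals of [start, end) not covered by the interval set."""
    cur = start
    for s, e in iset.intervals(chrom):
        if e <= cur or s >= end:
            continue
        if s > cur:
            yield cur, min(s, end)
        cur = max(cur, e)
        if cur >= end:
            return
    if cur < end:
        yield cur, end

def _intersect_gene(chrom, start, end, genes: _IntervalSet):
    for s, e in genes.intervals(chrom):
        a, b = max(start, s), min(end, e)
        if a < b:
            yield a, b


def intronic_reference_mean(
    track: ConservationTrack,
    annotation: RegionAnnotation,
    flank_nt: int = DEFAULT_FLANK_NT,
) -> float:
    """Pooled mean conservation over all splice-flank positions with data.

    This is the reference level against which mid-intron/intergenic sites
    are judged; raises if the track covers no splice-flank position.
    """
    count, total = 0, 0.0
    for chrom, start, end in splice_flank_intervals(annotation, flank_nt):
        c, t = track.coverage_sum(chrom, start, end)
        count += c
        total += t
    if count == 0:
        raise ValueError(
            "conservation track covers no splice-flank position; "
            "disable the conservation filter or supply a wider track"
        )
    return total / count


def conservation_filter(
    sites,
    track: ConservationTrack | None,
    reference: float | None,
    enabled: bool = True,
    environment_nt: int = DEFAULT_ENVIRONMENT_NT,
):
    """Drop non-conserved mid-intron/intergenic sites.

    A site in the mid-intron/intergenic class is removed iff the mean
    conservation of its environment is strictly below ``reference``.  Sites
    in every other class, sites without genomic coordinates or track
    coverage (no positive evidence of non-conservation), and all sites when
    the filter is disabled, are kept.  Each surviving site records whether
    the filter was evaluated for it (``conservation_passed``).
    """
    if not enabled:
        return list(sites)
    out = []
    for s in sites:
        if s.region_class != "mid_intron_intergenic":
            out.append(s)
            continue
        if track is None or reference is None or s.genomic_start is None or s.chrom is None:
            out.append(replace(s, conservation_passed=None))
            continue
        start0 = s.genomic_start - 1  # stored 1-based
        iv = GenomicInterval(s.chrom, start0, start0 + len(s.kmer))
        mean = mean_conservation(track, iv, environment_nt)
        if mean is None:
            out.append(replace(s, conservation_passed=None))
        elif mean < reference:
            continue
        else:
            out.append(replace(s, conservation_passed=True))
    return out
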