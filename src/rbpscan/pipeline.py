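"""Input reading, pipeline orchestration and output writing.

Queries arrive either as FASTA records or as BED-style genomic coordinates
plus a reference FASTA; both are normalized to :class:`QueryRecord` objects
carrying an RNA sequence and, when available, a genomic anchor used for
region classification, conservation filtering and BedGraph output.  Records
violating the input contract (length outside 21-10,000 nt, batch above
5,000 entries) are rejected individually with machine-readable reason codes
while the rest of the batch proceeds.

:func:`run_pipeline` drives the full per-record x per-motif chain — scan,
anchor selection, WR scoring, Z-test, region classification, conservation
filter — and returns the surviving sites plus a run report.  Outputs are a
TSV summary table (sites grouped by protein) and a BedGraph track file (one
track block per protein, each site at its first genomic position).
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .motifs import Motif
from .regions import (
    ConservationTrack,
    GenomicInterval,
    RegionAnnotation,
    classify,
    conservation_filter,
    intronic_reference_mean,
)
from .scanning import DEFAULT_STRINGENCY, FINAL_P, BackgroundModel, StringencyLevel, STRINGENCY
from .wr import WINDOW_NT, BindingSite, call_sites

MIN_QUERY_LEN = 21
MAX_QUERY_LEN = 10_000
MAX_BATCH = 5_000

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    return _to_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QueryRecord:
    """One validated query sequence."""

    id: str
    sequence: str  # RNA alphabet
    anchor: GenomicInterval | None = None
    source: str = "fasta"


@dataclass(frozen=True)
class Rejection:
    record_id: str
    reason: str  # machine-readable code
    detail: str = ""


def _validate_length(seq_id: str, seq: str) -> Rejection | None:
    if len(seq) < MIN_QUERY_LEN:
        return Rejection(seq_id, "too_short", f"{len(seq)} < {MIN_QUERY_LEN}")
    if len(seq) > MAX_QUERY_LEN:
        return Rejection(seq_id, "too_long", f"{len(seq)} > {MAX_QUERY_LEN}")
    return None


def read_fasta(stream) -> tuple[list[QueryRecord], list[Rejection]]:
    """Read query records from FASTA, applying the input contract.

    Length violations and records beyond the batch cap are rejected
    per-record; duplicate ids are disambiguated with numeric suffixes.
    Raises if no record survives.
    """
    records: list[QueryRecord] = []
    rejections: list[Rejection] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(stream, "fasta"):
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}_{seen[rid]}"
            warnings.warn(f"duplicate FASTA id {rid!r} renamed to {new_id!r}")
            rid = new_id
        else:
            seen[rid] = 1
        seq = _to_rna(str(rec.seq))
        bad = _validate_length(rid, seq)
        if bad is not None:
            rejections.append(bad)
            continue
        if len(records) >= MAX_BATCH:
            rejections.append(Rejection(rid, "batch_limit", f"batch cap {MAX_BATCH}"))
            continue
        records.append(QueryRecord(id=rid, sequence=seq, source="fasta"))
    if not records:
        raise ValueError("no valid query records in FASTA input")
    return records, rejections


def read_coordinates(stream, reference) -> tuple[list[QueryRecord], list[Rejection]]:
    """Read BED-style coordinate queries against a reference FASTA.

    ``reference`` is a path/stream of chromosome FASTA or a mapping
    chrom -> sequence.  Minus-strand records are reverse-complemented to the
    sense (RNA) strand; the genomic anchor is retained for output
    coordinates.
    """
    if not isinstance(reference, dict):
        reference = {r.id: str(r.seq) for r in SeqIO.parse(reference, "fasta")}
    records: list[QueryRecord] = []
    rejections: list[Rejection] = []
    n_line = 0
    for ln in stream:
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        n_line += 1
        parts = ln.split("\t")
        if len(parts) < 3:
            rejections.append(Rejection(f"line{n_line}", "malformed", ln[:60]))
            continue
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        except ValueError:
            rejections.append(Rejection(f"line{n_line}", "malformed", ln[:60]))
            continue
        name = parts[3] if len(parts) > 3 and parts[3] != "." else f"{chrom}:{start}-{end}"
        strand = parts[5] if len(parts) > 5 else "+"
        if end <= start:
            rejections.append(Rejection(name, "empty_interval", f"{start}>={end}"))
            continue
        if chrom not in reference:
            rejections.append(Rejection(name, "unknown_chrom", chrom))
            continue
        if start < 0 or end > len(reference[chrom]):
            rejections.append(Rejection(name, "out_of_reference", f"{chrom}:{start}-{end}"))
            continue
        seq = _to_rna(reference[chrom][start:end])
        if strand == "-":
            seq = reverse_complement(seq)
        bad = _validate_length(name, seq)
        if bad is not None:
            rejections.append(bad)
            continue
        if len(records) >= MAX_BATCH:
            rejections.append(Rejection(name, "batch_limit", f"batch cap {MAX_BATCH}"))
            continue
        records.append(
            QueryRecord(
                id=name,
                sequence=seq,
                anchor=GenomicInterval(chrom, start, end, strand),
                source="coordinates",
            )
        )
    if not records:
        raise ValueError("no valid query records in coordinate input")
    return records, rejections


@dataclass
class RunConfig:
    """Run-level knobs of the site-calling pipeline."""

    stringency: StringencyLevel = DEFAULT_STRINGENCY
    conservation_enabled: bool = True
    mode: str = "database-genome"
    window_nt: int = WINDOW_NT
    final_p: float = FINAL_P
    flank_nt: int = 100
    environment_nt: int = 50
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.stringency, str):
            self.stringency = STRINGENCY[self.stringency]
        if not (0 < self.final_p < 1):
            raise ValueError("final_p must be in (0, 1)")


@dataclass
class RunReport:
    n_records: int = 0
    n_rejected: int = 0
    n_windows: int = 0
    n_anchors: int = 0
    n_sites: int = 0
    n_conservation_removed: int = 0
    rejections: list = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["rejections"] = [r.__dict__ for r in self.rejections]
        return json.dumps(d, indent=1)


@dataclass
class RunResult:
    sites_by_record: dict[str, list[BindingSite]]
    report: RunReport

    @property
    def sites(self) -> list[BindingSite]:
        return [s for sites in self.sites_by_record.values() for s in sites]


def _genomic_window_start(anchor: GenomicInterval, offset: int, k: int) -> int:
    """0-based genomic start of the window at sequence offset (5'-most base)."""
    if anchor.strand == "-":
        return anchor.end - offset - k
    return anchor.start + offset


def run_pipeline(
    records: list[QueryRecord],
    motifs: list[Motif],
    config: RunConfig,
    backgrounds: dict[str, dict[str, BackgroundModel]] | None = None,
    annotation: RegionAnnotation | None = None,
    track: ConservationTrack | None = None,
    rejections: list[Rejection] | None = None,
) -> RunResult:
    """Run the full site-calling chain for every record x motif pair.

    ``backgrounds`` maps motif id -> region class -> background model
    (required in database-genome mode).  Conservation filtering needs both
    ``annotation`` (to derive the intronic reference level) and ``track``.
    """
    if not motifs:
        raise ValueError("no motifs selected")
    if config.mode == "database-genome" and backgrounds is None:
        raise ValueError("database-genome mode requires background models")

    reference_mean = None
    if config.conservation_enabled and track is not None and annotation is not None:
        reference_mean = intronic_reference_mean(track, annotation, config.flank_nt)

    report = RunReport(seed=config.seed, rejections=list(rejections or []))
    report.n_rejected = len(report.rejections)
    sites_by_record: dict[str, list[BindingSite]] = {}
    for rec in records:
        report.n_records += 1
        rec_sites: list[BindingSite] = []
        for m in motifs:
            k = m.length

            if rec.anchor is not None and annotation is not None:
                def classifier(offset: int, _rec=rec, _k=k) -> str:
                    gstart = _genomic_window_start(_rec.anchor, offset, _k)
                    return classify(
                        annotation,
                        GenomicInterval(_rec.anchor.chrom, gstart, gstart + _k),
                        config.flank_nt,
                    )
            else:
                classifier = lambda offset: "mid_intron_intergenic"

            stats: dict[str, int] = {}
            try:
                sites = call_sites(
                    rec.sequence,
                    m,
                    backgrounds=backgrounds.get(m.id) if backgrounds else None,
                    stringency=config.stringency,
                    region_classifier=classifier,
                    mode=config.mode,
                    seq_id=rec.id,
                    window_nt=config.window_nt,
                    final_p=config.final_p,
                    base_freqs=config.base_freqs,
                    stats=stats,
                )
            except KeyError as exc:
                raise RuntimeError(
                    f"record {rec.id!r}, motif {m.id!r}: {exc.args[0]}"
                ) from exc
            report.n_windows += stats.get("windows", 0)
            report.n_anchors += stats.get("anchors", 0)
            if rec.anchor is not None:
                sites = [
                    replace(
                        s,
                        chrom=rec.anchor.chrom,
                        genomic_start=_genomic_window_start(rec.anchor, s.anchor_offset, k) + 1,
                    )
                    for s in sites
                ]
            rec_sites.extend(sites)
        n_before = len(rec_sites)
        rec_sites = conservation_filter(
            rec_sites,
            track,
            reference_mean,
            enabled=config.conservation_enabled,
            environment_nt=config.environment_nt,
        )
        report.n_conservation_removed += n_before - len(rec_sites)
        report.n_sites += len(rec_sites)
        sites_by_record[rec.id] = sorted(
            rec_sites, key=lambda s: (s.anchor_offset, s.motif_id)
        )
    return RunResult(sites_by_record=sites_by_record, report=report)


def write_summary(sites: list[BindingSite], stream, mode: str = "database-genome",
                  seed: int | None = None) -> None:
    """Write the TSV summary table, sites grouped by protein.

    Positions are 1-based in the human-readable table; genomic coordinates
    are ``chrom:pos`` (1-based first genomic position) or ``NA`` for records
    without a genomic anchor.
    """
    if seed is not None:
        stream.write(f"# seed={seed}\n")
    if mode == "other-genome":
        cols = ["seq_id", "position", "genomic_coordinate", "protein", "motif",
                "occurrence", "match_score", "wr_score", "wr_cutoff"]
    else:
        cols = ["seq_id", "position", "genomic_coordinate", "protein", "motif",
                "occurrence", "match_score", "wr_score", "z_score", "p_value"]
    stream.write("\t".join(cols) + "\n")
    by_protein: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_protein.setdefault(s.protein, []).append(s)
    for protein in sorted(by_protein):
        rows = sorted(by_protein[protein], key=lambda s: (s.seq_id, s.anchor_offset, s.motif_id))
        for s in rows:
            coord = f"{s.chrom}:{s.genomic_start}" if s.genomic_start is not None else "NA"
            base = [s.seq_id, str(s.anchor_offset + 1), coord, s.protein, s.motif_id,
                    s.kmer, f"{s.match_score:.4f}", f"{s.wr_score:.4f}"]
            if mode == "other-genome":
                base.append(f"{s.wr_cutoff:.4f}" if s.wr_cutoff is not None else "NA")
            else:
                base.append(f"{s.z:.4f}" if s.z is not None else "NA")
                base.append(f"{s.p:.3e}" if s.p is not None else "NA")
            stream.write("\t".join(base) + "\n")


def write_bedgraph(sites: list[BindingSite], stream, seed: int | None = None) -> int:
    """Write one BedGraph track block per protein; returns lines written.

    Each site is reported at its first genomic position (0-based half-open
    single-base interval) with its WR score as the track value.  Sites
    without genomic anchors are skipped with a warning.
    """
    if seed is not None:
        stream.write(f"# seed={seed}\n")
    by_protein: dict[str, list[BindingSite]] = {}
    n_skipped = 0
    for s in sites:
        if s.genomic_start is None or s.chrom is None:
            n_skipped += 1
            continue
        by_protein.setdefault(s.protein, []).append(s)
    if n_skipped:
        warnings.warn(f"{n_skipped} site(s) without genomic anchors omitted from BedGraph")
    n = 0
    for protein in sorted(by_protein):
        stream.write(
            f'track type=bedGraph name="{protein}" description="predicted {protein} binding sites"\n'
        )
        rows = sorted(by_protein[protein], key=lambda s: (s.chrom, s.genomic_start))
        for s in rows:
            start0 = s.genomic_start - 1
            stream.write(f"{s.chrom}\t{start0}\t{start0 + 1}\t{s.wr_score:.4f}\n")
            n += 1
    return n
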