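"""Seeded synthetic data: background corpora, spiked binding sets, toy
gene models and conservation tracks.

Real background corpora are sampled from genomic regulatory regions; here
they are emulated as i.i.d. sequences whose base composition differs by
region class (exons GC-richer, 3' UTRs and intergenic sequence AU-richer,
splice flanks pyrimidine-rich), which reproduces the one property the
region-specific calibration actually consumes: region-dependent match-score
distributions.  "Strong binder" sets carry planted motif copies — an exact
consensus anchor, optionally flanked by one-mismatch suboptimal copies
within the clustering window — at a per-sequence rate; "weak binder" sets
are the same background with a low planting rate.  Every generated bundle
ships a ground-truth manifest and is byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .motifs import ALPHABET, Motif, _floor_matrix
from .regions import ConservationTrack, RegionAnnotation

#: per-region-class i.i.d. base compositions (A, C, G, U)
REGION_BASE_FREQS: dict[str, tuple[float, float, float, float]] = {
    "splice_flank": (0.20, 0.28, 0.17, 0.35),
    "internal_exon": (0.24, 0.26, 0.28, 0.22),
    "utr5_exon": (0.18, 0.30, 0.32, 0.20),
    "utr3_exon": (0.31, 0.19, 0.17, 0.33),
    "ncRNA": (0.25, 0.25, 0.25, 0.25),
    "mid_intron_intergenic": (0.29, 0.21, 0.21, 0.29),
}

#: background corpus defaults: sequences per region class and their length
BACKGROUND_N = 1000
BACKGROUND_LEN = 250

#: binding-set defaults: CLIP-like fragment length and planting rates
BINDING_SET_LEN = 100
STRONG_PLANT_RATE = 0.8
WEAK_PLANT_RATE = 0.05

_DEFAULT_MOTIF_ROWS = [
    # Fox-1-family-like UGCAUGU preference, softened into a realistic PSSM
    [0.05, 0.08, 0.07, 0.80],
    [0.10, 0.05, 0.75, 0.10],
    [0.08, 0.77, 0.08, 0.07],
    [0.80, 0.07, 0.06, 0.07],
    [0.06, 0.08, 0.08, 0.78],
    [0.10, 0.08, 0.72, 0.10],
    [0.12, 0.10, 0.08, 0.70],
]


def default_motif() -> Motif:
    """The bundled test motif: a 7-nt UGCAUGU-like PSSM."""
    raw = np.array(_DEFAULT_MOTIF_ROWS)
    raw = raw / raw.sum(axis=1, keepdims=True)
    return Motif(
        id="UGCAUGU_pssm",
        protein="FOX1_like",
        probs=_floor_matrix(raw),
        raw_probs=raw,
        origin="pssm",
    )


def random_sequences(rng: np.random.Generator, n: int, length: int, freqs) -> list[str]:
    """n i.i.d. RNA sequences of the given length and base composition."""
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()
    draws = rng.choice(4, size=(n, length), p=freqs)
    lut = np.array(list(ALPHABET))
    return ["".join(row) for row in lut[draws]]


def background_corpus(
    region_class: str,
    n: int = BACKGROUND_N,
    length: int = BACKGROUND_LEN,
    seed: int = 0,
) -> list[str]:
    """The background sequence set for one region class."""
    rng = np.random.default_rng([seed, _region_stream(region_class)])
    return random_sequences(rng, n, length, REGION_BASE_FREQS[region_class])


def _region_stream(region_class: str) -> int:
    # stable per-class RNG substream id
    return sorted(REGION_BASE_FREQS).index(region_class) + 1


def _mutate_one(rng: np.random.Generator, kmer: str) -> str:
    """One random substitution, guaranteed to change the base."""
    i = int(rng.integers(len(kmer)))
    alternatives = [b for b in ALPHABET if b != kmer[i]]
    return kmer[:i] + alternatives[int(rng.integers(3))] + kmer[i + 1 :]


@dataclass
class BindingSetManifest:
    """Ground truth of a spiked binding set."""

    plant_rate: float
    n_sequences: int
    planted: dict[str, list[int]] = field(default_factory=dict)  # seq_id -> anchor offsets
    suboptimal: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_planted(self) -> int:
        return sum(len(v) for v in self.planted.values())


def binding_set(
    m: Motif,
    n: int,
    plant_rate: float,
    length: int = BINDING_SET_LEN,
    n_suboptimal: int = 0,
    seed: int = 0,
    id_prefix: str = "seq",
) -> tuple[list[tuple[str, str]], BindingSetManifest]:
    """Generate a (possibly) motif-spiked sequence set with ground truth.

    Each sequence is intergenic-composition background; with probability
    ``plant_rate`` the motif's consensus (per-position argmax) is planted at
    a random offset, and ``n_suboptimal`` one-mismatch copies are planted at
    random distinct offsets within +/-25 nt of the anchor center.  Returns
    ``[(seq_id, sequence), ...]`` and the manifest of planted positions.
    """
    rng = np.random.default_rng([seed, 97])
    k = m.length
    consensus = m.best_kmer()
    seqs: list[tuple[str, str]] = []
    manifest = BindingSetManifest(plant_rate=plant_rate, n_sequences=n)
    bases = random_sequences(rng, n, length, REGION_BASE_FREQS["mid_intron_intergenic"])
    for i, base in enumerate(bases):
        sid = f"{id_prefix}{i:04d}"
        seq = list(base)
        if rng.random() < plant_rate:
            anchor_off = int(rng.integers(0, length - k + 1))
            seq[anchor_off : anchor_off + k] = consensus
            manifest.planted.setdefault(sid, []).append(anchor_off)
            placed = {anchor_off}
            for _ in range(n_suboptimal):
                lo = max(0, anchor_off - 25)
                hi = min(length - k, anchor_off + 25)
                for _attempt in range(20):
                    off = int(rng.integers(lo, hi + 1))
                    if all(abs(off - p) >= k for p in placed):
                        seq[off : off + k] = _mutate_one(rng, consensus)
                        manifest.suboptimal.setdefault(sid, []).append(off)
                        placed.add(off)
                        break
        seqs.append((sid, "".join(seq)))
    return seqs, manifest


@dataclass
class GeneModelFixture:
    """A toy single-chromosome gene model probing all six region classes."""

    chrom: str
    chrom_len: int
    annotation: RegionAnnotation
    #: hand-annotated truth: region class -> a genomic midpoint inside it
    probe_points: dict[str, int]
    annotation_bed: str  # serialized labeled BED


def toy_gene_model(chrom: str = "chrT", chrom_len: int = 10_000) -> GeneModelFixture:
    """A fixed toy locus: one coding gene, one ncRNA, intergenic flanks.

    Layout (0-based half-open):
      gene1   [1000, 5000): utr5 exon [1000,1200), internal exons
              [1800,1950) and [2600,2750), utr3 exon [4700,5000)
      ncgene  [6000, 6300): ncRNA transcript
    Splice flanks are the 100-nt intronic margins of every exon edge.
    """
    utr5 = [(chrom, 1000, 1200)]
    exons = [(chrom, 1800, 1950), (chrom, 2600, 2750)]
    utr3 = [(chrom, 4700, 5000)]
    nc = [(chrom, 6000, 6300)]
    genes = [(chrom, 1000, 5000), (chrom, 6000, 6300)]
    ann = RegionAnnotation.from_interval_lists(
        exons=exons, utr5_exons=utr5, utr3_exons=utr3, ncRNA=nc, gene_bounds=genes
    )
    probes = {
        "utr5_exon": 1100,
        "internal_exon": 1875,
        "utr3_exon": 4850,
        "ncRNA": 6150,
        "splice_flank": 1990,        # 40 nt past exon1 end (1950)
        "mid_intron_intergenic": 2275,  # mid-intron, >100 nt from any exon edge
    }
    lines = []
    for label, ivs in (("utr5", utr5), ("exon", exons), ("utr3", utr3),
                       ("ncRNA", nc), ("gene", genes)):
        lines += [f"{c}\t{s}\t{e}\t{label}" for c, s, e in ivs]
    return GeneModelFixture(
        chrom=chrom,
        chrom_len=chrom_len,
        annotation=ann,
        probe_points=probes,
        annotation_bed="\n".join(lines) + "\n",
    )


def toy_conservation_track(
    fixture: GeneModelFixture,
    conserved_value: float = 2.0,
    flank_value: float = 1.0,
    nonconserved_value: float = 0.0,
    flank_nt: int = 100,
) -> tuple[ConservationTrack, str]:
    """A dense toy track: exons conserved, splice flanks intermediate,
    everything else non-conserved.  Returns (track, bedGraph text)."""
    from .regions import splice_flank_intervals

    chrom, L = fixture.chrom, fixture.chrom_len
    levels = np.full(L, nonconserved_value)
    for chrom_i, s, e in splice_flank_intervals(fixture.annotation, flank_nt):
        levels[s:e] = flank_value
    exon_set = fixture.annotation.all_exon_set()
    for s, e in exon_set.intervals(chrom):
        levels[s:e] = conserved_value
    for s, e in fixture.annotation.ncRNA_intervals.intervals(chrom):
        levels[s:e] = conserved_value
    # run-length encode into bedGraph intervals
    ivs = []
    start = 0
    for i in range(1, L + 1):
        if i == L or levels[i] != levels[start]:
            ivs.append((chrom, start, i, float(levels[start])))
            start = i
    text = "".join(f"{c}\t{s}\t{e}\t{v:g}\n" for c, s, e, v in ivs)
    return ConservationTrack(ivs), text


@dataclass
class ConservationScenario:
    """Strong/weak sets laid out on a toy chromosome with a conservation
    gradient: strong-set loci conserved, weak-set loci not."""

    strong_records: list
    weak_records: list
    annotation: RegionAnnotation
    track: ConservationTrack
    strong_manifest: BindingSetManifest
    weak_manifest: BindingSetManifest


def conservation_scenario(
    m: Motif | None = None,
    n_strong: int = 500,
    n_weak: int = 500,
    length: int = BINDING_SET_LEN,
    seed: int = 0,
    chrom: str = "chrC",
) -> ConservationScenario:
    """Build the conservation-structured validation fixture.

    A toy gene (exons + 100-nt splice flanks) anchors the intronic reference
    conservation level at 1.0.  Each strong-set sequence occupies a distinct
    intergenic locus covered at conservation 2.0; each weak-set locus is
    covered at 0.0, so any site called there is positively non-conserved and
    removable by the filter.  Sequences are motif-spiked at the usual strong
    and weak planting rates.
    """
    from .pipeline import QueryRecord
    from .regions import GenomicInterval

    mm = m or default_motif()
    strong, s_manifest = binding_set(
        mm, n=n_strong, plant_rate=STRONG_PLANT_RATE, length=length,
        n_suboptimal=2, seed=seed * 1000 + 11, id_prefix="strong_",
    )
    weak, w_manifest = binding_set(
        mm, n=n_weak, plant_rate=WEAK_PLANT_RATE, length=length,
        seed=seed * 1000 + 13, id_prefix="weak_",
    )
    # gene model: two exons with intronic flanks; all query loci intergenic
    exons = [(chrom, 200, 400), (chrom, 800, 1000)]
    genes = [(chrom, 100, 1500)]
    ann = RegionAnnotation.from_interval_lists(exons=exons, gene_bounds=genes)

    pitch = length + 50
    base_strong = 10_000
    base_weak = base_strong + n_strong * pitch + 1_000
    track_ivs: list[tuple[str, int, int, float]] = []
    # splice flanks at the intronic reference level 1.0
    track_ivs.append((chrom, 400, 500, 1.0))
    track_ivs.append((chrom, 700, 800, 1.0))
    track_ivs.append((chrom, 100, 200, 1.0))
    track_ivs.append((chrom, 1000, 1100, 1.0))

    def _records(seqs, base, value):
        recs = []
        for i, (sid, s) in enumerate(seqs):
            start = base + i * pitch
            recs.append(
                QueryRecord(
                    id=sid, sequence=s, source="coordinates",
                    anchor=GenomicInterval(chrom, start, start + length, "+"),
                )
            )
            track_ivs.append((chrom, start - 25, start + length + 25, value))
        return recs

    strong_records = _records(strong, base_strong, 2.0)
    weak_records = _records(weak, base_weak, 0.0)
    return ConservationScenario(
        strong_records=strong_records,
        weak_records=weak_records,
        annotation=ann,
        track=ConservationTrack(track_ivs),
        strong_manifest=s_manifest,
        weak_manifest=w_manifest,
    )


def generate_fixtures(outdir, seed: int = 0, motif: Motif | None = None) -> dict:
    """Write the full fixture bundle to ``outdir``; returns the manifest.

    Bundle contents: one background FASTA per region class, strong/weak
    binding-set FASTAs, a labeled annotation BED, a bedGraph conservation
    track, the motif in MEME format, and ``manifest.json`` with the ground
    truth.  Byte-identical for a fixed seed.
    """
    from .motifs import write_meme

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = motif or default_motif()

    manifest: dict = {"seed": seed, "motif": m.id, "backgrounds": {}, "sets": {}}
    for region in sorted(REGION_BASE_FREQS):
        seqs = background_corpus(region, seed=seed)
        path = outdir / f"background_{region}.fasta"
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">{region}_{i:04d}\n{s}\n")
        manifest["backgrounds"][region] = {
            "file": path.name, "n": len(seqs), "length": BACKGROUND_LEN,
            "base_freqs": REGION_BASE_FREQS[region],
        }

    for name, rate, nsub, stream in (
        ("strong", STRONG_PLANT_RATE, 2, 11),
        ("weak", WEAK_PLANT_RATE, 0, 13),
    ):
        seqs, set_manifest = binding_set(
            m, n=500, plant_rate=rate, n_suboptimal=nsub,
            seed=seed * 1000 + stream, id_prefix=f"{name}_",
        )
        path = outdir / f"{name}.fasta"
        with open(path, "w") as fh:
            for sid, s in seqs:
                fh.write(f">{sid}\n{s}\n")
        manifest["sets"][name] = {
            "file": path.name,
            "n": set_manifest.n_sequences,
            "plant_rate": rate,
            "n_planted": set_manifest.n_planted,
            "planted": set_manifest.planted,
            "suboptimal": set_manifest.suboptimal,
        }

    fixture = toy_gene_model()
    (outdir / "annotation.bed").write_text(fixture.annotation_bed)
    _, bg_text = toy_conservation_track(fixture)
    (outdir / "conservation.bedgraph").write_text(bg_text)
    manifest["gene_model"] = {
        "chrom": fixture.chrom, "chrom_len": fixture.chrom_len,
        "probe_points": fixture.probe_points,
        "annotation_file": "annotation.bed",
        "conservation_file": "conservation.bedgraph",
    }
    with open(outdir / "motif.meme", "w") as fh:
        write_meme([m], fh)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
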