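"""Match scoring, background calibration and stringency thresholds.

Every window of motif width k in a query sequence receives a *match score*:
the log-odds of the window under the motif versus a uniform 0.25 background,
min-max normalized to [0, 1] so that the best achievable k-mer scores exactly
1 and the worst exactly 0.  Scores are made comparable across motifs this
way, and are converted to p-values against an empirical background built by
scanning region-specific background sequence sets (one background per motif
per genomic-region class).

Two calibration routes exist:

* database-genome mode: empirical backgrounds (:func:`build_background`)
  supply both the match-score sample used for anchor/suboptimal thresholds
  and the mean/sd of clustering (WR) scores used for the final Z-test;
* other-genome mode: no background corpus exists, so thresholds come from
  the exact analytic distribution of the match score of a random i.i.d.
  k-mer (:func:`analytic_score_distribution`), which reflects both motif
  length and complexity through the per-column score convolution.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass

import numpy as np

from .motifs import ALPHABET, Motif

UNIFORM_BG = 0.25
#: discretization bin (raw log-odds scale) for the analytic convolution
ANALYTIC_BIN = 1e-4

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("T")] = 3
_ENCODE[ord("t")] = 3


def encode_rna(seq: str) -> np.ndarray:
    """Encode a sequence as int8 indices into ACGU; ambiguous bases become -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoredPosition:
    """One motif-width window of a query sequence with its match score."""

    seq_id: str
    offset: int  # 0-based window start
    kmer: str
    match_score: float
    match_pvalue: float | None = None


@dataclass(frozen=True)
class StringencyLevel:
    """Anchor/suboptimal p-value pair defining the search stringency."""

    name: str
    p_significant: float
    p_suboptimal: float

    def __post_init__(self) -> None:
        if not (0 < self.p_significant <= self.p_suboptimal < 1):
            raise ValueError("need 0 < p_significant <= p_suboptimal < 1")


STRINGENCY = {
    "high": StringencyLevel("high", 0.001, 0.01),
    "medium": StringencyLevel("medium", 0.005, 0.01),
    "low": StringencyLevel("low", 0.01, 0.02),
}
DEFAULT_STRINGENCY = STRINGENCY["medium"]
#: final acceptance rule on the Z-test p-value of a clustering score
FINAL_P = 0.05


def _column_scores(m: Motif) -> np.ndarray:
    """Per-position log2(p/0.25) score table, shape (k, 4)."""
    return np.log2(m.probs / UNIFORM_BG)


def _score_bounds(m: Motif) -> tuple[float, float]:
    cs = _column_scores(m)
    return float(cs.min(axis=1).sum()), float(cs.max(axis=1).sum())


def match_score(m: Motif, kmer: str) -> float:
    """Min-max normalized log-odds match score of one k-mer, in [0, 1].

    Raises
    ------
    ValueError
        If the k-mer has the wrong length or contains ambiguous bases.
    """
    enc = encode_rna(kmer)
    if len(enc) != m.length:
        raise ValueError(f"k-mer length {len(enc)} != motif length {m.length}")
    if np.any(enc < 0):
        raise ValueError(f"ambiguous base in k-mer {kmer!r}")
    cs = _column_scores(m)
    raw = float(cs[np.arange(m.length), enc].sum())
    smin, smax = _score_bounds(m)
    if smax - smin < 1e-12:  # all-uniform motif: every k-mer is "best"
        return 1.0
    return (raw - smin) / (smax - smin)


def scan_sequence(m: Motif, seq: str, seq_id: str = "query") -> list[ScoredPosition]:
    """Score every overlapping window of width k; skip ambiguous windows."""
    scores, offsets = scan_scores(m, seq)
    useq = seq.upper().replace("T", "U")
    return [
        ScoredPosition(seq_id=seq_id, offset=int(o), kmer=useq[o : o + m.length],
                       match_score=float(s))
        for o, s in zip(offsets, scores)
    ]


def scan_scores(m: Motif, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized scan: (match scores, window offsets) for valid windows.

    Windows containing a base outside ACGU(T) are excluded.  A sequence
    shorter than k yields empty arrays.
    """
    k = m.length
    enc = encode_rna(seq)
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    cs = _column_scores(m)
    valid_base = enc >= 0
    # window is valid iff all k bases valid: rolling AND via cumulative sums
    bad = (~valid_base).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    window_ok = (cbad[k:] - cbad[:-k]) == 0
    raw = np.zeros(n)
    safe = np.where(valid_base, enc, 0)
    for i in range(k):
        raw += cs[i, safe[i : i + n]]
    smin, smax = _score_bounds(m)
    if smax - smin < 1e-12:
        scores = np.ones(n)
    else:
        scores = (raw - smin) / (smax - smin)
    offsets = np.nonzero(window_ok)[0]
    return scores[offsets], offsets


@dataclass
class BackgroundModel:
    """Per-motif, per-region empirical background.

    ``match_scores`` is the sorted sample of all background window scores;
    ``wr_mean``/``wr_sd`` summarize the clustering (WR) scores obtained by
    running the full anchor+WR procedure on the background corpus itself.
    """

    motif_id: str
    region_class: str
    match_scores: np.ndarray  # sorted ascending
    wr_mean: float
    wr_sd: float
    n_wr: int

    MIN_MATCH = 1000
    MIN_WR = 200

    def __post_init__(self) -> None:
        self.match_scores = np.sort(np.asarray(self.match_scores, dtype=float))
        if self.n_match < self.MIN_MATCH:
            raise ValueError(
                f"background needs >= {self.MIN_MATCH} match scores, got {self.n_match}"
            )
        if self.n_wr < self.MIN_WR:
            raise ValueError(f"background needs >= {self.MIN_WR} WR scores, got {self.n_wr}")
        if not self.wr_sd > 0:
            raise ValueError("degenerate background: WR standard deviation is 0")

    @property
    def n_match(self) -> int:
        return len(self.match_scores)

    def save(self, directory) -> pathlib.Path:
        """Write a TSV sample + JSON metadata bundle; returns the meta path."""
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = f"{self.motif_id}.{self.region_class}"
        sample_path = directory / f"{stem}.match_scores.tsv"
        with open(sample_path, "w") as fh:
            fh.write("match_score\n")
            for s in self.match_scores:
                fh.write(f"{s:.10g}\n")
        meta_path = directory / f"{stem}.meta.json"
        meta = {
            "motif_id": self.motif_id,
            "region_class": self.region_class,
            "n_match": self.n_match,
            "wr_mean": self.wr_mean,
            "wr_sd": self.wr_sd,
            "n_wr": self.n_wr,
            "sample_file": sample_path.name,
        }
        meta_path.write_text(json.dumps(meta, indent=1) + "\n")
        return meta_path

    @classmethod
    def load(cls, meta_path) -> "BackgroundModel":
        meta_path = pathlib.Path(meta_path)
        meta = json.loads(meta_path.read_text())
        sample = np.loadtxt(meta_path.parent / meta["sample_file"], skiprows=1)
        return cls(
            motif_id=meta["motif_id"],
            region_class=meta["region_class"],
            match_scores=sample,
            wr_mean=meta["wr_mean"],
            wr_sd=meta["wr_sd"],
            n_wr=meta["n_wr"],
        )


def empirical_pvalue(bg: BackgroundModel, score) -> float | np.ndarray:
    """Finite-sample-corrected empirical upper-tail p-value.

    ``p = (1 + #{background >= score}) / (1 + n)``; never 0, monotone
    non-increasing in score.  Accepts a scalar or an array of scores.
    """
    n = bg.n_match
    ge = n - np.searchsorted(bg.match_scores, score, side="left")
    p = (1.0 + ge) / (1.0 + n)
    return float(p) if np.isscalar(score) else p


def _threshold_from_sample(sample: np.ndarray, p: float) -> float:
    """Smallest score t whose corrected empirical p-value against the sorted
    sample is < p; ``inf`` if unattainable."""
    n = len(sample)
    # largest allowed count c of sample scores >= t: (1 + c) / (1 + n) < p
    c = int(math.ceil(p * (1 + n) - 1.0)) - 1
    while (1 + c + 1) / (1 + n) < p:
        c += 1
    while c >= 0 and (1 + c) / (1 + n) >= p:
        c -= 1
    if c < 0:
        return math.inf
    return float(np.nextafter(sample[n - 1 - c], math.inf))


def threshold_for(bg: BackgroundModel, p: float) -> float:
    """Smallest score t with ``empirical_pvalue(bg, t) < p``.

    Sites scoring >= t are called.  Returns ``inf`` if no score can reach
    significance p against this background (too small a sample).
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    return _threshold_from_sample(bg.match_scores, p)


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact (discretized) distribution of the match score of a random k-mer."""

    support: np.ndarray  # ascending match scores (bin centers)
    pmf: np.ndarray
    sf_values: np.ndarray  # P(score >= support[i])

    def sf(self, score) -> float | np.ndarray:
        """P(match score >= score) for a random i.i.d. background k-mer."""
        idx = np.searchsorted(self.support, score, side="left")
        out = np.where(idx < len(self.support), self.sf_values[np.minimum(idx, len(self.support) - 1)], 0.0)
        return float(out) if np.isscalar(score) else out

    def quantile_above(self, p: float) -> float:
        """Smallest support score t with sf(t) < p (inf if unattainable)."""
        below = np.nonzero(self.sf_values < p)[0]
        if len(below) == 0:
            return math.inf
        return float(self.support[below[0]])


def analytic_score_distribution(
    m: Motif, base_freqs=(0.25, 0.25, 0.25, 0.25)
) -> ScoreDistribution:
    """Exact distribution of the match score under an i.i.d. base model.

    Computed by per-column convolution of the raw log-odds score atoms on a
    grid of width ``ANALYTIC_BIN``; agrees with exhaustive 4^k enumeration.
    The distribution encodes both motif length (number of convolved columns)
    and complexity (per-column score spread), so its quantiles serve as the
    annotation-free theoretical thresholds.
    """
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-6 or np.any(freqs < 0):
        raise ValueError("base_freqs must be 4 non-negative values summing to 1")
    cs = _column_scores(m)
    smin, smax = _score_bounds(m)
    if smax - smin < 1e-12:  # all-uniform motif: point mass at score 1
        return ScoreDistribution(
            support=np.array([1.0]), pmf=np.array([1.0]), sf_values=np.array([1.0])
        )
    # integer bin offsets per column, shifted to start at 0
    col_bins = np.rint((cs - cs.min(axis=1, keepdims=True)) / ANALYTIC_BIN).astype(np.int64)
    total = int(col_bins.max(axis=1).sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    width = 0
    for i in range(m.length):
        new = np.zeros(total + 1)
        for b in range(4):
            if freqs[b] == 0:
                continue
            off = col_bins[i, b]
            new[off : off + width + 1] += freqs[b] * dist[: width + 1]
        width += int(col_bins[i].max())
        dist = new
    nz = np.nonzero(dist > 0)[0]
    raw = smin + nz * ANALYTIC_BIN
    support = (raw - smin) / (smax - smin)
    pmf = dist[nz]
    sf_values = np.cumsum(pmf[::-1])[::-1]
    return ScoreDistribution(support=support, pmf=pmf, sf_values=sf_values)


def theoretical_threshold(
    m: Motif,
    stringency: StringencyLevel = DEFAULT_STRINGENCY,
    base_freqs=(0.25, 0.25, 0.25, 0.25),
) -> tuple[float, float]:
    """Analytic (annotation-free) anchor and suboptimal score thresholds.

    Quantiles of :func:`analytic_score_distribution` at the stringency's
    significant and suboptimal p-values; higher-information motifs yield
    higher absolute raw-score cutoffs because their score distribution has a
    thinner upper tail.
    """
    dist = analytic_score_distribution(m, base_freqs)
    t_sig = dist.quantile_above(stringency.p_significant)
    t_sub = dist.quantile_above(stringency.p_suboptimal)
    return t_sig, t_sub


def build_background(
    m: Motif,
    region_sequences: list[str],
    region_class: str,
    stringency: StringencyLevel = DEFAULT_STRINGENCY,
    window_nt: int = 50,
) -> BackgroundModel:
    """Build the empirical background for one motif in one region class.

    All windows of every background sequence are scored (the match-score
    sample); the anchor+WR procedure is then run on the corpus itself with
    thresholds derived from that sample, and the resulting WR scores supply
    the mean and standard deviation used by the final Z-test.
    """
    from .wr import wr_scores_for_anchors  # deferred: wr imports this module

    all_scores: list[np.ndarray] = []
    per_seq: list[tuple[np.ndarray, np.ndarray]] = []
    for seq in region_sequences:
        scores, offsets = scan_scores(m, seq)
        if len(scores):
            all_scores.append(scores)
            per_seq.append((scores, offsets))
    n_match = sum(len(s) for s in all_scores)
    if n_match < BackgroundModel.MIN_MATCH:
        raise ValueError(
            f"insufficient background: {n_match} windows scanned, "
            f"need >= {BackgroundModel.MIN_MATCH}; supply more/longer sequences"
        )
    sample = np.sort(np.concatenate(all_scores))
    t_sig = _threshold_from_sample(sample, stringency.p_significant)
    t_sub = _threshold_from_sample(sample, stringency.p_suboptimal)

    wr_all: list[np.ndarray] = []
    for scores, offsets in per_seq:
        wr = wr_scores_for_anchors(scores, offsets, t_sig, t_sub, m.length, window_nt)
        if len(wr):
            wr_all.append(wr)
    wr_sample = np.concatenate(wr_all) if wr_all else np.empty(0)
    if len(wr_sample) < BackgroundModel.MIN_WR:
        raise ValueError(
            f"insufficient background: only {len(wr_sample)} anchor WR scores, "
            f"need >= {BackgroundModel.MIN_WR}; supply a larger background corpus"
        )
    sd = float(np.std(wr_sample, ddof=1))
    if not sd > 0:
        raise ValueError("degenerate background: WR standard deviation is 0")
    return BackgroundModel(
        motif_id=m.id,
        region_class=region_class,
        match_scores=sample,
        wr_mean=float(np.mean(wr_sample)),
        wr_sd=sd,
        n_wr=len(wr_sample),
    )
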