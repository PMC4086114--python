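"""Clustering-aware binding-site calling (Weighted-Rank engine).

Functional RBP binding sites tend to occur as clusters of a strong match
("anchor") surrounded by weaker, suboptimal matches.  The Weighted-Rank (WR)
score captures this: the anchor's match score is boosted by the match-score-
weighted density of suboptimal hits whose window centers lie within a 50-nt
window around the anchor center,

    WR = s_anchor * (1 + sum_{q in cluster} s_q / N),   N = window_nt - k + 1,

so an isolated anchor keeps its own match score (WR = s_anchor) and a fully
saturated window at most doubles it.  In database-genome mode each WR score
is converted to a Z-score against the mean and standard deviation of WR
scores observed on the matching region-specific background corpus, and a
site is reported only when the one-tailed normal p-value is below 0.05.  In
other-genome mode (no background corpus available) anchors come from the
analytic thresholds and the WR score is reported against the theoretical
cutoff (the WR of a bare anchor scoring exactly the significant threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.stats import norm

from .scanning import (
    DEFAULT_STRINGENCY,
    FINAL_P,
    BackgroundModel,
    ScoredPosition,
    StringencyLevel,
    scan_scores,
    theoretical_threshold,
    threshold_for,
)
from .motifs import Motif

WINDOW_NT = 50


@dataclass(frozen=True)
class BindingSite:
    """A significant, clustering-supported motif occurrence."""

    seq_id: str
    anchor_offset: int  # 0-based within the query sequence
    motif_id: str
    protein: str
    kmer: str
    match_score: float
    wr_score: float
    region_class: str
    z: float | None = None
    p: float | None = None
    wr_cutoff: float | None = None  # other-genome mode
    genomic_start: int | None = None  # 1-based, 5'-most base on + strand
    chrom: str | None = None
    conservation_passed: bool | None = None


def find_anchors(
    positions: list[ScoredPosition], t_significant: float
) -> list[ScoredPosition]:
    """Windows whose match score reaches the significant threshold."""
    return [p for p in positions if p.match_score >= t_significant]


def wr_score(
    anchor: ScoredPosition,
    positions: list[ScoredPosition],
    t_suboptimal: float,
    window_nt: int = WINDOW_NT,
    k: int | None = None,
) -> float:
    """WR score of one anchor given all scored windows of its sequence.

    Cluster members are windows other than the anchor itself whose k-mer
    centers lie within ``window_nt / 2`` of the anchor center and whose match
    score reaches the suboptimal threshold.
    """
    if k is None:
        k = len(anchor.kmer)
    half = window_nt / 2.0
    n_windows = window_nt - k + 1
    anchor_center = anchor.offset + k / 2.0
    boost = 0.0
    for q in positions:
        if q.offset == anchor.offset:
            continue
        if q.match_score < t_suboptimal:
            continue
        if abs((q.offset + k / 2.0) - anchor_center) <= half:
            boost += q.match_score
    return anchor.match_score * (1.0 + boost / n_windows)


def wr_scores_for_anchors(
    scores: np.ndarray,
    offsets: np.ndarray,
    t_significant: float,
    t_suboptimal: float,
    k: int,
    window_nt: int = WINDOW_NT,
) -> np.ndarray:
    """Vectorized WR scores for every anchor in one scanned sequence.

    ``scores``/``offsets`` are the valid-window outputs of
    :func:`rbpscan.scanning.scan_scores` (offsets ascending).
    """
    anchors = np.nonzero(scores >= t_significant)[0]
    if len(anchors) == 0:
        return np.empty(0)
    half = window_nt // 2
    n_windows = window_nt - k + 1
    sub = np.where(scores >= t_suboptimal, scores, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(sub)])
    a_off = offsets[anchors]
    lo = np.searchsorted(offsets, a_off - half, side="left")
    hi = np.searchsorted(offsets, a_off + half, side="right")
    in_window = csum[hi] - csum[lo] - sub[anchors]  # exclude the anchor itself
    return scores[anchors] * (1.0 + in_window / n_windows)


def z_and_p(wr: float, bg: BackgroundModel) -> tuple[float, float]:
    """Z-score of a WR value against the background and its one-tailed p.

    ``z = (wr - mu) / sigma``; ``p = 1 - Phi(z)`` (upper tail of the standard
    normal).
    """
    z = (wr - bg.wr_mean) / bg.wr_sd
    return float(z), float(norm.sf(z))


def _dedup_overlapping(sites: list[BindingSite], k: int) -> list[BindingSite]:
    """Collapse overlapping called anchors of one motif, keeping the max WR."""
    kept: list[BindingSite] = []
    for s in sorted(sites, key=lambda s: (s.seq_id, s.anchor_offset)):
        if (
            kept
            and s.seq_id == kept[-1].seq_id
            and s.anchor_offset < kept[-1].anchor_offset + k
        ):
            if s.wr_score > kept[-1].wr_score:
                kept[-1] = s
        else:
            kept.append(s)
    return kept


def call_sites(
    seq: str,
    m: Motif,
    backgrounds: Mapping[str, BackgroundModel] | None = None,
    stringency: StringencyLevel = DEFAULT_STRINGENCY,
    region_classifier: Callable[[int], str] | None = None,
    mode: str = "database-genome",
    seq_id: str = "query",
    window_nt: int = WINDOW_NT,
    final_p: float = FINAL_P,
    base_freqs=(0.25, 0.25, 0.25, 0.25),
    dedup: bool = True,
    stats: dict | None = None,
) -> list[BindingSite]:
    """End-to-end site calling for one sequence and one motif.

    database-genome mode: anchors are windows whose match score beats the
    region-matched empirical significant threshold; each anchor's WR score is
    Z-tested against the same region's WR background and kept iff p < 0.05.

    other-genome mode: anchors and suboptimals come from the analytic
    thresholds; each site reports its WR score and the theoretical WR cutoff
    (no Z/p, since no genome-specific background exists).

    ``region_classifier`` maps an anchor offset (0-based, within ``seq``) to a
    region-class name; every encountered class must have a background in
    database-genome mode, otherwise a ``KeyError`` naming the class is raised.
    """
    if mode not in ("database-genome", "other-genome"):
        raise ValueError(f"unknown mode {mode!r}")
    k = m.length
    scores, offsets = scan_scores(m, seq)
    useq = seq.upper().replace("T", "U")
    if region_classifier is None:
        region_classifier = lambda offset: "mid_intron_intergenic"
    if stats is not None:
        stats["windows"] = stats.get("windows", 0) + len(offsets)

    sites: list[BindingSite] = []
    if mode == "other-genome":
        t_sig, t_sub = theoretical_threshold(m, stringency, base_freqs)
        wr_cutoff = t_sig  # WR of an isolated anchor scoring exactly t_sig
        anchor_idx = np.nonzero(scores >= t_sig)[0]
        if stats is not None:
            stats["anchors"] = stats.get("anchors", 0) + len(anchor_idx)
        wr_vals = wr_scores_for_anchors(scores, offsets, t_sig, t_sub, k, window_nt)
        for i, wr in zip(anchor_idx, wr_vals):
            if wr < wr_cutoff:
                continue
            off = int(offsets[i])
            sites.append(
                BindingSite(
                    seq_id=seq_id,
                    anchor_offset=off,
                    motif_id=m.id,
                    protein=m.protein,
                    kmer=useq[off : off + k],
                    match_score=float(scores[i]),
                    wr_score=float(wr),
                    region_class=region_classifier(off),
                    wr_cutoff=float(wr_cutoff),
                )
            )
    else:
        if backgrounds is None:
            raise ValueError("database-genome mode requires background models")
        # region class per valid window (anchors only need it, but thresholds
        # are region-specific, so classify every candidate window once)
        region_by_window = [region_classifier(int(o)) for o in offsets]
        thresholds: dict[str, tuple[float, float]] = {}
        for region in set(region_by_window):
            if region not in backgrounds:
                raise KeyError(
                    f"no background model for region class {region!r} "
                    f"(motif {m.id!r})"
                )
            bg = backgrounds[region]
            thresholds[region] = (
                threshold_for(bg, stringency.p_significant),
                threshold_for(bg, stringency.p_suboptimal),
            )
        for i in range(len(offsets)):
            region = region_by_window[i]
            t_sig, t_sub = thresholds[region]
            if scores[i] < t_sig:
                continue
            if stats is not None:
                stats["anchors"] = stats.get("anchors", 0) + 1
            bg = backgrounds[region]
            # suboptimal support uses the anchor's own region thresholds
            half = window_nt // 2
            n_windows = window_nt - k + 1
            center_diff = np.abs(offsets - offsets[i])
            in_win = (center_diff <= half) & (np.arange(len(offsets)) != i)
            boost = float(np.sum(scores[in_win & (scores >= t_sub)]))
            wr = float(scores[i]) * (1.0 + boost / n_windows)
            z, p = z_and_p(wr, bg)
            if not p < final_p:
                continue
            off = int(offsets[i])
            sites.append(
                BindingSite(
                    seq_id=seq_id,
                    anchor_offset=off,
                    motif_id=m.id,
                    protein=m.protein,
                    kmer=useq[off : off + k],
                    match_score=float(scores[i]),
                    wr_score=wr,
                    region_class=region,
                    z=z,
                    p=p,
                )
            )
    if dedup:
        sites = _dedup_overlapping(sites, k)
    return sites
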