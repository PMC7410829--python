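"""Empirical-Bayes footprint posteriors and the consensus footprint index.

Across a cohort, each nucleotide gets a prior on protection from the number
of samples whose independent de novo calls cover it (Laplace-smoothed), and
per-sample occupied/unoccupied likelihoods from the sample's dispersion
model: the unoccupied likelihood is the NB pmf at the expected rate, the
occupied likelihood averages the NB pmf over a grid of depletion ratios.
Per-sample posterior segments (posterior > 0.99 by default) are then
collated across samples into distinct consensus footprints by a greedy
max-support / median-boundary procedure, and consensus footprints can be
annotated with precomputed motif hits by fractional overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dispersion import MIN_EXPECTED, DispersionModel, nb_logpmf
from .tracks_io import GenomicInterval

__all__ = [
    "PosteriorTrack",
    "SampleSegment",
    "ConsensusFootprint",
    "MotifHit",
    "MotifAssignment",
    "DEFAULT_DEPLETION_GRID",
    "footprint_prior",
    "occupancy_likelihoods",
    "posterior_track",
    "sample_segments",
    "consensus_index",
    "assign_motifs",
]

DEFAULT_DEPLETION_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass
class PosteriorTrack:
    """Per-nucleotide footprint posterior for one sample over one interval."""

    interval: GenomicInterval
    sample_id: str
    posterior: np.ndarray
    prior: np.ndarray
    tested: np.ndarray


@dataclass(frozen=True)
class SampleSegment:
    """A posterior-thresholded footprinted segment from one sample."""

    sample_id: str
    interval: GenomicInterval
    mean_posterior: float = float("nan")


@dataclass
class ConsensusFootprint:
    interval: GenomicInterval
    n_supporting_samples: int
    mean_posterior: float
    members: list[SampleSegment] = field(default_factory=list)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    motif_id: str
    score: float
    strand: str = "."


@dataclass
class MotifAssignment:
    footprint: ConsensusFootprint
    hits: list[tuple[MotifHit, float]]  # (hit, overlap fraction), score-ranked
    classification: str  # unambiguous | ranked | unassigned


def footprint_prior(
    per_sample_calls: Sequence[Sequence],
    interval: GenomicInterval,
    a: float = 1.0,
    b: float = 1.0,
) -> np.ndarray:
    """Cross-sample occurrence prior: (k_i + a) / (N + a + b).

    ``per_sample_calls`` holds, per sample, that sample's de novo calls
    (objects with an ``interval`` attribute, or bare intervals); ``k_i`` is
    the number of samples whose calls cover position i.  Laplace pseudocounts
    keep the prior strictly inside (0, 1).
    """
    n_samples = len(per_sample_calls)
    if n_samples < 1:
        raise ValueError("need at least one sample")
    k = np.zeros(len(interval), dtype=float)
    for calls in per_sample_calls:
        covered = np.zeros(len(interval), dtype=bool)
        for c in calls:
            iv = getattr(c, "interval", c)
            if not iv.overlaps(interval):
                continue
            lo = max(iv.start, interval.start) - interval.start
            hi = min(iv.end, interval.end) - interval.start
            covered[lo:hi] = True
        k += covered
    return (k + a) / (n_samples + a + b)


def occupancy_likelihoods(
    obs,
    exp,
    model: DispersionModel,
    depletion_grid: Sequence[float] = DEFAULT_DEPLETION_GRID,
    min_expected: float = MIN_EXPECTED,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(L_occ, L_unocc, tested) at each position.

    L_unocc is the NB pmf of the observed count at the model's expected
    mean; L_occ averages the pmf over the depletion-ratio grid.  Untested
    positions (expected < ``min_expected``) return NaN likelihoods with
    ``tested`` False.
    """
    obs, exp = np.broadcast_arrays(
        np.asarray(obs, dtype=float), np.asarray(exp, dtype=float)
    )
    grid = np.asarray(depletion_grid, dtype=float)
    if grid.size == 0 or np.any((grid <= 0) | (grid > 1)):
        raise ValueError("depletion grid values must lie in (0, 1]")
    tested = exp >= min_expected
    l_occ = np.full(exp.shape, np.nan)
    l_unocc = np.full(exp.shape, np.nan)
    if tested.any():
        mu = model.mu(exp[tested])
        r = model.r(exp[tested])
        x = obs[tested]
        l_unocc[tested] = np.exp(nb_logpmf(x, mu, r))
        grid_pmf = np.exp(
            nb_logpmf(x[None, :], grid[:, None] * mu[None, :], r[None, :])
        )
        l_occ[tested] = grid_pmf.mean(axis=0)
    return l_occ, l_unocc, tested


def posterior_track(
    obs,
    exp,
    model: DispersionModel,
    prior: np.ndarray,
    depletion_grid: Sequence[float] = DEFAULT_DEPLETION_GRID,
    sample_id: str = "sample",
    interval: GenomicInterval | None = None,
    min_expected: float = MIN_EXPECTED,
) -> PosteriorTrack:
    """Bayes combination: prior x L_occ / (prior x L_occ + (1-prior) x L_unocc).

    Untested positions inherit the prior (flagged via ``tested``).
    """
    if interval is None:
        interval = getattr(obs, "interval", None)
    obs_arr = np.asarray(getattr(obs, "combined", obs), dtype=float)
    exp_arr = np.asarray(getattr(exp, "combined", exp), dtype=float)
    prior = np.asarray(prior, dtype=float)
    if np.any((prior < 0) | (prior >= 1)):
        raise ValueError("prior must lie in [0, 1)")
    l_occ, l_unocc, tested = occupancy_likelihoods(
        obs_arr, exp_arr, model, depletion_grid, min_expected
    )
    post = prior.astype(float).copy()
    num = prior[tested] * l_occ[tested]
    den = num + (1.0 - prior[tested]) * l_unocc[tested]
    with np.errstate(invalid="ignore", divide="ignore"):
        post[tested] = np.where(den > 0, num / den, 0.0)
    if interval is None:
        interval = GenomicInterval("track", 0, obs_arr.size)
    return PosteriorTrack(interval, sample_id, post, prior, tested)


def sample_segments(
    track: PosteriorTrack, cutoff: float = 0.99
) -> list[SampleSegment]:
    """Maximal runs of positions with posterior strictly above ``cutoff``."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    above = track.posterior > cutoff
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    out = []
    for s, e in zip(starts, ends):
        lo, hi = int(idx[s]), int(idx[e]) + 1
        iv = GenomicInterval(
            track.interval.contig,
            track.interval.start + lo,
            track.interval.start + hi,
        )
        out.append(
            SampleSegment(track.sample_id, iv, float(track.posterior[lo:hi].mean()))
        )
    return out


def _median_bounds(segments: Sequence[SampleSegment]) -> tuple[int, int]:
    starts = sorted(s.interval.start for s in segments)
    ends = sorted(s.interval.end for s in segments)
    n = len(segments)
    if n % 2 == 1:
        return starts[n // 2], ends[n // 2]
    # even count: lower-median start, upper-median end (widest central span)
    return starts[n // 2 - 1], ends[n // 2]


def consensus_index(segments: Iterable[SampleSegment]) -> list[ConsensusFootprint]:
    """Collate per-sample footprinted segments into consensus footprints.

    Greedy centroid collation: repeatedly take the genomic position covered
    by the most remaining segments (ties resolved leftmost), gather every
    segment covering it, emit the interval spanned by the median start and
    median end of the gathered segments, and remove them.  Output order and
    content are independent of input order; emitted footprints may abut but
    are never merged.
    """
    by_contig: dict[str, list[SampleSegment]] = {}
    for seg in segments:
        by_contig.setdefault(seg.interval.contig, []).append(seg)
    out: list[ConsensusFootprint] = []
    for contig in sorted(by_contig):
        segs = sorted(
            by_contig[contig], key=lambda s: (s.interval.start, s.interval.end, s.sample_id)
        )
        lo = min(s.interval.start for s in segs)
        hi = max(s.interval.end for s in segs)
        cov = np.zeros(hi - lo + 1, dtype=int)
        for s in segs:
            cov[s.interval.start - lo] += 1
            cov[s.interval.end - lo] -= 1
        cov = np.cumsum(cov)
        remaining = list(segs)
        while remaining:
            peak = int(np.argmax(cov[: hi - lo]))  # leftmost max
            pos = lo + peak
            gathered = [
                s for s in remaining if s.interval.start <= pos < s.interval.end
            ]
            if not gathered:  # numerical guard; cannot happen while segments remain
                break
            start, end = _median_bounds(gathered)
            posteriors = [
                s.mean_posterior for s in gathered if np.isfinite(s.mean_posterior)
            ]
            out.append(
                ConsensusFootprint(
                    GenomicInterval(contig, start, end),
                    n_supporting_samples=len({s.sample_id for s in gathered}),
                    mean_posterior=float(np.mean(posteriors)) if posteriors else float("nan"),
                    members=gathered,
                )
            )
            for s in gathered:
                cov[s.interval.start - lo : s.interval.end - lo] -= 1
                remaining.remove(s)
    out.sort(key=lambda f: (f.interval.contig, f.interval.start, f.interval.end))
    return out


def assign_motifs(
    footprints: Sequence[ConsensusFootprint],
    hits: Sequence[MotifHit],
    min_overlap_frac: float = 0.9,
) -> list[MotifAssignment]:
    """Annotate consensus footprints with motif hits by fractional overlap.

    A hit qualifies when overlap / motif length >= ``min_overlap_frac``
    (default 0.9).  Qualifying hits are ranked by match score descending;
    the classification is ``unambiguous`` (one candidate), ``ranked``
    (several) or ``unassigned`` (none).
    """
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    out = []
    for fp in footprints:
        qualifying = []
        for hit in hits:
            frac = fp.interval.overlap_length(hit.interval) / len(hit.interval)
            if frac >= min_overlap_frac:
                qualifying.append((hit, frac))
        qualifying.sort(key=lambda hf: (-hf[0].score, hf[0].interval.start))
        if len(qualifying) == 0:
            cls = "unassigned"
        elif len(qualifying) == 1:
            cls = "unambiguous"
        else:
            cls = "ranked"
        out.append(MotifAssignment(fp, qualifying, cls))
    return out
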