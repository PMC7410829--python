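"""De novo per-sample footprint discovery.

Per-nucleotide depletion p-values are combined over small centred windows
with Stouffer's method (several window widths; the per-position statistic is
the minimum combined z over widths, so short and wide footprints are both
sharp).  Significance is calibrated empirically: counts are resampled from
the fitted negative-binomial null at each position, pushed through the
identical statistic pipeline, and the empirical false-discovery rate at
statistic threshold t is

    FDR(t) = (#null <= t / R) / max(1, #observed <= t),

monotonised step-up over increasing t.  Positions at FDR <= 1% (default) are
segmented into footprint calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cleavage_bias import (
    BiasModel,
    ExpectedProfile,
    build_bias_table,
    expected_profile,
    preference_track,
)
from .dispersion import (
    MIN_EXPECTED,
    DispersionModel,
    depletion_pvalue,
    fit_dispersion,
    sample_null,
)
from .tracks_io import CleavageProfile, GenomeSequence, GenomicInterval

__all__ = [
    "DetectParams",
    "FdrTrack",
    "FootprintCall",
    "DetectResult",
    "windowed_stat",
    "empirical_fdr",
    "segment_footprints",
    "detect_sample",
    "run_de_novo",
    "estimate_depletion",
    "Z_CAP",
]

Z_CAP = 8.2  # z assigned to untested positions (effectively "p -> 1")


@dataclass
class DetectParams:
    """Tunable knobs of the per-sample detection pipeline (defaults shown)."""

    k: int = 6
    offset: int = 3
    window_half: int = 50
    widths: tuple[int, ...] = (3, 5, 7, 9, 11, 13)
    fdr_threshold: float = 0.01
    merge_gap: int = 3
    min_width: int = 6
    min_expected: float = MIN_EXPECTED
    null_replicates: int = 20
    boundary_p: float | None = 0.25

    @property
    def edge_pad(self) -> int:
        """Flank width whose positions are never tested (incomplete windows)."""
        return self.window_half + self.k


@dataclass
class FdrTrack:
    interval: GenomicInterval
    statistic: np.ndarray
    fdr: np.ndarray


@dataclass
class FootprintCall:
    interval: GenomicInterval
    best_fdr: float
    width: int
    sample_id: str
    mean_posterior: float | None = None
    depletion: float | None = None

    @property
    def score(self) -> int:
        """BED score: -10 log10(best FDR), capped at 1000."""
        if self.best_fdr <= 0:
            return 1000
        return int(min(1000, round(-10.0 * np.log10(self.best_fdr))))


@dataclass
class DetectResult:
    sample_id: str
    stats: list
    fdr_tracks: list[FdrTrack]
    calls: list[FootprintCall]


def windowed_stat(
    pvalues: np.ndarray,
    tested: np.ndarray,
    widths: Sequence[int] = (3, 5, 7, 9, 11, 13),
) -> np.ndarray:
    """Min-over-widths Stouffer combination of depletion p-values.

    For each odd width w, Z_w(i) = sum of probit(p) over the centred window
    divided by sqrt(w); untested positions (and positions beyond the array)
    contribute the cap ``Z_CAP``.  More negative means more protected.
    """
    p = np.asarray(pvalues, dtype=float)
    tested = np.asarray(tested, dtype=bool)
    for w in widths:
        if w < 1 or w % 2 == 0:
            raise ValueError(f"window widths must be odd and >= 1; got {w}")
    z = np.where(tested, norm.ppf(np.clip(p, 1e-300, 1.0)), Z_CAP)
    z = np.minimum(z, Z_CAP)
    stat = np.full(p.shape, np.inf)
    for w in widths:
        half = w // 2
        padded = np.concatenate([np.full(half, Z_CAP), z, np.full(half, Z_CAP)])
        cs = np.concatenate([[0.0], np.cumsum(padded)])
        zw = (cs[w:] - cs[:-w]) / np.sqrt(w)
        stat = np.minimum(stat, zw)
    return stat


def empirical_fdr(
    observed_stats: np.ndarray,
    null_stats: Sequence[np.ndarray] | np.ndarray,
) -> np.ndarray:
    """Per-position empirical FDR from null-replicate statistics.

    ``null_stats`` is a sequence of R arrays, each from one null replicate
    processed identically to the observed data.  The estimate at threshold t
    counts null positions per replicate against observed positions, clipped
    to [0, 1] and monotonised (step-up) over increasing t; each position is
    assigned the FDR at its own statistic.
    """
    obs = np.asarray(observed_stats, dtype=float).ravel()
    if isinstance(null_stats, np.ndarray) and null_stats.ndim == 1:
        null_stats = [null_stats]
    reps = [np.asarray(a, dtype=float).ravel() for a in null_stats]
    if len(reps) == 0:
        raise ValueError("need at least one null replicate")
    r_reps = len(reps)
    null_sorted = np.sort(np.concatenate(reps))
    uniq = np.unique(obs)
    obs_sorted = np.sort(obs)
    n_obs_le = np.searchsorted(obs_sorted, uniq, side="right")
    n_null_le = np.searchsorted(null_sorted, uniq, side="right") / r_reps
    raw = np.clip(n_null_le / np.maximum(1, n_obs_le), 0.0, 1.0)
    mono = np.minimum.accumulate(raw[::-1])[::-1]
    return mono[np.searchsorted(uniq, obs)]


def segment_footprints(
    fdr: np.ndarray | FdrTrack,
    interval: GenomicInterval | None = None,
    threshold: float = 0.01,
    merge_gap: int = 3,
    min_width: int = 6,
    sample_id: str = "sample",
) -> list[FootprintCall]:
    """Segment positions at FDR <= threshold into footprint calls.

    Runs separated by at most ``merge_gap`` failing/untested positions are
    merged; runs narrower than ``min_width`` are discarded.  Each call keeps
    the minimum per-position FDR within its run.
    """
    if isinstance(fdr, FdrTrack):
        interval = fdr.interval
        fdr = fdr.fdr
    if interval is None:
        raise ValueError("an interval is required alongside a bare FDR array")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    fdr = np.asarray(fdr, dtype=float)
    passing = fdr <= threshold
    if not passing.any():
        return []
    idx = np.flatnonzero(passing)
    # group passing positions into runs allowing gaps of <= merge_gap
    breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    calls = []
    for s, e in zip(starts, ends):
        lo, hi = int(idx[s]), int(idx[e]) + 1
        if hi - lo < min_width:
            continue
        sub = GenomicInterval(interval.contig, interval.start + lo, interval.start + hi)
        calls.append(
            FootprintCall(
                sub,
                best_fdr=float(fdr[lo:hi].min()),
                width=hi - lo,
                sample_id=sample_id,
            )
        )
    return calls


def refine_boundaries(
    call: FootprintCall,
    pvalues: np.ndarray,
    tested: np.ndarray,
    interval: GenomicInterval,
    boundary_p: float = 0.25,
) -> FootprintCall:
    """Re-delineate a call's edges from single-nucleotide depletion evidence.

    The windowed statistic that discovers a footprint blurs its boundaries
    by up to half a window; at the depths where footprints are detectable the
    individual protected nucleotides themselves carry evidence (p well below
    ``boundary_p``) while flanking unprotected positions are null-uniform.
    Edges are trimmed inward to the outermost position with p <=
    ``boundary_p`` and extended outward over contiguous qualifying
    positions.  If no position in the call qualifies, the call is returned
    unchanged.
    """
    lo = call.interval.start - interval.start
    hi = call.interval.end - interval.start
    good = tested & (pvalues <= boundary_p)
    if not good[lo:hi].any():
        return call
    while not good[lo]:
        lo += 1
    while not good[hi - 1]:
        hi -= 1
    while lo > 0 and good[lo - 1]:
        lo -= 1
    while hi < good.size and good[hi]:
        hi += 1
    new_iv = GenomicInterval(interval.contig, interval.start + lo, interval.start + hi)
    return FootprintCall(
        new_iv, call.best_fdr, hi - lo, call.sample_id, call.mean_posterior
    )


def _core_mask(n: int, pad: int) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    if n > 2 * pad:
        m[pad : n - pad] = True
    return m


def detect_sample(
    profiles: Sequence[CleavageProfile],
    genome: GenomeSequence,
    bias: BiasModel,
    model: DispersionModel,
    params: DetectParams = DetectParams(),
    seed=0,
    sample_id: str = "sample",
    expected: Sequence[ExpectedProfile] | None = None,
) -> DetectResult:
    """Full per-sample de novo footprint discovery over a set of intervals.

    Expected profiles, depletion p-values, windowed statistics and null
    replicates are computed per interval; the empirical FDR is estimated on
    the statistics pooled over all intervals, then mapped back and segmented
    per interval.  Intervals should carry ``params.edge_pad`` of flanking
    context: the flanks stabilise windows/contexts and are never tested.
    Deterministic given ``seed``.
    """
    from .dispersion import NucleotideStats

    if expected is None:
        expected = [
            expected_profile(p, genome, bias, params.window_half) for p in profiles
        ]
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(params.null_replicates, len(profiles)))

    stats_out: list[NucleotideStats] = []
    obs_stats: list[np.ndarray] = []
    for prof, exp in zip(profiles, expected):
        p, tested = depletion_pvalue(
            prof.combined, exp.combined, model, params.min_expected
        )
        core = _core_mask(len(prof.interval), params.edge_pad)
        tested &= core
        p = np.where(tested, p, 1.0)
        stats_out.append(
            NucleotideStats(prof.interval, prof.combined, exp.combined, p, tested)
        )
        obs_stats.append(windowed_stat(p, tested, params.widths))

    null_stats: list[np.ndarray] = []
    for rep in range(params.null_replicates):
        per_interval = []
        for j, exp in enumerate(expected):
            null_prof = sample_null(exp, model, int(rep_seeds[rep, j]))
            p, tested = depletion_pvalue(
                null_prof.combined, exp.combined, model, params.min_expected
            )
            core = _core_mask(len(exp.interval), params.edge_pad)
            tested &= core
            p = np.where(tested, p, 1.0)
            per_interval.append(windowed_stat(p, tested, params.widths))
        null_stats.append(np.concatenate(per_interval))

    pooled_obs = np.concatenate(obs_stats)
    pooled_fdr = empirical_fdr(pooled_obs, null_stats)

    tracks: list[FdrTrack] = []
    calls: list[FootprintCall] = []
    off = 0
    for prof, stat in zip(profiles, obs_stats):
        n = stat.size
        fdr = pooled_fdr[off : off + n]
        off += n
        track = FdrTrack(prof.interval, stat, fdr)
        tracks.append(track)
        interval_calls = segment_footprints(
            track,
            threshold=params.fdr_threshold,
            merge_gap=params.merge_gap,
            min_width=params.min_width,
            sample_id=sample_id,
        )
        if params.boundary_p is not None:
            nstats = stats_out[len(tracks) - 1]
            interval_calls = [
                refine_boundaries(
                    c, nstats.pvalue, nstats.tested, prof.interval, params.boundary_p
                )
                for c in interval_calls
            ]
        calls.extend(interval_calls)
    return DetectResult(sample_id, stats_out, tracks, calls)


def estimate_depletion(
    profile: CleavageProfile,
    genome: GenomeSequence,
    bias: BiasModel,
    footprint: GenomicInterval,
    window_half: int = 50,
    within: GenomicInterval | None = None,
    exclude: Sequence[GenomicInterval] = (),
) -> float:
    """Estimate the protection ratio (obs/exp in (0, 1]) of one footprint.

    The unprotected expectation inside the footprint is taken from the
    surrounding window with the footprint's own (depleted) positions removed
    from the windowed redistribution, which avoids the downward bias the
    footprint itself induces on the smoothed expected rate.  ``within``
    clips the flank window (typically to the hypersensitive region, so
    low-rate flanking chromatin does not dilute the unprotected rate) and
    ``exclude`` masks other footprints out of the flanks.
    """
    iv = profile.interval
    if not iv.overlaps(footprint):
        raise ValueError("footprint outside profile interval")
    lo = footprint.start - iv.start
    hi = footprint.end - iv.start
    wlo = max(0, lo - window_half)
    whi = min(len(iv), hi + window_half)
    if within is not None:
        wlo = max(wlo, within.start - iv.start)
        whi = min(whi, within.end - iv.start)
    flank = np.zeros(len(iv), dtype=bool)
    flank[wlo:lo] = True
    flank[hi:whi] = True
    for other in exclude:
        if other.overlaps(iv):
            flank[max(0, other.start - iv.start) : max(0, other.end - iv.start)] = False
    b_plus, b_minus = preference_track(genome, iv, bias)
    num = 0.0
    den = 0.0
    for counts, b in ((profile.counts_plus, b_plus), (profile.counts_minus, b_minus)):
        counts = np.asarray(counts, dtype=float)
        out_b = b[flank].sum()
        if out_b <= 0:
            continue
        rate = counts[flank].sum() / out_b  # cleavage per unit preference
        num += counts[lo:hi].sum()
        den += rate * b[lo:hi].sum()
    if den <= 0:
        return float("nan")
    return float(num / den)


def run_de_novo(
    genome: GenomeSequence,
    counts_plus: dict[str, np.ndarray],
    counts_minus: dict[str, np.ndarray],
    intervals: Sequence[GenomicInterval],
    params: DetectParams = DetectParams(),
    seed=0,
    sample_id: str = "sample",
    bias: BiasModel | None = None,
    model: DispersionModel | None = None,
) -> tuple[BiasModel, DispersionModel, DetectResult]:
    """Learn bias, fit dispersion and detect footprints for one sample.

    ``counts_plus`` / ``counts_minus`` map contig name to full-contig
    per-base cleavage counts; ``intervals`` are the hypersensitive regions to
    analyse (padded internally by ``params.edge_pad``).  A pre-learned bias
    table or dispersion model can be supplied to skip those steps.
    """
    profiles = []
    cores = list(intervals)
    for iv in intervals:
        piv = iv.padded(params.edge_pad, genome.lengths[iv.contig])
        profiles.append(
            CleavageProfile(
                piv,
                counts_plus[iv.contig][piv.start : piv.end],
                counts_minus[iv.contig][piv.start : piv.end],
            )
        )
    if bias is None:
        bias = build_bias_table(genome, profiles, params.k, params.offset)
    expected = [
        expected_profile(p, genome, bias, params.window_half) for p in profiles
    ]
    if model is None:
        pad = params.edge_pad
        obs_core = [p.combined[pad:-pad] for p in profiles if len(p.interval) > 2 * pad]
        exp_core = [e.combined[pad:-pad] for e in expected if len(e.interval) > 2 * pad]
        model = fit_dispersion(obs_core, exp_core)
    result = detect_sample(
        profiles, genome, bias, model, params, seed, sample_id, expected
    )
    # annotate calls with flank-normalised depletion estimates, keeping the
    # flank inside the analysed core and clear of sibling calls
    all_call_ivs = [c.interval for c in result.calls]
    for call in result.calls:
        for prof, core in zip(profiles, cores):
            if prof.interval.overlaps(call.interval):
                call.depletion = estimate_depletion(
                    prof,
                    genome,
                    bias,
                    call.interval,
                    params.window_half,
                    within=core,
                    exclude=[o for o in all_call_ivs if o is not call.interval],
                )
                break
    return bias, model, result
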