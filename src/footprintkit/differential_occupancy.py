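"""Per-nucleotide differential occupancy between two sample groups.

At each testable position, the observed count of sample *s* is modelled as
NB(phi_g(s) * mu_s, r_s), where mu_s and r_s come from the sample's own
dispersion model at its expected rate (so per-sample depth, bias and
technical variability enter as offsets) and phi is a group-level relative
cleavage ratio.  The likelihood is maximised over separate (phi_A, phi_B)
and over a single shared phi by golden-section search on log phi; the
likelihood-ratio statistic 2 * (l_free - l_shared) is referred to chi-square
with one degree of freedom and corrected with Benjamini-Hochberg across all
tested positions in a run.  This mirrors how differential expression is
tested for counts, applied per nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, false_discovery_control

from .bayes_index import ConsensusFootprint
from .dispersion import MIN_EXPECTED, DispersionModel, nb_logpmf
from .tracks_io import GenomicInterval

__all__ = [
    "GroupDesign",
    "DifferentialResult",
    "select_testable_dhs",
    "differential_nucleotide_test",
    "differential_scan",
    "aggregate_differential",
    "PHI_BOUNDS",
]

PHI_BOUNDS = (1e-3, 10.0)


@dataclass(frozen=True)
class GroupDesign:
    """Two-group sample design: parallel sample ids and A/B labels."""

    samples: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.labels):
            raise ValueError("samples and labels differ in length")
        bad = set(self.labels) - {"A", "B"}
        if bad:
            raise ValueError(f"labels must be 'A' or 'B'; got {sorted(bad)}")
        for g in "AB":
            if g not in self.labels:
                raise ValueError(f"group {g} is empty")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "GroupDesign":
        return cls(tuple(mapping.keys()), tuple(mapping.values()))

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.labels])


@dataclass
class DifferentialResult:
    """Per-position differential test output over one interval."""

    interval: GenomicInterval | None
    tested: np.ndarray
    phi_a: np.ndarray
    phi_b: np.ndarray
    phi_shared: np.ndarray
    lrt: np.ndarray
    p: np.ndarray
    q: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        pos = (
            np.arange(self.tested.size) + self.interval.start
            if self.interval is not None
            else np.arange(self.tested.size)
        )
        return pd.DataFrame(
            {
                "contig": self.interval.contig if self.interval else ".",
                "position": pos,
                "tested": self.tested,
                "phi_a": self.phi_a,
                "phi_b": self.phi_b,
                "lrt": self.lrt,
                "p": self.p,
                "q": self.q,
            }
        )


def select_testable_dhs(
    accessibility: pd.DataFrame,
    design: GroupDesign,
    min_samples: int = 10,
    min_density: float = 1.0,
) -> pd.Index:
    """Keep DHSs highly accessible in both groups.

    ``accessibility`` is a DHS-by-sample matrix of normalised cleavage
    density (tags per 150 bp per million reads).  A DHS qualifies when at
    least ``min_samples`` samples in EACH group reach ``min_density``
    (boundary inclusive).
    """
    missing = [s for s in design.samples if s not in accessibility.columns]
    if missing:
        raise KeyError(f"samples missing from accessibility matrix: {missing}")
    keep = pd.Series(True, index=accessibility.index)
    for g in "AB":
        cols = [s for s, lab in zip(design.samples, design.labels) if lab == g]
        keep &= (accessibility[cols] >= min_density).sum(axis=1) >= min_samples
    return accessibility.index[keep]


def _golden_max(
    f: Callable[[np.ndarray], np.ndarray],
    lo: float,
    hi: float,
    n_points: int,
    iters: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised golden-section maximisation over [lo, hi] per element."""
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.full(n_points, lo)
    b = np.full(n_points, hi)
    for _ in range(iters):
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        left = f(c) >= f(d)
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    x = (a + b) / 2.0
    return x, f(x)


def differential_nucleotide_test(
    obs: np.ndarray,
    exp: np.ndarray,
    models: Sequence[DispersionModel],
    design: GroupDesign,
    interval: GenomicInterval | None = None,
    min_expected: float = MIN_EXPECTED,
    min_samples: int = 10,
    compute_q: bool = True,
) -> DifferentialResult:
    """Likelihood-ratio test of group-level relative cleavage per position.

    ``obs`` and ``exp`` are samples-by-positions arrays sharing the interval;
    ``models[s]`` supplies mu/r offsets for sample s.  A position is tested
    only when at least ``min_samples`` samples per group have expected >=
    ``min_expected``; samples below the threshold are dropped from the
    likelihood at that position.
    """
    obs = np.asarray(obs, dtype=float)
    exp = np.asarray(exp, dtype=float)
    n_s, n_p = obs.shape
    if exp.shape != obs.shape:
        raise ValueError("obs and exp must share shape (samples, positions)")
    if len(models) != n_s or len(design.samples) != n_s:
        raise ValueError("models/design length must match sample count")

    mu = np.empty_like(exp)
    r = np.empty_like(exp)
    for s in range(n_s):
        mu[s] = models[s].mu(exp[s])
        r[s] = models[s].r(exp[s])

    ok = exp >= min_expected  # per-sample usable positions
    mask_a = design.group_mask("A")[:, None] & ok
    mask_b = design.group_mask("B")[:, None] & ok
    tested = (mask_a.sum(axis=0) >= min_samples) & (mask_b.sum(axis=0) >= min_samples)

    phi_a = np.full(n_p, np.nan)
    phi_b = np.full(n_p, np.nan)
    phi_shared = np.full(n_p, np.nan)
    lrt = np.full(n_p, np.nan)
    p = np.full(n_p, np.nan)

    if tested.any():
        t = tested
        mu_safe = np.where(mu > 0, mu, 1e-300)

        def make_ll(mask: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
            w = mask[:, t].astype(float)
            o = obs[:, t]
            m = mu_safe[:, t]
            rr = r[:, t]

            def ll(log_phi: np.ndarray) -> np.ndarray:
                phi = np.exp(log_phi)[None, :]
                return np.sum(w * nb_logpmf(o, phi * m, rr), axis=0)

            return ll

        lo, hi = np.log(PHI_BOUNDS[0]), np.log(PHI_BOUNDS[1])
        npos = int(t.sum())
        xa, la = _golden_max(make_ll(mask_a), lo, hi, npos)
        xb, lb = _golden_max(make_ll(mask_b), lo, hi, npos)
        xs, ls = _golden_max(make_ll(mask_a | mask_b), lo, hi, npos)
        phi_a[t] = np.exp(xa)
        phi_b[t] = np.exp(xb)
        phi_shared[t] = np.exp(xs)
        stat = np.maximum(0.0, 2.0 * (la + lb - ls))
        lrt[t] = stat
        p[t] = chi2.sf(stat, df=1)

    q = np.full(n_p, np.nan)
    if compute_q and tested.any():
        q[tested] = false_discovery_control(p[tested], method="bh")
    return DifferentialResult(interval, tested, phi_a, phi_b, phi_shared, lrt, p, q)


def differential_scan(
    obs_by_interval: Sequence[np.ndarray],
    exp_by_interval: Sequence[np.ndarray],
    models: Sequence[DispersionModel],
    design: GroupDesign,
    intervals: Sequence[GenomicInterval] | None = None,
    **kwargs,
) -> list[DifferentialResult]:
    """Run the per-position test over many intervals with BH pooled globally."""
    results = []
    for i, (o, e) in enumerate(zip(obs_by_interval, exp_by_interval)):
        iv = intervals[i] if intervals is not None else None
        results.append(
            differential_nucleotide_test(
                o, e, models, design, interval=iv, compute_q=False, **kwargs
            )
        )
    all_p = np.concatenate([res.p[res.tested] for res in results])
    if all_p.size:
        all_q = false_discovery_control(all_p, method="bh")
        off = 0
        for res in results:
            n = int(res.tested.sum())
            res.q[res.tested] = all_q[off : off + n]
            off += n
    return results


def aggregate_differential(
    results: DifferentialResult | Sequence[DifferentialResult],
    footprints: Sequence[ConsensusFootprint | GenomicInterval],
    dhs_intervals: Sequence[GenomicInterval],
    q_cutoff: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll per-position calls up to footprints and DHSs.

    A footprint is differential iff it contains at least one position with
    q <= ``q_cutoff``; a DHS is differential iff it contains at least one
    differential footprint.  Returns (per-footprint, per-DHS) tables, the
    latter with the count of differential footprints it contains.
    """
    if isinstance(results, DifferentialResult):
        results = [results]
    sig_positions: list[tuple[str, int, float]] = []
    for res in results:
        if res.interval is None:
            raise ValueError("aggregation requires results with intervals")
        hits = np.flatnonzero(res.tested & (res.q <= q_cutoff))
        for i in hits:
            sig_positions.append(
                (res.interval.contig, res.interval.start + int(i), float(res.q[i]))
            )

    fp_rows = []
    for fp in footprints:
        iv = getattr(fp, "interval", fp)
        qs = [q for c, pos, q in sig_positions if iv.contains_position(c, pos)]
        fp_rows.append(
            {
                "contig": iv.contig,
                "start": iv.start,
                "end": iv.end,
                "n_significant_positions": len(qs),
                "min_q": min(qs) if qs else np.nan,
                "differential": bool(qs),
            }
        )
    fp_df = pd.DataFrame(
        fp_rows,
        columns=[
            "contig",
            "start",
            "end",
            "n_significant_positions",
            "min_q",
            "differential",
        ],
    )

    dhs_rows = []
    for dhs in dhs_intervals:
        n_diff = 0
        for row in fp_rows:
            if not row["differential"]:
                continue
            fp_iv = GenomicInterval(row["contig"], row["start"], row["end"])
            if dhs.overlaps(fp_iv):
                n_diff += 1
        dhs_rows.append(
            {
                "contig": dhs.contig,
                "start": dhs.start,
                "end": dhs.end,
                "n_differential_footprints": n_diff,
                "differential": n_diff > 0,
            }
        )
    dhs_df = pd.DataFrame(
        dhs_rows,
        columns=["contig", "start", "end", "n_differential_footprints", "differential"],
    )
    return fp_df, dhs_df
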