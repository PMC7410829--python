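"""Per-sample negative-binomial cleavage-variability model.

Observed per-nucleotide counts are binned by their rounded expected rate;
within each bin a negative binomial NB(mu, r) is fitted by maximum likelihood
(the NB mean MLE is the sample mean, so only the size parameter ``r`` needs a
one-dimensional search).  Smooth trends are then fitted across bins:

* ``mu(n)``: a weighted least-squares line through the per-bin means,
  constrained to be non-decreasing and non-negative;
* ``r(n)``: a weighted linear fit of log r against log(1 + n).

Evaluation outside the fitted bin range is clamped to the endpoints.  The
resulting model is the null for the one-sided per-nucleotide depletion test
(protection = fewer cleavages than expected) and the generator for the
empirical-FDR null resampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import nbinom

from .cleavage_bias import ExpectedProfile
from .tracks_io import CleavageProfile, GenomicInterval

__all__ = [
    "DispersionModel",
    "NucleotideStats",
    "fit_dispersion",
    "depletion_pvalue",
    "sample_null",
    "nb_logpmf",
    "nb_cdf",
    "MIN_EXPECTED",
]

MIN_EXPECTED = 0.1  # expected counts below this are never tested
R_MIN, R_MAX = 1e-2, 1e8


def nb_logpmf(x, mu, r):
    """Log pmf of NB with mean ``mu`` and size ``r`` (var = mu + mu^2/r).

    Stable for very large ``r`` (Poisson regime); ``mu == 0`` is the point
    mass at zero.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    mu_safe = np.where(mu > 0, mu, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = (
            gammaln(x + r)
            - gammaln(r)
            - gammaln(x + 1)
            - r * np.log1p(mu_safe / r)
            + x * np.log(mu_safe / (r + mu_safe))
        )
    zero_mu = np.broadcast_to(mu, lp.shape) == 0
    if np.any(zero_mu):
        lp = np.where(zero_mu, np.where(x == 0, 0.0, -np.inf), lp)
    return lp


def nb_cdf(x, mu, r):
    """P(X <= x) for NB(mean mu, size r); mu == 0 gives 1."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    mu_safe = np.where(mu > 0, mu, 1.0)
    p = nbinom.cdf(x, r, r / (r + mu_safe))
    return np.where(mu > 0, p, np.where(x >= 0, 1.0, 0.0))


def _fit_bin_r(counts: np.ndarray, mu: float) -> float:
    """MLE of the NB size parameter with the mean fixed at the sample mean."""
    if mu <= 0:
        return R_MAX
    var = counts.var()
    if var <= mu * (1 + 1e-12):
        return R_MAX  # at/below the Poisson limit

    def neg_ll(log_r: float) -> float:
        return -float(np.sum(nb_logpmf(counts, mu, np.exp(log_r))))

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log(R_MIN), np.log(R_MAX)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def _weighted_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    sxx = np.average((x - xm) ** 2, weights=w)
    if sxx == 0:
        return 0.0, float(ym)
    slope = float(np.average((x - xm) * (y - ym), weights=w) / sxx)
    return slope, float(ym - slope * xm)


@dataclass
class DispersionModel:
    """Smooth mean/size trends of observed counts given expected counts."""

    mu_intercept: float
    mu_slope: float
    r_log_intercept: float
    r_log1p_slope: float
    fit_min: float
    fit_max: float
    bin_table: pd.DataFrame | None = None

    def _clamp(self, expected) -> np.ndarray:
        return np.clip(np.asarray(expected, dtype=float), self.fit_min, self.fit_max)

    def mu(self, expected) -> np.ndarray:
        e = self._clamp(expected)
        return np.maximum(0.0, self.mu_intercept + self.mu_slope * e)

    def r(self, expected) -> np.ndarray:
        e = self._clamp(expected)
        r = np.exp(self.r_log_intercept + self.r_log1p_slope * np.log1p(e))
        return np.clip(r, R_MIN, R_MAX)

    @classmethod
    def from_trend(
        cls,
        *,
        r: float = 8.0,
        mu_slope: float = 1.0,
        mu_intercept: float = 0.0,
        r_log1p_slope: float = 0.0,
        fit_range: tuple[float, float] = (0.0, 1e6),
    ) -> "DispersionModel":
        """Build a model directly from known trends (no fitting).

        Useful for simulations and for testing against analytically known
        nulls: the default is the identity mean trend with constant size r.
        """
        return cls(
            mu_intercept,
            mu_slope,
            float(np.log(r)),
            r_log1p_slope,
            fit_range[0],
            fit_range[1],
        )

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "mu_intercept": self.mu_intercept,
            "mu_slope": self.mu_slope,
            "r_log_intercept": self.r_log_intercept,
            "r_log1p_slope": self.r_log1p_slope,
            "fit_min": self.fit_min,
            "fit_max": self.fit_max,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            if self.bin_table is not None:
                self.bin_table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DispersionModel":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError(f"{path}: missing coefficient header")
            header = json.loads(first[1:])
            rest = fh.read()
        table = None
        if rest.strip():
            from io import StringIO

            table = pd.read_csv(StringIO(rest), sep="\t")
        return cls(
            header["mu_intercept"],
            header["mu_slope"],
            header["r_log_intercept"],
            header["r_log1p_slope"],
            header["fit_min"],
            header["fit_max"],
            table,
        )


@dataclass
class NucleotideStats:
    """Per-position deviation-test inputs/outputs over one interval."""

    interval: GenomicInterval
    observed: np.ndarray
    expected: np.ndarray
    pvalue: np.ndarray
    tested: np.ndarray


def _as_array(x) -> np.ndarray:
    if isinstance(x, (CleavageProfile, ExpectedProfile)):
        return np.asarray(x.combined, dtype=float)
    return np.asarray(x, dtype=float).ravel()


def fit_dispersion(
    observed: Sequence,
    expected: Sequence,
    min_positions_per_bin: int = 100,
    min_bins: int = 5,
) -> DispersionModel:
    """Fit the per-sample NB dispersion model from paired observed/expected.

    ``observed`` / ``expected`` are parallel sequences of count and rate
    arrays (or :class:`CleavageProfile` / :class:`ExpectedProfile` objects,
    whose combined-strand arrays are used).
    """
    obs = np.concatenate([_as_array(o) for o in observed])
    exp = np.concatenate([_as_array(e) for e in expected])
    if obs.size != exp.size:
        raise ValueError("observed and expected arrays differ in total length")
    if not obs.any():
        raise ValueError("all observed counts are zero; nothing to fit")

    bins = np.rint(exp).astype(int)
    rows = []
    for b in range(1, int(bins.max()) + 1):
        mask = bins == b
        n_pos = int(mask.sum())
        if n_pos < min_positions_per_bin:
            continue
        counts = obs[mask]
        mu = float(counts.mean())
        rows.append((b, n_pos, mu, _fit_bin_r(counts, mu)))
    if len(rows) < min_bins:
        counts_by_bin = {b: int((bins == b).sum()) for b in np.unique(bins) if b >= 1}
        raise ValueError(
            f"only {len(rows)} expected-count bins have >= "
            f"{min_positions_per_bin} positions (need {min_bins}); "
            f"bin sizes: {counts_by_bin}"
        )
    table = pd.DataFrame(rows, columns=["bin", "n_positions", "mu", "r"])
    w = table["n_positions"].to_numpy(dtype=float)
    x = table["bin"].to_numpy(dtype=float)

    mu_slope, mu_intercept = _weighted_line(x, table["mu"].to_numpy(), w)
    if mu_slope < 0:  # enforce a non-decreasing mean trend
        mu_slope = 0.0
        mu_intercept = float(np.average(table["mu"], weights=w))

    r_slope, r_intercept = _weighted_line(
        np.log1p(x), np.log(table["r"].to_numpy()), w
    )
    return DispersionModel(
        mu_intercept,
        mu_slope,
        r_intercept,
        r_slope,
        float(x.min()),
        float(x.max()),
        table,
    )


def depletion_pvalue(
    obs,
    exp,
    model: DispersionModel,
    min_expected: float = MIN_EXPECTED,
) -> tuple[np.ndarray, np.ndarray]:
    """Lower-tail one-sided p = P(X <= obs) under the fitted NB null.

    Positions with expected rate below ``min_expected`` are untested and get
    the sentinel p = 1.  Including the observed value in the tail keeps the
    discrete test conservative.  Returns ``(p, tested)`` arrays.
    """
    obs, exp = np.broadcast_arrays(
        np.asarray(obs, dtype=float), np.asarray(exp, dtype=float)
    )
    tested = exp >= min_expected
    p = np.ones(exp.shape, dtype=float)
    if np.any(tested):
        mu = model.mu(exp[tested])
        r = model.r(exp[tested])
        p[tested] = nb_cdf(obs[tested], mu, r)
    return p, tested


def sample_null(
    expected,
    model: DispersionModel,
    seed,
) -> CleavageProfile:
    """Draw a null cleavage profile from the fitted NB at each position.

    Sampling is gamma-Poisson (exact NB) and deterministic given ``seed``;
    positions with zero expected rate always draw zero.  The combined draw is
    split between strands at random (downstream testing uses combined
    counts).
    """
    if isinstance(expected, ExpectedProfile):
        interval = expected.interval
        exp = expected.combined
    else:
        exp = np.asarray(expected, dtype=float)
        interval = GenomicInterval("null", 0, exp.size)
    rng = np.random.default_rng(seed)
    total = np.zeros(exp.size, dtype=np.int64)
    nz = exp > 0
    if nz.any():
        mu = model.mu(exp[nz])
        r = model.r(exp[nz])
        lam = rng.gamma(shape=r, scale=np.where(mu > 0, mu, 0.0) / r)
        total[nz] = rng.poisson(lam)
    plus = rng.binomial(total, 0.5)
    return CleavageProfile(interval, plus, total - plus)
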