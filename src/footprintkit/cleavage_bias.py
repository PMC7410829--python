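"""Hexamer cleavage-preference model and bias-aware expected cleavage rates.

DNase I cuts with a mild sequence preference that is well captured by the
k-mer context surrounding the cleaved phosphate (k = 6 by default: three
bases 5' of the cleaved base, the base itself, and two bases 3').  This
module learns the relative per-context cleavage rate from observed cleavage
tracks and uses it to redistribute locally observed counts into an expected
per-nucleotide cleavage rate: within a centred window of half-width
``window_half`` around position *i*,

    expected_i = (sum of observed counts in window) * b_i / (sum of b_j in window)

per strand, where ``b`` is the context preference (reverse-complemented for
minus-strand contexts).  Windows are clipped at interval edges, so when the
window spans the whole interval the expected profile conserves the observed
total exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .tracks_io import CleavageProfile, GenomeSequence, GenomicInterval

__all__ = [
    "BiasModel",
    "ExpectedProfile",
    "build_bias_table",
    "expected_profile",
    "preference_track",
    "kmer_to_code",
    "code_to_kmer",
]

_BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map an A/C/G/T/N string to codes 0-3 (-1 for N)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_to_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        i = _BASES.find(b)
        if i < 0:
            raise ValueError(f"k-mer {kmer!r} contains a non-ACGT character")
        code = code * 4 + i
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def _context_codes(
    codes: np.ndarray, k: int, offset: int, strand: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context code and validity for one strand.

    Plus strand at position i uses bases ``[i-offset, i-offset+k)``; the minus
    strand uses the reverse complement of ``[i-(k-1-offset), i+offset+1)`` so
    that the cleavage-assigned base sits at index ``offset`` of the k-mer on
    its own strand.
    """
    n = codes.size
    padded = np.full(n + 2 * k, -1, dtype=np.int64)
    padded[k : k + n] = codes
    ctx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        if strand == "+":
            b = padded[k - offset + j : k - offset + j + n]
        else:
            b = padded[k + offset - j : k + offset - j + n]
            b = np.where(b >= 0, 3 - b, b)
        valid &= b >= 0
        ctx = ctx * 4 + np.where(b >= 0, b, 0)
    return ctx, valid


@dataclass
class BiasModel:
    """Relative cleavage preference per k-mer context.

    ``preference`` is a dense array of length ``4**k``; contexts never
    observed (or containing N) are NaN and treated as neutral (1.0) at
    lookup.  Preferences are normalised so the mean over observed k-mers
    is 1.
    """

    k: int
    offset: int
    preference: np.ndarray
    total_cleavages: float = 0.0
    total_contexts: float = 0.0

    def __post_init__(self) -> None:
        self.preference = np.asarray(self.preference, dtype=float)
        if self.preference.shape != (4**self.k,):
            raise ValueError("preference table must have length 4**k")
        finite = self.preference[np.isfinite(self.preference)]
        if finite.size and (finite <= 0).any():
            raise ValueError("preference values must be positive")

    def lookup(self, ctx: np.ndarray, valid: np.ndarray) -> np.ndarray:
        b = np.ones(ctx.shape, dtype=float)
        v = valid & np.isfinite(self.preference[np.where(valid, ctx, 0)])
        b[v] = self.preference[ctx[v]]
        return b

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# k={self.k} offset={self.offset} "
                f"total_cleavages={self.total_cleavages:g} "
                f"total_contexts={self.total_contexts:g}\n"
            )
            fh.write("kmer\tpreference\n")
            for code in np.flatnonzero(np.isfinite(self.preference)):
                fh.write(
                    f"{code_to_kmer(int(code), self.k)}\t"
                    f"{self.preference[code]:.8g}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BiasModel":
        meta: dict[str, float] = {}
        rows: list[tuple[str, float]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    for kv in line[1:].split():
                        key, _, val = kv.partition("=")
                        if val:
                            meta[key] = float(val)
                    continue
                if not line or line.startswith("kmer"):
                    continue
                kmer, pref = line.split("\t")
                rows.append((kmer, float(pref)))
        k = int(meta.get("k", len(rows[0][0])))
        table = np.full(4**k, np.nan)
        for kmer, pref in rows:
            table[kmer_to_code(kmer)] = pref
        return cls(
            k,
            int(meta.get("offset", 3)),
            table,
            meta.get("total_cleavages", 0.0),
            meta.get("total_contexts", 0.0),
        )

    @classmethod
    def uniform(cls, k: int = 6, offset: int = 3) -> "BiasModel":
        return cls(k, offset, np.ones(4**k))


@dataclass
class ExpectedProfile:
    """Bias-aware expected per-nucleotide cleavage rates over an interval."""

    interval: GenomicInterval
    expected_plus: np.ndarray
    expected_minus: np.ndarray
    window_half: int

    def __post_init__(self) -> None:
        n = len(self.interval)
        self.expected_plus = np.asarray(self.expected_plus, dtype=float)
        self.expected_minus = np.asarray(self.expected_minus, dtype=float)
        for arr in (self.expected_plus, self.expected_minus):
            if arr.shape != (n,):
                raise ValueError("expected array length must equal interval length")
            if not np.all(np.isfinite(arr)) or (arr < 0).any():
                raise ValueError("expected rates must be finite and non-negative")

    @property
    def combined(self) -> np.ndarray:
        return self.expected_plus + self.expected_minus


def build_bias_table(
    genome: GenomeSequence,
    profiles: Iterable[CleavageProfile],
    k: int = 6,
    offset: int = 3,
) -> BiasModel:
    """Learn the k-mer relative cleavage-preference table by direct tallying.

    preference(m) = (cleavages in context m / occurrences of m)
                    / (total cleavages / total contexts),
    re-normalised to unit mean over observed k-mers.  Minus-strand cleavages
    are tallied against the reverse-complement context; positions whose
    context includes N (or falls off the contig) are skipped on that strand.
    """
    nk = 4**k
    cleav = np.zeros(nk, dtype=float)
    occ = np.zeros(nk, dtype=float)
    any_counts = False
    for prof in profiles:
        seq = genome.fetch(prof.interval)
        codes = encode_sequence(seq)
        for strand, counts in (("+", prof.counts_plus), ("-", prof.counts_minus)):
            ctx, valid = _context_codes(codes, k, offset, strand)
            np.add.at(occ, ctx[valid], 1.0)
            c = np.asarray(counts, dtype=float)
            if c.any():
                any_counts = True
            np.add.at(cleav, ctx[valid], c[valid])
    if not any_counts:
        raise ValueError("no cleavages supplied; cannot learn a bias table")
    total_cleav = cleav.sum()
    total_occ = occ.sum()
    if total_cleav < 10 * nk:
        warnings.warn(
            f"only {total_cleav:g} cleavages for {nk} contexts; "
            "bias estimates will be noisy",
            stacklevel=2,
        )
    unseen = occ == 0
    if unseen.all():
        raise ValueError("no valid k-mer contexts in input")
    pref = np.full(nk, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ > 0, cleav / np.maximum(occ, 1), np.nan)
    global_rate = total_cleav / total_occ
    pref[occ > 0] = rate[occ > 0] / global_rate
    # keep zero-cleavage contexts at the global floor: a strictly positive
    # preference is required downstream, so clamp at a small fraction
    pref[(occ > 0) & (pref == 0)] = 1e-3
    pref /= np.nanmean(pref)
    return BiasModel(k, offset, pref, total_cleav, total_occ)


def preference_track(
    genome: GenomeSequence, interval: GenomicInterval, bias: BiasModel
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position (plus, minus) context preferences over ``interval``.

    Contexts reach ``bias.k`` bases beyond the interval where the contig
    allows; unresolvable contexts get a neutral preference of 1.
    """
    contig_len = genome.lengths[interval.contig]
    lo = max(0, interval.start - bias.k)
    hi = min(contig_len, interval.end + bias.k)
    seq = genome.fetch(GenomicInterval(interval.contig, lo, hi))
    codes = encode_sequence(seq)
    off = interval.start - lo
    n = len(interval)
    out = []
    for strand in "+-":
        ctx, valid = _context_codes(codes, bias.k, bias.offset, strand)
        out.append(bias.lookup(ctx, valid)[off : off + n])
    return out[0], out[1]


def _windowed_sum(x: np.ndarray, half: int) -> np.ndarray:
    """Centred moving sum with windows clipped at the array edges."""
    cs = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    idx = np.arange(x.size)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(x.size, idx + half + 1)
    return cs[hi] - cs[lo]


def expected_profile(
    observed: CleavageProfile,
    genome: GenomeSequence,
    bias: BiasModel,
    window_half: int = 50,
) -> ExpectedProfile:
    """Redistribute windowed observed counts by context preference, per strand."""
    n = len(observed.interval)
    if n < 1:
        raise ValueError("empty interval")
    if 2 * window_half + 1 <= 0:
        raise ValueError("window_half must be non-negative")
    b_plus, b_minus = preference_track(genome, observed.interval, bias)
    out = []
    for counts, b in (
        (observed.counts_plus, b_plus),
        (observed.counts_minus, b_minus),
    ):
        s_obs = _windowed_sum(np.asarray(counts, dtype=float), window_half)
        s_b = _windowed_sum(b, window_half)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = np.where(s_b > 0, s_obs * b / s_b, 0.0)
        out.append(e)
    return ExpectedProfile(observed.interval, out[0], out[1], window_half)
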