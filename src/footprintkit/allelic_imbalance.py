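"""Allelic imbalance of cleavage at heterozygous SNVs.

Reads overlapping a heterozygous variant are tallied by the base they carry
(reference / alternate / other) across all contributing heterozygous
samples.  Variants with at least ``min_depth`` informative reads (ref + alt,
default 35) are tested with a two-sided exact binomial test against the
expected reference fraction (default 0.5; a measured reference-mapping bias
can be supplied instead), corrected with Benjamini-Hochberg, and flagged
imbalanced at q <= 0.2 by default.  Enrichment of imbalanced variants in
footprinted versus non-footprinted DHS positions is summarised with an exact
2x2 test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import binom, fisher_exact, false_discovery_control

from .tracks_io import (
    GT_HET,
    GenomicInterval,
    VariantRecord,
    _read_retained,
)

__all__ = [
    "AlleleCounts",
    "tally_alleles",
    "imbalance_test",
    "binomial_imbalance_pvalue",
    "footprint_overlap_enrichment",
]


@dataclass
class AlleleCounts:
    """Allele-resolved read tallies at one variant, summed over het samples."""

    variant: VariantRecord
    n_ref: int
    n_alt: int
    n_other: int
    n_het_samples: int

    @property
    def depth(self) -> int:
        """Informative depth used by the depth rule (ref + alt only)."""
        return self.n_ref + self.n_alt


def _base_at(read: "pysam.AlignedSegment", ref_pos: int) -> tuple[str, int] | None:
    """Base and quality the read places at a reference position, if aligned."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == ref_pos:
            qual = read.query_qualities[qpos] if read.query_qualities is not None else 255
            return read.query_sequence[qpos], qual
    return None


def tally_alleles(
    alignments: Mapping[str, "str | Path | pysam.AlignmentFile"],
    variants: Sequence[VariantRecord],
    *,
    min_baseq: int = 20,
    min_mapq: int = 0,
) -> list[AlleleCounts]:
    """Tally ref/alt/other bases over reads of heterozygous samples.

    Only samples genotyped heterozygous at a variant contribute to it.
    Reads failing alignment flags, ``min_mapq`` or ``min_baseq`` at the
    variant base are skipped.
    """
    handles: dict[str, pysam.AlignmentFile] = {}
    own: list[pysam.AlignmentFile] = []
    for sample, src in alignments.items():
        if isinstance(src, (str, Path)):
            af = pysam.AlignmentFile(str(src))
            own.append(af)
        else:
            af = src
        handles[sample] = af
    try:
        out = []
        for v in variants:
            n_ref = n_alt = n_other = n_het = 0
            for sample, af in handles.items():
                if v.genotypes.get(sample) != GT_HET:
                    continue
                n_het += 1
                if v.contig not in af.references:
                    raise ValueError(
                        f"variant contig {v.contig!r} absent from alignments "
                        f"of sample {sample!r}"
                    )
                for read in af.fetch(v.contig, v.position, v.position + 1):
                    if not _read_retained(read, min_mapq):
                        continue
                    hit = _base_at(read, v.position)
                    if hit is None:
                        continue
                    base, qual = hit
                    if qual < min_baseq:
                        continue
                    if base == v.ref:
                        n_ref += 1
                    elif base == v.alt:
                        n_alt += 1
                    else:
                        n_other += 1
            out.append(AlleleCounts(v, n_ref, n_alt, n_other, n_het))
        return out
    finally:
        for af in own:
            af.close()


def binomial_imbalance_pvalue(
    n_ref: int, n_alt: int, expected_ratio: float = 0.5
) -> float:
    """Two-sided exact binomial p by doubling the smaller tail (capped at 1)."""
    n = n_ref + n_alt
    if n == 0:
        return 1.0
    lower = binom.cdf(n_ref, n, expected_ratio)
    upper = binom.sf(n_ref - 1, n, expected_ratio)
    return float(min(1.0, 2.0 * min(lower, upper)))


def imbalance_test(
    counts: Sequence[AlleleCounts],
    expected_ratio: float = 0.5,
    q_cutoff: float = 0.2,
    min_depth: int = 35,
) -> pd.DataFrame:
    """Exact binomial imbalance test across testable variants.

    Variants with informative depth below ``min_depth`` are kept in the
    output but flagged untestable (no p/q).  q-values are BH-corrected over
    the testable set only; ``imbalanced`` requires both the depth rule and
    q <= ``q_cutoff``.
    """
    if not counts:
        raise ValueError("no allele counts supplied")
    rows = []
    for c in counts:
        depth = c.depth
        ratio = c.n_ref / depth if depth else np.nan
        fold = np.nan
        if depth:
            a, b = max(ratio, 1 - ratio), min(ratio, 1 - ratio)
            fold = np.inf if b == 0 else a / b
        rows.append(
            {
                "contig": c.variant.contig,
                "position": c.variant.position,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "n_ref": c.n_ref,
                "n_alt": c.n_alt,
                "n_other": c.n_other,
                "n_het_samples": c.n_het_samples,
                "testable": depth >= min_depth,
                "ratio": ratio,
                "fold_imbalance": fold,
            }
        )
    df = pd.DataFrame(rows)
    df["p"] = np.nan
    df["q"] = np.nan
    testable = df["testable"].to_numpy()
    if testable.any():
        ps = np.array(
            [
                binomial_imbalance_pvalue(nr, na, expected_ratio)
                for nr, na in zip(
                    df.loc[testable, "n_ref"], df.loc[testable, "n_alt"]
                )
            ]
        )
        df.loc[testable, "p"] = ps
        df.loc[testable, "q"] = false_discovery_control(ps, method="bh")
    df["imbalanced"] = testable & (df["q"] <= q_cutoff)
    return df


def footprint_overlap_enrichment(
    results: pd.DataFrame,
    footprints: Sequence,
    dhs_intervals: Sequence[GenomicInterval] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Compare imbalance rates inside vs outside footprinted DHS positions.

    ``results`` is the :func:`imbalance_test` table.  Variants are
    partitioned by overlap with the footprint intervals (optionally
    restricted to those inside a DHS).  Returns the annotated table and a
    summary with per-partition imbalanced fractions, their ratio (NaN when
    undefined) and a Fisher exact p-value.
    """
    fp_ivs = [getattr(f, "interval", f) for f in footprints]
    df = results.copy()
    in_fp = []
    for contig, pos in zip(df["contig"], df["position"]):
        in_fp.append(any(iv.contains_position(str(contig), int(pos)) for iv in fp_ivs))
    df["in_footprint"] = in_fp
    if dhs_intervals is not None:
        in_dhs = [
            any(iv.contains_position(str(c), int(p)) for iv in dhs_intervals)
            for c, p in zip(df["contig"], df["position"])
        ]
        df = df[np.asarray(in_dhs)]

    tested = df[df["testable"]]
    fp = tested[tested["in_footprint"]]
    non = tested[~tested["in_footprint"]]
    frac_fp = float(fp["imbalanced"].mean()) if len(fp) else np.nan
    frac_non = float(non["imbalanced"].mean()) if len(non) else np.nan
    if np.isnan(frac_fp) or np.isnan(frac_non) or frac_non == 0:
        ratio = np.nan
    else:
        ratio = frac_fp / frac_non
    if len(fp) and len(non):
        table = [
            [int(fp["imbalanced"].sum()), int((~fp["imbalanced"]).sum())],
            [int(non["imbalanced"].sum()), int((~non["imbalanced"]).sum())],
        ]
        p_value = float(fisher_exact(table)[1])
    else:
        p_value = np.nan
    summary = {
        "n_footprinted": int(len(fp)),
        "n_non_footprinted": int(len(non)),
        "frac_imbalanced_footprinted": frac_fp,
        "frac_imbalanced_non_footprinted": frac_non,
        "enrichment_ratio": ratio,
        "p_value": p_value,
    }
    return df, summary
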