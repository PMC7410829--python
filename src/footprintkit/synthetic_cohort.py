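"""Synthetic cleavage cohorts with fully known ground truth.

The generator emulates the data-generating assumptions of digital genomic
footprinting: hypersensitive regions (DHSs) of elevated cleavage rate on a
uniform-ACGT genome, a 6-mer sequence preference modulating per-base rates,
planted protected footprints that multiply the rate by a depletion ratio
delta in (0, 1), negative-binomial count noise with a configurable size
parameter, group-specific footprints for differential testing, and
heterozygous variants that modulate protection on one haplotype (allele
counts are recorded for cleavages a typical read length around the
variant).  The per-position rate for a sample is

    lambda_i = depth * dhs_multiplier * bias(context_i) * delta_i,

split equally between strands and (for het carriers) haplotypes, each
component drawn NB with a proportional share of the size parameter so the
combined count is NB(lambda_i, r).  Everything is deterministic given the
seed.  The sampler is written directly against the generative model and
shares no code with the fitting/testing path, so it can serve as an
independent oracle for it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .cleavage_bias import BiasModel, _context_codes, encode_sequence
from .tracks_io import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    CleavageProfile,
    GenomeSequence,
    GenomicInterval,
    VariantRecord,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_vcf,
)

__all__ = [
    "CohortSpec",
    "PlantedVariant",
    "PlantedFootprint",
    "SampleInfo",
    "SimulationTruth",
    "SimulatedSample",
    "simulate_truth",
    "simulate_sample",
    "simulate_cohort",
]

_BASES = "ACGT"


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults describe a desk-scale cohort: a 2 Mb uniform-ACGT genome with
    ~500 non-overlapping 200-bp DHSs, footprints (width 8-30 bp, depletion
    ratio 0.1-0.4) planted in half of them, log-normal 6-mer bias with
    sd 0.25, NB noise with size r = 8, and 20-30 expected cleavages per bp
    inside DHSs.
    """

    genome_length: int = 2_000_000
    contig: str = "chrS"
    n_dhs: int = 500
    dhs_width: int = 200
    dhs_gap_min: int = 500
    dhs_multiplier_range: tuple[float, float] = (1.0, 1.5)
    footprint_fraction: float = 0.5
    footprints_per_dhs: tuple[int, int] = (1, 3)
    footprint_width_range: tuple[int, int] = (8, 30)
    depletion_range: tuple[float, float] = (0.1, 0.4)
    edge_margin: int = 10
    footprint_spacing: int = 8
    n_samples_a: int = 2
    n_samples_b: int = 2
    depth_range: tuple[float, float] = (20.0, 30.0)
    bias_sd: float = 0.25
    bias_k: int = 6
    bias_offset: int = 3
    r_dispersion: float = 8.0
    frac_group_specific: float = 0.0
    frac_variant_footprints: float = 0.0
    alt_allele_modifier: float = 0.5  # alt haplotype: delta * modifier
    read_span: int = 36
    background_rate: float = 0.0  # DHS-relative rate outside DHSs

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (*self.footprints_per_dhs, "footprints_per_dhs"),
            (*self.footprint_width_range, "footprint_width_range"),
            (*self.depletion_range, "depletion_range"),
            (*self.depth_range, "depth_range"),
            (*self.dhs_multiplier_range, "dhs_multiplier_range"),
        ):
            if lo > hi:
                raise ValueError(f"{name} bounds out of order: ({lo}, {hi})")
        if not 0 < self.depletion_range[0] <= self.depletion_range[1] < 1:
            raise ValueError("depletion ratios must lie in (0, 1)")
        if min(self.n_dhs, self.genome_length) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PlantedVariant:
    position: int
    ref: str
    alt: str
    ref_modifier: float = 1.0
    alt_modifier: float = 0.5


@dataclass
class PlantedFootprint:
    interval: GenomicInterval
    depletion: float
    group: str = "both"  # both | A | B
    variant: PlantedVariant | None = None
    dhs_index: int | None = None  # index of the parent DHS in the truth

    def active_for(self, group: str) -> bool:
        return self.group in ("both", group)


@dataclass
class SampleInfo:
    sample_id: str
    group: str
    individual: str
    depth: float


@dataclass
class SimulationTruth:
    spec: CohortSpec
    seed: int
    genome: GenomeSequence
    dhs: list[tuple[GenomicInterval, float]]
    footprints: list[PlantedFootprint]
    variants: list[VariantRecord]
    bias: BiasModel
    samples: list[SampleInfo]

    def active_footprints(self, group: str) -> list[PlantedFootprint]:
        return [fp for fp in self.footprints if fp.active_for(group)]


@dataclass
class SimulatedSample:
    info: SampleInfo
    profile: CleavageProfile
    allele_counts: dict[int, tuple[int, int]]  # variant index -> (n_ref, n_alt)


def _pack_intervals(
    span_lo: int,
    span_hi: int,
    widths: Sequence[int],
    gap_min: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Place non-overlapping intervals with minimum gaps, randomly spread."""
    n = len(widths)
    if n == 0:
        return []
    need = int(np.sum(widths)) + gap_min * (n - 1)
    space = span_hi - span_lo
    if need > space:
        raise ValueError(
            f"cannot pack {n} intervals totalling {int(np.sum(widths))} bp with "
            f"gaps >= {gap_min} bp into {space} bp"
        )
    extra = space - need
    slack = rng.multinomial(extra, np.full(n + 1, 1.0 / (n + 1)))
    out = []
    pos = span_lo
    for i, w in enumerate(widths):
        pos += int(slack[i]) + (gap_min if i > 0 else 0)
        out.append((pos, pos + int(w)))
        pos += int(w)
    return out


def simulate_truth(spec: CohortSpec, seed: int) -> SimulationTruth:
    """Draw a complete ground-truth configuration from the spec.

    The genome is i.i.d. uniform ACGT; DHSs are non-overlapping with at
    least ``dhs_gap_min`` bp between them; footprints sit inside DHSs with
    an edge margin and minimum spacing.  Raises when the requested elements
    cannot be packed into the genome.
    """
    rng = np.random.default_rng(seed)
    base_idx = rng.integers(0, 4, size=spec.genome_length)
    ascii_bases = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    sequence = ascii_bases[base_idx].tobytes().decode("ascii")
    genome = GenomeSequence({spec.contig: sequence})

    dhs_bounds = _pack_intervals(
        0,
        spec.genome_length,
        [spec.dhs_width] * spec.n_dhs,
        spec.dhs_gap_min,
        rng,
    )
    multipliers = rng.uniform(*spec.dhs_multiplier_range, size=spec.n_dhs)
    dhs = [
        (GenomicInterval(spec.contig, s, e), float(m))
        for (s, e), m in zip(dhs_bounds, multipliers)
    ]

    n_with_fp = int(round(spec.footprint_fraction * spec.n_dhs))
    with_fp = set(rng.choice(spec.n_dhs, size=n_with_fp, replace=False)) if n_with_fp else set()

    footprints: list[PlantedFootprint] = []
    variants: list[VariantRecord] = []
    genotypes = {"ind1": GT_HET, "ind2": GT_HOM_REF}
    for i, (iv, _m) in enumerate(dhs):
        if i not in with_fp:
            continue
        lo_n, hi_n = spec.footprints_per_dhs
        n_fp = int(rng.integers(lo_n, hi_n + 1)) if hi_n > lo_n else lo_n
        usable_lo = iv.start + spec.edge_margin
        usable_hi = iv.end - spec.edge_margin
        widths = rng.integers(
            spec.footprint_width_range[0],
            spec.footprint_width_range[1] + 1,
            size=n_fp,
        )
        # drop footprints until the set packs into the usable span
        while n_fp > 0:
            need = int(widths[:n_fp].sum()) + spec.footprint_spacing * (n_fp - 1)
            if need <= usable_hi - usable_lo:
                break
            n_fp -= 1
        if n_fp == 0:
            continue
        bounds = _pack_intervals(
            usable_lo, usable_hi, list(widths[:n_fp]), spec.footprint_spacing, rng
        )
        for s, e in bounds:
            delta = float(rng.uniform(*spec.depletion_range))
            group = "both"
            if rng.random() < spec.frac_group_specific:
                group = "A" if rng.random() < 0.5 else "B"
            variant = None
            if rng.random() < spec.frac_variant_footprints:
                pos = (s + e) // 2
                ref = genome[spec.contig][pos]
                alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                variant = PlantedVariant(
                    pos, ref, alt, 1.0, spec.alt_allele_modifier
                )
                variants.append(
                    VariantRecord(spec.contig, pos, ref, alt, dict(genotypes))
                )
            footprints.append(
                PlantedFootprint(
                    GenomicInterval(spec.contig, s, e), delta, group, variant, i
                )
            )

    nk = 4**spec.bias_k
    pref = rng.lognormal(mean=0.0, sigma=spec.bias_sd, size=nk)
    pref /= pref.mean()
    bias = BiasModel(spec.bias_k, spec.bias_offset, pref)

    samples = []
    individuals = ("ind1", "ind2")
    for group, n in (("A", spec.n_samples_a), ("B", spec.n_samples_b)):
        for j in range(n):
            samples.append(
                SampleInfo(
                    sample_id=f"{group}{j + 1:02d}",
                    group=group,
                    individual=individuals[j % 2],
                    depth=float(rng.uniform(*spec.depth_range)),
                )
            )
    return SimulationTruth(spec, seed, genome, dhs, footprints, variants, bias, samples)


def _haplotype_depletion(
    truth: SimulationTruth, info: SampleInfo
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position rate multipliers for the (ref-carrying, alt-carrying)
    haplotypes of this sample.

    Every active footprint depletes both haplotypes by its delta.  A
    variant-linked footprint additionally scales its parent DHS per
    haplotype by the variant's allele modifier (a chromatin-altering
    variant changes accessibility of the whole element on its allele), so
    the expected allelic ratio at the variant is
    ref_modifier / (ref_modifier + alt_modifier).
    """
    n = truth.spec.genome_length
    d_ref = np.ones(n)
    d_alt = np.ones(n)
    for fp in truth.footprints:
        if not fp.active_for(info.group):
            continue
        sl = slice(fp.interval.start, fp.interval.end)
        d_ref[sl] *= fp.depletion
        d_alt[sl] *= fp.depletion
        if fp.variant is not None:
            gt = None
            for v in truth.variants:
                if v.position == fp.variant.position:
                    gt = v.genotypes.get(info.individual, GT_HOM_REF)
                    break
            dhs_iv = truth.dhs[fp.dhs_index][0]
            dsl = slice(dhs_iv.start, dhs_iv.end)
            if gt == GT_HET:
                d_ref[dsl] *= fp.variant.ref_modifier
                d_alt[dsl] *= fp.variant.alt_modifier
            elif gt == GT_HOM_ALT:
                d_ref[dsl] *= fp.variant.alt_modifier
                d_alt[dsl] *= fp.variant.alt_modifier
            else:
                d_ref[dsl] *= fp.variant.ref_modifier
                d_alt[dsl] *= fp.variant.ref_modifier
    return d_ref, d_alt


def simulate_sample(
    truth: SimulationTruth, sample: int | str | SampleInfo, seed
) -> SimulatedSample:
    """Draw one sample's cleavage profile (and allele tallies) from truth."""
    spec = truth.spec
    if isinstance(sample, SampleInfo):
        info = sample
    elif isinstance(sample, str):
        info = next(s for s in truth.samples if s.sample_id == sample)
    else:
        info = truth.samples[sample]
    rng = np.random.default_rng(seed)
    n = spec.genome_length

    lam_base = np.zeros(n)
    for iv, mult in truth.dhs:
        lam_base[iv.start : iv.end] = info.depth * mult
    if spec.background_rate > 0:
        lam_base[lam_base == 0] = info.depth * spec.background_rate

    codes = encode_sequence(truth.genome[spec.contig])
    b_strand = {}
    for strand in "+-":
        ctx, valid = _context_codes(codes, spec.bias_k, spec.bias_offset, strand)
        b_strand[strand] = truth.bias.lookup(ctx, valid)

    d_ref, d_alt = _haplotype_depletion(truth, info)

    nz = np.flatnonzero(lam_base > 0)
    r_comp = spec.r_dispersion / 4.0  # 2 strands x 2 haplotypes
    counts = {}
    for strand in "+-":
        for hap, d_hap in (("ref", d_ref), ("alt", d_alt)):
            lam = lam_base[nz] * b_strand[strand][nz] * d_hap[nz] / 4.0
            draw = np.zeros(n, dtype=np.int64)
            gam = rng.gamma(shape=r_comp, scale=lam / r_comp)
            draw[nz] = rng.poisson(gam)
            counts[(strand, hap)] = draw

    plus = counts[("+", "ref")] + counts[("+", "alt")]
    minus = counts[("-", "ref")] + counts[("-", "alt")]
    profile = CleavageProfile(
        GenomicInterval(spec.contig, 0, n), plus, minus
    )

    allele_counts: dict[int, tuple[int, int]] = {}
    span = spec.read_span
    for vi, v in enumerate(truth.variants):
        if v.genotypes.get(info.individual) != GT_HET:
            continue
        tallies = []
        for hap in ("ref", "alt"):
            # a plus-strand read cut at x covers [x, x+span); minus at x covers (x-span, x]
            p_lo, p_hi = max(0, v.position - span + 1), v.position + 1
            m_lo, m_hi = v.position, min(n, v.position + span)
            tallies.append(
                int(counts[("+", hap)][p_lo:p_hi].sum())
                + int(counts[("-", hap)][m_lo:m_hi].sum())
            )
        allele_counts[vi] = (tallies[0], tallies[1])
    return SimulatedSample(info, profile, allele_counts)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_cohort(
    spec: CohortSpec,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[SimulationTruth, list[SimulatedSample]]:
    """Simulate truth plus every sample; optionally write a fixture directory.

    Per-sample seeds are derived from the cohort seed, so a rerun with the
    same seed reproduces every file byte for byte.  The directory holds the
    genome FASTA, per-strand bedGraphs and allele tallies per sample, truth
    BEDs (DHSs and footprints), a VCF of planted heterozygous variants for
    the two synthetic individuals, the true bias table, a sample sheet and a
    checksum manifest.
    """
    truth = simulate_truth(spec, seed)
    samples = [
        simulate_sample(truth, i, seed=[seed, 1000 + i])
        for i in range(len(truth.samples))
    ]
    if out_dir is None:
        return truth, samples

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    fasta = out / "genome.fa"
    write_fasta(fasta, truth.genome.contigs)
    files.append(fasta)

    import pandas as pd

    dhs_df = pd.DataFrame(
        [
            (iv.contig, iv.start, iv.end, f"dhs{i}", f"{m:.4f}", ".")
            for i, (iv, m) in enumerate(truth.dhs)
        ]
    )
    write_bed(out / "dhs.bed", dhs_df)
    files.append(out / "dhs.bed")

    fp_df = pd.DataFrame(
        [
            (
                fp.interval.contig,
                fp.interval.start,
                fp.interval.end,
                f"fp{i}",
                f"{fp.depletion:.4f}",
                ".",
                fp.group,
            )
            for i, fp in enumerate(truth.footprints)
        ]
    )
    write_bed(out / "footprints.bed", fp_df)
    files.append(out / "footprints.bed")

    if truth.variants:
        write_vcf(
            out / "variants.vcf",
            truth.variants,
            ["ind1", "ind2"],
            truth.genome.lengths,
        )
        files.append(out / "variants.vcf")

    truth.bias.to_tsv(out / "bias.tsv")
    files.append(out / "bias.tsv")

    sheet = pd.DataFrame(
        [
            (s.info.sample_id, s.info.group, s.info.individual, f"{s.info.depth:.4f}")
            for s in samples
        ],
        columns=["sample", "group", "individual", "depth"],
    )
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    files.append(out / "samples.tsv")

    contig_iv = GenomicInterval(spec.contig, 0, spec.genome_length)
    for s in samples:
        for strand, arr in (
            ("plus", s.profile.counts_plus),
            ("minus", s.profile.counts_minus),
        ):
            p = out / f"{s.info.sample_id}.{strand}.bedGraph"
            write_bedgraph(p, contig_iv, arr)
            files.append(p)
        if s.allele_counts:
            rows = [
                (
                    truth.variants[vi].contig,
                    truth.variants[vi].position,
                    nr,
                    na,
                )
                for vi, (nr, na) in sorted(s.allele_counts.items())
            ]
            p = out / f"{s.info.sample_id}.alleles.tsv"
            pd.DataFrame(
                rows, columns=["contig", "position", "n_ref", "n_alt"]
            ).to_csv(p, sep="\t", index=False)
            files.append(p)

    manifest = {
        "seed": int(seed),
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return truth, samples
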