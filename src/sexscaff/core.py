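"""Shared domain types for the sex-linked scaffold classification pipeline.

The pipeline classifies assembly contigs into autosomal, haplotype-duplicate,
X-linked, Y-linked and pseudoautosomal (PAR) regions from the relative
sequencing depth of one male and one female sample, then evaluates the
consequences for downstream population-genetic statistics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np


class RegionClass(str, enum.Enum):
    """True (or called) class of a genomic region.

    AUTOSOME: diploid in both sexes (full depth in both).
    HAPLOTYPE: alternate-allele duplicate, half depth in both sexes.
    X: half depth in males, full in females.
    Y: half depth in males, ~zero in females.
    PAR: pseudoautosomal, full depth in both sexes but X/Y linked.
    OUTLIER: repeat/collapsed region with ~0% or >100% depth.
    """

    AUTOSOME = "AUTOSOME"
    HAPLOTYPE = "HAPLOTYPE"
    X = "X"
    Y = "Y"
    PAR = "PAR"
    OUTLIER = "OUTLIER"


class CallClass(str, enum.Enum):
    """Region call emitted by the male/female depth combination rules."""

    AUTOSOME = "AUTOSOME"
    HAPLOTYPE = "HAPLOTYPE"
    X = "X"
    Y = "Y"
    PAR = "PAR"
    UNCLASSIFIED = "UNCLASSIFIED"


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class CovState(enum.IntEnum):
    """Hidden state of the coverage HMM (fraction of expected full depth)."""

    ZERO = 0
    HALF = 1
    FULL = 2
    EXCESS = 3


#: Mapping from HMM state to the percent-coverage vocabulary used in the
#: male/female combination rules.
STATE_LEVEL = {
    CovState.ZERO: "0%",
    CovState.HALF: "50%",
    CovState.FULL: "100%",
    CovState.EXCESS: ">100%",
}

#: Expected depth multiplier per (region class, sex).
DEPTH_MULTIPLIER = {
    (RegionClass.AUTOSOME, Sex.MALE): 1.0,
    (RegionClass.AUTOSOME, Sex.FEMALE): 1.0,
    (RegionClass.HAPLOTYPE, Sex.MALE): 0.5,
    (RegionClass.HAPLOTYPE, Sex.FEMALE): 0.5,
    (RegionClass.PAR, Sex.MALE): 1.0,
    (RegionClass.PAR, Sex.FEMALE): 1.0,
    (RegionClass.X, Sex.MALE): 0.5,
    (RegionClass.X, Sex.FEMALE): 1.0,
    (RegionClass.Y, Sex.MALE): 0.5,
    (RegionClass.Y, Sex.FEMALE): 0.0,
}


@dataclass(frozen=True)
class Contig:
    contig_id: str
    length: int
    true_class: RegionClass

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.contig_id}: length must be > 0")

    def n_windows(self, window_size: int) -> int:
        return math.ceil(self.length / window_size)


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.contig_id}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig_id: str, pos: int) -> bool:
        return contig_id == self.contig_id and self.start <= pos <= self.end


@dataclass
class GenomeLayout:
    """Synthetic truth: contigs with per-window class labels.

    ``contigs[i].true_class`` records the class a contig was generated for;
    ``window_classes[contig_id]`` carries the authoritative per-window truth
    (a contig generated for the PAR carries an X-linked block followed by a
    PAR block, mimicking a sex chromosome whose pseudoautosomal tail still
    recombines).
    """

    contigs: list[Contig]
    window_classes: dict[str, list[RegionClass]]
    window_size: int
    slr_interval: Interval | None = None
    par_interval: Interval | None = None

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        lengths = {c.contig_id: c.length for c in self.contigs}
        for cid, classes in self.window_classes.items():
            want = math.ceil(lengths[cid] / self.window_size)
            if len(classes) != want:
                raise ValueError(f"{cid}: {len(classes)} window labels, expected {want}")
        for iv in (self.slr_interval, self.par_interval):
            if iv is not None and iv.end > lengths[iv.contig_id]:
                raise ValueError(f"interval {iv} exceeds contig length")
        if (
            self.slr_interval is not None
            and self.par_interval is not None
            and self.slr_interval.contig_id == self.par_interval.contig_id
            and not (
                self.slr_interval.end < self.par_interval.start
                or self.par_interval.end < self.slr_interval.start
            )
        ):
            raise ValueError("SLR and PAR intervals overlap")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.contig_id: c.length for c in self.contigs}

    def class_of_site(self, contig_id: str, pos: int) -> RegionClass:
        """Truth class of a 1-based position (class of its window)."""
        return self.window_classes[contig_id][(pos - 1) // self.window_size]

    def window_count(self, cls: RegionClass) -> int:
        return sum(c == cls for labels in self.window_classes.values() for c in labels)


@dataclass
class DepthTrack:
    """Windowed sequencing depth along one contig for one sex."""

    contig_id: str
    sex: Sex
    window_size: int
    depths: np.ndarray
    base_depth: float

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 1:
            raise ValueError("depths must be one-dimensional")
        if np.any(self.depths < 0):
            raise ValueError("depths must be non-negative")
        if self.base_depth <= 0:
            raise ValueError("base_depth must be > 0")

    @property
    def n_windows(self) -> int:
        return int(self.depths.size)

    def window_start(self, i: int) -> int:
        """1-based start position of window i."""
        return i * self.window_size + 1


@dataclass
class VariantTable:
    """In-memory biallelic SNP table with per-genotype GT/GQ/DP fields.

    Genotype allele codes: 0 ref, 1 alt, -1 missing call, -2 copy absent
    (second slot of a haploid call, or both slots for a sample that carries
    no copy of the region, e.g. a female at a Y-linked site).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    samples: list[str]
    sample_sex: list[Sex]
    gt: np.ndarray  # (n_sites, n_samples, 2) int8
    gq: np.ndarray  # (n_sites, n_samples) int16
    dp: np.ndarray  # (n_sites, n_samples) int16

    def __post_init__(self) -> None:
        n = len(self.pos)
        k = len(self.samples)
        if self.gt.shape != (n, k, 2):
            raise ValueError(f"gt shape {self.gt.shape} != ({n}, {k}, 2)")
        if self.gq.shape != (n, k) or self.dp.shape != (n, k):
            raise ValueError("gq/dp shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            qual=self.qual[mask],
            samples=list(self.samples),
            sample_sex=list(self.sample_sex),
            gt=self.gt[mask],
            gq=self.gq[mask],
            dp=self.dp[mask],
        )

    # ---------------------------------------------------------------- VCF IO

    def to_vcf(self, path, contig_lengths: dict[str, int] | None = None) -> None:
        """Write as uncompressed VCF v4.2 with GT:GQ:DP genotype fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=sexscaff\n")
            if contig_lengths:
                for cid, ln in contig_lengths.items():
                    fh.write(f"##contig=<ID={cid},length={ln}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for i in range(self.n_sites):
                fields = [
                    str(self.chrom[i]),
                    str(int(self.pos[i])),
                    ".",
                    str(self.ref[i]),
                    str(self.alt[i]),
                    f"{float(self.qual[i]):.2f}",
                    "PASS",
                    ".",
                    "GT:GQ:DP",
                ]
                for j in range(self.n_samples):
                    a, b = int(self.gt[i, j, 0]), int(self.gt[i, j, 1])
                    if a == -2:
                        gt = "."
                    elif b == -2:
                        gt = "." if a == -1 else str(a)
                    elif a == -1 or b == -1:
                        gt = "./."
                    else:
                        gt = f"{a}/{b}"
                    gq, dp = int(self.gq[i, j]), int(self.dp[i, j])
                    fields.append(f"{gt}:{gq}:{dp}")
                fh.write("\t".join(fields) + "\n")


def variant_table_from_vcf(path, sample_sex: dict[str, Sex]) -> VariantTable:
    """Read a biallelic-SNP VCF (plain text) produced by :meth:`VariantTable.to_vcf`.

    Uses cyvcf2 for parsing; ploidy is recovered from the GT field shape.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, qual = [], [], [], [], []
    gts, gqs, dps = [], [], []
    for rec in vcf:
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0] if rec.ALT else ".")
        qual.append(rec.QUAL if rec.QUAL is not None else 0.0)
        row = np.full((len(samples), 2), -2, dtype=np.int8)
        for j, g in enumerate(rec.genotypes):  # [allele1, allele2?, phased]
            alleles = g[:-1]
            for slot, a in enumerate(alleles[:2]):
                row[j, slot] = -1 if a < 0 else a
        gts.append(row)
        gq = rec.format("GQ")
        dp = rec.format("DP")
        gqs.append(
            np.zeros(len(samples), dtype=np.int16)
            if gq is None
            else np.nan_to_num(gq.astype(float).ravel()).astype(np.int16)
        )
        dps.append(
            np.zeros(len(samples), dtype=np.int16)
            if dp is None
            else np.nan_to_num(dp.astype(float).ravel()).astype(np.int16)
        )
    return VariantTable(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        qual=np.array(qual, dtype=float),
        samples=samples,
        sample_sex=[sample_sex[s] for s in samples],
        gt=np.stack(gts) if gts else np.zeros((0, len(samples), 2), dtype=np.int8),
        gq=np.stack(gqs) if gqs else np.zeros((0, len(samples)), dtype=np.int16),
        dp=np.stack(dps) if dps else np.zeros((0, len(samples)), dtype=np.int16),
    )
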