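"""Variant filtering, ploidy-aware windowed nucleotide diversity and
compartment comparisons.

Nucleotide diversity (π) is estimated per site as the unbiased pooled
heterozygosity n/(n-1) * (1 - Σ p_a²) over the allele copies actually
present after ploidy resolution (haploid male calls contribute one copy
inside the sex-linked region and on the Y, diploid calls two), summed over
sites and divided by window length — 100 kb non-overlapping windows by
default. Compartment differences are tested pairwise, choosing the paired
t-test when the paired differences look normal (Shapiro–Wilk) and the
Wilcoxon signed-rank test otherwise.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Interval, Sex, VariantTable

__all__ = [
    "FilterConfig",
    "FilterReport",
    "PiWindow",
    "Compartment",
    "CompartmentTest",
    "filter_variants",
    "windowed_pi",
    "compartment_tests",
    "paired_compartment_test",
    "neutral_expectation",
]


class Compartment(str, enum.Enum):
    AUTOSOME = "AUTOSOME"
    SLR = "SLR"
    PAR = "PAR"
    Y = "Y"


@dataclass(frozen=True)
class FilterConfig:
    """Site/genotype filter thresholds (VCFtools-style conventions).

    ``max_missing`` follows the VCFtools ``--max-missing`` meaning: a site is
    kept when its call rate is at least this fraction (so 0.2 keeps sites
    with >= 20% of samples called — the flag name inverts intuition).
    """

    min_gq: int = 20
    min_site_qual: float = 30.0
    min_mean_dp: float = 3.0
    max_mean_dp: float = 35.0
    min_maf: float = 0.05
    max_missing: float = 0.2
    exclude_bed: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if self.min_mean_dp >= self.max_mean_dp:
            raise ValueError("min_mean_dp must be < max_mean_dp")


@dataclass
class FilterReport:
    """Counts of genotypes masked and sites removed per rule."""

    n_input_sites: int = 0
    n_genotypes_masked: int = 0
    removed_qual: int = 0
    removed_mean_dp: int = 0
    removed_maf: int = 0
    removed_missing: int = 0
    removed_excluded: int = 0

    @property
    def n_kept(self) -> int:
        return (
            self.n_input_sites
            - self.removed_qual
            - self.removed_mean_dp
            - self.removed_maf
            - self.removed_missing
            - self.removed_excluded
        )


def filter_variants(
    table: VariantTable, cfg: FilterConfig
) -> tuple[VariantTable, FilterReport]:
    """Apply genotype- and site-level filters; returns the surviving table
    and a per-rule removal report.

    Genotypes with GQ below the threshold are set missing first; site rules
    (QUAL, mean depth, minor-allele frequency, call rate, excluded
    intervals) are then evaluated jointly on the masked table, so the
    surviving site set is independent of rule order.
    """
    rep = FilterReport(n_input_sites=table.n_sites)
    if table.n_sites == 0:
        return table, rep
    gt = table.gt.copy()
    called = gt >= 0
    low_gq_gt = (table.gq < cfg.min_gq) & called.any(axis=2)
    rep.n_genotypes_masked = int(low_gq_gt.sum())
    gt[low_gq_gt[:, :, None] & called] = -1

    present_copies = (gt != -2).sum(axis=(1, 2))  # copies the sample set carries
    called_copies = (gt >= 0).sum(axis=(1, 2))
    alt_copies = (gt == 1).sum(axis=(1, 2))

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called_copies > 0, alt_copies / np.maximum(called_copies, 1), 0.0)
        maf = np.minimum(p, 1 - p)
        call_rate = np.where(present_copies > 0, called_copies / np.maximum(present_copies, 1), 0.0)
    # mean DP over samples that carry the region at all
    carries = (table.gt != -2).any(axis=2)
    mean_dp = np.where(
        carries.sum(axis=1) > 0,
        (table.dp * carries).sum(axis=1) / np.maximum(carries.sum(axis=1), 1),
        0.0,
    )

    fail_qual = table.qual < cfg.min_site_qual
    fail_dp = (mean_dp < cfg.min_mean_dp) | (mean_dp > cfg.max_mean_dp)
    fail_maf = maf < cfg.min_maf
    fail_missing = call_rate < cfg.max_missing
    fail_excl = np.zeros(table.n_sites, dtype=bool)
    for iv in cfg.exclude_bed:
        fail_excl |= (table.chrom == iv.contig_id) & (table.pos >= iv.start) & (
            table.pos <= iv.end
        )

    # attribute each removed site to the first failing rule, for reporting
    removed = fail_qual | fail_dp | fail_maf | fail_missing | fail_excl
    rep.removed_qual = int(fail_qual.sum())
    rep.removed_mean_dp = int((fail_dp & ~fail_qual).sum())
    rep.removed_maf = int((fail_maf & ~fail_qual & ~fail_dp).sum())
    rep.removed_missing = int((fail_missing & ~fail_qual & ~fail_dp & ~fail_maf).sum())
    rep.removed_excluded = int(
        (fail_excl & ~fail_qual & ~fail_dp & ~fail_maf & ~fail_missing).sum()
    )
    out = table.subset_sites(~removed)
    out.gt = gt[~removed]
    return out, rep


@dataclass(frozen=True)
class PiWindow:
    """Nucleotide diversity in one genomic window (per-site units)."""

    chrom: str
    start: int  # 1-based
    end: int
    pi: float
    n_sites_used: int
    compartment: Compartment
    short_window: bool = False  # terminal window shorter than the nominal size
    no_data: bool = False  # zero callable allele copies in the window


def _site_pi(gt_row: np.ndarray) -> tuple[float, int]:
    """Unbiased per-site heterozygosity from one site's genotype matrix."""
    alleles = gt_row[gt_row >= 0]
    n = alleles.size
    if n < 2:
        return 0.0, n
    x = int((alleles == 1).sum())
    return 2.0 * x * (n - x) / (n * (n - 1)), n


def windowed_pi(
    table: VariantTable,
    haploid_male_intervals: tuple[Interval, ...] = (),
    contig_lengths: dict[str, int] | None = None,
    compartment_of: dict[str, Compartment] | None = None,
    compartment_intervals: list[tuple[Interval, Compartment]] | None = None,
    window: int = 100_000,
) -> list[PiWindow]:
    """Windowed nucleotide diversity with mixed ploidy.

    ``haploid_male_intervals`` declares where male calls must be haploid
    (the sex-linked region of the X and the whole Y); a male genotype with
    two called copies inside such an interval is a ploidy violation and is
    rejected. Monomorphic sites between the table's variant sites contribute
    zero, so window π is the sum of per-site values divided by the window's
    true length (terminal windows are divided by their own length and
    flagged).

    The compartment of a window defaults to ``compartment_of[chrom]``
    (AUTOSOME when absent); ``compartment_intervals`` overrides it for
    sub-contig partitions such as the SLR/PAR split of a sex chromosome,
    decided by the window midpoint.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    male_cols = np.array([s is Sex.MALE for s in table.sample_sex])
    # ploidy validation
    for iv in haploid_male_intervals:
        in_iv = (table.chrom == iv.contig_id) & (table.pos >= iv.start) & (table.pos <= iv.end)
        if not in_iv.any():
            continue
        male_gt = table.gt[np.ix_(np.flatnonzero(in_iv), np.flatnonzero(male_cols))]
        if (male_gt >= 0).all(axis=2).any():
            raise ValueError(
                f"male diploid genotype inside haploid interval "
                f"{iv.contig_id}:{iv.start}-{iv.end}"
            )

    out: list[PiWindow] = []
    chroms = list(dict.fromkeys(table.chrom.tolist()))
    if contig_lengths:
        for cid in contig_lengths:
            if cid not in chroms:
                chroms.append(cid)
    for cid in chroms:
        mask = table.chrom == cid
        pos = table.pos[mask]
        gts = table.gt[mask]
        length = (contig_lengths or {}).get(cid, int(pos.max()) if pos.size else 0)
        if length == 0:
            continue
        comp = (compartment_of or {}).get(cid, Compartment.AUTOSOME)
        nw = math.ceil(length / window)
        pis = np.zeros(nw)
        counts = np.zeros(nw, dtype=int)
        copies = np.zeros(nw, dtype=int)
        for i in range(pos.size):
            w = (int(pos[i]) - 1) // window
            v, n = _site_pi(gts[i])
            pis[w] += v
            counts[w] += 1
            copies[w] = max(copies[w], n)
        for w in range(nw):
            start = w * window + 1
            end = min((w + 1) * window, length)
            wl = end - start + 1
            wcomp = comp
            if compartment_intervals:
                mid = (start + end) // 2
                for iv, ivcomp in compartment_intervals:
                    if iv.contains(cid, mid):
                        wcomp = ivcomp
                        break
            out.append(
                PiWindow(
                    chrom=cid,
                    start=start,
                    end=end,
                    pi=pis[w] / wl,
                    n_sites_used=int(counts[w]),
                    compartment=wcomp,
                    short_window=wl < window,
                    no_data=copies[w] == 0,
                )
            )
    return out


class TestKind(str, enum.Enum):
    WILCOXON_SIGNED_RANK = "WILCOXON_SIGNED_RANK"
    PAIRED_T = "PAIRED_T"


@dataclass(frozen=True)
class CompartmentTest:
    comparison: str
    statistic: float
    p_value: float
    test_used: TestKind
    n_pairs: int
    significant: bool = False  # at the 0.05 threshold

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError("p_value outside [0, 1]")


def paired_compartment_test(
    a: np.ndarray, b: np.ndarray, comparison: str, alpha_normality: float = 0.05
) -> CompartmentTest:
    """Paired two-sided comparison of two matched vectors of π means.

    Uses the paired t-test when Shapiro–Wilk does not reject normality of
    the paired differences at ``alpha_normality``, otherwise the Wilcoxon
    signed-rank test. Degenerate difference vectors (zero variance) fall
    back to the signed-rank convention with a warning; identical vectors
    return p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and the same length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    diff = a - b
    if np.allclose(diff, diff[0]):
        if np.allclose(diff, 0.0):
            return CompartmentTest(comparison, 0.0, 1.0, TestKind.WILCOXON_SIGNED_RANK, n)
        warnings.warn("constant nonzero paired differences: falling back to signed-rank")
        res = stats.wilcoxon(diff)
        return CompartmentTest(
            comparison, float(res.statistic), float(res.pvalue),
            TestKind.WILCOXON_SIGNED_RANK, n, bool(res.pvalue < 0.05),
        )
    sw_p = stats.shapiro(diff).pvalue
    if sw_p >= alpha_normality:
        res = stats.ttest_rel(a, b)
        kind = TestKind.PAIRED_T
    else:
        res = stats.wilcoxon(diff)
        kind = TestKind.WILCOXON_SIGNED_RANK
    return CompartmentTest(
        comparison, float(res.statistic), float(res.pvalue), kind, n,
        bool(res.pvalue < 0.05),
    )


def compartment_tests(
    pi_by_population: dict[str, dict[Compartment, list[PiWindow]]],
    alpha_normality: float = 0.05,
) -> list[CompartmentTest]:
    """Pairwise compartment comparisons of per-population mean π.

    Each population contributes one mean π per compartment (mean over its
    windows with data); compartment pairs present in every population are
    compared with matched pairs across populations.
    """
    pops = list(pi_by_population)
    comps = sorted(
        {c for d in pi_by_population.values() for c in d}, key=lambda c: c.value
    )
    means: dict[Compartment, list[float]] = {}
    for comp in comps:
        vals = []
        for pop in pops:
            wins = [w for w in pi_by_population[pop].get(comp, []) if not w.no_data]
            if not wins:
                break
            vals.append(float(np.mean([w.pi for w in wins])))
        else:
            means[comp] = vals
    out: list[CompartmentTest] = []
    usable = list(means)
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            ca, cb = usable[i], usable[j]
            out.append(
                paired_compartment_test(
                    np.array(means[ca]),
                    np.array(means[cb]),
                    comparison=f"{ca.value}_vs_{cb.value}",
                    alpha_normality=alpha_normality,
                )
            )
    return out


def neutral_expectation(pi_autosome: float, compartment: Compartment | str) -> float:
    """Neutral equilibrium diversity expectation relative to autosomes:
    3/4 of the autosomal π for the X, 1/4 for the Y (equal breeding sex
    numbers)."""
    if pi_autosome < 0:
        raise ValueError("pi_autosome must be >= 0")
    comp = compartment if isinstance(compartment, str) else compartment.value
    if comp in ("X", "SLR"):
        return 0.75 * pi_autosome
    if comp == "Y":
        return 0.25 * pi_autosome
    raise ValueError(f"no neutral expectation for compartment {compartment!r}")


def write_pi_windows(windows: list[PiWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_sites\tpi\tcompartment\tshort_window\tno_data\n")
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_sites_used}\t{w.pi:.8g}"
                f"\t{w.compartment.value}\t{int(w.short_window)}\t{int(w.no_data)}\n"
            )
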