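"""Synthetic genomes, depth tracks, variant tables and Wright–Fisher simulations.

Everything downstream of read alignment is exercised against data generated
here, with known truth: a contig set with autosome / haplotype-duplicate /
X / Y / PAR / repeat-outlier composition, male and female window depth tracks
whose means sit at 0%, 50%, 100% or >100% of a base depth (~100x linked-read
coverage), variant tables with ploidy that differs between the sexes on the
sex chromosomes, and forward Wright–Fisher simulations of the neutral
X/autosome and Y/autosome diversity ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEPTH_MULTIPLIER,
    Contig,
    DepthTrack,
    GenomeLayout,
    Interval,
    RegionClass,
    Sex,
    VariantTable,
)

__all__ = [
    "generate_layout",
    "simulate_depth",
    "simulate_variants",
    "WFConfig",
    "WFDiversity",
    "wf_diversity",
    "write_layout_bed",
    "write_depth_tsv",
]

#: fraction of a PAR-requested contig occupied by the X-linked (SLR-like) block
_PAR_X_FRACTION = 0.6


# --------------------------------------------------------------------- layout


def generate_layout(
    n_contigs_per_class: dict[RegionClass, int],
    length_range: tuple[int, int],
    window_size: int = 10_000,
    seed: int = 0,
) -> GenomeLayout:
    """Generate a contig set with known per-window class labels.

    Contigs requested for ``PAR`` are built as sex-chromosome contigs whose
    first ~60% of windows are X-linked (the non-recombining SLR) and whose
    tail is pseudoautosomal; the first such contig defines the layout's SLR
    and PAR intervals. All other classes give single-class contigs.

    Parameters
    ----------
    n_contigs_per_class
        Number of contigs to generate per class. Classes absent from the
        mapping get zero contigs. At least one contig must be requested.
    length_range
        (min, max) contig length in bp, inclusive; must be >= window_size.
    """
    counts = {RegionClass(k): int(v) for k, v in n_contigs_per_class.items()}
    if sum(counts.values()) <= 0:
        raise ValueError("at least one contig must be requested")
    lo, hi = length_range
    if lo > hi or lo < window_size:
        raise ValueError("length_range must satisfy window_size <= min <= max")
    if window_size <= 0:
        raise ValueError("window_size must be > 0")

    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    window_classes: dict[str, list[RegionClass]] = {}
    slr_iv: Interval | None = None
    par_iv: Interval | None = None
    idx = 0
    # deterministic class order, independent of dict insertion order
    for cls in sorted(counts, key=lambda c: c.value):
        for _ in range(counts[cls]):
            idx += 1
            cid = f"ctg{idx:04d}"
            length = int(rng.integers(lo, hi + 1))
            nw = math.ceil(length / window_size)
            if cls is RegionClass.PAR:
                n_x = max(1, min(nw - 1, round(nw * _PAR_X_FRACTION))) if nw > 1 else 0
                labels = [RegionClass.X] * n_x + [RegionClass.PAR] * (nw - n_x)
                if slr_iv is None and n_x > 0:
                    slr_iv = Interval(cid, 1, n_x * window_size)
                    par_iv = Interval(cid, n_x * window_size + 1, length)
            else:
                labels = [cls] * nw
            contigs.append(Contig(cid, length, cls))
            window_classes[cid] = labels
    if slr_iv is None:
        # fall back to the first pure-X contig for the SLR interval
        for c in contigs:
            if c.true_class is RegionClass.X:
                slr_iv = Interval(c.contig_id, 1, c.length)
                break
    return GenomeLayout(
        contigs=contigs,
        window_classes=window_classes,
        window_size=window_size,
        slr_interval=slr_iv,
        par_interval=par_iv,
    )


# ---------------------------------------------------------------- depth tracks


def _outlier_depths(n: int, base_depth: float, rng: np.random.Generator) -> np.ndarray:
    """Outlier window depths: 50/50 near-zero vs a discrete power-law tail
    above 150% of the base depth."""
    out = np.empty(n)
    near_zero = rng.random(n) < 0.5
    k = int(near_zero.sum())
    # near-zero arm: a few percent of base depth
    out[near_zero] = rng.gamma(shape=2.0, scale=0.01 * base_depth, size=k)
    # excess arm: zeta-distributed integer depths truncated to >= 1.5x base
    m = n - k
    if m:
        kmin = max(1, math.ceil(1.5 * base_depth))
        ks = np.arange(kmin, kmin + 50 * max(1, int(base_depth)))
        p = ks.astype(float) ** -2.5
        out[~near_zero] = rng.choice(ks, size=m, p=p / p.sum())
    return out


def simulate_depth(
    layout: GenomeLayout,
    sex: Sex,
    base_depth: float = 100.0,
    dispersion: float = 5.0,
    seed: int = 0,
) -> list[DepthTrack]:
    """Simulate one windowed depth track per contig for one sex.

    Expected window depth is ``base_depth * m(class, sex)`` with m = 1 for
    autosomes and the PAR, 0.5 for haplotype duplicates in both sexes and for
    X/Y in males, 1 for the female X and 0 for the female Y. Noise is gamma
    distributed with variance ``dispersion**2 * (mean / base_depth)``, i.e.
    the standard deviation equals ``dispersion`` at full coverage and scales
    Poisson-like below it; ``dispersion=0`` gives noiseless means.
    """
    if base_depth <= 0:
        raise ValueError("base_depth must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    sex = Sex(sex)
    rng = np.random.default_rng(seed)
    tracks: list[DepthTrack] = []
    for contig in layout.contigs:
        labels = layout.window_classes[contig.contig_id]
        depths = np.zeros(len(labels))
        arr = np.array([c.value for c in labels])
        for cls in set(labels):
            mask = arr == cls.value
            n = int(mask.sum())
            if cls is RegionClass.OUTLIER:
                depths[mask] = _outlier_depths(n, base_depth, rng)
                continue
            if (cls, sex) not in DEPTH_MULTIPLIER:
                raise ValueError(f"unknown class label {cls!r}")
            mu = base_depth * DEPTH_MULTIPLIER[(cls, sex)]
            if mu == 0 or dispersion == 0:
                depths[mask] = mu
            else:
                var = dispersion**2 * (mu / base_depth)
                shape = mu**2 / var
                depths[mask] = rng.gamma(shape=shape, scale=var / mu, size=n)
        tracks.append(
            DepthTrack(
                contig_id=contig.contig_id,
                sex=sex,
                window_size=layout.window_size,
                depths=depths,
                base_depth=base_depth,
            )
        )
    return tracks


# ------------------------------------------------------------- variant tables

#: per-site copy number by (class, sex); None = sample carries no copy
_PLOIDY = {
    RegionClass.AUTOSOME: {Sex.MALE: 2, Sex.FEMALE: 2},
    RegionClass.HAPLOTYPE: {Sex.MALE: 2, Sex.FEMALE: 2},
    RegionClass.PAR: {Sex.MALE: 2, Sex.FEMALE: 2},
    RegionClass.X: {Sex.MALE: 1, Sex.FEMALE: 2},
    RegionClass.Y: {Sex.MALE: 1, Sex.FEMALE: 0},
}

_BASES = np.array(list("ACGT"))


def simulate_variants(
    layout: GenomeLayout,
    pi_target: float,
    n_males: int,
    n_females: int,
    seed: int = 0,
) -> VariantTable:
    """Simulate a biallelic SNP table whose realized per-site heterozygosity
    matches ``pi_target`` in expectation.

    Sites are dropped on each non-outlier region independently; segregating
    sites occur at rate ``pi_target * a_n`` per bp (a_n the harmonic number
    of the sample's allele-copy count) with derived-allele counts drawn from
    the neutral site-frequency spectrum P(i) ∝ 1/i, so that the expected
    heterozygosity per segregating site is 1/a_n and per-bp diversity equals
    ``pi_target``. Males are haploid on X and Y sites; females carry no Y.
    """
    if not 0 < pi_target < 0.01:
        raise ValueError("pi_target must be in (0, 0.01)")
    if n_males < 2 or n_females < 2:
        raise ValueError("need at least 2 individuals per sex")
    rng = np.random.default_rng(seed)
    samples = [f"M{i+1}" for i in range(n_males)] + [f"F{i+1}" for i in range(n_females)]
    sexes = [Sex.MALE] * n_males + [Sex.FEMALE] * n_females
    k = len(samples)

    chrom: list[str] = []
    pos: list[int] = []
    gt_rows: list[np.ndarray] = []

    for contig in layout.contigs:
        labels = layout.window_classes[contig.contig_id]
        # contiguous runs of one class
        run_start = 0
        for w in range(1, len(labels) + 1):
            if w == len(labels) or labels[w] != labels[run_start]:
                cls = labels[run_start]
                start_bp = run_start * layout.window_size + 1
                end_bp = min(w * layout.window_size, contig.length)
                run_start = w
                if cls is RegionClass.OUTLIER:
                    continue
                pl = _PLOIDY[cls]
                n_copies = pl[Sex.MALE] * n_males + pl[Sex.FEMALE] * n_females
                if n_copies < 2:
                    continue
                a_n = np.sum(1.0 / np.arange(1, n_copies))
                length = end_bp - start_bp + 1
                n_sites = rng.poisson(pi_target * length * a_n)
                if n_sites == 0:
                    continue
                site_pos = np.sort(
                    rng.choice(np.arange(start_bp, end_bp + 1), size=n_sites, replace=False)
                    if n_sites <= length
                    else rng.integers(start_bp, end_bp + 1, size=n_sites)
                )
                # derived counts from the neutral SFS
                i_vals = np.arange(1, n_copies)
                p_sfs = (1.0 / i_vals) / a_n
                derived = rng.choice(i_vals, size=n_sites, p=p_sfs)
                for s in range(n_sites):
                    row = np.full((k, 2), -2, dtype=np.int8)
                    copy_owner: list[tuple[int, int]] = []
                    for j, sx in enumerate(sexes):
                        for slot in range(pl[sx]):
                            row[j, slot] = 0
                            copy_owner.append((j, slot))
                    chosen = rng.choice(len(copy_owner), size=int(derived[s]), replace=False)
                    for c in chosen:
                        j, slot = copy_owner[c]
                        row[j, slot] = 1
                    chrom.append(contig.contig_id)
                    pos.append(int(site_pos[s]))
                    gt_rows.append(row)

    n = len(pos)
    gt = np.stack(gt_rows) if n else np.zeros((0, k, 2), dtype=np.int8)
    refalt = rng.integers(0, 4, size=(n, 2))
    refalt[:, 1] = (refalt[:, 0] + rng.integers(1, 4, size=n)) % 4
    gq = np.clip(rng.normal(70, 20, size=(n, k)), 2, 99).astype(np.int16)
    dp = rng.poisson(20, size=(n, k)).astype(np.int16)
    qual = 30.0 + rng.exponential(300.0, size=n)
    order = np.lexsort((np.array(pos), np.array(chrom, dtype=object)))
    return VariantTable(
        chrom=np.array(chrom, dtype=object)[order] if n else np.array([], dtype=object),
        pos=np.array(pos, dtype=np.int64)[order] if n else np.array([], dtype=np.int64),
        ref=_BASES[refalt[:, 0]][order] if n else np.array([], dtype=object),
        alt=_BASES[refalt[:, 1]][order] if n else np.array([], dtype=object),
        qual=qual[order] if n else np.array([], dtype=float),
        samples=samples,
        sample_sex=sexes,
        gt=gt[order] if n else gt,
        gq=gq[order] if n else gq,
        dp=dp[order] if n else dp,
    )


# ------------------------------------------------- Wright–Fisher forward model


@dataclass(frozen=True)
class WFConfig:
    """Configuration of the forward Wright–Fisher diversity simulation.

    ``n_generations`` should be >= 10x the pairwise coalescent time scale
    (~2(n_males+n_females) generations for autosomes) for equilibrium; this
    is recommended, not enforced.
    """

    n_males: int = 50
    n_females: int = 50
    mutation_rate: float = 1e-3  # per locus per generation
    n_generations: int = 2000
    n_loci_per_compartment: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 2 or self.n_females < 2:
            raise ValueError("n_males and n_females must each be >= 2")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")


@dataclass(frozen=True)
class WFDiversity:
    """Per-locus mean pairwise diversity with Monte-Carlo standard errors."""

    pi_autosome: float
    pi_x: float
    pi_y: float
    se_autosome: float
    se_x: float
    se_y: float
    n_loci: int

    def ratio_x(self) -> tuple[float, float]:
        """(pi_X / pi_A, propagated SE)."""
        return _ratio(self.pi_x, self.se_x, self.pi_autosome, self.se_autosome)

    def ratio_y(self) -> tuple[float, float]:
        return _ratio(self.pi_y, self.se_y, self.pi_autosome, self.se_autosome)


def _ratio(a: float, sa: float, b: float, sb: float) -> tuple[float, float]:
    if b == 0:
        return math.nan, math.nan
    r = a / b
    se = abs(r) * math.sqrt((sa / a) ** 2 + (sb / b) ** 2) if a != 0 else sa / b
    return r, se


def _simulate_pool_pi(
    compartment: str,
    cfg: WFConfig,
    rng: np.random.Generator,
    n_sample: int = 16,
    chunk: int = 64,
) -> np.ndarray:
    """Forward-simulate unlinked loci for one inheritance compartment and
    return per-locus mean pairwise diversity.

    Each locus gets an independent pedigree realization. The simulation runs
    forward recording, per generation, which parental copy each offspring
    copy descends from; pairwise coalescence times of copies sampled in the
    final generation are then read off the recorded ancestry, and pairwise
    differences are drawn Poisson(2 * mu * T) under infinite sites.
    """
    nm, nf = cfg.n_males, cfg.n_females
    G, L = cfg.n_generations, cfg.n_loci_per_compartment
    if compartment == "A":
        K = 2 * (nm + nf)
    elif compartment == "X":
        K = nm + 2 * nf
    elif compartment == "Y":
        K = nm
    else:
        raise ValueError(compartment)
    ns = min(n_sample, K)
    pis = np.empty(L)
    done = 0
    while done < L:
        lc = min(chunk, L - done)
        parents = np.empty((G, lc, K), dtype=np.int32)
        for g in range(G):
            parents[g] = _one_generation(compartment, nm, nf, lc, rng)
        # sample distinct final-generation copies per locus (same indices all loci)
        sample_idx = rng.choice(K, size=ns, replace=False)
        paths = np.empty((G + 1, lc, ns), dtype=np.int32)
        paths[0] = np.broadcast_to(sample_idx, (lc, ns))
        rows = np.arange(lc)[:, None]
        for t in range(G):
            paths[t + 1] = parents[G - 1 - t][rows, paths[t]]
        ii, jj = np.triu_indices(ns, k=1)
        eq = paths[1:, :, ii] == paths[1:, :, jj]  # (G, lc, npairs)
        coalesced = eq.any(axis=0)
        tcoal = eq.argmax(axis=0) + 1.0  # generations back to MRCA
        tcoal[~coalesced] = G  # conservative cap; negligible at G >> E[T]
        diffs = rng.poisson(2.0 * cfg.mutation_rate * tcoal)
        pis[done : done + lc] = diffs.mean(axis=1)
        done += lc
    return pis


def _one_generation(
    compartment: str, nm: int, nf: int, lc: int, rng: np.random.Generator
) -> np.ndarray:
    """Parent copy index for each offspring copy, vectorised over lc loci.

    Individual layout: males 0..nm-1, females nm..nm+nf-1. Autosomal copies
    of individual j live at 2j, 2j+1; X copies: male j at index j (one copy),
    female f at nm + 2f, nm + 2f + 1; Y copies: male j at index j.
    """
    n = nm + nf
    if compartment == "A":
        mothers = rng.integers(0, nf, size=(lc, n))
        fathers = rng.integers(0, nm, size=(lc, n))
        mat = 2 * (nm + mothers) + rng.integers(0, 2, size=(lc, n))
        pat = 2 * fathers + rng.integers(0, 2, size=(lc, n))
        out = np.empty((lc, 2 * n), dtype=np.int32)
        out[:, 0::2] = mat
        out[:, 1::2] = pat
        return out
    if compartment == "X":
        # sons: one X from mother; daughters: one X from mother + father's X
        son_mothers = rng.integers(0, nf, size=(lc, nm))
        dau_mothers = rng.integers(0, nf, size=(lc, nf))
        dau_fathers = rng.integers(0, nm, size=(lc, nf))
        son_x = nm + 2 * son_mothers + rng.integers(0, 2, size=(lc, nm))
        dau_mat = nm + 2 * dau_mothers + rng.integers(0, 2, size=(lc, nf))
        out = np.empty((lc, nm + 2 * nf), dtype=np.int32)
        out[:, :nm] = son_x
        out[:, nm::2] = dau_mat
        out[:, nm + 1 :: 2] = dau_fathers  # father's single X is at his index
        return out
    # Y: each son copies his father's Y
    return rng.integers(0, nm, size=(lc, nm)).astype(np.int32)


def wf_diversity(config: WFConfig) -> WFDiversity:
    """Forward Wright–Fisher simulation of autosomal, X-linked and Y-linked
    pairwise nucleotide diversity with separate sexes.

    At demographic equilibrium with equal numbers of breeding males and
    females, X-linked diversity is expected at 3/4 and Y-linked diversity at
    1/4 of the autosomal level; this simulator recovers those ratios within
    Monte-Carlo error.
    """
    rng = np.random.default_rng(config.seed)
    pi_a = _simulate_pool_pi("A", config, rng)
    pi_x = _simulate_pool_pi("X", config, rng)
    pi_y = _simulate_pool_pi("Y", config, rng)
    L = config.n_loci_per_compartment
    return WFDiversity(
        pi_autosome=float(pi_a.mean()),
        pi_x=float(pi_x.mean()),
        pi_y=float(pi_y.mean()),
        se_autosome=float(pi_a.std(ddof=1) / math.sqrt(L)),
        se_x=float(pi_x.std(ddof=1) / math.sqrt(L)),
        se_y=float(pi_y.std(ddof=1) / math.sqrt(L)),
        n_loci=L,
    )


# ------------------------------------------------------------------ text IO


def write_layout_bed(layout: GenomeLayout, bed_path, tsv_path) -> None:
    """Write truth labels as BED (0-based half-open, merged runs) and a
    contig class TSV."""
    ws = layout.window_size
    lengths = layout.contig_lengths
    with open(bed_path, "w") as bed:
        for cid, labels in layout.window_classes.items():
            run = 0
            for w in range(1, len(labels) + 1):
                if w == len(labels) or labels[w] != labels[run]:
                    start0 = run * ws
                    end0 = min(w * ws, lengths[cid])
                    bed.write(f"{cid}\t{start0}\t{end0}\t{labels[run].value}\n")
                    run = w
    with open(tsv_path, "w") as tsv:
        tsv.write("contig_id\tlength\ttrue_class\n")
        for c in layout.contigs:
            tsv.write(f"{c.contig_id}\t{c.length}\t{c.true_class.value}\n")


def write_depth_tsv(tracks: list[DepthTrack], path) -> None:
    """3-column windowed depth TSV: contig, 1-based window start, depth."""
    with open(path, "w") as fh:
        for t in tracks:
            for i, d in enumerate(t.depths):
                fh.write(f"{t.contig_id}\t{t.window_start(i)}\t{d:.6g}\n")
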