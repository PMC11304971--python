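"""Assembly contiguity statistics and version-comparison arithmetic.

N50, totals, per-linkage-group lengths and contig counts, gap counting
(runs of N in scaffold sequence), and the percent-change / count-ratio
arithmetic used when comparing assembly versions (e.g. a "+4.19%" N50
change or a "4.4 times more contigs assigned" ratio).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "AssemblyStats",
    "ComparisonRow",
    "compute_stats",
    "compute_n50",
    "count_gaps",
    "pct_change",
    "count_ratio",
    "compare_assemblies",
    "read_fasta_lengths",
]

_N_RUN = re.compile(r"[Nn]+")


def read_fasta_lengths(path) -> tuple[dict[str, int], dict[str, int]]:
    """Sequence lengths and N-run gap counts from a FASTA file."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    lengths = {name: len(fa[name]) for name in fa.keys()}
    gaps = {name: count_gaps(str(fa[name][:])) for name in fa.keys()}
    return lengths, gaps


def count_gaps(sequence: str) -> int:
    """Number of gaps in a scaffold = number of maximal runs of N (length >= 1)."""
    return len(_N_RUN.findall(sequence))


def compute_n50(lengths) -> int:
    """N50: length of the shortest sequence in the smallest set of longest
    sequences covering at least half the total assembly length."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0 or (arr <= 0).any():
        raise ValueError("need a non-empty set of positive lengths")
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[int(np.searchsorted(csum, half))])


@dataclass
class AssemblyStats:
    n50: int
    total_length: int
    n_contigs_in_lgs: int
    n_unassigned: int
    unassigned_length: int
    n_gaps_autosomes: int
    per_lg: dict[str, tuple[int, int]] = field(default_factory=dict)  # LG -> (length, n)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature\tvalue\n")
            fh.write(f"n50\t{self.n50}\n")
            fh.write(f"total_length\t{self.total_length}\n")
            fh.write(f"contigs_in_lgs\t{self.n_contigs_in_lgs}\n")
            fh.write(f"unassigned_contigs\t{self.n_unassigned}\n")
            fh.write(f"unassigned_length\t{self.unassigned_length}\n")
            fh.write(f"gaps_autosomes\t{self.n_gaps_autosomes}\n")
            for lg, (ln, n) in sorted(self.per_lg.items()):
                fh.write(f"{lg}_length\t{ln}\n")
                fh.write(f"{lg}_contigs\t{n}\n")


def compute_stats(
    lengths: dict[str, int],
    lg_assignment: dict[str, str] | None = None,
    gaps: dict[str, int] | None = None,
    sex_lgs: frozenset[str] = frozenset({"LG12", "LG22"}),
) -> AssemblyStats:
    """Contiguity statistics from sequence lengths, LG assignment and
    per-sequence gap counts.

    ``lg_assignment`` maps contig/scaffold id to its linkage group;
    unassigned sequences are those absent from the mapping. Autosomal gaps
    sum over sequences whose LG is not one of ``sex_lgs``.
    """
    if not lengths:
        raise ValueError("no sequences")
    lg_assignment = lg_assignment or {}
    unknown = set(lg_assignment) - set(lengths)
    if unknown:
        raise ValueError(f"assigned contigs absent from sequences: {sorted(unknown)[:5]}")
    per_lg: dict[str, tuple[int, int]] = {}
    for cid, lg in lg_assignment.items():
        ln, n = per_lg.get(lg, (0, 0))
        per_lg[lg] = (ln + lengths[cid], n + 1)
    unassigned = [cid for cid in lengths if cid not in lg_assignment]
    gaps = gaps or {}
    n_gaps_auto = sum(
        gaps.get(cid, 0)
        for cid in lengths
        if lg_assignment.get(cid) is not None and lg_assignment[cid] not in sex_lgs
    )
    return AssemblyStats(
        n50=compute_n50(lengths.values()),
        total_length=int(sum(lengths.values())),
        n_contigs_in_lgs=len(lg_assignment),
        n_unassigned=len(unassigned),
        unassigned_length=int(sum(lengths[c] for c in unassigned)),
        n_gaps_autosomes=int(n_gaps_auto),
        per_lg=per_lg,
    )


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct_change(v_old: float, v_new: float, decimals: int = 2) -> float:
    """Percent change (v_new - v_old) / v_old * 100, rounded half-up."""
    if v_old == 0:
        raise ValueError("v_old must be nonzero")
    return _round_half_up((v_new - v_old) / v_old * 100.0, decimals)


def count_ratio(
    numerator: int, denominator: int, decimals: int = 1, as_percent: bool = False
) -> float:
    """Ratio of two counts, optionally as a percentage, rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    r = numerator / denominator
    if as_percent:
        r *= 100.0
    return _round_half_up(r, decimals)


@dataclass(frozen=True)
class ComparisonRow:
    feature: str
    v_old: float
    v_new: float
    pct_change: float


def compare_assemblies(
    old: dict[str, float], new: dict[str, float], decimals: int = 2
) -> pd.DataFrame:
    """Feature-by-feature comparison table with the percent-change column."""
    rows = []
    for feat in old:
        if feat not in new:
            continue
        rows.append(
            ComparisonRow(feat, old[feat], new[feat], pct_change(old[feat], new[feat], decimals))
        )
    return pd.DataFrame([r.__dict__ for r in rows])
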