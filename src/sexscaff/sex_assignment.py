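"""Male/female segmentation combination: region calls, PAR separation,
linkage-map marker emission and truth-based evaluation.

The combination rule table: a window is called AUTOSOME when both sexes show
100% coverage, HAPLOTYPE when both show 50%, X when the male shows 50% and
the female 100%, Y when the male shows 50% and the female 0%. Any pair
involving >100% in either sex — and every other pair — is UNCLASSIFIED
(candidate repeat or collapsed region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import STATE_LEVEL, CallClass, CovState, GenomeLayout, RegionClass
from .coverage_model import StateSegmentation

__all__ = [
    "RegionCall",
    "MapMarker",
    "LEVEL_PAIR_RULES",
    "classify_regions",
    "separate_par",
    "emit_map_markers",
    "summarize_assignment",
    "AssignmentSummary",
]


@dataclass(frozen=True)
class RegionCall:
    """Classified interval, 1-based inclusive coordinates."""

    contig_id: str
    start: int
    end: int
    call: CallClass
    male_level: str
    female_level: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("require 1 <= start <= end")


@dataclass(frozen=True)
class MapMarker:
    """Coverage-derived linkage-map marker; always at 0 cM."""

    contig_id: str
    position: int
    linkage_group: str
    map_position_cM: float = 0.0


def _pair_call(male: CovState, female: CovState) -> CallClass:
    if male is CovState.EXCESS or female is CovState.EXCESS:
        return CallClass.UNCLASSIFIED
    if male is CovState.FULL and female is CovState.FULL:
        return CallClass.AUTOSOME
    if male is CovState.HALF and female is CovState.HALF:
        return CallClass.HAPLOTYPE
    if male is CovState.HALF and female is CovState.FULL:
        return CallClass.X
    if male is CovState.HALF and female is CovState.ZERO:
        return CallClass.Y
    return CallClass.UNCLASSIFIED


#: The full 16-entry rule table over (male level, female level) pairs.
LEVEL_PAIR_RULES: dict[tuple[str, str], CallClass] = {
    (STATE_LEVEL[m], STATE_LEVEL[f]): _pair_call(m, f)
    for m in CovState
    for f in CovState
}


def classify_regions(
    male_seg: StateSegmentation,
    female_seg: StateSegmentation,
    window_size: int,
    contig_length: int | None = None,
) -> list[RegionCall]:
    """Combine the two sexes' Viterbi paths into merged region calls."""
    if male_seg.contig_id != female_seg.contig_id:
        raise ValueError("segmentations are for different contigs")
    if male_seg.n_windows != female_seg.n_windows:
        raise ValueError("segmentations have mismatched window grids")
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    m = male_seg.states
    f = female_seg.states
    calls: list[RegionCall] = []
    start = 0
    n = m.size

    def key(i: int) -> tuple[int, int]:
        return int(m[i]), int(f[i])

    for i in range(1, n + 1):
        if i == n or key(i) != key(start):
            ms, fs = CovState(int(m[start])), CovState(int(f[start]))
            end_bp = i * window_size
            if contig_length is not None:
                end_bp = min(end_bp, contig_length)
            calls.append(
                RegionCall(
                    contig_id=male_seg.contig_id,
                    start=start * window_size + 1,
                    end=end_bp,
                    call=_pair_call(ms, fs),
                    male_level=STATE_LEVEL[ms],
                    female_level=STATE_LEVEL[fs],
                )
            )
            start = i
    # merge adjacent same-call regions (level pairs may differ within a call)
    merged: list[RegionCall] = []
    for c in calls:
        if merged and merged[-1].call is c.call and merged[-1].end + 1 == c.start:
            prev = merged.pop()
            c = RegionCall(c.contig_id, prev.start, c.end, c.call, prev.male_level, prev.female_level)
        merged.append(c)
    return merged


def separate_par(calls: list[RegionCall], x_linked_contigs: set[str]) -> list[RegionCall]:
    """Relabel AUTOSOME calls as PAR on X-linked contigs.

    The pseudoautosomal region shows 100% coverage in both sexes and is thus
    called AUTOSOME by the rule table; it is recognised by sitting on a
    contig with X calls or prior X-linkage evidence (the ``x_linked_contigs``
    set) and kept with the X linkage group.
    """
    out: list[RegionCall] = []
    for c in calls:
        if c.call is CallClass.AUTOSOME and c.contig_id in x_linked_contigs:
            c = RegionCall(c.contig_id, c.start, c.end, CallClass.PAR, c.male_level, c.female_level)
        out.append(c)
    return out


def emit_map_markers(calls: list[RegionCall], marker_spacing: int = 10_000) -> list[MapMarker]:
    """Emit 0 cM linkage-map markers: X and PAR regions feed the X-linked
    group (LG12), Y regions the Y-linked group (LG22); one marker per
    ``marker_spacing`` bp within each region."""
    if marker_spacing <= 0:
        raise ValueError("marker_spacing must be > 0")
    lg_of = {CallClass.X: "LG12", CallClass.PAR: "LG12", CallClass.Y: "LG22"}
    markers: list[MapMarker] = []
    for c in calls:
        lg = lg_of.get(c.call)
        if lg is None:
            continue
        for pos in range(c.start, c.end + 1, marker_spacing):
            markers.append(MapMarker(c.contig_id, pos, lg, 0.0))
    return markers


@dataclass
class AssignmentSummary:
    """Window-level confusion matrix (truth rows, call columns) and per-class
    precision/recall."""

    confusion: pd.DataFrame
    precision: dict[str, float]
    recall: dict[str, float]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            self.confusion.to_csv(fh, sep="\t")
            fh.write("\nclass\tprecision\trecall\n")
            for cls in self.confusion.index:
                fh.write(
                    f"{cls}\t{self.precision.get(cls, float('nan')):.4f}"
                    f"\t{self.recall.get(cls, float('nan')):.4f}\n"
                )


_TRUTH_TO_CALL = {
    RegionClass.AUTOSOME: CallClass.AUTOSOME,
    RegionClass.HAPLOTYPE: CallClass.HAPLOTYPE,
    RegionClass.X: CallClass.X,
    RegionClass.Y: CallClass.Y,
    RegionClass.PAR: CallClass.PAR,
    RegionClass.OUTLIER: CallClass.UNCLASSIFIED,  # repeat outliers have no call class
}


def summarize_assignment(calls: list[RegionCall], truth: GenomeLayout) -> AssignmentSummary:
    """Window-level evaluation of region calls against the synthetic truth.

    PAR and AUTOSOME share a coverage level pair, so their mutual confusion
    is visible as distinct off-diagonal cells rather than being folded
    together.
    """
    ws = truth.window_size
    classes = [c.value for c in CallClass]
    lengths = truth.contig_lengths
    pred: dict[str, np.ndarray] = {}
    for cid, labels in truth.window_classes.items():
        pred[cid] = np.full(len(labels), -1, dtype=int)
    for c in calls:
        if c.contig_id not in pred:
            raise ValueError(f"call on unknown contig {c.contig_id}")
        w0 = (c.start - 1) // ws
        w1 = (min(c.end, lengths[c.contig_id]) - 1) // ws
        pred[c.contig_id][w0 : w1 + 1] = classes.index(c.call.value)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    unk = classes.index(CallClass.UNCLASSIFIED.value)
    for cid, labels in truth.window_classes.items():
        for w, true_cls in enumerate(labels):
            t = classes.index(_TRUTH_TO_CALL[true_cls].value)
            p = pred[cid][w]
            conf[t, unk if p < 0 else p] += 1
    df = pd.DataFrame(conf, index=classes, columns=classes)
    precision = {
        cls: float(df.loc[cls, cls] / df[cls].sum()) if df[cls].sum() else float("nan")
        for cls in classes
    }
    recall = {
        cls: float(df.loc[cls, cls] / df.loc[cls].sum()) if df.loc[cls].sum() else float("nan")
        for cls in classes
    }
    return AssignmentSummary(confusion=df, precision=precision, recall=recall)


# ------------------------------------------------------------------- text IO


def write_region_calls(calls: list[RegionCall], bed_path, tsv_path=None) -> None:
    """Region calls as BED (0-based half-open) and optionally a full TSV."""
    with open(bed_path, "w") as fh:
        for c in calls:
            fh.write(f"{c.contig_id}\t{c.start - 1}\t{c.end}\t{c.call.value}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("contig_id\tstart\tend\tcall\tmale_level\tfemale_level\n")
            for c in calls:
                fh.write(
                    f"{c.contig_id}\t{c.start}\t{c.end}\t{c.call.value}"
                    f"\t{c.male_level}\t{c.female_level}\n"
                )


def read_region_calls_bed(path) -> list[RegionCall]:
    """Read calls back from BED; level columns are not recoverable from BED."""
    calls = []
    with open(path) as fh:
        for line in fh:
            cid, s0, e0, name = line.rstrip("\n").split("\t")[:4]
            calls.append(
                RegionCall(cid, int(s0) + 1, int(e0), CallClass(name), "", "")
            )
    return calls


def write_map_markers(markers: list[MapMarker], path) -> None:
    """4-column linkage-map text: contig, position, linkage group, cM."""
    with open(path, "w") as fh:
        for m in markers:
            fh.write(f"{m.contig_id}\t{m.position}\t{m.linkage_group}\t{m.map_position_cM:g}\n")
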