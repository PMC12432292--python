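"""Clade-diagnostic motif screening over a multiple sequence alignment.

The screen looks for short windows of the alignment that are (i) embedded in
conserved context, (ii) shared — up to a small amount of IUPAC-coded
within-clade variation — by the members of one clade, and (iii) nearly
absent outside it. Such windows are molecular synapomorphies: alignment
motifs usable as diagnostic characters for the clade.

Definitions
-----------
conserved column
    A column whose modal non-gap residue reaches frequency ``cons_col``
    among covering sequences and whose gap fraction is at most
    ``max_gap_frac``. A window is *conserved* when at least a fraction
    ``cons_window`` of its columns are conserved; diagnostic columns are by
    construction variable across the whole alignment, so the rule tolerates
    them inside otherwise conserved context.
clade consensus
    Per window column, the minimal IUPAC code covering every residue
    observed among the supporting clade members. Members whose terminal
    missing-data span does not cover the whole window are excluded from
    support; a member with an *internal* gap inside the window rejects the
    window for that clade (the clade does not share an ungapped motif
    there).
out-clade occurrence
    The fraction of out-clade sequences (including unassigned ones) whose
    residues at the homologous window columns all fall inside the consensus
    IUPAC sets. A gap never matches. Sequences not covering the window are
    excluded from the denominator. A motif is diagnostic only when this
    fraction is strictly below ``outclade_max`` (default: strictly less
    than 10%).
uniqueness
    The consensus, scanned as a degenerate pattern along each supporting
    member's gap-stripped sequence, must occur exactly once — repeated
    motifs are not diagnostic characters.

Selection among overlapping candidates is greedy and deterministic:
ascending out-clade fraction, then descending length, then ascending start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import iupac
from .alignio import Alignment, CladePartition
from .errors import BoundsError

__all__ = [
    "ScreenParams",
    "ConservationProfile",
    "MotifCandidate",
    "SynapomorphyReport",
    "conservation_profile",
    "window_is_conserved",
    "clade_consensus",
    "outclade_occurrence",
    "enumerate_candidates",
    "select_nonoverlapping",
    "screen_all_clades",
    "cross_clade_summary",
    "write_motif_report",
]

#: masks with more than one base bit set are degenerate IUPAC codes
_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)


@dataclass(frozen=True)
class ScreenParams:
    """Screening configuration (all thresholds are exposed knobs).

    min_len/max_len
        Window lengths screened, in alignment columns.
    cons_col
        Minimum modal-residue frequency for a column to count as conserved.
    max_gap_frac
        Maximum gap fraction for a conserved column.
    cons_window
        Minimum fraction of conserved columns in a window.
    max_degenerate
        Maximum number of degenerate IUPAC characters in a consensus.
    outclade_max
        Out-clade occurrence must be STRICTLY below this fraction.
    min_support
        Minimum number of clade members that must cover the window.
    """

    min_len: int = 10
    max_len: int = 40
    cons_col: float = 0.90
    max_gap_frac: float = 0.10
    cons_window: float = 0.80
    max_degenerate: int = 2
    outclade_max: float = 0.10
    min_support: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("need 1 <= min_len <= max_len")
        if not (0.0 < self.outclade_max <= 1.0):
            raise ValueError("outclade_max must be in (0, 1]")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation statistics under the missing-data convention.

    ``gap_fraction`` counts internal gaps among sequences covering the
    column; ``majority_frequency`` is the modal non-gap residue's frequency
    among the non-gap residues of covering sequences. Uncovered columns get
    gap_fraction 1 and majority_frequency 0.
    """

    gap_fraction: np.ndarray
    majority_frequency: np.ndarray
    covered_count: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.gap_fraction)

    def conserved_columns(self, params: ScreenParams) -> np.ndarray:
        """Boolean per-column mask of conserved columns."""
        return (self.majority_frequency >= params.cons_col) & (
            self.gap_fraction <= params.max_gap_frac
        )


@dataclass(frozen=True)
class MotifCandidate:
    """A candidate diagnostic motif: one window + consensus for one clade.

    ``start`` is a 1-based inclusive alignment column, as reported.
    """

    clade: str
    start: int
    length: int
    consensus: str
    in_clade_support: int
    degenerate_positions: int
    outclade_fraction: float
    outclade_evaluated: int
    low_evidence: bool = False

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def columns(self) -> range:
        """0-based half-open column range of the motif."""
        return range(self.start0, self.start0 + self.length)


@dataclass
class SynapomorphyReport:
    """Selected non-overlapping motifs for one clade, sorted by start."""

    clade: str
    motifs: list[MotifCandidate] = field(default_factory=list)
    parameters: ScreenParams = field(default_factory=ScreenParams)
    n_candidates: int = 0


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def conservation_profile(alignment: Alignment) -> ConservationProfile:
    m = alignment.mask_matrix
    n, c = m.shape
    spans = alignment.coverage_spans
    cols = np.arange(c)
    covering = (spans[:, :1] <= cols) & (cols <= spans[:, 1:2])  # (n, c)
    covered_count = covering.sum(axis=0)
    gap_count = (covering & (m == 0)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        gap_fraction = np.where(covered_count > 0, gap_count / np.maximum(covered_count, 1), 1.0)
    # modal non-gap residue among covering sequences; residues may be
    # ambiguity codes and are counted as the characters they are
    nongap = covered_count - gap_count
    counts = np.zeros((16, c), dtype=np.int64)
    for code_mask in range(1, 16):
        counts[code_mask] = (covering & (m == code_mask)).sum(axis=0)
    modal = counts.max(axis=0)
    majority_frequency = np.where(nongap > 0, modal / np.maximum(nongap, 1), 0.0)
    return ConservationProfile(
        gap_fraction=gap_fraction.astype(float),
        majority_frequency=majority_frequency.astype(float),
        covered_count=covered_count,
    )


def window_is_conserved(
    profile: ConservationProfile, start0: int, length: int, params: ScreenParams
) -> bool:
    """True iff >= cons_window of the window's columns are conserved.

    ``start0`` is a 0-based column index; the comparison is inclusive at
    the threshold.
    """
    if start0 < 0 or length < 1 or start0 + length > profile.n_columns:
        raise BoundsError(
            f"window [{start0}, {start0 + length}) outside 0..{profile.n_columns}"
        )
    ok = profile.conserved_columns(params)[start0 : start0 + length]
    return bool(ok.sum() + 1e-9 >= params.cons_window * length)


# ---------------------------------------------------------------------------
# consensus and out-clade occurrence (single-window reference forms)
# ---------------------------------------------------------------------------

def _clade_rows(alignment: Alignment, partition: CladePartition, clade: str) -> np.ndarray:
    members = partition.members(clade)  # raises KeyError on unknown clade
    return np.array([alignment.row_index(i) for i in members], dtype=np.int64)


def clade_consensus(
    alignment: Alignment,
    partition: CladePartition,
    clade: str,
    start0: int,
    length: int,
    min_support: int = 2,
) -> tuple[str, int] | None:
    """Minimal IUPAC consensus of a clade over one window, or None (reject).

    Members whose coverage span misses part of the window are excluded
    from support. Returns None when support falls below ``min_support`` or
    when any supporting member carries an internal gap in the window.
    """
    if start0 < 0 or start0 + length > alignment.n_columns:
        raise BoundsError(f"window [{start0}, {start0 + length}) out of bounds")
    rows = _clade_rows(alignment, partition, clade)
    spans = alignment.coverage_spans[rows]
    covering = (spans[:, 0] <= start0) & (spans[:, 1] >= start0 + length - 1)
    sub = alignment.mask_matrix[rows[covering], start0 : start0 + length]
    if covering.sum() < min_support:
        return None
    if (sub == 0).any():  # internal gap in a supporting member
        return None
    colmask = np.bitwise_or.reduce(sub, axis=0)
    return iupac.string_from_masks(colmask), int(covering.sum())


def outclade_occurrence(
    alignment: Alignment,
    partition: CladePartition,
    clade: str,
    start0: int,
    consensus: str,
) -> tuple[float, int]:
    """Fraction of out-clade sequences matching the consensus at the window.

    A sequence matches iff at every window column its residue set is
    contained in the consensus IUPAC set; a gap (or missing data) never
    matches. Sequences whose span misses part of the window are excluded
    from the denominator; when nothing is evaluable the fraction is 0 and
    callers should flag low evidence.
    """
    length = len(consensus)
    member_set = set(partition.members(clade))
    rows = np.array(
        [i for i, s in enumerate(alignment.sequences) if s.id not in member_set],
        dtype=np.int64,
    )
    if len(rows) == 0:
        return 0.0, 0
    spans = alignment.coverage_spans[rows]
    covering = (spans[:, 0] <= start0) & (spans[:, 1] >= start0 + length - 1)
    evaluated = int(covering.sum())
    if evaluated == 0:
        return 0.0, 0
    pat = iupac.masks_from_string(consensus)
    sub = alignment.mask_matrix[rows[covering], start0 : start0 + length]
    bad = (sub == 0) | ((sub & ~pat) != 0)
    matches = int((~bad.any(axis=1)).sum())
    return matches / evaluated, evaluated


def _count_occurrences(ungapped_masks: np.ndarray, pattern: np.ndarray) -> int:
    """Occurrences of a degenerate pattern along a gap-stripped sequence."""
    n, l = len(ungapped_masks), len(pattern)
    if n < l:
        return 0
    bad = np.zeros(n - l + 1, dtype=bool)
    for j in range(l):
        bad |= (ungapped_masks[j : j + n - l + 1] & ~pattern[j]) != 0
    return int((~bad).sum())


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _sliding_sum(values: np.ndarray, length: int) -> np.ndarray:
    cs = np.concatenate([[0], np.cumsum(values, dtype=np.int64)])
    return cs[length:] - cs[:-length]


def enumerate_candidates(
    alignment: Alignment,
    partition: CladePartition,
    clade: str,
    params: ScreenParams = ScreenParams(),
    profile: ConservationProfile | None = None,
) -> list[MotifCandidate]:
    """All windows passing the conservation, consensus, out-clade and
    uniqueness rules for one clade, at every length in
    ``[min_len, max_len]`` and stride 1. Deterministic; may be empty.
    """
    if profile is None:
        profile = conservation_profile(alignment)
    m = alignment.mask_matrix
    n_cols = alignment.n_columns
    spans = alignment.coverage_spans
    rows = _clade_rows(alignment, partition, clade)
    member_set = set(partition.members(clade))
    out_rows = np.array(
        [i for i, s in enumerate(alignment.sequences) if s.id not in member_set],
        dtype=np.int64,
    )
    col_ok = profile.conserved_columns(params).astype(np.int64)

    # internal-gap indicator per clade row (gaps inside the coverage span)
    cols = np.arange(n_cols)
    internal_gap = (m[rows] == 0) & (spans[rows, :1] <= cols) & (cols <= spans[rows, 1:2])

    ungapped = {int(r): m[r][m[r] != 0] for r in rows}

    candidates: list[MotifCandidate] = []
    for length in range(params.min_len, params.max_len + 1):
        if length > n_cols:
            break
        n_windows = n_cols - length + 1
        starts = np.arange(n_windows)

        conserved_ok = _sliding_sum(col_ok, length) + 1e-9 >= params.cons_window * length

        # per clade row: inclusive start range over which the row covers
        a = spans[rows, 0]
        b = spans[rows, 1] - length + 1
        covers = (a[:, None] <= starts) & (starts <= b[:, None])  # (k, n_windows)
        support = covers.sum(axis=0)

        gap_in_window = np.vstack([_sliding_sum(g, length) for g in internal_gap])
        reject = (covers & (gap_in_window > 0)).any(axis=0)

        # out-clade coverage (independent of the supporting set)
        if len(out_rows):
            ao = spans[out_rows, 0]
            bo = spans[out_rows, 1] - length + 1
            covers_out = (ao[:, None] <= starts) & (starts <= bo[:, None])
            evaluated = covers_out.sum(axis=0)
        else:
            covers_out = np.zeros((0, n_windows), dtype=bool)
            evaluated = np.zeros(n_windows, dtype=np.int64)

        viable = conserved_ok & ~reject & (support >= params.min_support)
        if not viable.any():
            continue

        # decompose starts into runs with a constant supporting row set
        breaks = {0, n_windows}
        for ar, br in zip(a, b):
            if br >= ar:
                breaks.add(int(max(ar, 0)))
                breaks.add(int(min(br + 1, n_windows)))
        edges = sorted(x for x in breaks if 0 <= x <= n_windows)
        for x, y in zip(edges[:-1], edges[1:]):
            if not viable[x:y].any():
                continue
            seg_rows = rows[(a <= x) & (b >= y - 1)]
            if len(seg_rows) < params.min_support:
                continue
            colmask = np.bitwise_or.reduce(m[seg_rows], axis=0)
            deg = _sliding_sum((_POPCOUNT[colmask] > 1).astype(np.int64), length)
            ok = viable[x:y] & (deg[x:y] <= params.max_degenerate)
            if not ok.any():
                continue
            if len(out_rows):
                bad = (m[out_rows] == 0) | ((m[out_rows] & ~colmask) != 0)
                badsum = np.vstack([_sliding_sum(row, length) for row in bad])
                matches = (covers_out & (badsum == 0)).sum(axis=0)
            else:
                matches = np.zeros(n_windows, dtype=np.int64)
            for s in np.nonzero(ok)[0] + x:
                ev = int(evaluated[s])
                frac = (matches[s] / ev) if ev > 0 else 0.0
                if ev > 0 and not frac < params.outclade_max:
                    continue
                pat = colmask[s : s + length]
                if any(
                    _count_occurrences(ungapped[int(r)], pat) != 1 for r in seg_rows
                ):
                    continue
                candidates.append(
                    MotifCandidate(
                        clade=clade,
                        start=int(s) + 1,
                        length=length,
                        consensus=iupac.string_from_masks(pat),
                        in_clade_support=len(seg_rows),
                        degenerate_positions=int(deg[s]),
                        outclade_fraction=float(frac),
                        outclade_evaluated=ev,
                        low_evidence=(ev == 0),
                    )
                )
    candidates.sort(key=lambda c: (c.start, c.length))
    return candidates


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_nonoverlapping(
    candidates: Iterable[MotifCandidate],
    params: ScreenParams = ScreenParams(),
) -> SynapomorphyReport:
    """Greedy non-overlapping selection from one clade's candidates.

    Order: ascending out-clade fraction, then descending length, then
    ascending start. A candidate is taken iff it shares no alignment
    column with an already selected motif. Output sorted by start.
    """
    cands = list(candidates)
    clades = {c.clade for c in cands}
    if len(clades) > 1:
        raise ValueError(f"candidates from multiple clades: {sorted(clades)}")
    clade = clades.pop() if clades else ""
    order = sorted(cands, key=lambda c: (c.outclade_fraction, -c.length, c.start))
    taken: list[MotifCandidate] = []
    occupied: list[tuple[int, int]] = []  # 0-based half-open intervals
    for cand in order:
        lo, hi = cand.start0, cand.start0 + cand.length
        if all(hi <= s or lo >= e for s, e in occupied):
            taken.append(cand)
            occupied.append((lo, hi))
    taken.sort(key=lambda c: c.start)
    return SynapomorphyReport(
        clade=clade, motifs=taken, parameters=params, n_candidates=len(cands)
    )


def screen_all_clades(
    alignment: Alignment,
    partition: CladePartition,
    params: ScreenParams = ScreenParams(),
) -> dict[str, SynapomorphyReport]:
    """Run the full screen for every clade in the partition.

    Clades with fewer members than ``min_support`` yield an empty report
    with a warning. The result is deterministic in the inputs and
    independent of sequence order.
    """
    partition.validate_against(alignment)
    profile = conservation_profile(alignment)
    reports: dict[str, SynapomorphyReport] = {}
    for clade in sorted(partition.clades):
        if len(partition.members(clade)) < params.min_support:
            warnings.warn(
                f"clade {clade!r} has fewer than {params.min_support} members; "
                "no motifs can be supported",
                stacklevel=2,
            )
            reports[clade] = SynapomorphyReport(clade=clade, parameters=params)
            continue
        cands = enumerate_candidates(alignment, partition, clade, params, profile)
        reports[clade] = select_nonoverlapping(cands, params)
    return reports


def cross_clade_summary(reports: Mapping[str, SynapomorphyReport]) -> pd.DataFrame:
    """Columns covered by selected motifs of more than one clade.

    One row per shared 1-based column with the sorted list of clades —
    the data behind a side-by-side comparison of clade motif maps.
    """
    by_col: dict[int, set[str]] = {}
    for clade, report in reports.items():
        for motif in report.motifs:
            for col0 in motif.columns:
                by_col.setdefault(col0 + 1, set()).add(clade)
    rows = [
        {"column_1based": col, "clades": ",".join(sorted(cl))}
        for col, cl in sorted(by_col.items())
        if len(cl) > 1
    ]
    return pd.DataFrame(rows, columns=["column_1based", "clades"])


def write_motif_report(
    reports: Mapping[str, SynapomorphyReport], path
) -> pd.DataFrame:
    """Write the combined motif TSV; returns the table written."""
    rows = []
    for clade in sorted(reports):
        for i, mo in enumerate(reports[clade].motifs, start=1):
            rows.append(
                {
                    "clade": clade,
                    "motif_index": i,
                    "start_1based": mo.start,
                    "length": mo.length,
                    "consensus_iupac": mo.consensus,
                    "in_clade_support": mo.in_clade_support,
                    "degenerate_positions": mo.degenerate_positions,
                    "outclade_fraction": mo.outclade_fraction,
                    "outclade_evaluated": mo.outclade_evaluated,
                    "low_evidence": mo.low_evidence,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "clade",
            "motif_index",
            "start_1based",
            "length",
            "consensus_iupac",
            "in_clade_support",
            "degenerate_positions",
            "outclade_fraction",
            "outclade_evaluated",
            "low_evidence",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
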