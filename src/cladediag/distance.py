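"""Percent pairwise distances with terminal-overhang trimming.

The central procedure is a two-pass p-distance between two unaligned
sequences: (1) align them globally with free end gaps, (2) cut the
unaligned front and back overhangs, (3) realign the trimmed cores with end
gaps penalised, and (4) report the percent of differing sites over the
compared columns. The trimming step keeps partial sequences (common for
Sanger-derived rDNA) from inflating distances with terminal overhang.

The module also computes the master-alignment variant (column differences
between two rows of an existing MSA) and full distance matrices, and a
combination harness that runs every method x gap-mode pair — useful when a
published figure does not say how gaps were treated.

The aligner is an affine-gap Needleman–Wunsch/Gotoh with deterministic
tie-breaking (prefer a substitution over a gap, then a gap in the first
sequence over a gap in the second). A gap of length k scores
``gap_open + k * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import iupac
from .alignio import Alignment
from .errors import AllTrimmedError, EmptySequenceError

__all__ = [
    "ScoringScheme",
    "PairwiseDistanceResult",
    "global_align",
    "trim_unaligned_ends",
    "p_distance_two_pass",
    "nucleotide_differences",
    "msa_column_distance",
    "distance_matrix",
    "write_phylip",
    "combination_report",
]

_NEG = -np.inf


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; defaults favour long ungapped cores.

    ``end_gaps_free`` makes leading/trailing gaps in either sequence cost
    nothing (semi-global alignment), which is what overhang trimming
    needs in the first pass.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    end_gaps_free: bool = False

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


@dataclass(frozen=True)
class PairwiseDistanceResult:
    """Percent distance between two sequences plus trimming metadata.

    ``compared_columns`` is the denominator actually used under the chosen
    gap mode, so ``percent_distance == 100 * mismatches / compared_columns``
    always holds when the denominator is positive.
    """

    id_a: str
    id_b: str
    percent_distance: float
    compared_columns: int
    mismatches: int
    trim_front_a: int = 0
    trim_back_a: int = 0
    trim_front_b: int = 0
    trim_back_b: int = 0
    method: str = "two_pass"
    gap_mode: str = "exclude"


# ---------------------------------------------------------------------------
# global alignment (Gotoh, numpy rows, deterministic traceback)
# ---------------------------------------------------------------------------

def _substitution_row(a_char_mask: int, b_masks: np.ndarray,
                      scheme: ScoringScheme, iupac_overlap: bool) -> np.ndarray:
    if iupac_overlap:
        hits = (b_masks & a_char_mask) != 0
    else:
        hits = b_masks == a_char_mask
    return np.where(hits, scheme.match, scheme.mismatch)


def global_align(
    a: str,
    b: str,
    scheme: ScoringScheme = ScoringScheme(),
    iupac_overlap: bool = False,
) -> tuple[str, str, float]:
    """Optimal global alignment of two unaligned sequences.

    Returns ``(aligned_a, aligned_b, score)``; stripping gaps from either
    output restores its input. With ``scheme.end_gaps_free`` terminal gaps
    are unpenalised. Ties are broken deterministically: substitution over
    gap, then gap in ``a`` over gap in ``b``.
    """
    if not a or not b:
        raise EmptySequenceError("cannot align an empty sequence")
    am = iupac.masks_from_string(a).astype(np.int64)
    bm = iupac.masks_from_string(b).astype(np.int64)
    n, m_len = len(a), len(b)
    of = scheme.gap_open + scheme.gap_extend  # first gap character
    e = scheme.gap_extend
    free = scheme.end_gaps_free

    M = np.full((n + 1, m_len + 1), _NEG)
    Ix = np.full((n + 1, m_len + 1), _NEG)  # gap in b (consumes a)
    Iy = np.full((n + 1, m_len + 1), _NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    ii = np.arange(1, n + 1)
    jj = np.arange(1, m_len + 1)
    Ix[1:, 0] = 0.0 if free else of + e * (ii - 1)
    Iy[0, 1:] = 0.0 if free else of + e * (jj - 1)

    j_idx = np.arange(m_len + 1)
    for i in range(1, n + 1):
        sub = _substitution_row(int(am[i - 1]), bm, scheme, iupac_overlap)
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = sub + prev_best[:-1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + of, Ix[i - 1, 1:] + e
        )
        # Iy[i, j] = max_{k<j} max(M[i,k], Ix[i,k]) + of + e*(j-k-1): a scan
        r = np.maximum(M[i], Ix[i]) + of - e * (j_idx + 1)
        run = np.maximum.accumulate(r)
        Iy[i, 1:] = e * j_idx[1:] + run[:-1]

    return _traceback(a, b, M, Ix, Iy, scheme, iupac_overlap)


def _traceback(a, b, M, Ix, Iy, scheme, iupac_overlap):
    n, m_len = len(a), len(b)
    of = scheme.gap_open + scheme.gap_extend
    e = scheme.gap_extend
    tol = 1e-9

    def best_state(i, j):
        vals = {"M": M[i, j], "Iy": Iy[i, j], "Ix": Ix[i, j]}
        top = max(vals.values())
        for st in ("M", "Iy", "Ix"):  # substitution, gap-in-a, gap-in-b
            if vals[st] >= top - tol:
                return st, top
        raise AssertionError

    if scheme.end_gaps_free:
        # allow the alignment to end anywhere on the last row/column;
        # among maximal cells prefer the corner, then larger i+j, then larger i
        cells = [(i, m_len) for i in range(n + 1)] + [(n, j) for j in range(m_len)]
        score_at = {
            (i, j): max(M[i, j], Ix[i, j], Iy[i, j]) for (i, j) in cells
        }
        top = max(score_at.values())
        pool = [c for c, v in score_at.items() if v >= top - tol]
        end = max(pool, key=lambda c: (c == (n, m_len), c[0] + c[1], c[0]))
        i, j = end
        score = top
    else:
        i, j = n, m_len
        _, score = best_state(i, j)

    out_a: list[str] = []
    out_b: list[str] = []
    # free trailing overhang
    out_a.extend("-" * (m_len - j))
    out_b.extend(reversed(b[j:]))
    out_b.extend("-" * (n - i))
    out_a.extend(reversed(a[i:]))

    state, _ = best_state(i, j)
    while i > 0 or j > 0:
        if i == 0:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
            continue
        if j == 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j]
            hit = (
                (iupac.mask_of(a[i - 1]) & iupac.mask_of(b[j - 1]) != 0)
                if iupac_overlap
                else a[i - 1] == b[j - 1]
            )
            s = scheme.match if hit else scheme.mismatch
            i, j = i - 1, j - 1
            for st, val in (("M", M[i, j]), ("Iy", Iy[i, j]), ("Ix", Ix[i, j])):
                if s + val >= target - tol:
                    state = st
                    break
        elif state == "Iy":  # gap in a, consumes b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Iy[i, j]
            jp = j - 1
            if M[i, jp] + of >= target - tol:
                state = "M"
            elif Iy[i, jp] + e >= target - tol:
                state = "Iy"
            else:
                state = "Ix"
            j = jp
        else:  # Ix: gap in b, consumes a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            target = Ix[i, j]
            ip = i - 1
            if M[ip, j] + of >= target - tol:
                state = "M"
            elif Iy[ip, j] + of >= target - tol:
                state = "Iy"
            else:
                state = "Ix"
            i = ip
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


# ---------------------------------------------------------------------------
# trimming and the two-pass percent distance
# ---------------------------------------------------------------------------

def trim_unaligned_ends(aligned_a: str, aligned_b: str) -> tuple[str, str, dict[str, int]]:
    """Cut the terminal blocks where either row is gapped.

    Returns the gap-stripped cores of the remaining columns and the
    per-sequence counts of residues removed from each end.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned pair must have equal length")
    both = [ca != "-" and cb != "-" for ca, cb in zip(aligned_a, aligned_b)]
    if not any(both):
        raise AllTrimmedError("no mutually covered core after trimming")
    lo = both.index(True)
    hi = len(both) - 1 - both[::-1].index(True)
    trims = {
        "trim_front_a": sum(c != "-" for c in aligned_a[:lo]),
        "trim_back_a": sum(c != "-" for c in aligned_a[hi + 1 :]),
        "trim_front_b": sum(c != "-" for c in aligned_b[:lo]),
        "trim_back_b": sum(c != "-" for c in aligned_b[hi + 1 :]),
    }
    core_a = aligned_a[lo : hi + 1].replace("-", "")
    core_b = aligned_b[lo : hi + 1].replace("-", "")
    return core_a, core_b, trims


def _column_counts(aligned_a: str, aligned_b: str, gap_mode: str,
                   iupac_overlap: bool) -> tuple[int, int]:
    """(mismatches, compared_columns) over an aligned pair."""
    mm = 0
    compared = 0
    for ca, cb in zip(aligned_a, aligned_b):
        ga, gb = ca == "-", cb == "-"
        if ga and gb:
            continue
        if ga or gb:
            if gap_mode == "count":
                compared += 1
                mm += 1
            continue
        compared += 1
        if iupac_overlap:
            if iupac.mask_of(ca) & iupac.mask_of(cb) == 0:
                mm += 1
        elif ca != cb:
            mm += 1
    return mm, compared


def p_distance_two_pass(
    a: str,
    b: str,
    scheme: ScoringScheme = ScoringScheme(),
    gap_mode: str = "exclude",
    id_a: str = "a",
    id_b: str = "b",
    iupac_overlap: bool = False,
) -> PairwiseDistanceResult:
    """Two-pass percent distance: align, trim overhangs, realign, count.

    Pass 1 uses free end gaps so overhangs surface as terminal gap blocks;
    after cutting them the cores are realigned with end gaps penalised.
    ``gap_mode='exclude'`` (default) drops internal gap columns from both
    numerator and denominator; ``'count'`` scores them as mismatches.
    The result is exactly symmetric in its arguments.
    """
    if gap_mode not in ("exclude", "count"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    # canonical ordering guarantees symmetry under argument swap
    swapped = (b, id_b) < (a, id_a)
    x, y = (b, a) if swapped else (a, b)
    aligned_x, aligned_y, _ = global_align(
        x, y, replace(scheme, end_gaps_free=True), iupac_overlap
    )
    core_x, core_y, trims = trim_unaligned_ends(aligned_x, aligned_y)
    re_x, re_y, _ = global_align(
        core_x, core_y, replace(scheme, end_gaps_free=False), iupac_overlap
    )
    mm, compared = _column_counts(re_x, re_y, gap_mode, iupac_overlap)
    percent = 100.0 * mm / compared if compared else 0.0
    if swapped:
        trims = {
            "trim_front_a": trims["trim_front_b"],
            "trim_back_a": trims["trim_back_b"],
            "trim_front_b": trims["trim_front_a"],
            "trim_back_b": trims["trim_back_a"],
        }
    return PairwiseDistanceResult(
        id_a=id_a,
        id_b=id_b,
        percent_distance=percent,
        compared_columns=compared,
        mismatches=mm,
        method="two_pass",
        gap_mode=gap_mode,
        **trims,
    )


def nucleotide_differences(
    a: str, b: str, scheme: ScoringScheme = ScoringScheme()
) -> int:
    """Count of differing sites between two sequences (two-pass, gaps excluded)."""
    return p_distance_two_pass(a, b, scheme, gap_mode="exclude").mismatches


# ---------------------------------------------------------------------------
# master-alignment column distances
# ---------------------------------------------------------------------------

def msa_column_distance(
    alignment: Alignment,
    id_a: str,
    id_b: str,
    gap_mode: str = "exclude",
    iupac_overlap: bool = False,
) -> PairwiseDistanceResult:
    """Percent difference between two rows of an existing alignment.

    Columns outside either row's coverage span (terminal missing data) are
    always excluded. Under ``exclude``, columns where either row has an
    internal gap are also dropped; under ``count`` a residue-against-gap
    column is a mismatch (gap-against-gap columns carry no information and
    are dropped in both modes).
    """
    if gap_mode not in ("exclude", "count"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    ra = alignment.row_index(id_a)
    rb = alignment.row_index(id_b)
    m = alignment.mask_matrix
    spans = alignment.coverage_spans
    cols = np.arange(alignment.n_columns)
    in_both = (
        (spans[ra, 0] <= cols) & (cols <= spans[ra, 1])
        & (spans[rb, 0] <= cols) & (cols <= spans[rb, 1])
    )
    xa, xb = m[ra], m[rb]
    both_res = in_both & (xa != 0) & (xb != 0)
    if iupac_overlap:
        diff = both_res & ((xa & xb) == 0)
    else:
        diff = both_res & (xa != xb)
    mm = int(diff.sum())
    compared = int(both_res.sum())
    if gap_mode == "count":
        one_gap = in_both & ((xa == 0) ^ (xb == 0))
        mm += int(one_gap.sum())
        compared += int(one_gap.sum())
    percent = 100.0 * mm / compared if compared else 0.0
    return PairwiseDistanceResult(
        id_a=id_a,
        id_b=id_b,
        percent_distance=percent,
        compared_columns=compared,
        mismatches=mm,
        method="msa_columns",
        gap_mode=gap_mode,
    )


def distance_matrix(
    alignment: Alignment, gap_mode: str = "exclude", iupac_overlap: bool = False
) -> pd.DataFrame:
    """Symmetric percent-distance matrix over all rows of the alignment."""
    ids = alignment.ids
    k = len(ids)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = msa_column_distance(alignment, ids[i], ids[j], gap_mode, iupac_overlap)
            mat[i, j] = mat[j, i] = d.percent_distance
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_phylip(matrix: pd.DataFrame, path) -> None:
    """Write a square PHYLIP distance matrix (relaxed names, tab-separated)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{len(matrix)}\n")
        for name, row in matrix.iterrows():
            vals = "\t".join(f"{v:.6f}" for v in row)
            fh.write(f"{name}\t{vals}\n")


# ---------------------------------------------------------------------------
# combination harness
# ---------------------------------------------------------------------------

def combination_report(
    sequences: Mapping[str, str],
    pairs: Iterable[tuple[str, str]],
    alignment: Alignment | None = None,
    scheme: ScoringScheme = ScoringScheme(),
    methods: Sequence[str] = ("two_pass", "msa_columns"),
    gap_modes: Sequence[str] = ("exclude", "count"),
) -> pd.DataFrame:
    """Run every method x gap-mode combination for each pair.

    When a published percent difference does not document how it handled
    gaps (or whether it came from a fresh pairwise alignment or from the
    master alignment's columns), this table shows which combination
    reproduces it. ``msa_columns`` rows are emitted only when an alignment
    containing both ids is supplied.
    """
    rows = []
    for id_a, id_b in pairs:
        for method in methods:
            for gap_mode in gap_modes:
                if method == "two_pass":
                    res = p_distance_two_pass(
                        sequences[id_a], sequences[id_b], scheme, gap_mode,
                        id_a=id_a, id_b=id_b,
                    )
                elif method == "msa_columns":
                    if alignment is None or id_a not in alignment or id_b not in alignment:
                        continue
                    res = msa_column_distance(alignment, id_a, id_b, gap_mode)
                else:
                    raise ValueError(f"unknown method {method!r}")
                rows.append(
                    {
                        "id_a": id_a,
                        "id_b": id_b,
                        "method": res.method,
                        "gap_mode": res.gap_mode,
                        "percent_distance": res.percent_distance,
                        "mismatches": res.mismatches,
                        "compared_columns": res.compared_columns,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "method", "gap_mode",
            "percent_distance", "mismatches", "compared_columns",
        ],
    )
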