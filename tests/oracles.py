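"""Independent brute-force oracles used only by the tests.

These re-state the definitions directly over strings and Python sets, with
no numpy and no shared code paths with the package implementation, so that
agreement is meaningful.
"""

from __future__ import annotations

from Bio.Data import IUPACData

SETS = {c: set(b) for c, b in IUPACData.ambiguous_dna_values.items() if c != "X"}
CODE_OF = {frozenset(b): c for c, b in SETS.items()}


def brute_profile(rows: dict[str, str]):
    """Per-column (gap_fraction, majority_frequency, covered) by hand count."""
    n = len(next(iter(rows.values())))
    spans = {k: (len(v) - len(v.lstrip("-")),
                 len(v.rstrip("-")) - 1) for k, v in rows.items()}
    out = []
    for j in range(n):
        covering = [k for k in rows if spans[k][0] <= j <= spans[k][1]]
        residues = [rows[k][j] for k in covering if rows[k][j] != "-"]
        gaps = len(covering) - len(residues)
        gap_frac = gaps / len(covering) if covering else 1.0
        if residues:
            modal = max(set(residues), key=lambda r: (residues.count(r), r))
            maj = residues.count(modal) / len(residues)
        else:
            maj = 0.0
        out.append((gap_frac, maj, len(covering)))
    return out


def brute_enumerate(rows: dict[str, str], clade_of: dict[str, str], clade: str,
                    min_len=10, max_len=40, cons_col=0.90, max_gap_frac=0.10,
                    cons_window=0.80, max_degenerate=2, outclade_max=0.10,
                    min_support=2):
    """Every (start, length) window passing the screen, by direct definition.

    Returns tuples (start_1based, length, consensus, support, fraction,
    evaluated).
    """
    n = len(next(iter(rows.values())))
    spans = {k: (len(v) - len(v.lstrip("-")), len(v.rstrip("-")) - 1)
             for k, v in rows.items()}
    prof = brute_profile(rows)
    members = [k for k, c in clade_of.items() if c == clade]
    outsiders = [k for k in rows if clade_of.get(k) != clade]
    found = []
    for length in range(min_len, max_len + 1):
        for s in range(0, n - length + 1):
            cols = range(s, s + length)
            conserved = sum(
                1 for j in cols
                if prof[j][1] >= cons_col and prof[j][0] <= max_gap_frac
            )
            if conserved + 1e-9 < cons_window * length:
                continue
            sup = [m for m in members
                   if spans[m][0] <= s and spans[m][1] >= s + length - 1]
            if len(sup) < min_support:
                continue
            if any("-" in rows[m][s:s + length] for m in sup):
                continue  # internal gap -> REJECT
            consensus = []
            for j in cols:
                bases = set()
                for m in sup:
                    bases |= SETS[rows[m][j]]
                consensus.append(CODE_OF[frozenset(bases)])
            consensus = "".join(consensus)
            if sum(1 for c in consensus if len(SETS[c]) > 1) > max_degenerate:
                continue
            evaluable = [o for o in outsiders
                         if spans[o][0] <= s and spans[o][1] >= s + length - 1]
            matches = 0
            for o in evaluable:
                seg = rows[o][s:s + length]
                if all(ch != "-" and SETS[ch] <= SETS[cc]
                       for ch, cc in zip(seg, consensus)):
                    matches += 1
            frac = matches / len(evaluable) if evaluable else 0.0
            if evaluable and not frac < outclade_max:
                continue
            unique = True
            for m in sup:
                ungapped = rows[m].replace("-", "")
                count = 0
                for k in range(len(ungapped) - length + 1):
                    if all(SETS[ungapped[k + j]] <= SETS[consensus[j]]
                           for j in range(length)):
                        count += 1
                if count != 1:
                    unique = False
                    break
            if not unique:
                continue
            found.append((s + 1, length, consensus, len(sup), frac, len(evaluable)))
    return found


def gotoh_score(a: str, b: str, match=2.0, mismatch=-1.0, gap_open=-4.0,
                gap_extend=-1.0, free_ends=False) -> float:
    """Plain-Python affine-gap global alignment score (lists, no numpy).

    A gap of length k scores gap_open + k*gap_extend; with free_ends,
    terminal gaps in either sequence are unpenalised.
    """
    NEG = float("-inf")
    of = gap_open + gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if free_ends else of + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if free_ends else of + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + of, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + of)
            Y[i][j] = max(M[i][j - 1] + of, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + of)
    if not free_ends:
        return max(M[n][m], X[n][m], Y[n][m])
    best = NEG
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best
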