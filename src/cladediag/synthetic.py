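"""Clade-structured synthetic rDNA-like alignments with planted truth.

The generator emulates the features of a curated small-subunit rDNA
alignment that the motif screen and the distance procedures key on:

* a long, mostly conserved template (rDNA cores are highly conserved);
* clades whose members carry planted diagnostic motifs — short blocks that
  differ from the template at a couple of sites and are shared clade-wide;
* clade-specific inserts: blocks of columns with residues in the owning
  clade(s) and gaps everywhere else (the hallmark separating freshwater
  from marine goniomonad 18S sequences). Identical inserts may be shared
  by several clades;
* within-clade polymorphism: single-site variants (IUPAC-degenerate
  consensus columns) and single-column deletions in individual members
  (length-variable flanks around conserved motifs);
* terminal truncation: members with leading/trailing missing data, so the
  screen must exclude them from early/late windows rather than fail them;
* iid substitution noise outside planted motif columns.

There is no phylogenetic tree simulation: the screen is positional and
never consults a tree, so clade templates plus iid noise are sufficient.
All randomness flows from one seeded generator in a fixed draw order, so
(alignment, partition, truth) are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignio import AlignedSequence, Alignment, CladePartition
from .distance import msa_column_distance
from .errors import ConfigError, OverlapError

__all__ = [
    "CladeSpec",
    "SyntheticTruth",
    "generate_template",
    "generate_dataset",
    "summarize_dataset",
    "default_clade_specs",
    "default_dataset",
    "landmark_dataset",
    "load_config",
]

_BASES = np.array(list("ACGT"))
_NEXT_BASE = {"A": "C", "C": "G", "G": "T", "T": "A"}


@dataclass(frozen=True)
class CladeSpec:
    """Recipe for one clade of the synthetic alignment.

    Columns are 1-based template columns. ``planted_motifs`` overwrite
    template columns for every member; ``inserts`` are (position, text)
    blocks appearing *after* the given template column, present only in
    clades that list an identical (position, text) insert. ``missing_prefix``
    / ``missing_suffix`` are per-member maximum truncation lengths (drawn
    uniformly per member); ``truncate_members`` restricts truncation to the
    given member indices. ``member_deletions`` knock single template
    columns out of single members (internal-gap polymorphism) and
    ``site_variants`` overwrite single sites in single members
    (within-clade substitutions, e.g. a T-vs-C polymorphism inside a
    motif).
    """

    label: str
    n_members: int
    planted_motifs: tuple[tuple[int, str], ...] = ()
    inserts: tuple[tuple[int, str], ...] = ()
    substitution_rate: float = 0.0
    missing_prefix: int = 0
    missing_suffix: int = 0
    truncate_members: tuple[int, ...] | None = None
    member_deletions: tuple[tuple[int, int], ...] = ()
    site_variants: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must be in [0, 1)")
        spans = sorted(
            (start, start + len(motif) - 1) for start, motif in self.planted_motifs
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise OverlapError(
                    f"motifs overlap within clade {self.label!r}: "
                    f"[{s1},{e1}] and [{s2},{e2}]"
                )
        # an insert sits between template columns pos and pos+1; it only
        # interrupts a motif when both flanking columns belong to it
        for pos, _ in self.inserts:
            for s, e in spans:
                if s <= pos < e:
                    raise OverlapError(
                        f"insert after column {pos} interrupts a motif of "
                        f"clade {self.label!r}"
                    )


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth for a generated dataset."""

    seed: int
    #: (clade, template_start, alignment_start, length, motif) — 1-based
    motifs: list[tuple[str, int, int, int, str]] = field(default_factory=list)
    #: (owners, template_position, alignment_start, length, text)
    inserts: list[tuple[tuple[str, ...], int, int, int, str]] = field(default_factory=list)
    #: (sequence_id, template_col, alignment_col, old, new, kind)
    substitutions: list[tuple[str, int, int, str, str, str]] = field(default_factory=list)
    #: (sequence_id, residues_cut_front, residues_cut_back)
    truncations: list[tuple[str, int, int]] = field(default_factory=list)
    #: sorted (insert_position, insert_length) pairs defining the column map
    insert_layout: list[tuple[int, int]] = field(default_factory=list)

    def template_to_alignment(self, template_col: int) -> int:
        """Map a 1-based template column to its 1-based alignment column."""
        shift = sum(ln for pos, ln in self.insert_layout if pos < template_col)
        return template_col + shift

    def motif_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"clade": c, "start_1based": a, "length": ln, "motif": mo}
                for c, _t, a, ln, mo in self.motifs
            ],
            columns=["clade", "start_1based", "length", "motif"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.motif_table().to_csv(path, sep="\t", index=False)


def generate_template(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random ACGT template with the requested GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = [
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,        # C
        gc_fraction / 2,        # G
        (1 - gc_fraction) / 2,  # T
    ]
    return "".join(rng.choice(_BASES, size=length, p=p))


def _merged_inserts(clade_specs: list[CladeSpec]) -> dict[int, tuple[str, tuple[str, ...]]]:
    """position -> (text, owner labels); identical inserts merge across clades."""
    merged: dict[int, tuple[str, list[str]]] = {}
    for spec in clade_specs:
        for pos, text in spec.inserts:
            if pos in merged:
                prev_text, owners = merged[pos]
                if prev_text != text:
                    raise OverlapError(
                        f"conflicting inserts at template position {pos}: "
                        f"{prev_text!r} vs {text!r}"
                    )
                owners.append(spec.label)
            else:
                merged[pos] = (text, [spec.label])
    return {p: (t, tuple(o)) for p, (t, o) in merged.items()}


def _check_cross_spec(clade_specs: list[CladeSpec], template_len: int,
                      inserts: dict[int, tuple[str, tuple[str, ...]]]) -> None:
    occupied: dict[int, str] = {}
    for spec in clade_specs:
        for start, motif in spec.planted_motifs:
            if start < 1 or start + len(motif) - 1 > template_len:
                raise OverlapError(
                    f"motif at {start} in clade {spec.label!r} outside template"
                )
            for col in range(start, start + len(motif)):
                if col in occupied:
                    raise OverlapError(
                        f"template column {col} claimed by motifs of clades "
                        f"{occupied[col]!r} and {spec.label!r}"
                    )
                occupied[col] = spec.label
    for pos in inserts:
        if not (0 <= pos <= template_len):
            raise OverlapError(f"insert position {pos} outside template")
        for spec in clade_specs:
            for start, motif in spec.planted_motifs:
                if start <= pos < start + len(motif) - 1:
                    raise OverlapError(
                        f"insert after column {pos} interrupts the motif of "
                        f"clade {spec.label!r} at {start}"
                    )


def generate_dataset(
    template: str,
    clade_specs: list[CladeSpec],
    seed: int = 0,
) -> tuple[Alignment, CladePartition, SyntheticTruth]:
    """Emit (Alignment, CladePartition, SyntheticTruth) for the given specs.

    Member ids are ``<label>_<k>``. Substitution noise never lands on
    planted motif columns of the member's own clade. Draw order (fixed,
    documented): clades in list order; per member, substitution-site
    vector, substituted-base choices, then front and back truncation
    lengths.
    """
    L = len(template)
    inserts = _merged_inserts(clade_specs)
    _check_cross_spec(clade_specs, L, inserts)
    rng = np.random.default_rng(seed)
    layout = sorted((pos, len(text)) for pos, (text, _) in inserts.items())

    truth = SyntheticTruth(seed=seed, insert_layout=layout)
    for pos in sorted(inserts):
        text, owners = inserts[pos]
        start = truth.template_to_alignment(pos) + 1  # first insert column
        truth.inserts.append((owners, pos, start, len(text), text))

    sequences: list[AlignedSequence] = []
    assignments: dict[str, str] = {}

    for spec in clade_specs:
        motif_cols: set[int] = set()
        for start, motif in spec.planted_motifs:
            motif_cols.update(range(start, start + len(motif)))
            truth.motifs.append(
                (
                    spec.label,
                    start,
                    truth.template_to_alignment(start),
                    len(motif),
                    motif,
                )
            )
        mutable = np.array(
            [c + 1 not in motif_cols for c in range(L)], dtype=bool
        )
        for k in range(spec.n_members):
            seq_id = f"{spec.label}_{k + 1}"
            chars = list(template)
            for start, motif in spec.planted_motifs:
                chars[start - 1 : start - 1 + len(motif)] = list(motif)
            # iid substitution noise outside planted motif columns
            hits = np.nonzero((rng.random(L) < spec.substitution_rate) & mutable)[0]
            for col0 in hits:
                old = chars[col0]
                choices = [b for b in "ACGT" if b != old]
                new = choices[int(rng.integers(0, 3))]
                chars[col0] = new
                truth.substitutions.append(
                    (seq_id, col0 + 1, truth.template_to_alignment(col0 + 1),
                     old, new, "noise")
                )
            for member, col, base in spec.site_variants:
                if member == k:
                    old = chars[col - 1]
                    chars[col - 1] = base
                    truth.substitutions.append(
                        (seq_id, col, truth.template_to_alignment(col),
                         old, base, "variant")
                    )
            for member, col in spec.member_deletions:
                if member == k:
                    chars[col - 1] = "-"
            # splice inserts: residues for owners, gap blocks otherwise
            row: list[str] = []
            for t in range(L + 1):
                if t > 0:
                    row.append(chars[t - 1])
                if t in inserts:
                    text, owners = inserts[t]
                    row.append(text if spec.label in owners else "-" * len(text))
            aligned = "".join(row)
            # terminal truncation = missing data
            eligible = spec.truncate_members is None or k in spec.truncate_members
            n_front = (
                int(rng.integers(0, spec.missing_prefix + 1))
                if eligible and spec.missing_prefix
                else 0
            )
            n_back = (
                int(rng.integers(0, spec.missing_suffix + 1))
                if eligible and spec.missing_suffix
                else 0
            )
            if n_front or n_back:
                aligned = _truncate(aligned, n_front, n_back)
                truth.truncations.append((seq_id, n_front, n_back))
            sequences.append(
                AlignedSequence(id=seq_id, residues=aligned, source_note="synthetic")
            )
            assignments[seq_id] = spec.label

    alignment = Alignment(sequences)
    partition = CladePartition(assignments)
    return alignment, partition, truth


def _truncate(aligned: str, n_front: int, n_back: int) -> str:
    """Replace the first/last n residues (skipping gaps) with gaps."""
    chars = list(aligned)
    cut = n_front
    for i, ch in enumerate(chars):
        if cut == 0:
            break
        if ch != "-":
            chars[i] = "-"
            cut -= 1
    cut = n_back
    for i in range(len(chars) - 1, -1, -1):
        if cut == 0:
            break
        if chars[i] != "-":
            chars[i] = "-"
            cut -= 1
    return "".join(chars)


def summarize_dataset(
    alignment: Alignment, partition: CladePartition, truth: SyntheticTruth
) -> pd.DataFrame:
    """Per-clade member counts, mean within/between percent distances and
    planted motif counts (distances from master-alignment columns,
    gaps excluded)."""
    clades = partition.clades
    members = {c: partition.members(c) for c in clades}
    rows = []
    for clade in clades:
        ids = members[clade]
        within = [
            msa_column_distance(alignment, a, b).percent_distance
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        ]
        others = [i for c in clades if c != clade for i in members[c]]
        between = [
            msa_column_distance(alignment, a, b).percent_distance
            for a in ids
            for b in others
        ]
        rows.append(
            {
                "clade": clade,
                "n_members": len(ids),
                "mean_within_pct": float(np.mean(within)) if within else 0.0,
                "mean_between_pct": float(np.mean(between)) if between else 0.0,
                "planted_motifs": sum(1 for m in truth.motifs if m[0] == clade),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canned datasets
# ---------------------------------------------------------------------------

def _derived_motif(template: str, start: int, length: int = 12,
                   diag_offsets: tuple[int, ...] = (3, 8)) -> str:
    """A planted motif: the template block with diagnostic substitutions.

    The diagnostic offsets are spread so that every sub-window of length
    >= 10 contains at least one diagnostic column.
    """
    block = list(template[start - 1 : start - 1 + length])
    for off in diag_offsets:
        block[off] = _NEXT_BASE[block[off]]
    return "".join(block)


def default_clade_specs(template: str) -> list[CladeSpec]:
    """The default study conditions: 3 clades x 8 members, 8 planted 12-nt
    motifs in the freshwater-style clade, two 15-nt inserts, substitution
    rate 0.005, and terminal truncation in two members.

    Each planted motif carries two diagnostic substitutions and is flanked
    by single-column deletion polymorphisms (members 1 and 2), modelling
    the length-variable context that bounds a conserved motif.
    """
    motif_starts = (135, 360, 580, 800, 1020, 1240, 1460, 1680)
    motifs = tuple((s, _derived_motif(template, s)) for s in motif_starts)
    deletions = tuple(
        d for s in motif_starts for d in ((0, s - 1), (1, s + 12))
    )
    rng = np.random.default_rng(len(template))  # insert text fixed by template size
    ins_text = ["".join(rng.choice(_BASES, size=15)) for _ in range(2)]
    inserts = ((470, ins_text[0]), (1820, ins_text[1]))
    return [
        CladeSpec(
            label="Goniomonas",
            n_members=8,
            planted_motifs=motifs,
            inserts=inserts,
            substitution_rate=0.005,
            missing_prefix=200,
            missing_suffix=100,
            truncate_members=(6, 7),
            member_deletions=deletions,
        ),
        CladeSpec(label="Marigoniomonas", n_members=8, substitution_rate=0.005),
        CladeSpec(label="Poseidogoniomonas", n_members=8, substitution_rate=0.005),
    ]


def default_dataset(seed: int = 0):
    """Generate the default dataset; returns (alignment, partition, truth)."""
    template = generate_template(2000, 0.5, seed)
    return generate_dataset(template, default_clade_specs(template), seed + 1)


def landmark_dataset(seed: int = 0):
    """A fixture recreating the coordinate landmarks of a curated goniomonad
    18S alignment, synthetically:

    * total alignment length 2188 columns;
    * a 15-column insert shared by the two freshwater-style clades
      (Goniomonas, Aquagoniomonas) starting at alignment column 136, so
      every other clade shows a gap after position 135;
    * a within-clade T/C polymorphism at alignment column 345 inside a
      planted motif of the Poseidogoniomonas clade, whose consensus is
      therefore the IUPAC code Y at that column;
    * one private diagnostic motif per clade.
    """
    template = generate_template(2173, 0.5, seed)
    rng = np.random.default_rng(seed + 2)
    shared_insert = (135, "".join(rng.choice(_BASES, size=15)))
    # Poseidogoniomonas motif: template cols 319..330 -> alignment 334..345;
    # its last column is the polymorphic site (alignment column 345)
    # two members carry C, two carry T at the last motif column, so the
    # clade consensus there is Y; the diagnostic column at offset 3 keeps
    # the motif clade-exclusive whatever the template base is
    posei_motif = list(_derived_motif(template, 319, 12, diag_offsets=(3,)))
    posei_motif[11] = "C"
    variant_base = "T"
    specs = [
        CladeSpec(
            label="Goniomonas",
            n_members=4,
            planted_motifs=((124, _derived_motif(template, 124)),),
            inserts=(shared_insert,),
            substitution_rate=0.002,
        ),
        CladeSpec(
            label="Aquagoniomonas",
            n_members=4,
            planted_motifs=((500, _derived_motif(template, 500)),),
            inserts=(shared_insert,),
            substitution_rate=0.002,
        ),
        CladeSpec(
            label="Limnogoniomonas",
            n_members=4,
            planted_motifs=((800, _derived_motif(template, 800)),),
            substitution_rate=0.002,
        ),
        CladeSpec(
            label="Poseidogoniomonas",
            n_members=4,
            planted_motifs=((319, "".join(posei_motif)),),
            site_variants=((2, 330, variant_base), (3, 330, variant_base)),
            # single-column deletion polymorphisms flanking the motif pin
            # the reported window to the planted columns 334..345
            member_deletions=((0, 318), (1, 331)),
            substitution_rate=0.002,
        ),
    ]
    return generate_dataset(template, specs, seed + 3)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[dict, list[CladeSpec]]:
    """Read a simulate config: template parameters and clade specs.

    Returns ``(template_params, clade_specs)`` where template_params has
    keys ``length`` and ``gc_fraction``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    tmpl = raw.get("template", {})
    if not isinstance(tmpl, dict):
        raise ConfigError("template: must be a mapping")
    params = {
        "length": int(tmpl.get("length", 2000)),
        "gc_fraction": float(tmpl.get("gc_fraction", 0.5)),
    }
    specs = []
    clades = raw.get("clades")
    if not isinstance(clades, list) or not clades:
        raise ConfigError("clades: must be a non-empty list")
    for i, c in enumerate(clades):
        try:
            specs.append(
                CladeSpec(
                    label=str(c["label"]),
                    n_members=int(c["n_members"]),
                    planted_motifs=tuple(
                        (int(m["start"]), str(m["motif"]).upper())
                        for m in c.get("planted_motifs", [])
                    ),
                    inserts=tuple(
                        (int(m["position"]), str(m["insert"]).upper())
                        for m in c.get("inserts", [])
                    ),
                    substitution_rate=float(c.get("substitution_rate", 0.0)),
                    missing_prefix=int(c.get("missing_prefix", 0)),
                    missing_suffix=int(c.get("missing_suffix", 0)),
                    truncate_members=(
                        tuple(int(x) for x in c["truncate_members"])
                        if "truncate_members" in c
                        else None
                    ),
                    member_deletions=tuple(
                        (int(d["member"]), int(d["column"]))
                        for d in c.get("member_deletions", [])
                    ),
                    site_variants=tuple(
                        (int(v["member"]), int(v["column"]), str(v["base"]).upper())
                        for v in c.get("site_variants", [])
                    ),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"clades[{i}]: {exc}") from exc
    return params, specs
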