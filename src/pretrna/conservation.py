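"""Annotate a protein multiple sequence alignment against a reference row.

Each non-reference cell is classed as identical (same residue as the
reference), conserved (different residue but same side-chain group), none,
or gap.  The five side-chain groups are acidic/amide {D,E,N,Q}, basic
{K,R,H}, aromatic {F,W,Y}, aliphatic-hydrophobic {V,I,L,M} and hydroxyl
{S,T}; glycine, alanine, cysteine and proline belong to no group, so e.g.
G/A counts as not conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import AlignIO

#: the fixed side-chain groups used for the "conserved" call
CONSERVATION_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("DENQ"),
    frozenset("KRH"),
    frozenset("FWY"),
    frozenset("VILM"),
    frozenset("ST"),
)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = {"-", "."}

_GROUP_OF: dict[str, int] = {
    aa: i for i, grp in enumerate(CONSERVATION_GROUPS) for aa in grp
}

CLASSES = ("identical", "conserved", "none", "gap")


@dataclass
class ProteinAlignment:
    """Equal-length aligned rows plus the id of the reference row."""

    ids: list[str]
    rows: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if self.reference_id not in self.ids:
            raise ValueError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.ids.index(self.reference_id)]


def load_alignment(path: str | Path, reference_id: str | None = None,
                   fmt: str | None = None) -> ProteinAlignment:
    """Read an aligned FASTA or Clustal file.

    Format is inferred from the first character when not given ('>' means
    FASTA).  The reference defaults to the first row.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fasta" if first == ">" else "clustal"
    aln = AlignIO.read(str(path), fmt)
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    if reference_id is None:
        reference_id = ids[0]
    return ProteinAlignment(ids=ids, rows=rows, reference_id=reference_id)


def classify_residue_pair(ref_aa: str, other_aa: str) -> str:
    """Class of one residue against the reference residue at a column.

    Gap if either is a gap; identical if equal; conserved if distinct but in
    the same side-chain group; otherwise none.  Unknown letters are an error.
    """
    ref_aa, other_aa = ref_aa.upper(), other_aa.upper()
    if ref_aa in GAP_CHARS or other_aa in GAP_CHARS:
        return "gap"
    for aa in (ref_aa, other_aa):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown amino-acid code {aa!r}")
    if ref_aa == other_aa:
        return "identical"
    if _GROUP_OF.get(ref_aa, -1) == _GROUP_OF.get(other_aa, -2):
        return "conserved"
    return "none"


def annotate_alignment(aln: ProteinAlignment) -> pd.DataFrame:
    """Classify every non-reference cell against the reference residue.

    Returns a long-format DataFrame (row_id, column, ref_aa, aa, class);
    columns where the reference itself is a gap are flagged ``unalignable``
    and every cell there is classed as gap.
    """
    ref = aln.reference_row
    records = []
    for row_id, row in zip(aln.ids, aln.rows):
        if row_id == aln.reference_id:
            continue
        for col, (r, a) in enumerate(zip(ref, row)):
            if r in GAP_CHARS:
                cls, flag = "gap", "unalignable"
            else:
                cls, flag = classify_residue_pair(r, a), ""
            records.append({"row_id": row_id, "column": col, "ref_aa": r,
                            "aa": a, "class": cls, "flag": flag})
    return pd.DataFrame(records)


def column_summary(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-column fractions of identical and conserved cells (gaps excluded
    from the denominator)."""
    rows = []
    for col, sub in annotation.groupby("column"):
        informative = sub[sub["class"] != "gap"]
        n = len(informative)
        rows.append({
            "column": int(col),
            "n_rows": n,
            "frac_identical": (informative["class"] == "identical").mean() if n else 0.0,
            "frac_conserved": (informative["class"] == "conserved").mean() if n else 0.0,
            "unalignable": bool((sub["flag"] == "unalignable").any()),
        })
    return pd.DataFrame(rows)


def render_text(aln: ProteinAlignment, annotation: pd.DataFrame,
                width: int = 60) -> str:
    """Plain-text three-tone rendering: uppercase = identical, lowercase =
    conserved, '.' = not conserved, '-' = gap (reference shown verbatim)."""
    ref = aln.reference_row
    coded: dict[str, str] = {}
    for row_id, sub in annotation.groupby("row_id"):
        chars = []
        ordered = sub.sort_values("column")
        for aa, cls in zip(ordered["aa"], ordered["class"]):
            if cls == "identical":
                chars.append(aa.upper())
            elif cls == "conserved":
                chars.append(aa.lower())
            elif cls == "gap":
                chars.append("-")
            else:
                chars.append(".")
        coded[row_id] = "".join(chars)
    name_w = max(len(i) for i in aln.ids) + 2
    blocks = []
    for off in range(0, aln.length, width):
        lines = [f"{aln.reference_id:<{name_w}}{ref[off:off + width]}"]
        for row_id in aln.ids:
            if row_id == aln.reference_id:
                continue
            lines.append(f"{row_id:<{name_w}}{coded[row_id][off:off + width]}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
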