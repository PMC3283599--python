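"""Amplicon fragment coordinate table for the two-marker tiling design.

The study design tiles the mitochondrial cytochrome b gene (cytb, fragments
C1..C11 with primed variants) with 15 short overlapping amplicons of
97-219 bp including primers, and the first exon of the nuclear IRBP gene
with 4 amplicons (I1..I4).  Coordinates are 1-based inclusive on each
gene's own reference frame; amplicon length is therefore end - start + 1.

The built-in table mirrors the published primer design and is the default
fragment layout of the simulator and the demo pipeline.  Custom layouts are
read from a TSV with columns fragment_id, start, end (length and tm
optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class Fragment:
    """One designed amplicon: id, 1-based inclusive coordinates, gene."""

    fragment_id: str
    start: int
    end: int
    gene: str = ""  # "mt" or "nuclear"; inferred from the id when empty

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.fragment_id}: end {self.end} < start {self.start}")
        if not self.gene:
            object.__setattr__(self, "gene", infer_gene(self.fragment_id))
        if self.gene not in ("mt", "nuclear"):
            raise ValueError(f"{self.fragment_id}: unknown gene {self.gene!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def infer_gene(fragment_id: str) -> str:
    """C* ids target the mitochondrial gene, I* ids the nuclear gene."""
    if fragment_id.upper().startswith("C"):
        return "mt"
    if fragment_id.upper().startswith("I"):
        return "nuclear"
    raise ValueError(f"cannot infer gene for fragment id {fragment_id!r}")


# fragment_id, start, end, printed length, annealing Tm (degC)
_DESIGN_ROWS = [
    ("C1", 1, 159, 159, 54),
    ("C2", 116, 311, 196, 50),
    ("C3", 237, 349, 113, 54),
    ("C3'", 237, 424, 188, 52),
    ("C4", 357, 529, 173, 52),
    ("C5", 472, 647, 176, 52),
    ("C6", 551, 647, 97, 52),
    ("C6'", 551, 714, 164, 52),
    ("C6''", 551, 769, 219, 52),
    ("C7", 587, 714, 128, 52),
    ("C7'", 587, 769, 183, 52),
    ("C8", 607, 769, 163, 55),
    ("C9", 710, 900, 191, 42),
    ("C10", 789, 941, 153, 52),
    ("C11", 843, 1031, 189, 50),
    ("I1", 887, 1037, 151, 52),
    ("I2", 965, 1131, 167, 52),
    ("I3", 965, 1087, 123, 52),
    ("I4", 1053, 1204, 152, 52),
]


def design_table() -> pd.DataFrame:
    """The published 19-row amplicon design as a DataFrame.

    Columns: fragment_id, start, end, length (as printed), tm, gene.
    """
    df = pd.DataFrame(
        _DESIGN_ROWS, columns=["fragment_id", "start", "end", "length", "tm"]
    )
    df["gene"] = [infer_gene(f) for f in df["fragment_id"]]
    return df


def design_fragments(gene: str | None = None) -> list[Fragment]:
    """Built-in fragment layout, optionally restricted to one gene."""
    frags = [Fragment(fid, s, e) for fid, s, e, _, _ in _DESIGN_ROWS]
    if gene is not None:
        frags = [f for f in frags if f.gene == gene]
    return frags


def load_fragments(path: str | Path) -> list[Fragment]:
    """Read a fragment coordinate TSV (fragment_id, start, end[, gene])."""
    df = pd.read_csv(path, sep="\t")
    required = {"fragment_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"fragment table needs columns {sorted(required)}")
    has_gene = "gene" in df.columns
    return [
        Fragment(
            str(r.fragment_id),
            int(r.start),
            int(r.end),
            str(r.gene) if has_gene else "",
        )
        for r in df.itertuples()
    ]
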