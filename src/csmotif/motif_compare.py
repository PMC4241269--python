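"""Cross-family and cross-subfamily motif comparison.

Homologous motifs from two protein groups are compared position by
position: a pair of residues is *identical* if the letters match,
*similar* if their distance in the 5-D physicochemical space is at most
the similarity threshold, and *different* otherwise — the vocabulary
behind statements like "4 of the 6 identical residues and 2 other
similar residues".

Presence/absence of a motif inventory across groups is decided by
interval overlap against anchor intervals in a shared master numbering:
a group has a motif if one of its detected motifs covers at least half
of the anchor interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

from .motif_finder import Motif, MotifSet
from .pcp_space import SIMILARITY_THRESHOLD, PCPVectorTable, load_default_table, pcp_distance

Verdict = Literal["identical", "similar", "different"]


class LengthMismatchError(ValueError):
    """Motif pair of unequal length compared without trimming enabled."""


@dataclass(frozen=True)
class ComparisonResult:
    """Position-wise verdicts and counts for one motif pair."""

    paired_positions: tuple[tuple[str, str, Verdict], ...]
    n_identical: int
    n_similar: int
    n_different: int

    @property
    def length(self) -> int:
        return len(self.paired_positions)

    def __post_init__(self) -> None:
        if self.n_identical + self.n_similar + self.n_different != self.length:
            raise ValueError("verdict counts must partition the compared length")


def _residue_string(m) -> str:
    if isinstance(m, Motif):
        return m.residues
    return str(m).upper()


def _verdict(a: str, b: str, table: PCPVectorTable, tau: float) -> Verdict:
    if a == b:
        return "identical"
    try:
        if pcp_distance(a, b, table) <= tau:
            return "similar"
    except ValueError:
        pass  # nonstandard letters (X, ...) can only be identical or different
    return "different"


def compare_motifs(a, b, table: PCPVectorTable | None = None,
                   tau: float = SIMILARITY_THRESHOLD,
                   trim: bool = True) -> ComparisonResult:
    """Compare two position-aligned motifs residue by residue.

    ``a`` and ``b`` may be :class:`~csmotif.motif_finder.Motif` objects or
    plain residue strings.  Motifs of unequal length are compared after a
    gap-free end-anchored trim to the shorter length, choosing among the
    ``|len(a) - len(b)| + 1`` offsets the one maximizing the identical
    count (ties break toward the leftmost offset); pass ``trim=False`` to
    require equal lengths instead.
    """
    if table is None:
        table = load_default_table()
    ra, rb = _residue_string(a), _residue_string(b)
    if len(ra) != len(rb):
        if not trim:
            raise LengthMismatchError(
                f"motif lengths differ ({len(ra)} vs {len(rb)}) and trimming is disabled"
            )
        short, long_ = (ra, rb) if len(ra) < len(rb) else (rb, ra)
        best_off, best_ident = 0, -1
        for off in range(len(long_) - len(short) + 1):
            ident = sum(x == y for x, y in zip(short, long_[off:off + len(short)]))
            if ident > best_ident:
                best_off, best_ident = off, ident
        window = long_[best_off:best_off + len(short)]
        ra, rb = (short, window) if len(ra) < len(rb) else (window, short)

    pairs = tuple((x, y, _verdict(x, y, table, tau)) for x, y in zip(ra, rb))
    verdicts = [v for _, _, v in pairs]
    return ComparisonResult(
        paired_positions=pairs,
        n_identical=verdicts.count("identical"),
        n_similar=verdicts.count("similar"),
        n_different=verdicts.count("different"),
    )


@dataclass(frozen=True)
class PresenceMatrix:
    """Presence/absence of anchor-labelled motifs per group."""

    groups: tuple[str, ...]
    anchor_ids: tuple[str, ...]
    cells: tuple[tuple[bool, ...], ...]  # rows follow groups, columns anchors

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if len(set(self.anchor_ids)) != len(self.anchor_ids):
            raise ValueError("anchor ids must be unique")
        if len(self.cells) != len(self.groups) or any(
                len(row) != len(self.anchor_ids) for row in self.cells):
            raise ValueError("every cell must be assigned")

    def present(self, group: str, anchor_id: str) -> bool:
        return self.cells[self.groups.index(group)][self.anchor_ids.index(anchor_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [["present" if c else "absent" for c in row] for row in self.cells],
            index=list(self.groups), columns=list(self.anchor_ids),
        )


def build_presence_matrix(groups: Mapping[str, MotifSet | Sequence[Motif]],
                          anchors: Mapping[str, tuple[int, int]],
                          min_overlap: float = 0.5) -> PresenceMatrix:
    """Decide which anchor motifs each group possesses.

    A cell is present iff some motif of the group, in master coordinates
    projected through the shared reference numbering, overlaps the anchor
    interval by at least ``min_overlap`` of the anchor length.
    """
    for label, (a0, a1) in anchors.items():
        if a1 < a0:
            raise ValueError(f"anchor {label!r} has nonpositive length")
    rows = []
    for _, motifset in groups.items():
        row = []
        for a0, a1 in anchors.values():
            need = min_overlap * (a1 - a0 + 1)
            hit = any(
                m.master_start is not None
                and min(m.master_end, a1) - max(m.master_start, a0) + 1 >= need
                for m in motifset
            )
            row.append(hit)
        rows.append(tuple(row))
    return PresenceMatrix(
        groups=tuple(groups), anchor_ids=tuple(anchors), cells=tuple(rows),
    )
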