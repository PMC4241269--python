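"""Detection of conserved sequence motifs from column profiles.

Columns whose relative entropy clears a data-driven threshold become
*seeds*; maximal runs of seeds separated by at most ``gap_tolerance``
sub-threshold columns are merged into candidate motifs; runs with fewer
than ``min_length`` seed columns are discarded.  Each surviving motif
carries a *rank* — the mean per-column relative entropy over its span —
and is rendered in master-sequence coordinates as ``start-RESIDUES-end``
(equivalently the caret dialect ``^start^RESIDUES^end^``).

The threshold is scale-free by construction (mean + alpha*SD, or a
quantile, of the column RE distribution), so rank orderings between
motifs are meaningful even though absolute rank magnitudes depend on the
alignment and background at hand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .column_profiling import ColumnProfile
from .msa_io import CoordinateMap


@dataclass(frozen=True)
class MotifParams:
    """Knobs of the motif clustering step.

    threshold_mode : ``mean_plus_alpha_sd`` (threshold = mean + alpha*SD of
        column RE over eligible columns) or ``quantile`` (the q-quantile).
    alpha : SD multiplier (default 2.0, the two-sigma outlier convention:
        under a signal-free alignment the column-RE distribution is
        right-skewed and a one-sigma cut seeds ~10-15% of columns, enough
        for chance runs to clear ``min_length``; two sigma suppresses
        chance clusters while conserved blocks sit far above it).
    quantile : quantile level when in quantile mode (default 0.8).
    gap_tolerance : max sub-threshold columns bridged inside a motif (default 2).
    min_length : minimum number of seed columns per motif (default 4).
    max_gap_fraction : columns gappier than this are never seeds (default 0.5).
    """

    threshold_mode: Literal["mean_plus_alpha_sd", "quantile"] = "mean_plus_alpha_sd"
    alpha: float = 2.0
    quantile: float = 0.8
    gap_tolerance: int = 2
    min_length: int = 4
    max_gap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.gap_tolerance < 0:
            raise ValueError("gap_tolerance must be >= 0")
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must lie in [0, 1]")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")


@dataclass(frozen=True)
class Motif:
    """A contiguous high-conservation block.

    Column coordinates are 0-based alignment columns (inclusive); master
    coordinates are 1-based residue numbers of the master sequence
    (inclusive), ``None`` when the span is entirely master-gap.  ``tiers``
    holds one character per master residue: H/I/L for high, intermediate,
    low identity conservation.  ``partial`` flags motifs with interior
    master-gap columns (skipped in the residue string).
    """

    motif_id: str
    column_start: int
    column_end: int
    master_start: Optional[int]
    master_end: Optional[int]
    residues: str
    tiers: str
    rank: float
    partial: bool = False

    def __post_init__(self) -> None:
        if self.column_start > self.column_end:
            raise ValueError("column_start must be <= column_end")
        if self.rank < 0:
            raise ValueError("rank must be nonnegative")
        if (self.master_start is not None and not self.partial
                and len(self.residues) != self.master_end - self.master_start + 1):
            raise ValueError("residue string inconsistent with master span")

    @property
    def length(self) -> int:
        return self.column_end - self.column_start + 1


@dataclass(frozen=True)
class MotifSet:
    """Motifs of one alignment, ordered and non-overlapping in columns."""

    motifs: tuple[Motif, ...]
    alignment_id: str = ""
    params: Optional[MotifParams] = None

    def __post_init__(self) -> None:
        starts = [m.column_start for m in self.motifs]
        if starts != sorted(starts):
            raise ValueError("motifs must be sorted by column_start")
        for a, b in zip(self.motifs, self.motifs[1:]):
            if b.column_start <= a.column_end:
                raise ValueError("motifs must not overlap in columns")

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)


class MapMismatchError(ValueError):
    """Profiles reference columns the coordinate map does not cover."""


def rank_motif(columns: Sequence[int], profiles: Sequence[ColumnProfile]) -> float:
    """Mean column relative entropy over a column range (nats).

    Deterministic and order-invariant; an empty range is a value error.
    """
    cols = list(columns)
    if not cols:
        raise ValueError("cannot rank an empty column range")
    by_col = {p.column: p for p in profiles}
    return float(np.mean([by_col[c].re for c in cols]))


def compute_threshold(profiles: Sequence[ColumnProfile], params: MotifParams) -> float:
    """The seed threshold over eligible (not too gappy) columns."""
    res = np.array([p.re for p in profiles if p.gap_fraction <= params.max_gap_fraction])
    if res.size == 0:
        return np.inf
    if params.threshold_mode == "mean_plus_alpha_sd":
        return float(res.mean() + params.alpha * res.std(ddof=0))
    return float(np.quantile(res, params.quantile))


def find_motifs(profiles: Sequence[ColumnProfile], params: MotifParams,
                cmap: CoordinateMap) -> MotifSet:
    """Cluster high-relative-entropy columns into motifs.

    Seeds are columns with RE >= threshold (ties count) and gap fraction at
    most ``max_gap_fraction``.  Seeds separated by at most ``gap_tolerance``
    sub-threshold columns merge into one run; runs with fewer than
    ``min_length`` seeds are dropped.  Master coordinates come from the
    coordinate map; master-gap columns are skipped in the residue string
    and flag the motif as partial.
    """
    if not profiles:
        return MotifSet(motifs=(), params=params)
    if max(p.column for p in profiles) >= len(cmap.column_to_residue):
        raise MapMismatchError("coordinate map shorter than the profiled columns")

    thr = compute_threshold(profiles, params)
    seeds = [p.column for p in profiles
             if p.re >= thr and p.gap_fraction <= params.max_gap_fraction]

    runs: list[list[int]] = []
    for s in seeds:
        if runs and s - runs[-1][-1] <= params.gap_tolerance + 1:
            runs[-1].append(s)
        else:
            runs.append([s])

    by_col = {p.column: p for p in profiles}
    motifs = []
    for i, run in enumerate(r for r in runs if len(r) >= params.min_length):
        c0, c1 = run[0], run[-1]
        span = range(c0, c1 + 1)
        residues, tiers, numbers = [], [], []
        for c in span:
            num = cmap.column_to_residue[c]
            if num is None:
                continue
            numbers.append(num)
            prof = by_col[c]
            residues.append(cmap.master_sequence[c] if cmap.master_sequence else "?")
            tiers.append({"high": "H", "intermediate": "I", "low": "L"}[prof.tier])
        motifs.append(Motif(
            motif_id=f"motif_{i + 1}",
            column_start=c0, column_end=c1,
            master_start=numbers[0] if numbers else None,
            master_end=numbers[-1] if numbers else None,
            residues="".join(residues), tiers="".join(tiers),
            rank=rank_motif(span, profiles),
            partial=bool(numbers) and len(numbers) != (c1 - c0 + 1),
        ))
    return MotifSet(motifs=tuple(motifs), alignment_id=cmap.master_id, params=params)


# ---------------------------------------------------------------------------
# rendering

_PLAIN = re.compile(r"^(\d+)-([A-Za-z]+)-(\d+)$")
_CARET = re.compile(r"^\^(\d+)\^([A-Za-z]+)\^(\d+)\^$")


class MotifSyntaxError(ValueError):
    """A motif string does not match either rendering dialect."""


class MotifConsistencyError(ValueError):
    """Motif string coordinates disagree with the residue count."""


def render_motif(m: Motif, dialect: Literal["plain", "caret"] = "plain") -> str:
    """Render a fully mappable motif as ``start-RESIDUES-end``.

    A partially mappable motif renders with a trailing ``!partial`` flag
    because its residue string skips master-gap columns.
    """
    if m.master_start is None:
        raise ValueError(f"motif {m.motif_id} has no master coordinates")
    if dialect == "caret":
        s = f"^{m.master_start}^{m.residues}^{m.master_end}^"
    else:
        s = f"{m.master_start}-{m.residues}-{m.master_end}"
    return s + "!partial" if m.partial else s


def parse_motif(s: str) -> tuple[int, str, int]:
    """Parse ``start-RESIDUES-end`` or ``^start^RESIDUES^end^``.

    Validates ``end == start + len(residues) - 1`` and returns
    ``(start, residues, end)``.
    """
    match = _PLAIN.match(s.strip()) or _CARET.match(s.strip())
    if not match:
        raise MotifSyntaxError(f"unparseable motif string {s!r}")
    start, residues, end = int(match.group(1)), match.group(2).upper(), int(match.group(3))
    expected = start + len(residues) - 1
    if end != expected:
        raise MotifConsistencyError(
            f"motif {s!r}: end {end} inconsistent with start {start} and "
            f"{len(residues)} residues (expected end {expected})"
        )
    return start, residues, end


def assign_csm_labels(motifs: MotifSet, anchors: dict[str, tuple[int, int]],
                      min_overlap: float = 0.5) -> dict[str, Optional[str]]:
    """Label detected motifs with anchor ids (e.g. CSM numbers) by interval overlap.

    Anchor ids are inventory labels assigned by position against a reference
    interval set, not detector output.  A motif maps to the anchor whose
    master interval it overlaps by at least ``min_overlap`` of the anchor
    length (best overlap wins); unmatched motifs map to ``None``.
    """
    out: dict[str, Optional[str]] = {}
    for m in motifs:
        best, best_frac = None, 0.0
        if m.master_start is not None:
            for label, (a0, a1) in anchors.items():
                if a1 < a0:
                    raise ValueError(f"anchor {label!r} has nonpositive length")
                ov = min(m.master_end, a1) - max(m.master_start, a0) + 1
                frac = ov / (a1 - a0 + 1)
                if frac >= min_overlap and frac > best_frac:
                    best, best_frac = label, frac
        out[m.motif_id] = best
    return out
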