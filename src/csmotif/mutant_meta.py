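"""Meta-analysis of a directed-evolution mutant catalogue.

The catalogue lists functionally important substitutions found by random
mutagenesis across several CYP enzymes, each annotated with the region of
the fold it falls in (D helix ... L helix) and its position relative to
the conserved-sequence-motif (CSM) inventory ("8-9" = between CSM 8 and
CSM 9).  The analysis counts *distinct residue positions* — S334P and
P334S are one residue — and reports regional enrichment as exact
fractions, e.g. the share of positions falling between helices E and I.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .motif_finder import MotifSet

_SUBST = re.compile(r"^([A-Z])(\d+)([A-Z])$")

#: Region vocabulary of the catalogue, N- to C-terminal order of the fold.
REGION_ORDER: tuple[str, ...] = (
    "D helix", "E helix", "F helix", "F-G loop", "G helix", "G-H loop",
    "H helix", "I helix", "J-J' loop", "K'-L loop", "L helix",
)

#: Regions spanning helices E through I inclusive.
E_TO_I_REGIONS = frozenset(REGION_ORDER[1:8])

#: Regions spanning helices E through H inclusive (E-I minus the I helix).
E_TO_H_REGIONS = frozenset(REGION_ORDER[1:7])


class CatalogueValidationError(ValueError):
    """A catalogue row fails cross-validation (e.g. substitution vs position)."""


@dataclass(frozen=True)
class MutantRecord:
    """One reported substitution in one enzyme."""

    enzyme: str
    substitution: str
    position: int
    csm_label: str
    region: str
    active_site: bool = False
    function_notes: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CatalogueValidationError(f"position {self.position} must be >= 1")
        m = _SUBST.match(self.substitution)
        if not m:
            raise CatalogueValidationError(
                f"substitution {self.substitution!r} is not of the form S183C"
            )
        if int(m.group(2)) != self.position:
            raise CatalogueValidationError(
                f"substitution {self.substitution!r} embeds position {m.group(2)}, "
                f"row says {self.position}"
            )


def load_catalogue(source=None) -> list[MutantRecord]:
    """Load and validate a mutant catalogue TSV.

    With no argument the packaged catalogue fixture is used.  Required
    columns: enzyme, substitution, position, csm_label, region; optional:
    active_site (true/false), function_notes.
    """
    if source is None:
        with resources.as_file(
            resources.files("csmotif.data").joinpath("table1_mutants.tsv")
        ) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(source, sep="\t", dtype=str)
    required = {"enzyme", "substitution", "position", "csm_label", "region"}
    missing = required - set(frame.columns)
    if missing:
        raise CatalogueValidationError(f"catalogue lacks columns {sorted(missing)}")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(MutantRecord(
                enzyme=row["enzyme"],
                substitution=row["substitution"],
                position=int(row["position"]),
                csm_label=row["csm_label"],
                region=row["region"],
                active_site=str(row.get("active_site", "false")).lower() == "true",
                function_notes=str(row.get("function_notes", "") or ""),
            ))
        except CatalogueValidationError as exc:
            raise CatalogueValidationError(f"row {i + 2}: {exc}") from exc
    return records


def _distinct_positions(records: Iterable[MutantRecord]) -> set[tuple[str, int]]:
    return {(r.enzyme, r.position) for r in records}


def _filtered(records: Sequence[MutantRecord], enzyme: Optional[str],
              regions: Optional[Iterable[str]],
              exclude_positions: Optional[Iterable[int]]) -> list[MutantRecord]:
    if enzyme is not None and enzyme not in {r.enzyme for r in records}:
        raise KeyError(f"unknown enzyme label {enzyme!r}")
    region_set = set(regions) if regions is not None else None
    excl = set(exclude_positions) if exclude_positions is not None else set()
    return [
        r for r in records
        if (enzyme is None or r.enzyme == enzyme)
        and (region_set is None or r.region in region_set)
        and r.position not in excl
    ]


def count_residues(records: Sequence[MutantRecord], enzyme: Optional[str] = None,
                   regions: Optional[Iterable[str]] = None,
                   exclude_positions: Optional[Iterable[int]] = None) -> int:
    """Count distinct mutated residue positions matching all filters.

    Recurrent substitutions at one position (S334P / P334S) count once.
    Without an enzyme filter, positions are distinct per (enzyme, position)
    pair, since numbering is enzyme-specific.
    """
    return len(_distinct_positions(_filtered(records, enzyme, regions, exclude_positions)))


@dataclass(frozen=True)
class EnrichmentResult:
    """An exact regional-enrichment fraction with its provenance."""

    numerator: int
    denominator: int
    regions: frozenset[str]
    exclusions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError("numerator cannot exceed denominator")

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def value(self) -> float:
        return self.numerator / self.denominator

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} = {self.value:.3f}"


def regional_fraction(records: Sequence[MutantRecord], regions: Iterable[str],
                      exclude_positions: Optional[Iterable[int]] = None,
                      enzyme: Optional[str] = None) -> EnrichmentResult:
    """Fraction of distinct mutated positions lying in a region set.

    The denominator is every distinct position surviving the exclusions;
    the numerator restricts to the given regions.  An empty denominator is
    an error.  Unknown region labels are rejected to catch typos.
    """
    region_set = set(regions)
    vocab = {r.region for r in records}
    unknown = region_set - vocab - set(REGION_ORDER)
    if unknown:
        raise ValueError(f"region labels not in the catalogue vocabulary: {sorted(unknown)}")
    denom_records = _filtered(records, enzyme, None, exclude_positions)
    denominator = len(_distinct_positions(denom_records))
    if denominator == 0:
        raise ZeroDivisionError("no positions remain after exclusions")
    numerator = len(_distinct_positions(
        [r for r in denom_records if r.region in region_set]
    ))
    return EnrichmentResult(
        numerator=numerator, denominator=denominator,
        regions=frozenset(region_set),
        exclusions=frozenset(exclude_positions or ()),
    )


@dataclass(frozen=True)
class RegionMap:
    """Named residue intervals per enzyme, for annotating new positions.

    ``intervals[enzyme]`` is an ordered tuple of ``(label, start, end)``
    with 1-based inclusive, non-overlapping, sorted intervals.
    """

    intervals: Mapping[str, tuple[tuple[str, int, int], ...]]

    def __post_init__(self) -> None:
        for enzyme, ivs in self.intervals.items():
            last_end = 0
            for label, start, end in ivs:
                if start > end:
                    raise ValueError(f"{enzyme} {label}: empty interval {start}-{end}")
                if start <= last_end:
                    raise ValueError(f"{enzyme} {label}: intervals overlap or are unsorted")
                last_end = end

    def lookup(self, enzyme: str, position: int) -> Optional[str]:
        for label, start, end in self.intervals[enzyme]:
            if start <= position <= end:
                return label
        return None


def csm_label_for(position: int, anchors: Mapping[int, tuple[int, int]]) -> str:
    """The CSM label of a position relative to anchor intervals.

    ``"k"`` inside CSM k; ``"k-(k+1)"`` strictly between CSM k and the next
    anchored CSM; ``"<first"`` / ``">last"`` at the flanks.
    """
    ids = sorted(anchors)
    for k in ids:
        a0, a1 = anchors[k]
        if a0 <= position <= a1:
            return str(k)
    if position < anchors[ids[0]][0]:
        return f"<{ids[0]}"
    if position > anchors[ids[-1]][1]:
        return f">{ids[-1]}"
    for k, nxt in zip(ids, ids[1:]):
        if anchors[k][1] < position < anchors[nxt][0]:
            return f"{k}-{nxt}"
    raise AssertionError("unreachable: anchors cover all remaining cases")


def annotate_position(enzyme: str, position: int, region_map: RegionMap,
                      csm_anchors: Mapping[int, tuple[int, int]],
                      motifs: Optional[MotifSet] = None) -> tuple[Optional[str], str]:
    """Annotate a residue position with its region and CSM label.

    Returns ``(region label or None, csm_label)``.  A position beyond all
    region intervals gets region ``None`` and a flank CSM label.  When a
    detected :class:`MotifSet` is supplied, its motif intervals override
    the anchor intervals for the "inside a CSM" decision.
    """
    if enzyme not in region_map.intervals:
        raise KeyError(f"enzyme {enzyme!r} not in the region map")
    region = region_map.lookup(enzyme, position)
    anchors = dict(csm_anchors)
    if motifs is not None:
        labels = {m.motif_id: (m.master_start, m.master_end) for m in motifs
                  if m.master_start is not None}
        # motif intervals refine anchors that they overlap
        for k, (a0, a1) in list(anchors.items()):
            for m0, m1 in labels.values():
                if min(m1, a1) - max(m0, a0) + 1 >= 0.5 * (a1 - a0 + 1):
                    anchors[k] = (m0, m1)
                    break
    return region, csm_label_for(position, anchors)
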