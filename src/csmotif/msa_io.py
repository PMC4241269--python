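"""Alignment input, validation, and master-sequence coordinate mapping.

Alignments are consumed, never built: any aligner (ClustalW, MAFFT, ...)
may produce the input, in aligned FASTA or Clustal format.  Motif positions
are reported in the residue numbering of one designated *master* sequence,
the convention used when a family-level motif is written as, say,
``193-YKDKEFLS-200`` on a chosen representative enzyme.

Coordinates are 1-based and inclusive throughout; GFF3 shares that
convention natively.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import AlignIO

from .pcp_space import STANDARD_RESIDUES

log = logging.getLogger(__name__)

GAP = "-"
UNKNOWN = "X"
_VALID_CHARS = set(STANDARD_RESIDUES) | {GAP, UNKNOWN}


class AlignmentFormatError(ValueError):
    """Malformed alignment input (ragged records, duplicate identifiers...)."""


class AlignmentContentError(ValueError):
    """Structurally valid input that cannot form a usable alignment."""


@dataclass(frozen=True)
class Alignment:
    """An immutable protein multiple sequence alignment.

    ``records`` is an ordered tuple of ``(identifier, aligned_sequence)``;
    sequences are uppercase over the 20 standard residues plus ``-`` (gap)
    and ``X`` (unknown).
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentContentError("an alignment needs at least 2 sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            for i, (rid, seq) in enumerate(self.records, start=1):
                if len(seq) != len(self.records[0][1]):
                    raise AlignmentFormatError(
                        f"record {i} ({rid!r}) has length {len(seq)}, "
                        f"expected {len(self.records[0][1])}"
                    )
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = next(r for r in ids if ids.count(r) > 1)
            raise AlignmentFormatError(f"duplicate sequence identifier {dup!r}")
        for rid, seq in self.records:
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise AlignmentFormatError(
                    f"record {rid!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    def sequence(self, identifier: str) -> str:
        for rid, seq in self.records:
            if rid == identifier:
                return seq
        raise KeyError(f"no sequence {identifier!r} in alignment")

    def column(self, index: int) -> str:
        """The residues of a 0-based column, one character per sequence."""
        return "".join(seq[index] for _, seq in self.records)

    def to_fasta(self) -> str:
        return "".join(f">{rid}\n{seq}\n" for rid, seq in self.records)


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP).replace("~", GAP)


def read_alignment(source, fmt: str = "fasta") -> Alignment:
    """Read an alignment from a path, stream, or string of FASTA/Clustal text.

    Residue letters are uppercased; ``.`` and ``~`` gap spellings are
    normalized to ``-``.  Ragged records, duplicate identifiers and
    single-sequence files raise.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if isinstance(source, (str, Path)) and not (
        isinstance(source, str) and source.lstrip().startswith((">", "CLUSTAL"))
    ):
        handle: io.TextIOBase = open(source)
        close = True
    elif isinstance(source, str):
        handle, close = io.StringIO(source), False
    else:
        handle, close = source, False
    try:
        try:
            seqs = list(AlignIO.read(handle, fmt))
        except ValueError as exc:
            # Bio.AlignIO rejects ragged FASTA; re-inspect for a precise message.
            if fmt == "fasta":
                handle.seek(0)
                from Bio import SeqIO

                recs = list(SeqIO.parse(handle, "fasta"))
                if len(recs) >= 2:
                    want = len(recs[0].seq)
                    for i, r in enumerate(recs, start=1):
                        if len(r.seq) != want:
                            raise AlignmentFormatError(
                                f"record {i} ({r.id!r}) has length {len(r.seq)}, "
                                f"expected {want}"
                            ) from None
            raise AlignmentFormatError(str(exc)) from exc
    finally:
        if close:
            handle.close()
    return Alignment(tuple((rec.id, _normalize(str(rec.seq))) for rec in seqs))


@dataclass(frozen=True)
class CoordinateMap:
    """Mapping between alignment columns and master-sequence residue numbers.

    ``column_to_residue[i]`` is the 1-based residue number of 0-based column
    ``i`` in the ungapped master sequence, or ``None`` where the master has
    a gap.  ``residue_to_column`` is the inverse (partial) map.
    """

    master_id: str
    column_to_residue: tuple[Optional[int], ...]
    residue_to_column: dict[int, int] = field(repr=False)
    master_sequence: Optional[str] = field(default=None, repr=False)  # aligned row

    def __post_init__(self) -> None:
        if (self.master_sequence is not None
                and len(self.master_sequence) != len(self.column_to_residue)):
            raise ValueError("aligned master sequence length disagrees with the map")
        nums = [n for n in self.column_to_residue if n is not None]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("master residue numbers must be strictly increasing")
        for col, num in enumerate(self.column_to_residue):
            if num is not None and self.residue_to_column.get(num) != col:
                raise ValueError("residue_to_column is not the inverse of column_to_residue")

    @property
    def n_residues(self) -> int:
        return len(self.residue_to_column)


def build_coordinate_map(aln: Alignment, master_id: str, offset: int = 1) -> CoordinateMap:
    """Number the master's non-gap columns ``offset, offset+1, ...`` left to right.

    ``offset`` lets numbering start at any residue (a fragment of a longer
    protein keeps its native coordinates).
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    master = aln.sequence(master_id)  # raises KeyError for unknown id
    col_to_res: list[Optional[int]] = []
    res_to_col: dict[int, int] = {}
    n = offset
    for col, ch in enumerate(master):
        if ch == GAP:
            col_to_res.append(None)
        else:
            col_to_res.append(n)
            res_to_col[n] = col
            n += 1
    return CoordinateMap(master_id, tuple(col_to_res), res_to_col, master)


_ANNOT_COLUMNS = ("motif_id", "master_start", "master_end", "residue_string", "rank", "tier_string")


def write_motif_annotations(motifs: Iterable, cmap: CoordinateMap, sink,
                            gff3_sink=None) -> None:
    """Write motifs as TSV and optionally GFF3 (1-based inclusive intervals).

    A motif whose span is entirely master-gap is written with empty
    coordinates and a warning is logged.
    """
    rows = []
    for m in motifs:
        if m.master_start is None or m.master_end is None:
            log.warning("motif %s spans only master-gap columns; coordinates omitted", m.motif_id)
            rows.append((m.motif_id, "", "", m.residues, f"{m.rank:.6g}", m.tiers))
        else:
            rows.append((m.motif_id, str(m.master_start), str(m.master_end),
                         m.residues, f"{m.rank:.6g}", m.tiers))
    text = "\t".join(_ANNOT_COLUMNS) + "\n"
    text += "".join("\t".join(r) + "\n" for r in rows)
    Path(sink).write_text(text)

    if gff3_sink is not None:
        lines = ["##gff-version 3"]
        for m in motifs:
            if m.master_start is None:
                continue
            lines.append("\t".join([
                cmap.master_id, "csmotif", "conserved_motif",
                str(m.master_start), str(m.master_end), f"{m.rank:.6g}",
                ".", ".", f"ID={m.motif_id};residues={m.residues};tiers={m.tiers}",
            ]))
        Path(gff3_sink).write_text("\n".join(lines) + "\n")


def read_motif_annotations(path) -> list[dict]:
    """Parse a TSV written by :func:`write_motif_annotations`."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if tuple(header) != _ANNOT_COLUMNS:
        raise AlignmentFormatError(f"unexpected annotation header {header}")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        out.append({
            "motif_id": f[0],
            "master_start": int(f[1]) if f[1] else None,
            "master_end": int(f[2]) if f[2] else None,
            "residue_string": f[3],
            "rank": float(f[4]),
            "tier_string": f[5],
        })
    return out
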