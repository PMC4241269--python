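"""Synthetic alignments with planted conserved blocks and known truth.

Sequences follow a star phylogeny: every column is drawn independently
for every sequence, with no tree correlation — appropriate because the
profiling statistics downstream are purely column-wise.  A planted block
emits its modal residue with probability ``conservation`` and otherwise a
background draw *excluding* the modal residue, so the planted
conservation level is exactly the expected identity fraction of the
column.  Gaps are inserted i.i.d. after residue sampling.

All randomness flows through one :func:`numpy.random.default_rng`
generator seeded from the spec, so a spec reproduces its alignment
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .msa_io import GAP, Alignment
from .pcp_space import STANDARD_RESIDUES

_RES_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}


class SpecError(ValueError):
    """An invalid synthetic-alignment specification."""


@dataclass(frozen=True)
class PlantedBlock:
    """A contiguous conserved block: 0-based start column, modal residue
    string (one letter per column), and target identity fraction."""

    start: int
    modal_residues: str
    conservation: float

    def __post_init__(self) -> None:
        if not self.modal_residues or any(c not in _RES_INDEX for c in self.modal_residues):
            raise SpecError("modal_residues must be nonempty standard residues")
        if not 0.0 <= self.conservation <= 1.0:
            raise SpecError("conservation must lie in [0, 1]")
        if self.start < 0:
            raise SpecError("start column must be >= 0")

    @property
    def length(self) -> int:
        return len(self.modal_residues)

    @property
    def end(self) -> int:
        """Last column of the block, 0-based inclusive."""
        return self.start + self.length - 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic alignment."""

    n_seqs: int
    n_cols: int
    planted: tuple[PlantedBlock, ...] = ()
    background: Optional[np.ndarray] = None  # 20 probabilities; None = flat
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 2 or self.n_cols < 1:
            raise SpecError("need n_seqs >= 2 and n_cols >= 1")
        if not 0.0 <= self.gap_rate < 1.0:
            raise SpecError("gap_rate must lie in [0, 1)")
        bg = (np.full(20, 0.05) if self.background is None
              else np.asarray(self.background, dtype=float))
        if bg.shape != (20,) or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise SpecError("background must be 20 probabilities summing to 1")
        object.__setattr__(self, "background", bg)
        blocks = tuple(sorted(self.planted, key=lambda b: b.start))
        for b in blocks:
            if b.end >= self.n_cols:
                raise SpecError(f"planted block at {b.start} exceeds n_cols={self.n_cols}")
        for a, b in zip(blocks, blocks[1:]):
            if b.start <= a.end:
                raise SpecError("planted blocks must not overlap")
        object.__setattr__(self, "planted", blocks)


@dataclass(frozen=True)
class GroundTruth:
    """Per-block column intervals and per-column generating distributions."""

    blocks: tuple[PlantedBlock, ...]
    column_distributions: np.ndarray  # (n_cols, 20) residue probabilities

    def block_columns(self) -> set[int]:
        return {c for b in self.blocks for c in range(b.start, b.end + 1)}


def generate_msa(spec: SyntheticSpec) -> tuple[Alignment, GroundTruth]:
    """Draw an alignment from a spec; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    dists = np.tile(spec.background, (spec.n_cols, 1))
    for b in spec.planted:
        for j, modal in enumerate(b.modal_residues):
            col = b.start + j
            m = _RES_INDEX[modal]
            off = spec.background.copy()
            off[m] = 0.0
            total = off.sum()
            if total == 0 and b.conservation < 1.0:
                raise SpecError(f"no off-modal mass available in column {col}")
            p = off / total * (1.0 - b.conservation) if total > 0 else np.zeros(20)
            p[m] = b.conservation
            dists[col] = p

    res = np.empty((spec.n_seqs, spec.n_cols), dtype="U1")
    letters = np.array(list(STANDARD_RESIDUES))
    for col in range(spec.n_cols):
        draws = rng.choice(20, size=spec.n_seqs, p=dists[col])
        res[:, col] = letters[draws]
    if spec.gap_rate > 0:
        gaps = rng.random((spec.n_seqs, spec.n_cols)) < spec.gap_rate
        res[gaps] = GAP

    records = tuple(
        (f"seq{i + 1:04d}", "".join(res[i])) for i in range(spec.n_seqs)
    )
    return Alignment(records), GroundTruth(blocks=spec.planted, column_distributions=dists)


def spec_from_dict(d: dict) -> SyntheticSpec:
    """Build a spec from a plain mapping (YAML-friendly)."""
    planted = tuple(
        PlantedBlock(start=int(b["start"]), modal_residues=str(b["modal_residues"]),
                     conservation=float(b["conservation"]))
        for b in d.get("planted", [])
    )
    bg = d.get("background")
    return SyntheticSpec(
        n_seqs=int(d["n_seqs"]), n_cols=int(d["n_cols"]), planted=planted,
        background=None if bg is None else np.asarray(bg, dtype=float),
        gap_rate=float(d.get("gap_rate", 0.0)), seed=int(d.get("seed", 0)),
    )


def random_planted_spec(n_seqs: int, n_cols: int, block_length: int,
                        conservation: float, seed: int,
                        gap_rate: float = 0.0) -> SyntheticSpec:
    """A spec with one planted block at a seed-derived random position.

    The block's position and modal residues are drawn from the same seed
    that later drives sequence sampling, so truth and data stay coupled.
    """
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, n_cols - block_length + 1))
    modal = "".join(rng.choice(list(STANDARD_RESIDUES), size=block_length))
    return SyntheticSpec(
        n_seqs=n_seqs, n_cols=n_cols,
        planted=(PlantedBlock(start=start, modal_residues=modal,
                              conservation=conservation),),
        gap_rate=gap_rate, seed=seed,
    )


def make_fixture_suite(outdir) -> None:
    """Write the bundled in-study fixtures (mutant catalogue, motif table,
    fixture README) into a directory."""
    from importlib import resources

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pkg = resources.files("csmotif.data")
    for name in ("table1_mutants.tsv", "table3_motifs.tsv", "FIXTURES_README.md"):
        target = out / ("README.md" if name == "FIXTURES_README.md" else name)
        target.write_text(pkg.joinpath(name).read_text())
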