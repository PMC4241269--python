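"""Five-dimensional physicochemical property (PCP) space for amino acids.

Each of the 20 standard amino acids is represented by a 5-component vector
of factor scores obtained by principal component analysis of a large matrix
of published amino-acid property indices.  The first component tracks
hydrophilicity; distances in the 5-space quantify physicochemical
similarity between residues (e.g. Asp/Glu are close, Asp/Phe are not).

The packaged table ships with the distribution and is the default;
:func:`derive_table` regenerates an equivalent embedding from any property
matrix with at least five property columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import dist as _euclid

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Number of components of the embedding.
N_COMPONENTS: int = 5

#: Default physicochemical similarity threshold (Euclidean distance in the
#: packaged 5-space).  Fixed as the smallest two-decimal value admitting the
#: five canonical conservative substitutions D/E, I/L, F/Y, K/R and S/T as
#: "similar"; the binding pair is F/Y at distance 0.5093.
SIMILARITY_THRESHOLD: float = 0.51

#: Canonical conservative residue pairs used to calibrate the threshold.
CONSERVATIVE_PAIRS: tuple[tuple[str, str], ...] = (
    ("D", "E"), ("I", "L"), ("F", "Y"), ("K", "R"), ("S", "T"),
)


class ResourceError(RuntimeError):
    """A packaged data resource is missing or corrupt."""


@dataclass(frozen=True)
class PropertyMatrix:
    """A residues-by-properties matrix of real-valued amino-acid indices.

    Parameters
    ----------
    residues : sequence of str
        The 20 standard one-letter codes, in row order.
    values : ndarray, shape (20, P)
        One column per property index; unitless after standardization.
    property_names : sequence of str
        Labels for the P property columns.
    """

    residues: tuple[str, ...]
    values: np.ndarray
    property_names: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if sorted(self.residues) != sorted(STANDARD_RESIDUES):
            raise ValueError("PropertyMatrix must cover exactly the 20 standard residues")
        if vals.shape != (20, len(self.property_names)):
            raise ValueError(
                f"values shape {vals.shape} inconsistent with 20 residues x "
                f"{len(self.property_names)} properties"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("PropertyMatrix contains missing or non-finite values")

    @classmethod
    def from_tsv(cls, path) -> "PropertyMatrix":
        """Read a property matrix from TSV with a ``residue`` column and one
        header-labelled column per property."""
        frame = pd.read_csv(path, sep="\t")
        frame = frame.set_index(frame.columns[0])
        return cls(
            residues=tuple(frame.index),
            values=frame.to_numpy(dtype=float),
            property_names=tuple(frame.columns),
        )


@dataclass(frozen=True)
class PCPVectorTable:
    """The 5-component physicochemical embedding of the 20 amino acids."""

    vectors: dict[str, np.ndarray]
    explained_variance: np.ndarray
    provenance: str = "packaged"
    _matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if set(self.vectors) != set(STANDARD_RESIDUES):
            raise ValueError("PCPVectorTable must have exactly 20 residue entries")
        vecs = {r: np.asarray(v, dtype=float) for r, v in self.vectors.items()}
        for r, v in vecs.items():
            if v.shape != (N_COMPONENTS,) or not np.all(np.isfinite(v)):
                raise ValueError(f"vector for {r} must be 5 finite components")
        ev = np.asarray(self.explained_variance, dtype=float)
        if ev.shape != (N_COMPONENTS,) or np.any(ev < 0) or ev.sum() > 1 + 1e-9:
            raise ValueError("explained_variance must be 5 nonnegative fractions summing to <= 1")
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")
        object.__setattr__(self, "vectors", vecs)
        object.__setattr__(self, "explained_variance", ev)
        object.__setattr__(
            self, "_matrix", np.array([vecs[r] for r in STANDARD_RESIDUES])
        )

    def vector(self, residue: str) -> np.ndarray:
        """The 5-component vector of a standard residue (value error otherwise)."""
        try:
            return self.vectors[residue.upper()]
        except KeyError:
            raise ValueError(f"{residue!r} is not a standard amino-acid code") from None

    def matrix(self) -> np.ndarray:
        """20x5 matrix of vectors, rows ordered as :data:`STANDARD_RESIDUES`."""
        return self._matrix.copy()


def _data_path(name: str):
    return resources.files("csmotif.data").joinpath(name)


def load_hydrophilicity() -> dict[str, float]:
    """The bundled hydrophilicity scale (octanol-water transfer free energies,
    sign-flipped so hydrophilic residues score high)."""
    try:
        with resources.as_file(_data_path("hydrophilicity.tsv")) as p:
            frame = pd.read_csv(p, sep="\t")
    except (FileNotFoundError, OSError) as exc:
        raise ResourceError("packaged hydrophilicity scale unavailable") from exc
    return dict(zip(frame["residue"], frame["hydrophilicity"].astype(float)))


def load_default_table() -> PCPVectorTable:
    """Load the packaged 5-component factor-score table.

    The packaged scores are rescaled to equal per-component variance (the
    convention of published amino-acid factor-score tables), so the table's
    own explained-variance fractions are uniform by construction; component
    order still follows the magnitude order of the underlying derivation.
    Component 1 correlates positively with the bundled hydrophilicity scale
    (Pearson r ~ 0.92).
    """
    try:
        with resources.as_file(_data_path("pcp_vectors.tsv")) as p:
            frame = pd.read_csv(p, sep="\t")
    except (FileNotFoundError, OSError) as exc:
        raise ResourceError("packaged PCP vector table unavailable") from exc
    cols = [f"c{k}" for k in range(1, N_COMPONENTS + 1)]
    if list(frame.columns) != ["residue"] + cols or len(frame) != 20:
        raise ResourceError("packaged PCP vector table is corrupt")
    vectors = {
        row["residue"]: np.array([row[c] for c in cols], dtype=float)
        for _, row in frame.iterrows()
    }
    return PCPVectorTable(
        vectors=vectors,
        explained_variance=np.full(N_COMPONENTS, 1.0 / N_COMPONENTS),
        provenance="packaged",
    )


def derive_table(props: PropertyMatrix) -> PCPVectorTable:
    """Derive a fresh 5-component table by PCA of a property matrix.

    Each property column is standardized to zero mean and unit variance over
    the 20 residues, then the top five principal-component scores per residue
    are returned.  Component signs are fixed so that component 1 correlates
    positively with the bundled hydrophilicity scale and the largest-magnitude
    score of every other component is positive.

    Raises
    ------
    ValueError
        If fewer than five property columns are supplied, or a property
        column has zero variance (the offending column is named).
    """
    if len(props.property_names) < N_COMPONENTS:
        raise ValueError(
            f"need at least {N_COMPONENTS} property columns, got {len(props.property_names)}"
        )
    sds = props.values.std(axis=0, ddof=0)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance property column: {props.property_names[dead[0]]!r}"
        )
    z = (props.values - props.values.mean(axis=0)) / sds

    pca = PCA(n_components=N_COMPONENTS, svd_solver="full")
    scores = pca.fit_transform(z)
    explained = pca.explained_variance_ratio_.copy()

    order = list(props.residues)
    hydro = load_hydrophilicity()
    hvec = np.array([hydro[r] for r in order])
    if np.corrcoef(scores[:, 0], hvec)[0, 1] < 0:
        scores[:, 0] *= -1
    for k in range(1, N_COMPONENTS):
        if scores[np.argmax(np.abs(scores[:, k])), k] < 0:
            scores[:, k] *= -1

    return PCPVectorTable(
        vectors={r: scores[i] for i, r in enumerate(order)},
        explained_variance=explained,
        provenance="derived",
    )


def pcp_distance(a: str, b: str, table: PCPVectorTable | None = None) -> float:
    """Euclidean distance between two residues in the 5-space.

    Symmetric, zero iff ``a == b``; raises ``ValueError`` for nonstandard
    residue codes (including gap, X, B, Z, U, O).
    """
    if table is None:
        table = load_default_table()
    return _euclid(table.vector(a), table.vector(b))


def is_similar(a: str, b: str, table: PCPVectorTable | None = None,
               tau: float = SIMILARITY_THRESHOLD) -> bool:
    """Whether two distinct residues are physicochemically similar (distance <= tau)."""
    return pcp_distance(a, b, table) <= tau
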