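"""Time-sliced word embeddings and PCA projection.

Diachronic chaining models operate in a semantic space that changes over
time: each time bin (e.g. a decade) carries its own embedding table so that
a word's representation at time ``t`` reflects only usage up to ``t``.
Tables are read from the plain-text word2vec dialect used by HistWords-style
releases: a ``"V D"`` header line followed by ``V`` lines of
``"word x1 ... xD"``.

Clustering in the raw high-dimensional space degenerates, so category
clustering runs in a PCA-reduced subspace (30 dimensions by default) while
centroids and similarities are computed in the full space.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "EmbeddingSlice",
    "TimeSlicedEmbeddings",
    "Projection",
    "load_embeddings",
    "save_embeddings",
    "fit_projection",
    "project",
]


class EmbeddingFormatError(ValueError):
    """Raised when an embedding text file violates the word2vec dialect."""


@dataclass
class EmbeddingSlice:
    """One time bin's embedding table: a vocabulary and a row-vector matrix."""

    words: list[str]
    vectors: np.ndarray  # (V, dim) float64
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise EmbeddingFormatError("vector matrix must be 2-D")
        if len(self.words) != self.vectors.shape[0]:
            raise EmbeddingFormatError(
                f"{len(self.words)} words but {self.vectors.shape[0]} vector rows"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise EmbeddingFormatError("non-finite vector entries")
        self._index = {}
        for i, w in enumerate(self.words):
            if w in self._index:
                raise EmbeddingFormatError(f"duplicate word {w!r}")
            self._index[w] = i

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    def get_matrix(self, words: Iterable[str]) -> np.ndarray:
        """Stack the vectors for ``words`` (KeyError on a missing word)."""
        return self.vectors[[self._index[w] for w in words]]

    def subset(self, words: Iterable[str]) -> "EmbeddingSlice":
        kept = [w for w in words if w in self._index]
        return EmbeddingSlice(kept, self.get_matrix(kept))


@dataclass
class TimeSlicedEmbeddings:
    """Map from integer time-bin label (bin start year) to an embedding slice.

    Bins are half-open ``[t, t + delta)``; the label is the bin start.
    """

    slices: dict[int, EmbeddingSlice] = field(default_factory=dict)

    def __getitem__(self, time_bin: int) -> EmbeddingSlice:
        return self.slices[time_bin]

    def __contains__(self, time_bin: int) -> bool:
        return time_bin in self.slices

    @property
    def bins(self) -> list[int]:
        return sorted(self.slices)

    def add(self, time_bin: int, slice_: EmbeddingSlice) -> None:
        self.slices[int(time_bin)] = slice_

    @classmethod
    def from_dir(cls, directory: str | Path, suffix: str = ".txt") -> "TimeSlicedEmbeddings":
        """Load every ``<bin><suffix>`` file in ``directory`` (bin = int stem)."""
        out = cls()
        for path in sorted(Path(directory).glob(f"*{suffix}")):
            out.add(int(path.stem), load_embeddings(path))
        if not out.slices:
            raise FileNotFoundError(f"no embedding files under {directory}")
        return out


def load_embeddings(path: str | Path | io.TextIOBase) -> EmbeddingSlice:
    """Read one slice from the word2vec plain-text dialect.

    The file starts with a ``"V D"`` header and then holds ``V`` rows of
    ``word`` followed by ``D`` numeric coordinates, whitespace-separated.
    Duplicate words, wrong row arity and non-numeric coordinates raise
    :class:`EmbeddingFormatError`.
    """
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8") as fh:
            return _parse_w2v(fh)
    return _parse_w2v(path)


def _parse_w2v(fh: io.TextIOBase) -> EmbeddingSlice:
    header = fh.readline().split()
    if len(header) != 2:
        raise EmbeddingFormatError("header must be 'V D'")
    try:
        n_words, dim = int(header[0]), int(header[1])
    except ValueError as exc:
        raise EmbeddingFormatError(f"non-integer header: {header}") from exc
    words: list[str] = []
    rows = np.empty((n_words, dim), dtype=np.float64)
    for i in range(n_words):
        parts = fh.readline().split()
        if len(parts) != dim + 1:
            raise EmbeddingFormatError(
                f"row {i}: expected {dim + 1} fields, got {len(parts)}"
            )
        words.append(parts[0])
        try:
            rows[i] = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise EmbeddingFormatError(f"row {i}: non-numeric coordinate") from exc
    if fh.readline().strip():
        raise EmbeddingFormatError("trailing content after declared rows")
    return EmbeddingSlice(words, rows)


def save_embeddings(slice_: EmbeddingSlice, path: str | Path, fmt: str = "%.17g") -> None:
    """Write a slice back to the word2vec text dialect (lossless round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(slice_)} {slice_.dim}\n")
        for word, vec in zip(slice_.words, slice_.vectors):
            coords = " ".join(fmt % x for x in vec)
            fh.write(f"{word} {coords}\n")


@dataclass
class Projection:
    """A fitted centered principal-component projection.

    ``components`` is the (dim, k) loading matrix; projecting the fitted mean
    yields the zero vector. Explained-variance fractions are non-increasing.
    """

    mean: np.ndarray
    components: np.ndarray  # (dim, k)
    explained_variance_ratio: np.ndarray

    @property
    def dim(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]

    @property
    def cumulative_explained_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        return project(self, vectors)


def fit_projection(matrix: np.ndarray, k: int = 30) -> Projection:
    """Fit a k-component PCA (centering, no scaling) on the slice vocabulary.

    ``k`` must satisfy 1 <= k <= min(n_rows, dim). The default of 30 matches
    the reduced clustering space used throughout the historical analyses.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n, d = matrix.shape
    if not (1 <= k <= d):
        raise ValueError(f"k={k} must lie in [1, dim={d}]")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(matrix)
    return Projection(
        mean=pca.mean_.copy(),
        components=pca.components_.T.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project(projection: Projection, vectors: np.ndarray) -> np.ndarray:
    """Apply a fitted projection: center by the mean, multiply by loadings."""
    vectors = np.asarray(vectors, dtype=np.float64)
    squeeze = vectors.ndim == 1
    if squeeze:
        vectors = vectors[None, :]
    if vectors.shape[1] != projection.dim:
        raise ValueError(
            f"vectors have dim {vectors.shape[1]}, projection expects {projection.dim}"
        )
    reduced = (vectors - projection.mean) @ projection.components
    return reduced[0] if squeeze else reduced
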