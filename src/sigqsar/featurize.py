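"""Sparse featurization against a signature dictionary.

The dictionary fixes the feature space: a lexicographically ordered list of
distinct signature texts, with 1-based feature indices given by position.
A molecule becomes a sparse count vector over that space; query-time
signatures absent from the dictionary are ignored (no out-of-vocabulary
feature is ever added), so a trained model can score any molecule.

On disk the dictionary is a plain-text *signature list* (one text per
line, line number = feature index) and datasets are sparse matrices in
LIBSVM text format (``<label> <idx>:<value> ...`` with ascending 1-based
indices).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .chemio import MolecularGraph
from .signatures import molecule_signatures

logger = logging.getLogger("sigqsar")


@dataclass(frozen=True)
class SignatureDictionary:
    """Bijection between signature texts and 1-based feature indices."""

    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("signature dictionary entries must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def index(self) -> dict[str, int]:
        return {text: i + 1 for i, text in enumerate(self.entries)}

    def text_of(self, index: int) -> str:
        if not (1 <= index <= len(self.entries)):
            raise IndexError(f"feature index {index} out of range 1..{len(self.entries)}")
        return self.entries[index - 1]


@dataclass(frozen=True)
class SparseVector:
    """Sparse count vector: 1-based feature index -> positive count."""

    components: dict[int, float]

    def __post_init__(self) -> None:
        if any(v == 0 for v in self.components.values()):
            raise ValueError("zero-valued components must not be stored")

    def l1(self) -> float:
        return float(sum(abs(v) for v in self.components.values()))


def build_dictionary(multisets: Sequence[Counter]) -> SignatureDictionary:
    """Union the distinct signature texts of the training molecules.

    The entries are sorted lexicographically, so the dictionary depends
    only on the set of molecules, not on their order.
    """
    if not multisets:
        raise ValueError("at least one molecule's signature multiset is required")
    texts: set[str] = set()
    for ms in multisets:
        texts.update(ms)
    return SignatureDictionary(tuple(sorted(texts)))


def vectorize_multiset(multiset: Counter, dictionary: SignatureDictionary) -> SparseVector:
    """Project a signature multiset onto the dictionary's feature space."""
    index = dictionary.index
    components: dict[int, float] = {}
    ignored = 0
    for text, count in multiset.items():
        i = index.get(text)
        if i is None:
            ignored += 1
        elif count:
            components[i] = float(count)
    if ignored:
        logger.debug("vectorize: %d signature texts not in dictionary", ignored)
    return SparseVector(components)


def vectorize(
    graph: MolecularGraph,
    dictionary: SignatureDictionary,
    heights: Iterable[int] = (1, 2, 3),
    *,
    binary: bool = False,
) -> SparseVector:
    """Sparse count vector of one molecule against the dictionary.

    With ``binary`` the counts are clipped to presence/absence.
    """
    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    vec = vectorize_multiset(molecule_signatures(graph, heights), dictionary)
    if binary:
        vec = SparseVector({i: 1.0 for i in vec.components})
    return vec


def vectors_to_csr(vectors: Sequence[SparseVector], n_features: int) -> sp.csr_matrix:
    """Stack sparse vectors into a CSR matrix (columns 0-based internally)."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for vec in vectors:
        for i in sorted(vec.components):
            indices.append(i - 1)
            data.append(vec.components[i])
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(vectors), n_features),
    )


def featurize_molecules(
    graphs: Sequence[MolecularGraph],
    dictionary: SignatureDictionary,
    heights: Iterable[int] = (1, 2, 3),
    *,
    binary: bool = False,
) -> sp.csr_matrix:
    """Featurize a list of molecules into one sparse count matrix."""
    vecs = [vectorize(g, dictionary, heights, binary=binary) for g in graphs]
    return vectors_to_csr(vecs, len(dictionary))


# -- LIBSVM sparse text format --------------------------------------------


def _format_value(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_sparse_matrix(labels, matrix: sp.spmatrix, path) -> None:
    """Write labelled sparse rows in LIBSVM text format.

    One record per line: ``<label> <idx>:<value> ...`` with ascending
    1-based indices; a record with no components is a bare label line.
    """
    matrix = sp.csr_matrix(matrix)
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != matrix.shape[0]:
        raise ValueError("labels and matrix row counts differ")
    with open(path, "w") as fh:
        for r in range(matrix.shape[0]):
            lo, hi = matrix.indptr[r], matrix.indptr[r + 1]
            cols = matrix.indices[lo:hi]
            vals = matrix.data[lo:hi]
            order = np.argsort(cols, kind="stable")
            parts = [repr(float(labels[r]))]
            parts += [f"{cols[k] + 1}:{_format_value(vals[k])}" for k in order]
            fh.write(" ".join(parts) + "\n")


def read_sparse_matrix(path, n_features: int | None = None):
    """Read a LIBSVM text file back into ``(labels, csr_matrix)``.

    Raises
    ------
    ValueError
        On a malformed line, with its 1-based line number.
    """
    labels: list[float] = []
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split()
            try:
                labels.append(float(tokens[0]))
                prev = 0
                for token in tokens[1:]:
                    idx_text, val_text = token.split(":")
                    idx = int(idx_text)
                    if idx <= prev:
                        raise ValueError("indices not ascending")
                    prev = idx
                    indices.append(idx - 1)
                    data.append(float(val_text))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed LIBSVM line {lineno}: {exc}") from exc
            indptr.append(len(indices))
    width = n_features if n_features is not None else (max(indices) + 1 if indices else 0)
    matrix = sp.csr_matrix(
        (np.asarray(data), np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
        shape=(len(labels), width),
    )
    return np.asarray(labels), matrix


# -- signature-list file ----------------------------------------------------


def write_signature_list(dictionary: SignatureDictionary, path) -> int:
    """Write the signature list (one text per line); returns file size in bytes."""
    with open(path, "w") as fh:
        for text in dictionary.entries:
            fh.write(text + "\n")
    import os

    size = os.path.getsize(path)
    logger.info("wrote signature list %s (%d entries, %d bytes)", path, len(dictionary), size)
    return size


def read_signature_list(path) -> SignatureDictionary:
    """Read a signature list; duplicate lines violate the bijection and fail."""
    with open(path) as fh:
        entries = [line.rstrip("\n") for line in fh]
    while entries and entries[-1] == "":
        entries.pop()
    seen: set[str] = set()
    for lineno, text in enumerate(entries, start=1):
        if text in seen:
            raise ValueError(f"{path}: duplicate signature on line {lineno}")
        seen.add(text)
    return SignatureDictionary(tuple(entries))
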