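"""Sequence embedders behind a single shape contract.

Every embedder maps a length-L nucleotide string to an ``(L+2) x D`` real
matrix.  The two extra rows are sentinel rows emulating the boundary tokens
a nucleic-acid foundation model prepends/appends to a sequence (a 200-nt
feature sequence embeds to a 202 x 2560 matrix through such a model).

Three embedders are provided:

``OneHotEmbedder``
    the classic low-dimensional baseline: A,C,G,T -> unit basis vectors,
    N -> zero row, zero sentinel rows; D = 4.
``MockEmbedder``
    a deterministic high-dimensional stand-in honouring the foundation-model
    shape contract (D = 2560 by default) for offline testing: each row is a
    pure hash of (position, token, seed).
``ExternalEmbedder``
    an adapter around a user-supplied foundation-model handle; it only
    validates the returned matrix against the contract.

All three are sklearn-style transformers: ``transform`` takes a list of
equal-length sequences and returns an ``(n, L+2, D)`` array.
"""

from __future__ import annotations

import hashlib
import importlib

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .genome_io import VALID_ALPHABET

MOCK_DIM = 2560  # embedding width of the reference foundation model
EXTERNAL_MAX_LEN = 1280  # the foundation model's maximum sequence length

_BASE_ORDER = "ACGT"
_BOS, _EOS = "<bos>", "<eos>"


class EmbedderNotAvailableError(RuntimeError):
    """The external foundation-model adapter could not be loaded."""


class EmbeddingContractError(ValueError):
    """An embedder returned a matrix violating the (L+2) x D contract."""


def validate_embedding(matrix: np.ndarray, seq_len: int, embedder_id: str = "") -> np.ndarray:
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise EmbeddingContractError(f"{embedder_id}: expected a 2-D matrix, got {matrix.ndim}-D")
    if matrix.shape[0] != seq_len + 2:
        raise EmbeddingContractError(
            f"{embedder_id}: expected {seq_len + 2} rows for a {seq_len}-nt input, "
            f"got {matrix.shape[0]}"
        )
    if matrix.shape[1] < 1:
        raise EmbeddingContractError(f"{embedder_id}: embedding dimension must be positive")
    if not np.isfinite(matrix).all():
        raise EmbeddingContractError(f"{embedder_id}: non-finite values in embedding")
    return matrix


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")


class _EmbedderBase(BaseEstimator, TransformerMixin):
    """Shared stacking logic; subclasses implement embed() for one sequence."""

    def fit(self, X, y=None):  # stateless
        return self

    def embed(self, seq: str) -> np.ndarray:
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        seqs = [x.sequence if hasattr(x, "sequence") else x for x in X]
        if not seqs:
            dim = getattr(self, "dim", 1)
            return np.empty((0, 0, dim))
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences must share one length, got lengths {sorted(lengths)}")
        return np.stack([self.embed(s) for s in seqs])


class OneHotEmbedder(_EmbedderBase):
    """One-hot nucleotide encoding with zero sentinel rows (D = 4)."""

    embedder_id = "one_hot"
    dim = 4

    def embed(self, seq: str) -> np.ndarray:
        _check_alphabet(seq)
        mat = np.zeros((len(seq) + 2, 4))
        for i, base in enumerate(seq):
            j = _BASE_ORDER.find(base)
            if j >= 0:  # N stays a zero row
                mat[i + 1, j] = 1.0
        return validate_embedding(mat, len(seq), self.embedder_id)


class MockEmbedder(_EmbedderBase):
    """Deterministic pseudo-random embedding honouring the contract.

    Each row depends only on (position token, nucleotide, seed): the triple
    is hashed into a stream seed and expanded to ``dim`` uniform values in
    [-1, 1].  Sequences differing in one base therefore differ in exactly
    the corresponding row, and the same (seq, seed) always yields
    bit-identical matrices.
    """

    def __init__(self, dim: int = MOCK_DIM, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._row_cache: dict[tuple[int, str], np.ndarray] = {}

    @property
    def embedder_id(self) -> str:
        return f"mock_d{self.dim}_s{self.seed}"

    def _row(self, position: int, token: str) -> np.ndarray:
        key = (position, token)
        if key not in self._row_cache:
            digest = hashlib.blake2b(
                f"{position}|{token}|{self.seed}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            self._row_cache[key] = rng.uniform(-1.0, 1.0, self.dim)
        return self._row_cache[key]

    def embed(self, seq: str) -> np.ndarray:
        _check_alphabet(seq)
        tokens = [_BOS, *seq, _EOS]
        mat = np.stack([self._row(i, t) for i, t in enumerate(tokens)])
        return validate_embedding(mat, len(seq), self.embedder_id)


class ExternalEmbedder(_EmbedderBase):
    """Adapter for a user-supplied foundation-model handle.

    ``handle`` is any callable mapping a nucleotide string to an
    ``(L+2) x D`` array; the adapter validates the shape contract before
    anything flows downstream.  Inputs longer than ``max_len`` are rejected
    (the reference model caps sequences at 1280 tokens).
    """

    embedder_id = "external"

    def __init__(self, handle, max_len: int = EXTERNAL_MAX_LEN):
        self.handle = handle
        self.max_len = max_len

    def embed(self, seq: str) -> np.ndarray:
        _check_alphabet(seq)
        if len(seq) > self.max_len:
            raise ValueError(f"sequence length {len(seq)} exceeds adapter maximum {self.max_len}")
        return validate_embedding(self.handle(seq), len(seq), self.embedder_id)


def load_external_embedder(spec: str, max_len: int = EXTERNAL_MAX_LEN) -> ExternalEmbedder:
    """Import an adapter given ``"module:attribute"``.

    Raises :class:`EmbedderNotAvailableError` when the module is missing, so
    the rest of the toolkit works without the optional dependency.
    """
    module_name, _, attr = spec.partition(":")
    if not module_name or not attr:
        raise ValueError(f"adapter spec must look like 'module:attribute', got {spec!r}")
    try:
        module = importlib.import_module(module_name)
    except ImportError as exc:
        raise EmbedderNotAvailableError(
            f"external embedder adapter {spec!r} not installed: {exc}"
        ) from exc
    return ExternalEmbedder(getattr(module, attr), max_len=max_len)


def one_hot_embed(seq: str) -> np.ndarray:
    """Functional shortcut for :class:`OneHotEmbedder`."""
    return OneHotEmbedder().embed(seq)


def mock_embed(seq: str, dim: int = MOCK_DIM, seed: int = 0) -> np.ndarray:
    """Functional shortcut for :class:`MockEmbedder`."""
    return MockEmbedder(dim=dim, seed=seed).embed(seq)


def external_embed(seq: str, handle) -> np.ndarray:
    """Functional shortcut for :class:`ExternalEmbedder`."""
    return ExternalEmbedder(handle).embed(seq)


def make_embedder(kind: str, dim: int | None = None, seed: int = 0, handle_spec: str | None = None):
    """Factory used by the CLI: kind in {one_hot, mock, external}."""
    if kind == "one_hot":
        return OneHotEmbedder()
    if kind == "mock":
        return MockEmbedder(dim=dim or MOCK_DIM, seed=seed)
    if kind == "external":
        if not handle_spec:
            raise ValueError("external embedder requires an adapter spec 'module:attribute'")
        return load_external_embedder(handle_spec)
    raise ValueError(f"unknown embedder kind {kind!r}")
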