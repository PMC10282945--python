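"""Mutual information, the information bottleneck, and its upper bound.

All quantities are plug-in estimates over finite symbol alphabets, in bits
(log base 2).  High-dimensional binary patterns are first quantized into
symbols; the default quantizer is an exact unique-pattern dictionary, with
a seeded random binary projection as the fallback for very large alphabets.

Along the Markov chain X → Y → Z (input → SDR → reconstruction) the
standard information-bottleneck objective is

    L_IB = I(X;Y) - beta * I(Y;Z),

trading compression of the input against preservation of information
relevant to the reconstruction.  The modified objective replaces the
relevance term with the end-to-end information:

    L_MIB = I(X;Y) - beta * I(X;Z).

By the data-processing inequality I(X;Z) <= I(Y;Z), so for the same
beta >= 0 the modified objective upper-bounds the standard one:
L_MIB >= L_IB.  Minimizing the upper bound therefore also drives the
standard objective down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import PatternSet
from .spatial_pooler import SDR
from .reconstruction import Reconstruction

logger = logging.getLogger(__name__)

__all__ = [
    "PatternQuantizer",
    "JointDistribution",
    "IBResult",
    "quantize",
    "default_quantizer",
    "estimate_joint",
    "mutual_information",
    "ib_lagrangian",
    "modified_ib",
    "evaluate_chain",
    "markov_chain_joints",
]


def _to_matrix(patterns) -> np.ndarray:
    """Coerce PatternSet / SDR list / Reconstruction list / array to 2-D uint8."""
    if isinstance(patterns, PatternSet):
        return patterns.patterns
    if isinstance(patterns, (list, tuple)) and patterns:
        first = patterns[0]
        if isinstance(first, SDR):
            return np.vstack([s.to_dense() for s in patterns])
        if isinstance(first, Reconstruction):
            return np.vstack([r.binary for r in patterns])
    arr = np.asarray(patterns, dtype=np.uint8)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D binary array or a list of SDR/Reconstruction")
    return arr


class PatternQuantizer:
    """Maps binary patterns to integer symbols over a finite alphabet.

    Methods
    -------
    ``dictionary``
        Exact: each distinct pattern gets the next integer in first-seen
        order.  The codebook persists across calls, so identical patterns
        always share a symbol.
    ``projection``
        Seeded random binary projection to ``b`` parity bits (alphabet size
        <= 2**b); used when the distinct-pattern count would be unwieldy.
    ``cluster``
        Centroid clustering with ``m`` centroids (k-means on the distinct
        patterns); falls back to the dictionary when m exceeds the number
        of distinct patterns.
    """

    def __init__(self, method: str = "dictionary", b: int = 10, m: int | None = None,
                 seed: int = 0) -> None:
        if method not in ("dictionary", "projection", "cluster"):
            raise ValueError(f"unknown quantizer method {method!r}")
        if method == "cluster" and (m is None or m < 1):
            raise ValueError("cluster method requires m >= 1 centroids")
        self.method = method
        self.b = int(b)
        self.m = m
        self.seed = seed
        self._codebook: dict[bytes, int] = {}
        self._masks: np.ndarray | None = None
        self._kmeans = None
        self._fallback = False

    @property
    def alphabet_size(self) -> int:
        if self.method == "projection":
            return 2 ** self.b
        if self.method == "cluster" and not self._fallback:
            return int(self.m)
        return len(self._codebook)

    def _dictionary(self, mat: np.ndarray) -> np.ndarray:
        out = np.empty(len(mat), dtype=np.int64)
        book = self._codebook
        for i, row in enumerate(mat):
            key = row.tobytes()
            code = book.get(key)
            if code is None:
                code = len(book)
                book[key] = code
            out[i] = code
        return out

    def _projection(self, mat: np.ndarray) -> np.ndarray:
        if self._masks is None:
            rng = np.random.default_rng(self.seed)
            self._masks = rng.integers(0, 2, size=(self.b, mat.shape[1]), dtype=np.uint8)
        if self._masks.shape[1] != mat.shape[1]:
            raise ValueError("pattern width differs from the quantizer's first call")
        parity = (mat.astype(np.int64) @ self._masks.T) & 1
        weights = 1 << np.arange(self.b, dtype=np.int64)
        return parity @ weights

    def _cluster(self, mat: np.ndarray) -> np.ndarray:
        uniq = np.unique(mat, axis=0)
        if self._kmeans is None and not self._fallback:
            if self.m > len(uniq):
                logger.warning(
                    "cluster quantizer: m=%d exceeds %d distinct patterns; "
                    "falling back to the dictionary", self.m, len(uniq),
                )
                self._fallback = True
            else:
                from sklearn.cluster import KMeans

                self._kmeans = KMeans(
                    n_clusters=self.m, n_init=4, random_state=self.seed
                ).fit(uniq.astype(np.float64))
        if self._fallback:
            return self._dictionary(mat)
        return self._kmeans.predict(mat.astype(np.float64)).astype(np.int64)

    def __call__(self, patterns) -> np.ndarray:
        mat = _to_matrix(patterns)
        if self.method == "dictionary":
            return self._dictionary(mat)
        if self.method == "projection":
            return self._projection(mat)
        return self._cluster(mat)


def quantize(patterns, quantizer: PatternQuantizer) -> np.ndarray:
    """Deterministic integer symbol per pattern (see :class:`PatternQuantizer`)."""
    return quantizer(patterns)


#: Above this distinct-pattern count the default quantizer switches from the
#: exact dictionary to a 10-bit random projection.
DICTIONARY_LIMIT = 4096


def default_quantizer(patterns, seed: int = 0) -> PatternQuantizer:
    """Dictionary quantizer, or a 10-bit random projection for huge alphabets."""
    mat = _to_matrix(patterns)
    n_distinct = len({row.tobytes() for row in mat})
    if n_distinct <= DICTIONARY_LIMIT:
        return PatternQuantizer(method="dictionary")
    return PatternQuantizer(method="projection", b=10, seed=seed)


@dataclass
class JointDistribution:
    """A joint probability table over two finite symbol alphabets."""

    table: np.ndarray
    n_samples: int | None = None
    exact: bool = False

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.ndim != 2:
            raise ValueError("joint table must be 2-D")
        if (self.table < 0).any():
            raise ValueError("joint table entries must be nonnegative")
        if abs(self.table.sum() - 1.0) > 1e-12:
            raise ValueError(f"joint table mass {self.table.sum()} != 1")

    @property
    def marginal_a(self) -> np.ndarray:
        return self.table.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.table.sum(axis=0)

    def transpose(self) -> "JointDistribution":
        return JointDistribution(self.table.T, n_samples=self.n_samples, exact=self.exact)

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "JointDistribution":
        counts = np.asarray(counts, dtype=np.float64)
        total = counts.sum()
        if total <= 0:
            raise ValueError("counts sum to zero")
        return cls(counts / total, n_samples=int(round(total)), exact=False)

    @classmethod
    def from_table(cls, table: np.ndarray) -> "JointDistribution":
        return cls(np.asarray(table, dtype=np.float64), exact=True)


def estimate_joint(symbols_a: np.ndarray, symbols_b: np.ndarray) -> JointDistribution:
    """Plug-in joint from aligned symbol sequences (normalized co-occurrence counts)."""
    a = np.asarray(symbols_a)
    b = np.asarray(symbols_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"symbol sequences must be 1-D and aligned, got {a.shape} vs {b.shape}")
    if len(a) == 0:
        raise ValueError("cannot estimate a joint from zero samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.float64)
    np.add.at(counts, (ai, bi), 1.0)
    return JointDistribution.from_counts(counts)


def mutual_information(joint: JointDistribution) -> float:
    """Plug-in mutual information in bits, with the 0·log0 = 0 convention."""
    p = joint.table
    outer = np.outer(joint.marginal_a, joint.marginal_b)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def _check_beta(beta: float) -> None:
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")


def ib_lagrangian(I_xy: float, I_yz: float, beta: float) -> float:
    """Standard information-bottleneck objective I(X;Y) - beta * I(Y;Z)."""
    _check_beta(beta)
    return I_xy - beta * I_yz


def modified_ib(I_xy: float, I_xz: float, beta: float) -> float:
    """Modified objective I(X;Y) - beta * I(X;Z); upper-bounds the standard one."""
    _check_beta(beta)
    return I_xy - beta * I_xz


@dataclass(frozen=True)
class IBResult:
    """The three pairwise informations and both objectives at one beta (bits)."""

    I_xy: float
    I_yz: float
    I_xz: float
    beta: float
    L_IB: float
    L_MIB: float


def evaluate_chain(
    x_symbols: np.ndarray,
    y_symbols: np.ndarray,
    z_symbols: np.ndarray,
    beta: float,
) -> IBResult:
    """Estimate I(X;Y), I(Y;Z), I(X;Z) and both objectives from aligned triples."""
    _check_beta(beta)
    I_xy = mutual_information(estimate_joint(x_symbols, y_symbols))
    I_yz = mutual_information(estimate_joint(y_symbols, z_symbols))
    I_xz = mutual_information(estimate_joint(x_symbols, z_symbols))
    return IBResult(
        I_xy=I_xy,
        I_yz=I_yz,
        I_xz=I_xz,
        beta=beta,
        L_IB=ib_lagrangian(I_xy, I_yz, beta),
        L_MIB=modified_ib(I_xy, I_xz, beta),
    )


def markov_chain_joints(
    p_x: np.ndarray, p_y_given_x: np.ndarray, p_z_given_y: np.ndarray
) -> tuple[JointDistribution, JointDistribution, JointDistribution]:
    """Exact pairwise joints (XY, YZ, XZ) of a finite Markov chain X → Y → Z.

    ``p_y_given_x[x, y]`` and ``p_z_given_y[y, z]`` are row-stochastic.
    The returned tables are exact, so the data-processing inequality
    I(X;Z) <= I(Y;Z) holds to machine precision on them.
    """
    p_x = np.asarray(p_x, dtype=np.float64)
    p_y_given_x = np.asarray(p_y_given_x, dtype=np.float64)
    p_z_given_y = np.asarray(p_z_given_y, dtype=np.float64)
    if abs(p_x.sum() - 1.0) > 1e-12:
        raise ValueError("p_x must sum to 1")
    for name, mat in (("p_y_given_x", p_y_given_x), ("p_z_given_y", p_z_given_y)):
        if np.abs(mat.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError(f"{name} rows must sum to 1")
    j_xy = p_x[:, None] * p_y_given_x
    p_y = j_xy.sum(axis=0)
    j_yz = p_y[:, None] * p_z_given_y
    j_xz = j_xy @ p_z_given_y
    return (
        JointDistribution.from_table(j_xy),
        JointDistribution.from_table(j_yz),
        JointDistribution.from_table(j_xz),
    )
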