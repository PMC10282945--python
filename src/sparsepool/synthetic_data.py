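"""Synthetic binary pattern generation.

Every input the pipeline consumes is a fixed-width binary vector: a
prototype-based pattern family standing in for binarized image data, a
bit-flip-corrupted variant of it, or a scalar time series passed through a
contiguous-bucket scalar encoder.  An optional IDX reader lets externally
downloaded image files (MNIST-style) enter the same :class:`PatternSet`
container.

All generators take an explicit integer ``seed``; there is no module-level
random state, so every dataset is bit-exact reproducible from its
parameters.
"""

from __future__ import annotations

import gzip
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "FormatError",
    "PatternSet",
    "generate_prototypes",
    "sample_family",
    "flip_noise",
    "swap_noise",
    "encode_scalar_sequence",
    "read_idx_images",
    "save_patterns",
    "load_patterns",
]


class ConfigurationError(ValueError):
    """Raised when generator parameters cannot produce a valid dataset."""


class FormatError(ValueError):
    """Raised when an on-disk file does not follow its declared format."""


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (for x >= 0)."""
    return int(np.floor(x + 0.5))


def _as_pattern_matrix(patterns: np.ndarray) -> np.ndarray:
    arr = np.asarray(patterns, dtype=np.uint8)
    if arr.ndim != 2:
        raise ValueError(f"patterns must be 2-D (n_patterns, n_bits), got shape {arr.shape}")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("patterns must contain only 0/1 entries")
    return arr


@dataclass
class PatternSet:
    """An ordered collection of equal-width binary patterns.

    Parameters
    ----------
    patterns
        Array of shape ``(n_patterns, n_bits)`` with 0/1 entries.
    labels
        Optional integer label per pattern, aligned 1:1.
    is_sequence
        True when pattern order carries temporal meaning (encoded scalar
        series); sequence-only operations (HMM smoothing) require it.
    """

    patterns: np.ndarray
    labels: np.ndarray | None = None
    is_sequence: bool = False

    def __post_init__(self) -> None:
        self.patterns = _as_pattern_matrix(self.patterns)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.patterns),):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"{len(self.patterns)} patterns"
                )

    @property
    def n_bits(self) -> int:
        return self.patterns.shape[1]

    def __len__(self) -> int:
        return self.patterns.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.patterns[i]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.patterns)


def generate_prototypes(
    n_classes: int, n_bits: int, density: float, seed: int
) -> PatternSet:
    """Draw one random prototype pattern per class.

    Each prototype has exactly ``round(density * n_bits)`` active bits placed
    uniformly at random without replacement.
    """
    if n_bits < 1:
        raise ConfigurationError(f"n_bits must be >= 1, got {n_bits}")
    if n_classes < 1:
        raise ConfigurationError(f"n_classes must be >= 1, got {n_classes}")
    if not 0.0 < density < 1.0:
        raise ConfigurationError(f"density must lie strictly in (0, 1), got {density}")
    n_on = _round_half_away(density * n_bits)
    if n_on == 0:
        raise ConfigurationError(
            f"density {density} with n_bits {n_bits} yields 0 active bits"
        )
    rng = np.random.default_rng(seed)
    patterns = np.zeros((n_classes, n_bits), dtype=np.uint8)
    for c in range(n_classes):
        patterns[c, rng.choice(n_bits, size=n_on, replace=False)] = 1
    return PatternSet(patterns, labels=np.arange(n_classes))


def _flip_positions(bits: np.ndarray, positions: np.ndarray) -> np.ndarray:
    out = bits.copy()
    out[positions] ^= 1
    return out


def flip_noise(pattern: np.ndarray, noise_pct: float, seed: int) -> np.ndarray:
    """Invert a fixed fraction of positions chosen uniformly without replacement.

    Exactly ``round(noise_pct / 100 * n_bits)`` distinct positions are
    flipped — active bits become inactive and vice versa — so the Hamming
    distance to the input is deterministic for every seed.
    """
    if not 0.0 <= noise_pct <= 100.0:
        raise ValueError(f"noise_pct must be in [0, 100], got {noise_pct}")
    bits = np.asarray(pattern, dtype=np.uint8)
    n_bits = bits.shape[-1]
    m = _round_half_away(noise_pct / 100.0 * n_bits)
    if m == 0:
        return bits.copy()
    rng = np.random.default_rng(seed)
    return _flip_positions(bits, rng.choice(n_bits, size=m, replace=False))


def swap_noise(pattern: np.ndarray, noise_pct: float, seed: int) -> np.ndarray:
    """Density-preserving noise: relocate a fraction of the active bits.

    Turns exactly ``round(noise_pct / 100 * n_active)`` active bits off and
    the same number of inactive bits on, both chosen uniformly without
    replacement, so the number of active bits never changes.  This is the
    convention of the classic Spatial Pooler noise-robustness experiment
    (a noise level names the fraction of the signal's on-bits displaced),
    in contrast to :func:`flip_noise`, which inverts a fraction of all
    positions and therefore changes the density of sparse patterns.
    """
    if not 0.0 <= noise_pct <= 100.0:
        raise ValueError(f"noise_pct must be in [0, 100], got {noise_pct}")
    bits = np.asarray(pattern, dtype=np.uint8)
    active = np.flatnonzero(bits)
    inactive = np.flatnonzero(bits == 0)
    m = min(_round_half_away(noise_pct / 100.0 * active.size), active.size, inactive.size)
    if m == 0:
        return bits.copy()
    rng = np.random.default_rng(seed)
    out = bits.copy()
    out[rng.choice(active, size=m, replace=False)] = 0
    out[rng.choice(inactive, size=m, replace=False)] = 1
    return out


def sample_family(
    prototypes: PatternSet, n_per_class: int, corruption_pct: float, seed: int
) -> PatternSet:
    """Expand prototypes into a labelled family via bit-flip corruption.

    Each sample is its class prototype with :func:`flip_noise` applied at
    ``corruption_pct``; labels carry the class index, grouped by class in
    prototype order.
    """
    if len(prototypes) == 0:
        raise ConfigurationError("prototypes must contain at least one pattern")
    if not 0.0 <= corruption_pct <= 100.0:
        raise ValueError(f"corruption_pct must be in [0, 100], got {corruption_pct}")
    if n_per_class < 1:
        raise ConfigurationError(f"n_per_class must be >= 1, got {n_per_class}")
    n_bits = prototypes.n_bits
    m = _round_half_away(corruption_pct / 100.0 * n_bits)
    rng = np.random.default_rng(seed)
    patterns = np.empty((len(prototypes) * n_per_class, n_bits), dtype=np.uint8)
    labels = np.repeat(np.arange(len(prototypes)), n_per_class)
    row = 0
    for proto in prototypes:
        for _ in range(n_per_class):
            if m:
                patterns[row] = _flip_positions(
                    proto, rng.choice(n_bits, size=m, replace=False)
                )
            else:
                patterns[row] = proto
            row += 1
    return PatternSet(patterns, labels=labels)


def encode_scalar_sequence(
    values: Sequence[float],
    n_bits: int,
    n_active: int,
    min_val: float,
    max_val: float,
) -> PatternSet:
    """Encode a scalar series as contiguous runs of active bits.

    The standard HTM scalar encoder: each value maps to ``n_active``
    consecutive ones whose start position scales linearly with
    ``(value - min_val) / (max_val - min_val)``.  Values outside the range
    are clipped (with a warning); nearby values share buckets, so encodings
    of close values overlap heavily.
    """
    if not min_val < max_val:
        raise ConfigurationError(f"min_val {min_val} must be < max_val {max_val}")
    if not 0 < n_active < n_bits:
        raise ConfigurationError(
            f"need 0 < n_active < n_bits, got n_active={n_active}, n_bits={n_bits}"
        )
    vals = np.asarray(values, dtype=float)
    if ((vals < min_val) | (vals > max_val)).any():
        logger.warning(
            "encode_scalar_sequence: %d value(s) outside [%g, %g] clipped",
            int(((vals < min_val) | (vals > max_val)).sum()), min_val, max_val,
        )
        vals = np.clip(vals, min_val, max_val)
    n_buckets = n_bits - n_active  # start index range is [0, n_buckets]
    frac = (vals - min_val) / (max_val - min_val)
    starts = np.floor(frac * (n_buckets + 1)).astype(int)
    starts = np.clip(starts, 0, n_buckets)
    patterns = np.zeros((len(vals), n_bits), dtype=np.uint8)
    for i, s in enumerate(starts):
        patterns[i, s : s + n_active] = 1
    return PatternSet(patterns, is_sequence=True)


_IDX_IMAGE_MAGIC = 0x00000803


def read_idx_images(path: str | Path, threshold: int = 128) -> PatternSet:
    """Read an IDX image file (optionally gzipped) and binarize it.

    A pixel maps to 1 when its intensity is >= ``threshold``.  Each image
    becomes one pattern of width ``rows * cols``.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    path = Path(path)
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    if len(raw) < 16:
        raise FormatError(f"{path}: truncated header at offset {len(raw)} (need 16 bytes)")
    magic, n_images, rows, cols = struct.unpack(">IIII", raw[:16])
    if magic != _IDX_IMAGE_MAGIC:
        raise FormatError(
            f"{path}: bad magic number 0x{magic:08x} at offset 0 "
            f"(expected 0x{_IDX_IMAGE_MAGIC:08x})"
        )
    n_expected = 16 + n_images * rows * cols
    if len(raw) < n_expected:
        raise FormatError(
            f"{path}: truncated pixel data at offset {len(raw)} (need {n_expected} bytes)"
        )
    pixels = np.frombuffer(raw, dtype=np.uint8, count=n_images * rows * cols, offset=16)
    patterns = (pixels.reshape(n_images, rows * cols) >= threshold).astype(np.uint8)
    return PatternSet(patterns)


_HEADER_PREFIX = "#patternset"


def save_patterns(pset: PatternSet, path: str | Path) -> None:
    """Write a PatternSet to the plain-text format (one 0/1 string per line)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"{_HEADER_PREFIX} n_bits={pset.n_bits} "
            f"labels={int(pset.labels is not None)} "
            f"sequence={int(pset.is_sequence)}\n"
        )
        for i, row in enumerate(pset.patterns):
            line = "".join("1" if b else "0" for b in row)
            if pset.labels is not None:
                line += f"\t{pset.labels[i]}"
            fh.write(line + "\n")


def load_patterns(path: str | Path) -> PatternSet:
    """Read a PatternSet written by :func:`save_patterns`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith(_HEADER_PREFIX):
            raise FormatError(f"{path}: missing '{_HEADER_PREFIX}' header line")
        fields = dict(tok.split("=") for tok in header.split()[1:])
        n_bits = int(fields["n_bits"])
        has_labels = bool(int(fields.get("labels", "0")))
        is_sequence = bool(int(fields.get("sequence", "0")))
        rows, labels = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts[0]) != n_bits:
                raise FormatError(
                    f"{path}:{lineno}: pattern width {len(parts[0])} != n_bits {n_bits}"
                )
            rows.append([1 if ch == "1" else 0 for ch in parts[0]])
            if has_labels:
                labels.append(int(parts[1]))
    patterns = np.asarray(rows, dtype=np.uint8).reshape(len(rows), n_bits)
    return PatternSet(
        patterns,
        labels=np.asarray(labels) if has_labels else None,
        is_sequence=is_sequence,
    )
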