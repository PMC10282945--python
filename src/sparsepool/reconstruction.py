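"""Reconstructing inputs from SDRs.

The decoder is a probabilistic mapping: during fitting it counts, for every
(column, input bit) pair, how often the bit was on while the column was
active.  Decoding an SDR averages the Laplace-smoothed per-bit conditional
frequencies of its active columns, giving a probability map over input bits
that is thresholded into a binary reconstruction.  Because decoding reads
only the SDR, the reconstruction Z is conditionally independent of the
input X given the SDR Y — the Markov chain X → Y → Z holds by construction,
which is what makes the data-processing-inequality analyses downstream
valid.

For temporally ordered data an optional HMM stage smooths the frame-by-frame
probability maps: hidden states are quantized reconstruction symbols,
transition/emission tables are estimated by counting with add-one smoothing,
and forward–backward posteriors replace each frame by a posterior-weighted
mean of state centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic_data import PatternSet
from .spatial_pooler import SDR

logger = logging.getLogger(__name__)

__all__ = [
    "DecoderModel",
    "Reconstruction",
    "fit_decoder",
    "decode",
    "decode_batch",
    "hmm_smooth",
    "reconstruction_error",
]


@dataclass
class DecoderModel:
    """Column → input-bit co-activation statistics.

    ``coactivation_counts[c, i]`` counts training pairs where column c was
    active and bit i was on; ``column_counts[c]`` counts pairs where c was
    active at all.  ``bit_prior`` is the empirical per-bit frequency, used
    as the fallback map for an empty SDR.
    """

    coactivation_counts: np.ndarray  # (n_columns, n_bits) float64 integers
    column_counts: np.ndarray        # (n_columns,)
    smoothing_alpha: float
    bit_prior: np.ndarray            # (n_bits,)

    @property
    def n_columns(self) -> int:
        return self.coactivation_counts.shape[0]

    @property
    def n_bits(self) -> int:
        return self.coactivation_counts.shape[1]

    def conditionals(self) -> np.ndarray:
        """Smoothed P(bit on | column active), shape (n_columns, n_bits)."""
        a = self.smoothing_alpha
        return (self.coactivation_counts + a) / (
            self.column_counts[:, None] + 2.0 * a
        )


@dataclass
class Reconstruction:
    """Per-bit activation probabilities and their thresholded binary form."""

    probability_map: np.ndarray
    binary: np.ndarray


def _activity_matrix(sdrs: list[SDR], n_columns: int) -> np.ndarray:
    # float32 is exact here: entries are 0/1 and count sums stay far below 2**24
    Y = np.zeros((len(sdrs), n_columns), dtype=np.float32)
    for t, sdr in enumerate(sdrs):
        Y[t, sdr.active_columns] = 1.0
    return Y


def fit_decoder(
    inputs: PatternSet, sdrs: list[SDR], smoothing_alpha: float = 1.0
) -> DecoderModel:
    """Count column/bit co-activations over aligned (input, SDR) pairs."""
    if len(inputs) != len(sdrs):
        raise ValueError(f"{len(inputs)} inputs but {len(sdrs)} SDRs")
    if smoothing_alpha <= 0:
        raise ValueError(f"smoothing_alpha must be > 0, got {smoothing_alpha}")
    if not sdrs:
        raise ValueError("cannot fit a decoder on zero pairs")
    n_columns = sdrs[0].n_columns
    Y = _activity_matrix(sdrs, n_columns)
    X = inputs.patterns.astype(np.float32)
    coact = (Y.T @ X).astype(np.float64)  # exact integer counts
    col_counts = Y.sum(axis=0, dtype=np.float64)
    return DecoderModel(
        coactivation_counts=coact,
        column_counts=col_counts,
        smoothing_alpha=smoothing_alpha,
        bit_prior=inputs.patterns.mean(axis=0),
    )


def decode(model: DecoderModel, sdr: SDR, binarize_threshold: float = 0.5) -> Reconstruction:
    """Average the active columns' smoothed conditionals; threshold with >=."""
    if len(sdr) == 0:
        logger.warning("decode: empty SDR, returning the bit prior")
        pmap = model.bit_prior.copy()
    else:
        pmap = model.conditionals()[sdr.active_columns].mean(axis=0)
    binary = (pmap >= binarize_threshold).astype(np.uint8)
    return Reconstruction(probability_map=pmap, binary=binary)


def decode_batch(
    model: DecoderModel, sdrs: list[SDR], binarize_threshold: float = 0.5
) -> list[Reconstruction]:
    """Vectorized :func:`decode` over many SDRs (single matmul)."""
    if not sdrs:
        return []
    cond = model.conditionals()
    Y = _activity_matrix(sdrs, model.n_columns).astype(np.float64)
    counts = Y.sum(axis=1)
    empty = counts == 0
    counts[empty] = 1.0
    maps = (Y @ cond) / counts[:, None]
    if empty.any():
        logger.warning("decode_batch: %d empty SDR(s), using the bit prior", empty.sum())
        maps[empty] = model.bit_prior
    return [
        Reconstruction(probability_map=m, binary=(m >= binarize_threshold).astype(np.uint8))
        for m in maps
    ]


def forward_backward(
    start: np.ndarray, trans: np.ndarray, emis: np.ndarray, obs: np.ndarray
) -> np.ndarray:
    """Scaled forward–backward smoothing posteriors for a discrete HMM.

    Returns gamma[t, s] = P(state_t = s | obs_1..T).
    """
    T, S = len(obs), len(start)
    alpha = np.zeros((T, S))
    beta = np.zeros((T, S))
    scale = np.zeros(T)
    alpha[0] = start * emis[:, obs[0]]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ trans) * emis[:, obs[t]]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = trans @ (emis[:, obs[t + 1]] * beta[t + 1]) / scale[t + 1]
    gamma = alpha * beta
    return gamma / gamma.sum(axis=1, keepdims=True)


def hmm_smooth(
    frames: np.ndarray,
    n_states: int,
    quantizer=None,
    seed: int = 0,
    is_sequence: bool = True,
    binarize_threshold: float = 0.5,
) -> list[Reconstruction]:
    """Temporal smoothing of reconstruction probability maps with an HMM.

    Hidden states are quantized reconstruction symbols (centroid clustering
    by default); transition and emission tables come from counting over the
    training sequence with add-one smoothing; each frame is replaced by the
    forward–backward posterior-weighted mean of the state centroid maps.

    Only valid for temporally ordered data.
    """
    if not is_sequence:
        raise ValueError("hmm_smooth requires temporally ordered (sequence) data")
    if n_states < 2:
        raise ValueError(f"n_states must be >= 2, got {n_states}")
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 2 or len(frames) < 2:
        raise ValueError("frames must be a (T >= 2, n_bits) array of probability maps")

    from .info_measures import PatternQuantizer, quantize

    binary = (frames >= binarize_threshold).astype(np.uint8)
    if quantizer is None:
        quantizer = PatternQuantizer(method="cluster", m=n_states, seed=seed)
    symbols = quantize(binary, quantizer)
    # relabel to a dense 0..S-1 alphabet
    uniq, symbols = np.unique(symbols, return_inverse=True)
    S = len(uniq)

    centroids = np.vstack([frames[symbols == s].mean(axis=0) for s in range(S)])
    start = np.bincount(symbols[:1], minlength=S) + 1.0
    start /= start.sum()
    trans = np.ones((S, S))
    np.add.at(trans, (symbols[:-1], symbols[1:]), 1.0)
    trans /= trans.sum(axis=1, keepdims=True)
    emis = np.ones((S, S))
    np.add.at(emis, (symbols, symbols), 1.0)
    emis /= emis.sum(axis=1, keepdims=True)

    if S == 1:
        gamma = np.ones((len(frames), 1))
    else:
        try:
            from hmmlearn.hmm import CategoricalHMM

            model = CategoricalHMM(n_components=S, init_params="", params="")
            model.startprob_ = start
            model.transmat_ = trans
            model.emissionprob_ = emis
            model.n_features = S
            gamma = model.predict_proba(symbols.reshape(-1, 1))
        except ImportError:  # pragma: no cover
            gamma = forward_backward(start, trans, emis, symbols)
    maps = gamma @ centroids
    return [
        Reconstruction(probability_map=m, binary=(m >= binarize_threshold).astype(np.uint8))
        for m in maps
    ]


def reconstruction_error(original: np.ndarray, recon: Reconstruction) -> float:
    """Normalized Hamming distance between the input and the binary reconstruction."""
    orig = np.asarray(original, dtype=np.uint8)
    if orig.shape != recon.binary.shape:
        raise ValueError(
            f"width mismatch: original {orig.shape} vs reconstruction {recon.binary.shape}"
        )
    return float(np.mean(orig != recon.binary))
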