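"""The HTM Spatial Pooler.

Maps binary inputs to sparse distributed representations (SDRs) with a
fixed number of active columns.  Each column holds a permanence value per
potential synapse; a synapse is connected when its permanence reaches a
threshold.  An input's overlap with a column is the number of connected
synapses on active input bits; global inhibition keeps exactly the top-k
columns active, and Hebbian learning nudges permanences of the winning
columns toward the input.  Exponential boosting (driven by activation duty
cycles) can push chronically silent columns back into competition.

The canonical algorithm is implemented: global inhibition without topology,
lowest-index tie-breaking (so runs are fully deterministic given the seed),
and no stimulus threshold — a zero-overlap column can only become active as
a fill when fewer than k columns overlap the input at all.

``fit`` and batch SDR computation have a numba fast path that is
bit-identical to the pure-numpy single-step operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import ConfigurationError, PatternSet, _round_half_away

logger = logging.getLogger(__name__)

__all__ = [
    "SPConfig",
    "SPState",
    "SDR",
    "init_pooler",
    "compute_overlap",
    "inhibit",
    "learn_step",
    "fit",
    "compute_sdr",
    "compute_sdrs",
    "sdr_change",
]


@dataclass(frozen=True)
class SPConfig:
    """Spatial Pooler parameters.

    ``column_activation_pct`` is the sparsity knob: the percentage of
    columns active after inhibition (2% is the classic HTM operating
    point).  ``n_iterations`` defaults to 21 full passes over the data,
    enough for the permanence matrix to reach a stable representation.
    """

    n_inputs: int
    n_columns: int = 1024
    potential_fraction: float = 0.8
    perm_connected: float = 0.5
    perm_inc: float = 0.05
    perm_dec: float = 0.008
    column_activation_pct: float = 2.0
    boost_strength: float = 0.0
    duty_cycle_period: int = 1000
    n_iterations: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_columns < 1:
            raise ConfigurationError("n_inputs and n_columns must be >= 1")
        if not 0.0 < self.potential_fraction <= 1.0:
            raise ConfigurationError(
                f"potential_fraction must be in (0, 1], got {self.potential_fraction}"
            )
        if not 0.0 <= self.perm_connected <= 1.0:
            raise ConfigurationError("perm_connected must be in [0, 1]")
        if self.perm_inc < 0 or self.perm_dec < 0:
            raise ConfigurationError("perm_inc and perm_dec must be >= 0")
        if self.boost_strength < 0:
            raise ConfigurationError("boost_strength must be >= 0")
        if self.duty_cycle_period < 1:
            raise ConfigurationError("duty_cycle_period must be >= 1")
        if self.k < 1:
            raise ConfigurationError(
                f"column_activation_pct {self.column_activation_pct}% of "
                f"{self.n_columns} columns rounds to 0 active columns"
            )
        if self.n_potential < 1:
            raise ConfigurationError("potential pool has size 0")

    @property
    def k(self) -> int:
        """Number of active columns after inhibition."""
        return _round_half_away(self.column_activation_pct / 100.0 * self.n_columns)

    @property
    def n_potential(self) -> int:
        """Potential synapses per column."""
        return _round_half_away(self.potential_fraction * self.n_inputs)


@dataclass
class SPState:
    """Mutable Spatial Pooler state: permanences, boosting bookkeeping."""

    config: SPConfig
    permanences: np.ndarray          # (n_columns, n_inputs) float64, 0 outside mask
    potential_mask: np.ndarray       # (n_columns, n_inputs) bool
    potential_idx: np.ndarray        # (n_columns, n_potential) int32, sorted
    connected_t: np.ndarray          # (n_inputs, n_columns) uint8 cache, transposed for locality
    boost_factors: np.ndarray        # (n_columns,) float64 > 0
    active_duty_cycles: np.ndarray   # (n_columns,) float64 in [0, 1]
    trained: bool = False


@dataclass(frozen=True)
class SDR:
    """A sparse distributed representation: the sorted active column set."""

    active_columns: np.ndarray
    n_columns: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "active_columns", np.asarray(self.active_columns, dtype=np.int64)
        )
        ac = self.active_columns
        if ac.size and (ac.min() < 0 or ac.max() >= self.n_columns):
            raise ValueError("active column index out of range")
        if not np.all(np.diff(ac) > 0):
            object.__setattr__(self, "active_columns", np.unique(ac))

    def __len__(self) -> int:
        return len(self.active_columns)

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.n_columns, dtype=np.uint8)
        dense[self.active_columns] = 1
        return dense


def init_pooler(config: SPConfig) -> SPState:
    """Initialize permanences and potential pools from the config seed.

    Each column samples ``round(potential_fraction * n_inputs)`` input bits
    without replacement; permanences inside the pool start uniform in
    ``[perm_connected - 0.1, perm_connected + 0.1]`` clipped to [0, 1], so
    roughly half the pool is connected before any learning.
    """
    rng = np.random.default_rng(config.seed)
    C, N, S = config.n_columns, config.n_inputs, config.n_potential
    # per-column sample without replacement, vectorized via random keys
    keys = rng.random((C, N))
    pot_idx = np.sort(np.argsort(keys, axis=1)[:, :S], axis=1).astype(np.int32)
    mask = np.zeros((C, N), dtype=bool)
    np.put_along_axis(mask, pot_idx, True, axis=1)
    perms = np.zeros((C, N), dtype=np.float64)
    init_vals = rng.uniform(config.perm_connected - 0.1, config.perm_connected + 0.1, (C, S))
    np.clip(init_vals, 0.0, 1.0, out=init_vals)
    np.put_along_axis(perms, pot_idx, init_vals, axis=1)
    connected_t = np.ascontiguousarray(
        ((perms >= config.perm_connected) & mask).astype(np.uint8).T
    )
    return SPState(
        config=config,
        permanences=perms,
        potential_mask=mask,
        potential_idx=pot_idx,
        connected_t=connected_t,
        boost_factors=np.ones(C, dtype=np.float64),
        active_duty_cycles=np.zeros(C, dtype=np.float64),
    )


def _check_width(state: SPState, pattern: np.ndarray) -> np.ndarray:
    bits = np.asarray(pattern, dtype=np.uint8)
    if bits.shape != (state.config.n_inputs,):
        raise ValueError(
            f"input width {bits.shape} does not match n_inputs {state.config.n_inputs}"
        )
    return bits


def compute_overlap(state: SPState, pattern: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw and boosted overlaps of every column with a binary input.

    Raw overlap of a column is the count of its connected synapses that sit
    on active input bits; the boosted overlap multiplies in the column's
    boost factor.
    """
    bits = _check_width(state, pattern)
    active = np.flatnonzero(bits)
    if active.size:
        raw = state.connected_t[active].sum(axis=0, dtype=np.int64)
    else:
        raw = np.zeros(state.config.n_columns, dtype=np.int64)
    return raw, raw * state.boost_factors


def inhibit(boosted_overlaps: np.ndarray, k: int) -> SDR:
    """Global inhibition: keep exactly the k highest boosted overlaps.

    Ties break toward the lower column index.  Zero-overlap columns are
    admitted only as fill when fewer than k columns overlap the input.
    """
    boosted = np.asarray(boosted_overlaps, dtype=np.float64)
    n_columns = boosted.shape[0]
    if not 1 <= k <= n_columns:
        raise ValueError(f"k must be in [1, {n_columns}], got {k}")
    order = np.argsort(-boosted, kind="stable")
    winners = order[:k]
    n_positive = int((boosted > 0).sum())
    if n_positive < k:
        logger.debug(
            "inhibit: only %d columns have positive overlap; %d zero-overlap "
            "columns selected as fill", n_positive, k - n_positive,
        )
    return SDR(active_columns=np.sort(winners), n_columns=n_columns)


def learn_step(state: SPState, pattern: np.ndarray, sdr: SDR) -> SPState:
    """Hebbian permanence update for the active columns, plus boosting.

    Active columns raise permanences on active input bits by ``perm_inc``
    and lower them on inactive bits by ``perm_dec`` (potential pool only,
    clipped to [0, 1]).  All columns update their activation duty cycle as
    an exponential moving average over ``duty_cycle_period`` and recompute
    ``boost = exp(boost_strength * (k / n_columns - duty))``.
    """
    cfg = state.config
    bits = _check_width(state, pattern)
    act = sdr.active_columns
    if act.size:
        delta = np.where(bits.astype(bool), cfg.perm_inc, -cfg.perm_dec)
        rows = state.permanences[act] + delta * state.potential_mask[act]
        np.clip(rows, 0.0, 1.0, out=rows)
        state.permanences[act] = rows
        state.connected_t[:, act] = (
            (rows >= cfg.perm_connected) & state.potential_mask[act]
        ).astype(np.uint8).T
    indicator = sdr.to_dense().astype(np.float64)
    p = cfg.duty_cycle_period
    state.active_duty_cycles = (state.active_duty_cycles * (p - 1) + indicator) / p
    target_density = cfg.k / cfg.n_columns
    state.boost_factors = np.exp(
        cfg.boost_strength * (target_density - state.active_duty_cycles)
    )
    return state


def compute_sdr(state: SPState, pattern: np.ndarray, learn: bool = False) -> SDR:
    """One overlap → inhibition pass; applies a learning step when asked."""
    _, boosted = compute_overlap(state, pattern)
    sdr = inhibit(boosted, state.config.k)
    if learn:
        learn_step(state, pattern, sdr)
    return sdr


def _pattern_indices(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pack per-pattern active-bit indices into a padded int32 matrix."""
    lengths = patterns.sum(axis=1).astype(np.int32)
    width = max(int(lengths.max()), 1) if len(lengths) else 1
    idx = np.zeros((len(patterns), width), dtype=np.int32)
    for t, row in enumerate(patterns):
        nz = np.flatnonzero(row)
        idx[t, : nz.size] = nz
    return idx, lengths


def fit(state: SPState, data: PatternSet, n_iterations: int | None = None) -> SPState:
    """Train in place: full overlap→inhibit→learn passes over the data in order.

    Deterministic given (config, seed, data order); the default iteration
    count comes from the config (21).
    """
    if len(data) == 0:
        raise ConfigurationError("cannot fit on an empty dataset")
    cfg = state.config
    if data.n_bits != cfg.n_inputs:
        raise ValueError(f"dataset width {data.n_bits} != n_inputs {cfg.n_inputs}")
    n_iterations = cfg.n_iterations if n_iterations is None else n_iterations
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    from . import _kernels

    if _kernels.HAVE_NUMBA:
        x_idx, x_len = _pattern_indices(data.patterns)
        perm_pot = np.ascontiguousarray(
            np.take_along_axis(state.permanences, state.potential_idx, axis=1)
        )
        conn_pot = (perm_pot >= cfg.perm_connected).astype(np.uint8)
        _kernels.sp_fit(
            perm_pot,
            state.potential_idx,
            conn_pot,
            state.connected_t,
            state.boost_factors,
            state.active_duty_cycles,
            x_idx,
            x_len,
            cfg.k,
            cfg.perm_connected,
            cfg.perm_inc,
            cfg.perm_dec,
            cfg.boost_strength,
            cfg.duty_cycle_period,
            cfg.k / cfg.n_columns,
            n_iterations,
        )
        np.put_along_axis(state.permanences, state.potential_idx, perm_pot, axis=1)
    else:  # pragma: no cover - exercised only without numba
        for _ in range(n_iterations):
            for pattern in data:
                compute_sdr(state, pattern, learn=True)
    state.trained = True
    return state


def compute_sdrs(state: SPState, patterns: np.ndarray | PatternSet) -> list[SDR]:
    """Batch SDR computation without learning (numba fast path when present)."""
    mat = patterns.patterns if isinstance(patterns, PatternSet) else np.asarray(patterns, dtype=np.uint8)
    from . import _kernels

    if _kernels.HAVE_NUMBA and len(mat):
        x_idx, x_len = _pattern_indices(mat)
        active = _kernels.sp_sdrs(
            state.connected_t, state.boost_factors, x_idx, x_len, state.config.k
        )
        return [
            SDR(active_columns=row.astype(np.int64), n_columns=state.config.n_columns)
            for row in active
        ]
    return [compute_sdr(state, row, learn=False) for row in mat]


def sdr_change(reference: SDR, other: SDR) -> float:
    """Fractional change 1 - |reference ∩ other| / |reference|."""
    if reference.n_columns != other.n_columns:
        raise ValueError("SDRs come from different column counts")
    if len(reference) == 0:
        raise ValueError("reference SDR is empty")
    inter = np.intersect1d(reference.active_columns, other.active_columns).size
    return 1.0 - inter / len(reference)
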