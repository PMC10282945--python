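"""Sweep orchestration: sparsity × noise × beta grids over the full pipeline.

Each grid cell trains a Spatial Pooler at one column-activation level on a
(possibly noise-corrupted) synthetic pattern family, reconstructs the SDRs
with the probabilistic-mapping decoder, quantizes the input X, SDR Y and
reconstruction Z, and evaluates the standard and modified information
bottleneck objectives at every beta.  The noise-curve runner reproduces the
classic robustness experiment: how much a trained (or untrained) pooler's
output changes as input bits are flipped.

Conventions baked in here:

* X for all information quantities is the **clean** input; noise enters only
  through the corruption fed to the SP.  I(X;Z) then measures reconstruction
  fidelity against the uncorrupted signal.
* Injected noise is density-preserving (:func:`~sparsepool.synthetic_data.
  swap_noise`): a noise level names the fraction of a pattern's active bits
  displaced, the convention of the classic SP noise-robustness experiment.
* In the IB sweep, the SP at each noise level is trained on the corrupted
  inputs (the noisy family is the training set); the decoder is always fit
  on (clean input, SDR) pairs.  The noise-curve experiment instead trains
  once on its clean dataset and probes it with corrupted inputs.
* The noise-curve experiment runs on random sparse patterns sized near the
  pooler's dedicated-column capacity (about ``n_columns / k`` patterns),
  the regime of the original robustness experiment; the IB sweep runs on
  the clustered prototype family.
* Stochastic orderings are reported as means over several seeds (default 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import PatternSet, generate_prototypes, sample_family, _round_half_away
from .spatial_pooler import SPConfig, init_pooler, fit, compute_sdrs, sdr_change
from .reconstruction import fit_decoder, decode_batch, reconstruction_error
from .info_measures import PatternQuantizer, default_quantizer, quantize, evaluate_chain

logger = logging.getLogger(__name__)

__all__ = [
    "SweepConfig",
    "SweepRecord",
    "RESULT_COLUMNS",
    "make_dataset",
    "make_noise_dataset",
    "corrupt_patterns",
    "train_pooler",
    "evaluate_cell",
    "run_noise_curve",
    "run_ib_sweep",
    "write_results",
    "read_results",
    "plot_curves",
]

#: fixed column order of results files
RESULT_COLUMNS = [
    "sparsity_pct",
    "noise_pct",
    "beta",
    "iteration_count",
    "seed",
    "I_xy",
    "I_yz",
    "I_xz",
    "L_IB",
    "L_MIB",
    "mean_sdr_change",
    "mean_reconstruction_error",
]


@dataclass(frozen=True)
class SweepConfig:
    """Grid and dataset specification for the sweep experiments.

    Defaults follow the study conditions: column activation levels
    {2, 10, 20, 30, 40}%, noise 0–75% in 5% steps, beta in
    {0.01, 0.1, 1, 10}, a 10-class prototype family of 2000-bit patterns at
    density 0.1 with 200 samples per class and 10% within-class corruption,
    21 training iterations, and 5 seeds for averaged orderings.
    """

    sparsity_levels: tuple[float, ...] = (2.0, 10.0, 20.0, 30.0, 40.0)
    noise_levels: tuple[float, ...] = tuple(range(0, 76, 5))
    betas: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    n_classes: int = 10
    n_bits: int = 2000
    density: float = 0.1
    n_per_class: int = 200
    corruption_pct: float = 10.0
    n_random_patterns: int = 100
    n_columns: int = 1024
    n_iterations: int = 21
    n_seeds: int = 5
    base_seed: int = 0
    boost_strength: float = 0.0
    smoothing_alpha: float = 1.0
    binarize_threshold: float = 0.5
    sp_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sparsity_levels", "noise_levels", "betas"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        for pct in list(self.sparsity_levels) + list(self.noise_levels):
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"percentage {pct} outside [0, 100]")

    def seeds(self) -> list[int]:
        rng = np.random.default_rng(self.base_seed)
        return [int(s) for s in rng.integers(0, 2**31 - 1, size=self.n_seeds)]


@dataclass(frozen=True)
class SweepRecord:
    """One (sparsity, noise, beta, seed) cell of the sweep."""

    sparsity_pct: float
    noise_pct: float
    beta: float
    iteration_count: int
    seed: int
    I_xy: float
    I_yz: float
    I_xz: float
    L_IB: float
    L_MIB: float
    mean_sdr_change: float
    mean_reconstruction_error: float


def make_dataset(config: SweepConfig, seed: int) -> PatternSet:
    """The clean prototype family for one seed."""
    protos = generate_prototypes(
        config.n_classes, config.n_bits, config.density, seed=seed
    )
    return sample_family(
        protos, config.n_per_class, config.corruption_pct, seed=seed + 1
    )


def make_noise_dataset(config: SweepConfig, seed: int) -> PatternSet:
    """Random sparse patterns for the noise-robustness experiment.

    Sized near the pooler's dedicated-column capacity so each pattern can
    recruit a stable winner set.
    """
    return generate_prototypes(
        config.n_random_patterns, config.n_bits, config.density, seed=seed
    )


def corrupt_patterns(patterns: np.ndarray, noise_pct: float, seed: int) -> np.ndarray:
    """Density-preserving corruption of every pattern (swap_noise convention).

    For each pattern, exactly ``round(noise_pct% of its active bits)``
    active bits are turned off and the same number of inactive bits on.
    """
    out = patterns.copy()
    if noise_pct == 0:
        return out
    rng = np.random.default_rng(seed)
    for row in out:
        active = np.flatnonzero(row)
        inactive = np.flatnonzero(row == 0)
        m = min(
            _round_half_away(noise_pct / 100.0 * active.size),
            active.size,
            inactive.size,
        )
        if m:
            row[rng.choice(active, size=m, replace=False)] = 0
            row[rng.choice(inactive, size=m, replace=False)] = 1
    return out


def _sp_config(config: SweepConfig, sparsity_pct: float, seed: int) -> SPConfig:
    kwargs = dict(
        n_inputs=config.n_bits,
        n_columns=config.n_columns,
        column_activation_pct=sparsity_pct,
        boost_strength=config.boost_strength,
        n_iterations=config.n_iterations,
        seed=seed,
    )
    kwargs.update(config.sp_overrides)
    return SPConfig(**kwargs)


def train_pooler(config: SweepConfig, train_patterns: np.ndarray,
                 sparsity_pct: float, seed: int):
    """Initialize and fit an SP at one sparsity level on the given patterns."""
    state = init_pooler(_sp_config(config, sparsity_pct, seed))
    return fit(state, PatternSet(train_patterns), config.n_iterations)


def evaluate_cell(
    config: SweepConfig,
    state,
    data: PatternSet,
    noisy_patterns: np.ndarray,
    clean_sdrs: list,
    seed: int,
    noise_pct: float,
) -> list[SweepRecord]:
    """Decode, quantize and score one trained (sparsity, noise, seed) cell."""
    sdrs = compute_sdrs(state, noisy_patterns)
    decoder = fit_decoder(data, sdrs, config.smoothing_alpha)
    recons = decode_batch(decoder, sdrs, config.binarize_threshold)

    x_sym = quantize(data, default_quantizer(data))
    y_sym = quantize(sdrs, default_quantizer(sdrs))
    z_sym = quantize(recons, default_quantizer(recons))

    mean_change = float(
        np.mean([sdr_change(r, s) for r, s in zip(clean_sdrs, sdrs)])
    )
    mean_err = float(
        np.mean([reconstruction_error(x, r) for x, r in zip(data, recons)])
    )
    records = []
    for beta in config.betas:
        ib = evaluate_chain(x_sym, y_sym, z_sym, beta)
        records.append(
            SweepRecord(
                sparsity_pct=state.config.column_activation_pct,
                noise_pct=noise_pct,
                beta=beta,
                iteration_count=config.n_iterations,
                seed=seed,
                I_xy=ib.I_xy,
                I_yz=ib.I_yz,
                I_xz=ib.I_xz,
                L_IB=ib.L_IB,
                L_MIB=ib.L_MIB,
                mean_sdr_change=mean_change,
                mean_reconstruction_error=mean_err,
            )
        )
    return records


def run_noise_curve(
    config: SweepConfig,
    with_learning: bool = True,
    sparsity_pct: float | None = None,
    n_iterations: int | None = None,
) -> pd.DataFrame:
    """Mean SDR change vs input noise for a trained or untrained pooler.

    The pooler is trained once on the clean random-pattern dataset (skipped
    when ``with_learning`` is False); at each noise level every input is
    corrupted and its SDR compared with the noiseless SDR.  Returns a frame
    with columns (noise_pct, mean_sdr_change) averaged over seeds.
    """
    sparsity = config.sparsity_levels[0] if sparsity_pct is None else sparsity_pct
    n_iter = config.n_iterations if n_iterations is None else n_iterations
    per_seed = np.zeros((config.n_seeds, len(config.noise_levels)))
    for si, seed in enumerate(config.seeds()):
        data = make_noise_dataset(config, seed)
        state = init_pooler(_sp_config(config, sparsity, seed))
        if with_learning:
            fit(state, data, n_iter)
        ref = compute_sdrs(state, data)
        for ni, noise in enumerate(config.noise_levels):
            noisy = corrupt_patterns(data.patterns, noise, seed=seed + 1000 + ni)
            sdrs = compute_sdrs(state, noisy)
            per_seed[si, ni] = np.mean(
                [sdr_change(r, s) for r, s in zip(ref, sdrs)]
            )
    return pd.DataFrame(
        {"noise_pct": list(config.noise_levels), "mean_sdr_change": per_seed.mean(axis=0)}
    )


def run_ib_sweep(config: SweepConfig) -> pd.DataFrame:
    """The full sparsity × noise × beta sweep; one row per grid cell and seed."""
    records: list[SweepRecord] = []
    for seed in config.seeds():
        data = make_dataset(config, seed)
        for sparsity in config.sparsity_levels:
            for ni, noise in enumerate(config.noise_levels):
                noisy = corrupt_patterns(data.patterns, noise, seed=seed + 1000 + ni)
                state = train_pooler(config, noisy, sparsity, seed)
                clean_sdrs = compute_sdrs(state, data)
                records.extend(
                    evaluate_cell(config, state, data, noisy, clean_sdrs, seed, noise)
                )
        logger.info("run_ib_sweep: finished seed %d (%d records)", seed, len(records))
    return pd.DataFrame([asdict(r) for r in records], columns=RESULT_COLUMNS)


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """CSV with one header line and the fixed column order."""
    frame = records.loc[:, RESULT_COLUMNS] if set(RESULT_COLUMNS) <= set(records.columns) else records
    frame.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def plot_curves(records: pd.DataFrame, out_dir: str | Path, beta: float = 10.0) -> list[Path]:
    """Noise-vs-objective and sparsity-vs-objective curves at one beta."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sel = records[np.isclose(records["beta"], beta)]
    agg = sel.groupby(["sparsity_pct", "noise_pct"], as_index=False)["L_MIB"].mean()
    paths = []

    fig, ax = plt.subplots(figsize=(6, 4))
    for sparsity, grp in agg.groupby("sparsity_pct"):
        ax.plot(grp["noise_pct"], grp["L_MIB"], marker="o", label=f"{sparsity:g}%")
    ax.set_xlabel("noise (%)")
    ax.set_ylabel(f"modified-IB objective (bits), beta={beta:g}")
    ax.legend(title="column activation")
    fig.tight_layout()
    p = out_dir / "noise_vs_modified_ib.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    for noise, grp in agg.groupby("noise_pct"):
        ax.plot(grp["sparsity_pct"], grp["L_MIB"], marker="o", label=f"{noise:g}%")
    ax.set_xlabel("column activation (%)")
    ax.set_ylabel(f"modified-IB objective (bits), beta={beta:g}")
    ax.legend(title="noise", ncol=2, fontsize=8)
    fig.tight_layout()
    p = out_dir / "sparsity_vs_modified_ib.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)
    return paths
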