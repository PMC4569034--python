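"""Empirical CDFs of the metrics and bootstrap confidence bands.

The empirical CDF of a metric answers "what fraction of records falls
within a given effect size", letting a reader apply their own threshold
instead of the conventional one.  Uncertainty is bracketed with three
resampling schemes, each run for a configurable number of replicates
(5000 by convention):

``RESAMPLE_BLOCKS``
    ordinary bootstrap over blocks; each block's four cells are resampled
    as a single unit.
``DEVIATES_CORR0``
    block bootstrap plus an independent Gaussian deviate on every cell
    mean with standard deviation equal to that cell's SEM (correlation 0
    among the four cells of a block).
``DEVIATES_CORR1``
    block bootstrap plus a single standard-normal draw per block scaling
    every cell's SEM (correlation 1).  Together with CORR0 this brackets
    the plausible range of nonnegative within-block correlations.

Bands are pointwise percentile intervals on a fixed grid (the sorted
observed metric values, plus the threshold if given).  Reproducibility:
one root seed spawns an independent substream per replicate, so replicate
r is identical regardless of how many replicates are requested.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .metrics import Metric
from .records import CELL_KEYS, TraitBlock

__all__ = [
    "ResamplingMethod",
    "BootstrapCDF",
    "metric_values",
    "ecdf",
    "bootstrap_cdf",
    "bootstrap_samples",
    "plot_cdf",
]


class ResamplingMethod(str, enum.Enum):
    RESAMPLE_BLOCKS = "blocks"
    DEVIATES_CORR0 = "corr0"
    DEVIATES_CORR1 = "corr1"


def _block_arrays(blocks: Sequence[TraitBlock]) -> tuple[np.ndarray, np.ndarray]:
    """Cell means and SEMs as (4, n_blocks) arrays in canonical cell order."""
    means = np.array([[b.cells[k].mean for b in blocks] for k in CELL_KEYS], dtype=float)
    sems = np.array([[b.cells[k].se for b in blocks] for k in CELL_KEYS], dtype=float)
    return means, sems


def _values_from_means(means: np.ndarray, metric: Metric) -> np.ndarray:
    """Metric values for every record given a (4, n) means array.

    Degenerate records (zero standardizer) come back as NaN and are
    dropped by the callers; per-pair metrics yield 2n values, block-level
    metrics n.
    """
    aina, ainb, binb, bina = means
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric is Metric.PLASTICITY:
            num = np.concatenate([np.abs(aina - ainb), np.abs(binb - bina)])
            den = np.concatenate([np.abs(aina), np.abs(binb)])
        elif metric is Metric.DIFFERENTIATION:
            num = np.abs(aina - binb)
            den = np.abs((aina + binb) / 2.0)
        elif metric is Metric.PAIR_ADAPTIVENESS:
            num = np.concatenate([np.abs(ainb - binb), np.abs(bina - aina)])
            den = np.concatenate([np.abs(aina - binb), np.abs(binb - aina)])
        elif metric is Metric.BLOCK_ADAPTIVENESS:
            num = np.maximum(np.abs(ainb - binb), np.abs(bina - aina))
            den = np.abs(aina - binb)
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(f"unknown metric {metric!r}")
        values = np.where(den == 0, np.nan, num / den)
    return values


def metric_values(
    blocks: Sequence[TraitBlock], metric: Metric | str
) -> tuple[np.ndarray, int]:
    """Finite metric values across a dataset plus the degenerate count."""
    metric = Metric(metric)
    values = _values_from_means(_block_arrays(blocks)[0], metric)
    finite = np.isfinite(values)
    return values[finite], int((~finite).sum())


@dataclass
class BootstrapCDF:
    """A step-function CDF on a fixed grid, optionally with bootstrap bands."""

    grid: np.ndarray
    cdf: np.ndarray
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None
    method: ResamplingMethod | None = None
    replicates: int = 0
    level: float | None = None
    seed: int | None = None
    n_values: int = 0
    n_degenerate: int = 0
    replicate_values: list[np.ndarray] | None = field(default=None, repr=False)

    def evaluate(self, x: float | np.ndarray) -> np.ndarray | float:
        """Right-continuous CDF value(s) at ``x`` (fraction of records <= x)."""
        idx = np.searchsorted(self.grid, np.asarray(x, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cdf])
        out = padded[idx]
        return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out

    def to_frame(self):
        import pandas as pd

        data = {"grid": self.grid, "cdf": self.cdf}
        if self.band_lo is not None:
            data["lo"] = self.band_lo
            data["hi"] = self.band_hi
        return pd.DataFrame(data)


def _ecdf_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(values), grid, side="right") / values.size


def ecdf(values: Iterable[float]) -> BootstrapCDF:
    """Empirical CDF of a collection of metric values (no bands).

    Non-finite values (degenerate +inf records) are excluded and counted
    in ``n_degenerate``.
    """
    arr = np.asarray(list(values), dtype=float)
    finite = np.isfinite(arr)
    n_degenerate = int((~finite).sum())
    arr = arr[finite]
    if arr.size == 0:
        raise ValueError("ecdf requires at least one finite value")
    grid = np.unique(arr)
    return BootstrapCDF(
        grid=grid,
        cdf=_ecdf_on_grid(arr, grid),
        n_values=int(arr.size),
        n_degenerate=n_degenerate,
    )


def bootstrap_samples(
    blocks: Sequence[TraitBlock],
    metric: Metric | str,
    method: ResamplingMethod | str = ResamplingMethod.RESAMPLE_BLOCKS,
    replicates: int = 5000,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Per-replicate finite metric values under a resampling scheme.

    The low-level engine behind :func:`bootstrap_cdf`, exposed so that
    summary statistics other than the CDF (e.g. the bootstrap SD of a
    single record's metric) can be computed from the same streams.
    """
    metric = Metric(metric)
    method = ResamplingMethod(method)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    means, sems = _block_arrays(blocks)
    n = means.shape[1]
    if n == 0:
        raise ValueError("bootstrap requires at least one block")
    if method is not ResamplingMethod.RESAMPLE_BLOCKS and not np.all(np.isfinite(sems)):
        bad = np.argwhere(~np.isfinite(sems))
        key, blk = bad[0]
        raise ValueError(
            f"missing SEM for cell {CELL_KEYS[key]} of block {blocks[blk].block_id}"
        )

    children = np.random.SeedSequence(seed).spawn(replicates)
    out: list[np.ndarray] = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        sample = means[:, idx]
        if method is ResamplingMethod.DEVIATES_CORR0:
            sample = sample + rng.standard_normal(sample.shape) * sems[:, idx]
        elif method is ResamplingMethod.DEVIATES_CORR1:
            z = rng.standard_normal(n)
            sample = sample + z[np.newaxis, :] * sems[:, idx]
        values = _values_from_means(sample, metric)
        out.append(values[np.isfinite(values)])
    return out


def bootstrap_cdf(
    blocks: Sequence[TraitBlock],
    metric: Metric | str,
    method: ResamplingMethod | str = ResamplingMethod.RESAMPLE_BLOCKS,
    replicates: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    theta: float | None = None,
    keep_replicates: bool = False,
) -> BootstrapCDF:
    """Point-estimate CDF with pointwise percentile confidence bands.

    Parameters
    ----------
    blocks, metric:
        Dataset and which standardized metric to summarize.
    method:
        One of the three resampling schemes.
    replicates, level, seed:
        Bootstrap settings; identical seed and inputs give bit-identical
        bands.
    theta:
        Optional threshold to include as a grid point so the CDF can be
        read off exactly at the classification cutoff.
    """
    metric = Metric(metric)
    method = ResamplingMethod(method)
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    observed, n_degenerate = metric_values(blocks, metric)
    if observed.size == 0:
        raise ValueError("no finite metric values in the dataset")
    grid = np.unique(
        observed if theta is None else np.concatenate([observed, [float(theta)]])
    )
    point = _ecdf_on_grid(observed, grid)

    samples = bootstrap_samples(blocks, metric, method, replicates, seed)
    mat = np.full((replicates, grid.size), np.nan)
    for r, values in enumerate(samples):
        if values.size:
            mat[r] = _ecdf_on_grid(values, grid)
    alpha = (1.0 - level) / 2.0
    band_lo, band_hi = np.nanpercentile(mat, [100 * alpha, 100 * (1 - alpha)], axis=0)

    return BootstrapCDF(
        grid=grid,
        cdf=point,
        band_lo=band_lo,
        band_hi=band_hi,
        method=method,
        replicates=replicates,
        level=level,
        seed=seed,
        n_values=int(observed.size),
        n_degenerate=n_degenerate,
        replicate_values=samples if keep_replicates else None,
    )


def plot_cdf(cdf: BootstrapCDF, ax=None, theta: float | None = None, **step_kwargs):
    """Minimal CDF figure: the step function, bands if present, and theta.

    Returns the matplotlib axes.  Purely a convenience; publication
    aesthetics are out of scope.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(cdf.grid, cdf.cdf, where="post", **step_kwargs)
    if cdf.band_lo is not None:
        ax.fill_between(
            cdf.grid, cdf.band_lo, cdf.band_hi, step="post", alpha=0.3, linewidth=0
        )
    if theta is not None:
        ax.axvline(theta, linestyle="--", color="grey")
    ax.set_xlabel("effect size")
    ax.set_ylabel("fraction of records")
    ax.set_ylim(0, 1.02)
    return ax
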