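"""Accuracy metrics for comparing estimated against reference PSI values.

Two metrics support benchmarking: the Pearson correlation of paired PSI
vectors, and the cumulative distribution of the absolute PSI error
|estimated - reference|, read as "the fraction of events predicted within
a given maximum deviation from the reference". Pairs with a missing value
on either side are dropped before either metric, restricting the
comparison to events quantified by both sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class PairedPsi:
    """PSI values for the events present, non-missing, in both inputs."""

    event_ids: tuple[str, ...]
    estimated: np.ndarray
    reference: np.ndarray

    def __len__(self) -> int:
        return len(self.event_ids)

    @property
    def abs_delta(self) -> np.ndarray:
        return np.abs(self.estimated - self.reference)


def pair_common(estimated: pd.Series, reference: pd.Series) -> PairedPsi:
    """Inner-join two PSI columns on event id, dropping any pair with a
    missing value; the dropped count is logged."""
    joined = pd.concat(
        {"est": estimated, "ref": reference}, axis=1, join="inner"
    )
    if joined.empty:
        raise EvaluationError("no events in common between the two inputs")
    complete = joined.dropna()
    dropped = len(joined) - len(complete)
    if dropped:
        logger.info("dropped %d event pair(s) with missing PSI", dropped)
    if complete.empty:
        raise EvaluationError(
            "all common events have a missing PSI on at least one side"
        )
    return PairedPsi(
        event_ids=tuple(complete.index),
        estimated=complete["est"].to_numpy(dtype=float),
        reference=complete["ref"].to_numpy(dtype=float),
    )


def correlation(p: PairedPsi) -> float:
    """Pearson correlation of estimated versus reference PSI."""
    if len(p) < 3:
        raise EvaluationError(
            f"need at least 3 pairs for a correlation, got {len(p)}"
        )
    if np.ptp(p.estimated) == 0 or np.ptp(p.reference) == 0:
        raise EvaluationError("zero variance on one side of the comparison")
    return float(stats.pearsonr(p.estimated, p.reference).statistic)


DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.05, 0.05), 2))


def abs_delta_cdf(
    p: PairedPsi, grid: tuple[float, ...] | np.ndarray = DEFAULT_GRID
) -> np.ndarray:
    """Empirical CDF of |estimated - reference| on a threshold grid.

    Entry ``i`` is the fraction of pairs with absolute deviation at most
    ``grid[i]``; the curve is non-decreasing and reaches 1 at threshold 1.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or (np.diff(grid) <= 0).any():
        raise EvaluationError("grid must be strictly increasing")
    if grid.min() < 0 or grid.max() > 1:
        raise EvaluationError("grid thresholds must lie in [0, 1]")
    delta = np.sort(p.abs_delta)
    return np.searchsorted(delta, grid, side="right") / len(delta)
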