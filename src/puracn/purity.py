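"""Tumor purity estimation from read depths of copy-number-loss regions.

A sequenced tumor sample is a mixture of tumor cells (fraction alpha, the
purity) and normal diploid cells.  At a region deleted in the tumor, the
observed read depth R is a purity-weighted blend of the tumor's depleted
signal and the normal cells' two-copy signal.  Losses come in exactly two
flavors — heterozygous (one copy left, tumor CN 1) and homozygous (both
copies gone, tumor CN 0) — which makes the model identifiable without any
pre-called genotypes:

    Q = (R - (1 - alpha) * r_bar) / alpha          (absolute RD in the pure tumor)
    E[R] = alpha * r_bar * B / 2 + (1 - alpha) * r_bar

where r_bar is the genome-wide mean RD (taken as the normal two-copy
level, since CNVs cover a small genome fraction) and B is 0 for a
homozygous loss and 1 for a heterozygous one.  For each candidate alpha on
a grid, losses are classified into the two groups by exact 1-D two-means
clustering of Q, expected RDs are computed, and the mean absolute
deviation d = mean|E[R] - R| is recorded; the alpha minimizing d is the
estimate.  At the true purity the two recovered groups sit at 0 and
r_bar/2, so the deviation collapses.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cnv_detect import CNVRegion

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_MIN = 0.05
DEFAULT_ALPHA_MAX = 0.95
DEFAULT_ALPHA_STEP = 0.01


@dataclass
class LossSet:
    """Observed read depths of the copy-number-loss regions.

    ``R`` holds one observed RD per loss region (the region's mean
    corrected rd).  ``regions`` is optional: the purity math needs only R.
    """

    R: np.ndarray
    regions: list[CNVRegion] | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 1:
            raise ValueError("R must be a 1-D vector of observed RDs")
        if self.regions is not None and len(self.regions) != len(self.R):
            raise ValueError("regions and R lengths differ")

    @property
    def n(self) -> int:
        return len(self.R)

    @property
    def weights(self) -> np.ndarray | None:
        """Per-region bin counts, if regions are attached."""
        if self.regions is None:
            return None
        return np.array([r.n_bins for r in self.regions], dtype=float)

    @classmethod
    def from_regions(cls, regions: Sequence[CNVRegion], r_bar: float) -> "LossSet":
        """Keep the loss-direction regions; verify they sit below r_bar."""
        losses = [r for r in regions if r.direction == "loss"]
        for r in losses:
            if r.observed_rd >= r_bar:
                raise ValueError(
                    f"loss region {r.chrom}:{r.start}-{r.end} has observed rd "
                    f"{r.observed_rd:.4g} >= mean RD {r_bar:.4g}")
        return cls(np.array([r.observed_rd for r in losses]), list(losses))


@dataclass
class PurityEstimate:
    """Deviation curve over the purity grid and its arg-min solution."""

    alpha_grid: np.ndarray
    deviations: np.ndarray
    alpha_hat: float
    d_min: float
    B_hat: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_hom(self) -> int:
        return int(np.sum(self.B_hat == 0))

    @property
    def n_het(self) -> int:
        return int(np.sum(self.B_hat == 1))


def recover_absolute_rd(
    R: Sequence[float], alpha: float, r_bar: float
) -> np.ndarray:
    """Absolute (pure-tumor) RDs: Q = (R - (1 - alpha) * r_bar) / alpha.

    Negative values are permitted here — they are what lets the two-means
    step separate homozygous from heterozygous losses when the candidate
    alpha is below the truth.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {alpha}")
    if r_bar <= 0:
        raise ValueError("mean RD must be positive")
    R = np.asarray(R, dtype=float)
    return (R - (1.0 - alpha) * r_bar) / alpha


def classify_losses(Q: Sequence[float]) -> np.ndarray:
    """Split absolute RDs into homozygous (0) and heterozygous (1) losses.

    Exact 1-D two-means: the globally optimal two-cluster partition of a
    1-D sample is a threshold in sorted order, so scanning the n-1
    breakpoints and minimizing the within-cluster sum of squares finds the
    partition any converged K-means (K=2) run could at best reach.  The
    lower-mean cluster is labeled 0, the higher-mean cluster 1.
    """
    Q = np.asarray(Q, dtype=float)
    n = len(Q)
    if n < 2:
        raise ValueError("need >= 2 loss regions to classify loss types")
    if np.all(Q == Q[0]):
        logger.warning("all absolute RDs identical: no hom/het separation, "
                       "labeling every loss heterozygous")
        return np.ones(n, dtype=int)
    order = np.argsort(Q, kind="stable")
    qs = Q[order]
    # prefix sums give each split's within-cluster SS in O(1)
    csum = np.cumsum(qs)
    csum2 = np.cumsum(qs ** 2)
    total, total2 = csum[-1], csum2[-1]
    k = np.arange(1, n)  # left cluster sizes
    left_ss = csum2[:-1] - csum[:-1] ** 2 / k
    right_ss = (total2 - csum2[:-1]) - (total - csum[:-1]) ** 2 / (n - k)
    split = int(np.argmin(left_ss + right_ss)) + 1
    labels = np.empty(n, dtype=int)
    labels[order[:split]] = 0
    labels[order[split:]] = 1
    return labels


def expected_rd(
    B: Sequence[int], alpha: float, r_bar: float
) -> np.ndarray:
    """Model-expected RDs: E[R] = alpha * r_bar * B / 2 + (1 - alpha) * r_bar."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {alpha}")
    B = np.asarray(B, dtype=float)
    if not np.all(np.isin(B, (0.0, 1.0))):
        raise ValueError("B must contain only 0s and 1s")
    return alpha * r_bar * B / 2.0 + (1.0 - alpha) * r_bar


def deviation(
    E: Sequence[float], R: Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    """Mean absolute difference between expected and observed RDs.

    Unweighted by default (each region counts once); pass per-region
    weights (e.g. bin counts) for a length-weighted variant.
    """
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    if E.shape != R.shape:
        raise ValueError(f"length mismatch: {E.shape} vs {R.shape}")
    if len(E) == 0:
        raise ValueError("deviation needs at least one region")
    if weights is None:
        return float(np.mean(np.abs(E - R)))
    w = np.asarray(weights, dtype=float)
    if w.shape != E.shape:
        raise ValueError("weights length mismatch")
    return float(np.sum(w * np.abs(E - R)) / np.sum(w))


def make_alpha_grid(
    alpha_min: float = DEFAULT_ALPHA_MIN,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    step: float = DEFAULT_ALPHA_STEP,
) -> np.ndarray:
    """Inclusive purity grid alpha_min, alpha_min+step, ..., alpha_max."""
    if not 0.0 < alpha_min <= alpha_max < 1.0:
        raise ValueError("need 0 < alpha_min <= alpha_max < 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(np.floor((alpha_max - alpha_min) / step + 1e-9))
    grid = alpha_min + step * np.arange(n_steps + 1)
    return np.round(grid, 10)


def grid_search_purity(
    losses: LossSet,
    r_bar: float,
    alpha_min: float = DEFAULT_ALPHA_MIN,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    step: float = DEFAULT_ALPHA_STEP,
    weight_by_bins: bool = False,
) -> PurityEstimate:
    """Exhaustive purity search minimizing the observed-expected deviation.

    For every alpha on the grid the pipeline recover -> classify ->
    expect -> deviate is evaluated; the smallest alpha attaining the
    minimum deviation is returned (deterministic tie-break) together with
    the full deviation curve and the loss labels at the solution.
    """
    if losses.n < 2:
        raise ValueError("need >= 2 loss regions to estimate purity")
    grid = make_alpha_grid(alpha_min, alpha_max, step)
    if len(grid) == 0:
        raise ValueError("empty purity grid")
    weights = losses.weights if weight_by_bins else None
    devs = np.empty(len(grid))
    for i, alpha in enumerate(grid):
        Q = recover_absolute_rd(losses.R, alpha, r_bar)
        B = classify_losses(Q)
        E = expected_rd(B, alpha, r_bar)
        devs[i] = deviation(E, losses.R, weights)
    best = int(np.argmin(devs))  # argmin takes the first = smallest alpha
    alpha_hat = float(grid[best])
    B_hat = classify_losses(recover_absolute_rd(losses.R, alpha_hat, r_bar))
    return PurityEstimate(grid, devs, alpha_hat, float(devs[best]), B_hat)


def write_purity_report(
    estimate: PurityEstimate, path: str | os.PathLike
) -> None:
    """Write the full deviation curve as TSV with a one-line summary header."""
    with open(path, "w") as fh:
        fh.write(f"# alpha_hat={estimate.alpha_hat:.4g}"
                 f"\td_min={estimate.d_min:.6g}"
                 f"\tn_losses={len(estimate.B_hat)}"
                 f"\tn_hom={estimate.n_hom}\tn_het={estimate.n_het}\n")
        fh.write("alpha\tdeviation\n")
        for a, d in zip(estimate.alpha_grid, estimate.deviations):
            fh.write(f"{a:.4g}\t{d:.6g}\n")
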