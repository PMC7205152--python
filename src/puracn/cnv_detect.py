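"""CNV detection from anomaly scores on binned read depths.

Each unmasked bin's read depth is scored by an isolation forest (how easily
the value is isolated by random axis-aligned splits), the scores are
smoothed by exact 1-D total-variation denoising per chromosome (copy
numbers are locally correlated, so true CNV signal is piecewise constant),
and the smoothed scores are tested against a Gamma null fitted by the
method of moments.  Bins whose upper-tail p-value falls below the
significance level are flagged and merged into directional gain/loss
regions.  Any external caller can replace this stage: `load_external_calls`
turns a BED file into the same region objects.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import IsolationForest

from .rd_profile import RDProfile

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 256
DEFAULT_SUBSAMPLE = 256
DEFAULT_LEVEL = 0.01
#: TV weight as a multiple of the raw-score standard deviation.
DEFAULT_LAM_SD_FACTOR = 0.3


@dataclass
class CNVRegion:
    """A called copy-number segment (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    direction: str  # "gain" | "loss"
    observed_rd: float
    n_bins: int
    abs_cn: float | None = None
    score: float | None = None  # -10*log10(best bin p-value), if available

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain/loss, got {self.direction!r}")
        if self.start >= self.end:
            raise ValueError("region start must be < end")
        if self.n_bins < 1:
            raise ValueError("region must cover at least one bin")


@dataclass
class AnomalyScores:
    """Per-unmasked-bin anomaly scores with their significance calls."""

    raw: np.ndarray
    smoothed: np.ndarray
    pvalue: np.ndarray
    calls: np.ndarray  # bool flags
    level: float


def build_isolation_forest(
    rd_values: Sequence[float],
    n_trees: int = DEFAULT_N_TREES,
    subsample: int = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> IsolationForest:
    """Grow ``n_trees`` isolation trees, each on ``subsample`` bins.

    The default 256 trees x 256 bins subsamples 256*256 bins in total from
    the genome.  If there are fewer bins than ``subsample``, the subsample
    shrinks to the bin count with a warning.
    """
    rd = np.asarray(rd_values, dtype=float).reshape(-1, 1)
    if len(rd) < subsample:
        logger.warning(
            "only %d bins available; reducing isolation-tree subsample "
            "from %d to %d", len(rd), subsample, len(rd))
        subsample = len(rd)
    forest = IsolationForest(
        n_estimators=n_trees,
        max_samples=subsample,
        bootstrap=False,
        random_state=seed,
    )
    forest.fit(rd)
    return forest


def anomaly_scores(forest: IsolationForest, rd_values: Sequence[float]) -> np.ndarray:
    """Raw isolation scores s = 2^(-E[h]/c(subsample)), one per bin, in (0, 1)."""
    rd = np.asarray(rd_values, dtype=float).reshape(-1, 1)
    # sklearn's score_samples returns -s
    return -forest.score_samples(rd)


def tv_denoise(scores: Sequence[float], lam: float) -> np.ndarray:
    """Exact solution of min_u 1/2 ||u - s||^2 + lam * sum|u[i+1] - u[i]|.

    Direct non-iterative taut-string algorithm; O(n) in practice.  With
    ``lam = 0`` the input is returned unchanged; for very large ``lam`` the
    output is constant at the mean.  Never increases total variation.
    """
    if lam < 0:
        raise ValueError("TV weight lam must be non-negative")
    y = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("scores must be finite")
    n = len(y)
    if lam == 0 or n <= 1:
        return y.copy()

    out = np.empty(n)
    k = k0 = kminus = kplus = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0.0:  # taut string must jump down at the end
                out[k0:kminus + 1] = vmin
                k0 = kminus + 1
                k = kminus = k0
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
            elif umax > 0.0:  # taut string must jump up at the end
                out[k0:kplus + 1] = vmax
                k0 = kplus + 1
                k = kplus = k0
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
            else:  # last segment: flush and finish
                out[k0:n] = vmin + umin / (k - k0 + 1)
                return out
            continue
        if y[k + 1] + umin < vmin - lam:  # downward jump is certain
            out[k0:kminus + 1] = vmin
            k0 = kminus + 1
            k = kminus = kplus = k0
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
        elif y[k + 1] + umax > vmax + lam:  # upward jump is certain
            out[k0:kplus + 1] = vmax
            k0 = kplus + 1
            k = kplus = kminus = k0
            vmax = y[k]
            vmin = y[k] - 2 * lam
            umin = lam
            umax = -lam
        else:  # no jump yet: extend the current segment
            k += 1
            umin += y[k] - vmin
            umax += y[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                kminus = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kplus = k


def gamma_test(
    smoothed: Sequence[float],
    level: float = DEFAULT_LEVEL,
    raw: Sequence[float] | None = None,
    bh_correct: bool = False,
) -> AnomalyScores:
    """Upper-tail Gamma test of smoothed anomaly scores.

    A Gamma(shape, scale) null is fitted to the smoothed scores by the
    method of moments; a bin is called a CNV when its upper-tail p-value is
    below ``level``.  Scores <= 0 are handled by shifting the whole vector
    to be positive.  ``bh_correct`` applies Benjamini-Hochberg to the
    p-values before thresholding.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("significance level must be in [0, 1]")
    s = np.asarray(smoothed, dtype=float)
    raw_arr = s.copy() if raw is None else np.asarray(raw, dtype=float)
    work = s.copy()
    if work.min() <= 0:
        work = work - work.min() + 1e-9
    mean = work.mean()
    var = work.var(ddof=1) if len(work) > 1 else 0.0
    if var <= 0 or mean <= 0:
        logger.warning("zero-variance anomaly scores: no CNV calls made")
        pvals = np.ones_like(work)
        return AnomalyScores(raw_arr, s, pvals, np.zeros(len(s), bool), level)
    shape = mean ** 2 / var
    scale = var / mean
    pvals = stats.gamma.sf(work, a=shape, scale=scale)
    thresholded = pvals if not bh_correct else _bh_adjust(pvals)
    calls = thresholded < level
    return AnomalyScores(raw_arr, s, pvals, calls, level)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = pvals[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def merge_calls(
    flags: Sequence[bool],
    profile: RDProfile,
    r_bar: float,
    pvalues: Sequence[float] | None = None,
) -> list[CNVRegion]:
    """Merge maximal runs of flagged unmasked bins into directional regions.

    ``flags`` (and ``pvalues``) are aligned to the profile's unmasked bins.
    A region's direction follows its mean corrected rd relative to
    ``r_bar``; a region whose mean rd equals r_bar exactly is dropped with
    a warning.
    """
    unmasked = profile.unmasked
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(unmasked):
        raise ValueError(
            f"{len(flags)} flags for {len(unmasked)} unmasked bins")
    pvals = None if pvalues is None else np.asarray(pvalues, dtype=float)
    chroms = unmasked["chrom"].to_numpy()
    starts = unmasked["start"].to_numpy()
    ends = unmasked["end"].to_numpy()
    rd = unmasked["rd"].to_numpy(dtype=float)

    regions: list[CNVRegion] = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flags[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        mean_rd = float(rd[i:j + 1].mean())
        if mean_rd == r_bar:
            logger.warning(
                "region %s:%d-%d has mean rd exactly r_bar; dropped",
                chroms[i], starts[i], ends[j])
        else:
            score = None
            if pvals is not None:
                best = max(float(pvals[i:j + 1].min()), 1e-300)
                score = -10.0 * np.log10(best)
            regions.append(CNVRegion(
                chrom=str(chroms[i]), start=int(starts[i]), end=int(ends[j]),
                direction="loss" if mean_rd < r_bar else "gain",
                observed_rd=mean_rd, n_bins=j - i + 1, score=score))
        i = j + 1
    return regions


def detect_cnvs(
    profile: RDProfile,
    level: float = DEFAULT_LEVEL,
    lam: float | None = None,
    n_trees: int = DEFAULT_N_TREES,
    subsample: int = DEFAULT_SUBSAMPLE,
    seed: int = 0,
    bh_correct: bool = False,
) -> tuple[list[CNVRegion], AnomalyScores]:
    """Full detection stage: score, smooth per chromosome, test, merge.

    ``lam`` defaults to 0.3 x SD of the raw scores.  Deterministic for a
    fixed seed.
    """
    unmasked = profile.unmasked
    if len(unmasked) == 0:
        raise ValueError("profile has no unmasked bins")
    rd = unmasked["rd"].to_numpy(dtype=float)
    forest = build_isolation_forest(rd, n_trees=n_trees, subsample=subsample,
                                    seed=seed)
    raw = anomaly_scores(forest, rd)
    if lam is None:
        lam = DEFAULT_LAM_SD_FACTOR * float(np.std(raw))
    smoothed = np.empty_like(raw)
    chroms = unmasked["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        smoothed[sel] = tv_denoise(raw[sel], lam)
    scores = gamma_test(smoothed, level=level, raw=raw, bh_correct=bh_correct)
    from .rd_profile import mean_rd as _mean_rd
    r_bar = _mean_rd(profile)
    regions = merge_calls(scores.calls, profile, r_bar, pvalues=scores.pvalue)
    logger.info("called %d CNV regions from %d bins at level %g",
                len(regions), len(rd), level)
    return regions, scores


def load_external_calls(
    path: str | os.PathLike, profile: RDProfile
) -> list[CNVRegion]:
    """Turn a 3+ column BED (0-based half-open) into CNVRegions.

    An optional 4th column may state the direction (``gain``/``loss``);
    otherwise it is inferred from the region's mean rd versus r_bar.
    Records overlapping no unmasked bin are skipped with a warning.
    """
    from .rd_profile import mean_rd as _mean_rd
    r_bar = _mean_rd(profile)
    unmasked = profile.unmasked
    contigs = set(unmasked["chrom"].unique())
    regions: list[CNVRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if chrom not in contigs:
                raise ValueError(
                    f"{path}:{lineno}: contig {chrom!r} not in profile")
            sel = ((unmasked["chrom"] == chrom)
                   & (unmasked["start"] < end) & (unmasked["end"] > start))
            if sel.sum() == 0:
                logger.warning(
                    "%s:%d: region %s:%d-%d overlaps no unmasked bin; skipped",
                    path, lineno, chrom, start, end)
                continue
            observed = float(unmasked.loc[sel, "rd"].mean())
            direction = None
            if len(fields) >= 4 and fields[3].lower() in ("gain", "loss"):
                direction = fields[3].lower()
            if direction is None:
                if observed == r_bar:
                    logger.warning(
                        "%s:%d: region mean rd equals r_bar; skipped",
                        path, lineno)
                    continue
                direction = "loss" if observed < r_bar else "gain"
            regions.append(CNVRegion(
                chrom=chrom, start=start, end=end, direction=direction,
                observed_rd=observed, n_bins=int(sel.sum())))
    return regions


def write_calls(
    regions: Sequence[CNVRegion],
    bed_path: str | os.PathLike,
    tsv_path: str | os.PathLike | None = None,
) -> None:
    """Write calls as BED6 (name = direction, score = -10*log10 best p)."""
    with open(bed_path, "w") as fh:
        for r in regions:
            score = 0.0 if r.score is None else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}"
                     f"\t{score:.4g}\t.\n")
    if tsv_path is not None:
        pd.DataFrame([
            dict(chrom=r.chrom, start=r.start, end=r.end,
                 direction=r.direction, observed_rd=r.observed_rd,
                 n_bins=r.n_bins)
            for r in regions
        ]).to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
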