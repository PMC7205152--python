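"""Synthetic tumor-normal admixed read-depth profiles with known truth.

Emulates a whole-chromosome shallow-sequencing experiment at the binned
read-depth level: a diploid background at a configurable base depth, a set
of planted segments carrying integer tumor copy numbers, and a normal-cell
admixture at a known purity.  A bin inside a segment of tumor copy number
c has expected depth

    base_rd * (purity * c + 2 * (1 - purity)) / 2

— the same mixture the inference inverts — with Poisson (or over-dispersed
negative-binomial) counting noise and an optional smooth GC-linked
multiplicative bias on top.  Defaults mirror a 10x, 100 bp-read experiment
over a chr21-sized genome in 1 kb bins (40,000 bins at base depth 100),
with planted copy numbers drawn from {0, 1, 4, 5, 8} and purities in the
0.2-0.8 range of interest.

Read-level simulation (FASTQ/BAM) is out of scope: the purity and CN math
consumes only binned depths, so this preserves the statistical structure
the pipeline actually sees.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv_detect import CNVRegion
from .absolute_cn import CNCall
from .purity import PurityEstimate
from .rd_profile import RDProfile

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 40_000       # ~ chr21 at 1 kb bins
DEFAULT_BASE_RD = 100.0       # 10x coverage, 100 bp reads, 1 kb bins
DEFAULT_CN_CHOICES = (0, 1, 4, 5, 8)
DEFAULT_CHROM = "chr21"
_GC_PERIOD_BINS = 2000        # period of the smooth GC covariate


@dataclass
class SimConfig:
    """Conditions of one simulated admixed profile."""

    purity: float
    n_bins: int = DEFAULT_N_BINS
    bin_size: int = 1000
    base_rd: float = DEFAULT_BASE_RD
    segments: list[tuple[int, int, int]] | None = None  # (start_bin, end_bin, cn)
    noise: str = "poisson"      # "poisson" | "nb" | "none"
    dispersion: float = 10.0    # NB size parameter (smaller = more dispersed)
    gc_bias_amplitude: float = 0.0
    seed: int = 0
    chrom: str = DEFAULT_CHROM

    def __post_init__(self) -> None:
        if not 0.0 < self.purity < 1.0:
            raise ValueError(f"purity must be in (0, 1), got {self.purity}")
        if self.noise not in ("poisson", "nb", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.segments is None:
            self.segments = default_segments(self.n_bins, self.seed)
        self._validate_segments()

    def _validate_segments(self) -> None:
        last_end = 0
        for start, end, cn in sorted(self.segments):
            if start < 0 or end > self.n_bins or start >= end:
                raise ValueError(f"segment ({start}, {end}) out of range")
            if start < last_end:
                raise ValueError("segments overlap")
            if cn < 0 or cn != int(cn):
                raise ValueError("copy numbers must be non-negative integers")
            last_end = end


@dataclass
class SimTruth:
    """Ground truth of a simulated profile."""

    purity: float
    segments: list[tuple[int, int, int]]  # (start_bin, end_bin, cn)
    expected_rd: np.ndarray               # per-bin mixture mean (no noise/bias)
    bin_size: int
    chrom: str = DEFAULT_CHROM


def default_segments(
    n_bins: int = DEFAULT_N_BINS, seed: int = 0
) -> list[tuple[int, int, int]]:
    """Default planted layout: 10 losses (cn 0/1) and 15 gains (cn 4/5/8).

    Segment lengths are drawn uniformly from 20-100 bins; each segment is
    placed at a random offset within its own equal-width block of the
    genome, which guarantees non-overlap with flanking normal sequence.
    """
    rng = np.random.default_rng(seed)
    cns = [0] * 5 + [1] * 5 + [4] * 5 + [5] * 5 + [8] * 5
    rng.shuffle(cns)
    n_seg = len(cns)
    block = n_bins // n_seg
    max_len = min(100, block - 2)
    if max_len < 20:
        raise ValueError(f"{n_bins} bins is too short for the default layout")
    segments = []
    for i, cn in enumerate(cns):
        length = int(rng.integers(20, max_len + 1))
        offset = int(rng.integers(1, block - length))
        start = i * block + offset
        segments.append((start, start + length, cn))
    return segments


def simulate_profile(config: SimConfig) -> tuple[RDProfile, SimTruth]:
    """Draw one admixed read-depth profile and its ground truth.

    Deterministic given ``config.seed``.  With ``noise="none"`` the bin
    values equal the mixture means exactly.
    """
    rng = np.random.default_rng(config.seed)
    cn = np.full(config.n_bins, 2, dtype=int)
    for start, end, c in config.segments:
        cn[start:end] = c
    mixture_mean = config.base_rd * (
        config.purity * cn + 2.0 * (1.0 - config.purity)) / 2.0

    i = np.arange(config.n_bins)
    gc = 0.45 + 0.15 * np.sin(2 * np.pi * i / _GC_PERIOD_BINS)
    mean = mixture_mean.copy()
    if config.gc_bias_amplitude > 0:
        bias = 1.0 + config.gc_bias_amplitude * (gc - 0.45) / 0.15
        mean = mean * bias

    if config.noise == "poisson":
        rd = rng.poisson(mean).astype(float)
    elif config.noise == "nb":
        size = config.dispersion
        rd = rng.negative_binomial(size, size / (size + mean)).astype(float)
    else:
        rd = mean.copy()

    starts = i * config.bin_size
    df = pd.DataFrame(dict(
        chrom=config.chrom, start=starts, end=starts + config.bin_size,
        gc=gc, n_frac=0.0, rd_raw=rd, rd=rd, masked=False))
    profile = RDProfile(df, config.bin_size)
    truth = SimTruth(config.purity, list(config.segments), mixture_mean,
                     config.bin_size, config.chrom)
    return profile, truth


def regions_from_truth(truth: SimTruth, profile: RDProfile) -> list[CNVRegion]:
    """Planted CNV segments as regions, with observed RDs from the profile.

    This is the external-calls path with a perfect caller: useful for
    exercising the purity and copy-number stages in isolation from the
    detector.
    """
    unmasked = profile.unmasked
    regions = []
    for start_bin, end_bin, cn in truth.segments:
        if cn == 2:
            continue
        start = start_bin * truth.bin_size
        end = end_bin * truth.bin_size
        sel = ((unmasked["chrom"] == truth.chrom)
               & (unmasked["start"] >= start) & (unmasked["end"] <= end))
        if sel.sum() == 0:
            logger.warning("planted segment %d-%d fully masked; skipped",
                           start, end)
            continue
        observed = float(unmasked.loc[sel, "rd"].mean())
        regions.append(CNVRegion(
            chrom=truth.chrom, start=start, end=end,
            direction="loss" if cn < 2 else "gain",
            observed_rd=observed, n_bins=int(sel.sum())))
    return regions


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def evaluate_estimate(
    estimate: PurityEstimate,
    cn_calls: Sequence[CNCall],
    truth: SimTruth,
) -> dict:
    """Score a purity estimate and CN calls against the planted truth.

    Returns the absolute purity error and the fraction of planted CNV
    segments (cn != 2) whose best >= 50%-reciprocal-overlap call carries
    the true integer copy number.
    """
    purity_error = abs(estimate.alpha_hat - truth.purity)
    planted = [(s * truth.bin_size, e * truth.bin_size, cn)
               for s, e, cn in truth.segments if cn != 2]
    n_correct = 0
    for start, end, cn in planted:
        best, best_ro = None, 0.0
        for call in cn_calls:
            if call.region.chrom != truth.chrom:
                continue
            ro = _reciprocal_overlap((start, end),
                                     (call.region.start, call.region.end))
            if ro >= 0.5 and ro > best_ro:
                best, best_ro = call, ro
        if best is not None and best.cn_int == cn:
            n_correct += 1
    return dict(
        purity_error=purity_error,
        alpha_hat=estimate.alpha_hat,
        true_purity=truth.purity,
        n_planted=len(planted),
        n_cn_correct=n_correct,
        cn_accuracy=n_correct / len(planted) if planted else float("nan"),
    )


def write_truth_bed(truth: SimTruth, path: str | os.PathLike) -> None:
    """Write planted segments as BED + copy-number column (cn=2 omitted)."""
    with open(path, "w") as fh:
        for start_bin, end_bin, cn in truth.segments:
            if cn == 2:
                continue
            fh.write(f"{truth.chrom}\t{start_bin * truth.bin_size}"
                     f"\t{end_bin * truth.bin_size}"
                     f"\t{'loss' if cn < 2 else 'gain'}\t{cn}\n")


def write_sim_config(config: SimConfig, path: str | os.PathLike) -> None:
    """Persist all simulation conditions as key=value lines."""
    with open(path, "w") as fh:
        fh.write(f"purity={config.purity}\nn_bins={config.n_bins}\n"
                 f"bin_size={config.bin_size}\nbase_rd={config.base_rd}\n"
                 f"noise={config.noise}\ndispersion={config.dispersion}\n"
                 f"gc_bias_amplitude={config.gc_bias_amplitude}\n"
                 f"seed={config.seed}\nchrom={config.chrom}\n")
        for start, end, cn in config.segments:
            fh.write(f"segment={start},{end},{cn}\n")


def read_sim_config(path: str | os.PathLike) -> SimConfig:
    """Read a key=value simulation config written by :func:`write_sim_config`."""
    kw: dict = {}
    segments = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            if key == "segment":
                s, e, c = value.split(",")
                segments.append((int(s), int(e), int(c)))
            elif key in ("n_bins", "bin_size", "seed"):
                kw[key] = int(value)
            elif key in ("purity", "base_rd", "dispersion", "gc_bias_amplitude"):
                kw[key] = float(value)
            elif key in ("noise", "chrom"):
                kw[key] = value
    if segments:
        kw["segments"] = segments
    return SimConfig(**kw)
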