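"""Binned read-depth profiles from alignments.

Turns a coordinate-sorted, indexed BAM plus its reference FASTA into a
GC-corrected, N-masked read-depth (RD) profile over fixed-size,
non-overlapping genome bins, and computes the genome-wide mean RD (r_bar)
that anchors the purity model downstream.

Conventions
-----------
* Coordinates are 0-based half-open internally and in all TSV/BED output.
* A read is assigned to exactly one bin by its leftmost mapped position;
  unmapped, secondary, supplementary and duplicate-flagged reads are
  excluded.  This makes binning conserve reads: the per-bin counts sum to
  the number of counted alignments.
* ``rd`` is the working read-depth column (raw count per bin, rescaled in
  place by GC correction); ``rd_raw`` keeps the original count.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 1000
DEFAULT_N_FRACTION_THRESHOLD = 0.5
DEFAULT_MIN_STRATUM_BINS = 20

#: Column order of the profile TSV written by :func:`write_profile`.
PROFILE_COLUMNS = ["chrom", "start", "end", "gc", "rd_raw", "rd_corrected", "masked"]


class GenomeBin(NamedTuple):
    """One fixed-size genome window with its read depth and GC content."""

    chrom: str
    start: int
    end: int
    rd: float
    gc: float
    masked: bool


@dataclass
class RDProfile:
    """Ordered per-bin read depths for one sample.

    Parameters
    ----------
    df
        One row per bin, sorted by (chrom, start), with columns
        ``chrom, start, end, gc, n_frac, rd_raw, rd, masked``.
    bin_size
        Nominal bin width in bp (the final bin of a chromosome may be
        shorter).
    """

    df: pd.DataFrame
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "gc", "rd_raw", "rd", "masked"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"profile is missing columns: {sorted(missing)}")
        if "n_frac" not in self.df.columns:
            self.df = self.df.assign(n_frac=0.0)
        self.df = self.df.reset_index(drop=True)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def unmasked(self) -> pd.DataFrame:
        return self.df[~self.df["masked"]]

    @property
    def mean_rd(self) -> float:
        """Genome-wide mean RD over unmasked bins (r_bar)."""
        return mean_rd(self)

    @property
    def bins(self) -> Iterator[GenomeBin]:
        for row in self.df.itertuples(index=False):
            yield GenomeBin(row.chrom, int(row.start), int(row.end),
                            float(row.rd), float(row.gc), bool(row.masked))

    def copy(self) -> "RDProfile":
        return RDProfile(self.df.copy(), self.bin_size)


def _window_gc_and_n(seq: str) -> tuple[float, float]:
    """GC fraction over non-N bases and N fraction of a window."""
    up = seq.upper()
    n = up.count("N")
    acgt = len(up) - n
    if acgt == 0:
        return 0.0, 1.0
    gc = up.count("G") + up.count("C")
    return gc / acgt, n / len(up)


def bin_read_counts(
    alignment_path: str | os.PathLike,
    reference_path: str | os.PathLike,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> RDProfile:
    """Count reads per non-overlapping genome bin.

    Each counted read is assigned to the bin containing its leftmost mapped
    position.  GC content and N fraction of each window are taken from the
    reference sequence.

    Raises
    ------
    ValueError
        If the alignment lacks an index, a contig is absent from the
        reference, or the file has no mapped reads.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be a positive integer")
    alignment_path = os.fspath(alignment_path)
    with pysam.AlignmentFile(alignment_path) as bam:
        if not bam.has_index():
            raise ValueError(
                f"{alignment_path} has no index; run 'samtools index' on a "
                "coordinate-sorted file first"
            )
        with pysam.FastaFile(os.fspath(reference_path)) as fasta:
            ref_contigs = set(fasta.references)
            for contig in bam.references:
                if contig not in ref_contigs:
                    raise ValueError(
                        f"contig {contig!r} from the alignment is absent "
                        "from the reference"
                    )
            rows: list[dict] = []
            total = 0
            for contig in bam.references:
                length = fasta.get_reference_length(contig)
                n_bins = max(1, -(-length // bin_size))
                counts = np.zeros(n_bins, dtype=np.int64)
                for read in bam.fetch(contig):
                    if (read.is_unmapped or read.is_secondary
                            or read.is_supplementary or read.is_duplicate):
                        continue
                    counts[read.reference_start // bin_size] += 1
                total += int(counts.sum())
                seq = fasta.fetch(contig)
                for i in range(n_bins):
                    start = i * bin_size
                    end = min(start + bin_size, length)
                    gc, n_frac = _window_gc_and_n(seq[start:end])
                    rows.append(dict(chrom=contig, start=start, end=end,
                                     gc=gc, n_frac=n_frac,
                                     rd_raw=float(counts[i]),
                                     rd=float(counts[i]), masked=False))
    if total == 0:
        raise ValueError(f"no mapped reads in {alignment_path}")
    df = pd.DataFrame(rows)
    logger.info("binned %d reads into %d bins of %d bp", total, len(df), bin_size)
    return RDProfile(df, bin_size)


def mask_n_bins(
    profile: RDProfile,
    reference_path: str | os.PathLike | None = None,
    n_fraction_threshold: float = DEFAULT_N_FRACTION_THRESHOLD,
    fill: str = "mask",
) -> RDProfile:
    """Flag N-dominated bins so they drop out of r_bar and detection.

    A bin is masked when its reference N fraction exceeds
    ``n_fraction_threshold`` (1.0 disables masking).  ``fill="mean"``
    instead replaces the masked bins' rd with the mean of the retained
    bins and leaves them unmasked.  Idempotent for ``fill="mask"``.
    """
    if not 0.0 <= n_fraction_threshold <= 1.0:
        raise ValueError("n_fraction_threshold must be in [0, 1]")
    if fill not in ("mask", "mean"):
        raise ValueError("fill must be 'mask' or 'mean'")
    out = profile.copy()
    if reference_path is not None:
        with pysam.FastaFile(os.fspath(reference_path)) as fasta:
            n_fracs = []
            for row in out.df.itertuples(index=False):
                seq = fasta.fetch(row.chrom, int(row.start), int(row.end))
                n_fracs.append(_window_gc_and_n(seq)[1])
        out.df["n_frac"] = n_fracs
    hit = out.df["n_frac"].to_numpy() > n_fraction_threshold
    if fill == "mask":
        out.df["masked"] = out.df["masked"].to_numpy() | hit
    else:
        keep = ~hit & ~out.df["masked"].to_numpy()
        if keep.sum() == 0:
            raise ValueError("no bins left to compute the fill value from")
        fill_value = float(out.df.loc[keep, "rd"].mean())
        out.df.loc[hit, "rd"] = fill_value
        out.df.loc[hit, "rd_raw"] = fill_value
    n_masked = int(out.df["masked"].sum())
    if n_masked:
        logger.info("masked %d/%d N-dominated bins", n_masked, out.n_bins)
    return out


def correct_gc_bias(
    profile: RDProfile,
    min_stratum_bins: int = DEFAULT_MIN_STRATUM_BINS,
) -> RDProfile:
    """Remove GC-content bias by median-ratio rescaling.

    Unmasked bins are grouped into 1%-wide GC strata; each bin's rd is
    multiplied by (global median rd) / (median rd of its stratum).  Strata
    with fewer than ``min_stratum_bins`` bins inherit the factor of the
    nearest sufficiently populated stratum, so sparse GC extremes are not
    rescaled by noisy medians.  Masked bins are untouched.  The global
    median rd of the unmasked bins is preserved.
    """
    out = profile.copy()
    unmasked = ~out.df["masked"].to_numpy()
    if unmasked.sum() == 0:
        raise ValueError("cannot GC-correct an all-masked profile")
    rd = out.df["rd"].to_numpy(dtype=float)
    gc = out.df["gc"].to_numpy(dtype=float)
    stratum = np.clip((gc * 100).astype(int), 0, 99)
    global_median = float(np.median(rd[unmasked]))
    if global_median <= 0:
        raise ValueError("global median rd is 0; profile carries no signal")

    factors = np.full(100, np.nan)
    counts = np.zeros(100, dtype=int)
    for s in np.unique(stratum[unmasked]):
        sel = unmasked & (stratum == s)
        counts[s] = int(sel.sum())
        med = float(np.median(rd[sel]))
        factors[s] = global_median / med if med > 0 else 1.0
    eligible = np.flatnonzero(counts >= min_stratum_bins)
    if eligible.size == 0:  # tiny profile: every stratum keeps its own factor
        eligible = np.flatnonzero(counts > 0)
    occupied = np.flatnonzero(counts > 0)
    for s in occupied:
        if counts[s] < min_stratum_bins:
            nearest = eligible[np.argmin(np.abs(eligible - s))]
            factors[s] = factors[nearest]

    rd_new = rd.copy()
    rd_new[unmasked] = rd[unmasked] * factors[stratum[unmasked]]
    out.df["rd"] = rd_new
    return out


def mean_rd(profile: RDProfile) -> float:
    """Arithmetic mean rd over unmasked bins (r_bar of the purity model)."""
    unmasked = profile.unmasked
    if len(unmasked) == 0:
        raise ValueError("no unmasked bins: cannot compute mean RD")
    value = float(unmasked["rd"].mean())
    if value <= 0:
        raise ValueError("mean RD is 0; an all-zero profile is invalid")
    return value


def write_profile(profile: RDProfile, path: str | os.PathLike) -> None:
    """Write the profile TSV (chrom, start, end, gc, rd_raw, rd_corrected, masked)."""
    df = profile.df.copy()
    df["rd_corrected"] = df["rd"]
    df["masked"] = df["masked"].astype(int)
    df[PROFILE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_profile(path: str | os.PathLike, bin_size: int | None = None) -> RDProfile:
    """Read a profile TSV written by :func:`write_profile`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile TSV {path} is missing columns {sorted(missing)}")
    df = df.rename(columns={"rd_corrected": "rd"})
    df["masked"] = df["masked"].astype(bool)
    if bin_size is None:
        bin_size = int((df["end"] - df["start"]).mode().iloc[0])
    return RDProfile(df, bin_size)
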