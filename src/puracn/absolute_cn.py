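"""Absolute copy numbers for CNV regions given an estimated purity.

Once the purity alpha is known, every CNV region's observed read depth can
be stripped of the normal-cell contribution (Q = (R - (1-alpha)*r_bar) /
alpha) and converted to a copy number by CN = 2 * Q / r_bar, since r_bar
corresponds to the diploid two-copy level.  Q is clipped at zero before
the conversion so noise can never yield a negative copy number; both the
continuous and the rounded integer CN are reported.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

from .cnv_detect import CNVRegion
from .purity import PurityEstimate


@dataclass
class CNCall:
    """One region's absolute copy number at the estimated purity."""

    region: CNVRegion
    q: float          # absolute RD, clipped at 0
    cn_real: float    # 2 * q / r_bar
    cn_int: int       # round-half-up, >= 0


def round_cn(cn_real: float) -> int:
    """Round-half-up to a non-negative integer (3.5 -> 4, -0.2 -> 0)."""
    if not math.isfinite(cn_real):
        raise ValueError("copy number must be finite")
    return max(0, math.floor(cn_real + 0.5))


def absolute_copy_number(
    regions: Sequence[CNVRegion], alpha: float, r_bar: float
) -> list[CNCall]:
    """Convert observed RDs of all CNV regions into absolute copy numbers."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {alpha}")
    if r_bar <= 0:
        raise ValueError("mean RD must be positive")
    calls = []
    for region in regions:
        q = max(0.0, (region.observed_rd - (1.0 - alpha) * r_bar) / alpha)
        cn_real = 2.0 * q / r_bar
        region.abs_cn = cn_real
        calls.append(CNCall(region, q, cn_real, round_cn(cn_real)))
    return calls


def write_cn_report(
    calls: Sequence[CNCall],
    path: str | os.PathLike,
    estimate: PurityEstimate | None = None,
) -> None:
    """Write the final per-region CN table, purity summary as comment lines."""
    with open(path, "w") as fh:
        if estimate is not None:
            fh.write(f"# alpha_hat={estimate.alpha_hat:.4g}\n")
            fh.write(f"# d_min={estimate.d_min:.6g}\n")
            fh.write(f"# n_losses={len(estimate.B_hat)}"
                     f"\tn_hom={estimate.n_hom}\tn_het={estimate.n_het}\n")
        fh.write("chrom\tstart\tend\tdirection\tobserved_rd\tcn_real\tcn_int\n")
        for c in calls:
            r = c.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}"
                     f"\t{r.observed_rd:.6g}\t{c.cn_real:.6g}\t{c.cn_int}\n")
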