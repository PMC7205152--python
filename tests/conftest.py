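"""Shared fixtures: tiny on-the-fly alignment/reference files and profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
import pytest

from puracn import RDProfile


def make_reference(path, sequences: dict[str, str]) -> str:
    """Write and faidx-index a FASTA from {contig: sequence}."""
    path = str(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    pysam.faidx(path)
    return path


def make_bam(path, contigs: dict[str, int],
             reads: list[tuple[str, int]],
             read_length: int = 100,
             index: bool = True,
             flags: list[int] | None = None) -> str:
    """Write a coordinate-sorted BAM of (contig, leftmost position) reads."""
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    names = list(contigs)
    reads = sorted(reads, key=lambda r: (names.index(r[0]), r[1]))
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for i, (contig, pos) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"read{i}"
            a.query_sequence = "A" * read_length
            a.reference_id = names.index(contig)
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigar = [(0, read_length)]
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            if flags is not None:
                a.flag = flags[i]
            out.write(a)
    if index:
        pysam.index(path)
    return path


def profile_from_rd(rd, chrom: str = "chr21", bin_size: int = 1000,
                    gc=None, masked=None) -> RDProfile:
    """Build an in-memory profile straight from an rd vector."""
    rd = np.asarray(rd, dtype=float)
    n = len(rd)
    starts = np.arange(n) * bin_size
    df = pd.DataFrame(dict(
        chrom=chrom, start=starts, end=starts + bin_size,
        gc=0.45 if gc is None else np.asarray(gc, dtype=float),
        n_frac=0.0, rd_raw=rd, rd=rd,
        masked=False if masked is None else np.asarray(masked, dtype=bool)))
    return RDProfile(df, bin_size)


@pytest.fixture
def small_genome(tmp_path):
    """A 3 kb single-contig reference with an N gap, plus 3 aligned reads."""
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), 3000))
    seq = seq[:2000] + "N" * 800 + seq[2800:]
    ref = make_reference(tmp_path / "ref.fa", {"ctg1": seq})
    bam = make_bam(tmp_path / "sample.bam", {"ctg1": 3000},
                   [("ctg1", 10), ("ctg1", 500), ("ctg1", 1500)])
    return bam, ref
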