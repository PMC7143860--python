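"""Detection and summarization of runs of homozygosity (ROH).

A ROH is a maximal stretch of consecutive homozygous SNP calls within
one chromosome of one individual.  With zero tolerated heterozygous and
missing calls, maximal runs are found by a single left-to-right sweep:
a run breaks at any heterozygous call, missing call, or inter-SNP gap
exceeding the gap limit, and is emitted if it carries enough SNPs and
spans enough base pairs.  This consecutive-extension formulation
coincides with window-based callers when no disqualifying calls are
tolerated inside a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

#: Length-class lower bounds in Mb; classes are half-open [lower, upper).
LENGTH_CLASS_BOUNDS_MB = (0, 2, 4, 8, 16)
LENGTH_CLASS_LABELS = ("0-2 Mb", "2-4 Mb", "4-8 Mb", "8-16 Mb", ">16 Mb")

SEGMENT_COLUMNS = ["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_bp"]


@dataclass(frozen=True)
class RohParams:
    """ROH constraint set.

    Defaults: minimum 1 Mb and 40 homozygous SNPs per run, no
    heterozygous or missing call tolerated, and a maximum inter-SNP gap
    of 1 Mb (inclusive) so that sparse map regions cannot bridge a run.
    """

    min_length_bp: int = 1_000_000
    min_snps: int = 40
    max_het: int = 0
    max_missing: int = 0
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("min_length_bp", "min_snps", "max_het", "max_missing", "max_gap_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_het > 0 or self.max_missing > 0:
            raise NotImplementedError(
                "heterozygote/missing-tolerant runs are outside this caller's scope"
            )


@dataclass(frozen=True)
class RohSegment:
    """One maximal homozygous run: 1-based inclusive bp span at SNP positions."""

    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def detect_roh(ds: GenotypeDataset, params: RohParams | None = None) -> list[RohSegment]:
    """Emit every maximal homozygous run satisfying ``params``.

    Runs are maximal: none can be extended by an adjacent SNP without
    meeting a heterozygous call, a missing call, the chromosome end, or
    a gap larger than ``max_gap_bp``.
    """
    params = params or RohParams()
    segments: list[RohSegment] = []
    chrom = ds.snps["chromosome"].to_numpy()
    pos = ds.snps["position_bp"].to_numpy()

    for c in np.unique(chrom):
        sel = chrom == c
        cpos = pos[sel]
        # break between consecutive SNPs whose gap exceeds the limit
        gap_break = np.diff(cpos) > params.max_gap_bp
        for i, sample in enumerate(ds.samples):
            calls = ds.calls[i, sel]
            hom = (calls == 0) | (calls == 2)
            # run boundaries: change of homozygosity status or a gap break
            breaks = np.flatnonzero(~hom[1:] | ~hom[:-1] | gap_break) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(calls)]))
            for s, e in zip(starts, ends):
                if e <= s or not hom[s]:
                    continue
                n_snps = e - s
                length = int(cpos[e - 1] - cpos[s] + 1)
                if n_snps >= params.min_snps and length >= params.min_length_bp:
                    segments.append(
                        RohSegment(sample, int(c), int(cpos[s]), int(cpos[e - 1]), int(n_snps))
                    )
    return segments


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    """Tabulate segments with the canonical column order."""
    return pd.DataFrame(
        [(s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_snps, s.length_bp)
         for s in segments],
        columns=SEGMENT_COLUMNS,
    )


def write_segments_bed(segments: list[RohSegment], bed_path) -> None:
    """Export segments as BED (0-based half-open), one row per segment."""
    df = segments_to_frame(segments)
    with open(bed_path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.start_bp - 1}\t{row.end_bp}\t{row.sample_id}\n")


def classify_roh(segments: list[RohSegment]) -> pd.DataFrame:
    """Tally segments into the five length classes (half-open Mb bins).

    Returns a table with one row per class: count and frequency.
    A segment of exactly 2 Mb falls in the 2-4 Mb class.
    """
    lengths = np.array([s.length_bp for s in segments], dtype=np.int64)
    bounds_bp = [b * 1_000_000 for b in LENGTH_CLASS_BOUNDS_MB] + [np.iinfo(np.int64).max]
    counts = [
        int(((lengths >= lo) & (lengths < hi)).sum())
        for lo, hi in zip(bounds_bp[:-1], bounds_bp[1:])
    ]
    total = len(lengths)
    freqs = [c / total if total else 0.0 for c in counts]
    return pd.DataFrame(
        {"length_class": LENGTH_CLASS_LABELS, "count": counts, "frequency": freqs}
    )


def roh_summary(
    segments: list[RohSegment],
    by: str = "sample",
    l_aut: int | None = None,
) -> pd.DataFrame:
    """Summarize segments per sample, per chromosome, or cohort-wide.

    Each row reports count and min/max/mean length.  At cohort level,
    the mean count per sample and (when ``l_aut`` is given) the percent
    of the autosomal genome covered per sample on average are included.
    """
    if by not in {"sample", "chromosome", "cohort"}:
        raise ValueError(f"unknown grouping {by!r}")
    df = segments_to_frame(segments)
    if df.empty:
        zero = {"count": [0], "min_length_bp": [0], "max_length_bp": [0],
                "mean_length_bp": [0.0], "total_length_bp": [0]}
        if by == "cohort":
            zero.update({"mean_count_per_sample": [0.0]})
            if l_aut:
                zero["mean_pct_genome_in_roh"] = [0.0]
        return pd.DataFrame(zero)

    if by == "cohort":
        n_samples = df["sample_id"].nunique()
        out = pd.DataFrame(
            {
                "count": [len(df)],
                "min_length_bp": [int(df["length_bp"].min())],
                "max_length_bp": [int(df["length_bp"].max())],
                "mean_length_bp": [float(df["length_bp"].mean())],
                "total_length_bp": [int(df["length_bp"].sum())],
                "mean_count_per_sample": [len(df) / n_samples],
            }
        )
        if l_aut:
            per_sample_cov = df.groupby("sample_id")["length_bp"].sum() / l_aut
            out["mean_pct_genome_in_roh"] = 100.0 * per_sample_cov.mean()
        return out

    key = "sample_id" if by == "sample" else "chromosome"
    g = df.groupby(key)["length_bp"]
    return pd.DataFrame(
        {
            "count": g.size(),
            "min_length_bp": g.min(),
            "max_length_bp": g.max(),
            "mean_length_bp": g.mean(),
            "total_length_bp": g.sum(),
        }
    ).reset_index()
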