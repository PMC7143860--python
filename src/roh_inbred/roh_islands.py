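"""ROH incidence per SNP, TOP_SNP/TOP_ROH island calling, and gene annotation.

A TOP_SNP is a SNP lying inside a ROH in at least 50%-of-samples-plus-one
individuals; a maximal run of map-consecutive TOP_SNPs on one chromosome
is a ROH island (TOP_ROH) — a candidate selection-signature region.
Islands are annotated by >=1 bp overlap against gene intervals from a
local GFF3 or BED file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotype_io import GenotypeDataset
from .roh_scan import RohSegment

logger = logging.getLogger(__name__)

ISLAND_COLUMNS = [
    "island_id", "chromosome", "start_bp", "end_bp",
    "n_snps", "min_samples", "max_samples",
]


@dataclass(frozen=True)
class RohIsland:
    """A maximal run of consecutive above-threshold SNPs on one chromosome."""

    island_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    min_samples: int
    max_samples: int
    top_snp_ids: tuple[str, ...]


def snp_roh_incidence(segments: list[RohSegment], ds: GenotypeDataset) -> np.ndarray:
    """Number of samples whose ROH cover each SNP position.

    A sample counts once per SNP however many of its segments cover it
    (segments of one sample are disjoint, so at most one can).
    """
    chrom = ds.snps["chromosome"].to_numpy()
    pos = ds.snps["position_bp"].to_numpy()
    counts = np.zeros(len(pos), dtype=np.int64)
    # group segments by chromosome; within a chromosome use searchsorted
    order = np.lexsort((pos, chrom))
    assert (order == np.arange(len(order))).all()  # dataset invariant
    chrom_offsets = {int(c): np.flatnonzero(chrom == c) for c in np.unique(chrom)}
    for seg in segments:
        idx = chrom_offsets.get(seg.chromosome)
        if idx is None:
            continue
        cpos = pos[idx]
        lo = np.searchsorted(cpos, seg.start_bp, side="left")
        hi = np.searchsorted(cpos, seg.end_bp, side="right")
        counts[idx[lo:hi]] += 1
    return counts


def occurrence_threshold(n_samples: int) -> int:
    """Minimum per-SNP sample count for TOP_SNP status: floor(n/2) + 1."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return n_samples // 2 + 1


def call_islands(
    incidence: np.ndarray, ds: GenotypeDataset, threshold: int
) -> list[RohIsland]:
    """Call TOP_ROH islands: maximal runs of map-consecutive TOP_SNPs.

    Island bounds are the first and last TOP_SNP positions; the
    min/max sample counts are taken over member SNPs.  Any
    map-consecutive SNP below threshold splits an island (no bridging).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    incidence = np.asarray(incidence)
    chrom = ds.snps["chromosome"].to_numpy()
    pos = ds.snps["position_bp"].to_numpy()
    ids = ds.snps["snp_id"].to_numpy()

    top = incidence >= threshold
    islands: list[RohIsland] = []
    # boundaries where TOP status or chromosome changes
    edge = np.flatnonzero((top[1:] != top[:-1]) | (chrom[1:] != chrom[:-1])) + 1
    starts = np.concatenate(([0], edge))
    ends = np.concatenate((edge, [len(top)]))
    k = 0
    for s, e in zip(starts, ends):
        if not top[s]:
            continue
        k += 1
        member = incidence[s:e]
        islands.append(
            RohIsland(
                island_id=f"ISL{k:03d}",
                chromosome=int(chrom[s]),
                start_bp=int(pos[s]),
                end_bp=int(pos[e - 1]),
                min_samples=int(member.min()),
                max_samples=int(member.max()),
                top_snp_ids=tuple(ids[s:e]),
            )
        )
    return islands


def islands_to_frame(islands: list[RohIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.island_id, i.chromosome, i.start_bp, i.end_bp, len(i.top_snp_ids),
          i.min_samples, i.max_samples) for i in islands],
        columns=ISLAND_COLUMNS,
    )


# ---------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------

def _normalize_chrom(name: str) -> str:
    return str(name).removeprefix("chr")


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Load named gene intervals from GFF3 or BED.

    GFF3: ``gene`` features carrying a ``Name`` or ``gene_name``
    attribute (features without an official name are dropped).  BED4+: columns chrom, start, end, name with
    0-based half-open coordinates converted to 1-based inclusive.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = []
        for feat in db.features_of_type("gene"):
            name = None
            for key in ("Name", "gene_name"):
                if key in feat.attributes:
                    name = feat.attributes[key][0]
                    break
            if not name:
                continue
            rows.append((_normalize_chrom(feat.seqid), feat.start, feat.end, name))
        return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp", "gene"])
    # BED4+
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chromosome", "start", "end", "gene"],
    )
    return pd.DataFrame(
        {
            "chromosome": bed["chromosome"].map(_normalize_chrom),
            "start_bp": bed["start"].astype(int) + 1,
            "end_bp": bed["end"].astype(int),
            "gene": bed["gene"],
        }
    )


def annotate_islands(islands: list[RohIsland], gene_path: str | Path) -> pd.DataFrame:
    """Genes overlapping each island by >=1 bp (1-based inclusive intervals).

    Returns one row per (island, gene) pair; islands without an
    overlapping named gene appear once with an empty gene field.
    Gene intervals on chromosomes absent from the islands' chromosome
    set trigger a counted warning, not an error.
    """
    genes = read_gene_intervals(gene_path)
    island_chroms = {str(i.chromosome) for i in islands}
    unknown = ~genes["chromosome"].isin(island_chroms)
    if unknown.any() and islands:
        logger.warning("%d gene intervals on chromosomes with no island", int(unknown.sum()))

    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # IntervalTree is half-open; +1 makes the inclusive end queryable
        trees.setdefault(str(row.chromosome), IntervalTree()).addi(
            row.start_bp, row.end_bp + 1, row.gene
        )

    rows = []
    for isl in islands:
        tree = trees.get(str(isl.chromosome))
        hits = sorted({iv.data for iv in tree.overlap(isl.start_bp, isl.end_bp + 1)}) if tree else []
        if hits:
            for g in hits:
                rows.append((isl.island_id, isl.chromosome, isl.start_bp, isl.end_bp, g))
        else:
            rows.append((isl.island_id, isl.chromosome, isl.start_bp, isl.end_bp, ""))
    return pd.DataFrame(
        rows, columns=["island_id", "chromosome", "start_bp", "end_bp", "gene"]
    )
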