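"""Synthetic cohorts with known ground-truth autozygosity.

Founder haplotypes are labeled chromosome-length segments whose alleles
are drawn from per-SNP ancestral frequencies; gene dropping transmits
them through a pedigree with Haldane (no-interference) recombination.
Because labels are tracked at segment resolution, the intervals where
an individual's two haplotypes descend from the same founder haplotype
— its autozygous tracts — are known exactly, not approximated from
genotypes.  Every pipeline stage (ROH detection, F_ROH, F_PED) can
therefore be validated against exact truth without external data.

Pedigree templates (``full_sib_mating``, ``half_sib_mating``,
``cousin_mating``) are replicated as independent families, one focal
offspring each, so Monte-Carlo means over offspring converge to the
template's pedigree expectation (0.25, 0.125, 0.0625).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, SNP_COLUMNS, GenotypeDataset
from .inbreeding import Pedigree

#: 5-chromosome 200 Mb profile: fast enough for routine validation runs.
FAST_CHROM_LENGTHS_BP: tuple[int, ...] = (
    50_000_000, 45_000_000, 40_000_000, 35_000_000, 30_000_000
)

#: Canine-scale profile: 38 autosomes with linearly decreasing lengths
#: summing to 2,201,412,378 bp (the autosomal extent of a ~100k array map).
FULL_GENOME_L_AUT: int = 2_201_412_378


def full_chrom_lengths_bp() -> tuple[int, ...]:
    weights = np.arange(38, 0, -1, dtype=float) + 10.0
    lengths = np.floor(FULL_GENOME_L_AUT * weights / weights.sum()).astype(np.int64)
    lengths[0] += FULL_GENOME_L_AUT - lengths.sum()
    return tuple(int(x) for x in lengths)


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Defaults emulate the validation ("fast") genome: 5 chromosomes
    totalling 200 Mb at 50 SNPs/Mb with a uniform 1 cM/Mb genetic map
    and U-shaped Beta(0.5, 0.5) ancestral allele frequencies typical of
    ascertained SNP arrays after drift.
    """

    chromosome_lengths_bp: tuple[int, ...] = FAST_CHROM_LENGTHS_BP
    snp_density_per_mb: float = 50.0
    founder_freq_beta: tuple[float, float] = (0.5, 0.5)
    genetic_map_rate_cm_per_mb: float = 1.0
    pedigree_design: str = "full_sib_mating"
    n_offspring: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths_bp or any(l <= 0 for l in self.chromosome_lengths_bp):
            raise ValueError("chromosome lengths must be positive")
        if self.snp_density_per_mb <= 0:
            raise ValueError("snp_density_per_mb must be > 0")
        if self.genetic_map_rate_cm_per_mb < 0:
            raise ValueError("genetic_map_rate_cm_per_mb must be >= 0")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths_bp)


# each mosaic is a list of (start_bp, end_bp, founder_haplotype_label)
Mosaic = list[tuple[int, int, int]]


@dataclass
class FounderPool:
    """SNP map, ancestral frequencies, and the founder haplotype registry.

    Haplotype allele arrays (B-allele indicators over all SNPs) are
    created on demand so the pool serves pedigrees of any size.
    """

    snp_map: pd.DataFrame
    freqs: np.ndarray
    chrom_slices: dict[int, slice]
    haplotypes: list[np.ndarray] = field(default_factory=list)

    def new_haplotype(self, rng: np.random.Generator) -> int:
        self.haplotypes.append(
            (rng.random(len(self.freqs)) < self.freqs).astype(np.uint8)
        )
        return len(self.haplotypes) - 1


@dataclass
class AutozygosityTrack:
    """Exact autozygous tracts of one individual, per chromosome."""

    individual_id: str
    intervals: dict[int, list[tuple[int, int]]]
    genome_length_bp: int

    @property
    def autozygous_length_bp(self) -> int:
        return sum(e - s + 1 for ivs in self.intervals.values() for s, e in ivs)

    @property
    def true_autozygosity_fraction(self) -> float:
        return self.autozygous_length_bp / self.genome_length_bp


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> FounderPool:
    """Build the SNP map and ancestral frequency track.

    SNP positions are uniform within each chromosome (sorted, distinct);
    per-SNP ancestral frequency of the B allele is Beta-distributed.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rows = []
    chrom_slices: dict[int, slice] = {}
    lo = 0
    for c, length in enumerate(cfg.chromosome_lengths_bp, start=1):
        n = int(round(length / 1e6 * cfg.snp_density_per_mb))
        if n == 0:
            raise ValueError(f"chromosome {c}: SNP density yields an empty map")
        pos = np.unique(rng.integers(1, length + 1, size=n))
        while len(pos) < n:  # top up collisions (rare at array density)
            pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n - len(pos))]))
        for p in pos[:n]:
            rows.append((f"snp_{c}_{p}", c, int(p), "A", "C"))
        chrom_slices[c] = slice(lo, lo + n)
        lo += n
    snp_map = pd.DataFrame(rows, columns=SNP_COLUMNS)
    a, b = cfg.founder_freq_beta
    freqs = rng.beta(a, b, size=len(snp_map))
    return FounderPool(snp_map=snp_map, freqs=freqs, chrom_slices=chrom_slices)


# ---------------------------------------------------------------------
# Pedigree templates
# ---------------------------------------------------------------------

TEMPLATE_EXPECTED_F = {
    "unrelated": 0.0,
    "full_sib_mating": 0.25,
    "half_sib_mating": 0.125,
    "cousin_mating": 0.0625,
}


def template_pedigree(design: str, n_offspring: int) -> tuple[Pedigree, list[str]]:
    """Replicated-family pedigree for a named mating design.

    Returns the pedigree and the focal offspring identifiers (one per
    family) whose expected autozygosity equals the design's F.
    """
    records: list[tuple[str, str, str]] = []
    focal: list[str] = []
    for k in range(n_offspring):
        f = f"fam{k:04d}"
        o = f"{f}_O"
        if design == "unrelated":
            records.append((o, "0", "0"))
        elif design == "full_sib_mating":
            records += [
                (f"{f}_A", "0", "0"), (f"{f}_B", "0", "0"),
                (f"{f}_S", f"{f}_A", f"{f}_B"), (f"{f}_D", f"{f}_A", f"{f}_B"),
                (o, f"{f}_S", f"{f}_D"),
            ]
        elif design == "half_sib_mating":
            records += [
                (f"{f}_A", "0", "0"), (f"{f}_B", "0", "0"), (f"{f}_C", "0", "0"),
                (f"{f}_S", f"{f}_A", f"{f}_B"), (f"{f}_D", f"{f}_A", f"{f}_C"),
                (o, f"{f}_S", f"{f}_D"),
            ]
        elif design == "cousin_mating":
            records += [
                (f"{f}_GA", "0", "0"), (f"{f}_GB", "0", "0"),
                (f"{f}_C", "0", "0"), (f"{f}_D", "0", "0"),
                (f"{f}_P", f"{f}_GA", f"{f}_GB"), (f"{f}_Q", f"{f}_GA", f"{f}_GB"),
                (f"{f}_X", f"{f}_P", f"{f}_C"), (f"{f}_Y", f"{f}_Q", f"{f}_D"),
                (o, f"{f}_X", f"{f}_Y"),
            ]
        else:
            raise ValueError(f"unknown pedigree design {design!r}")
        focal.append(o)
    return Pedigree(records), focal


# ---------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------

def _recombine(h1: Mosaic, h2: Mosaic, length_bp: int,
               rate_cm_per_mb: float, rng: np.random.Generator) -> Mosaic:
    """One meiosis: Haldane crossovers splice the two parental mosaics."""
    mean_crossovers = length_bp * rate_cm_per_mb / 1e8
    n_x = rng.poisson(mean_crossovers)
    xpos = np.sort(rng.integers(1, length_bp, size=n_x)) if n_x else np.empty(0, int)
    cur = int(rng.integers(2))
    parents = (h1, h2)
    bounds = [0, *xpos.tolist(), length_bp]
    child: Mosaic = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            cur ^= 1
            continue
        for s, e, lab in parents[cur]:
            if e < a + 1 or s > b:
                continue
            ns, ne = max(s, a + 1), min(e, b)
            if child and child[-1][2] == lab and child[-1][1] + 1 == ns:
                child[-1] = (child[-1][0], ne, lab)
            else:
                child.append((ns, ne, lab))
        cur ^= 1
    return child


def _ibd_intervals(m1: Mosaic, m2: Mosaic) -> list[tuple[int, int]]:
    """Intervals where the two mosaics carry the same founder label."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(m1) and j < len(m2):
        s = max(m1[i][0], m2[j][0])
        e = min(m1[i][1], m2[j][1])
        if s <= e and m1[i][2] == m2[j][2]:
            if out and out[-1][1] + 1 == s:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
        if m1[i][1] <= m2[j][1]:
            i += 1
        else:
            j += 1
    return out


def gene_drop(
    ped: Pedigree,
    pool: FounderPool,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    keep: list[str] | None = None,
) -> tuple[GenotypeDataset, dict[str, AutozygosityTrack]]:
    """Drop founder haplotypes through ``ped`` and genotype the result.

    Founders (both parents unknown) receive two fresh labeled
    haplotypes; every other individual must have both parents known.
    Returns genotypes for ``keep`` (default: all individuals in
    pedigree order) and the exact autozygosity track of each.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    chrom_lengths = dict(enumerate(cfg.chromosome_lengths_bp, start=1))
    genome_length = sum(chrom_lengths.values())

    mosaics: dict[str, tuple[dict[int, Mosaic], dict[int, Mosaic]]] = {}
    for ind in ped.order:
        sire, dam = ped.parents[ind]
        if (sire is None) != (dam is None):
            raise ValueError(f"{ind!r} has exactly one known parent; templates are complete")
        if sire is None:
            lab1, lab2 = pool.new_haplotype(rng), pool.new_haplotype(rng)
            m1 = {c: [(1, L, lab1)] for c, L in chrom_lengths.items()}
            m2 = {c: [(1, L, lab2)] for c, L in chrom_lengths.items()}
        else:
            m1 = {
                c: _recombine(mosaics[sire][0][c], mosaics[sire][1][c], L,
                              cfg.genetic_map_rate_cm_per_mb, rng)
                for c, L in chrom_lengths.items()
            }
            m2 = {
                c: _recombine(mosaics[dam][0][c], mosaics[dam][1][c], L,
                              cfg.genetic_map_rate_cm_per_mb, rng)
                for c, L in chrom_lengths.items()
            }
        mosaics[ind] = (m1, m2)

    keep = list(ped.order) if keep is None else list(keep)
    pos_by_chrom = {
        c: pool.snp_map["position_bp"].to_numpy()[pool.chrom_slices[c]]
        for c in chrom_lengths
    }

    calls = np.empty((len(keep), len(pool.snp_map)), dtype=np.int8)
    tracks: dict[str, AutozygosityTrack] = {}
    for i, ind in enumerate(keep):
        m1, m2 = mosaics[ind]
        for c in chrom_lengths:
            sl = pool.chrom_slices[c]
            pos = pos_by_chrom[c]
            geno = np.zeros(len(pos), dtype=np.int8)
            for mosaic in (m1[c], m2[c]):
                for s, e, lab in mosaic:
                    lo = np.searchsorted(pos, s, side="left")
                    hi = np.searchsorted(pos, e, side="right")
                    geno[lo:hi] += pool.haplotypes[lab][sl][lo:hi]
            calls[i, sl] = geno
        tracks[ind] = AutozygosityTrack(
            individual_id=ind,
            intervals={c: _ibd_intervals(m1[c], m2[c]) for c in chrom_lengths},
            genome_length_bp=genome_length,
        )
    return GenotypeDataset(keep, pool.snp_map.copy(), calls), tracks


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[GenotypeDataset, dict[str, AutozygosityTrack], Pedigree]:
    """Founders + template pedigree + gene drop in one seeded call.

    The returned dataset contains only the focal offspring (one per
    replicate family); all randomness flows from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = simulate_founders(cfg, rng)
    ped, focal = template_pedigree(cfg.pedigree_design, cfg.n_offspring)
    ds, tracks = gene_drop(ped, pool, cfg, rng, keep=focal)
    return ds, {k: tracks[k] for k in focal}, ped


def inject_noise(
    ds: GenotypeDataset, missing_rate: float, error_rate: float, seed: int
) -> GenotypeDataset:
    """Independently set calls MISSING, then perturb survivors to a
    uniformly random different code."""
    if not 0 <= missing_rate <= 1 or not 0 <= error_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    calls = ds.calls.copy()
    miss = rng.random(calls.shape) < missing_rate
    calls[miss] = MISSING
    err = (rng.random(calls.shape) < error_rate) & (calls != MISSING)
    if err.any():
        # shift by 1 or 2 mod 3 => uniform over the two other codes
        shift = rng.integers(1, 3, size=int(err.sum())).astype(np.int8)
        calls[err] = (calls[err] + shift) % 3
    return GenotypeDataset(list(ds.samples), ds.snps.copy(), calls)


def write_truth_tsv(tracks: dict[str, AutozygosityTrack], path: str | Path) -> None:
    """Ground-truth TSV: one row per autozygous interval plus the
    per-individual true fraction."""
    with open(path, "w") as fh:
        fh.write("individual\tchromosome\tstart_bp\tend_bp\ttrue_fraction\n")
        for ind, tr in tracks.items():
            frac = f"{tr.true_autozygosity_fraction:.6f}"
            wrote = False
            for c, ivs in sorted(tr.intervals.items()):
                for s, e in ivs:
                    fh.write(f"{ind}\t{c}\t{s}\t{e}\t{frac}\n")
                    wrote = True
            if not wrote:
                fh.write(f"{ind}\tNA\tNA\tNA\t{frac}\n")
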