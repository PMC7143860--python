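"""Inbreeding coefficients: F_HOM, F_ROH, and pedigree-based F_PED.

Three estimators of the same underlying quantity — the probability that
an individual's two alleles at a locus are identical by descent:

* ``F_HOM`` — excess of observed over expected homozygous genotypes
  (Wright's F_IS applied per individual), using allele frequencies
  estimated from the analyzed cohort:
  ``F_HOM = (HomOb - HomEx) / (N - HomEx)`` with
  ``HomEx = sum_j [1 - 2 p_j (1 - p_j)]`` over the individual's
  non-missing SNPs.  The count denominator ``N - HomEx`` makes the
  ratio dimensionless; it equals the proportion form obtained by
  dividing both homozygote counts by N.
* ``F_ROH`` — total ROH length divided by the autosomal map length
  ``L_aut``; also reported per chromosome against the SNP-covered span.
* ``F_PED`` — half the additive relationship between an individual's
  parents, computed by the tabular method over the pedigree in
  topological order with unknown parents treated as unrelated,
  non-inbred founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeDataset, allele_frequencies
from .roh_scan import RohSegment

UNKNOWN_PARENT = frozenset({"0", "", "NA", "na", "*", "."})


class PedigreeError(ValueError):
    pass


# ---------------------------------------------------------------------
# F_HOM
# ---------------------------------------------------------------------

def f_hom(ds: GenotypeDataset, small_sample_correction: bool = False) -> pd.Series:
    """Per-sample homozygosity-excess inbreeding coefficient.

    Expected homozygosity per SNP is ``1 - 2pq`` from cohort allele
    frequencies; with ``small_sample_correction`` the heterozygosity
    term becomes ``2pq * 2n/(2n - 1)`` (unbiased for the finite sample).
    Samples with zero non-missing SNPs get ``nan``.
    """
    p = allele_frequencies(ds)
    het_exp = 2.0 * p * (1.0 - p)
    if small_sample_correction:
        n_nonmiss_per_snp = (ds.calls != MISSING).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            het_exp = het_exp * (2.0 * n_nonmiss_per_snp) / (2.0 * n_nonmiss_per_snp - 1.0)
    hom_exp_snp = 1.0 - het_exp

    nonmiss = ds.calls != MISSING
    usable = nonmiss & ~np.isnan(hom_exp_snp)[None, :]
    hom_obs = (usable & ((ds.calls == 0) | (ds.calls == 2))).sum(axis=1)
    hom_exp = np.where(usable, hom_exp_snp[None, :], 0.0).sum(axis=1)
    n = usable.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (hom_obs - hom_exp) / (n - hom_exp)
    f = np.where(n == 0, np.nan, f)
    return pd.Series(f, index=ds.samples, name="f_hom")


# ---------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Autosomal map extent: per-chromosome first-to-last SNP spans.

    ``l_aut`` is the sum of spans unless pinned by ``l_aut_override``
    (e.g. to a published constant for comparability across studies).
    """

    chromosome_spans: dict[int, int]
    l_aut_override: int | None = None

    @property
    def l_aut(self) -> int:
        if self.l_aut_override is not None:
            return self.l_aut_override
        return sum(self.chromosome_spans.values())

    @classmethod
    def from_dataset(cls, ds: GenotypeDataset, l_aut_override: int | None = None) -> "GenomeSpec":
        spans = {}
        for c, grp in ds.snps.groupby("chromosome"):
            spans[int(c)] = int(grp["position_bp"].max() - grp["position_bp"].min() + 1)
        return cls(spans, l_aut_override)


def f_roh(
    segments: list[RohSegment],
    genome: GenomeSpec,
    samples: list[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Genome-wide and per-chromosome F_ROH per sample.

    Genome-wide: total segment length / ``genome.l_aut``.  Per
    chromosome: segment length on c / SNP-covered span of c.  Samples
    without segments (pass ``samples`` to include them) score 0.
    Raises if a segment extends beyond its chromosome's span.
    """
    ids = sorted({s.sample_id for s in segments}) if samples is None else list(samples)
    chroms = sorted(genome.chromosome_spans)
    totals = pd.Series(0.0, index=ids, name="f_roh")
    per_chrom = pd.DataFrame(0.0, index=ids, columns=chroms)
    for seg in segments:
        span = genome.chromosome_spans.get(seg.chromosome)
        if span is None or seg.length_bp > span:
            raise ValueError(
                f"segment {seg.sample_id} chr{seg.chromosome} "
                f"{seg.start_bp}-{seg.end_bp} exceeds chromosome span"
            )
        if seg.sample_id not in totals.index:
            continue
        totals[seg.sample_id] += seg.length_bp
        per_chrom.loc[seg.sample_id, seg.chromosome] += seg.length_bp
    totals = totals / genome.l_aut
    for c in chroms:
        per_chrom[c] = per_chrom[c] / genome.chromosome_spans[c]
    return totals, per_chrom


# ---------------------------------------------------------------------
# Pedigree and F_PED
# ---------------------------------------------------------------------

class Pedigree:
    """Directed acyclic parent map over individual identifiers.

    Unknown parents are entered as ``0``/``NA`` (or any token in
    ``UNKNOWN_PARENT``) and treated as unrelated non-inbred founders.
    Construction topologically orders individuals (parents first) and
    rejects cycles.
    """

    def __init__(self, records: list[tuple[str, str | None, str | None]]):
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        for ind, sire, dam in records:
            ind = str(ind)
            sire = None if sire is None or str(sire) in UNKNOWN_PARENT else str(sire)
            dam = None if dam is None or str(dam) in UNKNOWN_PARENT else str(dam)
            if ind in UNKNOWN_PARENT:
                raise PedigreeError(f"invalid individual id {ind!r}")
            if ind in self.parents:
                raise PedigreeError(f"duplicate pedigree record for {ind!r}")
            self.parents[ind] = (sire, dam)
        # parents referenced but never recorded are founders
        for sire, dam in list(self.parents.values()):
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self.order = self._topological_order()

    def _topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 unseen / 1 in progress / 2 done

        def visit(ind: str, stack: list[str]) -> None:
            if state.get(ind) == 2:
                return
            if state.get(ind) == 1:
                raise PedigreeError(f"pedigree cycle involving {ind!r}")
            state[ind] = 1
            for p in self.parents[ind]:
                if p is not None:
                    visit(p, stack + [ind])
            state[ind] = 2
            order.append(ind)

        for ind in self.parents:
            visit(ind, [])
        return order

    @classmethod
    def from_file(cls, path: str | Path) -> "Pedigree":
        """Read a 3-column (id, sire, dam) whitespace- or comma-separated table."""
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) < 3:
                    raise PedigreeError(f"{path}:{lineno}: expected 3 columns")
                if lineno == 1 and parts[0].lower() in {"id", "individual", "individual_id"}:
                    continue
                records.append((parts[0], parts[1], parts[2]))
        return cls(records)

    def relationship_matrix(self) -> pd.DataFrame:
        """Additive (numerator) relationship matrix A by the tabular method."""
        idx = {ind: k for k, ind in enumerate(self.order)}
        n = len(self.order)
        a = np.zeros((n, n))
        for i, ind in enumerate(self.order):
            sire, dam = self.parents[ind]
            si = idx[sire] if sire is not None else None
            di = idx[dam] if dam is not None else None
            for j in range(i):
                val = 0.0
                if si is not None:
                    val += 0.5 * a[j, si]
                if di is not None:
                    val += 0.5 * a[j, di]
                a[i, j] = a[j, i] = val
            a[i, i] = 1.0 + (0.5 * a[si, di] if si is not None and di is not None else 0.0)
        return pd.DataFrame(a, index=self.order, columns=self.order)


def f_ped(ped: Pedigree) -> pd.Series:
    """Per-individual pedigree inbreeding: half the parents' additive
    relationship; 0 when either parent is unknown."""
    a = ped.relationship_matrix()
    out = {}
    for ind in ped.order:
        sire, dam = ped.parents[ind]
        out[ind] = 0.5 * a.loc[sire, dam] if sire is not None and dam is not None else 0.0
    return pd.Series(out, name="f_ped")


# ---------------------------------------------------------------------
# Cross-comparison
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    correlation: float
    r_squared: float
    n: int


def coefficient_regression(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray) -> RegressionResult:
    """OLS of y on x with Pearson correlation and R^2 (= r^2 for simple OLS)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    if np.ptp(y) == 0:  # flat response: slope 0, nothing explained
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, len(x))
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        n=len(x),
    )


def inbreeding_table(
    ds: GenotypeDataset,
    segments: list[RohSegment],
    genome: GenomeSpec,
    pedigree: Pedigree | None = None,
) -> pd.DataFrame:
    """Per-sample table of f_hom, f_roh (genome-wide) and f_ped (if available)."""
    fh = f_hom(ds)
    fr, _ = f_roh(segments, genome, samples=ds.samples)
    out = pd.DataFrame({"f_hom": fh, "f_roh": fr})
    if pedigree is not None:
        fp = f_ped(pedigree)
        out["f_ped"] = fp.reindex(out.index)
    out.index.name = "sample_id"
    return out
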