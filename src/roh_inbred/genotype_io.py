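"""Reading, validating, filtering, and merging SNP genotype datasets.

Genotypes are held as a cohort-by-SNP matrix of codes
``0`` (homozygous for the A allele), ``1`` (heterozygous), ``2``
(homozygous for the B allele) and :data:`MISSING`.  A/B coding is by
lexicographic order of the alleles observed at each locus, so the
coding is a property of the data rather than of any external manifest.

All coordinates are 1-based inclusive, matching the MAP/VCF convention,
and only the 38 canine autosomes are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING: int = -1
N_AUTOSOMES: int = 38

SNP_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed (names the offending line)."""


class GenotypeDataError(ValueError):
    """Parsed data violate a dataset invariant (names the offending SNP)."""


@dataclass
class GenotypeDataset:
    """Cohort x SNP diploid genotype matrix with a physical SNP map.

    Parameters
    ----------
    samples
        Unique sample identifiers, one per matrix row.
    snps
        SNP map with columns ``snp_id, chromosome, position_bp,
        allele_a, allele_b``, sorted by (chromosome, position_bp).
    calls
        ``int8`` matrix of shape (n_samples, n_snps) with entries in
        {0, 1, 2, MISSING}.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeDataError("sample identifiers are not unique")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise GenotypeDataError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.samples)} samples, {len(self.snps)} SNPs)"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise GenotypeDataError("genotype codes outside {0,1,2,MISSING}")
        if len(self.snps):
            chrom = self.snps["chromosome"].to_numpy()
            pos = self.snps["position_bp"].to_numpy()
            if ((chrom < 1) | (chrom > N_AUTOSOMES)).any():
                raise GenotypeDataError("chromosome outside 1..38")
            if (pos < 1).any():
                raise GenotypeDataError("position_bp < 1")
            order = np.lexsort((pos, chrom))
            if not (order == np.arange(len(order))).all():
                raise GenotypeDataError("SNPs not sorted by (chromosome, position)")
            same_chrom = chrom[1:] == chrom[:-1]
            if (same_chrom & (np.diff(pos) <= 0)).any():
                raise GenotypeDataError("positions not strictly increasing within chromosome")
            if self.snps["snp_id"].duplicated().any():
                dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
                raise GenotypeDataError(f"duplicate snp_id {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        """New dataset keeping SNPs where ``mask`` is True (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            samples=list(self.samples),
            snps=self.snps.loc[mask, SNP_COLUMNS],
            calls=self.calls[:, mask],
        )


@dataclass(frozen=True)
class FilterSpec:
    """QC thresholds: SNPs with MAF <= ``maf_max_excluded`` are removed,
    SNPs with call rate < ``call_rate_min`` are removed."""

    maf_max_excluded: float = 0.01
    call_rate_min: float = 0.99

    def __post_init__(self) -> None:
        for name in ("maf_max_excluded", "call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------

def _read_map(map_path: Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeParseError(f"{map_path}:{lineno}: expected 4 MAP columns")
            chrom_str, snp_id, _cm, pos = parts[0], parts[1], parts[2], parts[3]
            try:
                chrom = int(chrom_str.removeprefix("chr"))
                pos_bp = int(pos)
            except ValueError as exc:
                raise GenotypeParseError(f"{map_path}:{lineno}: {exc}") from None
            rows.append((snp_id, chrom, pos_bp))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a PLINK text PED/MAP pair into a :class:`GenotypeDataset`.

    Alleles at each SNP are recoded A/B by lexicographic order of the
    observed allele characters; ``0 0`` becomes MISSING.  Non-autosomal
    rows (chromosome outside 1..38) are dropped with a logged count.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snp_map = _read_map(map_path)
    n_snps = len(snp_map)

    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2 x {n_snps} SNPs), found {len(parts)}"
                )
            samples.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype="U8").reshape(n_snps, 2))

    n_samples = len(samples)
    alleles = (
        np.stack(allele_rows, axis=0)
        if allele_rows
        else np.empty((0, n_snps, 2), dtype="U8")
    )

    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    allele_a = np.empty(n_snps, dtype="U8")
    allele_b = np.empty(n_snps, dtype="U8")
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise GenotypeDataError(
                f"SNP {snp_map['snp_id'].iat[j]!r}: >2 observed alleles {observed}"
            )
        a = observed[0] if observed else "A"
        b = observed[1] if len(observed) == 2 else a
        allele_a[j], allele_b[j] = a, b
        nonmiss = (col != "0").all(axis=1)
        if len(observed) == 2:
            calls[nonmiss, j] = (col[nonmiss] == b).sum(axis=1)
        else:  # monomorphic: every non-missing call is hom for the A allele
            calls[nonmiss, j] = 0

    snp_map["allele_a"] = allele_a
    snp_map["allele_b"] = allele_b

    autosomal = (snp_map["chromosome"] >= 1) & (snp_map["chromosome"] <= N_AUTOSOMES)
    n_dropped = int((~autosomal).sum())
    if n_dropped:
        logger.info("dropped %d non-autosomal SNPs", n_dropped)
    snp_map = snp_map.loc[autosomal].reset_index(drop=True)
    calls = calls[:, autosomal.to_numpy()]

    order = np.lexsort(
        (snp_map["position_bp"].to_numpy(), snp_map["chromosome"].to_numpy())
    )
    return GenotypeDataset(samples, snp_map.iloc[order][SNP_COLUMNS], calls[:, order])


def write_plink_text(ds: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP text files that round-trip through :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for row in ds.snps.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")
    a = ds.snps["allele_a"].to_numpy()
    b = ds.snps["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(ds.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            row = ds.calls[i]
            for j in range(ds.n_snps):
                c = row[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a[j], a[j]]
                elif c == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------

def read_vcf(vcf_path: str | Path) -> GenotypeDataset:
    """Read a VCF (v4.x, GT field) into a :class:`GenotypeDataset`.

    Multiallelic and non-SNP records are skipped with a logged count;
    REF/ALT become the lexicographically ordered A/B alleles.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    rows, call_cols = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        try:
            chrom = int(str(var.CHROM).removeprefix("chr"))
        except ValueError:
            n_skipped += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        codes = np.asarray(var.gt_types, dtype=np.int8)
        codes[codes == 3] = MISSING
        if alt < ref:  # recode so allele_a < allele_b lexicographically
            a, b = alt, ref
            flip = codes != MISSING
            codes[flip] = 2 - codes[flip]
        else:
            a, b = ref, alt
        rows.append((var.ID or f"{chrom}:{var.POS}", chrom, var.POS, a, b))
        call_cols.append(codes)
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP/non-autosomal records", n_skipped)

    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    calls = (
        np.stack(call_cols, axis=1)
        if call_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    autosomal = ((snps["chromosome"] >= 1) & (snps["chromosome"] <= N_AUTOSOMES)).to_numpy()
    snps, calls = snps.loc[autosomal], calls[:, autosomal]
    order = np.lexsort((snps["position_bp"].to_numpy(), snps["chromosome"].to_numpy()))
    return GenotypeDataset(samples, snps.iloc[order], calls[:, order])


def write_vcf(ds: GenotypeDataset, vcf_path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT only, using allele_a as REF."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(ds.snps["chromosome"].unique()):
            span = ds.snps.loc[ds.snps["chromosome"] == c, "position_bp"].max()
            fh.write(f"##contig=<ID={c},length={int(span) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ds.samples) + "\n")
        for j, row in enumerate(ds.snps.itertuples(index=False)):
            # monomorphic sites need a placeholder ALT nucleotide; the
            # B-allele count is zero either way so codes are unaffected
            alt = row.allele_b if row.allele_b != row.allele_a else (
                "C" if row.allele_a != "C" else "T"
            )
            gts = "\t".join(gt_map[int(c)] for c in ds.calls[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position_bp}\t{row.snp_id}\t"
                f"{row.allele_a}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------
# Frequencies, filtering, merging
# ---------------------------------------------------------------------

def allele_frequencies(ds: GenotypeDataset) -> np.ndarray:
    """Per-SNP frequency of the B allele among non-missing calls.

    SNPs with no non-missing calls get ``nan`` (and a logged warning).
    """
    calls = ds.calls
    nonmiss = calls != MISSING
    n_nonmiss = nonmiss.sum(axis=0)
    b_count = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_b = b_count / (2.0 * n_nonmiss)
    if (n_nonmiss == 0).any():
        logger.warning("%d SNPs have all calls missing; frequency undefined",
                       int((n_nonmiss == 0).sum()))
        p_b = np.where(n_nonmiss == 0, np.nan, p_b)
    return p_b


def minor_allele_frequencies(ds: GenotypeDataset) -> np.ndarray:
    p_b = allele_frequencies(ds)
    return np.minimum(p_b, 1.0 - p_b)


def filter_snps(ds: GenotypeDataset, spec: FilterSpec) -> GenotypeDataset:
    """Retain SNPs with MAF > ``maf_max_excluded`` and call rate >= ``call_rate_min``.

    Sample set and SNP order are unchanged; removal counts are logged
    per criterion.  Raises :class:`GenotypeDataError` if nothing survives.
    """
    maf = minor_allele_frequencies(ds)
    call_rate = (ds.calls != MISSING).sum(axis=0) / max(ds.n_samples, 1)
    pass_maf = np.nan_to_num(maf, nan=-1.0) > spec.maf_max_excluded
    pass_cr = call_rate >= spec.call_rate_min
    logger.info(
        "filter_snps: %d/%d removed for MAF <= %g, %d/%d removed for call rate < %g",
        int((~pass_maf).sum()), ds.n_snps, spec.maf_max_excluded,
        int((~pass_cr).sum()), ds.n_snps, spec.call_rate_min,
    )
    keep = pass_maf & pass_cr
    if not keep.any():
        raise GenotypeDataError("all SNPs removed by filtering")
    return ds.subset_snps(keep)


def merge_datasets(a: GenotypeDataset, b: GenotypeDataset) -> GenotypeDataset:
    """Merge two cohorts on the intersection of their SNP maps.

    SNPs are matched by ``snp_id`` and must agree on (chromosome,
    position); allele codes in ``b`` are flipped 0<->2 where its A/B
    labels are reversed relative to ``a``; SNPs with irreconcilable
    allele labels are dropped with a logged count.  Samples concatenate.
    """
    shared_samples = set(a.samples) & set(b.samples)
    if shared_samples:
        raise GenotypeDataError(f"shared sample identifiers: {sorted(shared_samples)}")

    ai = a.snps.set_index("snp_id")
    bi = b.snps.set_index("snp_id")
    common = ai.index.intersection(bi.index)
    if len(common) == 0:
        raise GenotypeDataError("no SNPs in common between datasets")

    a_pos = {sid: i for i, sid in enumerate(a.snps["snp_id"])}
    b_pos = {sid: i for i, sid in enumerate(b.snps["snp_id"])}

    keep_ids, flip_flags = [], []
    n_pos_mismatch = n_allele_drop = 0
    for sid in common:
        ra, rb = ai.loc[sid], bi.loc[sid]
        if (ra["chromosome"], ra["position_bp"]) != (rb["chromosome"], rb["position_bp"]):
            n_pos_mismatch += 1
            continue
        if (ra["allele_a"], ra["allele_b"]) == (rb["allele_a"], rb["allele_b"]):
            flip = False
        elif (ra["allele_a"], ra["allele_b"]) == (rb["allele_b"], rb["allele_a"]):
            flip = True
        elif {rb["allele_a"], rb["allele_b"]} <= {ra["allele_a"], ra["allele_b"]}:
            # b monomorphic with labels a subset of a's: codes already consistent
            flip = rb["allele_a"] == ra["allele_b"]
        else:
            n_allele_drop += 1
            continue
        keep_ids.append(sid)
        flip_flags.append(flip)
    if n_pos_mismatch:
        logger.warning("dropped %d SNPs with mismatched positions", n_pos_mismatch)
    if n_allele_drop:
        logger.warning("dropped %d SNPs with irreconcilable alleles", n_allele_drop)
    if not keep_ids:
        raise GenotypeDataError("no reconcilable SNPs in common between datasets")

    a_idx = np.array([a_pos[s] for s in keep_ids])
    b_idx = np.array([b_pos[s] for s in keep_ids])
    flips = np.array(flip_flags, dtype=bool)

    b_calls = b.calls[:, b_idx].copy()
    if flips.any():
        col = b_calls[:, flips]
        nm = col != MISSING
        col[nm] = 2 - col[nm]
        b_calls[:, flips] = col

    snps = a.snps.iloc[a_idx].reset_index(drop=True)
    calls = np.vstack([a.calls[:, a_idx], b_calls])
    order = np.lexsort((snps["position_bp"].to_numpy(), snps["chromosome"].to_numpy()))
    return GenotypeDataset(a.samples + b.samples, snps.iloc[order], calls[:, order])
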