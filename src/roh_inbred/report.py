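"""End-to-end pipeline: QC -> ROH -> islands -> inbreeding coefficients.

Outputs are TSV with a stable column order and fixed 6-decimal
formatting plus a JSON run manifest, so repeated runs from the same
inputs and configuration are byte-identical and any downstream stage
can be resumed from the files on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .genotype_io import (
    FilterSpec,
    GenotypeDataset,
    filter_snps,
    read_plink_text,
    read_vcf,
)
from .inbreeding import (
    GenomeSpec,
    Pedigree,
    coefficient_regression,
    f_roh,
    inbreeding_table,
)
from .roh_islands import (
    annotate_islands,
    call_islands,
    islands_to_frame,
    occurrence_threshold,
    snp_roh_incidence,
)
from .roh_scan import (
    RohParams,
    classify_roh,
    detect_roh,
    roh_summary,
    segments_to_frame,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, for the manifest."""

    out_dir: str | Path
    ped_path: str | Path | None = None
    map_path: str | Path | None = None
    vcf_path: str | Path | None = None
    pedigree_path: str | Path | None = None
    gene_annotation_path: str | Path | None = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    roh_params: RohParams = field(default_factory=RohParams)
    l_aut_override: int | None = None
    seed: int = 0

    def validate(self) -> None:
        has_plink = self.ped_path is not None and self.map_path is not None
        if not has_plink and self.vcf_path is None:
            raise ValueError("need either ped_path+map_path or vcf_path")
        for p in (self.ped_path, self.map_path, self.vcf_path,
                  self.pedigree_path, self.gene_annotation_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_pipeline(cfg: RunConfig, dataset: GenotypeDataset | None = None) -> Path:
    """Run QC, ROH detection, island calling and inbreeding coefficients.

    ``dataset`` may be passed directly (e.g. a simulated cohort),
    otherwise it is read from the configured input paths.  Returns the
    output directory; see the manifest there for the file inventory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            raise StageError(name, exc) from exc

    if dataset is None:
        cfg.validate()
        if cfg.vcf_path is not None:
            dataset = stage("load", lambda: read_vcf(cfg.vcf_path))
        else:
            dataset = stage("load", lambda: read_plink_text(cfg.ped_path, cfg.map_path))

    ds = stage("qc", lambda: filter_snps(dataset, cfg.filter_spec))

    segments = stage("roh_scan", lambda: detect_roh(ds, cfg.roh_params))
    seg_df = segments_to_frame(segments)
    _write_tsv(seg_df, out / "roh_segments.tsv")

    genome = GenomeSpec.from_dataset(ds, l_aut_override=cfg.l_aut_override)
    _write_tsv(classify_roh(segments), out / "roh_length_classes.tsv")
    _write_tsv(roh_summary(segments, by="sample"), out / "roh_summary_by_sample.tsv")
    _write_tsv(roh_summary(segments, by="chromosome"), out / "roh_summary_by_chromosome.tsv")
    _write_tsv(
        roh_summary(segments, by="cohort", l_aut=genome.l_aut),
        out / "roh_summary_cohort.tsv",
    )

    def islands_stage():
        inc = snp_roh_incidence(segments, ds)
        thr = occurrence_threshold(ds.n_samples)
        islands = call_islands(inc, ds, thr)
        return inc, thr, islands

    inc, thr, islands = stage("roh_islands", islands_stage)
    isl_df = islands_to_frame(islands)
    _write_tsv(isl_df, out / "roh_islands.tsv")
    inc_df = ds.snps[["snp_id", "chromosome", "position_bp"]].copy()
    inc_df["occurrence_count"] = inc
    _write_tsv(inc_df, out / "snp_roh_incidence.tsv")
    if cfg.gene_annotation_path is not None:
        _write_tsv(
            stage("annotate", lambda: annotate_islands(islands, cfg.gene_annotation_path)),
            out / "island_genes.tsv",
        )

    pedigree = (
        stage("pedigree", lambda: Pedigree.from_file(cfg.pedigree_path))
        if cfg.pedigree_path is not None
        else None
    )
    coef = stage(
        "inbreeding", lambda: inbreeding_table(ds, segments, genome, pedigree)
    )
    _write_tsv(coef, out / "inbreeding.tsv", index=True)
    _, per_chrom = f_roh(segments, genome, samples=ds.samples)
    per_chrom.index.name = "sample_id"
    _write_tsv(per_chrom, out / "f_roh_by_chromosome.tsv", index=True)

    reg_rows = []
    pairs = [("f_hom", "f_roh")]
    if pedigree is not None:
        pairs += [("f_hom", "f_ped"), ("f_roh", "f_ped")]
    for xcol, ycol in pairs:
        try:
            r = coefficient_regression(coef[xcol], coef[ycol])
            reg_rows.append((xcol, ycol, r.slope, r.intercept, r.correlation, r.r_squared, r.n))
        except ValueError as exc:
            logger.warning("regression %s~%s skipped: %s", ycol, xcol, exc)
    _write_tsv(
        pd.DataFrame(
            reg_rows,
            columns=["x", "y", "slope", "intercept", "correlation", "r_squared", "n"],
        ),
        out / "coefficient_regressions.tsv",
    )

    manifest = {
        "software": "roh-inbred",
        "version": __version__,
        "seed": cfg.seed,
        "filter_spec": dataclasses.asdict(cfg.filter_spec),
        "roh_params": dataclasses.asdict(cfg.roh_params),
        "l_aut": genome.l_aut,
        "l_aut_override": cfg.l_aut_override,
        "island_threshold": thr,
        "n_samples": ds.n_samples,
        "n_snps_after_qc": ds.n_snps,
        "n_roh_segments": len(segments),
        "n_islands": len(isl_df),
        "inputs": {
            k: str(getattr(cfg, k)) if getattr(cfg, k) is not None else None
            for k in ("ped_path", "map_path", "vcf_path", "pedigree_path",
                      "gene_annotation_path")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
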