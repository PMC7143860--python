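"""Simulate the study cohort: 34 dogs of mixed relatedness on a
38-autosome, 2.2 Gb genome at SNP-array density (~100k markers).

All matings draw their parents from a small shared base population
(8 founders), emulating a closed studbook, and the cohort mixes mating
designs (12 outbred-by-design, 10 cousin-mating, 7 half-sib-mating,
5 full-sib-mating offspring) so the three inbreeding coefficients span
a realistic range.  Genotypes (PED/MAP), the pedigree, exact
autozygosity truth, and a synthetic gene annotation are written under
scratch/ for the downstream stages.
"""

from pathlib import Path

import numpy as np

from roh_inbred.genotype_io import write_plink_text
from roh_inbred.inbreeding import Pedigree
from roh_inbred.synthetic_data import (
    SimConfig,
    full_chrom_lengths_bp,
    gene_drop,
    simulate_founders,
    write_truth_tsv,
)

SEED = 20260927
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"

DESIGN_MIX = [("unrelated", 12), ("cousin_mating", 10),
              ("half_sib_mating", 7), ("full_sib_mating", 5)]


N_BASE_FOUNDERS = 8


def mixed_pedigree(rng):
    """Pedigree whose family parents all descend from a shared base
    population, like litters of a closed studbook breed."""
    records = [(f"base{i}", "0", "0") for i in range(N_BASE_FOUNDERS)]
    focal = []

    def pick2():
        i, j = rng.choice(N_BASE_FOUNDERS, size=2, replace=False)
        return f"base{i}", f"base{j}"

    fam = 0
    for design, n in DESIGN_MIX:
        for _ in range(n):
            f = f"fam{fam:03d}"
            o = f"{f}_dog"
            if design == "unrelated":  # outbred by design, not by descent
                records.append((o, *pick2()))
            elif design == "full_sib_mating":
                a, b = pick2()
                records += [(f"{f}_S", a, b), (f"{f}_D", a, b),
                            (o, f"{f}_S", f"{f}_D")]
            elif design == "half_sib_mating":
                a, b = pick2()
                c = f"base{rng.integers(N_BASE_FOUNDERS)}"
                records += [(f"{f}_S", a, b), (f"{f}_D", a, c),
                            (o, f"{f}_S", f"{f}_D")]
            else:  # cousin_mating
                a, b = pick2()
                c, d = pick2()
                records += [(f"{f}_P", a, b), (f"{f}_Q", a, b),
                            (f"{f}_X", f"{f}_P", c), (f"{f}_Y", f"{f}_Q", d),
                            (o, f"{f}_X", f"{f}_Y")]
            focal.append(o)
            fam += 1
    return Pedigree(records), focal


def synthetic_gene_annotation(cfg, rng, path, n_genes=1500):
    """Synthetic gene intervals (uniformly placed, 5-100 kb) for the
    island-annotation stage; names are arbitrary placeholders."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        g = 0
        for c, length in enumerate(cfg.chromosome_lengths_bp, start=1):
            n_c = int(round(n_genes * length / sum(cfg.chromosome_lengths_bp)))
            starts = np.sort(rng.integers(1, length - 100_000, size=n_c))
            for s in starts:
                g += 1
                e = int(s + rng.integers(5_000, 100_000))
                fh.write(f"{c}\tsim\tgene\t{s}\t{e}\t.\t+\t.\t"
                         f"ID=g{g};Name=SIMG{g:04d}\n")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(
        chromosome_lengths_bp=full_chrom_lengths_bp(),
        snp_density_per_mb=46.0,
        pedigree_design="custom",
        n_offspring=34,
        seed=SEED,
    )
    rng = np.random.default_rng(cfg.seed)
    pool = simulate_founders(cfg, rng)
    ped, focal = mixed_pedigree(rng)
    ds, tracks = gene_drop(ped, pool, cfg, rng, keep=focal)

    write_plink_text(ds, OUT / "cohort.ped", OUT / "cohort.map")
    with open(OUT / "pedigree.txt", "w") as fh:
        for ind in ped.order:
            sire, dam = ped.parents[ind]
            fh.write(f"{ind} {sire or 0} {dam or 0}\n")
    write_truth_tsv({k: tracks[k] for k in focal}, OUT / "truth.tsv")
    synthetic_gene_annotation(cfg, rng, OUT / "genes_synthetic.gff3")

    fracs = [tracks[k].true_autozygosity_fraction for k in focal]
    print(f"cohort: {ds.n_samples} dogs x {ds.n_snps} SNPs on "
          f"{cfg.n_chromosomes} autosomes ({sum(cfg.chromosome_lengths_bp):,} bp)")
    print(f"true autozygosity: mean {np.mean(fracs):.4f}, "
          f"range {min(fracs):.4f}-{max(fracs):.4f}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
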