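"""Validate F_ROH against exact simulated truth: 200 gene-dropped
full-sib-mating offspring on the fast 5-chromosome / 200 Mb genome with
a dense (50 SNPs/Mb) noise-free map.

Checks that mean true autozygosity sits at the pedigree expectation of
0.25 and that per-individual F_ROH tracks true autozygosity closely.
Writes results/validation_recovery.tsv (per-individual estimate vs
truth) and prints the summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from roh_inbred.inbreeding import GenomeSpec, f_roh
from roh_inbred.roh_scan import RohParams, detect_roh
from roh_inbred.synthetic_data import SimConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    cfg = SimConfig(seed=0)  # full-sib design, 200 offspring, fast genome
    ds, tracks, _ = simulate_cohort(cfg)
    segments = detect_roh(ds, RohParams())
    est, _ = f_roh(segments, GenomeSpec.from_dataset(ds), samples=ds.samples)

    true = np.array([tracks[s].true_autozygosity_fraction for s in ds.samples])
    err = est.to_numpy() - true
    table = pd.DataFrame(
        {"sample_id": ds.samples, "f_roh": est.to_numpy(),
         "true_autozygosity": true, "error": err}
    )
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "validation_recovery.tsv", sep="\t",
                 index=False, float_format="%.6f")

    print(f"mean true autozygosity: {true.mean():.4f} (pedigree expectation 0.25)")
    print(f"mean |F_ROH - truth|:   {np.abs(err).mean():.4f}")
    print(f"within +/-0.03:         {np.mean(np.abs(err) <= 0.03):.1%} of offspring")
    print(f"written {RESULTS / 'validation_recovery.tsv'}")


if __name__ == "__main__":
    main()
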