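#!/usr/bin/env python
"""Generate the study-like synthetic cohort used by the downstream
analysis steps: a miRNA reference (hairpins, partner strands, three
co-regulated clusters), a 4-group x 6-replicate count matrix with six
planted perinatal fold-changes, and a small FASTQ demonstration subset.

Writes results/cohort/{reference.fa,reference.tsv,counts_raw.tsv} plus
results/cohort/fastq_demo/ for the read-processing step.
"""

from pathlib import Path

from mirvar import experiments as ex
from mirvar import normalize as norm
from mirvar import simulate

SEED = 20180328
OUT = Path("results/cohort")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bundle = ex.study_bundle(SEED)
    simulate.write_reference(bundle.reference, OUT / "reference.fa", OUT / "reference.tsv")
    norm.write_count_matrix(bundle.counts, OUT / "counts_raw.tsv")
    print(f"cohort: {len(bundle.reference.matures)} mature strands, "
          f"{bundle.counts.counts.shape[1]} libraries")
    print(f"planted perinatal strands: {', '.join(bundle.planted_strands)}")
    print("planted fold-changes:",
          {m: e.fce for m, e in bundle.config.planted_effects.items()})

    # small separate cohort for the read-level demonstration (step 02)
    demo_cfg = simulate.SimConfig(
        n_groups=2, n_hairpins=12, baseline_log_mean=3.2, baseline_log_sd=1.0,
        junk_fraction=0.05, rng_seed=SEED,
    )
    demo_ref = simulate.make_reference(demo_cfg)
    demo_counts = simulate.simulate_counts(demo_ref, demo_cfg)
    barcodes = simulate.default_barcodes(list(demo_counts.counts.columns))
    fq = OUT / "fastq_demo"
    fq.mkdir(exist_ok=True)
    simulate.write_reference(demo_ref, fq / "reference.fa", fq / "reference.tsv")
    norm.write_count_matrix(demo_counts, fq / "counts_true.tsv")
    import pandas as pd

    pd.DataFrame(
        {
            "library": list(barcodes),
            "barcode": list(barcodes.values()),
            "group": list(demo_counts.groups),
        }
    ).to_csv(fq / "barcodes.tsv", sep="\t", index=False)
    reads = simulate.simulate_reads(demo_counts, demo_ref, barcodes=barcodes, config=demo_cfg)
    for lib, recs in reads.items():
        simulate.write_fastq(recs, fq / f"{lib}.fastq")
    total = sum(len(r) for r in reads.values())
    print(f"read-level demo: {total} reads across {len(reads)} libraries (5% junk)")


if __name__ == "__main__":
    main()
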