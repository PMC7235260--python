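#!/usr/bin/env python
"""Simulate the synthetic study cohort and write its input files.

Builds a genome of 50 TADs with planted A/B chromatin classes, one TF with a
planted 10 kb decay distance, a 200-sample expression cohort coupled to the
TF's regulatory potential, a perturbation DE table, H3K27ac signal, eQTLs,
Hi-C contacts and a trait SNP set — every file format the downstream analyses
consume, with the ground truth recorded alongside.
"""

import argparse
from pathlib import Path

from cisrange import synthetic as syn
from cisrange.genome_io import write_gene_annotation, write_intervals
from cisrange.pipeline import write_tsv

DELTA_TRUE = 10_000.0


def main(seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    layout, ab = syn.make_genome(syn.SimConfig(seed=seed))
    tf_ids = [f"TF{i:02d}" for i in range(8)]
    targets = syn.partition_target_tads(layout, tf_ids, seed=seed + 1)
    cfgs = [
        syn.TfSimConfig(tf, delta_true=DELTA_TRUE, target_tads=targets[tf],
                        concentration=10.0)
        for tf in tf_ids
    ]
    peaksets = syn.make_peaks(layout, cfgs, seed=seed + 2)
    beta = syn.calibrate_beta(layout, peaksets[0], DELTA_TRUE)
    expr, tf_row = syn.make_expression(layout, peaksets[0], DELTA_TRUE,
                                       beta=beta, seed=seed + 3)
    de, de_table = syn.make_perturbation(layout, peaksets[0], DELTA_TRUE,
                                         seed=seed + 4)
    signal = syn.make_h3k27ac(layout, ab, seed=seed + 5)
    eqtls = syn.make_eqtls(layout, ab, seed=seed + 6)
    contacts = syn.make_contacts(layout, ab, seed=seed + 7)
    snps = syn.make_snps(layout, targets[tf_ids[0]], seed=seed + 8)

    import pandas as pd
    tad_df = pd.DataFrame(
        [(t.chrom, t.start, t.end, t.tad_id) for t in layout.tads],
        columns=["chrom", "start", "end", "name"],
    )
    write_intervals(tad_df, out / "tads.bed", comments=[f"seed={seed}"])
    write_gene_annotation(layout.genes, out / "genes.tsv")
    for ps in peaksets:
        write_intervals(ps.peaks.assign(name=ps.sample_id),
                        out / f"peaks_{ps.sample_id}.bed")
    write_tsv(expr, out / "expression.tsv")
    write_tsv(de_table, out / "perturbation.tsv", index=False)
    write_tsv(signal, out / "h3k27ac.tsv")
    write_tsv(eqtls, out / "eqtls.tsv", index=False)
    write_tsv(contacts, out / "contacts.tsv", index=False)
    write_tsv(snps, out / "snps.tsv", index=False)
    truth = syn.GroundTruth(
        syn.SimConfig(seed=seed), ab_labels=ab,
        delta_true={tf: DELTA_TRUE for tf in tf_ids}, target_tads=targets,
        extras={"beta": beta, "tf_expression_row": tf_row},
    )
    write_tsv(truth.to_frame(), out / "ground_truth.tsv", index=False)

    n_a = sum(1 for v in ab.values() if v == "A")
    print(f"simulated {len(layout.tads)} TADs ({n_a} A-type, "
          f"{len(layout.tads) - n_a} B-type), {len(layout.genes)} genes, "
          f"{len(peaksets)} TF samples, {expr.shape[1]} expression samples")
    print(f"planted decay distance {DELTA_TRUE / 1000:.0f} kb, "
          f"calibrated beta {beta:.5f}, {len(de.genes)} DE genes")
    print(f"inputs written to {out}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    a = ap.parse_args()
    main(a.seed, a.out)
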