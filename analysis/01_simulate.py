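"""Simulate the staged single-cell study design and write all inputs.

Generates the default population (9 ICM, 3 epiblast, 2+3+2 outgrowth,
12 ESC cells), the outgrowth qPCR marker panel and the miRNA fixture, and
writes counts, Ct and target tables plus planted truth under results/sim/.
"""

import argparse
from pathlib import Path

import pandas as pd

from sctrace import synthdata as sd


def main(seed: int, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    config, truth = sd.default_config(seed=seed)
    cm, truth = sd.generate_counts(config, truth)
    cm.to_tsv(out / "counts.tsv")
    cm.to_mtx(str(out / "counts"))
    cm.library_size.to_frame("library_size").join(cm.stage).to_csv(
        out / "cells.tsv", sep="\t"
    )
    pd.Series(truth.planted_de_genes, name="true_fold").to_csv(
        out / "truth_de_genes.tsv", sep="\t"
    )
    pd.Series(list(truth.anticorrelated_genes)).to_csv(
        out / "truth_anticorrelated.tsv", sep="\t", index=False, header=False
    )
    print(f"count matrix: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} cells")
    print(f"stages: {cm.stage.value_counts().to_dict()}")
    print(f"planted DE genes: {len(truth.planted_de_genes)}; "
          f"anti-correlated genes: {len(truth.anticorrelated_genes)}")

    ctm = sd.generate_ct_matrix(sd.default_ct_design(), seed=seed)
    ctm.to_csv(out / "ct_matrix.csv")
    print(f"Ct panel: {ctm.ct.shape[0]} genes x {ctm.ct.shape[1]} cells")

    profile, targets, mtruth = sd.generate_mirna_fixture(
        n_mirnas=330, seed=seed,
        planted_folds=sd.default_mirna_folds(n_differential=51, seed=seed),
    )
    profile.to_csv(out / "mirna_profile.tsv", sep="\t")
    targets.to_csv(out / "mirna_targets.tsv", sep="\t", index=False)
    pd.Series(list(mtruth.mirna_class_genes)).to_csv(
        out / "truth_mirna_class.tsv", sep="\t", index=False, header=False
    )
    print(f"miRNA profile: {profile.shape[0]} miRNAs x {profile.shape[1]} replicates; "
          f"target table: {len(targets)} predictions from 3 algorithms")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/sim")
    a = ap.parse_args()
    main(a.seed, a.out)
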