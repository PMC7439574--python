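#!/usr/bin/env python
"""Knockout-vs-control differential filters on simulated array and RNA data.

Simulates an EPIC-style beta matrix with planted hyper/hypomethylated probes
(plus X/Y and SNP-flagged probes that must be excluded first) and an RPM
expression table with planted fold changes, then applies the |delta beta| >
0.2 and |log2FC| > 2 filters and compares the recovered counts with the
planted truth.
"""

import argparse
from pathlib import Path

import pandas as pd

from methamp import (
    differential_cpgs,
    differential_genes,
    filter_probes,
    simulate_beta_matrix,
    simulate_expression_table,
)
from methamp.io import write_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-probes", type=int, default=10_000)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    betas, annotation, truth = simulate_beta_matrix(
        n_probes=args.n_probes, n_hyper=150, n_hypo=120,
        effect=0.3, noise_sd=0.02, seed=args.seed,
    )
    ko = dict(zip(betas["probe_id"], betas["beta_ko"]))
    wt = dict(zip(betas["probe_id"], betas["beta_wt"]))
    retained = filter_probes(ko, wt, annotation)
    dm = differential_cpgs(ko, wt, retained)
    planted_hyper = (truth.planted == "hyper").sum()
    planted_hypo = (truth.planted == "hypo").sum()
    print(
        f"methylation: {args.n_probes} probes, {len(retained)} after X/Y+SNP "
        f"exclusion; |delta beta| > {dm.threshold}: "
        f"{dm.n_hyper} hyper (planted {planted_hyper}), "
        f"{dm.n_hypo} hypo (planted {planted_hypo})"
    )

    expr, expr_truth = simulate_expression_table(
        n_genes=args.n_probes, n_up=30, n_down=25, fold=8.0, seed=args.seed + 1
    )
    de = differential_genes(
        dict(zip(expr["gene"], expr["rpm_ko"])),
        dict(zip(expr["gene"], expr["rpm_wt"])),
    )
    print(
        f"expression: {len(expr)} genes; |log2FC| > {de.log2fc_threshold}: "
        f"{de.n_up} up (planted {(expr_truth.planted == 'up').sum()}), "
        f"{de.n_down} down (planted {(expr_truth.planted == 'down').sum()})"
    )

    rows = [{"probe_id": p, "direction": "hyper"} for p in dm.hyper_ids]
    rows += [{"probe_id": p, "direction": "hypo"} for p in dm.hypo_ids]
    write_table(
        pd.DataFrame(rows, columns=["probe_id", "direction"]),
        args.out_dir / "differential_cpgs.csv",
        sort_by=["probe_id"],
    )
    hits = de.table[abs(de.table.log2fc) > de.log2fc_threshold]
    write_table(hits, args.out_dir / "differential_genes.csv", sort_by=["gene"])
    print(f"wrote {args.out_dir}/differential_cpgs.csv and differential_genes.csv")


if __name__ == "__main__":
    main()
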