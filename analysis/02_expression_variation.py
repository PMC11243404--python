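#!/usr/bin/env python
"""Expression normalization, variance ranking, and the TF-venom network.

Combines left/right gland replicates per individual, normalizes with
median-of-ratios size factors, ranks genes by expression variance across all
samples and within the focal lineage, contrasts venom-gene vs background
variance with a Welch t-test, and builds the significance-filtered (p<0.05,
FDR<0.1) TF-venom Pearson correlation matrix. Tables land in
results/expression/.
"""

import argparse
import importlib
from pathlib import Path

import pandas as pd

from regnet.expression import (
    combine_glands,
    expression_variance,
    normalize,
    tf_venom_correlation,
    top_variable_genes,
    variance_group_test,
)

ROOT = Path(__file__).resolve().parents[1]
sim = importlib.import_module("01_simulate_bundle")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    from regnet.simulate import build_bundle
    bundle = build_bundle(sim.study_config(), seed=args.seed)
    out = ROOT / "results" / "expression"
    out.mkdir(parents=True, exist_ok=True)

    # gland combining on the replicate matrices, then normalization
    gl = bundle.gland_counts
    both = pd.concat([gl["left"].add_suffix("_L"), gl["right"].add_suffix("_R")], axis=1)
    meta = {m.sample_id: m for m in bundle.gland_meta}
    combined, _ = combine_glands(both, list(meta.values()))
    assert combined.reindex(columns=bundle.counts.columns).equals(bundle.counts.loc[combined.index])

    norm = normalize(bundle.counts)
    norm.values.to_csv(out / "normalized.tsv", sep="\t", float_format="%.6g")

    focal = [s for s in bundle.samples if s.startswith("viridis")]
    var_all = expression_variance(norm)
    var_within = expression_variance(norm, samples=focal) if len(focal) >= 2 else None
    table = pd.DataFrame({"across": var_all})
    if var_within is not None:
        table["within_focal"] = var_within
    table.to_csv(out / "expression_variance.tsv", sep="\t", float_format="%.6g")

    venom_var = var_all.loc[bundle.venom_genes]
    bg_var = var_all.loc[[g for g in norm.values.index if g.startswith("BG")]]
    t, p = variance_group_test(venom_var, bg_var)
    print(f"venom vs background variance: t = {t:.2f}, p = {p:.3g}")
    print("top variable genes:", ", ".join(top_variable_genes(var_all, 5)))

    corr = tf_venom_correlation(norm, bundle.tf_genes, bundle.venom_genes)
    corr.rho.to_csv(out / "tf_venom_rho.tsv", sep="\t", float_format="%.4f")
    corr.significant.astype(int).to_csv(out / "tf_venom_significant.tsv", sep="\t")
    n_sig = int(corr.significant.to_numpy().sum())
    print(f"significant TF-venom correlations (p<0.05, FDR<0.1): {n_sig} "
          f"of {corr.rho.size} pairs")
    if n_sig:
        stacked = corr.rho.where(corr.significant).stack().dropna()
        tf, gene = stacked.abs().idxmax()
        print(f"strongest: {tf} ~ {gene}, rho = {stacked.loc[(tf, gene)]:.2f}")


if __name__ == "__main__":
    main()
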