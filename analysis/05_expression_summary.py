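#!/usr/bin/env python
"""Dot-plot summaries and cluster comparisons for GRIA2 expression.

Generates the synthetic stand-in for the macaque retina single-cell
dataset (per-cluster zero-inflated log(TPM+1) values for the AMPAR
subunit gene GRIA2), summarizes each cluster (mean, SD, percent
expressing), computes ratio-of-means fold differences between ganglion
cell clusters and the AII-amacrine cluster, and runs Bonferroni-
corrected unpaired t-tests.
"""
import pandas as pd

from synconduct.expression import (
    cluster_summary,
    compare_clusters,
    default_expression_spec,
    generate_expression_matrix,
    logfold_between_means,
)
from _util import RESULTS

SEED = 1
matrix = generate_expression_matrix(default_expression_spec(n_per_cluster=2000, seed=SEED))

clusters = ("MG_OFF", "MG_ON", "PG_OFF", "PG_ON", "AII")
summaries = {c: cluster_summary(matrix, "GRIA2", c) for c in clusters}
df = pd.DataFrame(
    {
        "cluster": clusters,
        "mean_log_tpm1": [round(summaries[c].mean_log_expr, 2) for c in clusters],
        "sd_log_tpm1": [round(summaries[c].sd_log_expr, 2) for c in clusters],
        "pct_expressing": [round(summaries[c].pct_expressing, 1) for c in clusters],
        "n_cells": [summaries[c].n_cells for c in clusters],
    }
)
df.to_csv(RESULTS / "gria2_cluster_summary.tsv", sep="\t", index=False)
print(df.to_string(index=False))

aii_mean = summaries["AII"].mean_log_expr
print("\nGRIA2 fold differences vs AII-amacrine (ratio of mean log(TPM+1)):")
for gc in ("MG_OFF", "MG_ON", "PG_OFF", "PG_ON"):
    fold = logfold_between_means(summaries[gc].mean_log_expr, aii_mean)
    comp = compare_clusters(matrix, "GRIA2", gc, "AII", m_comparisons=4)
    print(f"  {gc}: {fold:.2f} (adjusted p = {comp.p_adjusted:.2g})")
print(
    "\nParasol Off vs On fold difference "
    f"{logfold_between_means(summaries['PG_OFF'].mean_log_expr, summaries['PG_ON'].mean_log_expr):.2f} "
    f"(printed group means 0.90/0.85 give {logfold_between_means(0.90, 0.85):.2f}): "
    "ganglion-cell clusters express GRIA2 strongly and similarly, the "
    "AII-amacrine cluster weakly — consistent with calcium-permeable AMPA "
    "receptors residing on AII cells rather than on the ganglion cells."
)
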