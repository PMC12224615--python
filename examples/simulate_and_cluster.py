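"""Simulate a 3-cluster, 2-batch single-cell dataset and cluster it.

Generates counts with planted cell-type labels and a technical batch
shift, runs the full pipeline (normalize -> HVG -> grid filter ->
autoencoder -> Louvain init -> iterative optimization), and scores the
result against the planted truth.
"""

from gdesce import RunConfig, SyntheticConfig, generate, run_pipeline

counts, _ = generate(SyntheticConfig(seed=0))
print(f"simulated {counts.n_cells} cells x {counts.n_genes} genes, "
      f"{len(set(counts.truth))} planted populations, "
      f"{len(set(counts.batch))} batches")

out = run_pipeline(counts, RunConfig(seed=0))
r = out.report

# ARI = 1 means the planted populations were recovered exactly (on the
# cells the grid filter retained); batch KL near 0 means every cluster
# reproduces the global batch mix, i.e. clusters are not batch-driven.
print(f"clusters found (Louvain init): K = {r.K}")
print(f"epochs until label changes < {out.config.tol_threshold:.3f}: {r.n_epochs}")
print(f"cells removed by the grid filter: {r.n_outliers_removed}")
print(f"ARI vs planted labels: {r.ari:.4f}")
print(f"batch-mixing KL (final): {r.batch_kl:.5f}")
print(f"batch-mixing KL (Louvain init): {out.initial_batch_kl:.5f}")
print(f"mean label entropy: {r.mean_entropy:.5f} (0 = fully confident)")
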