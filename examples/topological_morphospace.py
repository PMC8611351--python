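"""Topological morphospace of a synthetic population, plus area regression.

Each leaf becomes a zero-padded vector of sorted bar lengths; centered PCA
of those vectors spans the morphospace.  PC1 tracks leaf size, PC2 furrow
depth, and a linear regression of blade area on the first two PCs measures
how strongly shape encodes area.
"""

import leafmorph as lm

bundle = lm.run_pipeline(lm.RunConfig(
    source="synthetic", n_synthetic=100, mode="topological",
    out_dir="scratch/topo_demo", seed=7))

topo = bundle["topological"]
evr = topo["pca"].explained_variance_ratio
print(f"pad length L = {topo['pad_length']}")
print(f"PC1 explains {evr[0]:.1%} of variance, PC2 {evr[1]:.1%}")
print(f"area ~ PC1 + PC2 regression: "
      f"R^2 = {topo['regression']['r_squared']:.3f}")
print(bundle["areas"]["group"].value_counts().sort_index().to_string())
# leaves increase in area along PC1; the four area groups (<=8, 8-16,
# 16-24, >24 cm^2) separate obliquely in the (PC1, PC2) plane
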