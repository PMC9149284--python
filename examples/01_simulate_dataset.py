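"""Generate a synthetic dataset with planted regulatory structure.

Builds the default study design — 3 nitrate conditions x 3 replicates, 30
TF, 20 miRNA, 10 cis- and 10 trans-lncRNA edges among 100 flat decoys —
and writes the fixture bundle (genome, GFF3, counts, sequences, truth).
"""

from lmrnet import SimulationConfig, simulate, write_fixture

cfg = SimulationConfig(seed=1)
ds = simulate(cfg)
paths = write_fixture(ds, "example_fixture")

print(f"genome length       : {len(ds.genome):,} bp")
print(f"annotated features  : {len(ds.annotation)}")
print(f"mRNA/TF/lncRNA rows : {len(ds.counts.feature_ids)}")
print(f"miRNA rows          : {len(ds.mirna_counts.feature_ids)}")
print(f"planted edges       : {len(ds.truth.edges)}")
print(f"expected DE features: {len(ds.truth.expected_de_features)}")
print(f"files written       : {len(paths)} (in example_fixture/)")
# The planted-edge table is the ground truth every downstream stage is
# scored against; expected DE features are those whose latent trajectory
# changes >= 2-fold against the first condition.
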