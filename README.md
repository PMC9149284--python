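# lmrnet

**lncRNA–miRNA–mRNA regulatory network construction from expression
profiles, with a planted-truth simulator.**

Plant nutrient studies (the motivating system is nitrate response in plant
roots, profiled under three nitrate regimes with three replicates each)
routinely integrate three RNA-seq layers — mRNA, small RNA and lncRNA —
into one regulatory network. `lmrnet` implements that integration as a
reusable, fully testable pipeline for anyone working from post-alignment
count tables rather than raw reads:

1. **Differential expression** — FPKM for mRNA/lncRNA, TPM for small RNA;
   per-contrast calls at |FC| ≥ 2 and Benjamini–Hochberg FDR < 0.05 (Welch
   t-test on log2(normalized + 1)).
2. **lncRNA targeting** — positional classes (lincRNA / intronic /
   antisense / sense); *cis* targets as genes within 10 kb of the locus;
   *trans* targets as DE lncRNA–gene pairs with Pearson r ≤ −0.9 and
   opposite differential calls.
3. **miRNA targeting** — plant-rule complementarity scoring (Watson–Crick
   0, G:U wobble 0.5, mismatch 1, indel 2 per base, positions 2–13
   doubled, ≤ 1 bulge, cutoff 4.0) plus coherent/noncoherent pairing of DE
   miRNAs with DE targets.
4. **TF regulation** — TF–gene pairs at |PCC| > 0.8 and p < 0.05, gated on
   a binding-element hit in the 2-kb promoter.
5. **Network assembly** — typed directed edges (`tf_binding`,
   `mirna_cleavage`, `lnc_cis`, `lnc_trans`) exported as edge TSV, SIF and
   GraphML, with precision/recall scoring against a known edge set.

Because the interesting claims of such an analysis are about *rules and
thresholds*, the package ships a first-class synthetic-data generator
(`lmrnet.sim`) that emits a complete dataset — genome FASTA, GFF3,
promoter/transcript/miRNA sequences, negative-binomial count matrices and
the planted regulatory truth — so every stage can be verified end to end
without any sequencing data.

## Worked example

```python
from lmrnet import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(outdir="example_run", seed=1, simulate=SimulationConfig())
res = run_pipeline(cfg)
print(res.network.role_counts())
for mech, m in res.recovery.items():
    print(mech, m["precision"], m["recall"])
```

prints (seed 1, default design: 30 TF, 20 miRNA, 10 cis, 10 trans planted
edges among 100 decoy features):

```
{'mRNA': 70, 'lncRNA': 20, 'miRNA': 20, 'TF': 30}
overall 1.0 1.0
tf_binding 1.0 1.0
mirna_cleavage 1.0 1.0
lnc_cis 1.0 1.0
lnc_trans 1.0 1.0
```

i.e. the assembled network contains 70 edges over 140 nodes, and every
planted regulatory interaction — and nothing else — was recovered:
precision and recall of 1.0 per mechanism. The same run writes each
stage's TSV table, `network.sif` / `network.graphml` for Cytoscape, and a
`manifest.json` recording the config hash, seed and per-stage row counts;
reruns with the same config and seed are byte-identical.

The `examples/` directory holds one short script per capability
(simulation, differential expression, lncRNA targets, miRNA targets, TF
pairs, full network); each prints what it computes and what the numbers
mean.

## Command line

```bash
lmrnet simulate sim.yaml --outdir fixture/   # write a synthetic bundle
lmrnet run config.yaml                       # full pipeline from YAML
lmrnet recover --edges run/network_edges.tsv --truth fixture/truth_edges.tsv
lmrnet version
```

The YAML config surfaces every threshold of the method
(`fc_threshold`, `fdr_threshold`, `pcc_threshold`, `p_threshold`,
`trans_r_threshold`, `cis_window_bp`, `mirna_cutoff`, `promoter_length`,
`small_rna_min/max`, `trans_correlation_mode`, `require_motif`) with the
defaults above, plus either an `inputs:` block of file paths or a
`simulate:` block embedding the generator configuration.

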