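# morphnet

Correlation-network clustering and enrichment analysis of patient
morphometry cohorts.

Given a table of MRI scans (raw morphometric measurements plus clinical
metadata), the pipeline:

1. **preprocesses** — normalizes each parameter by its registered
   denominator (total brain volume, body weight, or head angle), routes
   ventricle height into a categorical septal-integrity descriptor, and
   median-centers every parameter (ratio mode by default);
2. **correlates** — computes all-pairs Pearson correlations between scan
   profiles and keeps pairs with r above a threshold (default r > 0.7) as a
   weighted undirected graph, tracking scans left without any edge;
3. **clusters** — runs a from-scratch Markov clustering (MCL)
   implementation (default inflation 2.2, minimum cluster size 3) with a
   literal dense oracle kept for verification;
4. **enriches** — tests every cluster (and every diagnostic-class set) for
   over-representation of categorical descriptors (breed, breed group,
   craniofacial category, age category, sex/neuter status, septal
   integrity, clade) with exact one-sided hypergeometric p-values and
   Benjamini–Hochberg adjustment per category;
5. **estimates risk** — odds ratio / relative risk with exact two-sided
   Fisher p and Woolf or conditional-exact confidence intervals for a
   configurable exposure × outcome 2×2 contrast.

A synthetic-cohort generator with planted archetypes (including an
"aged-brain" motif), breed-linked demographics and a programmable
neuter-status × tumour odds ratio makes every stage testable without
clinical data, and `recovery_experiment` quantifies how well the pipeline
recovers the planted structure.

## CLI

```bash
# generate a synthetic cohort
morphnet simulate --seed 1 --n-scans 286 --out sim/

# full pipeline (writes matrix, edge list, GraphML, partition, enrichment
# tables, threshold sweep, risk statistics, summary and manifest)
morphnet run --cohort sim/cohort.tsv --out run/

# stages individually
morphnet preprocess --cohort sim/cohort.tsv --out pre/
morphnet network --matrix pre/matrix.tsv --threshold 0.7 --out net/
morphnet cluster --edges net/edges.tsv --inflation 2.2 --out clu/
morphnet enrich --partition clu/partition.tsv --annotations pre/annotations.tsv \
    --adjust bh --min-observed 3 --out enrichment.tsv
morphnet risk --table 10,2,3,25 --ci woolf
morphnet report --run-dir run/
```

Pipeline parameters (threshold, centering mode, MCL inflation, adjustment
method, risk contrast, parameter registry overrides) live in a single YAML
config passed via `--config`; defaults follow the reference analysis
(r > 0.7, inflation 2.2, minimum cluster size 3, minimum observed count 3).

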