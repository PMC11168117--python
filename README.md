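# cernet

Competing-endogenous-RNA (ceRNA) network inference for multi-class RNA-seq
experiments: lncRNA/circRNA–miRNA–mRNA regulatory networks built from count
matrices, transcript sequences and gene models.

## The problem

In poultry, broodiness (incubation behaviour) is accompanied by ovarian
regression and follicular atresia, and transcriptome studies of broody
versus laying hen ovaries look for the non-coding RNAs that drive the
change.  The ceRNA hypothesis frames this as competition: a lncRNA or
circRNA that shares miRNA binding sites with an mRNA can sequester those
miRNAs ("sponge" them) and relieve the mRNA's repression.  `cernet`
implements the standard inference recipe for such designs end to end:

1. **DE gating** — per-class CPM normalisation, a per-feature test (Welch
   *t* on log₂(CPM+1)), Benjamini–Hochberg FDR, and the gate
   *fold change ≥ 2 and FDR < 0.05*;
2. **Target prediction** — canonical seed matching (6mer / 7mer-A1 /
   7mer-m8 / 8mer) of differential miRNAs against transcript sequences;
3. **Correlation filtering** — miRNA–target pairs kept at Spearman
   ρ < −0.7, ceRNA–mRNA pairs at Pearson r > 0.9, both computed on
   log₂(CPM+1) over the pooled samples;
4. **Sponge test** — for a gene pair (A, B) with regulator miRNA sets C
   and D, the hypergeometric upper tail

   p = Σₖ₌ₓ^min(M,N) C(M,k)·C(U−M,N−k) / C(U,N)

   with x = |C∩D|, M = |C|, N = |D| and U the miRNA universe; pairs with
   p < 0.05 are accepted;
5. **Network assembly** — accepted triplets become typed nodes and edges,
   exported as GraphML and a Cytoscape-importable edge table.

The package also ships the published 25-gene broodiness candidate table
(gene → associated miRNAs/lncRNAs/circRNAs) for building candidate-gene
subnetworks, a positional lncRNA classifier (intergenic / bidirectional /
intronic / antisense / sense-overlapping), small-RNA tag filtering and
priority annotation, a 2^−ΔΔCt RT-qPCR utility, and a synthetic-data
generator that plants ceRNA triplets with known ground truth so the whole
pipeline can be validated without any external data.

## Worked example

The published candidate-gene subnetwork around *THBS1* and *MYLK*:

```python
>>> from cernet.io_formats import load_association_table
>>> from cernet.network_pipeline import subnetwork_for_genes, summarize_nodes
>>> net = subnetwork_for_genes(load_association_table(), ["THBS1", "MYLK"])
>>> summarize_nodes(net)
{'mRNA': 2, 'miRNA': 5, 'lncRNA': 18, 'circRNA': 4}
```

The two candidate genes are linked to 5 miRNAs, 18 lncRNAs and 4 circRNAs
(29 nodes in total, the lncRNA MSTRG.3306.4 and the circRNA
novel_circ_014674 being shared between both genes) — the published tally
for this subnetwork.

A fully synthetic end-to-end run:

```python
>>> from cernet.synthetic_data import ScenarioConfig, generate_scenario
>>> from cernet.network_pipeline import analyze_counts
>>> sc = generate_scenario(ScenarioConfig(
...     n_replicates_per_group=20, n_mirna=40, n_mrna=130, n_lncrna=120,
...     n_circrna=100, n_planted_triplets=30, nb_dispersion=0.05,
...     coupling_strength=2.0, seed=1))
>>> de, targets, edges, triplets = analyze_counts(sc.counts, sc.sequences)
>>> found = {(t.ce_id, t.mirna_id, t.mrna_id) for t in triplets}
>>> len(found & sc.truth.planted_triplets), len(found)
(30, 30)
```

All 30 planted triplets are recovered with no false positives: recall and
precision are both 1.0 for this scenario.

The same pipeline is available from a shell (`cernet simulate | de |
targets | cerna | network | run`); `cernet run config.yaml` executes the
whole analysis from a YAML config naming the count tables, condition map,
sequences and threshold overrides.

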