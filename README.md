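# netpharm

A systems-pharmacology screening pipeline for multi-herb drug formulas.
Given a table of herbal ingredients with predicted pharmacokinetic
parameters, compound→target link tables, disease evidence (a two-group
expression study plus database-exported target lists), a background protein
interactome and a gene-set collection, `netpharm` runs the whole chain that
turns raw ingredient chemistry into a ranked, pathway-annotated list of
candidate protein targets:

1. **ADME triage** — keep compounds with oral bioavailability OB ≥ 30%,
   drug-likeness DL ≥ 0.18, Caco-2 permeability ≥ −0.4 and half-life
   HL ≥ 4 h (all inclusive), with an explicit literature-rescue list for
   pharmacologically active compounds that miss the cutoffs.
2. **Compound–target network** — a bipartite graph over retained compounds
   and their targets, with degree summaries (promiscuous compounds,
   most-targeted proteins, shared cross-herb ingredients).
3. **Disease targets** — differentially expressed genes from a log2
   expression matrix (per-gene Welch t-test, significant at P < 0.01 and
   |log2FC| ≥ 1), merged with database target lists and intersected with the
   drug-target set.
4. **PPI core** — drug targets and disease targets each seed a
   first-neighbor expansion of the interactome; the two expanded networks
   intersect into the core PPI (CPPI).
5. **Topological screen** — six node centralities computed from scratch
   (degree DC, betweenness BC, eigenvector EC, closeness CC, network
   centrality NC, local average connectivity LAC); stage 1 keeps *hubs*
   with DC > 2 × median(DC); stage 2 recomputes all six measures on the
   hub-induced subgraph and keeps *candidate targets* strictly above all six
   medians simultaneously.
6. **Enrichment** — upper-tail hypergeometric over-representation of the
   candidates against a GMT collection (significant at raw P < 0.05, BH
   reported for information), with significant terms grouped into functional
   clusters via Cohen's kappa ≥ 0.4 on term gene memberships.

A seeded synthetic-data module generates inputs with known ground truth for
every stage, so the whole pipeline is testable offline at desk scale.

## Worked example

Simulate a full coherent input set and run every stage:

```bash
netpharm simulate --what all --seed 1 --out fixtures/
netpharm -v run-all --config run.yaml
```

with `run.yaml` pointing at the simulated files:

```yaml
inputs:
  compounds: fixtures/compounds.tsv
  rescue: fixtures/rescue.txt
  ct_links: fixtures/ct_links.tsv
  expression: fixtures/expression.tsv
  expression_labels: fixtures/labels.tsv
  disease_lists: [fixtures/disease_lists/omim.txt, fixtures/disease_lists/drugbank.txt,
                  fixtures/disease_lists/pharmgkb.txt, fixtures/disease_lists/gad.txt,
                  fixtures/disease_lists/ttd.txt]
  interactome: fixtures/interactome.tsv
  genesets: fixtures/genesets.gmt
params: {}
output_dir: out/
```

On the seed-1 fixture set this prints (abridged from the stage counts):

```
compound_screen: {n_input: 200, n_retained: 164, n_rescued: 4}
ct_network:      {n_nodes: 544, n_edges: 689, n_targets: 380}
disease_targets: {n_degs: 50, n_disease_targets: 523, n_drug_disease_overlap: 95}
ppi_core:        {cppi: {n_nodes: 396, n_edges: 1600}}
hub_screen:      {n_stage1_hubs: 59, n_candidates: 15}
enrichment:      {n_query: 15, n_significant: 1, n_groups: 1}
```

Read bottom-up: of 200 simulated ingredients, 164 survive the ADME rule
(4 by rescue); their 380 distinct targets and the 523 merged disease
targets seed two interactome expansions whose intersection — the 396-node
CPPI — is screened down to 59 hubs and then 15 candidate targets, of which
the enrichment stage finds 1 significantly over-represented gene-set term.
Every stage writes its intermediate (verdict TSVs, SIF/GraphML networks,
threshold JSON) under `out/`, and `out/run_report.json` collects all counts,
parameters and versions; reruns are byte-identical apart from timestamps.

Each stage is also a library function (`netpharm.screen_compounds`,
`netpharm.call_degs`, `netpharm.compute_all`, `netpharm.screen`,
`netpharm.hypergeom_enrich`, …) and a standalone subcommand
(`screen-compounds`, `deg`, `build-ppi`, `merge`, `centrality`,
`hub-screen`, `enrich`, …); see `netpharm --help`.

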