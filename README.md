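# ogclust

Comparative-genomics analysis of gene-family presence/absence across green
plants and algae: orthologous gene cluster (OGC) construction from all-vs-all
protein similarity hits, nine-way phyletic-pattern classification, GO
annotation transfer, and control-group binomial enrichment.

## The scientific problem

Land plants (embryophytes, **Emb**) evolved from charophyte green algae
(**Cha**), with chlorophytes (**Chl**) as the outgroup. The charophytes split
into an early-branching grade (**KCM**: Klebsormidiophyceae,
Chlorokybophyceae, Mesostigmatophyceae) and the land-plant-adjacent grade
(**ZCC**: Zygnematophyceae, Coleochaetophyceae, Charophyceae). Protein
families shared by charophytes and embryophytes but absent from chlorophytes
mark innovations of their common ancestor — cell-wall machinery being the
canonical example. This package reconstructs that analysis for a 14-species
panel (2 Chl, 2 KCM, 5 ZCC, 5 Emb):

1. **Filter** all-vs-all BLASTP-style hits: keep E-value < 1e-5 and query
   coverage (qend − qstart + 1)/qlen > 50%, both strict; drop self-hits.
   (An analogous filter for HMM domain hits — E < 1e-15, HMM coverage
   > 80% — is provided for CAZyme-style scans.)
2. **Cluster** the surviving hits with a from-scratch Markov cluster
   algorithm (MCL, inflation 1.5) on symmetrized −log₁₀ E weights, then
   retain clusters with ≥ 2 proteins from ≥ 2 species — these are the OGCs.
3. **Classify** each OGC into one of nine phyletic groups from the clades of
   its member species: Chl+Cha+Emb, Cha+Emb, Chl+Cha, Chl+Emb, Emb, Cha
   (both KCM and ZCC), ZCC, KCM, Chl. Tabulate per-group OGC/protein counts,
   the 3-set Venn regions, and per-species OGC occupancy.
4. **Annotate**: transfer GO terms from the best reference hits
   (E < 1e-10; all hits tied at the minimum E-value among GO-bearing
   references contribute).
5. **Enrich**: for each group, test every level-6 GO term against the
   Chl+Cha+Emb control with an exact one-sample binomial test,

   p = Σ_{j=k_T}^{n_T} C(n_T, j) p₀^j (1 − p₀)^{n_T − j},  p₀ = k_C / n_C,

   where n counts GO-annotated proteins only, followed by a Holm step-down
   adjustment per group; a term is over-represented when p_adj < 0.05 and
   k_T/n_T > p₀.

Because the original fourteen proteomes are not shipped, a **synthetic
cohort generator** produces the whole input bundle — species panel, gene
families with clade-structured presence/absence drawn from the nine group
rules, hit tables with decoys that violate the filters, a tree ontology,
and a reference GO map with a term planted at elevated frequency in a chosen
group — so every stage runs against a known ground truth.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1      # 300 families, 14 species
python analysis/02_filter_and_cluster.py
python analysis/03_classify_groups.py
python analysis/04_annotate_go.py
python analysis/05_enrich_go.py
python analysis/06_reference_table_checks.py
```

Step 02 prints

```
filter : 17746 hits -> 15136 kept (2610 removed by E-value/coverage/self-hit rules)
cluster: 300 clusters, 300 retained OGCs, 0 proteins excluded
ground-truth family partition recovered exactly: True
```

— every decoy hit fell to the filters and MCL reproduced the simulated
families exactly. Step 05 prints

```
2 significant group/term pairs (191 tests over 8 groups)
planted term GO:0000032 in Cha+Emb: k_T/n_T = 198/521, p0 = 0.0489, p_adj = 7.47e-117, significant = True
```

— of 521 annotated Cha+Emb proteins, 198 carry the planted level-6 term
versus a control frequency of 4.9%, and the enrichment stage flags it
decisively. The same pipeline is available as a CLI (`ogclust simulate`,
`filter-hits`, `cluster`, `classify`, `annotate`, `enrich`, `all`).

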