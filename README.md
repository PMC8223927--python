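# lysinscape

Sequence–function landscape analysis of phage lysins: the enzymes
(endolysins) that phages use to degrade the bacterial peptidoglycan at the
end of their infection cycle. Lysins from phages infecting Gram-negative
(G−) hosts tend to be short, monomodular and to carry cationic,
amphipathic, antimicrobial-peptide-like (AMP-like) regions at their C
terminus, while lysins from Gram-positive (G+) hosts are longer and
multimodular, pairing catalytic domains (EADs) with cell-wall-binding
domains (CWBDs). `lysinscape` implements the full analysis chain that
quantifies these differences, for anyone studying lysin engineering,
phage–host coevolution, or AMP mining from lysin sequences:

* **curation** of annotated gene products into an analyzable lysin set
  (keyword screen → 50–550 aa length window → 98%-identity de-duplication →
  domain-relevance filter at E ≤ 10 → host-genus assignment), with a
  telescoping per-stage report;
* **domain-architecture census**: PF hits per protein, collapsed
  architecture strings such as `[Amidase_2]5×[CW_binding_1]`, EAD flank
  lengths, genus/Gram/chemotype cross-tabulations;
* **physicochemical descriptors** at whole-sequence, sequence-quartile and
  11-aa-window resolution: net charge at pH 7 (Henderson–Hasselbalch with
  the Dawson pKa scale), NCPR, GRAVY (Kyte–Doolittle), per-residue
  hydrophobic moment μH at δ = 100° averaged over windows, and the
  aliphatic index;
* **robust statistics**: Yuen–Welch tests on γ = 0.2 trimmed means,
  Wilcox–Tian ζ effect sizes, Bonferroni adjustment;
* **Gram-group prediction** with a random forest (stratified 75/25 split,
  5×3 repeated CV, ROC best point by the Youden criterion, Gini
  importances);
* **sequence similarity networks**: all-vs-all Smith–Waterman identity,
  thresholded at ≈40% (≈30% for the diverse NAM-amidase sets), exported as
  GraphML;
* a **seeded synthetic-data generator** that reproduces the statistical
  structure of the curated database (length medians 164/317 aa,
  monomodularity, signal-peptide rates 27.9%/7.5%, the C-terminal cationic
  patch) and provides ground truth for every downstream test.

The key statistic for group comparisons is Yuen's trimmed-means t

&nbsp;&nbsp;&nbsp;&nbsp;t = (X̄ₜ₁ − X̄ₜ₂) / √(d₁ + d₂),&nbsp;
d_j = (n_j − 1) s²_{w,j} / (h_j (h_j − 1)),

with winsorized variances s²_w, post-trim counts h_j and
Welch–Satterthwaite degrees of freedom, and the explanatory effect size
ζ = √(σ̂²_between / σ̂²_total) computed from 20%-trimmed/winsorized
quantities (≈0.1 small, ≈0.3 medium, ≥0.5 large).

## Worked example

The numbered scripts under `analysis/` run the whole study on a generated
dataset (each reads the previous script's tables from `results/analysis/`):

```bash
for s in analysis/0*.py; do python "$s"; done
```

The first steps print, for the default seed (7):

```
630 records, 824 domain hits
length median G-: 163 (target 164), G+: 312 (target 317)
monomodular G-: 0.921 (target 0.90)
signal peptides: {'G+': 0.077, 'G-': 0.271} (targets G- 0.279, G+ 0.075)

annotation_screen     630 ->  630
length_filter         630 ->  630
identity_clustering   630 ->  600
domain_relevance      600 ->  600
host_assignment       600 ->  600
clusters with removed redundancy: 30
```

and the classifier step:

```
physchem4: AUC=0.968 accuracy=0.940 sens=0.987 spec=0.893 threshold=0.496 cv_acc=0.903
  importance ranking: ncpr > aliphatic_index > gravy > avg_hydrophobic_moment
extended7: AUC=0.992 accuracy=0.973 sens=0.973 spec=0.973 threshold=0.688 cv_acc=0.941
```

Reading: the generator planted 30 near-duplicate sequences, which the
98%-identity clustering removes (630 → 600); a random forest on the four
physicochemical descriptors alone separates G− from G+ lysins with AUC
0.97, NCPR being the most informative variable — the same ordering the
analysis finds on real lysin data — and adding length/architecture
variables improves it further. The remaining scripts produce the
architecture census (single-hit fractions 0.92 for G−, 0.69 for G+),
quartile charge comparisons (the planted C-terminal patch makes the final
quartile the most divergent, ζ = 1.0, large) and the subfamily similarity
networks (two planted subfamilies recovered as two pure components at the
40% cutoff).

The same stages are available as a CLI (`lysinscape simulate|curate|
physchem|architecture|stats|classify|ssn|run`) and as one orchestrated
pipeline (`lysinscape.pipeline.run_pipeline`).

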