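# Methods

This note documents the models, conventions and numerical choices behind
`lysinscape`: what each stage computes, which knobs matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## Scope and data model

The package analyzes phage lysins (peptidoglycan-degrading endolysins and
related enzymes) as rows of three joined tables: protein sequences with
free-text annotations and host genus (`LysinRecord`), Pfam-family domain
hits with 1-based inclusive coordinates and E-values (`DomainHit`), and
per-genus host metadata — Gram group, cell-envelope architecture and
Schleifer–Kandler peptidoglycan chemotype (`HostMetadata`). Mycolic-acid
diderms (*Mycobacterium*, *Rhodococcus*, *Corynebacterium*) are counted as
G+ throughout, following the convention of the source database. A built-in
copy of the per-genus classifier/yield table ships with the package
(`data/host_metadata.tsv`, 48 genera plus the PRD1-like enterobacterial
group row); the family → functional-class/activity map
(`data/family_classes.tsv`) is an editable seed covering the EAD, CWBD and
structural families that recur in lysins, with unmapped families falling
back to OTHER.

## Curation

Raw annotated gene products pass five deterministic stages:

1. **Annotation screen** — case-insensitive substring match against
   inclusion keywords (`lysin, lysozyme, murein, amidase, cell wall
   hydrolase, peptidase, peptidoglycan`) with overriding exclusion terms
   (`structural, tail, holin, baseplate, virion protein`). Substring
   semantics are the broadest reading under which "endolysin" matches
   "lysin"; exclusion always wins.
2. **Length window** — keep 50–550 aa, bounds inclusive (the bounds are
   stated as minimum/maximum without strictness; inclusivity is our choice).
3. **Redundancy removal** — greedy incremental clustering at 98% identity.
   Identity is identical aligned positions divided by the shorter sequence
   length, from a global alignment (BLOSUM62, gap open 10 / extend 1), i.e.
   the CD-HIT-style convention without reproducing that tool's word-filter
   heuristics. Records are processed longest-first with lexicographic id
   tie-break, which makes clustering independent of input order. An exact
   shared-8-mer prefilter skips hopeless alignments; at thresholds ≥ 0.9
   and lengths ≥ 50 a qualifying pair always shares an 8-mer (pigeonhole
   over ≤ 2% non-identical columns), so no merge can be lost.
4. **Domain relevance** — keep records with at least one hit of an EAD or
   CWBD family at E ≤ 10 (cutoff inclusive); configured structural
   exceptions can rescue virion-associated lysins.
5. **Host assignment** — Gram/architecture/chemotype copied from the
   metadata table; unknown genera are flagged and retained but excluded
   from Gram-stratified analyses.

The stage report telescopes (each stage's output count is the next stage's
input count), every removed id appears in exactly one stage, and the whole
procedure is idempotent.

## Physicochemical descriptors

* **Net charge** at pH 7.0 by Henderson–Hasselbalch summation over D, E, C,
  Y (acidic), K, R, H (basic) and the terminal amino/carboxyl groups, with
  the Dawson pKa table (D 3.9, E 4.0, C 8.3, Y 10.1, H 6.0, K 10.5, R 12.0,
  N-term 8.2, C-term 3.2). The table is data, not code: all charge tests are
  written against the shipped table and a replacement scale propagates
  everywhere. Whole-protein charge includes the termini; sliding-window
  charge uses side chains only (windows are internal peptide stretches);
  quartile fragments keep a terminal group only at the true protein ends,
  since internal cut points are amide-bonded in the real chain (a
  `fragment_termini` toggle restores free-peptide behaviour).
* **NCPR** — net charge divided by residue count.
* **GRAVY** — mean Kyte–Doolittle hydropathy.
* **Hydrophobic moment** μH = |Σₙ hₙ e^{iδn}|/N with δ = 100° (α-helical
  periodicity) and n starting at 0; normalized per residue and *averaged*
  over all 11-residue windows (not maximized — the average is what the
  downstream comparisons use). Sequences shorter than the window form a
  single window.
* **Aliphatic index** (Ikai): X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in
  mole percent.
* **X residues** are inert everywhere: zero hydropathy, non-ionizable,
  excluded from every mean and mole-percent denominator (they still occupy
  a helical position in μH).

Quartiles are four contiguous fragments of ⌊L/4⌋ residues with the
remainder appended to the last fragment (toggleable to spreading). Local
profiles evaluate a property on every 11-aa window and record absolute and
normalized (center/L) positions; group-level "average tendencies" pool all
windows of a label into 50 equal-width bins of normalized position and
report per-bin means, a deliberately plain substitute for GAM smoothing.

## Architecture census

Counts are in units of PF hits — repeats count individually, so a
[EAD]5×[CW_binding_1] lysin contributes six hits. Overlapping hits are
resolved by keeping the lower E-value (ties: longer span). Architecture
strings collapse consecutive identical families (`k×[family]`) and expand
back losslessly. EAD flanks are the residues before the first and after the
last EAD by coordinate, one pair per protein regardless of how many EADs it
carries; CWBDs between EADs are ignored for flank purposes; both flanks are
missing when a protein has no EAD. Cross-tabulations (genus × family,
chemotype × activity, …) carry marginals; hits that cannot be joined to a
record are counted under an `unassigned` row with a logged warning.

## Robust statistics

Descriptor distributions are non-normal and heteroskedastic, so two-group
comparisons use Yuen's generalization of Welch's test: means and variances
after trimming/winsorizing ⌊γ·n⌋ observations per tail (γ = 0.20 by
default), Welch–Satterthwaite degrees of freedom on the trimmed counts,
two-sided p from Student's t. At γ = 0 the test reduces exactly to Welch's
t-test (verified to 1e-9 against an independent implementation). Effect
sizes use the Wilcox–Tian explanatory measure ζ: the square root of the
ratio of the variance of the two trimmed means to the robust total
variance, the latter estimated as the average winsorized variance rescaled
by the winsorized variance of the standard normal at the same trimming
level (≈ 0.642² at γ = 0.2, computed in closed form for any γ). ζ is capped
at 1; with unequal group sizes it is the median over 100 seeded equal-size
subsamples, so it stays deterministic given the inputs. Interpretation tags
follow the usual reading (≈0.10 small, ≈0.30 medium, ≥0.50 large).
Families of comparisons (the four quartiles; the EAD families tested in one
call) are Bonferroni-adjusted with m equal to the comparisons performed in
that call, and significance is coded ≤0.05 / ≤0.01 / ≤0.001 as */**/***.

## Gram-group classifier

A random forest (500 trees, 4 candidate variables per node) predicts the
host Gram group, G+ positive. Feature sets: `physchem4` = {NCPR, average
μH, aliphatic index, GRAVY} — whole-sequence net charge is excluded as
redundant with NCPR × length but can be toggled in — and `extended7`
adding length, significant-hit count and the signal-peptide flag. Protocol:
stratified 75/25 split; 5-fold × 3-repeat cross-validation on the training
set retained as a sanity check (mtry stays fixed); ROC on held-out G+
probabilities; operating point at the Youden maximum of TPR − FPR with ties
broken toward the lower threshold (favoring sensitivity); accuracy,
sensitivity, specificity and the confusion matrix at that threshold; mean
Gini-decrease importances with alphabetical tie-break. Everything is
seed-reproducible.

## Sequence similarity networks

All-vs-all Smith–Waterman local alignment (BLOSUM62, gap open 10 /
extend 1); percent identity over the aligned columns including gaps (a
shorter-sequence denominator is available). Edges connect pairs at or above
the identity threshold — 40% for most family sets, 30% for the more diverse
NAM-amidase sets — and additionally require at least
min(50, shorter-sequence length) aligned columns: the optimal local
alignment of two unrelated proteins is frequently a short (< 20-column)
high-identity stretch, and the floor removes those spurious edges while
letting identical short sequences connect. Components are labeled largest
first; graphs export as GraphML (node attributes: gram, genus, chemotype;
edge attributes: score, identity) and TSV edge lists. Thresholding is done
on identity directly rather than on an E-value-like score, which is what
the quoted 30–40% cutoffs refer to; this diverges from alignment-score
thresholding tools and is documented as such.

## Synthetic-data generator

The generator emulates the statistical structure of the curated database,
not its biology. Per class: log-normal lengths (σ = 0.35 on the log scale)
rejection-sampled into the 50–550 aa window, with medians targeting 164 aa
(G−) and 317 aa (G+); residues i.i.d. from proteome-wide background
frequencies with mild class-specific multipliers (G−: K/R ×1.35, A/V/I/L
×1.15, D/E ×0.85; G+: D/E ×1.10) — these calibration constants live in the
config, chosen once so that Gram separability lands in a realistic AUC ≈
0.9–0.97 band rather than being trivial; a cationic/amphipathic C-terminal
patch (15–25 aa from a K/R- and aliphatic-rich composition, placed in the
last quartile ending within 3 residues of the C terminus) planted in 70% of
G− records; monomodular G− hit tables with probability 0.90 (one EAD near
the N terminus) and single-domain G+ tables with probability 0.60,
otherwise an EAD (30% chance of a medial start near coordinate 200)
followed by C-terminal CWBD repeats; signal-peptide flags at rates 0.279
(G−) and 0.075 (G+); host genera drawn from class-consistent pools.
E-values are 10^-U(5,60). An optional duplicate-injection rate appends
single-substitution copies for clustering tests. Every planted attribute is
recorded in a ground-truth table sufficient to recompute the class
differences without re-reading sequences, and output is byte-identical for
a fixed seed.

Presets capture targeted conditions: `only_ncpr_signal` (equal lengths, no
patch, charge composition only) for importance-recovery checks, and
`q4_patch_only` (identical classes except the planted last-quartile patch
on every G− record) for quartile-level detection specificity.

What the generator does **not** emulate: homology structure (sequences are
i.i.d. apart from injected duplicates and the separate subfamily-block
generator used for SSNs), realistic domain sequence models (hit coordinates
are annotations, not sequence signals), signal-peptide sequence motifs
(flags only), genus-level architecture idiosyncrasies, and the long tail of
rare families. Passing tests therefore demonstrate that the pipeline
recovers what was planted under the stated statistical conditions — not
that it would reproduce every real-data figure.

## Problem sizes and determinism

Default analysis sizes are 300–500 records per class for generation-backed
checks, 10,000 simulations at n = 50 for type-I calibration of the Yuen
test, and 30-node networks for SSN recovery; these sizes give stable Monte
Carlo estimates while keeping any run in the low minutes on one CPU. All
randomness flows from explicit seeds; the pipeline fans a single global
seed out to stages by stable hashing of the stage name, so disabling one
stage never shifts another's random stream.

## Known limitations

* The curation clustering is faithful to the greedy-representative idea but
  is not bit-compatible with the CD-HIT binary.
* The per-genus census of a real database depends on upstream annotation
  quality; the built-in yield table is a fixed snapshot.
* ζ for unequal group sizes relies on subsample medians (as in the
  reference robust-statistics implementation) rather than a closed form.
* SSN identity thresholding approximates, but is not identical to,
  alignment-score thresholding as performed by EFI-EST-style servers.
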