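# Methods

## The scoring model

The package ranks 24 *interventional nodes* — drug-actionable groups of
targets plus their upstream genes (receptors with their ligands, a kinase
with its regulators) — per patient, from matched tumor/normal omics. The
premise: the more disturbed a node's genes are in the tumor relative to
the patient's own normal tissue, the more likely a drug aimed at that node
is to matter for that tumor.

All expression quantities are tumor/normal fold changes in **ratio
space**: strictly positive, 1 = no change, down-regulation in (0, 1). The
ratio convention keeps the corrections below well defined (divide by a
miRNA mean, multiply by a copy-number ratio) without sign bookkeeping; the
alternative ±fold convention is not used anywhere.

Per patient and node *k* with gene set `M_k`:

1. **miRNA penalty.** For gene *i*, `A_i` is the arithmetic mean fold
   change of the ≤ 5 miRNAs predicted to target it (its "top 5" by target
   prediction rank). The corrected fold change divides by `A_i`: an miRNA
   that rises together with its target argues against effective
   translation of the excess mRNA, so concordant miRNA/mRNA changes are
   penalized. Unmapped genes (or an absent miRNA layer) take `A_i = 1`.
2. **Copy-number correction.** When gene *i* is called amplified, its fold
   change is multiplied by the copy-number ratio; otherwise the factor is
   1. For CNV tables without explicit calls a helper thresholds the ratio
   at ≥ 1.5 (configurable); published descriptions never define what
   counts as a detected amplification, and report that the correction had
   little impact in practice.
3. **Trim and average.** `F_i = fc_i · cnv_i / A_i`; the node mean
   `E_k = mean{ F_i : i ∈ M_k, max(F_i, 1/F_i) ≥ 1.3 }`.
   1.3 is the smallest fold change two-dye arrays detect reliably.
   "Absolute fold change" in ratio space is read as `max(r, 1/r)`, so a
   2-fold *loss* also passes the trim and contributes its ratio (< 1) to
   the mean — the literal reading of `E_k` as the plain average over the
   trimmed set. Published descriptions give the trim both as strict (>)
   and as inclusive (≥); ≥ is adopted and a strict-mode switch is
   exposed. Genes absent from the data
   are skipped; if nothing passes, the node is neutral (`E_k = 1`).
   Correction happens *before* trimming: the node average is taken over
   corrected fold changes, and the trim is applied to those same
   corrected values.
4. **Decile calibration.** `E_k` ranges differ wildly between nodes, so a
   calibrator cohort's per-node `E_k` values define an empirical CDF
   `F̂_k`, and the score is `clamp(ceil(10 · F̂_k(E_k)), 1, 10)` with ties
   counted ≤. This rule is deterministic, monotone in `E_k`, and
   self-uniform: scoring an all-distinct reference against itself fills
   each decile bin with ⌊N/10⌋–⌈N/10⌉ patients. The original work
   self-calibrated on its 121-patient cohort; `score_cohort` does the same
   by default and requires ≥ 10 patients, or accepts a saved calibrator.
   The serialized calibrator stores the sorted reference values (scoring
   uses those, bit-exactly) plus the nine 0.1…0.9 empirical quantiles
   (numpy's default linear interpolation) for inspection only.
5. **Mutation override.** A whitelisted activating event — by default
   EGFR/KRAS/BRAF/PIK3CA/ERBB2 point mutations or indels and ALK/ROS1/RET
   fusions — forces score 10 for **every** node containing the gene, and
   the transcriptomic evidence is ignored for those nodes. The published
   rule speaks of "the corresponding pathway" in the singular, but the
   gene→node mapping is many-to-many (BRCA1 sits in both PARP and DNA
   Repair), so the override is applied per containing node. TP53 is
   deliberately not whitelisted: p53 mutations are not uniformly
   activating or inactivating.

## Activation calls and combinations

Scores 8–10 are *high* activation, 6–7 *medium*, < 6 non-activated;
"activated" for all counting means score ≥ 6. The patient × label
activation matrix carries one column per node plus merged reporting
aliases — by default `mTOR/PI3K` = mTOR ∪ PI3K. Union semantics is the
only reading consistent with the published group counts (mTOR 30, PI3K
28, merged 42: above the max, below the sum).

All C(L, 3) label triplets are enumerated with exact patient-coverage
counts (patients with all three labels activated) and integer percentages
rounded half away from zero — the rounding that reproduces the published
63/121 → 52 %, 58/121 → 48 %, 36/121 → 30 %, 88/121 → 73 %. Optional
constraints: required labels (e.g. an immune-checkpoint arm) and excluded
label pairs; the default "mechanistic independence" exclusion list is all
label pairs sharing ≥ 1 gene (which also bars an alias from co-occurring
with its own members).

The combination menu maximizes distinct-patient coverage over k triplets.
Greedy set cover (pick the triplet covering the most not-yet-covered
patients; ties by raw count, then lexicographic) carries the standard
(1 − 1/e) guarantee but is *not* optimal even on six labels, so the
default method is exhaustive search whenever the label set is ≤ 8 and the
k-subset space is below 2·10⁵ combinations, greedy otherwise.

## Registry transcription

The bundled registry transcribes the published 24-row node table with
case normalization only; obvious misprints are kept verbatim and every
decision is recorded in `src/sims/data/provenance.md`. The transcription
yields 192 gene memberships (191 unique symbols) against a printed
headline of 183, which no literal enumeration of the printed rows
reproduces; the registry documents its own count. The published activation
tables score PDL1 and CTLA4 as separate columns even though the node
table lists one "Immune modulator" row; the registry keeps the 24 printed
rows, and the combination layer accepts arbitrary label sets so split
immune labels can be analyzed when a caller scores them separately.

## The synthetic cohort generator

Real per-patient processed data for the original cohort is not
redistributable, so the generator plants known activations and the test
suite measures recovery. Per patient each node is active with probability
`activation_prob`; genes of active nodes draw `log FC ~ N(effect_mu,
effect_sigma²)`, all others `N(0, noise_sigma²)`. An active node
containing a whitelisted gene is, with probability `mutation_rate`,
represented by a mutation *instead of* expression (its genes draw noise —
only the override path can recover it). With probability `mirna_coupling`
an active gene's targeting miRNAs rise like the gene (exercising the
penalty, which correctly *suppresses* such genes); with probability
`cnv_rate` an active gene is amplified (ratio ~ U(1.5, 3)).

Defaults (chosen once from the reported cohort structure, before any
recovery measurement): `n_patients = 200`, `activation_prob = 0.5` (the
published per-node activation frequencies cluster around half the
cohort), `effect_mu = ln 2.5` with `effect_sigma = 0.25` (clearly above
the 1.3 trim), `noise_sigma = 0.2`, `mutation_rate = 0.2`,
`mirna_coupling = 0.1`, `cnv_rate = 0.1`. Under self-calibration roughly
the top half of each node's `E_k` distribution scores ≥ 6, so with about
half the cohort planted active per node the decision boundary sits near
the planted/background divide; at these conditions recovery on seed 1 is
sensitivity ≈ specificity ≈ 0.96, and the packaged regression threshold
is 0.85 for both.

What the generator does **not** emulate: correlation between nodes beyond
shared genes, histology structure, realistic mutation spectra, dye-swap
replicate noise, or any survival signal. Passing recovery tests therefore
shows the pipeline's internal consistency — planted signals of realistic
magnitude are recovered through the full file → score → call path — not
clinical validity on real cohorts.

## Numerical choices and degenerate inputs

- Fold changes must be finite and > 0; zeros are data errors. Paired
  expression matrices are converted with `(tumor + ε)/(normal + ε)`,
  ε = 0 by default so that zero denominators fail loudly.
- Patient harmonization across layers is by intersection, never union.
- Empty trim set → `E_k = 1` (neutral), which the clamp maps to the lowest
  occupied decile — "no differential expression" scores minimally rather
  than erroring. Note the tie rule: if the calibrator itself contains a
  large tie block at 1.0, every tied patient receives the score at the
  *top* of the block.
- Calibration requires ≥ 10 reference values per node; smaller cohorts
  must supply an external calibrator.
- Percentages are integers, rounded half away from zero.

## Known limitations

- Whitelist membership is the only mutation criterion: no variant-effect
  prediction, no distinction between hotspot and passenger events.
- Down-regulated trim passers *lower* `E_k`, so loss of a tumor
  suppressor (PTEN, TP53) depresses its node's activation score — the
  literal published formula, arguably not the intended biology.
- Whether the original implementation averaged signed or ratio fold
  changes, and how dye-swap replicates were combined, is not recoverable;
  this implementation fixes the ratio-space reading and exposes the trim
  threshold/strictness in config.
- Node scores are comparable across nodes only through the decile
  calibration; absolute `E_k` values are not comparable between nodes.
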