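# Methods

This note documents the models, statistics and design choices behind
`critfact`, in the order the pipeline runs them.

## TF activity by iBAQ

Raw MS intensities from a TF-response-element pull-down are normalized to
intensity-based absolute quantification (iBAQ) values: intensity divided
by the number of theoretical tryptic peptides of length 6–30 residues.
Digestion follows the standard trypsin rule — cleave C-terminal to K or R
unless the next residue is P — with zero missed cleavages; both the
cleavage residues and the length window are parameters. The digest is a
partition of the sequence (property-tested), so peptide counting is exact.
Rows sharing a TF id (isoforms) are summed before normalization. Proteins
with zero theoretical peptides are non-quantifiable: they are excluded and
logged, never silently zeroed.

Per transition (condition B over A), the activity fold change is the ratio
of mean iBAQ values; replicates are aggregated by the arithmetic mean
(geometric available via `agg="geometric"`). Zero condition means are
replaced by a floor, defaulting to half the smallest nonzero iBAQ in the
table — this keeps on/off signals finite and extreme rather than dropping
them. Status thresholds are strict: activated above 2, repressed below
0.5, unchanged otherwise (a fold change of exactly 2 is unchanged); both
thresholds are parameters.

## Expression and fold changes

FPKM(g, s) = count(g, s) / (length_kb(g) · total_fragments(s)/10⁶).
Per-gene fold changes are ratios of mean FPKM across replicates, with a
pseudocount (default 1 FPKM unit) added to both means for stability; the
log2 companion derives from the same ratio. Fold changes are computed on
FPKM rather than raw counts so length and depth are normalized first. The
target/transcriptome vectors use linear fold changes, following the
method's plain-ratio formulation; the fold-change antisymmetry property
FC(A→B)·FC(B→A) = 1 holds when the pseudocount is 0.

DE flags are a pass-through for externally computed calls (count-based NB
model fits are routine upstream tooling and deliberately not reimplemented
here); absent external calls, genes with |log2 FC| ≥ 1 are flagged by sign.
The provenance (`external` vs `threshold-standin`) is recorded in every
output so results state which path produced them.

## The target-group permutation test

For TF t with usable target set T (targets present in the fold-change
domain; at least `min_targets` = 3, else the TF is flagged untestable),
the statistic is mean(T) − mean(G) where G is the whole fold-change
vector. The null is resampling: N (default 10 000) gene sets of size |T|
drawn without replacement from G, preserving the empirical fold-change
distribution. The empirical p-value uses the add-one estimator
(r + 1)/(N + 1), bounded below by 1/(N + 1) and never zero. The test is
two-sided by default with the direction reported post hoc from the sign of
the statistic; one-sided modes are available (the sidedness of the
original formulation is ambiguous, so both are exposed).

An exhaustive twin (`exhaustive_group_test`) enumerates all C(|G|, |T|)
subsets (capped at 10⁶) and returns the exact tail fraction — no add-one,
since nothing is estimated. The permutation p converges to it; the
acceptance suite verifies agreement within three binomial standard errors
at N = 10⁵ on random ≤12-gene universes.

Subset sampling is vectorized two ways: rejection sampling of index rows
when |T| ≤ |G|/8 (duplicate rows redrawn; expected O(1) rounds) and
random-key `argpartition` otherwise. Mean comparisons use a relative
tolerance of 1e-12 so exact ties (e.g. a permutation that redraws T
itself) count as "as extreme".

Per-TF permutation streams are spawned from the stage seed with
`SeedSequence.spawn` in sorted TF order, making full runs bit-for-bit
reproducible and standalone stage runs identical to orchestrated ones.
Multiple testing across TFs is reported raw by default with optional
Benjamini–Hochberg (`adjust="BH"`); the choice is recorded in the output.

## Classification and network intersection

A TF is critical when both filters fire: activity status activated or
repressed, and target-group test significant at α (default 0.05).
Direction consistency decides the class: activated-with-targets-up or
repressed-with-targets-down is an activator; the crossed combinations a
repressor. Condition networks wire each critical TF to its differentially
expressed targets only; TFs with no DE target are dropped. Intersection of
the per-transition networks is plain set logic on TF nodes and edges
(commutative, idempotent), yielding the co-regulated TF set.

`degree_comparison` contrasts undirected node degree between an annotated
TF subset and the rest via a two-sided Mann–Whitney U test: exact null
distribution when both groups have < 20 members, tie-corrected normal
approximation otherwise.

## Network pharmacology

PPI edges are kept at confidence ≥ 0.5 (inclusive, parameterized).
Co-activator candidates are retained when their gene is differentially
expressed in the treated transition — the implemented operationalization
of "co-expressed", which the source method leaves undefined; the candidate
list is an explicit input so alternative readings can be swapped in. The
tripartite graph contains compounds, retained co-activators and critical
TFs; a critical TF is *final* if a compound targets it directly or targets
a co-activator that touches it through a retained PPI edge. The rule that
fired (`direct` / `via_coactivator`) is annotated per TF. Lowering the
confidence cutoff can only grow the final set (monotonicity,
property-tested).

## The synthetic-data generator

The generator emulates the three-condition design (control → model →
treated) with three replicates per condition. What it models:

- **TF intensities**: baselines log-uniform over 10⁴–10⁷ (three orders of
  magnitude, reflecting the wide dynamic range and generally low abundance
  of TFs), multiplied per transition by `tf_effect_fc`^±1 (default 4) for
  planted TFs, with mean-one log-normal noise of coefficient of variation
  `noise_cv` (default 0.2). Planted activity directions are random ±1 in
  the first transition and reversed in the second — a rescue, mirroring
  the biology the pipeline is meant to resolve. In the noiseless limit
  realized ratios equal the configured multipliers exactly.
- **Counts**: negative binomial around log-uniform baseline means scaled
  to an expected library of 2×10⁷ fragments, dispersion 0.05 (RNA-seq
  convention; the source gives no generative model), Poisson when
  dispersion is 0. Targets of a planted activator shift their mean by
  `target_effect_fc`^±1 (default 2.5) in the TF's direction, repressor
  targets oppositely; effects multiply when planted TFs share a target and
  can cancel. A `fraction_targets_affected` knob (default 1.0) exposes
  partial-target effects. Gene lengths are uniform 500–5000 bp.
- **Pharmacology tables**: every intended final TF gets a compound →
  co-activator edge plus a co-activator–TF PPI edge with confidence in
  [0.6, 0.95]; decoy co-activators get compound edges and PPI edges to
  non-final critical TFs with confidence in [0.05, 0.45]. In the
  orchestrated simulation, bridge co-activators are gene ids drawn from
  genes realized as DE in the treated transition (preferring targets of
  the final TFs), so the co-expression filter keeps them and end-to-end
  recovery is exact at the defaults.
- **Seeding**: one master seed; each generator derives its own stream via
  a fixed labelled `SeedSequence` spawn key. Every generator is a pure
  function of the config.

What it does **not** model — and hence what passing tests do not show
about real data: peptide detectability and MS missingness, batch effects,
correlated gene-gene noise beyond shared TF targets, composition bias
large enough to distort FPKM ratios, mRNA–activity decoupling, and
incomplete or wrong regulatory annotations. Recovery rates on synthetic
data are upper bounds on what curated real inputs would give.

## Problem sizes and calibration behaviour

The default synthetic study (200 TFs, 2000 genes, 20 targets/TF, 10 + 10
planted, 10 000 permutations) runs in ~2 s per transition; the test suite
uses 50-TF configurations for structural checks and the defaults for the
recovery benchmark (10 seeds), and the acceptance script uses 3 seeds for
recovery and a 60-TF pipeline for the determinism/recovery checks. The
null-calibration check uses 500 null TFs on one shared transcriptome;
because all TFs are tested against the same realized fold-change vector
their p-values are positively dependent, so the observed rejection rate at
α = 0.05 fluctuates more across simulations than a binomial count would —
roughly 0.02–0.06 in practice — while the p-value distribution remains
uniform by construction (KS-tested).

## Known limitations

- The |log2FC| ≥ 1 DE stand-in is cruder than a count-based NB test; with
  external DE calls the pipeline matches whatever caller produced them.
- The double filter (activity and target test) makes false positives rare
  under the simulated noise, but real assays with heavier-tailed replicate
  noise would push more null TFs over the activity thresholds.
- "Co-expressed" for co-activators is a point decision (DE in the treated
  transition); a correlation-based reading would need replicate-level
  co-variation the current tables do not carry.
- The intersection treats transitions symmetrically; ordering effects
  (e.g. requiring opposite directions in the two transitions) are left to
  the caller, who can filter the per-transition critical tables directly.
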