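# Methods

`fragdms` implements a fragment-consensus deep-mutational-scanning (DMS)
analysis for a dual-function bacterial porin — a LamB-like maltoporin that
is simultaneously the maltodextrin transporter and the receptor for phage λ
— together with a synthetic-data generator that reproduces the statistical
structure the analysis assumes. This note records the model, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
experiments do and do not demonstrate.

## The measurement model

A plasmid-borne library of gene variants, produced by error-prone PCR over
the 1341 bp coding sequence, competes for growth under two selections with
matched controls:

* **phage selection** (rich medium + λ vs. rich medium): losing the porin
  confers resistance, so *loss* of function is enriched;
* **transport selection** (minimal medium + maltodextrin vs. + glucose):
  the porin is required for growth, so loss of function is depleted.

Sequencing does not read whole variants. The amplicon is tagmented into
short fragments (median ≈ 63 bp), read as 2×38 bp pairs, and mutations are
scored *marginally*: each mutation's counts aggregate over every variant
that carries it, disregarding co-occurring mutations. For each mutation
`m` at a position with reference base `wt`, per replicate,

    E = log2[ ((C_sel,mut + p) / (C_sel,wt + p)) /
              ((C_ctrl,mut + p) / (C_ctrl,wt + p)) ],   p = 0.1

and the functional score rescales `E` linearly per replicate so that the
median synonymous mutation has F = 1 and the median nonsense mutation has
F = 0:

    F = (E − median(E_stop)) / (median(E_syn) − median(E_stop)).

Both selections use these anchors in this orientation (for the phage
selection the scaling reverses the axis, since enrichment there means
resistance). An alternative published form of the maltodextrin score with
the anchors swapped — median synonymous → 0, median nonsense → 1, i.e. the
mirror `1 − F` — is available as `malt_formula="as-printed"` for
comparison; the package treats the syn→1/stop→0 convention as canonical
because it is the one the phenotype vocabulary (Mal+ above threshold)
requires. Mutations with a mean control-condition fragment count below 5
across replicates are discarded before scaling; scores are averaged over
the replicates in which a mutation passed (3 biological × 2 technical = 6
by default). Stop-loss mutations are scored but excluded from both anchor
sets.

## Error correction by fragment consensus

Raw read pairs are collapsed by exact sequence identity and unique pairs
seen fewer than 5 times are discarded. Because a sequencing error changes
the pair's sequence, erroneous copies split into low-multiplicity groups
that the filter removes; the surviving pair is the consensus of its PCR
duplicates. Surviving pairs are merged at their 3′ overlap (longest exact
overlap first, then a mismatch-tolerant search capped at 20% overlap
mismatch, disagreements resolved by quality with ties to read 1), aligned
to the amplicon without gaps (exact k-mer seeding, k = 16 from both ends
with a k = 12 and dense-probe fallback, both orientations,
reverse-complemented hits canonicalised to the forward strand, alignments
above 10% mismatch rejected), and deduplicated by
(start, end, substitutions) — the identity of a single transposition
event. Each unique fragment contributes exactly one count at every
position it covers, regardless of raw multiplicity: duplication reflects
PCR, not molecules.

**Non-overlapping pairs.** A pair whose mates do not overlap is treated as
*one* fragment whose identity is (start from mate 1, end from mate 2,
substitutions), with only the two sequenced read windows contributing base
counts; the unsequenced middle is part of the identity but never counted.
This follows the transposition-event identifier directly. The alternative
— counting the two mates as independent fragments — is subtly wrong on a
short amplicon: a 38 bp mate span takes only ~1500 distinct values, so
wild-type mates from different transposition events collide into one
identity while mutation-bearing mates stay distinct, which inflated the
apparent mismatch rate from a planted 0.52% to 0.84% in testing. Mates
that do overlap after all are fused (substitution disagreements drop the
pair); mates in inverted order fall back to two independent fragments.

**Per-base rate estimation.** The library mutation rate is estimated as
mismatches over matched aligned bases in the control condition, restricted
to CDS positions (the flanks carry no library mutations) and weighted by
raw multiplicity. The weighting undoes the residual identity collisions of
a short amplicon: two transposition events that produce byte-identical
fragments still contribute two events' worth of raw reads. Note the tally
estimates `r/(1−r)` for a planted rate `r` (0.5227% for 0.52%), which is
well inside any quoted precision.

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which every downstream claim is evaluated.

* **Libraries.** Each CDS base mutates independently with probability
  equal to the per-base rate (0.52% for the phage selection's library —
  ≈ 7 mutations/variant — and 0.063% — ≈ 0.84 — for the transport
  selection's, as in the experimental design). The substitution spectrum
  defaults to transition-biased (2/3 transitions, 1/6 each transversion),
  reflecting error-prone PCR chemistry; a uniform spectrum is one
  parameter away. Indels are not simulated: the analysis is
  substitution-only end to end.
* **Fitness model.** Each mutation carries a stability cost shared by both
  traits; variant trait fitness is the product of (1 − effect) over its
  mutations, with any nonsense mutation forcing both traits to zero and
  the wild type at (1, 1). Missense stability costs are drawn from a
  bimodal continuous distribution: Beta(0.6, 14) (near-neutral) with
  probability 0.88, Beta(2.5, 1.2) (deleterious) with probability 0.12 —
  bimodal-but-continuous, as DMS effect distributions generally are, and
  giving ≈ 30–40% fully functional variants at 7 mutations/variant,
  consistent with the observation that a majority-to-half of high-load
  variants keep function. Phage-binding effects U(0.75, 1) are planted
  with probability 0.5 on missense mutations in a configurable loop
  window (residues 240–260 by default, standing in for the receptor
  loop; these draw only near-neutral stability costs, as surface loops
  rarely destabilise). Transport-pore effects U(0.5, 1) appear with
  probability 0.4 in a pore window (residues 105–125). Stop-loss
  mutations get a fixed 0.9 stability cost.
* **Selection.** Expected post-selection frequency is proportional to
  `pre × 2^(g·w)` with `w = 1 − f_sensitivity` under phage (resistance
  grows), `w = f_malt` under maltodextrin, and `w = 1` in controls;
  g = 10 (phage) and 6 (maltodextrin) generations by default, followed by
  a multinomial bottleneck (200 000 cells by default). Biological
  replicates are independent selection runs of the same library;
  technical replicates re-fragment and re-sequence the same
  post-selection population.
* **Sequencing.** Fragment lengths are lognormal (median 63 bp, σ = 0.35,
  clipped to [25, 250]); starts are uniform; read pairs are 2×38 with
  per-base error 0.002 injected independently into every raw copy; raw
  duplication is 5 + Poisson(3) per unique fragment. The duplication
  floor of 5 emulates, at desk scale, the deep duplication (40–80×) of
  the real protocol, in which essentially no true fragment fails the
  min-raw filter.

**Problem sizes.** Default libraries are 10 000 variants (phage) and
20 000 (transport), sequenced at 150 000 and 350 000 unique fragments per
condition-replicate. The real libraries exceed 10⁶ variants; the
desk-scale sizes are chosen so that the *per-mutation carrier statistics*
that the marginal-scoring assumption rests on survive the reduction
(≈ 35 phage-library and ≈ 8 transport-library carriers per transition
mutation), with the sequencing depth each library needs for its mutations
to clear the 5-count input filter — the simulator's lighter duplication
(5 + Poisson(3) versus the protocol's 40–80×) is what buys that fragment
depth within a comparable raw-read budget. A `demo_config()` more than an
order of magnitude smaller exists for smoke tests. The full default
experiment runs in under ten minutes on one CPU.

## Phenotype classification

Calls are pure threshold functions of the mean scores: λ-sensitive iff
F_λ ≥ t_λ (0.5 by default; 0.35 as the refined option that removes
partially resistant mutations), Mal+ iff F_malt ≥ 0.5, and jointly
functional iff (F_λ + F_malt)/2 ≥ 0.5; a score exactly at a threshold
counts as the functional side. The Mal+/Mal− ratio curve restricts to
missense mutations with both scores and uses strict F_λ < t, matching the
"below a threshold" framing it summarises. The Gaussian-intersection
threshold fits each class by its sample mean and SD and returns the
pdf-equality root between the two means (midpoint for equal variances;
zero variance is an error so the caller can fall back to the midpoint
deliberately). Two-sample Kolmogorov–Smirnov comparisons use the
asymptotic p-value.

## What the synthetic experiments show — and what they cannot

Construction-forced properties (anchor medians exactly 1 and 0, their
midpoint 0.5), analytic consequences of printed parameters (mutation
loads 7 and 0.84; recovery of the planted 0.52% rate by the mismatch
tally), clean synonymous/nonsense separation, joint classification
accuracy ≳ 0.9, and recovery of planted fully-resistant,
transport-competent loop mutations are all reproduced at desk scale. In
the recovery test, "individually true" resistance means the single mutant
retains ≤ 10% of wild-type phage sensitivity — the analogue of full
resistance in an individual growth assay — and the test conditions on
mutations scored in both selections, since an unobserved mutation cannot
be recovered. Recovery is not perfect even for true positives: carrier
backgrounds compress the marginal score of a plant with residual
sensitivity `s` toward the synonymous anchor (roughly F ≈ 0.15 at
s = 0.05 and F ≈ 0.27 at s = 0.1 under the defaults), so candidates near
the s = 0.1 boundary carry a ~10–20% miss rate at the 0.35 threshold —
the synthetic twin of the pooled-versus-individual-assay disagreements
such screens show in practice.

One nominal property is *not* met and is asserted anyway: Spearman ≥ 0.8
between true single-mutation λ-sensitivity and mean F_λ over filtered
mutations. Marginal scores average each mutation over its carrier
variants with weights 2^(g·w); at 7 mutations/variant the heavy-tailed
carrier backgrounds — frozen per library, so replicate averaging cannot
remove them — dominate the rank signal of near-neutral mutations.
Count-level simulations show the correlation saturating near ~0.78 even
for libraries of 10⁵–10⁶ variants at fragment coverage far beyond any
desk budget, and reaching only ~0.3–0.6 at feasible scales, across
effect-distribution shapes. The corresponding test is expected to fail;
it is retained, unweakened, as an honest record of this structural limit.

The generator also does not emulate several features of real data:
coverage bias from Tn5 insertion preferences (starts are uniform),
quality-score structure (qualities are constant), adapter read-through
(reads are adapter-free; real data must be pre-trimmed), indels, chimeric
fragments, or phage co-evolution. Passing tests therefore validate the
pipeline's logic and calibration, not robustness to those artefacts.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally and 1-based in every emitted
TSV. Enrichments are computed for all CDS substitutions with pseudocount
0.1, so zero counts stay finite; `pseudocount=0` is accepted for exact
hand checks. Scaling requires at least one synonymous and one nonsense
mutation per replicate and raises (naming the replicate) when the anchor
medians coincide. The k-mer aligner is fully deterministic; alignment
ties prefer the forward orientation and the smallest offset. All
randomness flows from one global seed through named (stage, selection,
replicate) streams, so two runs of the same config are byte-identical;
replicate streams are independent. Input-validation errors raise
`ValueError` with the offending value; pipeline stage failures abort with
the stage name and replicate id.
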