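# Methods

## The model

`pascloud` treats a signaling pathway as a flat, role-annotated gene set: no
topology, no kinetics, and all members of equal |role weight| contribute
equally. This rests on the assumption that most signal-transduction
proteins operate far from saturation, so a pathway's net output responds
multiplicatively to the expression of its activators and inversely to its
repressors. The multiplicative disturbance estimator is

SPCD_p = Π_i [AGEL]_i / Π_j [RGEL]_j,

the product of activator expression levels over repressor levels (its
proportionality constant is fixed at 1; only ratios and orderings are
meaningful). Switching to logarithms gives the additive pathway activation
strength used everywhere in the package:

PAS_p = Σ_n ARR_n,p · BTIF_n · lg(ECR_n)

- **ECR** (enhanced-to-control ratio): the gene's expression in one case
  sample divided by its control-group mean, both stabilized by a
  pseudocount (below). Computed per case sample; the per-pathway aggregate
  is the arithmetic mean over case samples, with the sample SD reported
  alongside (undefined for a single case sample and reported as NaN).
- **ARR**: signed role weight. Default +1/−1/0 for
  activator/repressor/neutral; the pathway file may supply graded
  magnitudes in (0, 1] for weak roles. The sign is always forced by the
  role, so sign(ARR) = role holds by construction.
- **BTIF**: the beyond-tolerance flag gates every contribution. It is 1
  only when both (i) ECR > 3/2 or ECR < 2/3 (strict inequalities: a ratio
  of exactly 3/2 is inside tolerance) and (ii) |case − control mean| >
  2 × control SD. With perfectly constant controls (SD 0) criterion (ii)
  reduces to "the case value differs at all", since the strict inequality
  would otherwise make flags impossible. The lg is log base 10, the
  standard reading; any other base would only rescale PAS uniformly.

For unit role weights with every flag raised, 10^PAS = SPCD exactly; the
test suite asserts this to 1e-9 relative over random pathways.

The **signaling pathway cloud** is the set of pathways whose |aggregate
PAS| exceeds a threshold (default 0, i.e. any nonzero PAS — no principled
cutoff exists, so the default hides nothing), labeled activated (PAS > 0)
or repressed (PAS < 0) and sorted by descending |PAS| with ties broken by
pathway id.

## Tolerance policy parameters

| parameter | default | meaning |
|---|---|---|
| fold_upper | 3/2 | upper ECR bound of the tolerance interval (unitless ratio) |
| fold_lower | 2/3 | lower ECR bound; reciprocal of fold_upper, so the interval is symmetric on the log scale |
| sd_multiplier | 2 | control-SD multiples the case value must deviate by |
| pseudocount | auto | max(1e-8 × matrix median, 1e-12), added to ECR numerator and denominator; guards division by zero without distorting moderate expression. Set explicitly to override |
| min_control_n | 3 | below this, the control SD (n−1 denominator) is too degenerate for the SD criterion |
| use_sd_criterion | true | disabling reduces BTIF to the fold criterion alone (diagnostic use; also makes PAS exactly antisymmetric under ECR reciprocals) |

Expression input must be linear-scale and non-negative; log-transformed
data must be de-logged upstream, because the score mixes ratios and logs
explicitly. The default normalization is quantile normalization applied to
all samples jointly (cases and controls together), mapping every column
onto the mean order statistics; ties receive the mean of the tied targets,
which preserves within-column ranks but deliberately trades exact multiset
equality for rank stability when duplicates occur. `none` is available
when columns are already comparable.

Open modeling choices resolved here: the BTIF SD criterion compares each
**single case sample** to the control mean (not the case-group mean) — the
per-sample reading keeps PAS defined per sample and matches the method's
description of scoring "the sample" against the control group; multiple
case samples are aggregated by the arithmetic mean of per-sample PAS.
Pathway members absent from the expression matrix are skipped and surfaced
as a per-pathway coverage count (`n_measured` of `n_members`) rather than
an error, so partially measured platforms remain usable; a pathway with no
measured member gets an undefined (NaN) PAS, distinct from an exact 0.

## Enrichment

Pathway prioritization for a gene list uses the one-sided (enrichment)
Fisher exact test: p = P(X ≥ a) for the hypergeometric overlap count under
fixed margins, computed via the exact survival function. The background
universe defaults to the union of all database genes and can be replaced
by an explicit measured-gene list. Reported per pathway: the overlap
percentage (100·a / pathway size within the universe), the sample
cross-product odds ratio (a·d)/(b·c) — reported as ∞ when b·c = 0, with an
optional Haldane 0.5 correction — the raw p, and the Benjamini–Hochberg
adjusted p across all tested pathways. Note that published pathway tables
sometimes print odds ratios under other conventions (e.g. inverted or
continuity-corrected); the cross-product convention used here exceeds 1
under enrichment.

## Drug screening

A drug's signature is its aggregate PAS profile computed from treated vs
untreated expression by exactly the same engine (treated = case). Scores
against a target cloud restrict both vectors to the cloud's pathways
(target vector t, drug vector v, with v = 0 where the drug PAS is
undefined — such pathways still count against a reported coverage
fraction, so sparse drug data is visible rather than silently favorable):

- **mimic**: cos(v, t) ∈ [−1, 1] — scale-free reproduction of the cloud;
- **minimize**: cos(v, −t) — reversal of the cloud (identically
  mimic against the negated target). "Minimize" is read as reversing the
  disturbance; the alternative reading (shrinking |PAS| toward zero)
  describes the *absence* of signal and cannot rank drugs by itself;
- **exaggerate**: (v·t)/|t|² — the signed projection ratio; scores > 1
  certify beyond-target amplitude, which a cosine cannot express.

A weighted variant (weights ∝ |target PAS|) is available to emphasize the
cloud's strongest pathways. Drugs are ranked by descending score, ties
broken lexicographically by drug id; |v| = 0 yields score 0 with an
explicit zero-signal flag. Precomputed signature TSVs can stand in for raw
expression pairs in the library manifest.

## Synthetic data

The generator emulates the intended contrasts (e.g. enhanced vs. control
brain): per gene a log10 baseline drawn uniformly on (1, 3) — spanning
~10–1000 expression units, a realistic dynamic range for array-scale
data — and i.i.d. per-sample Gaussian noise on the log10 scale
(biological_sd, default 0.1 ≈ 26% CV). Planting a fold f on a pathway
multiplies its activators by f and its repressors by 1/f in case samples
only, so the expected PAS under full flag passage has the closed form
Σ_members |ARR| · log10 f. Default study conditions: 10 disjoint pathways
of 6–10 members (at least one activator and one repressor each, activator
fraction 0.7), 5 case and 5 control samples, planted fold 2. Drug
libraries contain mimics (same planted pathways/folds, optionally
attenuated as f^a) and decoys (disjoint random pathways, or reciprocal
folds for reversal studies). A single global seed feeds a named stream per
component, so adding a stage never perturbs another stage's draws, and
every artifact is byte-reproducible given the seed.

What the generator does **not** model: platform-specific noise (probe
effects, sequencing depth), correlated co-expression beyond pathway
membership, overlapping pathway gene sets, and cross-species ortholog
structure. Passing recovery tests therefore demonstrate the pipeline's
correctness and power under clean log-normal conditions, not performance
on real cross-platform data.

## Calibration and known limitations

Under pure noise at biological_sd = 0.1 with 5-sample control groups,
about 6.5–7% of gene×sample flags fire at the default policy. This is
intrinsic to the thresholds, not an implementation artifact: with exact
control statistics the binding 2-SD criterion alone admits P(|z| > 2) ≈
4.55%, and estimating the mean and SD from 5 controls (the SD is
downward-biased at 4 degrees of freedom) inflates the rate further. The
false-trigger rate drops steeply with noise (≈3% at sd 0.08, <0.5% at sd
0.05) and with larger control groups. Pathway-level scores are far better
calibrated than single flags because unplanted pathways average ~0 signed
contribution; the planted pathway is still recovered in ≈100% of
replicates at fold 2.

Other limitations: membership+role scoring ignores pathway topology and
post-transcriptional regulation; quantile normalization is the only
batch-correction offered; the exaggerate score is unbounded and should be
read together with the mimic cosine (a drug can "exaggerate" along a
direction far from the target); and screening validates recovery of
planted transcriptional signatures only — it makes no claim about actual
pharmacological efficacy, which requires downstream experimental
validation.
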