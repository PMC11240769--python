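# Methods

## Data model

A study is a non-negative integer count matrix (features × samples; feature
IDs are opaque and never parsed — exon-level, gene-level and miRNA matrices
are treated identically) plus one clinical record per sample: patient, tissue
(blood or tumor), phase (pre-surgery, post-surgery, recurrence) and day
offsets relative to surgery and, for recurrence draws, relative to the
recurrence diagnosis. Phases are taken from the metadata and never inferred
from day offsets: a recurrence-phase blood draw can precede the radiological
diagnosis (a negative diagnosis-relative day), and inferring the phase from
timing would misclassify exactly the clinically most interesting sample.
Tumor-tissue samples are ordinary columns flagged `tissue=tumor` with phase
`pre_surgery` (resected at surgery); they participate only in the expression
filter, never in fold-change baselines or the later filters. Validation
requires per patient at least one pre-surgery and one post-surgery blood
sample and at most one tumor sample. Missing counts are not represented;
absence must be encoded as zero upstream.

## Median-of-ratios normalization

Size factor of sample *j*: the median over reference features *i* of
`K[i,j] / ref[i]`, where `ref[i]` is the geometric mean of feature *i* across
samples and the reference set is the features strictly positive in every
sample (a zero anywhere makes the geometric mean degenerate). Even-length
medians use the midpoint convention. Size factors are *not* rescaled to
geometric mean one: the raw medians are the scale on which the "≥ 10
normalized counts" expression threshold is interpreted.

Two deliberate consequences:

* **Global scale invariance.** Multiplying every count by c > 0 leaves every
  ratio — hence every size factor — unchanged, and scales normalized counts
  by c. (The factors are relative quantities; only ratios between samples are
  identified.)
* **Scope.** Normalization is per patient by default, over that patient's
  blood and tumor columns jointly, so the expression threshold is comparable
  across the columns that filter 1 compares; a cohort-wide mode is available
  by configuration since the choice is not forced by the method.

For sparse matrices where no (or almost no) feature is positive everywhere, a
positive-subset fallback computes `ref[i]` over feature *i*'s positive samples
and each sample's median over the features positive in that sample. It is off
by default and logged when used; the plain procedure raises an explicit error
when the reference set is empty rather than silently switching.

## Fold-change trajectories and the triple filter

Baseline = arithmetic mean of normalized counts over the patient's pre-surgery
blood samples (the reference cohort designs have exactly one, so the mean is
an extension point, not a reinterpretation). FC is computed for every
post-surgery and recurrence blood sample. A zero baseline makes the
trajectory undefined; such features can pass no filter (with a positive
expression threshold they would already fail filter 1).

Filter semantics and the reasoning behind the non-obvious choices:

1. *Expressed pre-surgery*: normalized count ≥ `min_norm_count` (default 10)
   in **every** pre-surgery blood sample (a mean-based variant is
   configurable) and, when the patient has a tumor column under the default
   `auto` requirement, in the tumor sample as well. Patients without usable
   tumor RNA automatically fall back to the blood-only condition.
2. *Downregulated post-surgery*: fraction of post-surgery samples with
   FC ≤ `fc_down` (default 0.5) is **≥** `frac_down` (default 0.5).
   The at-least-half reading is forced by the method's own worked example: a
   published candidate shows post-surgery fold changes 0.6 and 0.09 — exactly
   one of two samples 2-fold down — and is reported as a candidate. A strict
   majority remains available via `frac_down` slightly above 0.5. Recurrence
   samples never count toward this fraction. Both FC boundaries are
   inclusive (FC ≤ 0.5 down; FC ≥ 1 rebound).
3. *Rebound at recurrence*: FC ≥ `fc_recur` (default 1.0) in at least one
   recurrence sample (`any`; earliest possible detection is the clinical
   intent). `majority` and `all` are stricter options for multi-draw
   patients. A patient without recurrence-phase samples yields no candidates
   (logged); the earlier filter sets are still reported.

Filters apply as ordered set intersections, so cascade counts are
non-increasing by construction, and tightening any threshold can only shrink
the candidate set. One patient's failure (e.g. an unnormalizable all-zero
patient) is logged and does not abort the cohort.

## Overlap and enrichment

Overlap: each feature in the union of per-patient candidate sets is assigned
to its exact membership pattern; all 2^k − 1 region counts are reported
(capped at k = 10 patients). The counts partition the union and, summed over
the regions containing a patient, recover that patient's candidate count.
Because the same gene is repeatedly detected on different exons, an optional
pass collapses feature IDs through a user-supplied feature→gene map before
counting; it is off by default because no map ships with the package.

Enrichment: for candidate list *n* from universe *N* and a set with *k*
members in the universe, expected = `n·k/N`, fold enrichment =
observed/expected computed from the unrounded expected value, p =
hypergeometric upper tail P(X ≥ observed), FDR = Benjamini–Hochberg across
the collection, rows sorted by ascending p. Only over-representation is
tested. The universe is caller-supplied — a natural choice is the features
passing filter 1 — because enrichment is only interpretable relative to what
the assay could have detected.

## Synthetic cohorts

The generator's mean model: feature *i* in sample *s* has mean
`mu_i · (1 + alpha · b(s))` for signal features, `mu_i · (1 + alpha · r(s))`
for surgery-response features, `mu_i` for background, each multiplied by a
per-sample depth factor. `b(s)` is the latent tumor burden (pre-surgery 1,
post-surgery 0, recurrence 1 by default; the early post-surgery value is the
*masking* knob, and tumor tissue uses b = 1 so filter 1's tumor requirement
is satisfiable by construction). `r(s)` is 1 only in early post-surgery blood
draws (≤ 14 days). Counts are negative-binomial with size parameter
`dispersion` (variance mu + mu²/size); feature means `mu_i` are log-normal;
depth factors are log-normal with sd `depth_sd`. A single seeded RNG drives
everything, and identical configs give byte-identical TSV output.

Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| n_features / n_signal / n_surgery_response | 2000 / 50 / 50 | desk-scale feature panel with a 2.5% planted signal |
| alpha | 3.0 | effect size: pre-surgery signal mean is (1+alpha) = 4× its resected level, so the expected post/pre FC is 0.25, comfortably inside the 2-fold filter |
| burden_recurrence | 1.0 | rebound exactly to the pre-surgery level — the weakest rebound the recurrence filter should accept in expectation |
| masking | 0.0 | residual early-post-surgery burden; 0.6 models strong acute surgical masking (early FC ≈ 0.7, outside the 2-fold filter) |
| dispersion | 10 | NB size; per-sample CV ≥ 1/√10 ≈ 0.32, a heavily overdispersed whole-blood regime |
| depth_sd | 0.3 | ~35% library-size spread for normalization to absorb |
| baseline_log_mean, baseline_log_sd | log 50, 1.0 | moderately expressed features spread over roughly an order of magnitude either way; chosen for testability — most features clear the expression filter so the later filters are the ones exercised. Real transcriptomes are far wider (the reference assay's expression filter removes > 99% of exons), which this generator does not emulate |

Default timelines replicate the seven reference designs (one pre-surgery
draw; 1–4 post-surgery draws; 1–2 recurrence draws, including one taken 13
days *before* the diagnosis; tumor tissue for four of seven patients), so the
edge cases — single post-surgery sample, pre-diagnosis recurrence draw,
missing tumor — are exercised by default. An `early_only_timelines` variant
moves every post-surgery draw into the early window while preserving counts,
for studying masking.

Recovery metrics: per patient, sensitivity = |candidates ∩ signal| / |signal|
and false-discovery proportion = |candidates \ signal| / max(|candidates|, 1);
pooled values aggregate the confusion counts across patients (and seeds), by
default restricted to patients whose cascade had a recurrence sample.

### What the reference scenario does and does not show

At the reference settings (alpha 3, dispersion 10, depth_sd 0.3, rebound 1.0,
no masking) the pipeline's operating point is **sensitivity ≈ 0.5 and FDP ≈
0.6**, and this is a property of the scenario, not an implementation defect:

* with the rebound at exactly the pre-surgery level, FC ≥ 1 at a recurrence
  draw is the event "recurrence count ≥ pre-surgery count" between two
  exchangeable noisy draws, which has probability ≈ ½ regardless of the noise
  level — the recurrence threshold sits at the *median* of the signal FC
  distribution. Raising `burden_recurrence` into the "even higher" regime
  moves signal features off the boundary and sensitivity rises accordingly;
* at dispersion 10, a null feature passes the 2-fold-down criterion in ≈ 6–7%
  of post-surgery samples, so filters 2–3 together pass a few percent of the
  null universe; with 50 signals among 2000 features, false candidates are
  then comparable in number to true ones. The screen is intentionally
  permissive — it shortlists candidates for per-patient follow-up rather than
  controlling an error rate.

The masking contrast is robust at these settings: with masking 0.6, cohorts
whose post-surgery draws are all early recover about 0.09 of the signal
versus about 0.41 when late draws are included (20-seed pooled values from
the acceptance script) — the simulation counterpart of the observation that
acute surgical effects hide tumor-associated downregulation in the first
days after surgery, and that later sampling points are necessary.

Passing tests on these synthetic cohorts show the pipeline's logic is correct
under its own assumptions; they do not certify performance on real whole-blood
data, whose feature-mean distribution, dispersion structure, batch effects and
cellular composition the generator does not model.

## Numerical choices and degenerate inputs

* Geometric means are computed in log space; medians use the midpoint
  convention.
* Oracle agreement tolerances: 1e-9 relative for size factors against the
  brute-force ratio-table oracle; 1e-12 absolute for hypergeometric p-values
  against exhaustive enumeration (universes ≤ 12).
* Ties at filter boundaries are kept (≤ / ≥ comparisons are inclusive).
* Zero baseline → undefined trajectory → excluded from filters 2–3.
* Empty reference set in normalization → explicit error naming the
  positive-subset fallback; an all-zero sample is an error in fallback mode.
* Enrichment with an empty-in-universe set: expected 0 and observed 0 give
  fold 0 and p = 1; observed > 0 with expected 0 is impossible when
  candidates ⊆ universe and raises.

## Known limitations

* No statistical test per gene (the screen defines none); no batch
  correction; no exon-to-gene aggregation beyond the optional overlap
  collapse; no dispersion estimation or differential-expression model.
* The simulator draws signal and background feature means from the same
  distribution; assay-specific mean–variance structure is out of scope.
* Enrichment results depend entirely on the user-supplied universe and GMT
  collection; no annotation database is bundled.
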