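# Methods

This note documents the modeling decisions behind `hcscreen`: what the
kinship model and criteria engine assume, how the validation statistics are
defined, what the synthetic cohort generator does and does not emulate, and
where the design was genuinely open.

## Kinship model

Relatives are captured by controlled labels, not an explicit genealogical
graph. Every label maps to a degree (1–3), a lineage (maternal, paternal, or
*both* for full siblings and descendants, who share both bloodlines), and a
generation offset. This matches how digital intake tools record family
history — degree plus side per affected relative — and is sufficient for
every implemented rule, including the two-successive-generations clause of
Amsterdam II. Degree beyond 3 is not representable: the tool's scope is the
three-generation pedigree.

Half-siblings must carry a side tag (maternal/paternal); an untagged
half-sibling has no defined lineage and is rejected at validation.

**Re-rooting.** Family-history mirroring (rule B18) re-expresses the pedigree
from the seat of a first- or second-degree relative. The relabeling is a
hand-built table over (root label × member label). Members whose relation to
the root is not derivable from labels alone are dropped rather than guessed:
a maternal great-grandparent is a grandparent of the proband's mother, but
the labels do not say on which of *her* sides, so no controlled label
applies. Niece/nephew and grandchild roots retain only themselves (the labels
do not identify the connecting parent); mirrored personal-history rules that
need no relatives (e.g. ovarian carcinoma in a niece) still fire there, which
is the clinically dominant case. One assumption is baked in: when re-rooting
at a child of the proband, the proband's other children are treated as full
siblings of the root.

These drops make the mirror slightly conservative for multi-relative clauses
evaluated at distant seats. The trade for auditable, total, deterministic
label algebra was judged worth it; an explicit-graph backend could lift the
limitation without changing the rule layer.

## Normalization

* Imprecise ages: early decade → start + 2, late decade → start + 8, whole
  decade → start + 5 (the decade median). Offsets are configurable
  (`DecadeOffsets`). Imputation is idempotent on exact ages and always lands
  inside the referenced decade.
* Unknown ages satisfy only "at any age" clauses — the engine never invents
  an age, matching pedigree-review practice.
* The tumor vocabulary ships 36 named canonical types plus
  `other_unspecified`; unmapped free text maps to the latter, never to an
  error, so evaluation is total over any input. The exact membership of the
  36-type list in deployed intake tools is not public; the shipped list
  covers the types the criteria reference (including the ovarian equivalents
  — fallopian tube, primary peritoneal — and the Lynch-related set with the
  Muir-Torre lesions) plus the common sporadic types, and is extensible via
  `CancerVocabulary.extend`.
* Prostate cancers without grading data are assumed high-risk
  (Gleason > 7), because pedigrees rarely record aggressivity. This is
  deliberately anti-conservative for the prostate-anchored rule (B16).

## Criteria engine

Age bounds: the BRCA breast bounds (45/50/60) are applied inclusively —
"diagnosed at or under 45" — while the Lynch and Amsterdam II bound is a
strict "before age 50". Both are configurable (`EngineConfig`).

Counting semantics for "index case + k close relatives" clauses: the counted
relatives must share one side of the family (both-lineage members count on
either side); the index person never supports their own clause; distinct
people are counted, not distinct tumors — except the second-breast-primary
rule, which is within-person by definition.

The limited-family-history clause (B7) needs an operational rule, since
"limited" is qualitative in the guidelines: a side counts as limited when
fewer than 2 relatives beyond the parents are reported or declared for it
(threshold configurable); both sides must be limited. B7 is anchored to the
respondent: the intake records family structure for the proband only, so the
clause is not mirrored onto relatives — a relative's own family size is
unknowable from the recorded pedigree, and mirroring it would flag any lone
young-breast-cancer relative as "limited family".

The third-degree-relative rule (B19) reads its printed form as: a TDR with
breast and/or ovarian carcinoma, plus at least two blood relatives on the
TDR's side (the proband may be one) each with breast and/or ovarian, of whom
at least one has breast at/under 50 **or** ovarian. The published wording is
grammatically ambiguous about whether the under-50 anchor can be satisfied by
an ovarian case; reading "and/or ovarian" as an alternative anchor keeps
ovarian-only clusters eligible, consistent with how ovarian carcinoma behaves
everywhere else in the rule set.

Known-mutation rules (B1/L1/P1) fire on a finding in any blood relative of
degree ≤ 3, or the proband. The polyposis rules are threshold rules
(cumulative adenoma count ≥ 10 by default, proband or FDR) — guideline
criteria here are count-based, and the threshold is exposed in both the
engine config and the registry file.

The registry (`data/criteria_v2_2017.yaml`) is the human-readable record of
the 28 implemented rules (id, syndrome, wording, parameters) and the
extension point: criteria sets in the guidelines are larger than the subset a
retrospective cohort exercises, and new ids can be added without engine
changes.

## Independent events and modeled low-risk cases

The unit of validation analysis is the independent event. High-risk
pedigrees contribute one event per fulfilled criterion (a pedigree can
fulfill several). Low-risk pedigrees contribute one event per recorded
(person, diagnosis) history — type, imputed age, degree, side — plus one
*combination* event per family side carrying ≥ 2 histories, or a single
*no family history* event when nothing is recorded. Whether a combination
groups a whole side or each pair is config-selectable (`GroupingMode`);
per-side is the default, as the minimal reading of "entered as a combination
event" (singular). The proband's own history never joins a family-side
combination.

Modeled low-risk cases remove qualifying history from a high-risk pedigree
until nothing fires. Removal is greedy and deterministic: at each step delete
the diagnosis/mutation/polyp record whose removal extinguishes the most
fulfilled criterion events, breaking ties by youngest age at diagnosis, then
by member order. All surviving history is preserved verbatim; the operation
is idempotent, and a pedigree whose entire history qualifies becomes a valid
no-family-history case.

Per-event entry (`event_pedigree`/`predict_event`) reconstructs what a tool
operator would enter for one event: low-risk events carry their histories
plus the family's declared size (the intake always asks it, and without it
the limited-family clause would misfire on lone histories); criterion events
are restricted to their index person and contributing relatives, which makes
every reported event self-certifying — the restriction must still evaluate
high-risk, and the tests enforce this.

## Validation statistics

Confidence intervals are Clopper–Pearson exact by default (beta-quantile
formulation, with lower = 0 at x = 0 and upper = 1 at x = n); Wilson and Wald
are available but non-default — only the exact method reproduces standard
published screening-validation bounds such as (α/2)^(1/n) for the x = n
lower bound. Proportions are reported as percentages rounded to 2 decimal
places. Quantities with zero denominators are reported as undefined, never
as zero. The sample-size planner is the one-sample normal-approximation
formula n = (z₁₋α/₂ + z₁₋β)² p(1−p)/δ², rounded up; at p = 0.90, δ = 0.05,
α = 0.05, power = 0.90 it gives 379 events per arm.

## Synthetic cohort generator

The generator emulates the study design, not population genetics. A pedigree
gets a three-generation structure (parents, four grandparents, Poisson
numbers of siblings, aunts/uncles, first cousins), sporadic background
cancers per relative at fixed per-type incidences with truncated-normal ages,
an ethnicity draw matching the study's demographic mix (≈ 7.5% Ashkenazi
Jewish), and a 25% chance per age of being recorded imprecisely (exercising
the imputation path). High-risk pedigrees add one sampled *motif* — early
breast, same-side breast cluster, ovarian, male breast, Ashkenazi + breast,
young colorectal/endometrial FDR, Lynch cluster, known mutation — and are
verified against the engine; low-risk pedigrees are background passed through
the low-risk modeler. Polyp incidence defaults to zero, so default cohorts
contain no polyposis events, as in the validation cohort the design mirrors.

Baseline incidences and motif weights were calibrated once so a full-size
cohort (197 high / 123 low) lands near the study's marginal event rates
(≈ 1.9 criterion events per high-risk pedigree, ≈ 3.1 history events per
low-risk pedigree); across seeds the totals vary within roughly ±15%.

Because gold labels come from the same criteria semantics the engine
implements, the simulator validates *pipeline plumbing*, not criteria
correctness — an unperturbed cohort is exactly concordant (B = C = 0) by
construction, and discordance can only be injected through the explicit
perturbation operator (age jitter across thresholds, tumor-type relabeling).
Criteria correctness is established separately: a brute-force
clause-enumeration oracle (subset enumeration over every index person,
relative combination, and side) must agree with the engine on the full
fulfilled-criterion id set over thousands of random pedigrees, alongside
hand-checked worked histories. The oracle shares the kinship label tables —
they are the published semantics of the labels — but none of the engine's
clause logic. What passing synthetic tests does **not** show: performance on
real transcription noise, recall-biased family reports, or cancer-type
distributions beyond the emulated mix.

## Numerical and degenerate-input conventions

* Everything stochastic takes a mandatory seed; same (seed, config) gives
  byte-identical output.
* Tie-breaks in the low-risk modeler are fully ordered (yield, age, member
  order, payload order), so modeling is deterministic.
* Unknown-age records sort as oldest for removal tie-breaks.
* Degenerate pedigrees (no members, no diagnoses) evaluate cleanly to
  not-meeting; empty low-risk extraction yields the no-family-history event.
* Evaluation is pure: inputs are never mutated, and re-evaluation is
  reproducible.

## Known limitations

* Tumor/somatic test results and mutation-probability models are out of
  scope by design, as are guideline versions other than the 2017 semantics
  encoded in the registry.
* The mirror drops label-ambiguous relatives (see Kinship model), slightly
  under-firing multi-relative clauses at second-degree seats.
* The label algebra cannot express consanguinity loops, adoption, or
  degree-4+ kin.
* The Ashkenazi rule uses the proband's recorded ancestry for mirrored
  evaluation too (blood relatives share ancestry); one-sided ancestry is not
  modeled.
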