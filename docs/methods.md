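# Methods

## The assessment model

`cdomeval` operationalises a desk audit of how completely the metadata
describing chronic-disease outcome ascertainment are publicly available for
observational studies. The unit of assessment is the (study, source, field)
cell: nine metadata fields — three general (prevalent/incident outcome,
ICD-10 availability, primary/secondary outcome), four self-report details
(mode & device, disease domain, reference period, verification/external
validation), study examinations, and administrative databases — scored in
each of four public source channels (scientific publications, study
website, study/trial registries, data documents).

### Rubric

Within a cell the auditor records, per examined outcome group
(cardiovascular disease, cancer, type 2 diabetes), whether the field's
description is *complete*, *partial*, or *absent*. The ordinal score is

* 3 if every group is completely described,
* 2 if at least one but not all groups are completely described,
* 1 if no group is complete but at least one is partially described,
* 0 otherwise.

Mixed coverage (one group complete, another partial) scores 2, not 1: a
complete description anywhere dominates partial coverage elsewhere. This
precedence is a package decision — the verbal rubric leaves the boundary
between 1 and 2 open for mixed patterns — and it is verified against all 16
study statuses in the packaged fixture by the test suite.

### Channels

Websites and registries also act as indirect metadata channels (links and
references to publications or documents). Every such cell therefore carries
two scores: *direct* (embedded metadata only) and *combined*
(direct + indirect). For publications and data documents the combined score
mirrors the direct one. The combined score can only add information, so
`combined ≥ direct` is expected; violations are surfaced as warnings, not
errors, because the packaged fixture itself contains one such printed cell
(HNRS, website, primary/secondary: "2 (0)"), preserved verbatim as a
suspected erratum rather than silently corrected.

### Aggregation and classification

The overall score of field *f* in study *s* is the maximum non-NA score
across the four sources. Aggregation defaults to the direct channel; in the
packaged fixture the combined channel yields the identical overall matrix
(no parenthetical value exceeds the per-field direct maximum), so the
channel switch is inert there but meaningful for other inventories. A field
is NA overall only when it is NA in every source; the propagated reason
prefers design/exemption (study-wide facts) over source absence.

The study-level status is derived from the applicable (non-NA) overall
scores: all-zero → *missing*; minimum 3 → *complete for all outcomes*;
minimum 2 → *complete for some outcomes*; otherwise *partial*. This min/max
rule is the package's reconstruction of the verbal status definitions; the
test suite requires it to reproduce all 16 fixture statuses exactly.

Field-wise medians across studies use the standard median (mean of central
pair for even counts) over non-NA values; fixture medians are integers
either way, so the interpolation choice only matters for synthetic data.

A source counts as *available* for a study only when it is present and has
at least one strictly positive score on the chosen channel — a source that
was found but described nothing (e.g. a website with only links, scored on
the direct channel) does not count. This is required to reproduce the
fixture's 16/15/11/10 availability counts.

### NA semantics

The printed score tables conflate two kinds of "not applicable" in one
token. The package separates them:

* **design** — the study's design rules the field out (no examinations, no
  administrative ascertainment, no self-report). Administrative databases
  count only when they contribute to outcome *ascertainment*; databases
  consulted solely to verify individual self-reported cases do not.
* **field_exempt** — a per-study exemption of an otherwise applicable field,
  carried on the design profile. The fixture needs this for GEDA, whose
  ICD-10-availability and self-report-verification columns are printed NA
  across all sources without a general design rule that would exclude them.
* **source_absent** — the source itself was not found; every applicable
  field in it is NA.

Applicability is decided by an explicit `StudyDesignProfile`, not inferred
from the evidence, so the two study-level NA kinds stay testable
independently of source presence.

## Fixture

The packaged fixture transcribes a published audit of 16 German
population-based observational studies as three CSV files: the study roster
with design profiles, infrastructure availability/accessibility plus the
reported per-study status, and the per-source score matrix with cells kept
in their printed form ("3", "1 (3)", "na."). SHA-256 checksums of the three
files are verified on load. The reported statuses are carried only for
cross-checking: the pipeline re-derives every status from the per-source
scores, and the derived-vs-reported discrepancy list is empty.

## FAIR survey

The checklist instantiates the fifteen standard FAIR guiding-principle
criteria (F1–F4, A1, A1.1, A1.2, A2, I1–I3, R1, R1.1–R1.3); item texts are
configurable so a consortium-specific wording can be dropped in.
Respondents (one principal investigator per study) answer yes/no per item
and rate four built-in barriers — limited financial, human, technical
resources, and limited incentives — on three importance levels; free-text
barriers are allowed and aggregated under a normalized name.

Aggregation conventions:

* Unconditional items: percent yes over all respondents; a blank answer
  counts as not-yes (respondents were instructed to always answer yes/no,
  so a blank is a deviation, not a skip).
* Conditional items (A1.x, R1.x): apply only when the parent is yes.
  Respondents with an unmet parent are excluded from numerator and
  denominator (percent of applicable); an alternative percent-of-all
  convention is available via a flag, since either reading is defensible. A
  zero denominator yields an undefined marker, never 0 %.
* Barrier percentages are reported to one decimal; for built-in barriers the
  three levels sum to 100 up to rounding.

No inferential statistics are computed — the survey summaries are
descriptive percentages over a handful of respondents.

## Synthetic data generator

The generator emulates the statistical structure of an audit so every
pipeline stage is testable at arbitrary scale. Defaults mirror the packaged
audit's marginal conditions: 16 studies; publications and websites always
findable, registries with probability 11/16 and data documents 10/16; a
design mix of 11/16 full three-route designs, 3/16 without administrative
ascertainment, 1/16 without examinations, 1/16 survey-only; infrastructure
available with probability 11/16 split 7:3:1 across accessibility
categories; 10 survey respondents with the two reported barrier
distributions (80/10/10 human, 60/30/10 financial) and mid-range settings
(50/30/20, 40/40/20) for the two barriers whose distributions are not
reported.

Coverage is sampled per (source, field, outcome group) through an
ordered-probit representation: a standard-normal draw cut at thresholds
matching the configured complete/partial/absent distribution (default
0.5/0.2/0.3), optionally shifted by a per-(study, source) latent quality
effect (`quality_sd`, default 0 = off). With the latent effect off, cells
are independent and the probability that a present cell scores 3 is exactly
`p_complete³`, which the recovery tests check against 99 % binomial bounds
at 2 000 studies. The combined channel upgrades each group's coverage one
level with probability `p_indirect_upgrade` (default 0.5), so combined
dominates direct by construction. All three outcome groups are examined by
every synthetic study.

What the generator does *not* emulate: the strong correlation of real
evidence across fields within a source (a cohort profile describes many
fields at once — the fixture's score distribution is bimodal at 0 and 3,
while independent sampling concentrates mass on 2), correlation between
sources of one study, and any free-text metadata content. Passing recovery
tests therefore demonstrate correctness of the sampling and scoring
machinery under the stated independence assumptions, not realism of any
single simulated audit table; the optional latent quality effect restores
within-source correlation when realism matters more than closed forms.

Randomness flows from one seeded generator with a fixed stream order
(studies → design/infrastructure → sources → fields → groups → upgrade
draws); inventories and survey responses use separate child streams of the
same seed. Identical config and seed give identical output across runs and
platforms.

## Numerical and interface choices

* Scores and statuses are small frozen pydantic models; the seven possible
  field-score values are interned, which keeps bulk generation cheap.
* Status ordering (missing < partial < complete_some < complete_all) is a
  total order used by the monotonicity property tests: raising any single
  cell score can never lower an overall score or the study status.
* CSV dialect: one row per (study, source), score columns in canonical
  field order, paired direct/combined columns, NA spelled `na:<reason>`;
  study-level attributes are repeated per row. The structured format is a
  JSON/YAML document with a `schema_version` key. Both round-trip
  losslessly, NA reasons included.
* The machine-readable record schema shipped in
  `data/cdom_record.schema.json` is generated from the pydantic model and
  versioned; validation itself runs through pydantic.
* Markdown tables are rendered by a small in-package writer with fixed
  column ordering so repeated runs are diff-stable.
* Open vocabularies: interview mode, reference period and verification
  methods accept free text because the published lists are illustrative;
  the three built-in outcome groups are fixed, further groups can be
  registered but never collide with built-ins.

## Known limitations

* The rubric's 1-vs-2 precedence for mixed coverage and the min/max status
  rule are reconstructions validated against one complete printed audit;
  other auditors' verbal interpretations could differ.
* The per-study field-exemption list records, but does not explain, printed
  NA entries that no general design rule covers.
* Survey aggregation assumes one respondent per study and reports
  descriptive percentages only.
* The acceptance computations are fixture-driven and deterministic;
  synthetic problem sizes used in tests (up to 2 000 studies, 2 000
  respondents) were chosen so binomial recovery bounds are tight while the
  whole suite stays fast.
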