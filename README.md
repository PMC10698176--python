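# cdomeval

Completeness scoring and FAIR-survey aggregation for **chronic disease
outcome metadata** (CDOM) from population-based observational studies.

Epidemiological studies ascertain chronic-disease outcomes — cardiovascular
disease, cancer, type 2 diabetes — in very different ways: self-report
questionnaires, study examinations, administrative databases, or
combinations of these. Whether that contextual information (prevalent vs
incident cases, ICD-10 codes, interview mode, reference period, verification
of self-reports, …) is *publicly findable* decides how reusable and
interpretable a study's data are. `cdomeval` is for data managers and
metadata auditors who want to score that public availability reproducibly:
it models a nine-field CDOM schema, scores each field per study and per
public metadata source on an ordinal rubric, classifies studies, and
aggregates principal-investigator survey responses on consistency with the
FAIR principles (Findability, Accessibility, Interoperability, Reusability).

## The scoring model

For study *s*, metadata source *k* (scientific publications, study website,
study/trial registries, data documents) and metadata field *f*, the audit
records an ordinal completeness score

* **3** — complete description for **all** examined outcome groups,
* **2** — complete for **some** but not all groups,
* **1** — partial description (details missing),
* **0** — nothing found,

or **NA** when the field does not apply (study design, per-study exemption)
or the source was not found. Websites and registries are scored twice: on
the **direct** channel (metadata embedded in the source) and the
**combined** channel (direct + metadata reachable through links and
references).

The per-study overall score of field *f* is the maximum across sources,
x_sf = max_k x_skf over non-NA sources, and the study's completeness status
follows from its applicable overall scores:

| condition (non-NA fields)  | status                             |
| -------------------------- | ---------------------------------- |
| max x_sf = 0               | metadata missing                   |
| min x_sf = 3               | complete metadata for all outcomes |
| min x_sf = 2               | complete metadata for some outcomes|
| otherwise                  | partial metadata                   |

Field-wise medians of the overall scores across studies, per-source
availability counts (a source counts when present with at least one score
> 0), and (meta-)data-infrastructure accessibility counts summarise an
audit. The FAIR survey module aggregates yes/no checklist answers (15
standard FAIR criteria, with A1.x/R1.x conditional on their parent) and
three-level barrier ratings into descriptive percentages.

A packaged fixture transcribes a published audit of 16 German
population-based observational studies; a seeded generator produces
synthetic inventories and survey responses with configurable source
presence, coverage distributions, and yes-rates.

## Worked example

Score the packaged fixture from the shell:

```
$ cdomeval score --fixture --out out/
status tally: complete_all=6 complete_some=4 partial=6 missing=0
median scores: prevalent_incident=3, icd10_available=2, primary_secondary=3, sr_mode_device=3, sr_domain=3, sr_reference_period=3, sr_verification_validation=3, study_examinations=3, administrative_databases=3
0 discrepancies between derived and reported statuses
wrote out/status_table.csv
wrote out/score_matrix.csv
wrote out/source_counts.csv
wrote out/infrastructure_counts.csv
wrote out/report.json
```

Of the 16 studies, 6 have complete publicly available outcome metadata for
all examined outcomes, 4 are complete for some outcomes, and 6 are partial;
ICD-10 code availability is the most often missing field (median overall
score 2, all other fields 3); the statuses derived from the per-source
scores agree with the study-level statuses recorded in the fixture for all
16 studies. Validation surfaces the fixture's single suspected erratum (a
combined score below its direct score):

```
$ cdomeval validate --fixture
16 studies, 1 warning(s)
warning: hnrs/study_website/primary_secondary: combined score 0 below direct score 2
```

The same pipeline is available as a library:

```python
from cdomeval import load_fixture, build_summary

report = build_summary(load_fixture())
print(report.tally_line())        # complete_all=6 complete_some=4 partial=6 missing=0
print(report.source_counts)       # publications 16, website 15, registries 11, documents 10
```

`cdomeval simulate --seed 9 --out sim/` writes a synthetic audit
(`inventories.csv`, `survey_responses.csv`) that can be fed back through
`cdomeval score` and `cdomeval survey`.

## Layout

| module               | contents                                              |
| -------------------- | ----------------------------------------------------- |
| `cdomeval.schema`    | CDOM schema, field/source taxonomies, design profiles |
| `cdomeval.inventory` | evidence data model, CSV/JSON/YAML IO, packaged fixture |
| `cdomeval.scoring`   | rubric, overall aggregation, classification, summaries |
| `cdomeval.survey`    | FAIR checklist model, validation, percentage summaries |
| `cdomeval.synthetic` | seeded generator for inventories and survey responses |
| `cdomeval.cli`       | `cdomeval validate / score / survey / simulate`       |

See `docs/methods.md` for the methodological details and design choices.
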