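# hcscreen

A rule engine for hereditary-cancer risk screening: it matches a structured
personal and family cancer history, one criterion at a time, against the
genetic-testing criteria for BRCA-related hereditary breast and ovarian
cancer (HBOC), Lynch syndrome, and polyposis syndromes, and ships the full
validation machinery a screening study needs around it.

It is written for two audiences: clinical-informatics engineers who need an
auditable, testable implementation of guideline criteria matching (every
verdict names the criterion and the contributing relatives), and
biostatisticians reproducing or planning a screening-tool validation
(independent-event extraction, modeled low-risk cases, confusion-matrix
statistics with exact confidence intervals, and a seeded synthetic pedigree
simulator so the whole pipeline runs with no patient data).

## The model

A family history is a **pedigree**: a proband plus relatives identified by
controlled kinship labels (mother, maternal aunt, paternal first cousin, ...).
Each label carries a consanguinity **degree** (FDR/SDR/TDR = first/second/
third-degree relative), a **lineage** (maternal or paternal bloodline; full
siblings and descendants share both), and a generation offset. A *close blood
relative* is a relative of degree 1–3 on one side of the family; criteria
never combine relatives across sides.

The engine evaluates 28 registered rules:

* **B1–B19** (BRCA-related HBOC): known BRCA1/2 mutation; breast cancer at or
  under 45; breast at or under 50 with a second primary, an affected close
  relative (breast/pancreatic/prostate), or a limited family history;
  triple-negative breast at or under 60; breast at any age with qualifying
  family clusters, a relative's ovarian carcinoma (which includes fallopian
  tube and primary peritoneal primaries), a male relative's breast cancer, or
  Ashkenazi Jewish ancestry; personal ovarian carcinoma; male breast cancer;
  high-risk prostate (Gleason > 7) or pancreatic cancer with a qualifying
  family pattern; **B18** mirrors every personal-history rule onto each first-
  or second-degree relative by re-rooting the pedigree at that relative; and
  a third-degree-relative breast/ovarian cluster rule (B19).
* **L1–L6** (Lynch syndrome): known mismatch-repair mutation; an FDR with
  colorectal or endometrial cancer before 50; an FDR with two Lynch-related
  primaries; two FDR/SDR with Lynch-related cancer (one before 50); three
  FDR/SDR with Lynch-related cancer at any age; Amsterdam II.
* **P1–P3** (polyposis): known APC/MUTYH mutation, or a cumulative adenoma
  count at/over a configurable threshold (default 10) in the proband or an
  FDR.

Imprecise ages are imputed deterministically: "early 70s" → 72, "late 70s" →
78, "70s" → 75; unknown ages satisfy only "at any age" clauses. Free-text
tumor labels normalize onto a closed 36-type vocabulary (anything else becomes
*other/unspecified*, never an error); prostate cancers without grading are
assumed high-risk.

For validation, a **ConfusionMatrix** (A = true positives, B = false
positives, C = false negatives, D = true negatives) yields sensitivity
A/(A+C), specificity D/(D+B), accuracy (A+D)/total, each with a
Clopper–Pearson exact 95% interval

lower = Beta(α/2; x, n−x+1), upper = Beta(1−α/2; x+1, n−x),

and sample sizes come from n = (z₁₋α/₂ + z₁₋β)² p(1−p)/δ².

## Worked example

`family.json` — a proband with breast cancer at 44 whose mother had ovarian
cancer in her early 60s, plus an unaffected-side lung cancer:

```json
{
  "proband": {
    "relationship": "self",
    "sex": "female",
    "diagnoses": [{"cancer_type": "breast", "age": {"kind": "exact", "value": 44}}]
  },
  "members": [
    {"relationship": "mother",
     "diagnoses": [{"cancer_type": "ovarian", "age": {"kind": "early_decade", "value": 60}}]},
    {"relationship": "maternal_grandfather",
     "diagnoses": [{"cancer_type": "lung", "age": {"kind": "exact", "value": 71}}]}
  ],
  "family_sizes": {"maternal": 4, "paternal": 3}
}
```

```text
$ hcscreen evaluate family.json --text
Result: genetic screening should be considered at this time

Fulfilled criteria:
  B2 [BRCA]: self
  B11 [BRCA]: self, mother
  B18 [BRCA] (mirrors B14): mother
```

Three independent criterion events: the proband's own breast cancer at or
under 45 (B2), her breast cancer at any age plus a close relative with
ovarian carcinoma (B11), and the mother independently qualifying through her
personal ovarian history when the pedigree is re-rooted at her (B18 mirroring
B14). The mother's "early 60s" age was imputed to 62. The grandfather's lung
cancer contributes to no rule, as it should.

The same library API:

```python
from hcscreen import evaluate, Pedigree
report = evaluate(Pedigree.model_validate_json(open("family.json").read()))
report.meets_any            # True
[e.criterion_id for e in report.events]   # ['B2', 'B11', 'B18']
```

Other subcommands: `events` (independent-event extraction), `model-low-risk`
(strip qualifying history), `simulate` (seeded synthetic cohorts), `validate`
(accuracy panel from a paired-label events CSV), `intake` (questionnaire →
pedigree JSON).

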