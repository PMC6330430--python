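# hcscreen criteria registry, version 2017.2
# Stable rule ids with their printed-guideline wording and bound parameters.
# The engine binds each id to a predicate; this file is the human-readable
# registry of record and the extension point for additional rules.
version: "2017.2"
criteria:
  - id: B1
    syndrome: BRCA
    description: >-
      Individual from a family with a known BRCA1/BRCA2 mutation.
  - id: B2
    syndrome: BRCA
    description: >-
      Personal history of breast cancer diagnosed at or under 45 years.
    parameters: {age_max: 45}
  - id: B3
    syndrome: BRCA
    description: >-
      Personal history of breast cancer diagnosed at or under 50 years with an
      additional breast cancer primary (bilateral disease or two or more
      clearly separate ipsilateral primary tumors).
    parameters: {age_max: 50}
  - id: B4
    syndrome: BRCA
    description: >-
      Personal history of breast cancer diagnosed at or under 50 years with at
      least one close blood relative with breast cancer.
    parameters: {age_max: 50}
  - id: B5
    syndrome: BRCA
    description: >-
      Personal history of breast cancer diagnosed at or under 50 years with at
      least one close blood relative with pancreatic cancer.
    parameters: {age_max: 50}
  - id: B6
    syndrome: BRCA
    description: >-
      Personal history of breast cancer diagnosed at or under 50 years with at
      least one close blood relative with prostate cancer.
    parameters: {age_max: 50}
  - id: B7
    syndrome: BRCA
    description: >-
      Personal history of breast cancer diagnosed at or under 50 years with an
      unknown or limited family history.
    parameters: {age_max: 50, per_side_relative_threshold: 2}
  - id: B8
    syndrome: BRCA
    description: >-
      Personal history of triple-negative breast cancer diagnosed at or under
      60 years.
    parameters: {age_max: 60}
  - id: B9
    syndrome: BRCA
    description: >-
      Personal history of breast cancer at any age with at least two close
      blood relatives with breast, pancreatic, or prostate cancer at any age.
  - id: B10
    syndrome: BRCA
    description: >-
      Personal history of breast cancer at any age with at least one close
      blood relative with breast cancer diagnosed at or under 50 years.
    parameters: {relative_age_max: 50}
  - id: B11
    syndrome: BRCA
    description: >-
      Personal history of breast cancer at any age with at least one close
      blood relative with ovarian carcinoma (including fallopian tube and
      primary peritoneal cancers).
  - id: B12
    syndrome: BRCA
    description: >-
      Personal history of breast cancer at any age with a close male blood
      relative with breast cancer.
  - id: B13
    syndrome: BRCA
    description: >-
      Personal history of breast cancer at any age in an individual of an
      ethnicity associated with higher mutation frequency (e.g. Ashkenazi
      Jewish); no additional family history may be required.
  - id: B14
    syndrome: BRCA
    description: >-
      Personal history of ovarian carcinoma (including fallopian tube and
      primary peritoneal cancers).
  - id: B15
    syndrome: BRCA
    description: Personal history of male breast cancer.
  - id: B16
    syndrome: BRCA
    description: >-
      Personal history of high-risk prostate cancer (Gleason score > 7) at any
      age with at least one close blood relative with ovarian carcinoma at any
      age or breast cancer at or under 50 years, or two relatives with breast,
      pancreatic, or prostate cancer at any age.
  - id: B17
    syndrome: BRCA
    description: >-
      Personal history of pancreatic cancer at any age with at least one close
      blood relative with ovarian carcinoma at any age or breast cancer at or
      under 50 years, or two relatives with breast, pancreatic, or prostate
      cancer at any age.
  - id: B18
    syndrome: BRCA
    description: >-
      Family history only: first- or second-degree blood relative meeting any
      of the personal-history criteria above.
  - id: B19
    syndrome: BRCA
    description: >-
      Family history only: third-degree relative with breast cancer and/or
      ovarian carcinoma with at least two close blood relatives with breast
      cancer (at least one at or under 50 years) and/or ovarian carcinoma.
  - id: L1
    syndrome: LYNCH
    description: Known Lynch syndrome mutation in the family.
  - id: L2
    syndrome: LYNCH
    description: >-
      At least one first-degree relative with colorectal or endometrial cancer
      diagnosed before 50 years.
    parameters: {age_strict_max: 50}
  - id: L3
    syndrome: LYNCH
    description: >-
      At least one first-degree relative with colorectal or endometrial cancer
      and another synchronous or metachronous Lynch-related cancer.
  - id: L4
    syndrome: LYNCH
    description: >-
      At least two first- or second-degree relatives with Lynch-related
      cancer, including one diagnosed before 50 years.
    parameters: {age_strict_max: 50}
  - id: L5
    syndrome: LYNCH
    description: >-
      At least three first- or second-degree relatives with Lynch-related
      cancer, regardless of age.
  - id: L6
    syndrome: LYNCH
    description: Family meets Amsterdam II criteria.
  - id: P1
    syndrome: POLYPOSIS
    description: Known APC or MUTYH mutation in the family.
  - id: P2
    syndrome: POLYPOSIS
    description: >-
      Personal cumulative adenoma count at or above the configured threshold.
    parameters: {polyp_threshold: 10}
  - id: P3
    syndrome: POLYPOSIS
    description: >-
      First-degree relative with a cumulative adenoma count at or above the
      configured threshold.
    parameters: {polyp_threshold: 10}
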