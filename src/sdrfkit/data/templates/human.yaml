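# Human-dataset template: disease annotation is mandatory, ancestry is
# recommended, the organism must be Homo sapiens, and control samples
# should carry the disease value "normal".
name: human
description: Requirements for human datasets (disease, ancestry, organism check).
rules:
  - id: H1
    severity: ERROR
    kind: require_column
    category: characteristics
    attribute: disease
    message: human datasets must annotate the disease under study
  - id: H2
    severity: WARNING
    kind: require_column
    category: characteristics
    attribute: ancestry
    message: human datasets should annotate sample ancestry
  - id: H3
    severity: ERROR
    kind: fixed_value
    category: characteristics
    attribute: organism
    value: Homo sapiens
    message: organism must be "Homo sapiens" under the human template
  - id: H4
    severity: INFO
    kind: expect_value
    category: characteristics
    attribute: disease
    value: normal
    message: no control sample is labeled with the disease value "normal"
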