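# Cell-line template: the cell line itself must be annotated when this
# template is requested.
name: cell-line
description: Requirements for cell-line experiments.
rules:
  - id: C1
    severity: ERROR
    kind: require_column
    category: characteristics
    attribute: cell line
    message: cell-line experiments must annotate characteristics[cell line]
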