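# Default template: the universal structural rules only, no extra
# experiment-type requirements.
name: default
description: Universal mandatory column set; adds no template-specific rules.
rules: []
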