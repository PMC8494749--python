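"""Quantification-channel label vocabulary shared by the validator and
the design generator."""

from __future__ import annotations

DEFAULT_LABEL = "label free sample"

TMT6_CHANNELS = ("TMT126", "TMT127", "TMT128", "TMT129", "TMT130", "TMT131")
TMT10_CHANNELS = (
    "TMT126", "TMT127N", "TMT127C", "TMT128N", "TMT128C",
    "TMT129N", "TMT129C", "TMT130N", "TMT130C", "TMT131",
)
TMT11_CHANNELS = TMT10_CHANNELS + ("TMT131C",)
TMTPRO_EXTRA_CHANNELS = ("TMT132N", "TMT132C", "TMT133N", "TMT133C", "TMT134N")
SILAC2_CHANNELS = ("SILAC light", "SILAC heavy")
SILAC3_CHANNELS = ("SILAC light", "SILAC medium", "SILAC heavy")

#: Every label value the validator accepts without warning.
KNOWN_LABELS = frozenset(
    (DEFAULT_LABEL,)
    + TMT6_CHANNELS
    + TMT11_CHANNELS
    + TMTPRO_EXTRA_CHANNELS
    + SILAC3_CHANNELS
)
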