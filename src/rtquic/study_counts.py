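"""Published count tables from a two-round olfactory-swab RT-QuIC study in PD.

These integer counts are the inputs to the statistics layer when raw
fluorescence data are not available: positivity proportions by specimen and
diagnosis, the first-round unpaired specimen-site comparison, the
second-round paired agger-nasi vs middle-turbinate comparison, and the
CSF/olfactory-mucosa combination counts.
"""

from __future__ import annotations

from .diagnostics import Table2x2

# First round: one swab per patient, site by recruiting centre.
FIRST_ROUND_AN_PD = (27, 32)      # agger-nasi swabs, PD patients: positive/total
FIRST_ROUND_MT_PD = (5, 11)       # middle-turbinate swabs, PD patients
FIRST_ROUND_NON_PD = (3, 29)      # non-PD patients, both sites pooled
FIRST_ROUND_PD_OVERALL = (32, 43)  # all PD patients, both sites

# Unpaired 2x2 (rows = AN, MT; columns = positive, negative) for the
# first-round PD site comparison.
FIRST_ROUND_SITE_TABLE = Table2x2(27, 5, 5, 6)

# Second round: 23 additional PD patients swabbed at BOTH sites.
SECOND_ROUND_AN_PD = (18, 23)
SECOND_ROUND_MT_PD = (10, 23)

# Paired layout: a = AN+/MT+, b = AN+/MT-, c = AN-/MT+, d = AN-/MT-.
SECOND_ROUND_PAIRED_TABLE = Table2x2(9, 9, 1, 4)

# CSF arm (subset of first-round patients with lumbar puncture).
CSF_PD = (22, 24)
CSF_NON_PD_POSITIVE = (1, 19)

# OR-rule combination for the 24 PD patients with both CSF and a swab:
# 22 CSF-positive; of the 2 CSF-negative, 1 was swab-positive.
COMBINED_CSF_OM_PD = (23, 24)
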