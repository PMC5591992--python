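"""Published per-segment results from the original Monte Carlo study.

These numbers come from full EGSnrc radiation-transport simulations of the
chamber mounted on a clinical linac; they are inputs for re-analysis (trend
refitting, derivative arithmetic), not quantities this package recomputes.
"""

from __future__ import annotations

#: Original segment areas (cm^2) of the six study segments.
REFERENCE_AREAS_CM2 = (1.00, 9.00, 19.99, 25.83, 47.49, 70.82)

#: Scatter-plot trend-line gradients (cm^-2) reported for those segments,
#: ordered to match REFERENCE_AREAS_CM2.
REFERENCE_SP_GRADIENTS = (1.045, 0.13, 0.06, 0.048, 0.030, 0.018)

#: Power law reported for the variance-based index versus area:
#: VAR = 0.555 * SA^-0.024.
REFERENCE_VAR_POWER_LAW = (0.555, -0.024)
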