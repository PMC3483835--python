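"""Grade an experimental design against the degradation-study checklist.

Declare a design as a set of ticked study-type rows and get the matched
combination rule, its conclusion, and the compulsory controls.
"""

from turnoverkit import appraise

# untagged protein, kinetic readout, Tet-off interference
report = appraise({1, 4, 8})
print(report.render())
print()

# the gold standard: untagged protein, SILAC turnover at steady state
print(appraise({1, 9}).render())
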