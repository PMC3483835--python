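"""Labeled-pool designs: radioactive pulse-chase and a SILAC medium switch.

Pulse-chase follows the decay of newly synthesized (labeled) protein;
SILAC reads turnover at steady state from the heavy/light exchange
without perturbing the cell at all.
"""

import numpy as np

from turnoverkit import TurnoverParams, preset, pulse_chase, rate_constants, silac_switch

params = TurnoverParams(mrna_copies=10, translation_rate=2.0,
                        mrna_half_life=0.5, protein_half_life=40.0, doubling_time=24.0)
rc = rate_constants(params)

tc = pulse_chase(params, pulse_duration=1.0, chase_scenario=preset("chx_chase"),
                 times=np.linspace(0, 40, 6))
frac = tc.protein_labeled / tc.protein_labeled[0]
print("pulse-chase: labeled fraction remaining", np.round(frac, 3))
print(f"(decays with the effective removal half-life {rc.effective_half_life:.1f} h)")

sl = silac_switch(params, np.linspace(0, 48, 7))
heavy = sl.protein_labeled / sl.protein_total
print("SILAC heavy fraction at", sl.times, "h:", np.round(heavy, 3))
print(f"total stays at P0 (max rel dev "
      f"{np.max(np.abs(sl.protein_total / sl.protein_total[0] - 1)):.1e}): "
      "turnover is read without changing abundance")
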