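"""The three predicted-postoperative calculators on one worked case.

A patient with preoperative %FEV1 of 95% facing a right lower lobectomy
(5 of 19 segments). Each method scales the preoperative value by the share
of function expected to remain.
"""

from ppolung import planar_ppo, sc_ppo, segments_for_resection, spectct_ppo

preop_fev1 = 95.0
resection = {"RLL"}
s, s_side, side = segments_for_resection(resection)
print(f"resection: {sorted(resection)} -> {s} of {s_side} {side}-side segments")

# Segment counting: the resected share is s/19 regardless of perfusion.
print(f"SC        ppoFEV1 = {sc_ppo(preop_fev1, s):.1f}%")

# Planar: the right lung carries 55% of perfusion on planar scintigraphy.
print(f"planar    ppoFEV1 = {planar_ppo(preop_fev1, 0.55, s, s_side):.1f}%")

# SPECT/CT: the RLL itself carries 29% of total perfusion counts.
print(f"SPECT/CT  ppoFEV1 = {spectct_ppo(preop_fev1, 0.29):.1f}%")

# All three agree exactly when perfusion is proportional to segment count
# (f_lobe = 5/19 ≈ 0.263); here the lobe is hyperperfused, so SPECT/CT
# predicts a lower residual function than segment counting.
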