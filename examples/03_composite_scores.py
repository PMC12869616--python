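"""Composite raised-cosine scores: one bounded number per probe/contrast.

|log2 fold-change| ramps from 0 to 1 between fold changes 1.1x and 1.5x;
-log10(FDR) ramps between FDR 0.10 and 0.001; their geometric mean
(scaled to 100, signed by direction) rewards probes strong on BOTH
effect size and statistical evidence.
"""

import rppashift as rs
from rppashift.scoring import ScoreParams, composite_score

params = ScoreParams()
print(f"LFC ramp knots:  a = {params.lfc_a:.3f} (log2 1.1), "
      f"b = {params.lfc_b:.3f} (log2 1.5)")
print(f"FDR ramp knots:  a = {params.fdr_a:.0f} (FDR 0.10), "
      f"b = {params.fdr_b:.0f} (FDR 0.001)\n")

cases = [
    ("saturated both ramps", 1.0, 0.0005),
    ("large effect, weak evidence", 1.0, 0.08),
    ("tiny effect, strong evidence", 0.10, 0.0001),
    ("mid effect, mid evidence", 0.36, 0.01),
    ("downregulated, saturated", -0.9, 0.0002),
]
for label, lfc, fdr in cases:
    s = composite_score(lfc, fdr, params)
    print(f"{label:32s} lfc={lfc:+.2f} fdr={fdr:<7g} -> score {s.signed_score:+7.1f} "
          f"(components {s.lfc_component:.2f} x {s.fdr_component:.2f})")
print("\nA zero in either component zeroes the score: imbalance is penalized.")
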