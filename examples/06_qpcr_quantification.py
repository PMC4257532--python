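"""The two qPCR quantification formulas: 2^-ddCt and percent-of-input.

Relative expression: target Ct is normalized to a reference gene (ΔCt),
then to the control condition (ΔΔCt); the linear fold change is 2^−ΔΔCt.
ChIP enrichment: the input Ct is adjusted for the chromatin fraction it
represents, and enrichment is 2^(adjusted input Ct − IP Ct).
"""

import pandas as pd

from synergyscan.preprocess import CtTable, ddct, percent_input

ct = CtTable(pd.DataFrame([
    # treated samples: target amplifies 1 cycle earlier relative to control
    {"sample_id": "t1", "target_ct": 24.8, "reference_ct": 20.0, "group": "treated"},
    {"sample_id": "t2", "target_ct": 25.1, "reference_ct": 20.1, "group": "treated"},
    {"sample_id": "t3", "target_ct": 25.1, "reference_ct": 20.0, "group": "treated"},
    {"sample_id": "c1", "target_ct": 26.0, "reference_ct": 20.0, "group": "control"},
    {"sample_id": "c2", "target_ct": 25.9, "reference_ct": 19.9, "group": "control"},
    {"sample_id": "c3", "target_ct": 26.1, "reference_ct": 20.1, "group": "control"},
]))
fold = ddct(ct)
print(f"2^-ddCt fold change vs control: {fold:.2f}")
print("(one cycle earlier relative to the reference gene ~ 2-fold induction)")

enrichment = percent_input(ip_ct=28.0, input_ct=25.0, input_fraction=0.10)
print(f"\nChIP enrichment (IP Ct 28, 10% input Ct 25): "
      f"{enrichment:.4f} = {100 * enrichment:.2f}% of input")
print("(the 10% input is first shifted by log2(10) ~ 3.32 cycles)")
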