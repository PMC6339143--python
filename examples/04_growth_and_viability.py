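"""Growth normalization, MTT viability and the blocker dilution.

The growth table summarises cell counts over 8 replicate electrodes and
normalizes each day to the final one; the MTT computation expresses each
condition's absorbance as a percentage of the untreated control; the
dilution arithmetic gives the final blocker concentration in the well.
"""
import numpy as np

from oncoephys import (CellCountTable, MTTPlate, dilution_concentration,
                       growth_summary, percent_viability)

# counts over 8 electrodes for days 1/2/3/4/8 (exponential-growth shape)
rng = np.random.default_rng(0)
means = [42.0, 93.75, 156.625, 285.0, 1193.625]
counts = np.maximum(0, rng.normal(means, np.multiply(means, 0.25),
                                  size=(8, 5))).round()
table = CellCountTable(counts, (1, 2, 3, 4, 8))
summary = growth_summary(table)
print("growth summary (final-day normalized):")
print(summary.to_frame().round(4).to_string())

plate = MTTPlate({
    "negative_control": [1.00, 1.04, 0.97],
    "gdcl3_10uM": [0.98, 0.95, 1.01],
    "gdcl3_250uM": [0.96, 0.93, 0.97],
    "positive_control": [0.22, 0.25, 0.20],
})
print("\nMTT percent viability vs negative control:")
print(percent_viability(plate).round(1).to_string(index=False))

c = dilution_concentration(added_volume_ul=3.0, stock_concentration_mm=1.0,
                           medium_volume_ul=280.0)
print(f"\n3 uL of 1 mM blocker into 280 uL of medium -> {c:.1f} uM "
      f"(inside the 10-20 uM working window)")
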