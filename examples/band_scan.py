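"""Scan 5 Hz frequency bands for the most decodable one.

The 5-35 Hz range is cut into six bands; each band is imaged into
feature tensors and scored with a fast band-power classifier under the
75/25 split protocol.  On data whose class difference lives in the mu
rhythm, the 10-15 Hz band wins.
"""

from mitopo import SyntheticConfig, band_scan, generate
from mitopo.classifiers import BandPowerLogistic

trials = generate(SyntheticConfig(n_trials_per_class=40, erd_effect=0.6, seed=3))
result = band_scan(trials, 5.0, 35.0, 5.0, eval_fn=BandPowerLogistic)

print("band        mean accuracy +/- std over repeated splits")
for band, acc, std in zip(result.bands, result.mean_accuracy, result.std_accuracy):
    marker = "  <- selected" if band == result.selected_band else ""
    print(f"{band[0]:5.1f}-{band[1]:5.1f} Hz   {100 * acc:5.1f}% +/- "
          f"{100 * std:4.1f}%{marker}")
print("\nBands outside the simulated ERD carry no class information, so "
      "they score near the 50% chance level.")
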