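"""Estimate fGNG for one plasma sample from its raw SIM intensities.

A sample measured at m/z 169 (M) and 170 (M+1) on the glucose penta-acetate
fragment, with body water at 6% D2O: the M+1/M ratio divided by the six
exchangeable sites gives the per-site fragment enrichment, and dividing by
the precursor (body-water) enrichment gives the fraction of circulating
glucose made by gluconeogenesis.
"""

from fgng import (
    BodyWaterEnrichment,
    IsotopologueMeasurement,
    estimate_sample,
)

meas = IsotopologueMeasurement(sample_id="rat-01_post", intensity_m=1.0e6, intensity_m1=2.8e5)
body_water = BodyWaterEnrichment(sample_id="rat-01_post", enrichment=0.06)

result = estimate_sample(meas, body_water)

print(f"M+1/M ratio           : {meas.intensity_m1 / meas.intensity_m:.4f}")
print(f"fragment enrichment   : {result.fragment_enrichment:.4f}  (per-site)")
print(f"body-water enrichment : {result.body_water_enrichment:.4f}")
print(f"fGNG                  : {result.fgng:.1%}")
print(f"feeding state         : {result.feeding_state} (overfed={result.overfed_flag})")
# fGNG ~78%: most of this animal's glucose is newly synthesized -> unfed,
# i.e. dietary energy intake is not meeting demand.
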