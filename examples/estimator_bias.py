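"""Bias of the first-order ratio estimator under exact binomial labeling.

The ratio-over-n estimator assumes the M+1 excess is linear in site
enrichment.  When every site is labeled independently (binomial
isotopologues), multiply-labeled molecules drain the M+1 mass and the
unlabeled M mass, producing opposing biases that cancel only near
fGNG ~ 0.85.  At 6% body water the net bias reaches about -6.6 points of
fGNG mid-range — worth knowing before comparing absolute levels across
studies run at different enrichments.
"""

import numpy as np

from fgng import IsotopologueMeasurement, fragment_enrichment, label_distribution

print("p_water  fGNG_true  fGNG_est   bias (points)")
for p_water in (0.02, 0.06):
    for f_true in (0.25, 0.50, 0.80, 1.00):
        d = label_distribution(p_water, f_true, mode="binomial")
        meas = IsotopologueMeasurement("x", d.probabilities[0], d.probabilities[1])
        est = fragment_enrichment(meas) / p_water
        print(f"  {p_water:.2f}     {f_true:.2f}      {est:.4f}    {100*(est-f_true):+6.2f}")
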