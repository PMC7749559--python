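"""Supporting assay computations: ddCt, respirometry, CSA bins, mass."""

import pandas as pd

from heavywater import CtPanel, RespTrace, bin_fiber_csa, ddct, normalize_mass, normalize_ocr

# relative gene expression: treated animal 1 cycle earlier than control -> 2x
ct = pd.DataFrame(
    {"18s": [10.0, 10.1, 10.0], "Runx1": [20.0, 20.1, 19.0]},
    index=["c1", "c2", "t1"],
)
panel = CtPanel(ct=ct, groups=pd.Series({"c1": "ctl", "c2": "ctl", "t1": "llc"}),
                calibrator_group="ctl")
print("2^-ddCt Runx1:\n", ddct(panel).round(3))

# oxygen consumption: antimycin-A floor subtracted, per mg wet weight
trace = RespTrace({"CI": 41.0, "CI+II": 60.0, "antimycinA": 5.0}, bundle_wet_weight=2.0)
print("normalized OCR:", {k: round(v, 2) for k, v in normalize_ocr(trace).items()})

# fibre-size distribution: small [200, 1200], average (1200, 2400], large > 2400 um^2
bins = bin_fiber_csa([350, 900, 1200, 1800, 2500, 3100])
print("CSA counts:", bins.counts, "frequencies:",
      {k: round(v, 2) for k, v in bins.frequencies.items()})

# muscle mass per gram of tumour-free body weight
print("normalized gastrocnemius mass:", normalize_mass(120.0, 25.0, 1.0), "mg/g")
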