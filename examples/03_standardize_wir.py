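"""Standardize covariate names into variable classes and compute WIR.

Country models use heterogeneous covariate sets, so raw importances are
incomparable.  The weighted importance rank rescales each country's
ranking to [0, 1]: 0 = most important covariate of that model, 1 =
least important.
"""

import pandas as pd

import dasypop as dp

imp = pd.DataFrame({
    "covariate": ["lights_at_night", "elevation and slope", "roads",
                  "schools", "dist_river"],
    "per_inc_mse": [42.0, 31.5, 12.0, 12.0, 3.1],
})
table = dp.compute_wir(imp, country="demo", region="region-1")
print(table[["covariate", "class", "per_inc_mse", "rank", "wir"]]
      .to_string(index=False))
# ties share an average rank (roads/schools both 3.5 -> same WIR);
# endpoints are forced: best covariate 0, worst 1.
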