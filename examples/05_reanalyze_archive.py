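"""Re-run the comparison stage from an exported importance table.

The input schema is ``country,region,covariate,per_inc_mse`` — the
shape of per-model summary exports from a multi-country population
mapping run.  Here a synthetic 32-country table stands in for such an
archive.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import dasypop as dp

rng = np.random.default_rng(7)
vocab = {"lights_at_night": 8.0, "urban_extent": 9.0, "elevation": 7.0,
         "slope": 6.5, "dist_roads": 5.0, "schools": 3.0,
         "dist_river": 2.0, "cropland": 2.5, "protected_area": 1.0,
         "populated_place_gazetteer": 4.5}
rows = []
for region in ("Africa", "C-America", "S-America", "SE-Asia"):
    for c in range(8):
        for cov in rng.choice(list(vocab), size=8, replace=False):
            rows.append({"country": f"{region}-{c + 1:02d}",
                         "region": region, "covariate": cov,
                         "per_inc_mse": vocab[cov] + rng.normal(0, 2)})
csv = Path(tempfile.mkdtemp()) / "importances.csv"
pd.DataFrame(rows).to_csv(csv, index=False)

result = dp.reanalyze(csv)
glob = next(r for r in result["reports"] if r.design == "global-by-class")
print(f"global Kruskal-Wallis: chi-squared = {glob.kw.statistic:.3f}, "
      f"d.f. = {glob.kw.df}, p = {glob.kw.pvalue:.3g}")
if glob.dunn is not None:
    sig = glob.dunn.pairs().query("p_holm <= 0.05")
    print(f"significant class pairs after Holm: {len(sig)}")
    print(sig.to_string(index=False))
# chi-squared is the tie-corrected H statistic; d.f. = classes - 1.
# Z > 0 means the first class has the larger mean rank, i.e. the
# *larger* WIR, i.e. is the less important of the pair.
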