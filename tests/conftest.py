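import numpy as np
import pandas as pd
import pytest

from dasypop.synth import CovariateSpec, LandscapeSpec, generate_country


@pytest.fixture(scope="session")
def tiny_spec():
    covs = [CovariateSpec("urban_extent", "binary-extent"),
            CovariateSpec("elevation", "smooth-field"),
            CovariateSpec("dist_roads", "distance-to-feature")]
    return LandscapeSpec(grid_rows=20, grid_cols=20, n_zones=12,
                         covariates=covs,
                         effect_weights={"urban_extent": 1.0,
                                         "elevation": -0.5},
                         noise_sd=0.2, seed=5)


@pytest.fixture(scope="session")
def tiny_country(tiny_spec):
    return generate_country(tiny_spec, region_label="region-1",
                            country_label="region-1-01")


@pytest.fixture(scope="session")
def synthetic_supplementary_table():
    """Synthetic stand-in for an extracted multi-country importance
    archive: 4 regions x 8 countries, 8-14 covariates each with
    class-structured importances.  Purely synthetic; no real model
    output behind it."""
    rng = np.random.default_rng(20260923)
    vocab = {
        "lights_at_night": 8.0, "urban_extent": 9.0, "ghsl": 8.5,
        "dist_roads": 5.0, "railways": 4.0, "elevation": 7.0,
        "slope": 6.5, "temperature": 6.0, "precipitation": 5.5,
        "schools": 3.0, "health_facilities": 3.0, "osm_places": 3.5,
        "dist_river": 2.0, "waterbodies": 2.0, "cropland": 2.5,
        "protected_area": 1.0, "populated_place_gazetteer": 4.5,
        "lc_woody": 1.5,
    }
    names = list(vocab)
    rows = []
    for region in ("Africa", "C-America", "S-America", "SE-Asia"):
        for c in range(8):
            k = int(rng.integers(8, 15))
            chosen = rng.choice(names, size=k, replace=False)
            for cov in chosen:
                rows.append({
                    "country": f"{region}-{c + 1:02d}",
                    "region": region,
                    "covariate": cov,
                    "per_inc_mse": vocab[cov] + rng.normal(0, 2.0),
                })
    return pd.DataFrame(rows)
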