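"""Covariate-class standardization and the weighted importance rank (WIR).

Country models are fitted on heterogeneous, country-specific covariate
sets, so raw importances are not comparable across models.  Two steps
make them comparable:

* each covariate name is mapped onto one of 18 standardized variable
  classes (vegetation land cover, transportation networks, built
  environment proxies, ...) via an ordered, editable pattern table;
* within each country, covariates are ranked by descending
  Per.Inc.m.s.e. and rescaled to the weighted importance rank
  ``WIR = (rank − 1) / (n − 1)``: 0 is the most important covariate in
  the country's final model, 1 the least important, regardless of how
  many covariates the model kept.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "VARIABLE_CLASSES",
    "UNCLASSIFIED",
    "CovariateClassMap",
    "load_default_class_map",
    "classify_covariate",
    "compute_wir",
    "assemble_study_table",
    "read_importance_csv",
    "write_wir_csv",
    "read_wir_csv",
]

log = logging.getLogger(__name__)

#: The closed vocabulary of standardized variable classes.
VARIABLE_CLASSES = (
    "natural/semi-natural vegetation LC",
    "cultivated/managed LC",
    "natural bare surfaces LC",
    "artificial surface LC",
    "no data",
    "residential LU",
    "non-residential LU",
    "protected LU",
    "general classified LU",
    "urban/suburban extents",
    "built environment and urban/suburban proxies",
    "classified populated place",
    "transportation networks",
    "climatic/environmental",
    "facilities and services",
    "places and POIs",
    "rivers/waterbodies/waterways",
    "populated place",
)

UNCLASSIFIED = "unclassified"

#: classes carried in tables but excluded from hypothesis testing
NON_TEST_CLASSES = frozenset({UNCLASSIFIED, "no data"})


def _normalize(name: str) -> str:
    return re.sub(r"[\s_]+", " ", name.strip().lower())


@dataclass
class CovariateClassMap:
    """Ordered pattern → class table; first matching pattern wins.

    A pattern matches when its normalized form (lower-case, collapsed
    whitespace/underscores) is a substring of the normalized covariate
    name.  The shipped table covers the standard covariate vocabulary
    plus common synonyms and is user-extensible via CSV.
    """

    patterns: list[tuple[str, str]]

    def __post_init__(self) -> None:
        for pat, cls in self.patterns:
            if cls not in VARIABLE_CLASSES:
                raise ValueError(f"pattern {pat!r} maps to unknown class "
                                 f"{cls!r}")
        self._norm = [(_normalize(p), c) for p, c in self.patterns]

    @classmethod
    def from_csv(cls, path) -> "CovariateClassMap":
        df = pd.read_csv(path)
        return cls(list(zip(df["pattern"], df["class"])))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.patterns, columns=["pattern", "class"]).to_csv(
            path, index=False)

    def classify(self, name: str) -> str:
        norm = _normalize(name)
        for pat, cls_ in self._norm:
            if pat in norm:
                return cls_
        return UNCLASSIFIED


def load_default_class_map() -> CovariateClassMap:
    """The packaged reclassification table."""
    ref = resources.files("dasypop.data") / "covariate_classes.csv"
    with resources.as_file(ref) as path:
        return CovariateClassMap.from_csv(path)


def classify_covariate(name: str,
                       cmap: CovariateClassMap | None = None) -> str:
    """Map a covariate name onto its standardized variable class.

    Unmatched names soft-fail to ``"unclassified"`` with a warning; such
    rows are retained in tables but excluded from class-level tests.
    """
    if not name or not name.strip():
        raise ValueError("covariate name must be non-empty")
    cmap = cmap or load_default_class_map()
    cls_ = cmap.classify(name)
    if cls_ == UNCLASSIFIED:
        log.warning("covariate %r matched no class pattern", name)
    return cls_


def compute_wir(importance: pd.DataFrame, country: str = "",
                region: str = "",
                cmap: CovariateClassMap | None = None) -> pd.DataFrame:
    """WIR rows for one country's final-model importance table.

    Rank 1 is the largest Per.Inc.m.s.e. (ties get average ranks);
    ``wir = (rank − 1)/(n − 1)``, and a single-covariate model scores 0.
    """
    imp = importance["per_inc_mse"].to_numpy(dtype=float)
    if np.isnan(imp).any():
        raise ValueError("NaN importance value")
    n = imp.size
    if n < 1:
        raise ValueError("at least one covariate required")
    ranks = rankdata(-imp, method="average")
    wir = (ranks - 1) / (n - 1) if n > 1 else np.zeros(n)
    cmap = cmap or load_default_class_map()
    return pd.DataFrame({
        "country": country,
        "region": region,
        "covariate": importance["covariate"].to_numpy(),
        "class": [cmap.classify(c) for c in importance["covariate"]],
        "per_inc_mse": imp,
        "rank": ranks,
        "wir": wir,
    })


def assemble_study_table(per_country: list[pd.DataFrame] | pd.DataFrame,
                         regions: dict[str, str] | None = None
                         ) -> pd.DataFrame:
    """Pool per-country WIR rows into one study table.

    ``regions`` may supply/override the region of each country; every
    country must end up with a region label.  Rows whose class is
    ``unclassified`` or ``no data`` are flagged ``testable=False``.
    """
    table = per_country.copy() if isinstance(per_country, pd.DataFrame) \
        else pd.concat(per_country, ignore_index=True)
    if regions:
        table["region"] = table["country"].map(regions).fillna(
            table["region"])
    missing = table.loc[table["region"].astype(str).str.len() == 0,
                        "country"].unique()
    if missing.size:
        raise ValueError(f"countries without a region: {missing.tolist()}")
    table["testable"] = ~table["class"].isin(NON_TEST_CLASSES)
    return table


def read_importance_csv(path) -> pd.DataFrame:
    """Read an external per-covariate importance table.

    Schema: ``country,region,covariate,per_inc_mse`` (the adapter point
    for re-analysing importance tables exported by other model runs).
    """
    df = pd.read_csv(path)
    required = {"country", "region", "covariate", "per_inc_mse"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"importance CSV lacks columns: {sorted(missing)}")
    return df


def wir_from_importances(df: pd.DataFrame,
                         cmap: CovariateClassMap | None = None
                         ) -> pd.DataFrame:
    """Full WIR study table from a pooled importance table."""
    cmap = cmap or load_default_class_map()
    parts = []
    for (country, region), grp in df.groupby(["country", "region"],
                                             sort=True):
        parts.append(compute_wir(grp.reset_index(drop=True),
                                 country=str(country), region=str(region),
                                 cmap=cmap))
    return assemble_study_table(parts)


WIR_COLUMNS = ["country", "region", "covariate", "class", "per_inc_mse",
               "rank", "wir"]


def write_wir_csv(path, table: pd.DataFrame) -> None:
    table.loc[:, WIR_COLUMNS].to_csv(path, index=False)


def read_wir_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"WIR CSV lacks columns: {sorted(missing)}")
    if "testable" not in df.columns:
        df["testable"] = ~df["class"].isin(NON_TEST_CLASSES)
    return df
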