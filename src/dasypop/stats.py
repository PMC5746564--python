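"""Hierarchical nonparametric comparison of WIR values.

Implements the tie-corrected Kruskal–Wallis test, the post-hoc Dunn
test on joint mid-ranks with Holm's step-down correction, and the four
comparison designs applied to a pooled WIR table:

* ``global-by-class``        — classes compared across all countries;
* ``inter-regional-by-region`` — regions compared within one class;
* ``intra-regional-by-country`` — countries compared within one
  region × class cell;
* ``intra-regional-by-class`` — classes compared within one region.

Dunn tests are gated on a significant Kruskal–Wallis test at the
configured alpha (0.05 unless stated otherwise); Holm is applied within
each Dunn family (the pairwise set of one Kruskal–Wallis test).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "KWResult",
    "DunnResult",
    "DesignReport",
    "kruskal_wallis",
    "dunn_posthoc",
    "holm_adjust",
    "run_design",
    "run_all_designs",
    "reports_to_frames",
]

log = logging.getLogger(__name__)

DESIGNS = ("global-by-class", "inter-regional-by-region",
           "intra-regional-by-country", "intra-regional-by-class")


@dataclass
class KWResult:
    """Tie-corrected Kruskal–Wallis statistic H (the tables' chi-squared),
    its degrees of freedom (groups − 1) and chi-squared p-value."""

    statistic: float
    df: int
    pvalue: float
    n_groups: int
    n_total: int


@dataclass
class DunnResult:
    """Pairwise Dunn Z-scores with raw and Holm-corrected two-sided
    p-values.  ``z.loc[a, b]`` is (mean rank a − mean rank b) / SE, so
    the matrix is antisymmetric."""

    groups: list[str]
    z: pd.DataFrame
    p_raw: pd.DataFrame
    p_holm: pd.DataFrame
    alpha: float = 0.05

    def pairs(self) -> pd.DataFrame:
        rows = []
        for a, b in itertools.combinations(self.groups, 2):
            rows.append({"group_a": a, "group_b": b,
                         "z": self.z.loc[a, b],
                         "p_raw": self.p_raw.loc[a, b],
                         "p_holm": self.p_holm.loc[a, b]})
        return pd.DataFrame(rows)


def _clean_groups(sample: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in sample.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            log.warning("dropping empty group %r", name)
            continue
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite value in group {name!r}")
        out[name] = arr
    return out


def _tie_sum(all_vals: np.ndarray) -> float:
    _, counts = np.unique(all_vals, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t ** 3 - t))


def kruskal_wallis(sample: dict[str, np.ndarray]) -> KWResult:
    """Tie-corrected Kruskal–Wallis H with chi-squared p-value.

    H = [12/(N(N+1)) · Σ R_j²/n_j − 3(N+1)] / C, with mid-ranks over the
    pooled sample and tie correction C = 1 − Σ(t³−t)/(N³−N).  When every
    value is identical, H = 0 and p = 1.
    """
    groups = _clean_groups(sample)
    if len(groups) < 2:
        raise ValueError("at least two non-empty groups required")
    all_vals = np.concatenate(list(groups.values()))
    n = all_vals.size
    if n < 3:
        raise ValueError("at least three observations required")
    ranks = rankdata(all_vals)
    h = 0.0
    pos = 0
    for vals in groups.values():
        r = ranks[pos:pos + vals.size]
        h += r.sum() ** 2 / vals.size
        pos += vals.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    c = 1.0 - _tie_sum(all_vals) / (n ** 3 - n)
    k = len(groups)
    if c <= 0:  # every observation tied
        h = 0.0
    else:
        h = h / c
    h = max(h, 0.0)
    df = k - 1
    p = 1.0 if h == 0.0 else float(chi2.sf(h, df))
    return KWResult(statistic=float(h), df=df, pvalue=p,
                    n_groups=k, n_total=n)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order.

    Sort ascending, multiply the i-th smallest by (m − i), enforce
    monotonicity with a running maximum and cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D list of p-values")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def dunn_posthoc(sample: dict[str, np.ndarray],
                 alpha: float = 0.05) -> DunnResult:
    """Pairwise Dunn tests on joint mid-ranks, Holm-corrected.

    Z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))·(1/n_i+1/n_j)]
    with two-sided normal p-values; Holm is applied across all pairs of
    this family.  When the variance term vanishes (all values tied) all
    Z are 0 and all corrected p are 1.
    """
    groups = _clean_groups(sample)
    names = list(groups.keys())
    if len(names) < 2:
        raise ValueError("at least two non-empty groups required")
    all_vals = np.concatenate([groups[g] for g in names])
    n = all_vals.size
    ranks = rankdata(all_vals)
    mean_rank, sizes = {}, {}
    pos = 0
    for g in names:
        m = groups[g].size
        mean_rank[g] = ranks[pos:pos + m].mean()
        sizes[g] = m
        pos += m
    tie_term = _tie_sum(all_vals) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    z = pd.DataFrame(0.0, index=names, columns=names)
    p_raw = pd.DataFrame(1.0, index=names, columns=names)
    pair_list = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pair_list:
        denom = var_base * (1.0 / sizes[a] + 1.0 / sizes[b])
        zij = 0.0 if denom <= 0 else \
            (mean_rank[a] - mean_rank[b]) / np.sqrt(denom)
        pij = float(2.0 * norm.sf(abs(zij)))
        z.loc[a, b], z.loc[b, a] = zij, -zij
        p_raw.loc[a, b] = p_raw.loc[b, a] = pij
        raw.append(pij)
    adj = holm_adjust(raw)
    p_holm = pd.DataFrame(1.0, index=names, columns=names)
    for (a, b), pv in zip(pair_list, adj):
        p_holm.loc[a, b] = p_holm.loc[b, a] = pv
    return DunnResult(groups=names, z=z, p_raw=p_raw, p_holm=p_holm,
                      alpha=alpha)


@dataclass
class DesignReport:
    """One comparison: the Kruskal–Wallis gate and, when it fires, the
    Dunn family.  ``untestable`` marks scopes with fewer than two
    groups (reported, never raised)."""

    design: str
    scope: str
    group_field: str
    kw: KWResult | None = None
    dunn: DunnResult | None = None
    untestable: bool = False
    group_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.kw is not None and self.dunn is not None


def _grouped(table: pd.DataFrame, by: str,
             value_col: str = "wir") -> dict[str, np.ndarray]:
    return {str(g): grp[value_col].to_numpy(dtype=float)
            for g, grp in table.groupby(by, sort=True)}


def _testable(table: pd.DataFrame) -> pd.DataFrame:
    if "testable" in table.columns:
        return table[table["testable"]]
    return table


def run_design(table: pd.DataFrame, design: str, scope: str | None = None,
               alpha: float = 0.05,
               per_country_median: bool = False) -> DesignReport:
    """Run one comparison design on a pooled WIR table.

    ``scope`` names the class (inter-regional), the region
    (intra-regional by class) or ``"region/class"`` (intra-regional by
    country).  ``per_country_median`` collapses each country's rows to
    their median before testing (pooled rows by default).
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    t = _testable(table)
    if design == "global-by-class":
        sub, by, scope_name = t, "class", "all"
    elif design == "inter-regional-by-region":
        if scope is None:
            raise ValueError("inter-regional design needs a class scope")
        sub, by, scope_name = t[t["class"] == scope], "region", scope
    elif design == "intra-regional-by-country":
        if scope is None or "/" not in scope:
            raise ValueError("scope must be 'region/class'")
        region, cls_ = scope.split("/", 1)
        sub = t[(t["region"] == region) & (t["class"] == cls_)]
        by, scope_name = "country", scope
    else:  # intra-regional-by-class
        if scope is None:
            raise ValueError("intra-regional design needs a region scope")
        sub, by, scope_name = t[t["region"] == scope], "class", scope

    if per_country_median and by != "country":
        sub = (sub.groupby(["country", by], sort=True, as_index=False)
               .agg({"wir": "median"}))
    groups = {g: v for g, v in _grouped(sub, by).items() if v.size > 0}
    sizes = {g: int(v.size) for g, v in groups.items()}
    report = DesignReport(design=design, scope=scope_name, group_field=by,
                          group_sizes=sizes)
    if len(groups) < 2 or sum(sizes.values()) < 3:
        report.untestable = True
        log.info("design %s scope %r untestable (<2 groups)", design,
                 scope_name)
        return report
    report.kw = kruskal_wallis(groups)
    if report.kw.pvalue <= alpha:
        log.info("design %s scope %r significant (p=%.4g): Dunn follow-up",
                 design, scope_name, report.kw.pvalue)
        report.dunn = dunn_posthoc(groups, alpha=alpha)
    else:
        log.info("design %s scope %r not significant (p=%.4g)", design,
                 scope_name, report.kw.pvalue)
    return report


def run_all_designs(table: pd.DataFrame, alpha: float = 0.05,
                    per_country_median: bool = False) -> list[DesignReport]:
    """All four designs over every applicable scope of the table."""
    t = _testable(table)
    reports = [run_design(table, "global-by-class", alpha=alpha,
                          per_country_median=per_country_median)]
    for cls_ in sorted(t["class"].unique()):
        reports.append(run_design(table, "inter-regional-by-region",
                                  scope=cls_, alpha=alpha,
                                  per_country_median=per_country_median))
    for region in sorted(t["region"].unique()):
        reports.append(run_design(table, "intra-regional-by-class",
                                  scope=str(region), alpha=alpha,
                                  per_country_median=per_country_median))
        for cls_ in sorted(t.loc[t["region"] == region, "class"].unique()):
            reports.append(run_design(
                table, "intra-regional-by-country",
                scope=f"{region}/{cls_}", alpha=alpha))
    return reports


def reports_to_frames(reports: list[DesignReport]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten reports to (KW summary frame, pairwise Dunn frame)."""
    kw_rows, pair_rows = [], []
    for rep in reports:
        kw_rows.append({
            "design": rep.design, "scope": rep.scope,
            "groups": rep.kw.n_groups if rep.kw else len(rep.group_sizes),
            "chi_squared": rep.kw.statistic if rep.kw else np.nan,
            "df": rep.kw.df if rep.kw else np.nan,
            "p": rep.kw.pvalue if rep.kw else np.nan,
            "untestable": rep.untestable,
        })
        if rep.dunn is not None:
            pairs = rep.dunn.pairs()
            pairs.insert(0, "scope", rep.scope)
            pairs.insert(0, "design", rep.design)
            pair_rows.append(pairs)
    kw_frame = pd.DataFrame(kw_rows)
    pair_frame = (pd.concat(pair_rows, ignore_index=True) if pair_rows
                  else pd.DataFrame(columns=["design", "scope", "group_a",
                                             "group_b", "z", "p_raw",
                                             "p_holm"]))
    return kw_frame, pair_frame
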