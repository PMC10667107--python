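"""CAP score, burden-of-pathology stratification and CSF analyte statistics.

Huntington's disease gene-expansion carriers (HDGECs) are staged from two
numbers measured at a single visit — the CAG repeat length of the expanded
*HTT* allele and the carrier's age:

    CAP    = 100 × age × (CAG − L) / S,   L = 30, S = 627
    burden = (CAG − 35.5) × age

The CAG Age Product (CAP) is normalized so it reaches ≈100 at the expected
age of clinical onset; the burden-of-pathology score splits premanifest
carriers into early (< 250) and late (≥ 250) groups.  Clinical group
placement further uses the UHDRS diagnostic confidence level (dcl; 4 means
manifest motor signs) and the total functional capacity (TFC, 0–13).

Analyte (e.g. CSF C3 / iC3b) statistics follow the standard battery: C3-type
analytes rise with normal aging, so carrier concentrations are adjusted
using the age slope fitted in controls; group differences use
Kruskal–Wallis with Dunn's pairwise comparisons; disease-burden association
uses Spearman rank correlation against CAP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CapModel",
    "AdjustmentModel",
    "GROUPS",
    "cap_score",
    "burden_score",
    "stratify",
    "stratify_table",
    "fit_age_model",
    "age_adjust",
    "dunn_test",
    "group_compare",
    "cap_correlation",
]

#: recognized group labels, in disease-stage order
GROUPS = (
    "healthy",
    "early_premanifest",
    "late_premanifest",
    "early_manifest",
    "unclassified",
)

#: burden score splitting early from late premanifest carriers
BURDEN_SPLIT = 250.0
#: minimum CAG for the premanifest groups
PREMANIFEST_MIN_CAG = 40
#: minimum CAG for early manifest placement
MANIFEST_MIN_CAG = 36
#: CAG at or below which a subject carries no expansion risk
HEALTHY_MAX_CAG = 35


@dataclass(frozen=True)
class CapModel:
    """Constants of the CAP formula.

    ``L`` anchors the lower end of pathologically relevant CAG lengths and
    ``S`` normalizes the score to ≈100 at the expected onset age.
    """

    L: float = 30.0
    S: float = 627.0
    scale: float = 100.0

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise ValueError("S must be > 0")


@dataclass
class AdjustmentModel:
    """Age-adjustment model fitted on controls: slope b and mean control age."""

    b: float
    mean_age: float
    analyte: str
    n_controls: int = 0
    b_stderr: float = float("nan")


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def cap_score(age: float, cag: float, model: CapModel = CapModel()) -> float:
    """CAG Age Product: ``scale × age × (cag − L) / S``."""
    if age <= 0:
        raise ValueError("age must be > 0")
    if cag < model.L:
        warnings.warn(
            f"CAG {cag} below the anchor L={model.L}; CAP score is negative"
        )
    return model.scale * age * (cag - model.L) / model.S


def burden_score(age: float, cag: float) -> float:
    """Burden of pathology: ``(cag − 35.5) × age``."""
    if age <= 0:
        raise ValueError("age must be > 0")
    return (cag - 35.5) * age


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify(
    age: float,
    cag: float,
    dcl: float,
    tfc: float | None = None,
) -> str:
    """Assign a subject to a disease-stage group.

    * healthy — no expansion risk (CAG ≤ 35) and no diagnostic motor signs;
    * early_premanifest — dcl < 4, CAG ≥ 40, burden < 250;
    * late_premanifest — dcl < 4, CAG ≥ 40, burden ≥ 250 (the boundary value
      250 itself is assigned late);
    * early_manifest — dcl = 4, CAG ≥ 36, TFC between 7 and 13 inclusive;
    * unclassified — anything else (e.g. intermediate alleles CAG 36–39
      without motor diagnosis, or manifest subjects with TFC < 7).
    """
    if age <= 0:
        raise ValueError("age must be > 0")
    missing = [n for n, v in (("cag", cag), ("dcl", dcl)) if v is None]
    if missing:
        raise ValueError(f"missing required fields: {', '.join(missing)}")
    if not (0 <= dcl <= 4):
        raise ValueError("dcl must be in [0, 4]")

    if dcl == 4:
        if tfc is None:
            raise ValueError("missing required fields: tfc (needed when dcl = 4)")
        if cag >= MANIFEST_MIN_CAG and 7 <= tfc <= 13:
            return "early_manifest"
        return "unclassified"
    if cag <= HEALTHY_MAX_CAG:
        return "healthy"
    if cag >= PREMANIFEST_MIN_CAG:
        if burden_score(age, cag) < BURDEN_SPLIT:
            return "early_premanifest"
        return "late_premanifest"
    return "unclassified"


def stratify_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Stratify every row of a cohort table; adds group/cap/burden columns."""
    required = {"age", "cag", "dcl"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    out = cohort.copy()
    out["assigned_group"] = [
        stratify(r.age, r.cag, r.dcl, getattr(r, "tfc", None))
        for r in cohort.itertuples()
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["cap"] = [cap_score(r.age, r.cag) for r in cohort.itertuples()]
    out["burden"] = [burden_score(r.age, r.cag) for r in cohort.itertuples()]
    return out


# ---------------------------------------------------------------------------
# age adjustment
# ---------------------------------------------------------------------------

def fit_age_model(controls: pd.DataFrame, analyte: str) -> AdjustmentModel:
    """OLS regression of an analyte on age in controls.

    Returns the slope b (units per year) and mean control age, the two
    quantities the adjustment formula needs.
    """
    data = controls[["age", analyte]].dropna()
    if len(data) < 3:
        raise ValueError(
            f"need >= 3 controls with {analyte!r}; got {len(data)}"
        )
    X = sm.add_constant(data["age"].to_numpy(dtype=float))
    fit = sm.OLS(data[analyte].to_numpy(dtype=float), X).fit()
    return AdjustmentModel(
        b=float(fit.params[1]),
        mean_age=float(data["age"].mean()),
        analyte=analyte,
        n_controls=len(data),
        b_stderr=float(fit.bse[1]),
    )


def age_adjust(
    y: float | np.ndarray, age: float | np.ndarray, model: AdjustmentModel
):
    """Remove the control-fitted age trend: ``y − b·(age − mean_age)``."""
    return np.asarray(y, dtype=float) - model.b * (
        np.asarray(age, dtype=float) - model.mean_age
    )


# ---------------------------------------------------------------------------
# group comparison battery
# ---------------------------------------------------------------------------

def dunn_test(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal–Wallis.

    Mean ranks over the pooled data are compared pairwise with the normal
    statistic z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j)),
    where T = Σ(t³ − t)/(12(N − 1)) corrects for ties.  P-values carry a
    Bonferroni family-wise adjustment over all pairs (capped at 1).
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))

    mean_ranks, sizes = {}, {}
    start = 0
    for g, v in zip(names, values):
        mean_ranks[g] = float(ranks[start : start + v.size].mean())
        sizes[g] = v.size
        start += v.size

    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term)
            * (1.0 / sizes[a] + 1.0 / sizes[b])
        )
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def group_compare(
    cohort: pd.DataFrame,
    analyte: str,
    group_col: str = "group",
    alpha: float = 0.05,
) -> dict:
    """Kruskal–Wallis omnibus test plus Dunn's pairwise comparisons.

    Orchestration over standard routines: the omnibus statistic comes from
    scipy, pairwise comparisons from :func:`dunn_test` at family-wise alpha.
    """
    data = cohort[[group_col, analyte]].dropna()
    groups = {
        g: sub[analyte].to_numpy(dtype=float)
        for g, sub in data.groupby(group_col, sort=False)
    }
    groups = {g: v for g, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    stat, p = stats.kruskal(*groups.values())
    return {
        "analyte": analyte,
        "groups": {g: int(v.size) for g, v in groups.items()},
        "kruskal_statistic": float(stat),
        "kruskal_p": float(p),
        "dunn": dunn_test(groups, alpha=alpha),
    }


def cap_correlation(
    cohort: pd.DataFrame,
    analyte: str,
    model: CapModel = CapModel(),
) -> dict:
    """Spearman correlation of CAP score with an analyte.

    Computed over the given subset (typically all gene-expansion carriers,
    or the premanifest subset).  A constant analyte makes the rank
    correlation undefined; the result is flagged rather than reported as 0.
    """
    data = cohort[["age", "cag", analyte]].dropna()
    if len(data) < 3:
        raise ValueError("need >= 3 subjects with analyte and CAP inputs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        caps = np.array(
            [cap_score(r.age, r.cag, model) for r in data.itertuples()]
        )
    values = data[analyte].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        return {
            "analyte": analyte, "n": len(data),
            "rho": float("nan"), "p": float("nan"), "undefined": True,
        }
    rho, p = stats.spearmanr(caps, values)
    return {
        "analyte": analyte, "n": len(data),
        "rho": float(rho), "p": float(p), "undefined": False,
    }
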