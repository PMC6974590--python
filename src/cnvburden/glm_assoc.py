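"""Covariate-adjusted logistic association models, overall and by sex.

The association grid crosses five carrier predictor definitions (any call,
lipid-set, small-intestine-set, lipid∩small-intestine, small-intestine∖
lipid) with three strata (all samples, women only, men only) — 15 binomial
GLMs in total, each adjusting for age, BMI, dataset and (in the unstratified
models) sex.  Wald z statistics, two-sided normal p-values and
exp-transformed estimates/intervals are reported per predictor.

Coding conventions: response 1 = case; carrier 0/1; sex male = 1 (female
reference, so a protective male effect appears as OR < 1); dataset as
indicator columns with the largest cohort as reference.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .burden import bonferroni_alpha
from .overlap_annot import (
    AnnotatedCall,
    LIPID_AND_SI_SET,
    LIPID_SET,
    SI_NOT_LIPID_SET,
    SI_SET,
)
from .types import ANY_SET, SampleRecord, Sex, Status, TypeStratum

log = logging.getLogger(__name__)

Z_95 = norm.ppf(0.975)  # 1.959964...
SEPARATION_BOUND = 15.0  # |log-odds| beyond this on a binary predictor


class PredictorSet(enum.Enum):
    """Carrier definitions used as the CNV predictor."""

    ANY_CNV = ANY_SET
    LIPID = LIPID_SET
    SMALL_INTESTINE = SI_SET
    LIPID_AND_SI = LIPID_AND_SI_SET
    SI_NOT_LIPID = SI_NOT_LIPID_SET


class Stratum(enum.Enum):
    ALL = "ALL"
    WOMEN = "WOMEN"
    MEN = "MEN"


@dataclass(frozen=True)
class GlmSpec:
    predictor_set: PredictorSet
    stratum: Stratum

    def covariates(self) -> list[str]:
        cols = ["cnv_carrier", "age"]
        if self.stratum is Stratum.ALL:
            cols.append("sex")
        cols.append("bmi")
        return cols


@dataclass
class GlmResult:
    spec: GlmSpec
    terms: pd.DataFrame  # index: term; columns: estimate, se, z, p, or, ci_low, ci_high
    n_samples: int
    converged: bool
    dropped_columns: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def _carrier_ids(
    annotated: Sequence[AnnotatedCall],
    set_name: str,
    type_stratum: TypeStratum = TypeStratum.ANY,
) -> set[str]:
    out: set[str] = set()
    for ac in annotated:
        if not type_stratum.matches(ac.call.cnv_type):
            continue
        if set_name == ANY_SET or set_name in ac.sets_hit:
            out.add(ac.call.sample_id)
    return out


def make_design(
    samples: Sequence[SampleRecord],
    annotated: Sequence[AnnotatedCall],
    spec: GlmSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and response for one model of the grid.

    Carrier status follows the burden count-once rule for the spec's
    predictor set.  Rows with missing covariates are dropped and logged.
    Strata with fewer than 10 cases or 10 controls are rejected as
    unstable.
    """
    if spec.stratum is Stratum.WOMEN:
        samples = [s for s in samples if s.sex is Sex.FEMALE]
    elif spec.stratum is Stratum.MEN:
        samples = [s for s in samples if s.sex is Sex.MALE]
    if not samples:
        raise ValueError(f"stratum {spec.stratum.value}: no samples")
    carriers = _carrier_ids(annotated, spec.predictor_set.value)
    rows = {
        "cnv_carrier": [float(s.sample_id in carriers) for s in samples],
        "age": [s.age for s in samples],
        "bmi": [s.bmi for s in samples],
    }
    if spec.stratum is Stratum.ALL:
        rows["sex"] = [float(s.sex is Sex.MALE) for s in samples]
    X = pd.DataFrame(rows, index=[s.sample_id for s in samples])
    X = X[spec.covariates()]
    cohorts = pd.Series([s.cohort for s in samples], index=X.index)
    counts = cohorts.value_counts()
    reference = counts.index[0]  # largest cohort
    for cohort in sorted(c for c in counts.index if c != reference):
        X[f"dataset_{cohort}"] = (cohorts == cohort).astype(float)
    y = pd.Series(
        [float(s.status is Status.CASE) for s in samples], index=X.index, name="case"
    )
    keep = X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropping %d rows with missing covariates", n_dropped)
        X, y = X[keep], y[keep]
    n_cases = int(y.sum())
    n_controls = len(y) - n_cases
    if n_cases < 10 or n_controls < 10:
        raise ValueError(
            f"stratum {spec.stratum.value}: {n_cases} cases / {n_controls} "
            "controls; at least 10 of each required for a stable fit"
        )
    return X, y


def _prune_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop trailing columns until the design (with intercept) is full rank."""
    dropped: list[str] = []
    while True:
        M = np.column_stack([np.ones(len(X)), X.to_numpy()])
        if np.linalg.matrix_rank(M) == M.shape[1]:
            break
        # find the first column linearly dependent on its predecessors
        for j in range(1, M.shape[1]):
            if np.linalg.matrix_rank(M[:, : j + 1]) < j + 1:
                name = X.columns[j - 1]
                dropped.append(name)
                X = X.drop(columns=[name])
                break
    if dropped:
        log.warning("dropped collinear design columns: %s", ", ".join(dropped))
    return X, dropped


def fit_logistic(X: pd.DataFrame, y: pd.Series, spec: Optional[GlmSpec] = None) -> GlmResult:
    """Maximum-likelihood logistic fit with Wald inference.

    Convergence requires successive log-likelihood changes < 1e-8 within
    100 Newton iterations.  Complete separation on a binary predictor
    (|estimate| > 15) is flagged via ``converged=False`` rather than
    reported as a trustworthy fit.
    """
    if y.nunique() < 2:
        raise ValueError("degenerate response: all outcomes identical")
    X, dropped = _prune_collinear(X)
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    separation_suspect = False
    try:
        fit = model.fit(disp=0, maxiter=100, tol=1e-8, warn_convergence=False)
    except np.linalg.LinAlgError:
        # Newton's Hessian goes singular under (quasi-)complete separation;
        # a gradient method still yields a diverging-but-finite fit we can
        # flag instead of crashing.
        log.warning("Newton failed (singular Hessian); refitting with BFGS")
        separation_suspect = True
        try:
            fit = model.fit(method="bfgs", disp=0, maxiter=200, gtol=1e-8)
        except Exception as exc:  # pragma: no cover - pathological designs
            raise ValueError(f"logistic fit failed: {exc}") from exc
    params = fit.params
    se = fit.bse
    z = params / se
    p = 2 * norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {
            "estimate": params,
            "se": se,
            "z": z,
            "p": p,
            "or": np.exp(params),
            "ci_low": np.exp(params - Z_95 * se),
            "ci_high": np.exp(params + Z_95 * se),
        }
    )
    converged = bool(fit.mle_retvals.get("converged", False)) and not separation_suspect
    binary_cols = [
        col for col in X.columns
        if set(np.unique(X[col])) <= {0.0, 1.0}
    ]
    for col in binary_cols:
        if abs(params[col]) > SEPARATION_BOUND:
            log.warning("possible complete separation on %s (|estimate| > %g)",
                        col, SEPARATION_BOUND)
            converged = False
    return GlmResult(
        spec=spec if spec is not None else GlmSpec(PredictorSet.ANY_CNV, Stratum.ALL),
        terms=terms,
        n_samples=len(y),
        converged=converged,
        dropped_columns=dropped,
    )


def run_glm_grid(
    samples: Sequence[SampleRecord],
    annotated: Sequence[AnnotatedCall],
    alpha: float = 0.05,
) -> list[Optional[GlmResult]]:
    """Fit the full 5 predictor-set × 3 stratum grid (15 models).

    Cells whose fit fails (tiny stratum, degenerate response, rank
    deficiency) are returned as None and the grid continues.
    """
    results: list[Optional[GlmResult]] = []
    for stratum in Stratum:
        for pred in PredictorSet:
            spec = GlmSpec(pred, stratum)
            try:
                X, y = make_design(samples, annotated, spec)
                results.append(fit_logistic(X, y, spec))
            except ValueError as exc:
                log.warning("grid cell %s/%s failed: %s",
                            pred.name, stratum.name, exc)
                results.append(None)
    return results


def grid_frame(results: Sequence[Optional[GlmResult]], alpha: float = 0.05) -> pd.DataFrame:
    """Forest-plot-ready carrier-term table for the 15-model grid."""
    adj = bonferroni_alpha(alpha, 15)
    rows = []
    for res in results:
        if res is None or "cnv_carrier" not in res.terms.index:
            continue
        t = res.term("cnv_carrier")
        rows.append(
            {
                "predictor_set": res.spec.predictor_set.name,
                "stratum": res.spec.stratum.name,
                "n": res.n_samples,
                "estimate": t["estimate"],
                "se": t["se"],
                "z": t["z"],
                "p": t["p"],
                "or": t["or"],
                "ci_low": t["ci_low"],
                "ci_high": t["ci_high"],
                "alpha_adjusted": adj,
                "significant": bool(t["p"] < adj),
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
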