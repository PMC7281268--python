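"""Pairwise meta-analysis of 2x2 non-response tables.

Study-level log-odds-ratios, Mantel-Haenszel fixed-effect pooling with the
Robins-Breslow-Greenland variance, DerSimonian-Laird random-effects
pooling with Cochran's Q / I-squared heterogeneity, and Egger's regression
test of funnel-plot asymmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    InestimableError,
    InsufficientStudiesError,
    UninformativeStudyError,
    ValidationError,
)
from .trial_data import Study, StudyArm, TreatmentNode

Z95 = 1.959963984540054  # normal 97.5th percentile


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log-odds-ratio of treatment vs control.

    ``cells`` are the original integer counts (a, b, c, d) = (events
    treatment, non-events treatment, events control, non-events control);
    ``y`` and ``se`` come from continuity-corrected cells iff ``corrected``.
    """

    study_id: str
    y: float
    se: float
    corrected: bool
    cells: tuple[int, int, int, int]

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.y)

    def ci95(self) -> tuple[float, float]:
        return (self.y - Z95 * self.se, self.y + Z95 * self.se)


@dataclass(frozen=True)
class PooledResult:
    method: str  # "mantel_haenszel_fixed" | "dersimonian_laird_random"
    pooled_log_or: float
    ci95: tuple[float, float]
    Q: float
    df: int
    i_squared: float
    tau_squared: float
    k: int

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    def or_ci95(self) -> tuple[float, float]:
        return (math.exp(self.ci95[0]), math.exp(self.ci95[1]))


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t: float
    df: int
    p: float
    slope: float


def study_log_or(arm_t: StudyArm, arm_c: StudyArm) -> EffectEstimate:
    """Log-odds-ratio of a treatment arm versus a control arm.

    Adds the Haldane-Anscombe 0.5 to all four cells when any cell is
    zero.  A double-zero (or double-full) study carries no information
    about the odds ratio and raises :class:`UninformativeStudyError` so
    the caller can exclude it from pooling.
    """
    if arm_t.study_id != arm_c.study_id:
        raise ValidationError(
            f"arms from different studies: {arm_t.study_id!r} vs {arm_c.study_id!r}"
        )
    a, b = arm_t.events, arm_t.total - arm_t.events
    c, d = arm_c.events, arm_c.total - arm_c.events
    if a == 0 and c == 0:
        raise UninformativeStudyError(f"{arm_t.study_id}: no events in either arm")
    if b == 0 and d == 0:
        raise UninformativeStudyError(f"{arm_t.study_id}: all events in both arms")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    y = math.log(aa * dd / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return EffectEstimate(arm_t.study_id, y, se, corrected, (a, b, c, d))


def pool_mh_fixed(estimates: list[EffectEstimate]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled odds ratio on uncorrected cells.

    pooled OR = sum(a_i d_i / N_i) / sum(b_i c_i / N_i); the CI uses the
    Robins-Breslow-Greenland variance of the log MH odds ratio.
    Heterogeneity (Q, I-squared) is reported from the inverse-variance
    log-OR decomposition around the MH estimate.
    """
    if not estimates:
        raise ValidationError("no informative tables to pool")
    a = np.array([e.cells[0] for e in estimates], float)
    b = np.array([e.cells[1] for e in estimates], float)
    c = np.array([e.cells[2] for e in estimates], float)
    d = np.array([e.cells[3] for e in estimates], float)
    N = a + b + c + d
    R = a * d / N
    S = b * c / N
    if S.sum() == 0 or R.sum() == 0:
        raise InestimableError("Mantel-Haenszel denominator is zero")
    pooled = math.log(R.sum() / S.sum())

    P = (a + d) / N
    Qc = (b + c) / N
    var = (
        (P * R).sum() / (2 * R.sum() ** 2)
        + ((P * S + Qc * R)).sum() / (2 * R.sum() * S.sum())
        + (Qc * S).sum() / (2 * S.sum() ** 2)
    )
    se = math.sqrt(var)

    y = np.array([e.y for e in estimates])
    w = 1.0 / np.array([e.se for e in estimates]) ** 2
    ybar = float((w * y).sum() / w.sum())
    Q = float((w * (y - ybar) ** 2).sum())
    df = len(estimates) - 1
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return PooledResult(
        "mantel_haenszel_fixed",
        pooled,
        (pooled - Z95 * se, pooled + Z95 * se),
        Q,
        df,
        i2,
        0.0,
        len(estimates),
    )


def pool_dl_random(estimates: list[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling of study log-odds-ratios.

    tau^2 = max(0, (Q - df) / C) with C = sum(w*) - sum(w*^2)/sum(w*) on
    fixed-effect weights w* = 1/se^2; the pooled effect uses weights
    1/(se^2 + tau^2) and a normal 95% CI.  k = 1 degenerates to the
    single estimate with tau^2 = 0.
    """
    if not estimates:
        raise ValidationError("no estimates to pool")
    y = np.array([e.y for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise ValidationError("all standard errors must be positive")
    k = len(estimates)
    wf = 1.0 / se**2
    ybar = float((wf * y).sum() / wf.sum())
    Q = float((wf * (y - ybar) ** 2).sum())
    df = k - 1
    if df > 0:
        C = float(wf.sum() - (wf**2).sum() / wf.sum())
        tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    else:
        tau2 = 0.0
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    w = 1.0 / (se**2 + tau2)
    pooled = float((w * y).sum() / w.sum())
    sep = math.sqrt(1.0 / w.sum())
    return PooledResult(
        "dersimonian_laird_random",
        pooled,
        (pooled - Z95 * sep, pooled + Z95 * sep),
        Q,
        df,
        i2,
        tau2,
        k,
    )


def egger_test(estimates: list[EffectEstimate]) -> EggerResult:
    """Egger's regression test for small-study effects.

    Ordinary least squares of the standardized effect y/se on precision
    1/se; the intercept measures funnel asymmetry and is tested with a
    two-sided t on k - 2 degrees of freedom.
    """
    k = len(estimates)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs k >= 3 studies, got {k}")
    y = np.array([e.y for e in estimates])
    se = np.array([e.se for e in estimates])
    x = 1.0 / se
    z = y / se
    if np.ptp(x) == 0:
        raise CollinearityError("all precisions identical: Egger design is singular")
    fit = stats.linregress(x, z)
    t = fit.intercept / fit.intercept_stderr
    df = k - 2
    p = 2 * stats.t.sf(abs(t), df)
    return EggerResult(fit.intercept, fit.intercept_stderr, float(t), df, float(p), fit.slope)


def forest_funnel_export(
    estimates: list[EffectEstimate], pooled: PooledResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready forest and funnel tables.

    Forest weights are the pooled model's weights renormalized to 100%;
    the funnel table pairs each log-OR with its standard error (plotted
    with the se axis inverted by convention).
    """
    y = np.array([e.y for e in estimates])
    se = np.array([e.se for e in estimates])
    tau2 = pooled.tau_squared if pooled.method == "dersimonian_laird_random" else 0.0
    w = 1.0 / (se**2 + tau2)
    weight_pct = 100.0 * w / w.sum()
    forest = pd.DataFrame(
        {
            "study_id": [e.study_id for e in estimates],
            "odds_ratio": np.exp(y),
            "or_lo": np.exp(y - Z95 * se),
            "or_hi": np.exp(y + Z95 * se),
            "weight_pct": weight_pct,
        }
    )
    funnel = pd.DataFrame(
        {"study_id": [e.study_id for e in estimates], "log_or": y, "se": se}
    )
    return forest, funnel


def iv_vs_po_estimates(studies: list[Study], registry: dict[str, TreatmentNode]) -> list[EffectEstimate]:
    """One IV-versus-oral contrast per eligible study.

    For each study containing at least one IV arm and at least one PO or
    no-iron arm, takes the first-listed IV arm as treatment and the
    first-listed non-IV arm as control (PO preferred over no-iron when
    both are present).  Studies uninformative for the odds ratio are
    silently excluded, mirroring standard double-zero handling.
    """
    out = []
    for s in studies:
        iv = [a for a in s.arms if registry[a.node].route == "IV"]
        po = [a for a in s.arms if registry[a.node].route == "PO"]
        none_ = [a for a in s.arms if registry[a.node].route == "none"]
        ctrl = po[0] if po else (none_[0] if none_ else None)
        if not iv or ctrl is None:
            continue
        try:
            out.append(study_log_or(iv[0], ctrl))
        except UninformativeStudyError:
            continue
    return out
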