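"""Consistency-vs-inconsistency model comparison via DIC.

The unrelated-mean-effects (UME) model keeps the binomial-logit
random-effects likelihood but gives every directly observed comparison
its own mean effect, dropping the consistency equations that tie
indirect and direct evidence together.  If the UME model fits clearly
better (lower DIC), the network's direct and indirect evidence disagree.
An absolute DIC difference below 3 is conventionally read as "no
material inconsistency" -- a heuristic, not a test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .nma import (
    NmaConfig,
    PosteriorSamples,
    _check_identifiable,
    _flatten,
    _FlatNetwork,
    _run_mcmc,
)
from .trial_data import Network

DIC_HEURISTIC_THRESHOLD = 3.0


@dataclass(frozen=True)
class ModelFitStats:
    dbar: float  # posterior mean deviance
    pd: float    # effective number of parameters, Dbar - D(posterior-mean fit)
    dic: float   # Dbar + pD


@dataclass(frozen=True)
class DicReport:
    consistency: ModelFitStats
    ume: ModelFitStats
    delta_dic: float  # DIC_consistency - DIC_ume
    interpretation: str

    def to_dict(self) -> dict:
        return {
            "consistency": vars(self.consistency),
            "ume": vars(self.ume),
            "delta_dic": self.delta_dic,
            "interpretation": self.interpretation,
        }


def _ume_design(flat: _FlatNetwork) -> tuple[np.ndarray, list[str]]:
    """One free parameter per unordered pair with direct baseline data.

    Each pair parameter is oriented as (baseline -> treatment) of the
    first study that contributes the comparison; a study observing the
    reverse orientation maps to -d, so opposite baselines share one
    parameter.
    """
    orient: dict[frozenset, tuple[str, str]] = {}
    for a in flat.nb_idx:
        t = flat.arm_node[a]
        b = flat.baseline_node[flat.arm_study[a]]
        orient.setdefault(frozenset((b, t)), (b, t))
    pairs = sorted(orient.values())
    col = {pr: j for j, pr in enumerate(pairs)}
    X = np.zeros((flat.M, len(pairs)))
    for m, a in enumerate(flat.nb_idx):
        t = flat.arm_node[a]
        b = flat.baseline_node[flat.arm_study[a]]
        pair = orient[frozenset((b, t))]
        X[m, col[pair]] = 1.0 if (b, t) == pair else -1.0
    labels = [f"{u}:{v}" for u, v in pairs]
    return X, labels


def fit_ume(network: Network, config: NmaConfig | None = None) -> PosteriorSamples:
    """Fit the unrelated-mean-effects model on the same likelihood as fit_nma."""
    config = config or NmaConfig()
    if len(network.node_labels) < 2:
        raise ValidationError("a network needs at least 2 treatment nodes")
    _check_identifiable(network)
    flat = _flatten(network)
    X, labels = _ume_design(flat)
    raw = _run_mcmc(flat, X, config)
    return PosteriorSamples(
        model="ume",
        param_labels=labels,
        node_labels=network.node_labels,
        reference=None,
        d=raw["d"],
        mu=raw["mu"],
        delta=raw["delta"],
        tau=raw["tau"],
        subgroup=network.subgroup,
        config=config,
        flat=flat,
        accept_rates=raw["rates"],
    )


def _binomial_deviance(p: np.ndarray, r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Saturated-model binomial deviance, summed over arms.

    ``p`` has shape (..., A); returns shape (...).  Terms with r = 0 or
    r = n contribute only their non-degenerate half; a perfect fit has
    deviance exactly 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(r / (n * p)), 0.0)
        t2 = np.where(n - r > 0, (n - r) * np.log((n - r) / (n * (1.0 - p))), 0.0)
    return 2.0 * (t1 + t2).sum(axis=-1)


def _fitted_p(samples: PosteriorSamples) -> np.ndarray:
    """(chains*draws, A) fitted event probabilities per arm."""
    flat = samples.flat
    C, T, _ = samples.mu.shape
    mu = samples.mu.reshape(C * T, -1)
    delta = samples.delta.reshape(C * T, -1)
    theta = mu[:, flat.arm_study].copy()
    theta[:, flat.nb_idx] += delta
    return 1.0 / (1.0 + np.exp(-theta))


def _model_stats(samples: PosteriorSamples) -> ModelFitStats:
    flat = samples.flat
    p = _fitted_p(samples)
    dev = _binomial_deviance(p, flat.r, flat.n)
    dbar = float(dev.mean())
    d_at_mean = float(_binomial_deviance(p.mean(axis=0), flat.r, flat.n))
    pd_ = dbar - d_at_mean
    return ModelFitStats(dbar, pd_, dbar + pd_)


def compare_dic(
    fit_consistency: PosteriorSamples, fit_ume_: PosteriorSamples, network: Network
) -> DicReport:
    """DIC comparison of the consistency and UME fits on identical data."""
    for fit, expected in ((fit_consistency, "consistency"), (fit_ume_, "ume")):
        if fit.model != expected:
            raise ValidationError(f"expected a {expected} fit, got {fit.model!r}")
    fa, fb = fit_consistency.flat, fit_ume_.flat
    net_flat = _flatten(network)
    for other in (fa, fb):
        if (
            other.study_ids != net_flat.study_ids
            or not np.array_equal(other.r, net_flat.r)
            or not np.array_equal(other.n, net_flat.n)
        ):
            raise ValidationError("fits were not produced from the given network")
    cons = _model_stats(fit_consistency)
    ume = _model_stats(fit_ume_)
    delta = cons.dic - ume.dic
    interp = (
        "no material inconsistency (|DIC difference| < 3, heuristic)"
        if abs(delta) < DIC_HEURISTIC_THRESHOLD
        else "possible inconsistency: UME model fits better"
        if delta > 0
        else "consistency model preferred"
    )
    return DicReport(cons, ume, float(delta), interp)


def ume_estimates(fit: PosteriorSamples) -> pd.DataFrame:
    """Per-comparison posterior OR summaries from a UME fit."""
    if fit.model != "ume":
        raise ValidationError("ume_estimates needs a UME fit")
    d = fit.d.reshape(-1, fit.d.shape[-1])
    rows = []
    for j, lbl in enumerate(fit.param_labels):
        u, v = lbl.split(":")
        med, lo, hi = np.percentile(np.exp(d[:, j]), [50.0, 2.5, 97.5])
        rows.append(
            {"reference": u, "comparator": v, "or_median": med, "or_lo": lo, "or_hi": hi}
        )
    return pd.DataFrame(rows)
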