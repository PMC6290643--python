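"""Parameter-recovery scoring against simulator truth.

Agreement rates for the skill profiles (attribute-wise and pattern-wise,
per time point), sensitivity/specificity of disengagement detection,
bias/RMSE of the population parameters across replicates, and Pearson
correlations between true and estimated person/item vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sampler import STRUCTURAL_FIELDS, PosteriorSummary
from .simulate import SimResult
from .types import DomainError


def attribute_agreement(alpha_true: np.ndarray, alpha_hat: np.ndarray,
                        d_hat: np.ndarray | None = None):
    """AAR and PAR per time point between true and estimated profiles.

    Learners estimated as disengaged at every time point are excluded: no
    engaged observation ties their data to a profile. Returns
    (aar (T,), par (T,), n_excluded).
    """
    alpha_true = np.asarray(alpha_true)
    alpha_hat = np.asarray(alpha_hat)
    if alpha_true.shape != alpha_hat.shape:
        raise DomainError("true and estimated profile arrays must match in shape")
    keep = np.ones(alpha_true.shape[0], dtype=bool)
    if d_hat is not None:
        keep = ~(np.asarray(d_hat) == 1).all(axis=1)
    if not keep.any():
        raise DomainError("all learners excluded; agreement rates undefined")
    at, ah = alpha_true[keep], alpha_hat[keep]
    match = at == ah
    aar = match.mean(axis=(0, 2))
    par = match.all(axis=2).mean(axis=0)
    return aar, par, int((~keep).sum())


def mode_detection_metrics(d_true: np.ndarray, d_hat: np.ndarray):
    """Sensitivity and specificity of disengagement detection over cells.

    Sensitivity = P(estimated disengaged | truly disengaged); specificity
    = P(estimated engaged | truly engaged). A side with no true cells is
    undefined and reported as NaN.
    """
    d_true = np.asarray(d_true)
    d_hat = np.asarray(d_hat)
    if d_true.shape != d_hat.shape:
        raise DomainError("mode arrays must match in shape")
    pos = d_true == 1
    neg = d_true == 0
    sens = float((d_hat[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((d_hat[neg] == 0).mean()) if neg.any() else float("nan")
    return sens, spec


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def recovery_stats(truths: list[SimResult], summaries: list[PosteriorSummary]):
    """Bias, RMSE and correlations across replicates.

    Bias and RMSE are computed over replicates for each scalar structural
    parameter (EAP minus truth). Correlations are computed within each
    replicate and then averaged: theta excludes learners whose *estimated*
    initial profile is full mastery (their transitions carry no
    information on theta); tau, a, gamma, s, g use all values.
    """
    if len(truths) != len(summaries) or not truths:
        raise DomainError("need matched, non-empty truth/estimate replicate lists")
    bias, rmse, corrs = {}, {}, {}
    for name in STRUCTURAL_FIELDS:
        err = np.array([summ.structural[name][0] - getattr(tr.structural, name)
                        for tr, summ in zip(truths, summaries)])
        bias[name] = float(err.mean())
        rmse[name] = float(np.sqrt((err ** 2).mean()))
    per_rep: dict[str, list[float]] = {k: [] for k in
                                       ("theta", "tau", "a", "gamma", "s", "g")}
    for tr, summ in zip(truths, summaries):
        full = 2 ** tr.data.n_skills - 1
        init_cls_hat = (summ.alpha_hat[:, 0, :] *
                        (1 << np.arange(tr.data.n_skills))).sum(axis=1)
        keep = init_cls_hat != full
        per_rep["theta"].append(_corr(tr.person_params.theta[keep],
                                      summ.person.theta[keep]))
        per_rep["tau"].append(_corr(tr.person_params.tau, summ.person.tau))
        per_rep["a"].append(_corr(tr.item_params.a, summ.item.a))
        per_rep["gamma"].append(_corr(tr.item_params.gamma, summ.item.gamma))
        per_rep["s"].append(_corr(tr.item_params.s, summ.item.s))
        per_rep["g"].append(_corr(tr.item_params.g, summ.item.g))
    for k, vals in per_rep.items():
        corrs[k] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
    return bias, rmse, corrs


@dataclass
class RecoveryReport:
    """Replicate-averaged recovery metrics, mirroring the study's tables."""

    aar: np.ndarray  # (T,) averaged over replicates
    par: np.ndarray
    sensitivity: float
    specificity: float
    bias: dict
    rmse: dict
    correlations: dict
    n_excluded: int
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.aar.shape[0]):
            rows.append(("AAR", f"t={t + 1}", self.aar[t]))
            rows.append(("PAR", f"t={t + 1}", self.par[t]))
        rows.append(("D", "sensitivity", self.sensitivity))
        rows.append(("D", "specificity", self.specificity))
        for name in self.bias:
            rows.append(("bias", name, self.bias[name]))
            rows.append(("rmse", name, self.rmse[name]))
        for name, rho in self.correlations.items():
            rows.append(("correlation", name, rho))
        return pd.DataFrame(rows, columns=["metric", "component", "value"])


def recovery_report(truths: list[SimResult],
                    summaries: list[PosteriorSummary]) -> RecoveryReport:
    """Full recovery report: agreement rates averaged over replicates,
    disengagement detection pooled over cells, bias/RMSE/correlations."""
    aars, pars, excl = [], [], 0
    tp = fn = tn = fp = 0
    for tr, summ in zip(truths, summaries):
        aar, par, ne = attribute_agreement(tr.latent.alpha, summ.alpha_hat,
                                           summ.d_hat)
        aars.append(aar)
        pars.append(par)
        excl += ne
        d_true, d_hat = tr.latent.d, summ.d_hat
        tp += int(((d_true == 1) & (d_hat == 1)).sum())
        fn += int(((d_true == 1) & (d_hat == 0)).sum())
        tn += int(((d_true == 0) & (d_hat == 0)).sum())
        fp += int(((d_true == 0) & (d_hat == 1)).sum())
    bias, rmse, corrs = recovery_stats(truths, summaries)
    return RecoveryReport(
        aar=np.mean(aars, axis=0), par=np.mean(pars, axis=0),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        bias=bias, rmse=rmse, correlations=corrs,
        n_excluded=excl, n_replicates=len(truths))
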