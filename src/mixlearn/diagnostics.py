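"""Convergence and model-fit diagnostics.

Gelman-Rubin PSRF for scalar chains, a joint (response + response-time)
deviance information criterion conditional on the sampled latent states,
and posterior predictive checks built on change scores and change times
between the first and last modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import _measurement_loglik, profile_index
from .sampler import McmcSamples, PosteriorSummary, posterior_summaries
from .types import DomainError, ItemParams, ObservedData, PersonParams


def psrf(chains) -> float:
    """Classic univariate potential scale reduction factor.

    ``chains`` is an (m, n) array or list of equal-length 1-D arrays.
    With W the mean within-chain variance and B/n the variance of the chain
    means, R-hat = sqrt(((n-1)/n W + B/n) / W). Identical chains give 1.0;
    distinct constant chains (zero within-variance) are an error.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DomainError("psrf needs >= 2 chains of equal length >= 2")
    m, n = arr.shape
    w = arr.var(axis=1, ddof=1).mean()
    b_over_n = arr.mean(axis=1).var(ddof=1)
    if w == 0.0:
        if b_over_n == 0.0:
            return 1.0
        raise DomainError("zero within-chain variance across distinct chains")
    v_hat = (n - 1) / n * w + b_over_n
    # the (n-1)/n deflation can push the ratio below 1 (e.g. identical
    # chains); floor at 1, the diagnostic's natural lower bound
    return float(max(np.sqrt(v_hat / w), 1.0))


def max_psrf(chains: list[McmcSamples], length: int | None = None,
             include_person: bool = True) -> tuple[float, dict]:
    """Maximum PSRF over all parameters, first half of the chain as burn-in.

    Returns (max R-hat, per-parameter dict). Parameters whose draws are
    identical across chains (e.g. a fixed value in a restricted fit)
    contribute R-hat = 1.
    """
    if len(chains) < 2:
        raise DomainError("max_psrf needs at least two chains")
    traces = [c.scalar_traces(include_person=include_person) for c in chains]
    out = {}
    for name in traces[0]:
        rows = [t[name] if length is None else t[name][:length] for t in traces]
        half = len(rows[0]) // 2
        rows = np.asarray([r[half:] for r in rows])
        if np.ptp(rows) == 0.0:
            out[name] = 1.0
            continue
        out[name] = psrf(rows)
    return max(out.values()), out


@dataclass
class DicResult:
    dic: float
    dbar: float
    dhat: float
    p_d: float


def joint_dic(samples: McmcSamples | list[McmcSamples], data: ObservedData) -> DicResult:
    """Deviance information criterion of the joint response/RT measurement.

    The deviance is -2 x (response log-likelihood + RT log-likelihood)
    conditional on the sampled latent states; D-bar averages it over the
    post-burn-in sweeps, and the plug-in deviance evaluates the EAP
    parameters at the dichotomized latent modes. DIC = D-bar + p_D with
    p_D = D-bar - D-hat.
    """
    chains = samples if isinstance(samples, list) else [samples]
    if not chains[0].person:
        raise DomainError("joint DIC needs stored person draws (store_person=True)")
    dbar = float(np.mean(np.concatenate([c.deviance[c.burn:] for c in chains])))
    summ = posterior_summaries(chains)
    cls_hat = profile_index(summ.alpha_hat)
    dhat = -2.0 * _measurement_loglik(data, cls_hat, summ.d_hat, summ.item,
                                      summ.person, summ.structural_params())
    p_d = dbar - dhat
    return DicResult(dic=dbar + p_d, dbar=dbar, dhat=dhat, p_d=p_d)


@dataclass
class PpcQuantity:
    """A per-learner change statistic aggregated over learners.

    kind 'score': total score at the last module minus the first;
    kind 'time': total response time (seconds) at the last module minus
    the first. Aggregator is min, mean or max over learners.
    """

    name: str
    kind: str  # 'score' | 'time'
    agg: str  # 'min' | 'mean' | 'max'

    def __post_init__(self) -> None:
        if self.kind not in ("score", "time") or self.agg not in ("min", "mean", "max"):
            raise DomainError("unknown PPC quantity definition")


DEFAULT_PPC_QUANTITIES = [
    PpcQuantity("change_score_min", "score", "min"),
    PpcQuantity("change_score_mean", "score", "mean"),
    PpcQuantity("change_score_max", "score", "max"),
    PpcQuantity("change_time_min", "time", "min"),
    PpcQuantity("change_time_mean", "time", "mean"),
    PpcQuantity("change_time_max", "time", "max"),
]


def _change_stat(x: np.ndarray, latency: np.ndarray, data: ObservedData,
                 q: PpcQuantity) -> float:
    first = data.items_at(0)
    last = data.items_at(data.n_times - 1)
    if q.kind == "score":
        per = x[:, last].sum(axis=1) - x[:, first].sum(axis=1)
    else:
        per = latency[:, last].sum(axis=1) - latency[:, first].sum(axis=1)
    return float(getattr(np, q.agg)(per))


def _simulate_replicate(snap: dict, data: ObservedData, eta: np.ndarray, rng):
    t_of = data.item_time
    j_idx = np.arange(data.n_items)
    eta_cells = eta[snap["cls"][:, t_of], j_idx[None, :]]
    dis = snap["d"][:, t_of].astype(bool)
    p = np.where(dis, snap["gstar"],
                 np.where(eta_cells == 1, 1.0 - snap["s"][None, :], snap["g"][None, :]))
    x = (rng.random(p.shape) < p).astype(np.int8)
    mean_eng = snap["gamma"][None, :] - (snap["tau"][:, None] + snap["phi"] * eta_cells)
    log_l = np.where(dis,
                     rng.normal(snap["mu1"], np.sqrt(snap["sigma1_sq"]), size=p.shape),
                     rng.standard_normal(p.shape) / snap["a"][None, :] + mean_eng)
    return x, np.exp(log_l)


def ppc_pvalues(samples: McmcSamples | list[McmcSamples], data: ObservedData,
                quantities: list[PpcQuantity] | None = None, seed=None) -> dict:
    """Posterior predictive p-values for change-score / change-time statistics.

    For each stored latent snapshot a replicate dataset is simulated from
    the fitted measurement model; p is the upper-tail fraction of
    replicates whose statistic is >= the observed one. Values outside
    (0.05, 0.95) are flagged as extreme in the returned records.
    """
    import warnings

    if data.n_times < 2:
        raise DomainError("posterior predictive change statistics need T >= 2")
    quantities = quantities or DEFAULT_PPC_QUANTITIES
    chains = samples if isinstance(samples, list) else [samples]
    snaps = [s for c in chains for s in c.snapshots]
    if len(snaps) < 50:
        warnings.warn(f"only {len(snaps)} stored draws for PPC; p-values are coarse")
    if not snaps:
        raise DomainError("no stored snapshots for posterior predictive checks")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from .likelihood import eta_table

    eta = eta_table(data.q.q)
    obs = {q.name: _change_stat(data.x, data.latency, data, q) for q in quantities}
    reps = {q.name: [] for q in quantities}
    for snap in snaps:
        x_rep, l_rep = _simulate_replicate(snap, data, eta, rng)
        for q in quantities:
            reps[q.name].append(_change_stat(x_rep, l_rep, data, q))
    out = {}
    for q in quantities:
        r = np.asarray(reps[q.name])
        p = float((r >= obs[q.name]).mean())
        out[q.name] = {"p": p, "observed": obs[q.name],
                       "extreme": bool(p < 0.05 or p > 0.95)}
    return out


def report_text(psrf_by_param: dict | None = None, dic: DicResult | None = None,
                ppc: dict | None = None) -> str:
    """Plain-text diagnostic report (PSRF table, DIC, PPC p-values)."""
    lines = ["Diagnostics report", "=" * 18]
    if psrf_by_param is not None:
        worst = sorted(psrf_by_param.items(), key=lambda kv: -kv[1])[:10]
        lines.append(f"max PSRF: {max(psrf_by_param.values()):.4f}")
        lines.append("worst parameters:")
        for k, v in worst:
            lines.append(f"  {k:>14s}  {v:.4f}")
    if dic is not None:
        lines.append(f"joint DIC (conditional on latents): {dic.dic:.1f} "
                     f"(D-bar {dic.dbar:.1f}, p_D {dic.p_d:.1f})")
    if ppc is not None:
        lines.append("posterior predictive p-values (upper tail):")
        for name, rec in ppc.items():
            flag = "  EXTREME" if rec["extreme"] else ""
            lines.append(f"  {name:>18s}  p = {rec['p']:.3f}{flag}")
    return "\n".join(lines)
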