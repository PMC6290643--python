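"""Model/Results facade over the Gibbs machinery.

`MixtureLearningModel` is constructed from an :class:`ObservedData` (or a
long-format DataFrame plus Q-matrix frame); ``fit`` runs one or more MCMC
chains and returns a `MixtureLearningResults` with EAP estimates,
posterior SDs, dichotomized latent states, diagnostics and a summary
table, in the spirit of statsmodels' model/results pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .sampler import (
    STRUCTURAL_FIELDS,
    McmcConfig,
    McmcSamples,
    PosteriorSummary,
    posterior_summaries,
    run_chains,
)
from .types import DomainError, ObservedData, PriorSpec, QMatrix


class MixtureLearningModel:
    """Two-mode (engaged/disengaged) hidden-Markov DINA model with
    joint response and response-time measurement.

    Parameters
    ----------
    data : ObservedData
        Responses and latencies over modules, with the Q-matrix.
    prior : PriorSpec, optional
        Hyperparameters; defaults follow the standard weak priors.
    mixture : bool
        If False, fit the engaged-only restriction (D = 0 everywhere,
        omega fixed at 0) — the non-mixture joint model.
    """

    def __init__(self, data: ObservedData, prior: PriorSpec | None = None,
                 mixture: bool = True):
        self.data = data
        self.prior = prior or PriorSpec()
        self.mixture = mixture

    @classmethod
    def from_frames(cls, data_df: pd.DataFrame, q_df: pd.DataFrame, **kw):
        """Build from long-format records and a Q-matrix frame (the CSV
        schemas of :mod:`mixlearn.io`, already loaded)."""
        import tempfile, os

        from . import io as mio

        with tempfile.TemporaryDirectory() as tmp:
            dp, qp = os.path.join(tmp, "d.csv"), os.path.join(tmp, "q.csv")
            data_df.to_csv(dp, index=False)
            q_df.to_csv(qp, index=False)
            data = mio.read_dataset(dp, qp)
        return cls(data, **kw)

    def fit(self, draws: int = 30_000, burn: int = 5_000, chains: int = 1,
            seed: int | None = None, **config_kw) -> "MixtureLearningResults":
        config = McmcConfig(draws=draws, burn=burn, chains=chains, seed=seed,
                            mixture=self.mixture, prior=self.prior, **config_kw)
        return MixtureLearningResults(self, run_chains(self.data, config))


class MixtureLearningResults:
    """Posterior estimates and diagnostics from one or more chains."""

    def __init__(self, model: MixtureLearningModel, chains: list[McmcSamples]):
        self.model = model
        self.chains = chains
        self._summary: PosteriorSummary | None = None

    @property
    def summary_data(self) -> PosteriorSummary:
        if self._summary is None:
            self._summary = posterior_summaries(self.chains)
        return self._summary

    # point estimates -------------------------------------------------
    @property
    def params(self) -> dict:
        """EAP estimates of the structural parameters."""
        return {k: v[0] for k, v in self.summary_data.structural.items()}

    @property
    def sd(self) -> dict:
        """Posterior standard deviations of the structural parameters."""
        return {k: v[1] for k, v in self.summary_data.structural.items()}

    @property
    def item_params(self):
        return self.summary_data.item

    @property
    def person_params(self):
        return self.summary_data.person

    @property
    def alpha_hat(self) -> np.ndarray:
        return self.summary_data.alpha_hat

    @property
    def d_hat(self) -> np.ndarray:
        return self.summary_data.d_hat

    @property
    def acceptance(self) -> dict:
        return {i: c.acceptance for i, c in enumerate(self.chains)}

    # diagnostics ------------------------------------------------------
    def max_psrf(self, length: int | None = None, include_person: bool = True):
        if len(self.chains) < 2:
            raise DomainError("PSRF needs at least two chains; refit with chains>=2")
        return diag.max_psrf(self.chains, length=length,
                             include_person=include_person)

    def dic(self) -> diag.DicResult:
        return diag.joint_dic(self.chains, self.model.data)

    def ppc(self, quantities=None, seed=None) -> dict:
        return diag.ppc_pvalues(self.chains, self.model.data,
                                quantities=quantities, seed=seed)

    def check_label_anchoring(self) -> bool:
        """Warn if the disengaged RT component has drifted on top of the
        engaged one, which would suggest the mixture labels lost their
        meaning. The comparison uses the identified engaged scale
        mean(gamma) - mean(tau): the likelihood is flat along a joint
        translation of intensities and speeds, so gamma alone is anchored
        only weakly by its prior."""
        import warnings

        from .likelihood import eta_table, profile_index

        mu1 = self.params["mu1"]
        summ = self.summary_data
        data = self.model.data
        eta = eta_table(data.q.q)
        cls_hat = profile_index(summ.alpha_hat)
        g_cells = eta[cls_hat[:, data.item_time], np.arange(data.n_items)[None, :]]
        pred = (summ.item.gamma[None, :] - summ.person.tau[:, None]
                - self.params["phi"] * g_cells)
        engaged = summ.d_hat[:, data.item_time] == 0
        engaged_scale = float(pred[engaged].mean()) if engaged.any() else np.inf
        ok = mu1 < engaged_scale
        if not ok:
            warnings.warn("disengaged log-RT mean exceeds the mean time "
                          "intensity; mixture components may have swapped roles")
        return ok

    def summary(self) -> str:
        """Plain-text summary table of the structural parameters."""
        lines = ["Mixture learning model results",
                 "=" * 46,
                 f"learners: {self.model.data.n_learners}   modules: "
                 f"{self.model.data.n_times}   items: {self.model.data.n_items}   "
                 f"skills: {self.model.data.n_skills}",
                 f"chains: {len(self.chains)}   draws/chain: {self.chains[0].draws}"
                 f"   burn-in: {self.chains[0].burn}",
                 "-" * 46,
                 f"{'parameter':>14s} {'EAP':>10s} {'SD':>10s}"]
        for k in STRUCTURAL_FIELDS:
            eap, sd = self.summary_data.structural[k]
            lines.append(f"{k:>14s} {eap:>10.3f} {sd:>10.3f}")
        full = self.summary_data.pi[-1]
        lines.append(f"{'pi[full]':>14s} {full:>10.3f} "
                     f"{self.summary_data.pi_sd[-1]:>10.3f}")
        nd = int(self.d_hat.sum())
        lines.append("-" * 46)
        lines.append(f"learner-module cells flagged disengaged: {nd}")
        acc = self.chains[0].acceptance
        lines.append(f"MH acceptance: theta {acc.get('theta', float('nan')):.2f}, "
                     f"lambda {acc.get('lambda', float('nan')):.2f}")
        return "\n".join(lines)
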