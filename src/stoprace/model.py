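"""Model / Results interface to the race-model fits.

The estimation machinery in :mod:`stoprace.sampler` is wrapped in the usual
modelling-object idiom: a model is built from data, ``fit()`` returns a
results object carrying draws, point estimates, uncertainties and
diagnostics, and ``summary()`` renders a table.  Simulation and plotting
hang off these objects.

Example
-------
>>> from stoprace import presets, simulate, model
>>> ps = presets.parameter_set("rifg_lesion")
>>> trials = simulate.simulate_participant(ps, seed=1)
>>> res = model.StopSignalModel(trials).fit(seed=2)
>>> print(res.summary())                           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .race import PARAM_NAMES, CensoringRule, ParameterSet
from .sampler import (
    HierPriors,
    PosteriorDraws,
    SamplerConfig,
    fit_hierarchical,
    fit_individual,
)
from .simulate import TaskDesign, simulate_participant
from . import inference as _inference

__all__ = ["StopSignalModel", "StopSignalResults",
           "HierarchicalStopSignalModel", "HierarchicalResults"]


def _summary_frame(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, x in samples.items():
        x = np.asarray(x)
        rows.append({
            "parameter": name, "mean": x.mean(), "sd": x.std(ddof=1),
            "ci_2.5%": np.percentile(x, 2.5),
            "ci_97.5%": np.percentile(x, 97.5),
        })
    return pd.DataFrame(rows).set_index("parameter")


def _render(title: str, frame: pd.DataFrame, extra: str = "") -> str:
    body = frame.to_string(float_format=lambda v: f"{v:10.3f}")
    bar = "=" * max(len(title), 40)
    return f"{bar}\n{title}\n{bar}\n{body}\n{extra}"


class StopSignalModel:
    """Race model with trigger failures for a single participant's trials."""

    def __init__(self, trials: pd.DataFrame,
                 censoring: CensoringRule = CensoringRule(),
                 priors: HierPriors | None = None):
        self.trials = trials
        self.censoring = censoring
        self.priors = priors or HierPriors()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StopSignalModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, config: SamplerConfig = SamplerConfig(),
            seed=None) -> "StopSignalResults":
        draws = fit_individual(self.trials, priors=self.priors,
                               config=config, cens=self.censoring, seed=seed)
        return StopSignalResults(model=self, draws=draws)


@dataclass
class StopSignalResults:
    """Posterior draws and point estimates of one participant's fit."""

    model: StopSignalModel
    draws: PosteriorDraws

    @property
    def params(self) -> ParameterSet:
        """Posterior-mean parameter set (the point estimate)."""
        return self.draws.subject_parameter_sets()[0]

    def param_samples(self) -> dict[str, np.ndarray]:
        nat = self.draws.subject_draws(natural=True)[:, :, 0, :]
        out = {n: nat[..., j].reshape(-1) for j, n in enumerate(PARAM_NAMES)}
        out["mean_go_rt"] = out["mu_go"] + out["tau_go"]
        out["mean_ssrt"] = out["mu_stop"] + out["tau_stop"]
        return out

    def rhat(self) -> dict[str, float]:
        return self.draws.rhat()

    def summary(self) -> str:
        frame = _summary_frame(self.param_samples())
        worst = max(self.rhat().values())
        return _render("Stop-signal race model (individual fit)", frame,
                       f"\nmax R-hat: {worst:.3f}")

    def simulate(self, design: TaskDesign = TaskDesign(), seed=None):
        """Replicate session from the posterior-mean parameters."""
        return simulate_participant(self.params, design, seed=seed)

    def posterior_predictive(self, design: TaskDesign = TaskDesign(),
                             n_draws: int = 100, seed=None):
        return _inference.posterior_predictive(
            self.draws, self.model.trials, design=design,
            n_draws=n_draws, seed=seed)

    def plot_fit(self, ax=None):
        """Observed go-RT histogram with the posterior-mean density."""
        import matplotlib.pyplot as plt

        from .exgauss import exg_pdf

        if ax is None:
            _, ax = plt.subplots()
        rt = self.model.trials.query("trial_type == 'go'")["rt_ms"].dropna()
        ax.hist(rt, bins=30, density=True, alpha=0.4, label="observed go RT")
        g = self.params.go
        grid = np.linspace(rt.min(), rt.max(), 300)
        ax.plot(grid, exg_pdf(grid, g.mu, g.sigma, g.tau),
                label="posterior-mean fit")
        ax.set_xlabel("RT (ms)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


class HierarchicalStopSignalModel:
    """Hierarchical race model over a group of participants."""

    def __init__(self, tables: list[pd.DataFrame],
                 censoring: CensoringRule = CensoringRule(),
                 priors: HierPriors | None = None):
        if len(tables) < 2:
            raise ValueError("need at least 2 participants")
        self.tables = list(tables)
        self.censoring = censoring
        self.priors = priors or HierPriors()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, participant_col: str = "participant",
                       **kwargs) -> "HierarchicalStopSignalModel":
        tables = [g.reset_index(drop=True)
                  for _, g in df.groupby(participant_col, sort=True)]
        return cls(tables, **kwargs)

    def fit(self, config: SamplerConfig = SamplerConfig(), seed=None,
            start="moments", progress=False) -> "HierarchicalResults":
        draws = fit_hierarchical(self.tables, priors=self.priors,
                                 config=config, cens=self.censoring,
                                 seed=seed, start=start, progress=progress)
        return HierarchicalResults(model=self, draws=draws)


@dataclass
class HierarchicalResults:
    """Population- and participant-level posterior of a group fit."""

    model: HierarchicalStopSignalModel
    draws: PosteriorDraws

    def population_samples(self) -> dict[str, np.ndarray]:
        """Per-draw population means on natural scales, plus derived means."""
        return _inference._population_samples(self.draws)

    def population_summary(self) -> pd.DataFrame:
        frame = _summary_frame(self.population_samples())
        rh = self.draws.rhat()
        frame["rhat_loc"] = [rh.get(f"loc_{n}", np.nan) for n in frame.index]
        return frame

    def participant_posterior_means(self) -> pd.DataFrame:
        """Per-participant point estimates, incl. the SSRT the EEG analysis uses."""
        means = self.draws.subject_posterior_means()
        df = pd.DataFrame(means, columns=PARAM_NAMES)
        df.insert(0, "subject", np.arange(len(df)))
        df["mean_go_rt"] = df["mu_go"] + df["tau_go"]
        df["mean_ssrt"] = df["mu_stop"] + df["tau_stop"]
        return df

    def rhat(self) -> dict[str, float]:
        return self.draws.rhat()

    def converged(self, threshold: float = 1.1) -> bool:
        return self.draws.converged(threshold)

    def summary(self) -> str:
        frame = self.population_summary()
        worst = max(self.rhat().values())
        n = self.draws
        extra = (f"\nchains: {n.n_chains}  retained draws/chain: {n.n_draws}"
                 f"  participants: {n.n_subjects}"
                 f"\nmax R-hat: {worst:.3f} "
                 f"({'converged' if worst < 1.1 else 'NOT converged'})")
        return _render("Hierarchical stop-signal race model", frame, extra)

    def compare(self, other: "HierarchicalResults",
                parameters=_inference.DERIVED_NAMES) -> pd.DataFrame:
        """Bayesian-p group comparison table against another group's fit."""
        return _inference.comparison_table(self.draws, other.draws, parameters)

    def posterior_predictive(self, subject: int,
                             design: TaskDesign = TaskDesign(),
                             n_draws: int = 100, seed=None):
        return _inference.posterior_predictive(
            self.draws, self.model.tables[subject], design=design,
            subject=subject, n_draws=n_draws, seed=seed)

    def plot_population(self, parameter: str = "mean_ssrt", ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.population_samples()[parameter]
        ax.hist(x, bins=40, density=True, alpha=0.6)
        ax.set_xlabel(parameter)
        ax.set_ylabel("posterior density")
        return ax
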