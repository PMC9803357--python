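"""Posterior summaries, group comparison, predictive checks, and mixing.

Group inference follows the Bayesian-p convention: the posterior samples of
two independently fitted groups are paired by (chain, iteration) index, the
per-draw difference A - B is formed after transforming draws to the
inferentially meaningful scale (truncated-normal locations to distribution
means, probit-scale trigger-failure parameters to population means of
p_tf), and p is the folded proportion min(p, 1 - p) of draws with A > B.
Values near 0 indicate group separation; the two-sided reporting threshold
is 0.05 (one-sided 0.025).

Derived means are linear: mean Go-RT = mu_go + tau_go and mean SSRT =
mu_stop + tau_stop, computed per MCMC iteration and collapsed across
chains.  Posterior predictive checks simulate replicate sessions from
posterior draws through the same staircase machinery that generated (or
collected) the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .race import PARAM_NAMES, ParameterSet
from .sampler import PosteriorDraws
from .simulate import TaskDesign, simulate_participant

__all__ = [
    "GroupComparison",
    "PpcReport",
    "derived_means",
    "bayesian_p",
    "comparison_table",
    "posterior_predictive",
    "mix_posteriors",
    "DERIVED_NAMES",
]

DERIVED_NAMES = PARAM_NAMES + ("mean_go_rt", "mean_ssrt")


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    mean_a: float
    mean_b: float
    diff_mean: float
    diff_ci: tuple
    bayesian_p: float

    def __post_init__(self):
        if not 0.0 <= self.bayesian_p <= 0.5 + 1e-12:
            raise ValueError("folded Bayesian p must lie in [0, 0.5]")
        if self.diff_ci[0] > self.diff_ci[1]:
            raise ValueError("CI bounds must be ordered")


def _population_samples(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Population-level per-draw samples on inference scales, plus derived."""
    if draws.pop_loc is None:
        nat = draws.subject_draws(natural=True)[:, :, 0, :]
        out = {name: nat[..., j].reshape(-1) for j, name in enumerate(PARAM_NAMES)}
    else:
        out = draws.population_means()
    out["mean_go_rt"] = out["mu_go"] + out["tau_go"]
    out["mean_ssrt"] = out["mu_stop"] + out["tau_stop"]
    return out


def derived_means(draws: PosteriorDraws):
    """Posterior distributions of mean Go-RT and mean SSRT.

    Returns ``(population, participant)``: the population dict maps
    ``mean_go_rt`` / ``mean_ssrt`` to chain-collapsed per-draw arrays (None
    for individual fits without a population level ... the participant
    entry is then the single subject); the participant entry is a DataFrame
    of per-subject posterior means of both derived quantities — the point
    estimates the burst analysis consumes.
    """
    nat = draws.subject_draws(natural=True)  # (C, K, S, 7)
    mean_go = nat[..., 0] + nat[..., 2]
    mean_ssrt = nat[..., 3] + nat[..., 5]
    participant = pd.DataFrame({
        "subject": np.arange(draws.n_subjects),
        "mean_go_rt": mean_go.mean(axis=(0, 1)),
        "mean_ssrt": mean_ssrt.mean(axis=(0, 1)),
    })
    if draws.pop_loc is not None:
        pop = _population_samples(draws)
        population = {"mean_go_rt": pop["mean_go_rt"],
                      "mean_ssrt": pop["mean_ssrt"]}
    else:
        population = {"mean_go_rt": mean_go[:, :, 0].reshape(-1),
                      "mean_ssrt": mean_ssrt[:, :, 0].reshape(-1)}
    return population, participant


def bayesian_p(draws_a, draws_b, parameter: str,
               rng=None) -> GroupComparison:
    """Folded posterior overlap of one parameter between two groups.

    ``draws_a`` / ``draws_b`` may be :class:`PosteriorDraws` or plain
    per-draw sample arrays.  Samples are paired by index after collapsing
    chains; unequal lengths are bootstrap-paired (resampled to the shorter
    length) using ``rng``.
    """
    def extract(d):
        if isinstance(d, PosteriorDraws):
            samples = _population_samples(d)
            if parameter not in samples:
                raise KeyError(
                    f"unknown parameter {parameter!r}; "
                    f"expected one of {DERIVED_NAMES}"
                )
            return np.asarray(samples[parameter], dtype=float)
        return np.asarray(d, dtype=float).reshape(-1)

    a, b = extract(draws_a), extract(draws_b)
    if len(a) != len(b):
        rng = np.random.default_rng() if rng is None else rng
        n = min(len(a), len(b))
        a = rng.choice(a, size=n, replace=False) if len(a) > n else a
        b = rng.choice(b, size=n, replace=False) if len(b) > n else b
    diff = a - b
    p_raw = float(np.mean(a > b))
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return GroupComparison(
        parameter=parameter, mean_a=float(a.mean()), mean_b=float(b.mean()),
        diff_mean=float(diff.mean()), diff_ci=(float(lo), float(hi)),
        bayesian_p=min(p_raw, 1.0 - p_raw),
    )


def comparison_table(draws_a, draws_b, parameters=DERIVED_NAMES) -> pd.DataFrame:
    """Group-comparison rows for several parameters (Table-style CSV export)."""
    rows = []
    for p in parameters:
        c = bayesian_p(draws_a, draws_b, p)
        rows.append({"parameter": p, "mean_a": c.mean_a, "mean_b": c.mean_b,
                     "diff_mean": c.diff_mean, "ci_low": c.diff_ci[0],
                     "ci_high": c.diff_ci[1], "bayesian_p": c.bayesian_p})
    return pd.DataFrame(rows)


@dataclass
class PpcReport:
    """Posterior predictive check curves and exceedance p-values."""

    go_rt_cdf: pd.DataFrame          # observed vs predicted CDF at deciles
    sr_rt_cdf: pd.DataFrame
    inhibition: pd.DataFrame         # per-SSD observed vs predicted P(inhibit)
    median_sr_rt: pd.DataFrame       # per-SSD observed vs predicted median SR-RT
    p_values: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        frames = []
        for name, df in (("go_rt_cdf", self.go_rt_cdf),
                         ("sr_rt_cdf", self.sr_rt_cdf),
                         ("inhibition", self.inhibition),
                         ("median_sr_rt", self.median_sr_rt)):
            d = df.copy()
            d.insert(0, "statistic", name)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


_DECILES = np.arange(0.1, 1.0, 0.1)


def _session_stats(df, ssd_bins):
    rt = df["rt_ms"].to_numpy(dtype=float)
    go = (df["trial_type"] == "go").to_numpy()
    stop = ~go
    responded = np.isfinite(rt)
    go_rts = rt[go & responded]
    sr_rts = rt[stop & responded]
    ssd = df["ssd_ms"].to_numpy(dtype=float)
    inh = np.full(len(ssd_bins), np.nan)
    med_sr = np.full(len(ssd_bins), np.nan)
    for i, s in enumerate(ssd_bins):
        m = stop & (ssd == s)
        if m.any():
            inh[i] = 1.0 - responded[m].mean()
            if (m & responded).any():
                med_sr[i] = np.median(rt[m & responded])
    go_q = np.quantile(go_rts, _DECILES) if len(go_rts) else \
        np.full(len(_DECILES), np.nan)
    sr_q = np.quantile(sr_rts, _DECILES) if len(sr_rts) else \
        np.full(len(_DECILES), np.nan)
    return go_q, sr_q, inh, med_sr


def posterior_predictive(draws: PosteriorDraws, data: pd.DataFrame,
                         design: TaskDesign = TaskDesign(),
                         subject: int = 0, n_draws: int = 100,
                         seed=None) -> PpcReport:
    """Simulate replicate sessions from posterior draws and compare curves.

    For each of ``n_draws`` posterior draws of the participant's parameters
    a replicate staircase session is simulated; the report aggregates go-RT
    and signal-respond-RT decile curves, the inhibition function over the
    observed SSD values, and median signal-respond RT by SSD.  The p-value
    per statistic is the fraction of replicates whose statistic exceeds the
    observed one (endpoints 0/1 reported exactly).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    rng = np.random.default_rng(seed)
    nat = draws.subject_draws(natural=True)[:, :, subject, :].reshape(-1, 7)
    idx = rng.choice(len(nat), size=min(n_draws, len(nat)), replace=False)

    stop_ssds = data.loc[data["trial_type"] == "stop", "ssd_ms"]
    ssd_bins = np.sort(stop_ssds.unique())
    obs_go_q, obs_sr_q, obs_inh, obs_med = _session_stats(data, ssd_bins)

    rep_go, rep_sr, rep_inh, rep_med = [], [], [], []
    for i in idx:
        ps = ParameterSet.from_vector(nat[i])
        rep = simulate_participant(ps, design, rng=rng)
        g, s, h, m = _session_stats(rep, ssd_bins)
        rep_go.append(g)
        rep_sr.append(s)
        rep_inh.append(h)
        rep_med.append(m)
    rep_go = np.stack(rep_go)
    rep_sr = np.stack(rep_sr)
    rep_inh = np.stack(rep_inh)
    rep_med = np.stack(rep_med)

    def frame(axis_name, axis, obs, rep):
        return pd.DataFrame({
            axis_name: axis, "observed": obs,
            "predicted": np.nanmean(rep, axis=0),
            "pred_low": np.nanpercentile(rep, 2.5, axis=0),
            "pred_high": np.nanpercentile(rep, 97.5, axis=0),
        })

    def exceed(obs_scalar, rep_scalars):
        rep_scalars = rep_scalars[np.isfinite(rep_scalars)]
        if not np.isfinite(obs_scalar) or len(rep_scalars) == 0:
            return float("nan")
        return float(np.mean(rep_scalars > obs_scalar))

    with np.errstate(invalid="ignore"):
        p_values = {
            "mean_go_rt": exceed(np.nanmean(obs_go_q),
                                 np.nanmean(rep_go, axis=1)),
            "mean_sr_rt": exceed(np.nanmean(obs_sr_q),
                                 np.nanmean(rep_sr, axis=1)),
            "mean_inhibition": exceed(np.nanmean(obs_inh),
                                      np.nanmean(rep_inh, axis=1)),
        }
        # Per-SSD inhibition-rate exceedance (the documented default).
        for i, s in enumerate(ssd_bins):
            p_values[f"inhibition@{s:g}"] = exceed(obs_inh[i], rep_inh[:, i])

    return PpcReport(
        go_rt_cdf=frame("decile", _DECILES, obs_go_q, rep_go),
        sr_rt_cdf=frame("decile", _DECILES, obs_sr_q, rep_sr),
        inhibition=frame("ssd_ms", ssd_bins, obs_inh, rep_inh),
        median_sr_rt=frame("ssd_ms", ssd_bins, obs_med, rep_med),
        p_values=p_values,
    )


def mix_posteriors(draws_list) -> PosteriorDraws:
    """Equal-weight concatenation of retained draws across refits.

    Used to pool a full-data fit with refits on SSD-subset data so that
    inference is robust to localized misfit; parameter spaces must match.
    """
    if not draws_list:
        raise ValueError("need at least one PosteriorDraws")
    first = draws_list[0]
    for d in draws_list[1:]:
        if d.subject.shape[0] != first.subject.shape[0] \
                or d.subject.shape[2:] != first.subject.shape[2:]:
            raise ValueError("parameter spaces / chain counts do not match")
        if (d.pop_loc is None) != (first.pop_loc is None):
            raise ValueError("cannot mix hierarchical with individual draws")
    subject = np.concatenate([d.subject for d in draws_list], axis=1)
    if first.pop_loc is not None:
        pop_loc = np.concatenate([d.pop_loc for d in draws_list], axis=1)
        pop_scale = np.concatenate([d.pop_scale for d in draws_list], axis=1)
    else:
        pop_loc = pop_scale = None
    return PosteriorDraws(subject=subject, pop_loc=pop_loc,
                          pop_scale=pop_scale, priors=first.priors)
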