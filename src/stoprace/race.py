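"""Ex-Gaussian race likelihood with trigger failures and upper censoring.

The horse-race model of the stop-signal task: on every trial a go runner
(finishing time ~ exGauss(mu_go, sigma_go, tau_go)) races, on stop trials,
against a stop runner (~ exGauss(mu_stop, sigma_stop, tau_stop)) launched
SSD ms later.  A response is emitted iff the go runner finishes before both
the stop runner (SSD + stop finishing time) and the response deadline.  With
probability ``p_tf`` (a trigger failure) the stop runner is never launched,
and the stop trial behaves like a go trial.

Observations slower than the deadline (default 1000 ms) are censored: the
likelihood of a go omission is the survivor mass beyond the deadline, and a
"successful stop" is simply the event that no response occurred before the
deadline.  Responses faster than the lower cutoff (default 200 ms,
anticipations) are removed before fitting and the likelihood is not
renormalised for this lower truncation.

The scalar functions here are the documented reference implementations
(adaptive quadrature); :func:`table_loglik` is the vectorised path used by
the MCMC sampler, which groups successful-stop trials by unique SSD and
integrates with fixed-node Gauss-Legendre quadrature.

All times are in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .exgauss import (
    exg_cdf,
    exg_logpdf,
    exg_logsf,
    exg_pdf,
    exg_sf,
)

__all__ = [
    "ExGaussParams",
    "ParameterSet",
    "CensoringRule",
    "RaceNumericalError",
    "loglik_go_response",
    "loglik_go_censored",
    "loglik_signal_respond",
    "loglik_successful_stop",
    "prob_respond_stop",
    "inhibition_function",
    "prepare_trials",
    "table_loglik",
    "BatchedTrialData",
    "batch_loglik",
    "PARAM_NAMES",
]

PARAM_NAMES = ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop", "p_tf")


class RaceNumericalError(RuntimeError):
    """Raised when quadrature fails to converge (never a silent NaN)."""


@dataclass(frozen=True)
class ExGaussParams:
    """Ex-Gaussian finishing-time parameters (ms)."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self):
        for name in ("mu", "sigma", "tau"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be strictly positive")

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def var(self) -> float:
        return self.sigma**2 + self.tau**2


@dataclass(frozen=True)
class ParameterSet:
    """One participant's race parameters: go runner, stop runner, P(TF)."""

    go: ExGaussParams
    stop: ExGaussParams
    p_tf: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.p_tf) or not 0.0 <= self.p_tf <= 1.0:
            raise ValueError(f"p_tf must lie in [0, 1], got {self.p_tf!r}")

    @property
    def mean_go_rt(self) -> float:
        """Mean of the go finishing-time distribution, mu_go + tau_go."""
        return self.go.mean

    @property
    def mean_ssrt(self) -> float:
        """Mean of the stop finishing-time distribution, mu_stop + tau_stop."""
        return self.stop.mean

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.go.mu, self.go.sigma, self.go.tau,
             self.stop.mu, self.stop.sigma, self.stop.tau, self.p_tf]
        )

    @classmethod
    def from_vector(cls, vec) -> "ParameterSet":
        vec = np.asarray(vec, dtype=float)
        return cls(
            go=ExGaussParams(vec[0], vec[1], vec[2]),
            stop=ExGaussParams(vec[3], vec[4], vec[5]),
            p_tf=float(vec[6]),
        )


@dataclass(frozen=True)
class CensoringRule:
    """Deadline censoring and lower anticipation cutoff (ms)."""

    deadline: float = 1000.0
    lower_cutoff: float = 200.0

    def __post_init__(self):
        if not self.lower_cutoff < self.deadline:
            raise ValueError("lower_cutoff must be below the deadline")


def _check_rt(rt, cens: CensoringRule):
    rt = float(rt)
    if not cens.lower_cutoff <= rt <= cens.deadline:
        raise ValueError(
            f"rt={rt} outside [{cens.lower_cutoff}, {cens.deadline}]; "
            "filter trials before evaluating the likelihood"
        )
    return rt


def loglik_go_response(rt, params: ParameterSet, cens: CensoringRule = CensoringRule()):
    """Log density of an observed go-trial response at ``rt``."""
    rt = _check_rt(rt, cens)
    g = params.go
    return float(exg_logpdf(rt, g.mu, g.sigma, g.tau))


def loglik_go_censored(params: ParameterSet, cens: CensoringRule = CensoringRule()):
    """Log mass of a censored go trial (omission / response past deadline)."""
    g = params.go
    return float(exg_logsf(cens.deadline, g.mu, g.sigma, g.tau))


def loglik_signal_respond(rt, ssd, params: ParameterSet,
                          cens: CensoringRule = CensoringRule()):
    """Log density of a failed-stop response at ``rt`` given the trial's SSD.

    Mixture over trigger state:
    ``p_tf * f_go(rt) + (1 - p_tf) * f_go(rt) * (1 - F_stop(rt - ssd))``.
    """
    rt = _check_rt(rt, cens)
    if ssd < 0:
        raise ValueError("ssd must be nonnegative")
    g, s, p = params.go, params.stop, params.p_tf
    lf_go = exg_logpdf(rt, g.mu, g.sigma, g.tau)
    lsf_stop = exg_logsf(rt - ssd, s.mu, s.sigma, s.tau)
    if p >= 1.0:
        return float(lf_go)
    if p <= 0.0:
        return float(lf_go + lsf_stop)
    return float(lf_go + np.logaddexp(np.log(p), np.log1p(-p) + lsf_stop))


def prob_respond_stop(ssd, params: ParameterSet,
                      cens: CensoringRule = CensoringRule(),
                      epsabs: float = 1e-10) -> float:
    """P(response emitted before the deadline | stop trial at ``ssd``).

    ``p_tf * F_go(D) + (1 - p_tf) * int_{-inf}^{D} f_go(t) (1 - F_stop(t - ssd)) dt``
    with the integral evaluated by adaptive (Gauss-Kronrod) quadrature.
    """
    if ssd < 0:
        raise ValueError("ssd must be nonnegative")
    g, s, p = params.go, params.stop, params.p_tf
    D = cens.deadline
    f_go_d = exg_cdf(D, g.mu, g.sigma, g.tau)
    if p >= 1.0:
        return float(f_go_d)

    def integrand(t):
        return exg_pdf(t, g.mu, g.sigma, g.tau) * exg_sf(
            t - ssd, s.mu, s.sigma, s.tau
        )

    lo = min(g.mu - 10.0 * g.sigma, ssd)
    # Beyond the go runner's upper tail the integrand is numerically zero;
    # capping keeps adaptive quadrature sharp when the deadline is remote.
    hi = min(D, g.mu + 10.0 * g.sigma + 60.0 * g.tau)
    if lo >= hi:
        integral = 0.0
    else:
        pts = [x for x in (ssd, ssd + s.mu) if lo < x < hi]
        integral, err = quad(integrand, lo, hi, points=pts or None,
                             epsabs=epsabs, limit=200)
        if not np.isfinite(integral) or err > max(1e-6, 1e-4 * abs(integral)):
            raise RaceNumericalError(
                f"successful-stop quadrature did not converge (err={err})"
            )
    return float(np.clip(p * f_go_d + (1.0 - p) * integral, 0.0, 1.0))


def loglik_successful_stop(ssd, params: ParameterSet,
                           cens: CensoringRule = CensoringRule()) -> float:
    """Log probability that no response occurs before the deadline."""
    p_inh = 1.0 - prob_respond_stop(ssd, params, cens)
    return float(np.log(max(p_inh, 1e-300)))


def inhibition_function(params: ParameterSet, ssd_grid,
                        cens: CensoringRule = CensoringRule()) -> np.ndarray:
    """P(successful stop | SSD) over a grid; nonincreasing in SSD."""
    ssd_grid = np.asarray(ssd_grid, dtype=float)
    if ssd_grid.size == 0:
        raise ValueError("ssd_grid must be nonempty")
    return np.array(
        [1.0 - prob_respond_stop(s, params, cens) for s in ssd_grid]
    )


# ---------------------------------------------------------------------------
# Vectorised sampler path
# ---------------------------------------------------------------------------

@dataclass
class TrialData:
    """Preprocessed per-participant data for fast likelihood evaluation."""

    go_rts: np.ndarray          # analyzable go RTs in [lower, deadline]
    n_go_censored: int          # go omissions + responses past deadline
    sr_rts: np.ndarray          # signal-respond RTs
    sr_ssds: np.ndarray         # their SSDs
    inh_ssds: np.ndarray        # unique SSDs of successful-stop trials
    inh_counts: np.ndarray      # counts per unique SSD
    cens: CensoringRule = field(default_factory=CensoringRule)

    @property
    def n_go(self) -> int:
        return len(self.go_rts) + self.n_go_censored

    @property
    def n_stop(self) -> int:
        return len(self.sr_rts) + int(self.inh_counts.sum())


def prepare_trials(df, cens: CensoringRule = CensoringRule()) -> TrialData:
    """Build :class:`TrialData` from a trial table (see :mod:`stoprace.simulate`).

    Applies the fitting filter: responses faster than the lower cutoff are
    dropped (their trials excluded entirely), incorrect responses dropped,
    and responses past the deadline treated as censored.
    """
    is_go = df["trial_type"].to_numpy() == "go"
    rt = df["rt_ms"].to_numpy(dtype=float)
    responded = np.isfinite(rt)
    correct = df["correct"].to_numpy() if "correct" in df else np.ones(len(df), bool)
    # Trials excluded outright: anticipations and wrong-key responses.
    excluded = responded & ((rt < cens.lower_cutoff) | ~correct)

    go_resp = is_go & responded & ~excluded & (rt <= cens.deadline)
    go_cens = is_go & ~excluded & (~responded | (responded & (rt > cens.deadline)))
    sr = ~is_go & responded & ~excluded & (rt <= cens.deadline)
    inh = ~is_go & ~excluded & (~responded | (responded & (rt > cens.deadline)))

    ssd = df["ssd_ms"].to_numpy(dtype=float)
    uniq, counts = np.unique(ssd[inh], return_counts=True)
    return TrialData(
        go_rts=rt[go_resp].copy(),
        n_go_censored=int(np.count_nonzero(go_cens)),
        sr_rts=rt[sr].copy(),
        sr_ssds=ssd[sr].copy(),
        inh_ssds=uniq,
        inh_counts=counts,
        cens=cens,
    )


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _succ_stop_integral(mu_g, sd_g, tau_g, mu_s, sd_s, tau_s, ssds, D):
    """``int_{-inf}^{D} f_go(t) (1 - F_stop(t - ssd)) dt``, broadcast.

    Parameters have shape (...); ``ssds`` has shape (..., U); returns
    (..., U).  The stop survival is ~1 below ``ssd + mu_stop - 8 sigma'``
    and ~0 above ``ssd + mu_stop + 8 sigma_stop + 15 tau_stop``, so that
    stretch is integrated exactly through the go CDF and fixed-node
    Gauss-Legendre quadrature only spans the transition region, keeping the
    rule accurate for arbitrarily small stop-runner scales.
    """
    lo = (mu_g - 10.0 * sd_g)[..., None]
    hi = np.minimum(D, mu_g + 10.0 * sd_g + 60.0 * tau_g)[..., None]
    hi = np.maximum(hi, lo + 1e-9)
    width = (sd_s + tau_s)[..., None]
    a = np.clip(ssds + (mu_s - sd_s)[..., None] - 8.0 * width, lo, hi)
    b = np.clip(ssds + mu_s[..., None] + 8.0 * sd_s[..., None]
                + 15.0 * tau_s[..., None], a, hi)
    # Exact go mass where the stop runner essentially always wins.
    head = exg_cdf(a, mu_g[..., None], sd_g[..., None], tau_g[..., None]) \
        - exg_cdf(lo, mu_g[..., None], sd_g[..., None], tau_g[..., None])
    half = 0.5 * (b - a)
    nodes = 0.5 * (b + a)[..., None] + half[..., None] * _GL_NODES
    f_go = np.exp(exg_logpdf(nodes, mu_g[..., None, None],
                             sd_g[..., None, None], tau_g[..., None, None]))
    sf_stop = exg_sf(nodes - ssds[..., None], mu_s[..., None, None],
                     sd_s[..., None, None], tau_s[..., None, None])
    tail = half * ((f_go * sf_stop) @ _GL_WEIGHTS)
    return head + tail


class BatchedTrialData:
    """Several participants' :class:`TrialData` padded into shared arrays.

    Lets the sampler evaluate all participants' likelihoods in one set of
    broadcast operations: padding entries carry zero weight.
    """

    def __init__(self, datasets: list[TrialData]):
        if not datasets:
            raise ValueError("need at least one TrialData")
        cens = datasets[0].cens
        if any(d.cens != cens for d in datasets):
            raise ValueError("all participants must share one censoring rule")
        self.cens = cens
        self.n_subjects = len(datasets)

        def pad(arrs, fill):
            width = max((len(a) for a in arrs), default=0)
            out = np.full((len(arrs), max(width, 1)), fill, dtype=float)
            mask = np.zeros_like(out, dtype=bool)
            for i, a in enumerate(arrs):
                out[i, :len(a)] = a
                mask[i, :len(a)] = True
            return out, mask

        self.go_rts, self.go_mask = pad([d.go_rts for d in datasets], 500.0)
        self.n_go_cens = np.array([d.n_go_censored for d in datasets], float)
        self.sr_rts, self.sr_mask = pad([d.sr_rts for d in datasets], 500.0)
        self.sr_ssds, _ = pad([d.sr_ssds for d in datasets], 0.0)
        self.inh_ssds, _ = pad([d.inh_ssds for d in datasets], 0.0)
        counts, _ = pad([d.inh_counts for d in datasets], 0.0)
        self.inh_counts = counts


def batch_loglik(theta, batch: BatchedTrialData) -> np.ndarray:
    """Vectorised log likelihood for a group: theta (C, S, 7) -> (C, S)."""
    th = np.asarray(theta, dtype=float)
    if th.ndim != 3 or th.shape[1] != batch.n_subjects or th.shape[2] != 7:
        raise ValueError("theta must have shape (chains, n_subjects, 7)")
    mu_g, sd_g, tau_g = th[..., 0], th[..., 1], th[..., 2]
    mu_s, sd_s, tau_s = th[..., 3], th[..., 4], th[..., 5]
    p_tf = th[..., 6]
    valid = (
        np.isfinite(th).all(axis=-1)
        & (sd_g > 0) & (tau_g > 0) & (sd_s > 0) & (tau_s > 0)
        & (p_tf >= 0) & (p_tf <= 1)
    )
    safe = lambda x, fill: np.where(valid, x, fill)
    mu_g, sd_g, tau_g = safe(mu_g, 500.0), safe(sd_g, 50.0), safe(tau_g, 50.0)
    mu_s, sd_s, tau_s = safe(mu_s, 200.0), safe(sd_s, 30.0), safe(tau_s, 30.0)
    p_tf = np.clip(safe(p_tf, 0.0), 0.0, 1.0)

    D = batch.cens.deadline
    ll = np.zeros(th.shape[:2])

    lp_go = exg_logpdf(batch.go_rts, mu_g[..., None], sd_g[..., None],
                       tau_g[..., None])
    ll += np.where(batch.go_mask, lp_go, 0.0).sum(axis=-1)
    ll += batch.n_go_cens * exg_logsf(D, mu_g, sd_g, tau_g)

    if batch.sr_mask.any():
        lf_go = exg_logpdf(batch.sr_rts, mu_g[..., None], sd_g[..., None],
                           tau_g[..., None])
        lsf_stop = exg_logsf(batch.sr_rts - batch.sr_ssds,
                             mu_s[..., None], sd_s[..., None],
                             tau_s[..., None])
        p = np.clip(p_tf[..., None], 0.0, 1.0 - 1e-16)
        with np.errstate(divide="ignore"):
            mix = np.logaddexp(np.log(np.clip(p, 1e-300, None)),
                               np.log1p(-p) + lsf_stop)
            mix = np.where(p > 0, mix, lsf_stop)
        ll += np.where(batch.sr_mask, lf_go + mix, 0.0).sum(axis=-1)

    if batch.inh_counts.any():
        f_go_d = exg_cdf(D, mu_g, sd_g, tau_g)
        integral = _succ_stop_integral(mu_g, sd_g, tau_g, mu_s, sd_s, tau_s,
                                       batch.inh_ssds[None, :, :], D)
        p_resp = p_tf[..., None] * f_go_d[..., None] \
            + (1.0 - p_tf[..., None]) * integral
        p_inh = np.clip(1.0 - p_resp, 1e-300, 1.0)
        ll += (batch.inh_counts * np.log(p_inh)).sum(axis=-1)

    return np.where(valid, ll, -np.inf)


def table_loglik(theta, data: TrialData) -> np.ndarray:
    """Race-model log likelihood of a trial table, broadcast over parameters.

    ``theta`` has shape (..., 7) ordered as :data:`PARAM_NAMES` with ``p_tf``
    on the probability scale.  Returns shape (...).  Invalid parameter rows
    (nonpositive sigma/tau, p_tf outside [0, 1]) get ``-inf``.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 1
    th = np.atleast_2d(theta)
    lead = th.shape[:-1]
    mu_g, sd_g, tau_g = th[..., 0], th[..., 1], th[..., 2]
    mu_s, sd_s, tau_s = th[..., 3], th[..., 4], th[..., 5]
    p_tf = th[..., 6]

    valid = (
        np.isfinite(th).all(axis=-1)
        & (sd_g > 0) & (tau_g > 0) & (sd_s > 0) & (tau_s > 0)
        & (p_tf >= 0) & (p_tf <= 1)
    )
    # Substitute a safe dummy for invalid rows; masked to -inf at the end.
    safe = lambda x, fill: np.where(valid, x, fill)
    mu_g, sd_g, tau_g = safe(mu_g, 500.0), safe(sd_g, 50.0), safe(tau_g, 50.0)
    mu_s, sd_s, tau_s = safe(mu_s, 200.0), safe(sd_s, 30.0), safe(tau_s, 30.0)
    p_tf = np.clip(safe(p_tf, 0.0), 0.0, 1.0)

    D = data.cens.deadline
    ll = np.zeros(lead)

    # Go responses.
    if len(data.go_rts):
        ll += exg_logpdf(
            data.go_rts, mu_g[..., None], sd_g[..., None], tau_g[..., None]
        ).sum(axis=-1)
    # Censored go trials.
    if data.n_go_censored:
        ll += data.n_go_censored * exg_logsf(D, mu_g, sd_g, tau_g)

    # Signal-respond RTs: f_go(rt) * [p_tf + (1-p_tf) * (1 - F_stop(rt-ssd))].
    if len(data.sr_rts):
        lf_go = exg_logpdf(
            data.sr_rts, mu_g[..., None], sd_g[..., None], tau_g[..., None]
        )
        lsf_stop = exg_logsf(
            data.sr_rts - data.sr_ssds,
            mu_s[..., None], sd_s[..., None], tau_s[..., None],
        )
        p = p_tf[..., None]
        with np.errstate(divide="ignore"):
            mix = np.logaddexp(
                np.where(p > 0, np.log(np.clip(p, 1e-300, None)), -np.inf),
                np.log1p(-np.clip(p, None, 1.0 - 1e-16)) + lsf_stop,
            )
        ll += (lf_go + mix).sum(axis=-1)

    # Successful stops, grouped by unique SSD.
    if len(data.inh_ssds):
        f_go_d = exg_cdf(D, mu_g, sd_g, tau_g)
        ssds = np.broadcast_to(data.inh_ssds, lead + data.inh_ssds.shape)
        integral = _succ_stop_integral(mu_g, sd_g, tau_g, mu_s, sd_s, tau_s,
                                       ssds, D)
        p_resp = p_tf[..., None] * f_go_d[..., None] + (1.0 - p_tf[..., None]) * integral
        p_inh = np.clip(1.0 - p_resp, 1e-300, 1.0)
        ll += (data.inh_counts * np.log(p_inh)).sum(axis=-1)

    ll = np.where(valid, ll, -np.inf)
    return ll[()] if not scalar else float(ll[0])
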