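"""Hierarchical Bayesian estimation of the race model by DE-MCMC.

Differential-Evolution MCMC runs an ensemble of chains; each proposal moves
a chain along the difference of two other randomly chosen chains' states
(scaled by ``gamma = 2.38 / sqrt(2 d)`` with a small uniform jitter), which
self-tunes the proposal to the posterior's scale and correlation.  During
burn-in, occasional migration steps cycle states between a random subset of
chains to free stuck ones; afterwards only crossover steps are performed.

Model structure
---------------
Each participant has seven parameters (``mu_go, sigma_go, tau_go, mu_stop,
sigma_stop, tau_stop, p_tf``); ``p_tf`` is sampled on the probit (z) scale
so it is unconstrained, and every other parameter lives inside truncation
bounds.  Participant-level parameters follow truncated-normal population
distributions parameterised by location and scale; locations and scales
carry truncated-normal hyperpriors.  The default chain count is three times
the participant parameter count (3 x 7 = 21) and retained draws are thinned
(every 15th by default) to reduce autocorrelation.

Updates alternate participant-level blocks (conditional on the population
parameters) and the population block (conditional on all participants).
Everything is vectorised across chains, and across participants where
possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from .race import PARAM_NAMES, BatchedTrialData, CensoringRule, \
    ParameterSet, TrialData, batch_loglik, prepare_trials, table_loglik

__all__ = [
    "TruncNormPrior",
    "HierPriors",
    "SamplerConfig",
    "PosteriorDraws",
    "fit_individual",
    "fit_hierarchical",
    "gelman_rubin",
    "rhat",
    "rhat_multivariate",
    "truncnorm_mean_sd",
    "probit_population_mean",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _norm_logpdf(x):
    return -0.5 * x * x - np.log(_SQRT_2PI)


@dataclass(frozen=True)
class TruncNormPrior:
    """Truncated normal prior TN(mean, sd) on (lower, upper)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")
        if self.lower >= self.upper:
            raise ValueError("prior bounds must be ordered")

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        z = (x - self.mean) / self.sd
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        log_z = np.log(ndtr(b) - ndtr(a))
        out = _norm_logpdf(z) - np.log(self.sd) - log_z
        return np.where((x >= self.lower) & (x <= self.upper), out, -np.inf)

    def rvs(self, size, rng):
        from scipy.stats import truncnorm as _tn

        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return _tn.rvs(a, b, loc=self.mean, scale=self.sd, size=size,
                       random_state=rng)


def _default_loc_priors():
    # Location supports coincide with the participant-level truncation
    # bounds: a location below the participants' lower bound would turn the
    # truncated-normal population into an unnormalisable boundary spike.
    ms_mu = TruncNormPrior(500.0, 1000.0, 0.0, 2000.0)
    ms_sd = TruncNormPrior(100.0, 1000.0, 1.0, 1000.0)
    return (ms_mu, ms_sd, ms_sd, ms_mu, ms_sd, ms_sd,
            TruncNormPrior(-1.5, 1.0, -6.0, 6.0))


def _default_scale_priors():
    # Scales are bounded away from zero: for weakly identified parameters
    # (notably sigma_stop at realistic trial counts) a scale prior reaching
    # 0 creates the hierarchical funnel's infinite coalescence spike.
    sc = TruncNormPrior(100.0, 1000.0, 1.0, 1000.0)
    return (sc, sc, sc, sc, sc, sc, TruncNormPrior(0.5, 1.0, 0.01, 3.0))


@dataclass(frozen=True)
class HierPriors:
    """Hyperpriors and participant-level truncation bounds.

    Defaults are weakly informative and cover a wide but realistic range of
    reaction-time parameters (ms; the trigger-failure entries operate on the
    probit scale).  Every setting is exposed so alternative priors can be
    dropped in.
    """

    loc: tuple = field(default_factory=_default_loc_priors)
    scale: tuple = field(default_factory=_default_scale_priors)
    subject_lower: np.ndarray = field(default_factory=lambda: np.array(
        [0.0, 1.0, 1.0, 0.0, 1.0, 1.0, -6.0]))
    subject_upper: np.ndarray = field(default_factory=lambda: np.array(
        [2000.0, 1000.0, 1000.0, 2000.0, 1000.0, 1000.0, 6.0]))

    def __post_init__(self):
        object.__setattr__(self, "subject_lower",
                           np.asarray(self.subject_lower, dtype=float))
        object.__setattr__(self, "subject_upper",
                           np.asarray(self.subject_upper, dtype=float))
        if len(self.loc) != 7 or len(self.scale) != 7:
            raise ValueError("need 7 location and 7 scale priors")


@dataclass(frozen=True)
class SamplerConfig:
    """DE-MCMC settings; defaults follow the standard tuning for this model."""

    n_chains: int = 21
    burn_in: int = 1000
    n_keep: int = 500
    thin: int = 15
    migration_prob: float = 0.05
    gamma: float | None = None     # default 2.38 / sqrt(2 d)
    jitter: float = 1e-3           # uniform jitter, scaled per-dimension
    pop_passes: int = 3            # population-block passes per sweep
    subject_passes: int = 2        # participant-block passes per sweep

    def __post_init__(self):
        if self.n_chains < 4:
            raise ValueError("DE-MCMC needs at least 4 chains")
        if min(self.burn_in, self.n_keep, self.thin, self.pop_passes) < 1:
            raise ValueError("burn_in, n_keep, thin, pop_passes must be positive")
        if not 0.0 <= self.migration_prob <= 1.0:
            raise ValueError("migration_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# Truncated-normal moment transforms (location/scale -> mean/SD)
# ---------------------------------------------------------------------------

def truncnorm_mean_sd(loc, scale, lower, upper):
    """Mean and SD of TN(loc, scale) truncated to (lower, upper)."""
    from scipy.stats import truncnorm as _tn

    loc = np.asarray(loc, dtype=float)
    scale = np.asarray(scale, dtype=float)
    a = (lower - loc) / scale
    b = (upper - loc) / scale
    mean, var = _tn.stats(a, b, loc=loc, scale=scale, moments="mv")
    return np.asarray(mean, dtype=float), np.sqrt(
        np.clip(np.asarray(var, dtype=float), 0.0, None))


def probit_population_mean(loc_z, scale_z):
    """Population mean of p_tf when probit(p_tf) ~ N(loc_z, scale_z**2).

    E[Phi(Z)] = Phi(loc / sqrt(1 + scale**2)) — exact for the untruncated
    normal; the (-6, 6) truncation changes it negligibly.
    """
    loc_z = np.asarray(loc_z, dtype=float)
    scale_z = np.asarray(scale_z, dtype=float)
    return ndtr(loc_z / np.sqrt(1.0 + scale_z**2))


# ---------------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Thinned retained draws, indexed (chain, iteration[, participant]).

    Arrays are stored on the sampling scale (``p_tf`` as probit z); accessors
    back-transform.  ``pop_loc``/``pop_scale`` are None for individual fits.
    """

    subject: np.ndarray                 # (C, K, S, 7)
    pop_loc: np.ndarray | None = None   # (C, K, 7)
    pop_scale: np.ndarray | None = None
    priors: HierPriors = field(default_factory=HierPriors)

    @property
    def n_chains(self):
        return self.subject.shape[0]

    @property
    def n_draws(self):
        return self.subject.shape[1]

    @property
    def n_subjects(self):
        return self.subject.shape[2]

    def subject_draws(self, natural: bool = True) -> np.ndarray:
        """(C, K, S, 7) participant draws; probit backtransformed if natural."""
        out = self.subject.copy()
        if natural:
            out[..., 6] = ndtr(out[..., 6])
        return out

    def population_means(self) -> dict[str, np.ndarray] | None:
        """Per-draw population *means* (chain-collapsed), on natural scales.

        Truncated-normal locations are transformed to distribution means;
        the probit-scale trigger-failure parameters to the population mean
        of p_tf.
        """
        if self.pop_loc is None:
            return None
        out = {}
        for j, name in enumerate(PARAM_NAMES):
            loc = self.pop_loc[..., j].reshape(-1)
            sc = self.pop_scale[..., j].reshape(-1)
            if name == "p_tf":
                out[name] = probit_population_mean(loc, sc)
            else:
                lo = self.priors.subject_lower[j]
                hi = self.priors.subject_upper[j]
                out[name], _ = truncnorm_mean_sd(loc, sc, lo, hi)
        return out

    def subject_posterior_means(self) -> np.ndarray:
        """(S, 7) posterior means of participant parameters (natural scale)."""
        nat = self.subject_draws(natural=True)
        return nat.mean(axis=(0, 1))

    def subject_parameter_sets(self) -> list[ParameterSet]:
        return [ParameterSet.from_vector(v) for v in self.subject_posterior_means()]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws (chain, iteration, level, subject, parameter)."""
        rows = []
        C, K, S, _ = self.subject.shape
        chain_idx = np.repeat(np.arange(C), K)
        iter_idx = np.tile(np.arange(K), C)
        nat = self.subject_draws(natural=True)
        for s in range(S):
            for j, name in enumerate(PARAM_NAMES):
                rows.append(pd.DataFrame({
                    "chain": chain_idx, "iteration": iter_idx,
                    "level": "subject", "subject": s, "parameter": name,
                    "value": nat[:, :, s, j].reshape(-1),
                }))
        if self.pop_loc is not None:
            for j, name in enumerate(PARAM_NAMES):
                for arr, lev in ((self.pop_loc, "pop_loc"),
                                 (self.pop_scale, "pop_scale")):
                    rows.append(pd.DataFrame({
                        "chain": chain_idx, "iteration": iter_idx,
                        "level": lev, "subject": -1, "parameter": name,
                        "value": arr[:, :, j].reshape(-1),
                    }))
        return pd.concat(rows, ignore_index=True)

    def rhat(self) -> dict[str, float]:
        """Gelman-Rubin PSRF per parameter (population level if present)."""
        out = {}
        if self.pop_loc is not None:
            for j, name in enumerate(PARAM_NAMES):
                out[f"loc_{name}"] = gelman_rubin(self.pop_loc[:, :, j])
                out[f"scale_{name}"] = gelman_rubin(self.pop_scale[:, :, j])
        else:
            for s in range(self.n_subjects):
                for j, name in enumerate(PARAM_NAMES):
                    key = name if self.n_subjects == 1 else f"{name}[{s}]"
                    out[key] = gelman_rubin(self.subject[:, :, s, j])
        return out

    def converged(self, threshold: float = 1.1) -> bool:
        return all(v < threshold for v in self.rhat().values())


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(draws: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``draws`` has shape (chains, iterations).  R-hat close to 1 indicates
    the between-chain variance matches the within-chain variance; values
    above ~1.1 flag non-convergence.  Degenerate zero-variance input
    returns a large finite guard value rather than inf/NaN.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("draws must be (chains, iterations)")
    m, n = x.shape
    if m < 2:
        raise ValueError("R-hat needs at least 2 chains")
    if n < 2:
        raise ValueError("R-hat needs at least 2 iterations per chain")
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0.0:
        return 1.0 if b <= 0.0 else 1e6
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def rhat(draws: "PosteriorDraws | np.ndarray"):
    """PSRF of a draws container (dict) or of a (chains, iterations) array."""
    if isinstance(draws, PosteriorDraws):
        return draws.rhat()
    return gelman_rubin(np.asarray(draws))


def rhat_multivariate(draws: np.ndarray) -> float:
    """Brooks-Gelman multivariate PSRF for draws shaped (chains, iters, dim)."""
    x = np.asarray(draws, dtype=float)
    if x.ndim != 3:
        raise ValueError("draws must be (chains, iterations, dim)")
    m, n, d = x.shape
    chain_means = x.mean(axis=1)
    w = np.zeros((d, d))
    for c in range(m):
        w += np.cov(x[c].T, ddof=1)
    w /= m
    b_over_n = np.cov(chain_means.T, ddof=1)
    try:
        lam = np.max(np.real(np.linalg.eigvals(np.linalg.solve(w, b_over_n))))
    except np.linalg.LinAlgError:
        return float("nan")
    return float(np.sqrt((n - 1) / n + (m + 1) / m * lam))


# ---------------------------------------------------------------------------
# Internal DE-MCMC machinery
# ---------------------------------------------------------------------------

def _de_partners(n_chains, shape, rng):
    """Index arrays (r1, r2) of two distinct partner chains per walker."""
    c = np.broadcast_to(np.arange(n_chains).reshape(
        (n_chains,) + (1,) * (len(shape) - 1)), shape)
    r1 = rng.integers(0, n_chains - 1, size=shape)
    r1 = np.where(r1 >= c, r1 + 1, r1)
    r2 = rng.integers(0, n_chains - 2, size=shape)
    r2 = np.where(r2 >= np.minimum(c, r1), r2 + 1, r2)
    r2 = np.where(r2 >= np.maximum(c, r1), r2 + 1, r2)
    return r1, r2


def _subject_logprior(theta, phi, psi, priors: HierPriors):
    """log p(theta | phi, psi): sum of TN densities over the 7 parameters.

    theta: (..., S, 7); phi, psi: (..., 7) broadcast over subjects.
    """
    lo = priors.subject_lower
    hi = priors.subject_upper
    phi_e = phi[..., None, :]
    psi_e = np.clip(psi[..., None, :], 1e-12, None)
    z = (theta - phi_e) / psi_e
    a = (lo - phi_e) / psi_e
    b = (hi - phi_e) / psi_e
    log_norm = np.log(np.clip(ndtr(b) - ndtr(a), 1e-300, None))
    lp = _norm_logpdf(z) - np.log(psi_e) - log_norm
    inside = (theta >= lo) & (theta <= hi)
    lp = np.where(inside, lp, -np.inf)
    return lp.sum(axis=-1)


def _pop_logprior(phi, psi, priors: HierPriors):
    """Hyperprior over (phi, psi): (..., 7) each -> (...)."""
    out = np.zeros(phi.shape[:-1])
    for j in range(7):
        out = out + priors.loc[j].logpdf(phi[..., j])
        out = out + priors.scale[j].logpdf(psi[..., j])
    return out


def _moment_start(data: TrialData, priors: HierPriors) -> np.ndarray:
    """Moments-based heuristic start vector (sampling scale)."""
    rts = data.go_rts
    if len(rts) >= 10:
        m, sd = float(np.mean(rts)), float(np.std(rts, ddof=1))
        skew = float(np.clip(
            np.mean(((rts - m) / max(sd, 1e-9)) ** 3), 0.05, 1.8))
        tau = max(sd * (skew / 2.0) ** (1.0 / 3.0), 10.0)
        sigma = max(np.sqrt(max(sd**2 - tau**2, 100.0)), 10.0)
        mu = max(m - tau, 50.0)
    else:
        mu, sigma, tau = 500.0, 80.0, 80.0
    start = np.array([mu, sigma, tau, 200.0, 40.0, 50.0, ndtri(0.05)])
    return np.clip(start, priors.subject_lower + 1e-3,
                   priors.subject_upper - 1e-3)


def _record_acceptance(acc, proposed, label, min_rate=0.01):
    rate = acc / max(proposed, 1)
    bad = np.where(rate < min_rate)[0]
    if len(bad):
        warnings.warn(
            f"{label}: chains {bad.tolist()} accepted <1% of proposals; "
            "they may be stuck"
        )
    return rate


def fit_hierarchical(tables, priors: HierPriors | None = None,
                     config: SamplerConfig = SamplerConfig(),
                     cens: CensoringRule = CensoringRule(),
                     seed=None, start: str | np.ndarray = "moments",
                     progress: bool = False) -> PosteriorDraws:
    """Fit the hierarchical race model to a group of trial tables.

    Parameters
    ----------
    tables : list of DataFrame or TrialData
        One trial table per participant (>= 4 recommended).
    start : "moments", "individual", or (S, 7) array
        Chain initialisation.  "individual" runs short non-hierarchical fits
        per participant and starts from their posterior means.
    """
    if priors is None:
        priors = HierPriors()
    datasets = [t if isinstance(t, TrialData) else prepare_trials(t, cens)
                for t in tables]
    S = len(datasets)
    if S < 2:
        raise ValueError("hierarchical fit needs at least 2 participants")
    if S < 4:
        warnings.warn("fewer than 4 participants; population fit is weak")

    C = config.n_chains
    rng = np.random.default_rng(seed)

    if isinstance(start, str) and start == "individual":
        quick = replace(config, burn_in=max(100, config.burn_in // 5),
                        n_keep=100, thin=2)
        start_mat = np.stack([
            fit_individual(d, priors=priors, config=quick,
                           seed=rng.integers(2**31)).subject[:, :, 0, :]
            .reshape(-1, 7).mean(axis=0)
            for d in datasets
        ])
    elif isinstance(start, str) and start == "moments":
        start_mat = np.stack([_moment_start(d, priors) for d in datasets])
    else:
        start_mat = np.asarray(start, dtype=float)
        if start_mat.shape != (S, 7):
            raise ValueError("start array must have shape (n_subjects, 7)")

    span = priors.subject_upper - priors.subject_lower
    theta = start_mat[None, :, :] + 0.05 * span * rng.standard_normal((C, S, 7))
    theta = np.clip(theta, priors.subject_lower + 1e-6,
                    priors.subject_upper - 1e-6)
    phi = theta.mean(axis=1) + 0.02 * span * rng.standard_normal((C, 7))
    phi = np.clip(phi, priors.subject_lower + 1e-6,
                  priors.subject_upper - 1e-6)
    psi = np.abs(theta.std(axis=1)) + 0.02 * span
    psi = np.clip(psi, 1e-3, np.array([s.upper for s in priors.scale]) - 1e-6)

    gamma_s = config.gamma or 2.38 / np.sqrt(2 * 7)
    gamma_p = config.gamma or 2.38 / np.sqrt(2 * 2)  # 2-dim population blocks
    jit = config.jitter * span

    batch = BatchedTrialData(datasets)

    def data_loglik(th):
        # th: (C, S, 7) sampling scale -> (C, S)
        nat = th.copy()
        nat[..., 6] = ndtr(nat[..., 6])
        return batch_loglik(nat, batch)

    ll = data_loglik(theta)
    lp_th = _subject_logprior(theta, phi, psi, priors)
    lp_pop = _pop_logprior(phi, psi, priors)

    n_sweeps = config.burn_in + config.n_keep * config.thin
    keep_sub = np.empty((C, config.n_keep, S, 7))
    keep_loc = np.empty((C, config.n_keep, 7))
    keep_scale = np.empty((C, config.n_keep, 7))
    k_out = 0
    acc_sub = np.zeros(C)
    n_sub_prop = 0

    iterator = range(n_sweeps)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="DE-MCMC")

    for sweep in iterator:
        # --- participant blocks (vectorised over chains and subjects) ---
        for _ in range(config.subject_passes):
            r1, r2 = _de_partners(C, (C, S), rng)
            prop = theta + gamma_s * (theta[r1, np.arange(S)] -
                                      theta[r2, np.arange(S)]) \
                + rng.uniform(-1, 1, size=(C, S, 7)) * jit
            lp_prop = _subject_logprior(prop, phi, psi, priors)
            feasible = np.isfinite(lp_prop)
            # evaluate the data loglik only where the prior admits the proposal
            ll_prop = data_loglik(np.where(feasible[..., None], prop, theta))
            log_alpha = (ll_prop + lp_prop) - (ll + lp_th)
            accept = np.log(rng.random((C, S))) < log_alpha
            accept &= feasible
            theta = np.where(accept[..., None], prop, theta)
            ll = np.where(accept, ll_prop, ll)
            lp_th = np.where(accept, lp_prop, lp_th)
            acc_sub += accept.mean(axis=1)
            n_sub_prop += 1

        # --- population blocks: per-parameter (location, scale) pairs.
        # The conditional posterior of (phi_j, psi_j) given the participant
        # draws factorises across j, so small 2-dim DE moves mix much better
        # than one joint 14-dim move; several passes per sweep cost little
        # next to the data likelihood and speed up scale mixing.
        for j in np.concatenate([rng.permutation(7)
                                 for _ in range(config.pop_passes)]):
            r1p, r2p = _de_partners(C, (C,), rng)
            phi_p = phi.copy()
            psi_p = psi.copy()
            phi_p[:, j] = phi[:, j] + gamma_p * (phi[r1p, j] - phi[r2p, j]) \
                + rng.uniform(-1, 1, C) * jit[j]
            psi_p[:, j] = psi[:, j] + gamma_p * (psi[r1p, j] - psi[r2p, j]) \
                + rng.uniform(-1, 1, C) * jit[j]
            lp_pop_p = _pop_logprior(phi_p, psi_p, priors)
            ok = np.isfinite(lp_pop_p) & (psi_p[:, j] > 0)
            lp_th_p = _subject_logprior(
                theta, np.where(ok[:, None], phi_p, phi),
                np.where(ok[:, None], psi_p, psi), priors)
            log_alpha = (lp_th_p.sum(axis=1) + lp_pop_p) - \
                (lp_th.sum(axis=1) + lp_pop)
            accept_p = (np.log(rng.random(C)) < log_alpha) & ok
            phi = np.where(accept_p[:, None], phi_p, phi)
            psi = np.where(accept_p[:, None], psi_p, psi)
            lp_th = np.where(accept_p[:, None], lp_th_p, lp_th)
            lp_pop = np.where(accept_p, lp_pop_p, lp_pop)

        # --- migration (burn-in only) ---
        if sweep < config.burn_in and rng.random() < config.migration_prob:
            k = int(rng.integers(2, C + 1))
            sel = rng.choice(C, size=k, replace=False)
            total = ll.sum(axis=1) + lp_th.sum(axis=1) + lp_pop
            snap = (theta.copy(), phi.copy(), psi.copy(), ll.copy(),
                    lp_th.copy(), lp_pop.copy(), total.copy())
            for i in range(k):
                src, dst = sel[i - 1], sel[i]
                if np.log(rng.random()) < snap[6][src] - total[dst]:
                    theta[dst] = snap[0][src]
                    phi[dst] = snap[1][src]
                    psi[dst] = snap[2][src]
                    ll[dst] = snap[3][src]
                    lp_th[dst] = snap[4][src]
                    lp_pop[dst] = snap[5][src]
                    total[dst] = snap[6][src]

        if sweep >= config.burn_in and \
                (sweep - config.burn_in + 1) % config.thin == 0:
            keep_sub[:, k_out] = theta
            keep_loc[:, k_out] = phi
            keep_scale[:, k_out] = psi
            k_out += 1

    _record_acceptance(acc_sub, n_sub_prop, "participant block")
    return PosteriorDraws(subject=keep_sub[:, :k_out],
                          pop_loc=keep_loc[:, :k_out],
                          pop_scale=keep_scale[:, :k_out], priors=priors)


def fit_individual(trials, priors: HierPriors | None = None,
                   config: SamplerConfig = SamplerConfig(),
                   cens: CensoringRule = CensoringRule(),
                   seed=None) -> PosteriorDraws:
    """Non-hierarchical Bayesian fit of a single participant.

    The location hyperpriors double as fixed parameter priors.  Posterior
    means serve as start values for the hierarchical routine.
    """
    if priors is None:
        priors = HierPriors()
    data = trials if isinstance(trials, TrialData) else prepare_trials(trials, cens)
    if data.n_go < 50 or data.n_stop < 20:
        warnings.warn(
            f"few trials (go={data.n_go}, stop={data.n_stop}); "
            "posterior will be diffuse"
        )
    if data.n_stop > 0:
        n_inh = int(data.inh_counts.sum())
        if n_inh == 0 or n_inh == data.n_stop:
            warnings.warn(
                "all-respond or all-inhibit stop data; p_tf weakly identified"
            )

    C = config.n_chains
    rng = np.random.default_rng(seed)
    span = priors.subject_upper - priors.subject_lower
    start = _moment_start(data, priors)
    theta = start[None, :] + 0.05 * span * rng.standard_normal((C, 7))
    theta = np.clip(theta, priors.subject_lower + 1e-6,
                    priors.subject_upper - 1e-6)

    def logprior(th):
        out = np.zeros(th.shape[:-1])
        for j in range(7):
            out = out + priors.loc[j].logpdf(th[..., j])
        return out

    def loglik(th):
        nat = th.copy()
        nat[..., 6] = ndtr(nat[..., 6])
        return table_loglik(nat, data)

    gamma = config.gamma or 2.38 / np.sqrt(2 * 7)
    jit = config.jitter * span
    ll = loglik(theta)
    lp = logprior(theta)

    n_sweeps = config.burn_in + config.n_keep * config.thin
    keep = np.empty((C, config.n_keep, 1, 7))
    k_out = 0
    acc = np.zeros(C)
    for sweep in range(n_sweeps):
        r1, r2 = _de_partners(C, (C,), rng)
        prop = theta + gamma * (theta[r1] - theta[r2]) \
            + rng.uniform(-1, 1, (C, 7)) * jit
        lp_p = logprior(prop)
        feasible = np.isfinite(lp_p)
        ll_p = loglik(np.where(feasible[:, None], prop, theta))
        log_alpha = (ll_p + lp_p) - (ll + lp)
        accept = (np.log(rng.random(C)) < log_alpha) & feasible
        theta = np.where(accept[:, None], prop, theta)
        ll = np.where(accept, ll_p, ll)
        lp = np.where(accept, lp_p, lp)
        acc += accept

        if sweep < config.burn_in and rng.random() < config.migration_prob:
            k = int(rng.integers(2, C + 1))
            sel = rng.choice(C, size=k, replace=False)
            total = ll + lp
            snap_theta, snap_ll, snap_lp = theta.copy(), ll.copy(), lp.copy()
            snap_total = total.copy()
            for i in range(k):
                src, dst = sel[i - 1], sel[i]
                if np.log(rng.random()) < snap_total[src] - total[dst]:
                    theta[dst] = snap_theta[src]
                    ll[dst] = snap_ll[src]
                    lp[dst] = snap_lp[src]
                    total[dst] = snap_total[src]

        if sweep >= config.burn_in and \
                (sweep - config.burn_in + 1) % config.thin == 0:
            keep[:, k_out, 0] = theta
            k_out += 1

    _record_acceptance(acc, n_sweeps, "individual fit")
    return PosteriorDraws(subject=keep[:, :k_out], priors=priors)
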