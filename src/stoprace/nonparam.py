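"""Trial filtering, behavioral summary metrics, and the integration SSRT.

The integration method estimates SSRT non-parametrically: find the quantile
of the go-RT distribution at the observed probability of responding on stop
trials, and subtract the mean SSD.  Go omissions are replaced by the
deadline value (the consensus recipe), which guards the estimate against
right-censoring of slow go responses.  The estimator is known to be inflated
by trigger failures: stop trials on which inhibition was never initiated
raise P(respond | stop) and hence the go-RT quantile.

All metrics are computed after removing incorrect responses and responses
faster than the lower cutoff, and treating responses slower than the
deadline as censored — with the exception of P(Go error), which is computed
before any filtering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .race import CensoringRule

__all__ = [
    "BehavioralSummary",
    "preprocess_trials",
    "integration_ssrt",
    "behavioral_summary",
]


@dataclass(frozen=True)
class BehavioralSummary:
    """Table of observed stop-signal performance metrics (ms / probability)."""

    mean_ssd: float
    go_rt: float
    ssrt: float
    sr_rt: float
    p_go_miss: float
    p_go_error: float
    p_inhibit: float

    def to_dict(self):
        return asdict(self)


def preprocess_trials(raw: pd.DataFrame,
                      cens: CensoringRule = CensoringRule()):
    """Apply the fitting filter; returns ``(trials, exclusion_log)``.

    Removes trials with incorrect responses or responses faster than the
    lower cutoff; marks responses slower than the deadline as censored
    (column ``censored``) without dropping them.  The exclusion log counts
    each category so exclusion rates can be audited.
    """
    if "outcome" not in raw:
        raise ValueError("trial table must carry outcome labels")
    df = raw.copy()
    rt = df["rt_ms"].to_numpy(dtype=float)
    responded = np.isfinite(rt)
    correct = df["correct"].to_numpy() if "correct" in df \
        else np.ones(len(df), bool)

    incorrect = responded & ~correct
    too_fast = responded & correct & (rt < cens.lower_cutoff)
    drop = incorrect | too_fast
    censored = responded & ~drop & (rt > cens.deadline)

    out = df.loc[~drop].copy()
    out["censored"] = censored[~drop]
    log = {
        "n_raw": int(len(df)),
        "n_incorrect": int(incorrect.sum()),
        "n_too_fast": int(too_fast.sum()),
        "n_censored": int(censored.sum()),
        "n_analyzable": int(len(out)),
    }
    return out, log


def integration_ssrt(trials: pd.DataFrame, deadline: float = 1000.0) -> float:
    """Integration-method SSRT with go-omission replacement (ms).

    ``p`` = P(respond | stop trial); go omissions are replaced by the
    deadline; SSRT = the ``ceil(p * n_go)``-th order statistic of the
    (replaced) go-RT distribution minus the mean SSD over stop trials.
    Returns NaN (flagged) when ``p`` is 0 or 1, where the estimator is
    undefined.
    """
    stop = trials[trials["trial_type"] == "stop"]
    go = trials[trials["trial_type"] == "go"]
    if len(stop) == 0 or len(go) == 0:
        return float("nan")
    if len(stop) < 20:
        warnings.warn("fewer than 20 stop trials; integration SSRT is noisy")

    responded = np.isfinite(stop["rt_ms"].to_numpy(dtype=float))
    p_respond = float(responded.mean())
    if p_respond <= 0.0 or p_respond >= 1.0:
        return float("nan")

    go_rts = go["rt_ms"].to_numpy(dtype=float)
    go_rts = np.where(np.isfinite(go_rts), go_rts, deadline)  # omission replacement
    if "censored" in go:
        go_rts = np.where(go["censored"].to_numpy(), deadline, go_rts)
    go_rts = np.sort(go_rts)
    k = min(max(math.ceil(p_respond * len(go_rts)), 1), len(go_rts))
    quantile_rt = go_rts[k - 1]
    mean_ssd = float(stop["ssd_ms"].mean())
    return float(quantile_rt - mean_ssd)


def behavioral_summary(trials: pd.DataFrame,
                       cens: CensoringRule = CensoringRule()) -> BehavioralSummary:
    """Compute the standard observed metrics from a *raw* trial table.

    P(Go error) is computed before filtering; everything else after.  Go RT
    and signal-respond RT means exclude censored (past-deadline) responses.
    Stop-dependent fields are NaN when there are no stop trials.
    """
    raw_go = trials[trials["trial_type"] == "go"]
    rt_raw = raw_go["rt_ms"].to_numpy(dtype=float)
    responded_raw = np.isfinite(rt_raw)
    if "correct" in raw_go and len(raw_go):
        p_go_error = float((responded_raw & ~raw_go["correct"].to_numpy()).mean())
    else:
        p_go_error = 0.0 if len(raw_go) else float("nan")

    df, _ = preprocess_trials(trials, cens)
    go = df[df["trial_type"] == "go"]
    stop = df[df["trial_type"] == "stop"]

    go_rt_arr = go["rt_ms"].to_numpy(dtype=float)
    go_responded = np.isfinite(go_rt_arr) & ~go["censored"].to_numpy()
    go_rt = float(go_rt_arr[go_responded].mean()) if go_responded.any() else float("nan")
    # A go miss: no usable response before the deadline.
    p_go_miss = float(1.0 - go_responded.mean()) if len(go) else float("nan")

    if len(stop):
        sr_arr = stop["rt_ms"].to_numpy(dtype=float)
        sr_resp = np.isfinite(sr_arr) & ~stop["censored"].to_numpy()
        mean_ssd = float(stop["ssd_ms"].mean())
        p_inhibit = float(1.0 - np.isfinite(sr_arr).mean())
        sr_rt = float(sr_arr[sr_resp].mean()) if sr_resp.any() else float("nan")
        ssrt = integration_ssrt(df, deadline=cens.deadline)
    else:
        mean_ssd = p_inhibit = sr_rt = ssrt = float("nan")

    summary = BehavioralSummary(
        mean_ssd=mean_ssd, go_rt=go_rt, ssrt=ssrt, sr_rt=sr_rt,
        p_go_miss=p_go_miss, p_go_error=p_go_error, p_inhibit=p_inhibit,
    )
    if np.isfinite(summary.sr_rt) and np.isfinite(summary.go_rt) \
            and summary.sr_rt > summary.go_rt:
        warnings.warn(
            "mean signal-respond RT exceeds mean go RT; "
            "data violate the race-model prediction"
        )
    return summary
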