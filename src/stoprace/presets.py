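"""Reference group-level parameter values for simulation and sanity checks.

Published hierarchical race-model estimates for stop-signal performance in
right-inferior-frontal-gyrus (rIFG) lesion patients, non-rIFG lesion
patients, and their matched healthy comparison groups.  The lesion groups
are characterised by markedly different trigger-failure rates (16% with
rIFG damage vs 2-4% otherwise), which makes these values useful generating
conditions: simulating from them reproduces the staircase's ~50% stopping
success and the trigger-failure-driven inflation of non-parametric SSRT.

All time parameters are posterior means in ms; ``p_tf`` is on the
probability scale.  ``NONPARAM_SSRT`` holds the corresponding observed
integration-method SSRT estimates (ms) for the same cohorts.
"""

from __future__ import annotations

from .race import ExGaussParams, ParameterSet

__all__ = ["GROUP_PARAMS", "NONPARAM_SSRT", "parameter_set"]

#: Posterior-mean race parameters per group (ms; p_tf as probability).
GROUP_PARAMS: dict[str, dict[str, float]] = {
    "rifg_lesion": {
        "mu_go": 479.0, "sigma_go": 75.0, "tau_go": 154.0,
        "mu_stop": 223.0, "sigma_stop": 40.0, "tau_stop": 45.0,
        "p_tf": 0.16,
    },
    "rifg_comparison": {
        "mu_go": 578.0, "sigma_go": 90.0, "tau_go": 76.0,
        "mu_stop": 198.0, "sigma_stop": 24.0, "tau_stop": 34.0,
        "p_tf": 0.03,
    },
    "non_rifg_lesion": {
        "mu_go": 547.0, "sigma_go": 98.0, "tau_go": 106.0,
        "mu_stop": 215.0, "sigma_stop": 54.0, "tau_stop": 29.0,
        "p_tf": 0.02,
    },
    "non_rifg_comparison": {
        "mu_go": 575.0, "sigma_go": 104.0, "tau_go": 85.0,
        "mu_stop": 199.0, "sigma_stop": 24.0, "tau_stop": 26.0,
        "p_tf": 0.04,
    },
}

#: Observed integration-method (non-parametric) SSRT per group, ms.
NONPARAM_SSRT: dict[str, float] = {
    "rifg_lesion": 307.0,
    "rifg_comparison": 231.0,
    "non_rifg_lesion": 255.0,
    "non_rifg_comparison": 238.0,
}


def parameter_set(group: str) -> ParameterSet:
    """Build a :class:`ParameterSet` from a named reference group."""
    if group not in GROUP_PARAMS:
        raise KeyError(f"unknown group {group!r}; "
                       f"choose from {sorted(GROUP_PARAMS)}")
    g = GROUP_PARAMS[group]
    return ParameterSet(
        go=ExGaussParams(g["mu_go"], g["sigma_go"], g["tau_go"]),
        stop=ExGaussParams(g["mu_stop"], g["sigma_stop"], g["tau_stop"]),
        p_tf=g["p_tf"],
    )
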