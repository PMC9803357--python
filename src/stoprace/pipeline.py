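"""End-to-end orchestration: simulate -> fit -> behavior -> bursts -> stats.

A run is configured by a plain-text (YAML) config, validated before any
computation; the resolved config is written next to the outputs, and one
integer seed expands deterministically into independent per-stage streams.
Each stage writes its outputs into the run directory and is skipped on
re-runs when its outputs already exist (delete a stage's files to recompute
it); given the same config and seed, outputs are reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eeg import BurstInjectionSpec, synthesize_eeg
from .bursts import burst_triggered_sensorimotor, detect_bursts, \
    frontal_burst_rate, morlet_tf
from .groupstats import mixed_anova_2x3, paired_t
from .model import HierarchicalStopSignalModel
from .nonparam import behavioral_summary
from .presets import GROUP_PARAMS
from .race import CensoringRule
from .sampler import SamplerConfig
from .simulate import PopulationSpec, TaskDesign, simulate_group

log = logging.getLogger("stoprace")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "stoprace_run"
    seed: int = 0
    n_subjects_per_group: int = 4
    groups: tuple = ("rifg_lesion", "rifg_comparison")
    population_scales: dict = field(default_factory=lambda: {
        "mu_go": 40.0, "sigma_go": 15.0, "tau_go": 25.0,
        "mu_stop": 20.0, "sigma_stop": 8.0, "tau_stop": 10.0, "p_tf": 0.3,
    })
    design: dict = field(default_factory=dict)        # TaskDesign overrides
    sampler: dict = field(default_factory=lambda: {
        "burn_in": 300, "n_keep": 100, "thin": 3})    # reduced-MCMC demo
    burst_spec: dict = field(default_factory=dict)    # BurstInjectionSpec overrides
    run_fit: bool = True
    run_eeg: bool = True

    def __post_init__(self):
        if self.n_subjects_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        for g in self.groups:
            if g not in GROUP_PARAMS:
                raise ValueError(f"unknown group preset {g!r}")
        TaskDesign(**self.design)          # validate eagerly
        SamplerConfig(**self.sampler)
        BurstInjectionSpec(**self.burst_spec)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)


def _population_spec(group: str, scales: dict) -> PopulationSpec:
    from scipy.special import ndtri

    p = GROUP_PARAMS[group]
    loc = np.array([p["mu_go"], p["sigma_go"], p["tau_go"], p["mu_stop"],
                    p["sigma_stop"], p["tau_stop"], ndtri(p["p_tf"])])
    order = ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop",
             "tau_stop", "p_tf")
    scale = np.array([scales[k] for k in order])
    return PopulationSpec(location=loc, scale=scale)


def _stage(name, out_dir, outputs, fn):
    """Run a stage unless all its output files already exist (re-entrant)."""
    paths = [Path(out_dir) / o for o in outputs]
    if paths and all(p.exists() for p in paths):
        log.info("stage %s: cached, skipping", name)
        return
    t0 = time.time()
    try:
        fn()
    except Exception as e:
        raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
    log.info("stage %s: %.1f s", name, time.time() - t0)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2,
                                                default=str))
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {n: s for n, s in zip(
        ("simulate", "fit", "eeg", "stats"), ss.spawn(4))}
    design = TaskDesign(**config.design)
    cens = CensoringRule(deadline=design.deadline)

    # ---- simulate -------------------------------------------------------
    sim_outputs = [f"trials_{g}.csv" for g in config.groups] + ["true_params.csv"]

    def do_simulate():
        rows = []
        children = stage_seeds["simulate"].spawn(len(config.groups))
        for g, child in zip(config.groups, children):
            pop = _population_spec(g, config.population_scales)
            sims = simulate_group(pop, config.n_subjects_per_group, design,
                                  seed=child)
            frames = []
            for i, (ps, df) in enumerate(sims):
                df = df.copy()
                df.insert(0, "participant", i)
                frames.append(df)
                rec = {"group": g, "participant": i}
                rec.update(zip(
                    ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop",
                     "tau_stop", "p_tf"), ps.to_vector()))
                rows.append(rec)
            pd.concat(frames, ignore_index=True).to_csv(
                out / f"trials_{g}.csv", index=False)
        pd.DataFrame(rows).to_csv(out / "true_params.csv", index=False)

    _stage("simulate", out, sim_outputs, do_simulate)

    # ---- behavioral summaries ------------------------------------------
    def do_behavior():
        rows = []
        for g in config.groups:
            df = pd.read_csv(out / f"trials_{g}.csv")
            for pid, sub in df.groupby("participant"):
                rec = {"group": g, "participant": pid}
                rec.update(behavioral_summary(sub, cens).to_dict())
                rows.append(rec)
        pd.DataFrame(rows).to_csv(out / "behavior_summary.csv", index=False)

    _stage("behavior", out, ["behavior_summary.csv"], do_behavior)

    # ---- hierarchical fit ----------------------------------------------
    ssrt_by_group: dict[str, pd.DataFrame] = {}
    if config.run_fit:
        def do_fit():
            cfg = SamplerConfig(**config.sampler)
            children = stage_seeds["fit"].spawn(len(config.groups))
            for g, child in zip(config.groups, children):
                df = pd.read_csv(out / f"trials_{g}.csv")
                m = HierarchicalStopSignalModel.from_dataframe(df,
                                                               censoring=cens)
                res = m.fit(cfg, seed=int(child.generate_state(1)[0] % 2**31))
                res.participant_posterior_means().to_csv(
                    out / f"participant_estimates_{g}.csv", index=False)
                res.population_summary().to_csv(
                    out / f"population_summary_{g}.csv")
                res.draws.to_dataframe().to_csv(
                    out / f"draws_{g}.csv.gz", index=False)

        _stage("fit", out, [f"population_summary_{g}.csv"
                            for g in config.groups], do_fit)
        for g in config.groups:
            p = out / f"participant_estimates_{g}.csv"
            if p.exists():
                ssrt_by_group[g] = pd.read_csv(p)

    # ---- EEG synthesis + burst analysis --------------------------------
    if config.run_eeg:
        def do_eeg():
            spec = BurstInjectionSpec(**config.burst_spec)
            children = stage_seeds["eeg"].spawn(len(config.groups))
            rate_rows, tc_frames = [], []
            for g, child in zip(config.groups, children):
                trials = pd.read_csv(out / f"trials_{g}.csv")
                est = ssrt_by_group.get(g)
                sub_seeds = child.spawn(trials["participant"].nunique())
                for pid, sub in trials.groupby("participant"):
                    sub = sub.reset_index(drop=True)
                    sub["trial"] = np.arange(len(sub))
                    if est is not None:
                        ssrt = float(est.loc[est["subject"] == pid,
                                             "mean_ssrt"].iloc[0])
                    else:
                        ssrt = 280.0
                    epochs = synthesize_eeg(sub, spec, seed=sub_seeds[int(pid)])
                    tf_fc = morlet_tf(epochs, spec.frontal_channel)
                    ev_fc = detect_bursts(tf_fc)
                    sm_parts = []
                    for ch in spec.sensorimotor_channels:
                        sm_parts.append(detect_bursts(morlet_tf(epochs, ch)))
                    ev_sm = pd.concat(sm_parts, ignore_index=True)
                    rates = frontal_burst_rate(ev_fc, sub, ssrt)
                    for _, r in rates.iterrows():
                        rate_rows.append({"group": g, "subject": pid,
                                          **r.to_dict()})
                    tc = burst_triggered_sensorimotor(
                        ev_fc, ev_sm, sub, ssrt,
                        seed=int(sub_seeds[int(pid)].generate_state(1)[0]))
                    tc.insert(0, "subject", pid)
                    tc.insert(0, "group", g)
                    tc_frames.append(tc)
            pd.DataFrame(rate_rows).to_csv(out / "burst_rates.csv", index=False)
            pd.concat(tc_frames, ignore_index=True).to_csv(
                out / "burst_timecourse.csv", index=False)

        _stage("eeg", out, ["burst_rates.csv", "burst_timecourse.csv"], do_eeg)

        # ---- group statistics ------------------------------------------
        def do_stats():
            rates = pd.read_csv(out / "burst_rates.csv")
            rates["uid"] = rates["group"] + "_" + rates["subject"].astype(str)
            rows = []
            if rates["group"].nunique() == 2:
                for r in mixed_anova_2x3(rates, subject="uid"):
                    rows.append({"test": f"anova_{r.effect}", "stat": r.F,
                                 "df1": r.df1, "df2": r.df2, "p": r.p,
                                 "effect_size": r.partial_eta_sq})
                wide = rates.pivot_table(index=["group", "subject"],
                                         columns="trial_type",
                                         values="normalized_rate")
                for g, sub in wide.groupby(level="group"):
                    t = paired_t(sub["successful_stop"], sub["go"])
                    rows.append({"test": f"paired_ss_vs_go_{g}", "stat": t.t,
                                 "df1": t.df, "df2": np.nan, "p": t.p,
                                 "effect_size": t.cohens_d})
            pd.DataFrame(rows).to_csv(out / "group_stats.csv", index=False)

        _stage("stats", out, ["group_stats.csv"], do_stats)

    return out
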