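"""End-to-end analysis pipeline: ingest -> segment -> summarize -> test -> report.

`run_pipeline` drives the complete sucrose-drinking analysis from a single
config (dict or YAML file): it loads or simulates an experiment, segments
every session at the configured interbout interval, builds per-animal means,
and runs the statistical battery —

* consumption ANOVA (handling x concentration, 2 x (2), mouse as unit);
* the same on weight-adjusted consumption (g solution per g mouse);
* lick-cluster-size ANOVA on log-transformed per-animal means with
  Bonferroni simple effects of handling at each concentration;
* the interbout-threshold robustness sweep, re-running the cluster-size
  ANOVA at each threshold.

`behavioural_tests_runner` applies the matching test to pre-scored
behavioural tables (elevated plus maze, open field, voluntary interaction):
scoring videos is out of scope, the pipeline consumes the scored numbers.

Reports are deterministic: the rendered body contains no wall-clock
timestamps, so re-running the same config on the same inputs reproduces it
byte for byte.  Provenance (config hash, seed, input digests) makes every
statistic traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import consumption as cons
from . import microstructure as micro
from .anova import Comparison, DesignSpec, MixedAnova, MixedAnovaResults, _fmt_p
from .errors import LickstructError, ValidationError
from .hypothesis_tests import TestResult, mann_whitney_u, unpaired_t
from .io_medpc import (
    read_consumption_table, read_lick_csv, read_metadata_table,
)
from .logistic import binary_logistic
from .simulate import SimConfig, handling_effect_preset, simulate_experiment

logger = logging.getLogger(__name__)

DEFAULT_SWEEP = (0.25, 0.50, 1.00)


@dataclass
class AnalysisReport:
    """Collected outputs of one pipeline run.

    ``blocks`` maps analysis name -> dict with the fitted results; the
    provenance dict carries the config hash, seed and input digests so every
    reported statistic is traceable.
    """

    blocks: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def render(self) -> str:
        lines = ["lickstruct analysis report", "=" * 60]
        for key, value in sorted(self.provenance.items()):
            lines.append(f"{key}: {value}")
        for name, block in self.blocks.items():
            lines += ["", "-" * 60, f"[{name}]"]
            res = block.get("results")
            if isinstance(res, MixedAnovaResults):
                lines.append(res.summary())
            for extra_name, extra in block.items():
                if extra_name == "results":
                    continue
                if isinstance(extra, list) and extra and isinstance(extra[0], TestResult):
                    lines.append(f"  {extra_name}:")
                    for t in extra:
                        lines.append(f"    {_render_test(t)}")
                elif isinstance(extra, pd.DataFrame):
                    lines.append(extra.to_string(index=False,
                                                 float_format=lambda v: f"{v:.4f}"))
                elif isinstance(extra, TestResult):
                    lines.append(f"  {extra_name}: {_render_test(extra)}")
                else:
                    lines.append(f"  {extra_name}: {extra}")
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.render(), encoding="utf-8")
        for name, block in self.blocks.items():
            res = block.get("results")
            if isinstance(res, MixedAnovaResults):
                res.anova_table.to_csv(out / f"{name}_anova.csv")
            if isinstance(res, pd.DataFrame):
                res.to_csv(out / f"{name}.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True), encoding="utf-8"
        )


def _render_test(t: TestResult) -> str:
    bits = [f"{t.name} = {t.value:.4f}"]
    if t.df is not None:
        bits.append(f"df = {t.df:g}")
    bits.append(f"p = {_fmt_p(t.p)}")
    if t.adjusted_p is not None:
        bits.append(f"Bonferroni p = {_fmt_p(t.adjusted_p)}")
    prefix = f"{t.label}: " if t.label else ""
    return prefix + ", ".join(bits)


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _build_sim_config(section: Mapping) -> SimConfig:
    preset = section.get("preset", "handling_effect")
    if preset == "handling_effect":
        cfg = handling_effect_preset()
    elif preset == "null":
        cfg = handling_effect_preset().equalized()
    elif preset == "default":
        cfg = SimConfig()
    else:
        raise ValidationError(f"unknown simulation preset {preset!r}")
    overrides = {
        k: v for k, v in section.items() if k not in ("preset",)
    }
    if overrides:
        import dataclasses
        cfg = dataclasses.replace(cfg, **overrides)
    return cfg


def run_pipeline(config, out_dir: str | Path | None = None) -> AnalysisReport:
    """Execute the configured analyses and return an :class:`AnalysisReport`.

    Config keys (dict or YAML file):

    ``seed``
        Master seed for simulation (required with ``simulate``).
    ``simulate``
        Section with ``preset`` (``handling_effect`` | ``null`` |
        ``default``) and optional SimConfig field overrides; mutually
        exclusive with ``inputs``.
    ``inputs``
        Section with ``licks``, ``metadata``, ``consumption`` CSV paths.
    ``interbout_interval`` (default 0.25), ``sweep`` (default
        [0.25, 0.5, 1.0]), ``min_licks`` (default 100),
    ``analyses``
        Subset of {consumption, consumption_weight_adjusted, cluster_size,
        sweep}; default all.
    """
    raw = _load_config(config)
    report = AnalysisReport()
    report.provenance["config_hash"] = _config_hash(raw)

    ici = float(raw.get("interbout_interval", micro.DEFAULT_INTERBOUT_INTERVAL))
    sweep_grid = tuple(raw.get("sweep", DEFAULT_SWEEP))
    min_licks = int(raw.get("min_licks", 100))
    analyses = list(raw.get(
        "analyses",
        ["consumption", "consumption_weight_adjusted", "cluster_size", "sweep"],
    ))

    # --- ingest ------------------------------------------------------------
    try:
        if "simulate" in raw:
            seed = int(raw.get("seed", 0))
            sim_cfg = _build_sim_config(raw["simulate"] or {})
            exp = simulate_experiment(sim_cfg, seed)
            subjects, trains, consumption_records = (
                exp.subjects, exp.trains, exp.consumption,
            )
            report.provenance["seed"] = seed
            report.provenance["source"] = f"simulated ({raw['simulate'].get('preset', 'handling_effect')})"
        elif "inputs" in raw:
            inputs = raw["inputs"]
            subjects = read_metadata_table(inputs["metadata"])
            trains = read_lick_csv(inputs["licks"])
            consumption_records = read_consumption_table(inputs["consumption"])
            for key, path in inputs.items():
                report.provenance[f"digest_{key}"] = _file_digest(path)
            report.provenance["source"] = "files"
        else:
            raise ValidationError("config must contain 'simulate' or 'inputs'")
    except Exception as err:
        raise LickstructError(f"stage ingest: {err}") from err

    handling_of = {s.subject_id: s.handling for s in subjects}

    # --- segment & summarize ----------------------------------------------
    try:
        summaries = [micro.summarize_session(t, ici) for t in trains]
        kept, flagged = micro.engagement_filter(summaries, min_licks=min_licks)
        if raw.get("apply_engagement_filter", False):
            summaries_used = kept
        else:
            # test-phase sessions are reported, not dropped: the engagement
            # criterion gates *training*, and these are test data
            summaries_used = summaries
        means = micro.subject_means(summaries_used)
        means["handling"] = means["subject_id"].map(handling_of)
    except LickstructError as err:
        raise LickstructError(f"stage segment: {err}") from err

    report.blocks["microstructure"] = {
        "n_sessions": len(summaries),
        "n_flagged_low_engagement": len(flagged),
        "interbout_interval": ici,
    }

    # --- consumption analyses ---------------------------------------------
    summaries_cons = cons.mean_consumption(consumption_records)
    cons_df = cons.consumption_frame(summaries_cons)
    cons_df["handling"] = cons_df["subject_id"].map(handling_of)

    if "consumption" in analyses:
        try:
            spec = DesignSpec(unit="subject_id", between="handling",
                              within=("concentration",), response="mean_mass")
            res = MixedAnova(cons_df, spec).fit()
            report.blocks["consumption"] = {"results": res}
        except LickstructError as err:
            raise LickstructError(f"stage consumption: {err}") from err

    if "consumption_weight_adjusted" in analyses:
        try:
            adj = cons.weight_adjusted(summaries_cons, subjects)
            adj_df = cons.consumption_frame(adj)
            adj_df["handling"] = adj_df["subject_id"].map(handling_of)
            spec = DesignSpec(unit="subject_id", between="handling",
                              within=("concentration",),
                              response="mean_mass_per_gram_bw")
            res = MixedAnova(adj_df, spec).fit()
            report.blocks["consumption_weight_adjusted"] = {"results": res}
        except LickstructError as err:
            raise LickstructError(f"stage consumption_weight_adjusted: {err}") from err

    # --- lick cluster size -------------------------------------------------
    if "cluster_size" in analyses:
        try:
            spec = DesignSpec(unit="subject_id", between="handling",
                              within=("concentration",),
                              response="mean_cluster_size", transform="log")
            model = MixedAnova(means, spec)
            res = model.fit()
            concs = sorted(means["concentration"].unique())
            pairwise = res.pairwise([
                Comparison("handling", where={"concentration": c},
                           label=f"handling simple effect at {c:g}%")
                for c in concs
            ])
            report.blocks["cluster_size"] = {
                "results": res,
                "bonferroni_simple_effects": pairwise,
            }
        except LickstructError as err:
            raise LickstructError(f"stage cluster_size: {err}") from err

    # --- threshold sweep ---------------------------------------------------
    if "sweep" in analyses:
        try:
            sweep_tab = micro.sweep_thresholds(trains, sweep_grid)
            rows = []
            for th, sub in sweep_tab.groupby("threshold"):
                sub_means = (
                    sub.dropna(subset=["mean_cluster_size"])
                    .groupby(["subject_id", "concentration"], as_index=False)
                    ["mean_cluster_size"].mean()
                )
                sub_means["handling"] = sub_means["subject_id"].map(handling_of)
                spec = DesignSpec(unit="subject_id", between="handling",
                                  within=("concentration",),
                                  response="mean_cluster_size", transform="log")
                r = MixedAnova(sub_means, spec).fit()
                inter = "handling x concentration"
                rows.append({
                    "threshold": th,
                    "F_handling": r.f_statistic("handling"),
                    "p_handling": r.p_value("handling"),
                    "F_concentration": r.f_statistic("concentration"),
                    "p_concentration": r.p_value("concentration"),
                    "F_interaction": r.f_statistic(inter),
                    "p_interaction": r.p_value(inter),
                })
            report.blocks["sweep"] = {"results": pd.DataFrame(rows)}
        except LickstructError as err:
            raise LickstructError(f"stage sweep: {err}") from err

    if out_dir is not None:
        report.write(out_dir)
    return report


# ---------------------------------------------------------------------------
# pre-scored behavioural tables
# ---------------------------------------------------------------------------

#: variable -> test mapping for the standard anxiety battery
VARIABLE_TESTS: dict[str, str] = {
    "open_arm_entries": "mann_whitney",      # elevated plus maze
    "open_arm_duration": "mann_whitney",
    "stretch_attend_postures": "unpaired_t",
    "epm_defecated": "logistic",
    "duration_moving": "unpaired_t",         # open field
    "duration_centre": "unpaired_t",
    "crosses_centre": "unpaired_t",
    "distance_travelled": "unpaired_t",
    "mean_velocity": "unpaired_t",
    "oft_defecated": "logistic",
    "interaction_time": "rm_anova",          # voluntary interaction, cage means
}


def behavioural_tests_runner(
    scored_table: pd.DataFrame,
    tests: Mapping[str, str] | None = None,
) -> dict[str, object]:
    """Apply the designated test to each behavioural variable.

    Parameters
    ----------
    scored_table : DataFrame
        Tidy scored data: columns ``unit``, ``group``, ``variable``,
        ``value``; rm-ANOVA variables additionally need ``day`` and ``time``
        columns (time = pre/post handling; the interaction window is 60 s,
        so percentages are value / 60 s).  The unit is the mouse, except for
        the voluntary-interaction test whose unit is the cage mean.
    tests : mapping, optional
        Overrides/extends the default variable -> test registry
        (:data:`VARIABLE_TESTS`); test names: ``mann_whitney``,
        ``unpaired_t``, ``logistic``, ``rm_anova``.

    Returns
    -------
    dict mapping variable -> TestResult (or MixedAnovaResults for rm_anova).
    """
    registry = dict(VARIABLE_TESTS)
    if tests:
        registry.update(tests)
    for col in ("unit", "group", "variable", "value"):
        if col not in scored_table.columns:
            raise ValidationError(f"scored table missing column {col!r}")

    results: dict[str, object] = {}
    for var, sub in scored_table.groupby("variable"):
        if var not in registry:
            raise ValidationError(
                f"unknown variable {var!r}; supported: {sorted(registry)}"
            )
        kind = registry[var]
        if kind == "rm_anova":
            spec = DesignSpec(unit="unit", between="group",
                              within=("day", "time"), response="value")
            results[var] = MixedAnova(sub, spec).fit()
            continue
        levels = sorted(sub["group"].unique())
        if len(levels) != 2:
            raise ValidationError(f"{var}: need exactly 2 groups, got {levels}")
        x = sub.loc[sub["group"] == levels[0], "value"].to_numpy()
        y = sub.loc[sub["group"] == levels[1], "value"].to_numpy()
        if kind == "mann_whitney":
            results[var] = mann_whitney_u(x, y)
        elif kind == "unpaired_t":
            results[var] = unpaired_t(x, y)
        elif kind == "logistic":
            results[var] = binary_logistic(
                sub["value"].to_numpy(), sub["group"].to_numpy()
            )
        else:
            raise ValidationError(f"unknown test kind {kind!r} for {var!r}")
    return results
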