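"""End-to-end study orchestration: simulate -> preprocess -> extract -> stats.

The entry points follow the model/results convention: a :class:`Study` is
built from a :class:`StudyConfig` (or plain dict) and its :meth:`Study.fit`
runs the full chain, returning a :class:`StudyResults` that carries the
per-subject response metrics, the statistical tables, grand-average time
courses and a reproducibility manifest, with a :meth:`StudyResults.summary`
text table.

The default simulated study mirrors the experimental analysis skeleton:
stimulus-vs-blank paired tests per chromophore, a repeated-measures ANOVA
across stimulation conditions, the adult-vs-child amplitude comparison,
and Spearman correlations between response amplitudes and AQ scores
(total + five subscales) with BH-FDR correction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg

import hemovis
from hemovis.errors import ConfigurationError
from hemovis.io import default_montage
from hemovis.preprocessing import PipelineConfig, preprocess_recording
from hemovis.response import CHROMOPHORES, blank_subtract, block_average, \
    extract_subject_metrics
from hemovis.simulate import (
    CohortSim,
    SimConfig,
    simulate_cohort,
    simulate_subject,
    subset_montage,
)
from hemovis.stats import StatResult, paired_t, rm_anova, spearman_bh
from hemovis.stimulus import TrialSchedule

__all__ = ["StudyConfig", "Study", "StudyResults", "run_study", "validate_config"]

AQ_SCALES = ["AQ", "AQ_S", "AQ_C", "AQ_A", "AQ_D", "AQ_I"]


@dataclass
class StudyConfig:
    """Configuration of a simulated end-to-end study."""

    seed: int = 0
    cohorts: tuple[str, ...] = ("adult", "child")
    n_subjects: dict = field(default_factory=lambda: {"adult": 10, "child": 10})
    conditions: tuple[str, ...] = ("L", "H")
    n_channels: int | None = None  # None = full 22-channel montage
    peak_mode: str = "timecourse"
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    sim: SimConfig = field(default_factory=SimConfig)


def validate_config(config) -> StudyConfig:
    """Normalize a dict (or StudyConfig) into a validated StudyConfig.

    Unknown keys are rejected with their key path; nested ``pipeline`` and
    ``sim`` blocks fill unset fields with the standard processing-stream
    defaults. The function is idempotent.
    """
    if isinstance(config, StudyConfig):
        cfg = config
    elif isinstance(config, dict):
        config = dict(config)
        kwargs = {}
        for block, cls in (("pipeline", PipelineConfig), ("sim", SimConfig)):
            if block in config:
                sub = config.pop(block)
                if isinstance(sub, cls):
                    kwargs[block] = sub
                else:
                    known = {f.name for f in dataclasses.fields(cls)}
                    bad = set(sub) - known
                    if bad:
                        raise ConfigurationError(
                            f"unknown keys: {', '.join(f'{block}.{k}' for k in sorted(bad))}"
                        )
                    kwargs[block] = cls(**sub)
        known = {f.name for f in dataclasses.fields(StudyConfig)}
        bad = set(config) - known
        if bad:
            raise ConfigurationError(f"unknown keys: {', '.join(sorted(bad))}")
        if "n_subjects" in config:
            config["n_subjects"] = dict(config["n_subjects"])
        if "cohorts" in config:
            config["cohorts"] = tuple(config["cohorts"])
        if "conditions" in config:
            config["conditions"] = tuple(config["conditions"])
        cfg = StudyConfig(**config, **kwargs)
    else:
        raise ConfigurationError("config must be a dict or StudyConfig")
    for cohort in cfg.cohorts:
        if cohort not in ("adult", "child"):
            raise ConfigurationError(f"cohorts: unknown cohort {cohort!r}")
        if cfg.n_subjects.get(cohort, 0) < 3:
            raise ConfigurationError(f"n_subjects.{cohort} must be >= 3")
    if not cfg.conditions:
        raise ConfigurationError("at least one condition is required")
    cfg.pipeline.validate(fs=cfg.sim.fs)
    return cfg


def _config_snapshot(cfg: StudyConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(cfg), default=str))


@dataclass
class StudyResults:
    """Fitted study: metrics, statistics, grand averages and manifest."""

    metrics: pd.DataFrame
    stats: pd.DataFrame
    grand_averages: dict
    manifest: dict
    truths: dict

    def summary(self) -> str:
        lines = ["Study summary", "=" * 60]
        counts = self.manifest["counts"]
        lines.append(
            f"subjects analyzed: {counts['subjects_analyzed']} "
            f"({', '.join(f'{k}: {v}' for k, v in counts['per_cohort'].items())})"
        )
        lines.append(f"channels pruned: {counts['channels_pruned']}, "
                     f"trials dropped: {counts['trials_dropped']}")
        lines.append("")
        with pd.option_context("display.width", 120, "display.precision", 4):
            for family, sub in self.stats.groupby("family", sort=False):
                lines.append(f"[{family}]")
                cols = [c for c in ("cohort", "condition", "label", "test",
                                    "statistic", "p", "adjusted_p", "effect_size")
                        if c in sub.columns]
                lines.append(sub[cols].to_string(index=False))
                lines.append("")
        return "\n".join(lines)

    def save(self, outdir: str | Path, plots: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        self.stats.to_csv(outdir / "stats.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        if plots:
            self._plot(outdir)

    def _plot(self, outdir: Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        colors = {"THb": "tab:green", "OHb": "tab:red", "DHb": "tab:blue"}
        for (cohort, condition), df in self.grand_averages.items():
            fig, ax = plt.subplots(figsize=(5, 3.2))
            for chrom in CHROMOPHORES:
                ax.plot(df["time_s"], df[chrom] * 1e4, color=colors[chrom],
                        label=chrom)
            ax.axvspan(0, 5, color="0.9", zorder=0)
            ax.set_xlabel("time from onset (s)")
            ax.set_ylabel(r"$\Delta$Hb ($\times 10^{-4}$)")
            ax.set_title(f"{cohort} / {condition} (blank-subtracted)")
            ax.legend(frameon=False, fontsize=8)
            fig.tight_layout()
            fig.savefig(outdir / f"block_average_{cohort}_{condition}.png",
                        dpi=120)
            plt.close(fig)


def cohort_amplitudes(sim: CohortSim,
                      pipeline_cfg: PipelineConfig | None = None,
                      peak_mode: str = "timecourse") -> pd.DataFrame:
    """Recover per-subject blank-subtracted peak amplitudes from a cohort.

    Runs the full processing stream on every simulated recording and
    returns one row per subject with the recovered THb/OHb/DHb amplitudes,
    the AQ total and the planted truth — the working currency for
    parameter-recovery and correlation checks.
    """
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    rows = []
    for rec, sched, st in zip(sim.recordings, sim.schedules, sim.truth.subjects):
        hb, keep, residual, _ = preprocess_recording(rec, pipeline_cfg)
        df = extract_subject_metrics(hb, sched, residual, keep, pipeline_cfg,
                                     subject_id=st.subject_id,
                                     peak_mode=peak_mode)
        sb = df[df.condition == "S-B"].set_index("chrom")
        rows.append({
            "subject_id": st.subject_id,
            "aq_total": st.aq_total,
            "thb": sb.loc["THb", "amplitude"],
            "ohb": sb.loc["OHb", "amplitude"],
            "dhb": sb.loc["DHb", "amplitude"],
            "channel": int(sb.loc["THb", "channel"]),
            "true_thb": st.thb_amplitude,
            "true_channel": st.best_channel,
        })
    return pd.DataFrame(rows)


class Study:
    """A simulated visual-stimulation fNIRS study, statsmodels-style.

    Build from a config (``Study(config)``) and call :meth:`fit` to run
    simulation, preprocessing, response extraction and statistics.
    """

    def __init__(self, config: StudyConfig | dict | None = None):
        self.config = validate_config(config or StudyConfig())

    def fit(self) -> StudyResults:
        return run_study(self.config)


def _stat_row(res: StatResult, family: str, cohort: str, condition: str,
              label: str) -> dict:
    return {
        "family": family, "cohort": cohort, "condition": condition,
        "label": label, "test": res.test, "statistic": res.statistic,
        "p": res.p_value, "adjusted_p": res.adjusted_p,
        "effect_size": res.effect_size, "n": res.n,
    }


def run_study(config: StudyConfig | dict | None = None) -> StudyResults:
    """Run the full simulated study and assemble the results bundle."""
    cfg = validate_config(config or StudyConfig())
    root = np.random.SeedSequence(cfg.seed)
    cohort_seeds = {c: int(s.generate_state(1)[0] % (2 ** 31))
                    for c, s in zip(cfg.cohorts, root.spawn(len(cfg.cohorts)))}

    metrics_rows = []
    ga_accum: dict = {}
    truths = {}
    counts = {"channels_pruned": 0, "trials_dropped": 0,
              "subjects_analyzed": 0, "per_cohort": {}}

    for cohort in cfg.cohorts:
        montage = default_montage(cohort)
        if cfg.n_channels is not None:
            montage = subset_montage(montage, cfg.n_channels)
        sim = simulate_cohort(cfg.n_subjects[cohort], cohort=cohort,
                              seed=cohort_seeds[cohort], cfg=cfg.sim,
                              montage=montage, pipeline_cfg=cfg.pipeline)
        truths[cohort] = sim.truth
        cond_rng = np.random.SeedSequence(cohort_seeds[cohort] + 1)
        extra_streams = cond_rng.spawn(len(cfg.conditions) * len(sim.recordings))

        for ci, condition in enumerate(cfg.conditions):
            for si, st in enumerate(sim.truth.subjects):
                sched = sim.schedules[si]
                if ci == 0:
                    rec = sim.recordings[si]
                else:
                    # same planted truth, fresh noise realization per condition
                    base = TrialSchedule(
                        trials=[(o - cfg.sim.start_s, c) for o, c in sched.trials],
                        on_duration_s=sched.on_duration_s,
                        off_duration_s=sched.off_duration_s)
                    rng = np.random.default_rng(
                        extra_streams[ci * len(sim.recordings) + si])
                    rec = simulate_subject(st, base, montage, cfg.sim, seed=rng,
                                           pipeline_cfg=cfg.pipeline)
                hb, keep, residual, log = preprocess_recording(rec, cfg.pipeline)
                df = extract_subject_metrics(hb, sched, residual, keep,
                                             cfg.pipeline,
                                             subject_id=st.subject_id,
                                             peak_mode=cfg.peak_mode)
                df["cohort"] = cohort
                df["condition_label"] = condition
                df["aq_total"] = st.aq_total
                for k, v in st.aq_subscales.items():
                    df[f"aq_{k}"] = v
                metrics_rows.append(df)
                counts["channels_pruned"] += log["n_pruned"]
                used = df.loc[df.condition == "S-B", "n_trials"].iloc[0]
                counts["trials_dropped"] += int(cfg.sim.n_stim + cfg.sim.n_mock
                                                - 2 * used)

                block = block_average(hb, sched, residual, cfg.pipeline)
                diff = blank_subtract(block)
                best = int(df["channel"].iloc[0])
                key = (cohort, condition)
                acc = ga_accum.setdefault(
                    key, {ch: [] for ch in CHROMOPHORES} | {"t": diff.time_s})
                for ch in CHROMOPHORES:
                    acc[ch].append(diff.traces["S-B"][ch][best])
            counts["subjects_analyzed"] += cfg.n_subjects[cohort]
        counts["per_cohort"][cohort] = cfg.n_subjects[cohort]

    metrics = pd.concat(metrics_rows, ignore_index=True)
    grand_averages = {
        key: pd.DataFrame({"time_s": acc["t"]} | {
            ch: np.mean(acc[ch], axis=0) for ch in CHROMOPHORES})
        for key, acc in ga_accum.items()
    }

    stats_rows = []
    first_cond = cfg.conditions[0]

    # family 1: stimulus vs blank, per cohort and chromophore
    for cohort in cfg.cohorts:
        sub = metrics[(metrics.cohort == cohort)
                      & (metrics.condition_label == first_cond)]
        for chrom in CHROMOPHORES:
            s = sub[(sub.chrom == chrom) & (sub.condition == "S")] \
                .set_index("subject_id")["amplitude"]
            b = sub[(sub.chrom == chrom) & (sub.condition == "B")] \
                .set_index("subject_id")["amplitude"]
            b = b.reindex(s.index)
            res = paired_t(s.to_numpy(), b.to_numpy())
            stats_rows.append(_stat_row(res, "stim_vs_blank", cohort,
                                        first_cond, chrom))

    # family 2: condition RM-ANOVA on blank-subtracted amplitudes
    if len(cfg.conditions) >= 2:
        for cohort in cfg.cohorts:
            sub = metrics[(metrics.cohort == cohort)
                          & (metrics.condition == "S-B")]
            for chrom in CHROMOPHORES:
                d = sub[sub.chrom == chrom].drop(columns="condition").rename(
                    columns={"subject_id": "subject",
                             "condition_label": "condition",
                             "amplitude": "value"})
                res = rm_anova(d[["subject", "condition", "value"]])
                stats_rows.append(_stat_row(res, "condition_anova", cohort,
                                            "all", chrom))

    # family 3: adult vs child amplitude comparison
    if set(cfg.cohorts) >= {"adult", "child"}:
        sel = metrics[(metrics.condition == "S-B")
                      & (metrics.condition_label == first_cond)]
        for chrom in CHROMOPHORES:
            a = sel[(sel.cohort == "adult") & (sel.chrom == chrom)]["amplitude"]
            c = sel[(sel.cohort == "child") & (sel.chrom == chrom)]["amplitude"]
            res_df = pg.ttest(c.to_numpy(), a.to_numpy(), paired=False)
            row = res_df.iloc[0]
            res = StatResult(test="ttest_ind", statistic=float(row["T"]),
                             p_value=float(row["p_val"]),
                             effect_size=float(row["cohen_d"]),
                             effect_name="cohen_d",
                             n=int(len(a) + len(c)))
            stats_rows.append(_stat_row(res, "cohort_comparison", "child-adult",
                                        first_cond, chrom))

    # family 4: amplitude-AQ Spearman with BH-FDR per cohort
    for cohort in cfg.cohorts:
        pairs = {}
        for condition in cfg.conditions:
            sub = metrics[(metrics.cohort == cohort)
                          & (metrics.condition == "S-B")
                          & (metrics.condition_label == condition)]
            for chrom in CHROMOPHORES:
                d = sub[sub.chrom == chrom]
                for scale in AQ_SCALES:
                    col = "aq_total" if scale == "AQ" else f"aq_{scale}"
                    pairs[f"{chrom}~{scale}@{condition}"] = (
                        d["amplitude"].to_numpy(), d[col].to_numpy())
        for res in spearman_bh(pairs):
            stats_rows.append(_stat_row(res, "aq_correlation", cohort,
                                        res.label.split("@")[1], res.label))

    stats = pd.DataFrame(stats_rows)
    manifest = {
        "package_version": hemovis.__version__,
        "seed": cfg.seed,
        "cohort_seeds": cohort_seeds,
        "config": _config_snapshot(cfg),
        "counts": counts,
        "stats_digest": hashlib.sha256(
            stats.to_csv(index=False).encode()).hexdigest(),
    }
    return StudyResults(metrics=metrics, stats=stats,
                        grand_averages=grand_averages, manifest=manifest,
                        truths=truths)
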