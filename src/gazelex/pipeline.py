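"""End-to-end analysis: files -> exclusion audit -> scores -> inference ->
timecourse, with a reproducible run manifest.

`run_analysis` executes the stages in order and returns a ResultBundle whose
every number is regenerable from the config and inputs alone.  Defaults
encode the analysis constants: windows [0, 367) and [367, 3500) ms, 20 ms
bins, the one-third minimum-looking rule, and the half-of-designed-trials
subject rule.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import GazelexError
from .glmm import GlmmResult, build_phase_counts, compare_models, fit_phase_glmm
from .io import load_study
from .scoring import ScoreTable, score_study
from .stats import (
    BootstrapResult,
    LmmResult,
    TestResult,
    bootstrap_item_grand_mean,
    exact_sign_test,
    fit_intercept_lmm,
    kendall_tau,
    one_sample_cohens_d,
    percentile_bootstrap_ci,
    wilcoxon_signed_rank,
)
from .timecourse import proportion_curve, smooth_curve
from .types import Experiment, Session
from .windowing import ClassifiedSession, classify_session, filter_subjects

log = logging.getLogger("gazelex")


@dataclass
class AnalysisConfig:
    """Settings for one analysis run; defaults are the standard settings."""

    experiment: Experiment = Experiment.NOUNS
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None
    bin_ms: float = 20.0
    bootstrap_reps: int = 10_000
    seed: int = 2024
    include_age_model: bool = True
    standardize_age: bool = True
    timecourse_grid_ms: float = 33.0
    timecourse_range_ms: tuple[float, float] = (-1000.0, 3500.0)
    loess_span: float = 0.25

    @property
    def random_effects(self) -> tuple[str, ...]:
        # the nouns design has 8 items, enough to estimate an item intercept;
        # the honorifics design (2 items) uses subject-only intercepts
        if self.experiment is Experiment.NOUNS:
            return ("subject", "item")
        return ("subject",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "experiment" in raw:
            raw["experiment"] = Experiment(str(raw["experiment"]).upper())
        if "timecourse_range_ms" in raw:
            raw["timecourse_range_ms"] = tuple(raw["timecourse_range_ms"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise GazelexError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["experiment"] = self.experiment.value
        d["timecourse_range_ms"] = list(self.timecourse_range_ms)
        return d


def paper_defaults(experiment: Experiment = Experiment.NOUNS) -> AnalysisConfig:
    """The preset reproducing the published analysis settings."""
    return AnalysisConfig(experiment=experiment)


@dataclass
class ResultBundle:
    config: AnalysisConfig
    audit: pd.DataFrame
    n_subjects_in: int
    n_subjects_retained: int
    scores: ScoreTable
    item_bootstrap: BootstrapResult
    subject_bootstrap: BootstrapResult
    item_wilcoxon: TestResult
    item_sign: TestResult
    subject_wilcoxon: TestResult
    subject_sign: TestResult
    item_cohens_d: float
    subject_cohens_d: float
    age_kendall: Optional[TestResult]
    lmm: LmmResult
    glmm_phase: GlmmResult
    glmm_age: Optional[GlmmResult]
    model_comparison: Optional[tuple[float, int, float]]
    timecourse: pd.DataFrame

    def run_manifest(self) -> dict:
        return {
            "gazelex_version": __version__,
            "config": self.config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(self.config.to_dict(), sort_keys=True).encode()
            ).hexdigest()[:16],
            "n_subjects_in": self.n_subjects_in,
            "n_subjects_retained": self.n_subjects_retained,
            "n_trials": int(len(self.audit)),
            "n_trials_excluded": int(self.audit["excluded"].sum()),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.audit.to_csv(outdir / "exclusion_audit.csv", index=False)
        self.scores.rows.to_csv(outdir / "pair_scores.csv", index=False)
        self.scores.item_means.rename("mean_score").to_csv(outdir / "item_means.csv")
        self.scores.subject_means.rename("mean_score").to_csv(
            outdir / "subject_means.csv"
        )
        self.glmm_phase.summary_frame().to_csv(
            outdir / "glmm_phase.csv", index=False
        )
        if self.glmm_age is not None:
            self.glmm_age.summary_frame().to_csv(
                outdir / "glmm_phase_age.csv", index=False
            )
        self.timecourse.to_csv(outdir / "timecourse.csv", index=False)
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(self.run_manifest(), fh, indent=2, sort_keys=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
        try:
            plot_timecourse(self.timecourse, outdir / "timecourse.png")
        except Exception as exc:  # plotting must never sink an analysis
            log.warning("timecourse figure not written: %s", exc)

    def summary(self) -> dict:
        item_means = self.scores.item_means
        subject_means = self.scores.subject_means
        out = {
            "item_grand_mean": self.scores.grand_item_mean,
            "item_ci": [self.item_bootstrap.ci_low, self.item_bootstrap.ci_high],
            "n_items_positive": int((item_means > 0).sum()),
            "n_items": int(len(item_means)),
            "item_wilcoxon_p": self.item_wilcoxon.p_value,
            "item_sign_p": self.item_sign.p_value,
            "item_cohens_d": self.item_cohens_d,
            "subject_grand_mean": self.scores.grand_subject_mean,
            "subject_ci": [
                self.subject_bootstrap.ci_low,
                self.subject_bootstrap.ci_high,
            ],
            "n_subjects_positive": int((subject_means > 0).sum()),
            "n_subjects_scored": int(len(subject_means)),
            "subject_wilcoxon_p": self.subject_wilcoxon.p_value,
            "subject_sign_p": self.subject_sign.p_value,
            "subject_cohens_d": self.subject_cohens_d,
            "lmm_intercept": self.lmm.intercept,
            "lmm_ci": [self.lmm.ci_low, self.lmm.ci_high],
            "lmm_t": self.lmm.t_value,
            "lmm_df": self.lmm.df,
            "lmm_lrt_chisq": self.lmm.lrt_chisq,
            "phase_or": self.glmm_phase.or_for("phase_post"),
            "phase_or_ci": [
                float(self.glmm_phase.or_ci_low[1]),
                float(self.glmm_phase.or_ci_high[1]),
            ],
            "phase_wald_chisq": float(self.glmm_phase.wald_chisq[1]),
        }
        if self.age_kendall is not None:
            out["age_kendall_tau"] = self.age_kendall.statistic
            out["age_kendall_p"] = self.age_kendall.p_value
        if self.model_comparison is not None:
            chisq, df, p = self.model_comparison
            out["age_model_lrt_chisq"] = chisq
            out["age_model_lrt_df"] = df
            out["age_model_lrt_p"] = p
        if self.glmm_age is not None:
            out["phase_age_or"] = self.glmm_age.or_for("phase_post:age")
        return out


def run_analysis(
    config: AnalysisConfig, sessions: Optional[Sequence[Session]] = None
) -> ResultBundle:
    """Execute the full pipeline on loaded sessions (or config.input_dir)."""
    if sessions is None:
        if config.input_dir is None:
            raise GazelexError("run_analysis needs sessions or config.input_dir")
        sessions = load_study(config.input_dir)
        log.info("loaded %d sessions from %s", len(sessions), config.input_dir)
    sessions = [s for s in sessions if s.experiment is config.experiment]
    if not sessions:
        raise GazelexError(f"no sessions for experiment {config.experiment.value}")

    classified = [classify_session(s) for s in sessions]
    retained, excluded, audit = filter_subjects(classified)
    log.info(
        "exclusions: %d/%d trials excluded; %d/%d subjects retained",
        int(audit["excluded"].sum()),
        len(audit),
        len(retained),
        len(classified),
    )
    if not retained:
        raise GazelexError("no subjects retained after exclusion")

    scores = score_study(retained)
    item_means = scores.item_means
    subject_means = scores.subject_means

    rng_seed = config.seed
    item_boot = bootstrap_item_grand_mean(
        scores.rows, n_reps=config.bootstrap_reps, seed=rng_seed
    )
    subject_boot = percentile_bootstrap_ci(
        subject_means.to_numpy(), n_reps=config.bootstrap_reps, seed=rng_seed + 1
    )
    item_wilcoxon = wilcoxon_signed_rank(item_means.to_numpy())
    item_sign = exact_sign_test(
        int((item_means > 0).sum()), int((item_means != 0).sum())
    )
    subject_wilcoxon = wilcoxon_signed_rank(subject_means.to_numpy())
    subject_sign = exact_sign_test(
        int((subject_means > 0).sum()), int((subject_means != 0).sum())
    )
    item_d = one_sample_cohens_d(item_means.to_numpy())
    subject_d = one_sample_cohens_d(subject_means.to_numpy())

    ages = {
        cs.session.subject.subject_id: cs.session.subject.age_months
        for cs in retained
    }
    age_kendall = None
    if len(subject_means) >= 3:
        age_kendall = kendall_tau(
            [ages[s] for s in subject_means.index], subject_means.to_numpy()
        )

    lmm = fit_intercept_lmm(scores.rows)

    counts = build_phase_counts(retained, bin_ms=config.bin_ms)
    glmm_phase = fit_phase_glmm(
        counts, include_age=False, random_effects=config.random_effects
    )
    glmm_age = None
    comparison = None
    if config.include_age_model:
        glmm_age = fit_phase_glmm(
            counts,
            include_age=True,
            random_effects=config.random_effects,
            standardize_age=config.standardize_age,
        )
        comparison = compare_models(glmm_phase, glmm_age)

    curve = proportion_curve(
        retained,
        grid_ms=config.timecourse_grid_ms,
        range_ms=config.timecourse_range_ms,
        seed=config.seed + 2,
    )
    curve = smooth_curve(curve, span=config.loess_span)

    bundle = ResultBundle(
        config=config,
        audit=audit,
        n_subjects_in=len(classified),
        n_subjects_retained=len(retained),
        scores=scores,
        item_bootstrap=item_boot,
        subject_bootstrap=subject_boot,
        item_wilcoxon=item_wilcoxon,
        item_sign=item_sign,
        subject_wilcoxon=subject_wilcoxon,
        subject_sign=subject_sign,
        item_cohens_d=item_d,
        subject_cohens_d=subject_d,
        age_kendall=age_kendall,
        lmm=lmm,
        glmm_phase=glmm_phase,
        glmm_age=glmm_age,
        model_comparison=comparison,
        timecourse=curve,
    )
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


def report_tables(bundle: ResultBundle) -> str:
    """Human-readable summary: marginal means, model terms, exclusion tallies."""
    lines = []
    s = bundle.summary()
    lines.append(f"Experiment: {bundle.config.experiment.value}")
    lines.append(
        f"Subjects: {bundle.n_subjects_retained}/{bundle.n_subjects_in} retained; "
        f"trials excluded: {int(bundle.audit['excluded'].sum())}/{len(bundle.audit)}"
    )
    reason_tally = (
        bundle.audit.loc[bundle.audit["reasons"] != "", "reasons"]
        .str.split(";")
        .explode()
        .value_counts()
    )
    for reason, n in reason_tally.items():
        lines.append(f"  {reason}: {n}")
    lines.append("")
    lines.append("Item means (difference score per word-pair):")
    lines.append(bundle.scores.item_means.round(4).to_string())
    lines.append(
        f"grand item mean = {s['item_grand_mean']:.3f} "
        f"95% CI [{s['item_ci'][0]:.3f}, {s['item_ci'][1]:.3f}], "
        f"{s['n_items_positive']}/{s['n_items']} positive, "
        f"Wilcoxon p = {s['item_wilcoxon_p']:.4g}, sign p = {s['item_sign_p']:.4g}, "
        f"d = {s['item_cohens_d']:.2f}"
    )
    lines.append("")
    lines.append("Subject means:")
    lines.append(bundle.scores.subject_means.round(4).to_string())
    lines.append(
        f"grand subject mean = {s['subject_grand_mean']:.3f} "
        f"95% CI [{s['subject_ci'][0]:.3f}, {s['subject_ci'][1]:.3f}], "
        f"{s['n_subjects_positive']}/{s['n_subjects_scored']} positive"
    )
    lines.append("")
    lines.append(
        f"LMM intercept = {s['lmm_intercept']:.3f} "
        f"[{s['lmm_ci'][0]:.3f}, {s['lmm_ci'][1]:.3f}], "
        f"t({s['lmm_df']:.2f}) = {s['lmm_t']:.2f}, "
        f"LRT chi2(1) = {s['lmm_lrt_chisq']:.2f}"
    )
    lines.append("")
    lines.append("Phase GLMM (binomial mixed logit):")
    lines.append(bundle.glmm_phase.summary_frame().round(4).to_string(index=False))
    if bundle.glmm_age is not None:
        lines.append("Phase + age GLMM:")
        lines.append(bundle.glmm_age.summary_frame().round(4).to_string(index=False))
        chisq, df, p = bundle.model_comparison
        lines.append(f"model comparison: chi2({df}) = {chisq:.2f}, p = {p:.4g}")
    return "\n".join(lines)


def plot_timecourse(curve: pd.DataFrame, path: str | Path) -> None:
    """Write the timecourse figure: points, CI band, loess overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.axvspan(367, 3500, color="0.92", zorder=0, label="analysis window")
    ax.axvline(0, color="crimson", lw=1.2, label="target-word onset")
    ax.axhline(0.5, color="0.6", lw=0.8, ls=":")
    ok = curve["proportion"].notna()
    ax.errorbar(
        curve.loc[ok, "t_ms"],
        curve.loc[ok, "proportion"],
        yerr=[
            (curve.loc[ok, "proportion"] - curve.loc[ok, "ci_low"]).clip(lower=0),
            (curve.loc[ok, "ci_high"] - curve.loc[ok, "proportion"]).clip(lower=0),
        ],
        fmt="o",
        ms=3,
        lw=0.6,
        alpha=0.6,
        color="steelblue",
    )
    if "smoothed" in curve:
        ax.plot(curve["t_ms"], curve["smoothed"], color="navy", lw=2)
    ax.set_xlabel("time from target-word onset (ms)")
    ax.set_ylabel("proportion looking to target")
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
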