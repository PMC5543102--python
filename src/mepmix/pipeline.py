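"""End-to-end run: simulate/load -> preprocess -> PDE -> GMM -> classify -> ABC -> stats.

One seed governs the run and fans out to per-stage child seeds by fixed
offsets, so each stage is independently reproducible.  All artifacts are
plain text (CSV / key-value model file / JSON report) and a run is
byte-identical given the same config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .abc_analysis import abc_partition, abc_responders, ltd_transform, partition_to_frame
from .cohort import BASELINE_BLOCKS, GeneratorConfig, generate_cohort
from .cohort_stats import DegenerateDataError, paired_t, posthoc_vs_baseline
from .mixture import rmse_to_pde, save_model, select_components
from .pde import pde
from .preprocess import filter_trials, summarize_cohort, timecourses_to_frame
from .subgroups import assignments_to_frame, classify_cohort, decision_boundaries

__all__ = ["PipelineError", "run_pipeline"]

# fixed offsets of the per-stage child seeds
_SEED_OFFSET_GENERATE = 0
_SEED_OFFSET_FIT = 1009


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(message)
        self.stage = stage


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError(name, f"stage '{name}' failed: {exc}") from exc
    return wrap


def _baseline_block_test(trials: pd.DataFrame):
    """Paired t of per-subject B1 vs B2 block means (baseline equivalence)."""
    means = (
        trials[trials["block"].isin(BASELINE_BLOCKS)]
        .groupby(["subject_id", "block"])["amplitude_mv"].mean().unstack()
    )
    try:
        res = paired_t(means["B1"], means["B2"])
        return {"t": res.statistic, "df": res.df, "p": res.p}
    except (DegenerateDataError, ValueError):
        return None


def run_pipeline(
    out_dir,
    *,
    input_csv=None,
    config: GeneratorConfig | None = None,
    simulate: bool = False,
    seed: int = 0,
    m_max: int = 4,
    alpha: float = 0.05,
    lr_df: int = 1,
    n_grid: int = 256,
) -> dict:
    """Run the full analysis and write its artifacts under ``out_dir``.

    Either ``input_csv`` (long-format trial CSV) or ``simulate=True`` with
    a :class:`GeneratorConfig` must be given.  Writes subjects.csv,
    model.txt, assignments.csv, abc.csv, pde.csv and report.json; returns
    the report as a dict.  On any stage failure the partial outputs are
    removed and :class:`PipelineError` is raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    try:
        # --- input ------------------------------------------------------
        if simulate:
            cfg = config or GeneratorConfig()
            cfg = GeneratorConfig(**{**cfg.to_dict(), "seed": seed + _SEED_OFFSET_GENERATE})
            trials, truth = _stage("simulate")(generate_cohort, cfg)
            emit("trials.csv", lambda p: trials.to_csv(p, index=False))
            emit("ground_truth.csv", lambda p: truth.to_csv(p, index=False))
            config_echo = cfg.to_dict()
        elif input_csv is not None:
            trials = _stage("load")(pd.read_csv, input_csv)
            config_echo = {"input_csv": str(input_csv)}
        else:
            raise PipelineError("input", "either input_csv or simulate=True is required")

        # --- preprocess ---------------------------------------------------
        filtered = _stage("preprocess")(filter_trials, trials)
        timecourses = _stage("preprocess")(summarize_cohort, filtered, True)
        subjects = timecourses_to_frame(timecourses)
        emit("subjects.csv", lambda p: subjects.to_csv(p, index=False))
        overall = subjects["overall_change_pct"].to_numpy()

        # --- density ------------------------------------------------------
        density = _stage("density")(pde, overall, n_grid)
        emit("pde.csv", lambda p: pd.DataFrame(
            {"grid_pct": density.grid, "density": density.density}).to_csv(p, index=False))

        # --- mixture fit + selection -------------------------------------
        selection = _stage("fit")(
            select_components, overall,
            M_max=m_max, alpha=alpha, df=lr_df, seed=seed + _SEED_OFFSET_FIT,
        )
        fit = selection.chosen
        emit("model.txt", lambda p: save_model(fit, p))

        # --- classification ----------------------------------------------
        assignments = _stage("classify")(classify_cohort, fit.model, timecourses)
        emit("assignments.csv", lambda p: assignments_to_frame(assignments).to_csv(p, index=False))
        limits = (
            list(decision_boundaries(fit.model).limits) if fit.model.M >= 2 else []
        )
        label_counts = {}
        for a in assignments:
            label_counts[a.label] = label_counts.get(a.label, 0) + 1

        # --- ABC analysis -------------------------------------------------
        ltd = _stage("abc")(ltd_transform, timecourses)
        try:
            partition = abc_partition(ltd)
            emit("abc.csv", lambda p: partition_to_frame(ltd, partition).to_csv(p, index=False))
            abc_report = {
                "set_A": sorted(partition.set_A),
                "set_B": sorted(partition.set_B),
                "set_C": sorted(partition.set_C),
                "responders": sorted(abc_responders(partition)),
            }
        except ValueError as exc:
            abc_report = {"error": str(exc)}

        # --- stats --------------------------------------------------------
        stats_report: dict = {"baseline_b1_vs_b2": _baseline_block_test(filtered)}
        by_label: dict[str, list] = {}
        for a, tc in zip(assignments, timecourses):
            by_label.setdefault(a.label, []).append(tc)
        posthoc = {}
        for label, group in sorted(by_label.items()):
            if len(group) < 2:
                posthoc[label] = {"error": "subgroup too small for paired tests"}
                continue
            try:
                res = posthoc_vs_baseline(group)
                posthoc[label] = {
                    blk: {"t": r.statistic, "df": r.df, "p": r.p} for blk, r in res.items()
                }
            except (DegenerateDataError, ValueError) as exc:
                posthoc[label] = {"error": str(exc)}
        stats_report["posthoc_vs_baseline"] = posthoc

        # --- report -------------------------------------------------------
        report = {
            "software": {"name": "mepmix", "version": __version__},
            "seed": seed,
            "child_seeds": {
                "generate": seed + _SEED_OFFSET_GENERATE,
                "fit": seed + _SEED_OFFSET_FIT,
            },
            "config": config_echo,
            "n_subjects": int(len(timecourses)),
            "pareto_radius_pct": density.pareto_radius,
            "chosen_M": selection.chosen_M,
            "lr_statistics": {str(k): v for k, v in selection.lr_statistics.items()},
            "lr_threshold": selection.threshold,
            "components": [
                {"m": c.m, "s": c.s, "w": c.w} for c in fit.model.components
            ],
            "loglik": fit.loglik,
            "rmse_to_pde": rmse_to_pde(fit.model, density),
            "decision_limits_pct": limits,
            "subgroup_counts": dict(sorted(label_counts.items())),
            "assignments": [
                {
                    "subject_id": a.subject_id,
                    "overall_change_pct": a.overall_change_pct,
                    "label": a.label,
                }
                for a in assignments
            ],
            "abc": abc_report,
            "stats": stats_report,
        }
        emit("report.json", lambda p: p.write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"))
        return report
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
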