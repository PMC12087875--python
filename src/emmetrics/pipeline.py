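"""End-to-end reproduction pipeline.

Chains the stages in study order — simulate (or load) a cohort, derive the
optics, summarise, fit the 1-D refractive bigaussian, fit the 5-D mixture,
calibrate the ellipse scale against the 1-D weights, classify, regress,
count uniqueness pairs, profile the relative geometry — and writes every
artifact (CSV, JSON, PNG, Markdown report) into one output directory.

All randomness flows from ``config.seed``; a given config and seed produce
byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__, analysis, classify, cohort, optics
from .bigaussian import (
    BIOMETRY_DIMENSIONS,
    eval_bigaussian,
    fit_bigaussian_1d,
    fit_multivariate_bigaussian,
)
from .io import RunConfig, config_hash, write_cohort
from .schema import SUBGROUP_COLUMN

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs were retained."""


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory.

    On a stage failure the partial outputs are kept, a ``failure.json``
    manifest records the failed stage and traceback, and a
    :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "failure.json").unlink(missing_ok=True)
    meta = {"version": __version__, "config_hash": config_hash(config),
            "seed": config.seed, "config": config.to_dict(), "stages": []}
    stage = "init"
    log: dict = {}
    try:
        # -- cohort ----------------------------------------------------------
        stage = "cohort"
        if config.input_csv:
            from .io import read_cohort
            raw = read_cohort(config.input_csv)
            log["cohort"] = {"source": str(config.input_csv), "n": len(raw)}
        else:
            spec = cohort.CohortSpec(n=config.n, seed=config.seed, mode=config.mode)
            syn = cohort.generate_cohort(spec)
            raw = syn.data
            validation = cohort.validate_cohort(syn)
            _dump({"checks": [{"name": n, "passed": ok, "detail": d}
                              for n, ok, d in validation.checks],
                   "info": validation.info}, out / "cohort_validation.json")
            log["cohort"] = {"source": "synthetic", "n": len(raw),
                             "rejection_rate": syn.rejection_rate}
        write_cohort(raw, out / "cohort.csv")
        meta["stages"].append(stage)

        # -- optics ----------------------------------------------------------
        stage = "derive"
        derived, exclusions = optics.derive_all(raw)
        write_cohort(derived, out / "derived.csv")
        _dump({"n_in": len(raw), "n_out": len(derived),
               "exclusions": [{"eye_id": e, "reason": r} for e, r in exclusions]},
              out / "exclusions.json")
        log["derive"] = {"n_in": len(raw), "n_out": len(derived)}
        meta["stages"].append(stage)

        # -- descriptives ----------------------------------------------------
        stage = "descriptives"
        criterion = analysis.EmmetropiaCriterion(*config.emmetropia_bounds)
        table = analysis.descriptive_table(derived, criterion)
        table.to_csv(out / "descriptive_table.csv")
        corr = analysis.correlation_matrix(derived)
        corr.r.to_csv(out / "correlations_r.csv")
        corr.p.to_csv(out / "correlations_p.csv")
        binned = analysis.binned_group_summary(derived)
        binned.to_csv(out / "binned_summary.csv", index=False)
        meta["stages"].append(stage)

        # -- refractive bigaussian ------------------------------------------
        stage = "fit-se"
        se_fit = fit_bigaussian_1d(
            derived["SE_D"].to_numpy(float),
            half_range=config.se_fit_half_range,
            bin_width=config.se_fit_bin_width,
            random_state=config.seed,
        )
        _dump({"params": {k: getattr(se_fit.params, k)
                          for k in ("a1", "mu1", "sigma1", "a2", "mu2", "sigma2")},
               "r2": se_fit.r2,
               "weights": list(se_fit.weights),
               "n_in_range": se_fit.histogram.n_in_range}, out / "se_fit.json")
        meta["stages"].append(stage)

        # -- multivariate mixture -------------------------------------------
        stage = "fit-biometry"
        X = derived[list(BIOMETRY_DIMENSIONS)].to_numpy(float)
        in_range = np.abs(X[:, 0]) <= config.se_fit_half_range
        mix = fit_multivariate_bigaussian(
            X[in_range], restarts=config.restarts, seed=config.seed
        )
        _dump({"dimensions": list(mix.dimensions), "weights": mix.weights,
               "means": mix.means, "covariances": mix.covariances,
               "log_likelihood": mix.log_likelihood, "aic": mix.aic,
               "n": int(in_range.sum())}, out / "mixture_fit.json")
        meta["stages"].append(stage)

        # -- classification --------------------------------------------------
        stage = "classify"
        eps, achieved = classify.calibrate_epsilon(
            X[in_range], mix, target_regulated_fraction=se_fit.weights[0],
            bracket=config.epsilon_bracket,
        )
        cls = classify.classify_cohort(X, mix, eps)
        classified = derived.copy()
        classified[SUBGROUP_COLUMN] = cls.labels
        write_cohort(classified, out / "classified.csv")
        emm = analysis.emmetropic_mask(derived, criterion)
        reg = cls.labels == classify.REGULATED
        summary = cls.summary()
        summary.update({
            "target_regulated_fraction": se_fit.weights[0],
            "achieved_on_fit_subset": achieved,
            "regulated_not_emmetropic_fraction":
                float(np.mean(~emm[reg])) if reg.any() else float("nan"),
            "emmetropic_regulated_fraction":
                float(np.mean(reg[emm])) if emm.any() else float("nan"),
            "emmetropic_dysregulated_fraction":
                float(np.mean(~reg[emm])) if emm.any() else float("nan"),
        })
        _dump(summary, out / "classification.json")
        meta["stages"].append(stage)

        # -- regressions -----------------------------------------------------
        stage = "regressions"
        regs = analysis.fit_alignment_regressions(derived, config.al_window)
        _dump({"ACD_tot": regs.acd_tot._asdict(), "ASL": regs.asl._asdict()},
              out / "regressions.json")
        regs.group_slopes.to_csv(out / "group_slopes.csv", index=False)
        meta["stages"].append(stage)

        # -- uniqueness ------------------------------------------------------
        stage = "uniqueness"
        uspec = analysis.UniquenessSpec(
            parameters=config.uniqueness_parameters,
            repeatabilities=config.uniqueness_repeatabilities,
            limit_factor=config.uniqueness_limit_factor,
        )
        n_pairs, pairs = analysis.uniqueness_pairs(derived, uspec, subset=emm)
        _dump({"n_pairs": n_pairs,
               "pairs": [[str(a), str(b)] for a, b in pairs],
               "subset": "emmetropic", "n_eyes": int(emm.sum())},
              out / "uniqueness.json")
        meta["stages"].append(stage)

        # -- relative scaling ------------------------------------------------
        stage = "scaling"
        profile = analysis.relative_scaling_profile(derived, include_effectivity=True)
        profile.to_csv(out / "scaling.csv", index=False)
        meta["stages"].append(stage)

        # -- figures ---------------------------------------------------------
        if config.make_figures:
            stage = "figures"
            _figures(out, derived, binned, se_fit, cls, emm)
            meta["stages"].append(stage)

        # -- report ----------------------------------------------------------
        stage = "report"
        _report(out, config, log, table, se_fit, summary, regs, n_pairs)
        meta["stages"].append(stage)

        _dump(meta, out / "manifest.json")
        return out
    except Exception as exc:
        _dump({"failed_stage": stage, "error": str(exc),
               "traceback": traceback.format_exc(), "completed": meta["stages"]},
              out / "failure.json")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _figures(out: Path, derived, binned, se_fit, cls, emm) -> None:
    # refractive distribution and its bigaussian fit
    fig, ax = plt.subplots(figsize=(6, 4))
    h = se_fit.histogram
    ax.bar(h.centers, h.proportions, width=h.bin_width * 0.9, color="0.8",
           label="observed proportion")
    xx = np.linspace(h.centers[0], h.centers[-1], 400)
    ax.plot(xx, eval_bigaussian(se_fit.params, xx), "r-", label="bigaussian fit")
    ax.set_xlabel("SE (D)")
    ax.set_ylabel("proportion per bin")
    ax.legend()
    fig.savefig(out / "fig_se_fit.png", dpi=110)
    plt.close(fig)

    # biometry vs refractive bin
    params = ["P_c_D", "P_lb_D", "ACD_tot_mm", "AL_mm"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, par in zip(axes.ravel(), params):
        sub = binned[binned["parameter"] == par]
        ax.errorbar(sub["bin_center"], sub["mean"],
                    yerr=[sub["mean"] - sub["ci_low"], sub["ci_high"] - sub["mean"]],
                    fmt="ko", ms=3, capsize=2)
        ax.set_title(par)
    for ax in axes[1]:
        ax.set_xlabel("SE bin (D)")
    fig.tight_layout()
    fig.savefig(out / "fig_binned.png", dpi=110)
    plt.close(fig)

    # pairwise scatter with subgroup colours (two illustrative pairs)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    reg = cls.labels == "Regulated"
    for ax, (xc, yc) in zip(axes, [("AL_mm", "P_lb_D"), ("P_c_D", "P_lb_D")]):
        ax.scatter(derived[xc][~reg], derived[yc][~reg], s=4, c="k",
                   alpha=0.4, label="Dysregulated")
        ax.scatter(derived[xc][reg], derived[yc][reg], s=4, c="r",
                   alpha=0.4, label="Regulated")
        ax.set_xlabel(xc)
        ax.set_ylabel(yc)
    axes[0].legend(markerscale=3)
    fig.tight_layout()
    fig.savefig(out / "fig_subgroups.png", dpi=110)
    plt.close(fig)


def _report(out: Path, config, log, table, se_fit, summary, regs, n_pairs) -> None:
    lines = [
        "# Cohort reproduction report",
        "",
        f"- package version: {__version__}",
        f"- config hash: {config_hash(config)}",
        f"- seed: {config.seed}",
        f"- cohort: {log['cohort']}",
        "",
        "## Refractive bigaussian fit",
        "",
        f"- weights (Regulated/Dysregulated): "
        f"{100 * se_fit.weights[0]:.1f}% / {100 * se_fit.weights[1]:.1f}%",
        f"- narrow component: mu = {se_fit.params.mu1:.3f} D, "
        f"sigma = {se_fit.params.sigma1:.3f} D",
        f"- broad component: mu = {se_fit.params.mu2:.3f} D, "
        f"sigma = {se_fit.params.sigma2:.3f} D",
        f"- r2 = {se_fit.r2:.4f}",
        "",
        "## Subgroup classification",
        "",
        f"- calibrated epsilon = {summary['epsilon']:.3f} "
        f"(1-D coverage {100 * summary['coverage_1d']:.2f}%, "
        f"single-ellipse 2-D coverage {100 * summary['coverage_2d_single_ellipse']:.2f}%)",
        f"- Regulated fraction = {100 * summary['regulated_fraction']:.1f}%",
        f"- emmetropic eyes classified Regulated: "
        f"{100 * summary['emmetropic_regulated_fraction']:.2f}%",
        f"- Regulated eyes that are not emmetropic: "
        f"{100 * summary['regulated_not_emmetropic_fraction']:.2f}%",
        "",
        "## Anterior-segment alignment",
        "",
        f"- ACD_tot = {regs.acd_tot.slope:.4f} AL + {regs.acd_tot.intercept:+.4f} "
        f"(r2 = {regs.acd_tot.r2:.3f}, residual SD = {regs.acd_tot.residual_sd:.2f} mm)",
        f"- ASL = {regs.asl.slope:.4f} AL + {regs.asl.intercept:+.4f} "
        f"(r2 = {regs.asl.r2:.3f}, residual SD = {regs.asl.residual_sd:.2f} mm)",
        "",
        "## Uniqueness",
        "",
        f"- indistinguishable emmetropic pairs at limits of agreement: {n_pairs}",
        "",
        "## Artifacts",
        "",
    ]
    lines += [f"- `{p.name}`" for p in sorted(out.iterdir()) if p.suffix in
              (".csv", ".json", ".png") and p.name != "manifest.json"]
    (out / "report.md").write_text("\n".join(lines) + "\n")
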