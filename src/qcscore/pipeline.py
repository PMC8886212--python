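"""Full analysis orchestration: one ratings table in, a report bundle out.

Reproduces the study's analysis sequence on any long-format rating table
(real or synthetic): (1) the overall manual-vs-automated comparison from the
random-intercept proportional-odds model, (2) the per-rater paired Wilcoxon
table, (3) inter-rater AC2 reliability per method and combined with
probabilistic benchmarks and a coefficient comparison, (4) subgroup odds
ratios by contour type and slice level within each method plus
method-interaction tests, and (5) per-pathology method odds ratios.

The orchestrator computes nothing itself: every number in the report is the
return value of one operation in the ratings/paired/agreement/ordinal
modules.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import agreement as agr
from . import ordinal, paired
from .ratings import RatingDataset, read_ratings, stratify

logger = logging.getLogger("qcscore")

DEFAULT_OPTIONS: Mapping = {
    "weight_family": "ordinal",
    "ci_level": 0.95,
    "benchmark_threshold": 0.95,
    "zero_method": "wilcox",
    "comparison_mode": "independent",
    "subgroup_factors": ("contour_type", "slice_level"),
    "holm": False,
    "min_images_for_random_effect": 3,
    "n_quadrature": 15,
}


class PipelineError(Exception):
    """A stage failed; the message names the stage."""


@dataclass
class AnalysisReport:
    overall: pd.DataFrame
    wilcoxon: pd.DataFrame
    agreement: pd.DataFrame
    agreement_comparison: pd.DataFrame
    subgroup_or: dict[str, pd.DataFrame]
    interactions: pd.DataFrame
    pathology_or: pd.DataFrame
    settings: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.overall.to_csv(os.path.join(out_dir, "overall_model.csv"))
        self.wilcoxon.to_csv(os.path.join(out_dir, "per_rater_wilcoxon.csv"), index=False)
        self.agreement.to_csv(os.path.join(out_dir, "agreement.csv"), index=False)
        self.agreement_comparison.to_csv(
            os.path.join(out_dir, "agreement_comparison.csv"), index=False
        )
        for factor, table in self.subgroup_or.items():
            table.to_csv(os.path.join(out_dir, f"subgroup_or_{factor}.csv"))
        self.interactions.to_csv(os.path.join(out_dir, "interaction_tests.csv"), index=False)
        self.pathology_or.to_csv(os.path.join(out_dir, "pathology_or.csv"), index=False)
        with open(os.path.join(out_dir, "settings.json"), "w") as fh:
            json.dump(self.settings, fh, indent=1, default=str)


def _holm(pvalues: pd.Series) -> pd.Series:
    """Holm step-down adjustment (monotone, family = the given series)."""
    p = pvalues.to_numpy(float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return pd.Series(adj, index=pvalues.index)


def _fit_method_or(
    ds: RatingDataset, options: Mapping, label: str
) -> tuple[pd.DataFrame, str]:
    """Method odds ratio for one (sub)dataset, degrading gracefully.

    Falls back to a plain ordered logit when too few images are present to
    identify an image-level random intercept.
    """
    n_images = ds.df["image_id"].nunique()
    random = "image_id" if n_images >= options["min_images_for_random_effect"] else None
    spec = ordinal.ModelSpec(
        fixed_effects=("method", "rater"),
        random_intercept=random,
        n_quadrature=options["n_quadrature"],
    )
    try:
        fit_res = ordinal.fit(spec, ds)
        table = ordinal.odds_ratios(fit_res, ["method[automated]"])
        note = "" if random else "plain ordered logit (too few images)"
        if not fit_res.converged:
            note = (note + "; " if note else "") + "optimizer did not fully converge"
        return table, note
    except (ordinal.FitError, KeyError, np.linalg.LinAlgError) as exc:
        empty = pd.DataFrame(
            [("method[automated]", *[np.nan] * 6)],
            columns=["term", "beta", "se", "or", "ci_low", "ci_high", "pvalue"],
        ).set_index("term")
        return empty, f"fit failed for {label}: {exc}"


def run_analysis(
    ratings,
    config: Mapping | None = None,
    out_dir: str | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Run the full analysis and optionally write the report bundle.

    ``ratings`` is a CSV path or an in-memory :class:`RatingDataset`.
    ``config`` overrides any key of :data:`DEFAULT_OPTIONS`.  The analysis is
    deterministic given its inputs; ``seed`` is recorded in the settings log
    for provenance of upstream simulation steps.
    """
    options = dict(DEFAULT_OPTIONS)
    if config:
        options.update({k: v for k, v in config.items() if k in DEFAULT_OPTIONS})
    ds = ratings if isinstance(ratings, RatingDataset) else read_ratings(ratings)
    logger.info("loaded %d ratings from %d raters", len(ds), len(ds.raters))

    # stage 1: overall mixed ordinal model -------------------------------
    try:
        spec = ordinal.ModelSpec(
            fixed_effects=("method", "rater"),
            n_quadrature=options["n_quadrature"],
        )
        overall_fit = ordinal.fit(spec, ds)
        overall = ordinal.odds_ratios(overall_fit)
        overall.attrs["sigma_u"] = overall_fit.sigma_u
        overall.attrs["loglik"] = overall_fit.loglik
    except Exception as exc:
        raise PipelineError(f"overall-model stage failed: {exc}") from exc

    # stage 2: per-rater Wilcoxon ----------------------------------------
    try:
        wilcoxon = paired.per_rater_table(ds, zero_method=options["zero_method"])
    except Exception as exc:
        raise PipelineError(f"paired-test stage failed: {exc}") from exc

    # stage 3: reliability ------------------------------------------------
    try:
        by_method = stratify(ds, "method")
        estimates: dict[str, agr.AgreementEstimate] = {}
        agreement_rows = []
        for label, sub in [("combined", ds)] + sorted(by_method.items()):
            est = agr.agreement_from_dataset(
                sub,
                family=options["weight_family"],
                ci_level=options["ci_level"],
            )
            bench = agr.benchmark(est, threshold=options["benchmark_threshold"])
            estimates[label] = est
            agreement_rows.append(
                {
                    "subset": label,
                    "ac2": est.coefficient,
                    "pa": est.pa,
                    "pe": est.pe,
                    "se": est.se,
                    "ci_low": est.ci[0],
                    "ci_high": est.ci[1],
                    "n_subjects": est.n_subjects,
                    "benchmark": bench.label,
                    "p_very_good": bench.memberships.get("very good", np.nan),
                }
            )
        agreement_table = pd.DataFrame(agreement_rows)
        comparison_rows = []
        if {"manual", "automated"} <= set(by_method):
            comp = agr.compare_coefficients(
                estimates["automated"], estimates["manual"],
                mode=options["comparison_mode"],
            )
            comparison_rows.append(
                {
                    "contrast": "automated - manual",
                    "diff": comp.diff,
                    "se": comp.se_diff,
                    "z": comp.z,
                    "pvalue": comp.pvalue,
                    "mode": comp.mode,
                }
            )
        agreement_comparison = pd.DataFrame(
            comparison_rows,
            columns=["contrast", "diff", "se", "z", "pvalue", "mode"],
        )
    except Exception as exc:
        raise PipelineError(f"agreement stage failed: {exc}") from exc

    # stage 4: subgroup ORs by factor, within method, plus interactions ---
    subgroup_or: dict[str, pd.DataFrame] = {}
    interaction_rows = []
    try:
        for factor in options["subgroup_factors"]:
            tables = []
            for method, sub in sorted(by_method.items()):
                n_images = sub.df["image_id"].nunique()
                random = (
                    "image_id"
                    if n_images >= options["min_images_for_random_effect"]
                    else None
                )
                fspec = ordinal.ModelSpec(
                    fixed_effects=(factor, "rater"),
                    random_intercept=random,
                    n_quadrature=options["n_quadrature"],
                )
                ftab = ordinal.odds_ratios(ordinal.fit(fspec, sub))
                ftab = ftab[ftab.index.str.startswith(f"{factor}[")].copy()
                ftab.insert(0, "method", method)
                tables.append(ftab)
            table = pd.concat(tables)
            if options["holm"]:
                table["pvalue_holm"] = _holm(table["pvalue"])
            subgroup_or[factor] = table

            ispec = ordinal.ModelSpec(
                fixed_effects=("method", "rater", factor),
                n_quadrature=options["n_quadrature"],
            )
            lrt = ordinal.interaction_test(ispec, ds, ("method", factor))
            interaction_rows.append(
                {
                    "interaction": f"method x {factor}",
                    "statistic": lrt.statistic,
                    "df": lrt.df,
                    "pvalue": lrt.pvalue,
                }
            )
    except Exception as exc:
        raise PipelineError(f"subgroup stage failed: {exc}") from exc
    interactions = pd.DataFrame(
        interaction_rows, columns=["interaction", "statistic", "df", "pvalue"]
    )

    # stage 5: per-pathology method ORs -----------------------------------
    try:
        pathology_rows = []
        for pathology, sub in sorted(stratify(ds, "pathology").items()):
            table, note = _fit_method_or(sub, options, pathology)
            row = table.loc["method[automated]"]
            pathology_rows.append(
                {
                    "pathology": pathology,
                    "n_ratings": len(sub),
                    "n_images": sub.df["image_id"].nunique(),
                    "or": row["or"],
                    "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"],
                    "pvalue": row["pvalue"],
                    "note": note,
                }
            )
        pathology_or = pd.DataFrame(pathology_rows)
        if options["holm"] and len(pathology_or):
            pathology_or["pvalue_holm"] = _holm(pathology_or["pvalue"].fillna(1.0))
    except Exception as exc:
        raise PipelineError(f"pathology stage failed: {exc}") from exc

    settings = {
        "options": {k: options[k] for k in sorted(options)},
        "seed": seed,
        "n_ratings": len(ds),
        "raters": list(ds.raters),
        "overall_sigma_u": overall.attrs.get("sigma_u"),
        "overall_loglik": overall.attrs.get("loglik"),
    }
    report = AnalysisReport(
        overall=overall,
        wilcoxon=wilcoxon,
        agreement=agreement_table,
        agreement_comparison=agreement_comparison,
        subgroup_or=subgroup_or,
        interactions=interactions,
        pathology_or=pathology_or,
        settings=settings,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
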