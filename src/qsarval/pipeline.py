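"""End-to-end pipeline: fit, validate and report on a flagged molecule table.

Runs the whole modelling-and-validation sequence — linear and quadratic OLS
fits, coefficient and ANOVA tables, external validation, leave-one-out
cross-validation, Y-randomization, applicability domain — and writes the
result bundle (CSV tables, a JSON acceptance report and a Williams plot) to
an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import QsarDataset, split
from .domain import williams_analysis
from .regression import (
    anova,
    build_poly_design,
    coefficient_table,
    fit_metrics,
    fit_ols,
    predict,
)
from .validation import (
    GTReport,
    golbraikh_tropsha,
    q2_loo,
    r2_external,
    r2_test,
    y_randomization,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("qsarval")


@dataclass
class RunConfig:
    """Pipeline switches: which models and validation stages to run."""

    model: str = "both"             # mlr | mnlr | both
    loo: bool = True
    external: bool = True
    yrand: bool = True
    ad: bool = True
    gt: bool = True
    n_randomizations: int = 100
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self):
        if self.model not in ("mlr", "mnlr", "both"):
            raise ValueError(f"unknown model kind {self.model!r}")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, keyed the way the reports are."""

    mlr: object = None
    mnlr: object = None
    metrics: dict = field(default_factory=dict)
    predictions: pd.DataFrame | None = None
    crossval: object = None
    randomization: object = None
    domain: object = None
    gt_report: GTReport | None = None

    @property
    def passed(self) -> bool:
        return self.gt_report.passed if self.gt_report is not None else True


def run_pipeline(dataset: QsarDataset, config: RunConfig | None = None) -> PipelineResult:
    """Run the modelling-and-validation sequence on a flagged dataset.

    The training partition fits the models; the non-outlier test partition
    drives external validation; validation statistics (always computed from
    the linear model, for comparability) feed the Golbraikh–Tropsha report.
    Writes the report bundle when ``config.out_dir`` is set.
    """
    config = config or RunConfig()
    result = PipelineResult()
    train, test = split(dataset, drop_outliers=True)
    X_train, y_train = train.X, train.y
    log.info("pipeline v%s seed=%d: n_train=%d n_test=%d",
             __version__, config.seed, len(train), len(test))

    do_mlr = config.model in ("mlr", "both")
    do_mnlr = config.model in ("mnlr", "both")

    if do_mlr:
        result.mlr = fit_ols(X_train, y_train)
        result.metrics["mlr"] = fit_metrics(result.mlr)
    poly_spec = None
    if do_mnlr:
        Xq, poly_spec = build_poly_design(X_train)
        result.mnlr = fit_ols(Xq, y_train)
        result.metrics["mnlr"] = fit_metrics(result.mnlr)
        result.metrics["mnlr"]["squared_terms"] = list(poly_spec.squared_terms)

    # per-molecule predictions (observed, fitted, cross-validated)
    preds = pd.DataFrame({"observed": dataset.y})
    preds["subset"] = [r.subset for r in dataset.records]
    X_all = dataset.X
    if do_mlr:
        preds["predicted_mlr"] = predict(result.mlr, X_all)
    if do_mnlr:
        X_all_q, _ = build_poly_design(X_all, spec=poly_spec)
        preds["predicted_mnlr"] = [
            float(v) for v in predict(result.mnlr, X_all_q)
        ]
    base = result.mlr if do_mlr else result.mnlr

    if config.loo:
        Xcv = X_train if do_mlr else build_poly_design(X_train)[0]
        result.crossval = q2_loo(Xcv, y_train)
        cv = result.crossval.to_frame(ids=train.ids)["predicted_cv"]
        preds = preds.join(cv)
        log.info("LOO Q2cv = %.6f", result.crossval.q2)

    external: dict[str, float] = {}
    if config.external and len(test) > 0:
        if do_mlr:
            p = predict(result.mlr, test.X)
            external["mlr"] = r2_external(test.y, p)
            external["mlr_pred_formula"] = r2_test(
                result.mlr, test.X, test.y, float(y_train.mean())
            )
        if do_mnlr:
            Xq_test, _ = build_poly_design(test.X, spec=poly_spec)
            p = predict(result.mnlr, Xq_test)
            external["mnlr"] = r2_external(test.y, p)
        result.metrics["external_r2"] = external
        log.info("external R2: %s", external)

    if config.yrand:
        Xr = X_train if do_mlr else build_poly_design(X_train)[0]
        result.randomization = y_randomization(
            Xr, y_train, n_runs=config.n_randomizations, seed=config.seed
        )
        log.info(
            "Y-randomization: avg R2 = %.4f, avg Q2 = %.4f, cR2p = %.4f",
            result.randomization.avg_R2,
            result.randomization.avg_Q2,
            result.randomization.crp2,
        )

    if config.ad:
        result.domain = williams_analysis(dataset, model=base)
        log.info("AD: h* = %.4f, outliers = %s",
                 result.domain.h_star, result.domain.outlier_ids)

    if config.gt:
        if not (config.loo and config.yrand and config.external and len(test)):
            raise ValueError(
                "Golbraikh-Tropsha report needs loo, external and yrand stages"
            )
        key = "mlr" if do_mlr else "mnlr"
        m = result.metrics[key]
        result.gt_report = golbraikh_tropsha(
            {
                "R2": m["R2"],
                "R2_adj": m["R2_adj"],
                "R2_test": external[key],
                "Q2_cv": result.crossval.q2,
                "avg_R2_rand": result.randomization.avg_R2,
                "avg_Q2_rand": result.randomization.avg_Q2,
                "cR2p": result.randomization.crp2,
            }
        )
        log.info("GT report: %s", "PASS" if result.gt_report.passed else "FAIL")

    result.predictions = preds
    if config.out_dir is not None:
        _write_bundle(result, config, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    base = result.mlr if result.mlr is not None else result.mnlr
    coefficient_table(base).to_csv(out / "coefficients.csv")
    anova(base).to_csv(out / "anova.csv")
    result.predictions.to_csv(out / "predictions.csv")
    if result.randomization is not None:
        result.randomization.to_frame().to_csv(out / "yrand.csv")
    if result.gt_report is not None:
        payload = result.gt_report.to_json_dict()
        payload["seed"] = config.seed
        payload["version"] = __version__
        (out / "gt_report.json").write_text(json.dumps(payload, indent=1))
    if result.domain is not None:
        result.domain.to_frame().to_csv(out / "domain.csv")
        _williams_plot(result.domain, out / "williams.png")
    log.info("report bundle written to %s", out)


def _williams_plot(domain, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    frame = domain.to_frame()
    in_dom = frame["classification"] == "in_domain"
    ax.scatter(frame.loc[in_dom, "leverage"], frame.loc[in_dom, "std_residual"],
               s=25, label="in domain")
    if (~in_dom).any():
        ax.scatter(frame.loc[~in_dom, "leverage"],
                   frame.loc[~in_dom, "std_residual"],
                   s=30, color="crimson", label="outlier")
        for mid, row in frame[~in_dom].iterrows():
            ax.annotate(str(mid), (row["leverage"], row["std_residual"]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.axvline(domain.h_star, ls="--", color="grey")
    ax.axhline(3, ls=":", color="grey")
    ax.axhline(-3, ls=":", color="grey")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.set_title(f"Williams plot (h* = {domain.h_star:.2f})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
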