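"""Orchestration of the survey analyses.

Ties the pieces together the way the study design prescribes: choose a
database variant (full, or reduced to one record per species), optionally
drop an over-represented family (mosquitoes), fit the habitat-contrast model
or independent intercept-only per-order models, turn the posterior draws into
incidence summaries, and gate everything on convergence (split-R-hat below
threshold for every parameter; on failure the draws and diagnostics are still
written but summaries are suppressed).

Every run emits a manifest (config, seed, data checksum, package version)
sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import __version__
from .incidence import (DEFAULT_THRESHOLD, IncidenceSummary, summarize_incidence,
                        summaries_to_frame, write_summaries)
from .model import ModelSpec
from .sampler import PosteriorDraws, SamplerConfig, sample_posterior, trace_export
from .survey import SurveyTable, exclude_family, reduce_one_per_species, subset

log = logging.getLogger("wolbsurvey")

DEFAULT_FAMILY = "Culicidae"


@dataclass(frozen=True)
class AnalysisPlan:
    """What to run: database variant, sensitivity switches, scope, configs."""

    database_variant: str = "reduced"          # 'full' or 'reduced'
    exclude_culicidae: bool = False
    scope: str = "habitat_contrast"            # or 'per_order'
    orders: tuple | None = None                # per_order: None = all present
    per_order_aquatic_only: bool = True
    family: str = DEFAULT_FAMILY
    sampler_config: SamplerConfig = field(default_factory=SamplerConfig)
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    threshold: float = DEFAULT_THRESHOLD
    ci_level: float = 0.95
    output_dir: str | None = None

    def __post_init__(self):
        if self.database_variant not in ("full", "reduced"):
            raise ValueError("database_variant must be 'full' or 'reduced'")
        if self.scope not in ("habitat_contrast", "per_order"):
            raise ValueError("scope must be 'habitat_contrast' or 'per_order'")


@dataclass
class FitResult:
    """One fitted model: summaries (None when convergence failed), draws,
    diagnostics and the manifest that reproduces it."""

    summaries: list[IncidenceSummary] | None
    draws: PosteriorDraws
    converged: bool
    manifest: dict

    @property
    def diagnostics(self) -> dict:
        return self.draws.diagnostics


def _derive_seed(base: int, label: str) -> int:
    """Stable sub-seed from a base seed and a text label (< 2^31)."""
    h = hashlib.sha256(f"{base}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _prepare_table(table: SurveyTable, plan: AnalysisPlan) -> SurveyTable:
    out = table
    if plan.database_variant == "reduced":
        out = reduce_one_per_species(out)
    if plan.exclude_culicidae:
        out = exclude_family(out, plan.family)
    return out


def _manifest(table: SurveyTable, plan: AnalysisPlan, spec: ModelSpec,
              config: SamplerConfig, extra: dict | None = None) -> dict:
    man = {
        "package_version": __version__,
        "seed": config.seed,
        "data_checksum": table.checksum(),
        "n_records": len(table),
        "database_variant": plan.database_variant,
        "exclude_family": plan.family if plan.exclude_culicidae else None,
        "scope": plan.scope,
        "threshold": plan.threshold,
        "ci_level": plan.ci_level,
        "sampler": {
            "n_chains": config.n_chains,
            "n_iterations": config.n_iterations,
            "n_warmup": config.n_warmup,
            "rhat_threshold": config.rhat_threshold,
        },
        "model_spec": spec.to_config(),
        "table_metadata": {k: v for k, v in table.metadata.items()
                           if isinstance(v, (str, int, float, bool, list))},
    }
    if extra:
        man.update(extra)
    return man


def _write_outputs(result: FitResult, out_dir: str | Path, stem: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_export(result.draws, out_dir / f"{stem}_draws.csv")
    diag = pd.DataFrame(
        [{"parameter": p, **d} for p, d in result.draws.diagnostics.items()]
    )
    diag.to_csv(out_dir / f"{stem}_diagnostics.csv", index=False)
    (out_dir / f"{stem}_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True), encoding="utf-8")
    if result.summaries is not None:
        write_summaries(result.summaries, out_dir / f"{stem}_summary.csv")


def run_habitat_contrast(table: SurveyTable, plan: AnalysisPlan) -> FitResult:
    """Fit the aquatic/terrestrial contrast model and summarize incidence.

    Emits per-draw and plug-in summaries for each habitat. If any parameter's
    split-R-hat reaches the threshold, summaries are suppressed (draws and
    diagnostics are preserved) — convergence is a gate, not a footnote.
    """
    prepared = _prepare_table(table, plan)
    habitats = set(prepared.frame["habitat"])
    if len(habitats) < 2:
        raise ValueError(
            f"habitat contrast needs both habitats, found {sorted(habitats)}; "
            "use the per-order scope for single-group fits"
        )
    spec = replace(plan.model_spec, include_covariate=True)
    draws = sample_posterior(prepared, spec, plan.sampler_config)
    converged = draws.converged(plan.sampler_config.rhat_threshold)
    summaries = None
    if converged:
        summaries = []
        for group in sorted(spec.covariate_coding):
            for method in ("per_draw", "plug_in"):
                summaries.append(summarize_incidence(
                    draws, group, spec, threshold=plan.threshold,
                    ci_level=plan.ci_level, method=method))
    else:
        log.warning("habitat contrast: convergence failed (max r-hat %.3f); "
                    "summaries suppressed", draws.max_rhat())
    manifest = _manifest(prepared, plan, spec, plan.sampler_config,
                         {"converged": converged})
    result = FitResult(summaries, draws, converged, manifest)
    if plan.output_dir:
        _write_outputs(result, plan.output_dir, "habitat_contrast")
    return result


@dataclass
class PerOrderResult:
    summaries: list[IncidenceSummary]
    fits: dict[str, FitResult]
    unfittable: dict[str, str]      # order -> reason (e.g. single sample)
    skipped: list[str]              # requested orders absent from the table


def run_per_order(table: SurveyTable, plan: AnalysisPlan) -> PerOrderResult:
    """Independent intercept-only fits per order (aquatic records by default).

    Orders with a single record get a "no estimate" note rather than a fit;
    requested orders absent from the table are listed as skipped and the run
    continues. Per-order seeds are derived from the plan seed and the order
    name, so execution order is irrelevant.
    """
    prepared = _prepare_table(table, plan)
    if plan.per_order_aquatic_only:
        prepared = subset(prepared, habitat="aquatic")
    present = list(dict.fromkeys(prepared.frame["order"]))
    requested = list(plan.orders) if plan.orders else present
    skipped = [o for o in requested if o not in present]
    spec = plan.model_spec.without_covariate()

    summaries: list[IncidenceSummary] = []
    fits: dict[str, FitResult] = {}
    unfittable: dict[str, str] = {}
    for order in requested:
        if order in skipped:
            continue
        sub = subset(prepared, order=order)
        if len(sub) < 2:
            unfittable[order] = (
                f"only {len(sub)} sample(s) in the database; no estimate provided"
            )
            continue
        config = plan.sampler_config.scaled(
            seed=_derive_seed(plan.sampler_config.seed, f"order:{order}"))
        draws = sample_posterior(sub, spec, config)
        converged = draws.converged(config.rhat_threshold)
        manifest = _manifest(sub, plan, spec, config,
                             {"order": order, "converged": converged})
        order_summaries = None
        if converged:
            order_summaries = [
                summarize_incidence(draws, order, spec, threshold=plan.threshold,
                                    ci_level=plan.ci_level, method=m)
                for m in ("per_draw", "plug_in")
            ]
            summaries.extend(order_summaries)
        else:
            log.warning("per-order fit %s: convergence failed (max r-hat %.3f)",
                        order, draws.max_rhat())
        fit = FitResult(order_summaries, draws, converged, manifest)
        fits[order] = fit
        if plan.output_dir:
            _write_outputs(fit, plan.output_dir, f"order_{order}")
    if skipped:
        log.warning("per-order: requested orders absent from table: %s", skipped)
    return PerOrderResult(summaries, fits, unfittable, skipped)


@dataclass
class SensitivityResult:
    with_family: FitResult | PerOrderResult
    without_family: FitResult | PerOrderResult
    differences: pd.DataFrame   # group, mean_with, mean_without, delta
    seeds: dict[str, int]


def _mean_table(res: FitResult | PerOrderResult) -> dict[str, float]:
    summaries = res.summaries or []
    return {s.group: s.mean for s in summaries if s.method == "per_draw"}


def run_culicidae_sensitivity(table: SurveyTable, plan: AnalysisPlan,
                              ) -> SensitivityResult:
    """Run the plan's scope with and without the flagged family.

    The two runs use distinct seeds derived from the plan seed (both recorded
    in the result), and the per-draw incidence means are differenced per
    group.
    """
    runner = run_habitat_contrast if plan.scope == "habitat_contrast" else run_per_order
    seeds = {
        "with_family": _derive_seed(plan.sampler_config.seed, "sensitivity:with"),
        "without_family": _derive_seed(plan.sampler_config.seed, "sensitivity:without"),
    }
    plan_with = replace(
        plan, exclude_culicidae=False,
        sampler_config=plan.sampler_config.scaled(seed=seeds["with_family"]),
        output_dir=None)
    plan_without = replace(
        plan, exclude_culicidae=True,
        sampler_config=plan.sampler_config.scaled(seed=seeds["without_family"]),
        output_dir=None)
    res_with = runner(table, plan_with)
    res_without = runner(table, plan_without)
    means_w = _mean_table(res_with)
    means_wo = _mean_table(res_without)
    groups = sorted(set(means_w) | set(means_wo))
    diff = pd.DataFrame({
        "group": groups,
        "mean_with": [means_w.get(g, np.nan) for g in groups],
        "mean_without": [means_wo.get(g, np.nan) for g in groups],
    })
    diff["delta"] = diff["mean_without"] - diff["mean_with"]
    result = SensitivityResult(res_with, res_without, diff, seeds)
    if plan.output_dir:
        out = Path(plan.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        diff.to_csv(out / "sensitivity_differences.csv", index=False)
        for tag, res in (("with", res_with), ("without", res_without)):
            if isinstance(res, FitResult):
                _write_outputs(res, out, f"sensitivity_{tag}")
    return result


# -- order-representation diagnostic -------------------------------------------

@dataclass(frozen=True)
class OrderRepresentation:
    """Species tested in an order vs. species described in catalogues."""

    order: str
    n_species_tested: int
    n_species_described: int

    def __post_init__(self):
        if self.n_species_tested < 0 or self.n_species_described < 0:
            raise ValueError("counts must be non-negative")
        if 0 < self.n_species_described < self.n_species_tested:
            log.warning("order %s: tested (%d) exceeds described (%d); "
                        "catalogue totals may lag", self.order,
                        self.n_species_tested, self.n_species_described)


def order_representation_check(reps: list[OrderRepresentation],
                               log_scale: bool = False) -> dict[str, float]:
    """OLS of species-tested against species-described across orders.

    A strong positive relationship indicates sampling effort tracks order
    size, i.e. no gross over-representation of small orders. ``log_scale``
    fits on log10 counts instead of raw counts.
    """
    pts = [r for r in reps if r.n_species_described > 0]
    if len(pts) < 3:
        raise ValueError("need at least 3 orders with described-species totals")
    x = np.array([r.n_species_described for r in pts], dtype=float)
    y = np.array([r.n_species_tested for r in pts], dtype=float)
    if log_scale:
        if np.any(y <= 0):
            raise ValueError("log-scale fit requires positive tested counts")
        x, y = np.log10(x), np.log10(y)
    fit = linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue ** 2), "n_orders": len(pts)}
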