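"""Full surrogacy evaluation per analysis set, with IQWiG classification.

IQWiG's surrogate-validation criteria act on the correlation scale R
(not R^2): the correlation is *high* when the lower 95% confidence limit
of R is at least 0.85 (R^2 0.72), *low* when the upper limit is at most
0.70 (R^2 0.49), and *medium* otherwise.  A high correlation validates
the surrogate outright; for a medium correlation conclusions are still
possible through the surrogate threshold effect; for a low correlation
no surrogacy statement can be made.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import __version__
from .brma import BivariateEffectsMeta, BRMAResults, IntervalEstimate
from .loocv import LoocvResult, run_loocv
from .trial_data import (
    DEFAULT_OUTLIER_IDS,
    AnalysisSet,
    TrialRecord,
    build_analysis_set,
    to_effects,
)
from .wlr_ste import SteResult, SurrogateRegression, WLRResults

__all__ = [
    "IqwigClass",
    "AnalysisOptions",
    "SurrogacyReport",
    "classify_iqwig",
    "flag_outliers",
    "run_analysis",
]

R_HIGH = 0.85
R_LOW = 0.70


@dataclass(frozen=True)
class IqwigClass:
    label: str  # high | medium | low
    rationale: str


def classify_iqwig(r2_interval: IntervalEstimate) -> IqwigClass:
    """Classify correlation strength from an R^2-scale confidence interval.

    Bounds are mapped to the R scale by square root; the *lower* limit
    decides "high", the *upper* limit decides "low".
    """
    lo, hi = r2_interval.lower, r2_interval.upper
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("R^2 interval bounds must lie in [0, 1]")
    r_lo, r_hi = np.sqrt(lo), np.sqrt(hi)
    if r_lo >= R_HIGH:
        return IqwigClass(
            "high", f"lower 95% limit of R = {r_lo:.3f} >= {R_HIGH}"
        )
    if r_hi <= R_LOW:
        return IqwigClass("low", f"upper 95% limit of R = {r_hi:.3f} <= {R_LOW}")
    return IqwigClass(
        "medium",
        f"lower 95% limit of R = {r_lo:.3f} < {R_HIGH} and upper limit"
        f" = {r_hi:.3f} > {R_LOW}",
    )


def flag_outliers(
    effects,
    level: float = 0.95,
    band: str = "prediction",
    weight_scheme: str = "inv_var_true",
    new_weight_rule: str = "mean_weight",
    df_rule: str = "t_nminus2",
) -> set[str]:
    """Trials whose true-endpoint effect falls outside the WLR band at
    their surrogate effect (scatterplot outlier rule; band configurable)."""
    if len(effects) < 4:
        raise ValueError("outlier flagging needs >= 4 trials")
    fit = SurrogateRegression(effects, weight_scheme=weight_scheme).fit()
    flagged = set()
    for e in effects:
        lo, hi = fit.prediction_interval(
            e.y1, level=level, band=band,
            new_weight_rule=new_weight_rule, df_rule=df_rule,
        )
        if not lo <= e.y2 <= hi:
            flagged.add(e.trial_id)
    return flagged


@dataclass(frozen=True)
class AnalysisOptions:
    """Every knob of the pipeline in one place (report provenance)."""

    level: float = 0.95
    within_corr: float = 0.0
    brma_method: str = "reml"
    r2_ci_method: str = "fisher_z"
    n_boot: int = 1000
    seed: int = 0
    weight_scheme: str = "inv_var_true"
    attenuation_correction: bool = False
    wlr_r2_ci_method: str = "fisher_z"
    ste_band: str = "confidence"
    ste_new_weight_rule: str = "mean_weight"
    ste_df_rule: str = "t_nminus2"
    outlier_band: str = "prediction"
    outlier_ids: tuple[str, ...] = DEFAULT_OUTLIER_IDS
    loocv_param_uncertainty: bool = False

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["outlier_ids"] = list(self.outlier_ids)
        return d


@dataclass
class SurrogacyReport:
    analysis_set: AnalysisSet
    options: AnalysisOptions
    brma: BRMAResults
    brma_r2_ci: IntervalEstimate
    brma_line: tuple[float, float]
    brma_iqwig: IqwigClass
    wlr: WLRResults
    wlr_r2_ci: IntervalEstimate
    wlr_iqwig: IqwigClass
    overall_iqwig: IqwigClass
    ste: SteResult
    loocv: LoocvResult
    trials: list[TrialRecord] = field(repr=False, default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ste_status(self) -> str:
        if self.overall_iqwig.label == "high":
            return "not required (high correlation); computed for information"
        if self.overall_iqwig.label == "medium":
            return "required (medium correlation)"
        return "not interpretable (low correlation: no surrogacy statement)"

    def to_dict(self) -> dict:
        def iv(x: IntervalEstimate) -> dict:
            return {"point": x.point, "lower": x.lower, "upper": x.upper,
                    "level": x.level, "method": x.method}

        return {
            "analysis_set": {
                "name": self.analysis_set.name,
                "included_ids": list(self.analysis_set.included_ids),
                "exclusion_reasons": dict(self.analysis_set.exclusion_reasons),
                "n_trials": len(self.analysis_set.included_ids),
                "n_patients": int(sum(t.n_patients for t in self.trials)),
            },
            "options": self.options.to_dict(),
            "brma": {
                **self.brma.to_dict(),
                "r2_interval": iv(self.brma_r2_ci),
                "line": {"intercept": self.brma_line[0], "slope": self.brma_line[1]},
                "iqwig": self.brma_iqwig.__dict__,
            },
            "wlr": {
                **self.wlr.to_dict(),
                "r2_interval": iv(self.wlr_r2_ci),
                "iqwig": self.wlr_iqwig.__dict__,
            },
            "overall_iqwig": self.overall_iqwig.__dict__,
            "ste": {**self.ste.__dict__, "status": self.ste_status},
            "loocv": self.loocv.to_dict(),
            "trials": [
                {
                    "trial_id": t.trial_id,
                    "n_patients": t.n_patients,
                    "hr_surrogate": t.hr_surrogate,
                    "ci_surrogate": list(t.ci_surrogate),
                    "hr_true": t.hr_true,
                    "ci_true": list(t.ci_true),
                    "ph_ok": t.ph_ok,
                }
                for t in self.trials
            ],
            "errors": self.errors,
            "software_version": __version__,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            f"Surrogacy evaluation: {self.analysis_set.name}"
            f" ({len(self.analysis_set.included_ids)} trials,"
            f" {sum(t.n_patients for t in self.trials)} patients)",
            "",
            self.brma.summary(),
            f"  R^2 {self.brma_r2_ci.point:.2f}"
            f" ({self.brma_r2_ci.lower:.2f}, {self.brma_r2_ci.upper:.2f})"
            f" -> IQWiG {self.brma_iqwig.label}",
            "",
            self.wlr.summary(),
            f"  R^2 {self.wlr_r2_ci.point:.2f}"
            f" ({self.wlr_r2_ci.lower:.2f}, {self.wlr_r2_ci.upper:.2f})"
            f" -> IQWiG {self.wlr_iqwig.label}",
            "",
            f"Overall IQWiG class: {self.overall_iqwig.label}",
            (
                f"STE: HR = {self.ste.ste_hr:.2f} [{self.ste_status}]"
                if self.ste.solvable
                else f"STE: unsolvable ({self.ste.message})"
            ),
            f"LOOCV accuracy: {self.loocv.accuracy:.0%}"
            f" ({int(round(self.loocv.accuracy * self.loocv.n))}/{self.loocv.n})",
        ]
        return "\n".join(lines)


def run_analysis(
    records: Sequence[TrialRecord],
    set_name: str = "primary",
    options: AnalysisOptions | None = None,
    partial: bool = False,
) -> SurrogacyReport:
    """Run the full pipeline on a named analysis set.

    Builds the analysis set, converts records to log effects, fits BRMA
    and WLR, computes R^2 intervals and IQWiG classes per method, the
    STE from the WLR fit, and BRMA LOOCV.  Deterministic given options.
    Stage errors abort unless ``partial=True``, in which case they are
    recorded on the report and dependent fields are left as None.
    """
    opts = options or AnalysisOptions()
    aset = build_analysis_set(list(records), set_name, opts.outlier_ids)
    trials = aset.select(list(records))
    effects = to_effects(trials)
    errors: dict[str, str] = {}

    def stage(name, func, default=None):
        try:
            return func()
        except Exception as exc:  # noqa: BLE001 - reported per stage
            if not partial:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            errors[name] = str(exc)
            return default

    brma_fit = stage(
        "brma",
        lambda: BivariateEffectsMeta(effects, within_corr=opts.within_corr).fit(
            method=opts.brma_method
        ),
    )
    brma_ci = stage(
        "brma_r2_interval",
        lambda: brma_fit.r2_interval(
            level=opts.level, method=opts.r2_ci_method,
            n_boot=opts.n_boot, seed=opts.seed,
        ),
    )
    brma_line = stage("brma_line", lambda: brma_fit.implied_line(), (np.nan, np.nan))
    wlr_fit = stage(
        "wlr",
        lambda: SurrogateRegression(
            effects,
            weight_scheme=opts.weight_scheme,
            attenuation_correction=opts.attenuation_correction,
        ).fit(),
    )
    wlr_ci = stage(
        "wlr_r2_interval",
        lambda: wlr_fit.r2_interval(
            level=opts.level, method=opts.wlr_r2_ci_method,
            n_boot=opts.n_boot, seed=opts.seed,
        ),
    )
    ste = stage(
        "ste",
        lambda: wlr_fit.compute_ste(
            level=opts.level, band=opts.ste_band,
            new_weight_rule=opts.ste_new_weight_rule, df_rule=opts.ste_df_rule,
        ),
    )
    loocv_res = stage(
        "loocv",
        lambda: run_loocv(
            effects,
            within_corr=opts.within_corr,
            method=opts.brma_method,
            level=opts.level,
            include_param_uncertainty=opts.loocv_param_uncertainty,
        ),
    )
    brma_iqwig = stage("brma_iqwig", lambda: classify_iqwig(brma_ci))
    wlr_iqwig = stage("wlr_iqwig", lambda: classify_iqwig(wlr_ci))
    # conservative overall label: the weaker of the two methods
    order = {"low": 0, "medium": 1, "high": 2}
    overall = stage(
        "overall_iqwig",
        lambda: min((brma_iqwig, wlr_iqwig), key=lambda c: order[c.label]),
    )
    return SurrogacyReport(
        analysis_set=aset,
        options=opts,
        brma=brma_fit,
        brma_r2_ci=brma_ci,
        brma_line=brma_line,
        brma_iqwig=brma_iqwig,
        wlr=wlr_fit,
        wlr_r2_ci=wlr_ci,
        wlr_iqwig=wlr_iqwig,
        overall_iqwig=overall,
        ste=ste,
        loocv=loocv_res,
        trials=trials,
        errors=errors,
    )
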