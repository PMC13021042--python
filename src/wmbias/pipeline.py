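"""High-level pipeline stages tying simulation, analysis and fitting together.

These functions take a trial table (synthetic or real, same schema) and run
the design-appropriate stages; the command-line interface and the example
scripts are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis as an
from . import fitting as ft
from .exceptions import InsufficientDataError, InvalidDesignError

__all__ = ["AnalysisReport", "FitReport", "analyze_table", "fit_table"]


@dataclass
class AnalysisReport:
    """Outputs of the behavioral pipeline for one trial table."""

    design_id: str
    offsets: pd.DataFrame
    retention: pd.DataFrame
    bias: an.BiasSummary
    judgment_bias: an.BiasSummary | None = None  # exp1: similar vs dissimilar
    judgment_contrast: dict | None = None
    ambivalent: an.AmbivalentResult | None = None
    ambivalent_test: dict | None = None
    side_contrast: dict | None = None  # exp2: |same| vs |opposite|
    precision_bias: an.CorrelationResult | None = None  # exp3
    per_participant: pd.DataFrame | None = None

    def group_stats(self) -> dict:
        """Group-level statistics as one JSON-serializable dict."""
        out = {"design_id": self.design_id,
               "bias": self.bias.group.to_dict(orient="records")}
        if self.judgment_bias is not None:
            out["judgment_bias"] = self.judgment_bias.group.to_dict(orient="records")
        if self.judgment_contrast is not None:
            out["judgment_contrast"] = self.judgment_contrast
        if self.ambivalent_test is not None:
            out["ambivalent_difference"] = self.ambivalent_test
        if self.side_contrast is not None:
            out["side_contrast"] = self.side_contrast
        if self.precision_bias is not None:
            c = self.precision_bias
            out["precision_bias"] = {
                "r": c.r, "df": c.df, "p": c.p,
                "r_all": c.r_all, "df_all": c.df_all, "p_all": c.p_all,
                "n_excluded": len(c.excluded_ids),
            }
        return out


def analyze_table(
    table: pd.DataFrame,
    seed: int = 0,
    high_confidence_only: bool = True,
    bin_width: float = 5.0,
    outlier_sd: float = 3.0,
) -> AnalysisReport:
    """Run the design-appropriate offset analyses on a trial table.

    The single-probe design adds the judgment split, the paired contrast
    between similar- and dissimilar-judged bias, and the ambivalent-probe
    analysis; the 2AFC design adds the same- vs opposite-side magnitude
    contrast; the individual-differences design adds the precision-bias
    correlation (bias from correctly judged high-confidence trials,
    precision from baseline).
    """
    design_id = str(table["design_id"].iloc[0])
    offsets = an.compute_offsets(table, seed=seed)
    if high_confidence_only:
        used, retention = an.filter_high_confidence(offsets)
    else:
        used, retention = offsets, an.filter_high_confidence(offsets)[1]
    report = AnalysisReport(
        design_id=design_id,
        offsets=offsets,
        retention=retention,
        bias=an.bias_magnitude(used),
    )
    if design_id == "exp1":
        comp = used[used["condition"] == "comparison"]
        by_judgment = comp.assign(condition=comp["judgment"])
        report.judgment_bias = an.bias_magnitude(by_judgment)
        report.judgment_contrast = an.paired_contrast(
            report.judgment_bias, "similar", "dissimilar"
        )
        report.ambivalent = an.ambivalent_probe_analysis(comp, bin_width=bin_width)
        diffs = report.ambivalent.per_participant["difference"].to_numpy()
        if len(diffs) >= 2:
            report.ambivalent_test = an._one_sample(diffs)
    elif design_id == "exp2":
        report.side_contrast = an.paired_contrast(
            report.bias, "same_side", "opposite_side", absolute=True
        )
    elif design_id == "exp3":
        rows = []
        for pid, sub in used.groupby("participant_id", sort=True):
            base = sub[sub["condition"] == "baseline"]["offset"]
            correct = sub[
                (sub["condition"] == "experimental") & (sub["judgment"] == "similar")
            ]["offset"]
            if len(base) < 20 or len(correct) < 5:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "kappa": an.estimate_precision(base).kappa,
                    "bias": float(correct.mean()),
                    "n_baseline": len(base),
                    "n_bias": len(correct),
                }
            )
        per = pd.DataFrame(rows)
        if len(per) < 4:
            raise InsufficientDataError("too few participants with usable exp3 cells")
        report.per_participant = per
        report.precision_bias = an.precision_bias_correlation(
            per["kappa"], per["bias"], ids=per["participant_id"],
            outlier_sd=outlier_sd,
        )
    else:
        raise InvalidDesignError(f"unknown design_id {design_id!r}")
    return report


@dataclass
class FitReport:
    """Per-participant model fits and the cohort-level comparison."""

    joint_fits: list
    mixture_fits: list
    wm_fits: dict  # participant_id -> StandardWMFit
    comparison: ft.ComparisonTable
    per_participant: pd.DataFrame

    def fits_json(self) -> dict:
        rows = []
        for jf, mf in zip(self.joint_fits, self.mixture_fits):
            rows.append(
                {
                    "joint": {"kappa_p": jf.params["kappa_p"],
                              "objective": jf.objective_value,
                              "log_likelihood": jf.log_likelihood,
                              "aic": jf.aic, "bic": jf.bic},
                    "mixture": {**mf.params, "objective": mf.objective_value,
                                "log_likelihood": mf.log_likelihood,
                                "aic": mf.aic, "bic": mf.bic},
                    "kappa_m": jf.kappa_m,
                    "kappa_m_source": jf.kappa_m_source,
                    "n_trials": jf.n_trials,
                }
            )
        return {"participants": rows,
                "comparison": self.comparison.table.to_dict(orient="records"),
                "preferred": {"ll": self.comparison.preferred_ll,
                              "aic": self.comparison.preferred_aic,
                              "bic": self.comparison.preferred_bic}}


def fit_table(
    table: pd.DataFrame,
    seed: int = 0,
    judged_similar_only: bool = True,
    kappa_m: float | None = None,
    min_trials: int = 10,
) -> FitReport:
    """Fit both representational models to every participant in a table.

    High-confidence comparison trials enter the fits (judged-similar trials
    only by default — those are the trials on which integration is claimed
    to act).  The memory precision kappa_m is, unless supplied, estimated
    per participant from the same table's high-confidence baseline offsets
    via the standard WM mixture (using the kappa component only).
    """
    offsets = an.compute_offsets(table, seed=seed)
    hc, _ = an.filter_high_confidence(offsets)
    if len(hc) == 0:
        raise InsufficientDataError("no high-confidence trials to fit")
    joint_fits, mixture_fits, wm_fits, rows = [], [], {}, []
    for pid, sub in hc.groupby("participant_id", sort=True):
        comp = sub.dropna(subset=["probe_distance"])
        if judged_similar_only:
            comp = comp[comp["judgment"] == "similar"]
        if len(comp) < min_trials:
            raise InsufficientDataError(
                f"participant {pid} has only {len(comp)} usable comparison trials"
            )
        if kappa_m is None:
            base = sub[sub["condition"].str.contains("baseline")]["offset"]
            wm = ft.fit_standard_wm(base)
            wm_fits[pid] = wm
            km, source = wm.kappa, "baseline"
        else:
            km, source = float(kappa_m), "provided"
        d = comp["probe_distance"].to_numpy()
        x = comp["offset"].to_numpy()
        joint_fits.append(ft.fit_joint_model(d, x, km, kappa_m_source=source))
        mixture_fits.append(ft.fit_mixture_model(d, x, km, kappa_m_source=source))
        rows.append(
            {
                "participant_id": pid,
                "kappa_m": km,
                "n_trials": len(comp),
                "joint_kappa_p": joint_fits[-1].params["kappa_p"],
                "mixture_alpha": mixture_fits[-1].params["alpha"],
                "mixture_kappa_p": mixture_fits[-1].params["kappa_p"],
            }
        )
    comparison = ft.compare_models(joint_fits, mixture_fits)
    return FitReport(
        joint_fits=joint_fits,
        mixture_fits=mixture_fits,
        wm_fits=wm_fits,
        comparison=comparison,
        per_participant=pd.DataFrame(rows),
    )
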