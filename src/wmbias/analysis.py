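"""Behavioral analyses for probe-comparison continuous-report experiments.

Implements the full offset pipeline: signed response offsets relative to a
reference probe (positive = toward the probe), random signing of baseline
offsets, high-confidence filtering, participant- and group-level bias
statistics, the ambivalent-probe-distance analysis that decouples subjective
from physical similarity, von Mises precision estimation, the
precision-bias correlation with outlier handling, smoothed offset
distributions, and the sample-size calculators used to plan such studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .circular import signed_circ_dist, smooth_circular
from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "AmbivalentResult",
    "BiasSummary",
    "CorrelationResult",
    "PrecisionEstimate",
    "ambivalent_probe_analysis",
    "assign_baseline_signs",
    "bias_magnitude",
    "compute_offsets",
    "discretize_probe_distance",
    "estimate_precision",
    "filter_high_confidence",
    "offset_distribution",
    "paired_contrast",
    "precision_bias_correlation",
    "required_n_correlation",
    "required_n_one_sample_t",
    "signed_offset_exp1",
    "signed_offset_exp2",
    "within_subject_sem",
]

KAPPA_CAP = 1e4


# ---------------------------------------------------------------------------
# signed offsets


def signed_offset_exp1(response, s_m, s_p, rng: np.random.Generator | None = None):
    """Signed response offset, positive toward the probe ``s_p``.

    The magnitude is the circular distance between response and target; the
    sign is positive iff the response is displaced in the probe's direction.
    When the probe coincides with the target the direction is undefined and
    the sign is assigned at random (a warning flags this).
    """
    offset = np.atleast_1d(signed_circ_dist(response, s_m)).astype(float)
    direction = np.sign(np.atleast_1d(signed_circ_dist(s_p, s_m)))
    undefined = direction == 0
    if np.any(undefined):
        warnings.warn(
            "probe coincides with target on some trials; signs assigned at random",
            stacklevel=2,
        )
        rng = rng if rng is not None else np.random.default_rng()
        direction[undefined] = rng.choice([-1.0, 1.0], size=int(undefined.sum()))
    out = offset * direction
    return float(out[0]) if np.isscalar(response) or np.ndim(response) == 0 else out


def signed_offset_exp2(response, s_m, first_similar_probe, rng=None):
    """Signed offset with the first pair's similar probe as the reference."""
    return signed_offset_exp1(response, s_m, first_similar_probe, rng=rng)


def assign_baseline_signs(offsets, rng: np.random.Generator) -> np.ndarray:
    """Random ±1 signing of baseline offset magnitudes (expected mean zero)."""
    mags = np.abs(np.asarray(offsets, dtype=float))
    return mags * rng.choice([-1.0, 1.0], size=mags.shape)


def compute_offsets(table: pd.DataFrame, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-trial offset table from a raw trial table.

    Comparison-condition offsets are signed toward the trial's reference
    probe (the single probe in the one-probe design; the first pair's
    similar probe in the 2AFC designs); baseline offsets get random signs.
    Returns one row per trial with participant, condition, probe distance,
    first judgment, signed offset and confidence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = table["probe1_sim"].isna()
    out = table[
        ["participant_id", "design_id", "condition", "judgment1", "confidence"]
    ].copy()
    out = out.rename(columns={"judgment1": "judgment"})

    offset = np.empty(len(table), dtype=float)
    distance = np.full(len(table), np.nan)
    raw = np.asarray(signed_circ_dist(table["response"], table["S_M"]), dtype=float)
    if baseline.any():
        offset[baseline.to_numpy()] = assign_baseline_signs(raw[baseline.to_numpy()], rng)
    comp = (~baseline).to_numpy()
    if comp.any():
        sub = table.loc[~baseline]
        offset[comp] = signed_offset_exp1(
            sub["response"].to_numpy(),
            sub["S_M"].to_numpy(),
            sub["probe1_sim"].to_numpy(),
            rng=rng,
        )
        distance[comp] = np.abs(
            signed_circ_dist(sub["probe1_sim"].to_numpy(), sub["S_M"].to_numpy())
        )
    out["probe_distance"] = distance
    out["offset"] = offset
    return out


def filter_high_confidence(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep confidence-1 rows only; also report per-cell retention fractions.

    Returns ``(filtered, retention)`` where ``retention`` has one row per
    participant x condition with the fraction and count of trials kept.
    Cells left empty by the filter are flagged with a warning.
    """
    if "confidence" not in table.columns:
        raise InvalidParameterError("table has no 'confidence' column")
    kept = table[table["confidence"] == 1].copy()
    grp = table.groupby(["participant_id", "condition"], sort=True)
    retention = grp["confidence"].agg(
        n_total="size", n_kept=lambda c: int((c == 1).sum())
    ).reset_index()
    retention["fraction"] = retention["n_kept"] / retention["n_total"]
    empty = retention[retention["n_kept"] == 0]
    if len(empty):
        warnings.warn(
            f"{len(empty)} participant x condition cells have no high-confidence "
            "trials",
            stacklevel=2,
        )
    return kept, retention


# ---------------------------------------------------------------------------
# bias statistics


@dataclass(frozen=True)
class BiasSummary:
    """Participant-level mean offsets and group-level one-sample statistics."""

    participant_means: pd.DataFrame  # participant_id, condition, mean_offset, n_trials
    group: pd.DataFrame  # condition, mean, sd, t, df, p, ci_low, ci_high, cohens_d, n


def _one_sample(values: np.ndarray, alpha: float = 0.05) -> dict:
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else np.nan
    if n < 2 or sd == 0:
        se = 0.0 if sd == 0 else np.nan
        t = np.inf * np.sign(mean) if sd == 0 and mean != 0 else np.nan
        return {
            "mean": mean, "sd": sd, "t": t, "df": n - 1, "p": np.nan,
            "ci_low": mean, "ci_high": mean,
            "cohens_d": np.inf * np.sign(mean) if sd == 0 and mean != 0 else np.nan,
            "n": n,
        }
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return {
        "mean": mean, "sd": sd, "t": float(t), "df": df, "p": float(p),
        "ci_low": mean - crit * se, "ci_high": mean + crit * se,
        "cohens_d": mean / sd, "n": n,
    }


def bias_magnitude(
    offsets: pd.DataFrame, group_col: str = "condition"
) -> BiasSummary:
    """Mean signed offset per participant x condition, with one-sample tests.

    The group-level test for each condition is a two-tailed one-sample t of
    the participant means against zero, with Cohen's d = mean / SD of the
    participant means and a 95% CI from the t distribution.
    """
    pm = (
        offsets.groupby(["participant_id", group_col], sort=True)["offset"]
        .agg(mean_offset="mean", n_trials="size")
        .reset_index()
    )
    rows = []
    for cond, sub in pm.groupby(group_col, sort=True):
        if len(sub) < 2:
            raise InsufficientDataError(
                f"condition {cond!r} has fewer than 2 participants"
            )
        rows.append({group_col: cond, **_one_sample(sub["mean_offset"].to_numpy())})
    return BiasSummary(participant_means=pm, group=pd.DataFrame(rows))


def paired_contrast(
    summary: BiasSummary, cond_a: str, cond_b: str, absolute: bool = False
) -> dict:
    """Paired t test of participant means between two conditions (a - b).

    With ``absolute=True`` the contrast is computed on |mean offsets| — the
    bias-magnitude comparison used for same- vs opposite-side probes.
    """
    pm = summary.participant_means.pivot(
        index="participant_id", columns=summary.group.columns[0], values="mean_offset"
    )
    if cond_a not in pm.columns or cond_b not in pm.columns:
        raise InvalidParameterError(f"conditions {cond_a!r}/{cond_b!r} not present")
    a, b = pm[cond_a].to_numpy(), pm[cond_b].to_numpy()
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise InsufficientDataError("fewer than 2 complete participant pairs")
    if absolute:
        a, b = np.abs(a), np.abs(b)
    return {"contrast": f"{cond_a} - {cond_b}", **_one_sample(a[ok] - b[ok])}


# ---------------------------------------------------------------------------
# ambivalent-probe analysis


@dataclass(frozen=True)
class AmbivalentResult:
    """Per-participant bias after similar vs dissimilar judgments at matched
    physical probe distances (bins eliciting both judgment types)."""

    per_participant: pd.DataFrame  # participant_id, n_bins, bias_similar,
    # bias_dissimilar, difference
    excluded: list  # participants with no ambivalent bins
    bin_width: float


def ambivalent_probe_analysis(
    offsets: pd.DataFrame, bin_width: float = 5.0
) -> AmbivalentResult:
    """Isolate subjective similarity by averaging over ambivalent distances.

    Probe distances are discretized into ``bin_width``-degree bins; within
    each participant, only bins containing at least one similar- and one
    dissimilar-judged trial contribute.  Per-bin mean offsets are computed
    separately per judgment and then averaged across the ambivalent bins, so
    physical distance is equated across judgment types by construction.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be > 0")
    comp = offsets.dropna(subset=["probe_distance", "judgment"]).copy()
    comp["dist_bin"] = np.floor(comp["probe_distance"] / bin_width).astype(int)
    rows, excluded = [], []
    for pid, sub in comp.groupby("participant_id", sort=True):
        cell = (
            sub.groupby(["dist_bin", "judgment"])["offset"].mean().unstack("judgment")
        )
        if "similar" not in cell.columns or "dissimilar" not in cell.columns:
            excluded.append(pid)
            continue
        both = cell.dropna(subset=["similar", "dissimilar"])
        if len(both) == 0:
            excluded.append(pid)
            continue
        bias_sim = float(both["similar"].mean())
        bias_dis = float(both["dissimilar"].mean())
        rows.append(
            {
                "participant_id": pid,
                "n_bins": len(both),
                "bias_similar": bias_sim,
                "bias_dissimilar": bias_dis,
                "difference": bias_sim - bias_dis,
            }
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} participant(s) had no ambivalent distance bins",
            stacklevel=2,
        )
    return AmbivalentResult(
        per_participant=pd.DataFrame(
            rows,
            columns=[
                "participant_id", "n_bins", "bias_similar",
                "bias_dissimilar", "difference",
            ],
        ),
        excluded=excluded,
        bin_width=bin_width,
    )


def discretize_probe_distance(
    distances, n_bins: int = 18, lo: float = 16.0, hi: float = 105.0
) -> np.ndarray:
    """Assign probe distances to ``n_bins`` equal-width bins over [lo, hi].

    Bins are numbered 1..n_bins, right-open except the last (so ``hi`` falls
    in bin ``n_bins``).  Out-of-range distances raise.
    """
    d = np.asarray(distances, dtype=float)
    if np.any((d < lo) | (d > hi)):
        raise InvalidParameterError(f"probe distances must lie within [{lo}, {hi}]")
    width = (hi - lo) / n_bins
    bins = np.floor((d - lo) / width).astype(int) + 1
    return np.minimum(bins, n_bins)


# ---------------------------------------------------------------------------
# precision estimation and the precision-bias correlation


@dataclass(frozen=True)
class PrecisionEstimate:
    """Maximum-likelihood von Mises concentration of zero-mean offsets."""

    kappa: float
    n: int
    capped: bool = False


def _a1(kappa: float) -> float:
    """Mean resultant length of a von Mises: A(k) = I1(k)/I0(k)."""
    return special.i1e(kappa) / special.i0e(kappa)


def _a1_inv(r: float, cap: float = KAPPA_CAP) -> tuple[float, bool]:
    if r >= _a1(cap):
        return cap, True
    if r <= 0:
        raise InsufficientDataError("resultant length ~ 0: kappa unidentifiable")
    if r <= _a1(1e-8):
        return 2.0 * r, False  # small-kappa limit A(k) ~ k/2
    return float(optimize.brentq(lambda k: _a1(k) - r, 1e-9, cap)), False


def estimate_precision(offsets, min_n: int = 20) -> PrecisionEstimate:
    """MLE of the concentration of a mean-zero von Mises fit to offsets.

    The estimate inverts the Bessel-function ratio A(k) = I1/I0 at the
    observed mean cosine of the offsets.  Degenerate data (all offsets ~ 0)
    cap the estimate and set ``capped``; invariant to sign flips.
    """
    x = np.asarray(offsets, dtype=float)
    if len(x) < min_n:
        raise InsufficientDataError(f"need >= {min_n} offsets, got {len(x)}")
    r = float(np.mean(np.cos(np.deg2rad(x))))
    kappa, capped = _a1_inv(r)
    return PrecisionEstimate(kappa=kappa, n=len(x), capped=capped)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with and without bivariate outlier exclusion."""

    r: float
    df: int
    p: float
    r_all: float
    df_all: int
    p_all: float
    excluded_ids: list


def precision_bias_correlation(
    precisions,
    biases,
    ids=None,
    outlier_sd: float = 3.0,
) -> CorrelationResult:
    """Pearson correlation between WM precision and bias across participants.

    Outliers beyond ``outlier_sd`` standard deviations from the mean on
    either variable are excluded (bivariate rule); results are also reported
    with all participants retained.  ``df = n - 2`` throughout.
    """
    x = np.asarray(precisions, dtype=float)
    y = np.asarray(biases, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("precisions and biases must be paired")
    ids = np.asarray(ids) if ids is not None else np.arange(len(x))
    if len(x) < 4:
        raise InsufficientDataError("need at least 4 participants")
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    keep = (np.abs(zx) <= outlier_sd) & (np.abs(zy) <= outlier_sd)
    if keep.sum() < 4:
        raise InsufficientDataError("fewer than 4 participants after exclusion")
    r_all, p_all = stats.pearsonr(x, y)
    r, p = stats.pearsonr(x[keep], y[keep])
    return CorrelationResult(
        r=float(r),
        df=int(keep.sum() - 2),
        p=float(p),
        r_all=float(r_all),
        df_all=len(x) - 2,
        p_all=float(p_all),
        excluded_ids=list(ids[~keep]),
    )


# ---------------------------------------------------------------------------
# distributions


def offset_distribution(
    offsets, window: float = 30.0, resolution: float = 1.0
) -> pd.DataFrame:
    """Smoothed response-proportion distribution over signed offsets.

    Offsets are histogrammed per degree over (-180, 180] and box-smoothed
    over a ``window``-degree span — the standard presentation of
    continuous-report error distributions.
    """
    n = int(round(360 / resolution))
    centers = -180.0 + resolution + np.arange(n) * resolution  # (-180, 180]
    x = np.asarray(offsets, dtype=float)
    # fold anything beyond the first bin's lower edge back onto the circle
    lo = centers[0] - resolution / 2
    x = np.where(x <= lo, x + 360.0, x)
    edges = np.concatenate([[lo], centers + resolution / 2])
    hist, _ = np.histogram(x, bins=edges)
    prop = hist / max(len(x), 1)
    smoothed = smooth_circular(prop, window=window, resolution=resolution)
    return pd.DataFrame({"offset": centers, "proportion": smoothed})


def within_subject_sem(values: pd.DataFrame) -> pd.Series:
    """Cousineau-Morey within-subject SEM per condition.

    ``values`` is wide-form: one row per participant, one column per
    condition.  Each participant's scores are centred on their own mean and
    shifted by the grand mean before the SEM is computed, then inflated by
    the Morey factor sqrt(C / (C - 1)).
    """
    arr = values.to_numpy(dtype=float)
    n, c = arr.shape
    if c < 2:
        raise InvalidParameterError("need at least 2 conditions")
    normalized = arr - arr.mean(axis=1, keepdims=True) + arr.mean()
    sem = normalized.std(axis=0, ddof=1) / np.sqrt(n)
    return pd.Series(sem * np.sqrt(c / (c - 1)), index=values.columns)


# ---------------------------------------------------------------------------
# power utilities


def _power_one_sample_t(n: int, d: float, alpha: float, tails: int) -> float:
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        crit = stats.t.ppf(1 - alpha / 2, df)
        return float(
            1 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)
        )
    crit = stats.t.ppf(1 - alpha, df)
    return float(1 - stats.nct.cdf(crit, df, nc))


def required_n_one_sample_t(
    d: float, alpha: float = 0.05, power: float = 0.8, tails: int = 2,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n at which a one-sample t test reaches the target power.

    Power is evaluated exactly from the noncentral t distribution with
    noncentrality ``d * sqrt(n)`` and ``df = n - 1``, scanning n upward.
    """
    if d <= 0 or not 0 < power < 1 or not 0 < alpha < 1 or tails not in (1, 2):
        raise InvalidParameterError("require d > 0, 0 < power < 1, tails in {1,2}")
    for n in range(2, max_n + 1):
        if _power_one_sample_t(n, d, alpha, tails) >= power:
            return n
    raise InvalidParameterError(f"power {power} unreachable below n={max_n}")


def required_n_correlation(
    rho: float, alpha: float = 0.05, power: float = 0.9, tails: int = 2,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n detecting a correlation ``rho`` via the Fisher z test.

    Power = Phi(|z(rho)| * sqrt(n - 3) - z_crit) with the usual two-tailed
    critical value; the scan starts at n = 4 (df = n - 2 >= 2).
    """
    if not 0 < abs(rho) < 1 or not 0 < power < 1 or tails not in (1, 2):
        raise InvalidParameterError("require 0 < |rho| < 1, 0 < power < 1")
    z = abs(np.arctanh(rho))
    crit = stats.norm.ppf(1 - alpha / tails)
    for n in range(4, max_n + 1):
        if stats.norm.cdf(z * np.sqrt(n - 3) - crit) >= power:
            return n
    raise InvalidParameterError(f"power {power} unreachable below n={max_n}")
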