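"""Seeded generators of synthetic continuous-report trial tables.

Emulates three delayed-estimation designs in which a remembered angle (shape
or color on a 360-valued wheel) is compared with probe stimuli before being
reported:

* ``exp1`` — a single probe 16-105 deg from the target with a binary
  similar/dissimilar judgment (12 blocks of 12 baseline + 36 comparison
  trials);
* ``exp2`` — two consecutive 2AFC probe pairs; each pair holds a *similar*
  probe 16-45 deg from the target and a *dissimilar* probe 180 deg opposite
  it, with the two similar probes drawn from the same or from opposite sides
  of the target (40 trials per condition, plus short/long-delay baselines);
* ``exp3`` — a single 2AFC judgment in an individual-differences design
  (4 blocks of 15 baseline + 15 experimental trials).

A generative :class:`ObserverSpec` controls memory precision, the
integration account used on comparison trials (joint / mixture /
baseline-only), a logistic similarity-judgment rule on the trial's noisy
memory sample, and lapse/confidence behavior.  All randomness flows from a
master seed through per-participant substreams, so tables are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circular import (
    DEFAULT_GRID,
    CircularGrid,
    signed_circ_dist,
    vm_product_closed_form,
    wrap_positive,
)
from .exceptions import InvalidDesignError, InvalidParameterError

__all__ = [
    "TABLE_COLUMNS",
    "ExperimentDesign",
    "ObserverSpec",
    "TrialRecord",
    "exp1_design",
    "exp2_design",
    "exp3_design",
    "generate_dataset",
    "generate_population_exp3",
    "sample_probe_exp1",
    "sample_probe_pairs_exp2",
    "simulate_2afc_choice",
    "simulate_similarity_judgment",
    "simulate_trial",
]

TABLE_COLUMNS = [
    "participant_id",
    "design_id",
    "condition",
    "block",
    "trial",
    "S_M",
    "probe1_sim",
    "probe1_dis",
    "probe2_sim",
    "probe2_dis",
    "judgment1",
    "judgment2",
    "response",
    "confidence",
]

SIMILAR = "similar"
DISSIMILAR = "dissimilar"


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial structure of one experiment.

    ``trials_per_block`` maps condition labels to per-block trial counts;
    ``probe_lo``/``probe_hi`` bound the sampled distance (degrees) between
    the target and the (similar) probe.
    """

    design_id: str
    stimulus_domain: str
    blocks: int
    trials_per_block: Mapping[str, int]
    probe_lo: int
    probe_hi: int

    def __post_init__(self):
        if self.design_id not in {"exp1", "exp2", "exp3"}:
            raise InvalidDesignError(f"unknown design_id {self.design_id!r}")
        if not 0 < self.probe_lo <= self.probe_hi < 180:
            raise InvalidDesignError("probe range must satisfy 0 < lo <= hi < 180")
        if self.blocks < 1 or any(v < 1 for v in self.trials_per_block.values()):
            raise InvalidDesignError("block and trial counts must be positive")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.trials_per_block)

    def trials_per_participant(self) -> int:
        return self.blocks * sum(self.trials_per_block.values())


def exp1_design(stimulus_domain: str = "shape") -> ExperimentDesign:
    """Single-probe similarity-judgment design: 12 x (12 baseline + 36 comparison)."""
    return ExperimentDesign(
        design_id="exp1",
        stimulus_domain=stimulus_domain,
        blocks=12,
        trials_per_block={"baseline": 12, "comparison": 36},
        probe_lo=16,
        probe_hi=105,
    )


def exp2_design(stimulus_domain: str = "color") -> ExperimentDesign:
    """Two-pair 2AFC design: 40 trials in each of four conditions."""
    return ExperimentDesign(
        design_id="exp2",
        stimulus_domain=stimulus_domain,
        blocks=8,
        trials_per_block={
            "short_baseline": 5,
            "long_baseline": 5,
            "same_side": 5,
            "opposite_side": 5,
        },
        probe_lo=16,
        probe_hi=45,
    )


def exp3_design(stimulus_domain: str = "color") -> ExperimentDesign:
    """Single-judgment individual-differences design: 4 x (15 + 15) trials."""
    return ExperimentDesign(
        design_id="exp3",
        stimulus_domain=stimulus_domain,
        blocks=4,
        trials_per_block={"baseline": 15, "experimental": 15},
        probe_lo=16,
        probe_hi=45,
    )


@dataclass(frozen=True)
class ObserverSpec:
    """Generative parameters of one simulated participant.

    ``generative_model`` selects how comparison-trial responses are produced:
    ``"joint"`` integrates every judged-similar probe into the memory density
    (normalized product), ``"mixture"`` reports the memory with probability
    ``alpha`` and a judged-similar probe otherwise, ``"baseline-only"``
    ignores probes entirely.  The similarity judgment is logistic in the
    distance between the probe and the trial's noisy memory sample, with
    criterion ``criterion_c`` (degrees, P(similar)=0.5 at that distance) and
    slope ``judgment_beta`` (degrees).  Lapses are uniform reports rated
    confidence 3; other reports are rated 1 (high) with probability
    ``p_high_conf``, else 2.
    """

    kappa_m: float = 12.0
    generative_model: str = "joint"
    kappa_p: float = 2.0
    alpha: float = 0.8
    criterion_c: float = 60.0
    judgment_beta: float = 15.0
    lapse_rate: float = 0.05
    p_high_conf: float = 0.8
    kappa_m_short: float | None = None  # short-delay baseline precision (exp2)

    def __post_init__(self):
        if self.generative_model not in {"joint", "mixture", "baseline-only"}:
            raise InvalidParameterError(
                f"unknown generative_model {self.generative_model!r}"
            )
        for name in ("kappa_m", "kappa_p"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")
        for name in ("alpha", "lapse_rate", "p_high_conf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.criterion_c <= 0 or self.judgment_beta <= 0:
            raise InvalidParameterError("criterion_c and judgment_beta must be > 0")


@dataclass(frozen=True)
class TrialRecord:
    """One simulated trial; ``None`` marks fields inapplicable to the design."""

    participant_id: int
    design_id: str
    condition: str
    block: int
    trial: int
    s_m: float
    probe1_sim: float | None = None
    probe1_dis: float | None = None
    probe2_sim: float | None = None
    probe2_dis: float | None = None
    judgment1: str | None = None
    judgment2: str | None = None
    response: float = 0.0
    confidence: int = 1

    def to_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "design_id": self.design_id,
            "condition": self.condition,
            "block": self.block,
            "trial": self.trial,
            "S_M": self.s_m,
            "probe1_sim": self.probe1_sim,
            "probe1_dis": self.probe1_dis,
            "probe2_sim": self.probe2_sim,
            "probe2_dis": self.probe2_dis,
            "judgment1": self.judgment1,
            "judgment2": self.judgment2,
            "response": self.response,
            "confidence": self.confidence,
        }


# ---------------------------------------------------------------------------
# probe sampling


def sample_probe_exp1(
    s_m: float, rng: np.random.Generator, lo: int = 16, hi: int = 105
) -> float:
    """One probe at an integer distance uniform on [lo, hi], side equiprobable."""
    dist = int(rng.integers(lo, hi + 1))
    side = 1 if rng.random() < 0.5 else -1
    return float(wrap_positive(s_m + side * dist))


def sample_probe_pairs_exp2(
    s_m: float,
    side_condition: str,
    rng: np.random.Generator,
    lo: int = 16,
    hi: int = 45,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Two (similar, dissimilar) probe pairs for the 2AFC design.

    Similar-probe distances are integer uniform on [lo, hi]; each dissimilar
    probe sits 180 deg from its similar probe.  In the ``"same"`` side
    condition both similar probes share the first pair's (equiprobable) side
    of the target; in ``"opposite"`` they straddle it.
    """
    if side_condition not in {"same", "opposite"}:
        raise InvalidDesignError(f"unknown side condition {side_condition!r}")
    side1 = 1 if rng.random() < 0.5 else -1
    side2 = side1 if side_condition == "same" else -side1
    pairs = []
    for side in (side1, side2):
        dist = int(rng.integers(lo, hi + 1))
        sim = float(wrap_positive(s_m + side * dist))
        dis = float(wrap_positive(sim + 180.0))
        pairs.append((sim, dis))
    return pairs[0], pairs[1]


# ---------------------------------------------------------------------------
# judgments


def simulate_similarity_judgment(
    x_m: float,
    s_p: float,
    c: float,
    beta: float,
    rng: np.random.Generator,
) -> str:
    """Binary similarity judgment from the noisy memory sample ``x_m``.

    P(similar) follows a logistic in the perceived memory-probe distance:
    0.5 at distance ``c``, approaching a hard threshold as ``beta`` shrinks.
    """
    if c <= 0 or beta <= 0:
        raise InvalidParameterError("c and beta must be > 0")
    from scipy.special import expit

    dist = abs(float(signed_circ_dist(x_m, s_p)))
    p_similar = float(expit((c - dist) / beta))
    return SIMILAR if rng.random() < p_similar else DISSIMILAR


def simulate_2afc_choice(
    x_m: float, probe_pair: Sequence[float], rng: np.random.Generator
) -> float:
    """Chosen probe of a pair: the one closer to the memory sample (ties random)."""
    d0 = abs(float(signed_circ_dist(x_m, probe_pair[0])))
    d1 = abs(float(signed_circ_dist(x_m, probe_pair[1])))
    if d0 == d1:
        return float(probe_pair[0] if rng.random() < 0.5 else probe_pair[1])
    return float(probe_pair[0] if d0 < d1 else probe_pair[1])


# ---------------------------------------------------------------------------
# single-trial simulation


def _sample_memory(s_m: float, kappa: float, rng: np.random.Generator) -> float:
    if kappa == 0:
        return float(rng.uniform(0.0, 360.0))
    return float(wrap_positive(s_m + np.rad2deg(rng.vonmises(0.0, kappa))))


def _sample_vm_grid(
    mu: float, kappa: float, rng: np.random.Generator, grid: CircularGrid
) -> float:
    """One draw from the discrete von Mises mass on ``grid``."""
    theta = np.deg2rad(grid.points - mu)
    w = np.exp(kappa * (np.cos(theta) - 1.0))
    cdf = np.cumsum(w)
    u = rng.random() * cdf[-1]
    idx = int(np.searchsorted(cdf, u, side="right"))
    return float(grid.points[min(idx, grid.n_points - 1)])


def _confidence(lapsed: bool, observer: ObserverSpec, rng: np.random.Generator) -> int:
    if lapsed:
        return 3
    return 1 if rng.random() < observer.p_high_conf else 2


def simulate_trial(
    design: ExperimentDesign,
    observer: ObserverSpec,
    condition: str,
    rng: np.random.Generator,
    participant_id: int = 0,
    block: int = 0,
    trial: int = 0,
    grid: CircularGrid = DEFAULT_GRID,
) -> TrialRecord:
    """Simulate one trial of ``design`` in ``condition`` for ``observer``.

    The target is uniform on the 360-valued wheel.  Probes and judgments are
    generated per the design; the report is drawn from the observer's
    generative response density (lapses report uniformly at confidence 3).
    Joint-model observers integrate each judged-similar probe sequentially
    into the memory density; mixture observers report a judged-similar probe
    instead of the memory with probability ``1 - alpha``.
    """
    if condition not in design.conditions:
        raise InvalidDesignError(
            f"condition {condition!r} not part of design {design.design_id}"
        )
    s_m = float(rng.integers(grid.n_points)) * grid.resolution
    kappa_m = observer.kappa_m
    if condition == "short_baseline" and observer.kappa_m_short is not None:
        kappa_m = observer.kappa_m_short
    x_m = _sample_memory(s_m, kappa_m, rng)

    probes: dict[str, float | None] = {
        "probe1_sim": None,
        "probe1_dis": None,
        "probe2_sim": None,
        "probe2_dis": None,
    }
    judgments: dict[str, str | None] = {"judgment1": None, "judgment2": None}
    integrated: list[float] = []  # probes the observer judged similar, in order

    is_baseline = condition in {"baseline", "short_baseline", "long_baseline"}
    if not is_baseline:
        if design.design_id == "exp1":
            probe = sample_probe_exp1(s_m, rng, design.probe_lo, design.probe_hi)
            probes["probe1_sim"] = probe
            judgments["judgment1"] = simulate_similarity_judgment(
                x_m, probe, observer.criterion_c, observer.judgment_beta, rng
            )
            if judgments["judgment1"] == SIMILAR:
                integrated.append(probe)
        else:
            if design.design_id == "exp2":
                side = "same" if condition == "same_side" else "opposite"
                pair1, pair2 = sample_probe_pairs_exp2(
                    s_m, side, rng, design.probe_lo, design.probe_hi
                )
                pairs = [pair1, pair2]
            else:  # exp3 experimental: a single pair, side equiprobable
                pair1, _ = sample_probe_pairs_exp2(
                    s_m, "same", rng, design.probe_lo, design.probe_hi
                )
                pairs = [pair1]
            for i, (sim, dis) in enumerate(pairs, start=1):
                probes[f"probe{i}_sim"] = sim
                probes[f"probe{i}_dis"] = dis
                chosen = simulate_2afc_choice(x_m, (sim, dis), rng)
                judgments[f"judgment{i}"] = SIMILAR if chosen == sim else DISSIMILAR
                integrated.append(chosen)

    lapsed = rng.random() < observer.lapse_rate
    if lapsed:
        response = float(rng.integers(grid.n_points)) * grid.resolution
    elif is_baseline or observer.generative_model == "baseline-only" or not integrated:
        response = _sample_vm_grid(s_m, kappa_m, rng, grid)
    elif observer.generative_model == "joint":
        mu, kappa = s_m, kappa_m
        for probe in integrated:
            mu, kappa = vm_product_closed_form(mu, kappa, probe, observer.kappa_p)
        response = _sample_vm_grid(mu, kappa, rng, grid)
    else:  # mixture
        if rng.random() < observer.alpha:
            response = _sample_vm_grid(s_m, kappa_m, rng, grid)
        else:
            target = integrated[int(rng.integers(len(integrated)))]
            response = _sample_vm_grid(target, observer.kappa_p, rng, grid)

    return TrialRecord(
        participant_id=participant_id,
        design_id=design.design_id,
        condition=condition,
        block=block,
        trial=trial,
        s_m=s_m,
        response=response,
        confidence=_confidence(lapsed, observer, rng),
        **probes,
        **judgments,
    )


# ---------------------------------------------------------------------------
# dataset generation


def generate_dataset(
    design: ExperimentDesign,
    population: Sequence[ObserverSpec],
    seed: int,
    grid: CircularGrid = DEFAULT_GRID,
) -> pd.DataFrame:
    """Simulate a full cohort: one row per trial, deterministic given ``seed``.

    Each participant runs on an independent substream spawned from the master
    seed, so per-participant data do not depend on cohort size or order of
    generation.
    """
    if len(population) == 0:
        raise InvalidParameterError("population must be non-empty")
    streams = np.random.SeedSequence(seed).spawn(len(population))
    rows: list[dict] = []
    for pid, (observer, ss) in enumerate(zip(population, streams)):
        rng = np.random.default_rng(ss)
        trial_no = 0
        for block in range(design.blocks):
            for condition, n in design.trials_per_block.items():
                for _ in range(n):
                    rec = simulate_trial(
                        design,
                        observer,
                        condition,
                        rng,
                        participant_id=pid,
                        block=block,
                        trial=trial_no,
                        grid=grid,
                    )
                    rows.append(rec.to_row())
                    trial_no += 1
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def generate_population_exp3(
    n: int,
    median_kappa: float = 12.0,
    sigma_log: float = 0.4,
    seed: int | np.random.Generator = 0,
    base: ObserverSpec | None = None,
) -> list[ObserverSpec]:
    """A population of observers whose memory precision varies log-normally.

    ``kappa_m`` is drawn i.i.d. from ``LogNormal(ln(median_kappa),
    sigma_log)``; all other parameters are shared (taken from ``base``).
    """
    if n < 2:
        raise InvalidParameterError("population size must be >= 2")
    if median_kappa <= 0 or sigma_log < 0:
        raise InvalidParameterError("median_kappa > 0 and sigma_log >= 0 required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = base if base is not None else ObserverSpec()
    kappas = rng.lognormal(mean=np.log(median_kappa), sigma=sigma_log, size=n)
    return [replace(base, kappa_m=float(k)) for k in kappas]
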