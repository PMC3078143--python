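"""Synthetic beat-interval cohorts with controllable STV.

Each subject's RR and QT series are independent stationary Gaussian AR(1)
processes around subject-level means.  The marginal noise SD is chosen by
inverting the STV definition: for lag-1 autocorrelation rho the successive
difference of a stationary AR(1) with marginal SD sigma is
N(0, 2 sigma^2 (1 - rho)), so over m differences normalised by 30*sqrt(2)

    E[STV] = (m / 30) * sigma * sqrt(2 (1 - rho) / pi)

and the calibrated SD for a target STV is

    sigma = target * (30 / m) * sqrt(pi / (2 (1 - rho)))

Subject heterogeneity is drawn on the scales the cohort is summarised on:
heart rate in bpm (RR mean = 60000/HR) and rate-corrected QT in ms, with
the subject QT mean tied to the subject RR mean through the
Fridericia-inverse coupling qt_mean = qtc * (rr_mean/1000)^(1/3).  The
population qtc is calibrated by Gauss-Hermite quadrature so that the
group-mean QT hits the scenario target despite the nonlinear coupling.
QT fluctuations are decoupled from RR fluctuations by construction, so
the two STV targets are independently controllable.

Ectopic contamination is injected as isolated 40%-premature RR beats that
keep the ``normal`` annotation — the preprocessing stage has to find them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .model import BeatIntervalSeries, SubjectRecord, ValidationError

__all__ = [
    "GroupScenario",
    "GeneratorConfig",
    "calibrate_noise_sd",
    "expected_stv",
    "generate_subject",
    "generate_cohort",
    "load_config",
    "soccer_study_config",
    "MANIFEST_COLUMNS",
]

#: fractional RR shortening of an injected premature (ectopic) beat
ECTOPIC_PREMATURITY = 0.40

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "true_hr_bpm",
    "true_rr_mean_ms",
    "true_qt_mean_ms",
    "true_qtc_ms",
    "true_stv_rr_ms",
    "true_stv_qt_ms",
    "sigma_rr_ms",
    "sigma_qt_ms",
    "lag1_corr",
    "n_ectopic_injected",
]


@dataclass(frozen=True)
class GroupScenario:
    """Generation targets for one group/session cell.

    Means and STV targets are group-level expectations; the four
    ``between_subject_sd_*`` fields control subject heterogeneity and
    default to 0 (every subject at the group target).
    """

    group: str
    session: str
    n_subjects: int
    mean_rr_ms: float
    mean_qt_ms: float
    target_stv_qt_ms: float
    target_stv_rr_ms: float
    lag1_corr: float = 0.0
    ectopic_rate: float = 0.0
    n_beats_per_subject: int = 300
    between_subject_sd_hr_bpm: float = 0.0
    between_subject_sd_qtc_ms: float = 0.0
    between_subject_sd_stv_qt_ms: float = 0.0
    between_subject_sd_stv_rr_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for name in ("mean_rr_ms", "mean_qt_ms", "target_stv_qt_ms", "target_stv_rr_ms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.mean_qt_ms >= self.mean_rr_ms:
            raise ValidationError("mean_qt_ms must be smaller than mean_rr_ms")
        if not 0 <= self.lag1_corr < 1:
            raise ValidationError("lag1_corr must be in [0, 1)")
        if not 0 <= self.ectopic_rate < 1:
            raise ValidationError("ectopic_rate must be in [0, 1)")
        if self.n_beats_per_subject < 40:
            raise ValidationError(
                "n_beats_per_subject must leave margin beyond the analysis "
                "window (>= 40)"
            )

    @property
    def hr_mean_bpm(self) -> float:
        return 60000.0 / self.mean_rr_ms


@dataclass(frozen=True)
class GeneratorConfig:
    """Scenario list plus the master seed.

    With ``standardize_traits`` (the default) the subject-level trait
    scores of each group are standardised to empirical mean 0 / SD 1, so
    the realised cohort moments match the scenario targets exactly
    (the ``mvrnorm(empirical=TRUE)`` convention); per-subject values are
    still Gaussian draws.  Set it to False for fully independent
    sampling, e.g. when studying cohort-to-cohort variability.
    """

    scenarios: tuple
    master_seed: int = 0
    standardize_traits: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        if not self.scenarios:
            raise ValidationError("config needs at least one scenario")


# ---------------------------------------------------------------------------
# STV calibration
# ---------------------------------------------------------------------------


def expected_stv(sigma: float, rho: float = 0.0, m: int = 30) -> float:
    """E[STV] of a stationary Gaussian AR(1) with marginal SD sigma."""
    if not 0 <= rho < 1:
        raise ValidationError("rho must be in [0, 1)")
    return (m / 30.0) * sigma * math.sqrt(2.0 * (1.0 - rho) / math.pi)


def calibrate_noise_sd(target_stv: float, rho: float = 0.0, m: int = 30) -> float:
    """Marginal AR(1) SD (ms) whose expected STV equals ``target_stv``.

    ``m`` is the number of successive differences the analysis window
    contributes (30 for the default 31-beat matched window).  At rho = 0
    this reduces to the i.i.d. form sigma = target * sqrt(pi/2) * 30/m.
    """
    if target_stv <= 0:
        raise ValidationError("target_stv must be positive")
    if not 0 <= rho < 1:
        raise ValidationError("rho must be in [0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return target_stv * (30.0 / m) * math.sqrt(math.pi / (2.0 * (1.0 - rho)))


def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary Gaussian AR(1) with marginal SD sigma, lag-1 corr rho."""
    if sigma == 0:
        return np.zeros(n)
    if rho == 0:
        return rng.normal(0.0, sigma, size=n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)  # stationary start
    e[1:] = rng.normal(0.0, sigma * math.sqrt(1.0 - rho * rho), size=n - 1)
    return signal.lfilter([1.0], [1.0, -rho], e)


def _expected_cbrt_factor(hr_mean: float, hr_sd: float) -> float:
    """E[(60/HR)^(1/3)] for HR ~ N(hr_mean, hr_sd), by Gauss-Hermite."""
    if hr_sd == 0:
        return (60.0 / hr_mean) ** (1.0 / 3.0)
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    h = np.maximum(hr_mean + hr_sd * nodes, 30.0)  # same floor as the draws
    return float(np.sum(weights * np.cbrt(60.0 / h)) / math.sqrt(2.0 * math.pi))


# ---------------------------------------------------------------------------
# Subject and cohort generation
# ---------------------------------------------------------------------------


def _place_ectopics(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    """Isolated (non-adjacent) beat indices in [6, n-2] for ectopic injection."""
    eligible = set(range(6, n - 1))
    chosen: list[int] = []
    order = rng.permutation(sorted(eligible))
    for idx in order:
        if len(chosen) == count:
            break
        if idx in eligible:
            chosen.append(int(idx))
            eligible -= {idx - 1, idx, idx + 1}
    return np.array(sorted(chosen), dtype=int)


def generate_subject(
    scenario: GroupScenario,
    seed: int | np.random.SeedSequence,
    subject_id: str = "S000",
    traits: dict | None = None,
) -> tuple[SubjectRecord, dict]:
    """One subject-session record plus its ground-truth parameters.

    ``traits`` optionally supplies the subject-level standard-normal
    scores (keys ``hr``, ``qtc``, ``stv_rr``, ``stv_qt``); sharing them
    across two scenarios of the same subject yields paired sessions with
    correlated traits.  Per-beat noise always comes from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if traits is None:
        traits = {k: float(rng.normal()) for k in ("hr", "qtc", "stv_rr", "stv_qt")}

    hr = max(scenario.hr_mean_bpm + scenario.between_subject_sd_hr_bpm * traits["hr"], 30.0)
    rr_mean = 60000.0 / hr
    qtc_pop = scenario.mean_qt_ms / _expected_cbrt_factor(
        scenario.hr_mean_bpm, scenario.between_subject_sd_hr_bpm
    )
    qtc_subject = qtc_pop + scenario.between_subject_sd_qtc_ms * traits["qtc"]
    qt_mean = qtc_subject * (rr_mean / 1000.0) ** (1.0 / 3.0)

    stv_rr_true = max(
        scenario.target_stv_rr_ms
        + scenario.between_subject_sd_stv_rr_ms * traits["stv_rr"],
        0.05 * scenario.target_stv_rr_ms,
    )
    stv_qt_true = max(
        scenario.target_stv_qt_ms
        + scenario.between_subject_sd_stv_qt_ms * traits["stv_qt"],
        0.05 * scenario.target_stv_qt_ms,
    )
    sigma_rr = calibrate_noise_sd(stv_rr_true, scenario.lag1_corr)
    sigma_qt = calibrate_noise_sd(stv_qt_true, scenario.lag1_corr)

    n = scenario.n_beats_per_subject
    rr = rr_mean + _ar1(rng, n, sigma_rr, scenario.lag1_corr)
    qt = qt_mean + _ar1(rng, n, sigma_qt, scenario.lag1_corr)

    n_ect = int(rng.binomial(n, scenario.ectopic_rate)) if scenario.ectopic_rate else 0
    ect_idx = _place_ectopics(rng, n, n_ect) if n_ect else np.array([], dtype=int)
    if ect_idx.size:
        rr[ect_idx] *= 1.0 - ECTOPIC_PREMATURITY

    # physiological containment: QT inside its cycle everywhere
    qt = np.minimum(qt, 0.9 * rr)

    rr = np.round(rr, 1)  # 0.1 ms quantisation, as acquired at ~1 kHz
    qt = np.round(qt, 1)
    ann = np.full(n, "normal", dtype="U10")  # injected ectopics stay hidden

    record = SubjectRecord(
        subject_id=subject_id,
        group=scenario.group,
        session=scenario.session,
        series=BeatIntervalSeries(rr, qt, ann),
    )
    truth = {
        "subject_id": subject_id,
        "group": scenario.group,
        "session": scenario.session,
        "true_hr_bpm": hr,
        "true_rr_mean_ms": rr_mean,
        "true_qt_mean_ms": qt_mean,
        "true_qtc_ms": qtc_subject,
        "true_stv_rr_ms": stv_rr_true,
        "true_stv_qt_ms": stv_qt_true,
        "sigma_rr_ms": sigma_rr,
        "sigma_qt_ms": sigma_qt,
        "lag1_corr": scenario.lag1_corr,
        "n_ectopic_injected": int(ect_idx.size),
    }
    return record, truth


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate every scenario; returns (records, ground-truth manifest).

    Subjects of a group appearing in several sessions (players at rest and
    post-game) share subject ids and subject-level trait scores, giving a
    paired design.  All randomness derives deterministically from
    ``config.master_seed``.
    """
    scenarios = config.scenarios
    # sessions of one group must pair up
    n_by_group: dict[str, int] = {}
    for sc in scenarios:
        if sc.group in n_by_group and n_by_group[sc.group] != sc.n_subjects:
            raise ValidationError(
                f"scenarios of group {sc.group!r} disagree on n_subjects"
            )
        n_by_group.setdefault(sc.group, sc.n_subjects)

    trait_rng = np.random.default_rng(
        np.random.SeedSequence(config.master_seed, spawn_key=(0,))
    )
    traits_by_group: dict[str, list[dict]] = {}
    for group in sorted(n_by_group):
        z = trait_rng.normal(size=(n_by_group[group], 4))
        if config.standardize_traits and len(z) >= 2:
            sd = z.std(axis=0)
            sd[sd == 0] = 1.0
            z = (z - z.mean(axis=0)) / sd
        traits_by_group[group] = [
            {"hr": row[0], "qtc": row[1], "stv_rr": row[2], "stv_qt": row[3]}
            for row in z
        ]

    noise_ss = np.random.SeedSequence(config.master_seed, spawn_key=(1,))
    children = iter(noise_ss.spawn(sum(sc.n_subjects for sc in scenarios)))

    records: list[SubjectRecord] = []
    truths: list[dict] = []
    for sc in scenarios:
        for i in range(sc.n_subjects):
            sid = f"{sc.group}_{i + 1:03d}"
            rec, truth = generate_subject(
                sc, next(children), subject_id=sid, traits=traits_by_group[sc.group][i]
            )
            records.append(rec)
            truths.append(truth)
    manifest = pd.DataFrame(truths, columns=MANIFEST_COLUMNS)
    return records, manifest


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------


def _scenario_from_mapping(d: dict) -> GroupScenario:
    try:
        return GroupScenario(**d)
    except TypeError as exc:
        raise ValidationError(f"bad scenario entry: {exc}") from exc


def load_config(path: str | Path, master_seed: int | None = None) -> GeneratorConfig:
    """Load a YAML scenario file; ``master_seed`` overrides the file's."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such scenario file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "scenarios" not in raw:
        raise ValidationError(f"{path}: scenario file needs a 'scenarios' list")
    scenarios = tuple(_scenario_from_mapping(d) for d in raw["scenarios"])
    seed = master_seed if master_seed is not None else int(raw.get("master_seed", 0))
    return GeneratorConfig(scenarios=scenarios, master_seed=seed)


def soccer_study_config(
    master_seed: int | None = None, n_subjects: int | None = None
) -> GeneratorConfig:
    """The packaged three-cell soccer-cohort scenario.

    Sedentary controls, professional players at rest and the same players
    post-game, calibrated to the reported group means (HR 72 vs 61 bpm,
    QT 390 vs 419 ms, STV_QT 3.5 / 4.8 / 4.3 ms, n = 76 per group).
    """
    with resources.as_file(
        resources.files("qtvar").joinpath("scenarios/soccer_cohort.yaml")
    ) as p:
        config = load_config(p, master_seed=master_seed)
    if n_subjects is not None:
        config = GeneratorConfig(
            scenarios=tuple(
                GroupScenario(**{**sc.__dict__, "n_subjects": n_subjects})
                for sc in config.scenarios
            ),
            master_seed=config.master_seed,
        )
    return config
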