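"""Synthetic paired hospital/verbal-autopsy cohorts.

Generates everything the validation pipeline consumes, with the statistical
structure the analysis assumes: a true (reference) cause drawn from a
configured cause-specific mortality fraction (CSMF) profile, a VA cause drawn
from a row-stochastic confusion matrix, case records whose eligibility flags
make the assignment hierarchy reproduce the reference cause exactly, and
dual-reviewer-plus-arbiter review tables whose adjudication reproduces the
configured consensus and arbiter-agreement rates.

The analysis labels emitted in ``labels`` are the drawn causes themselves:
reviewer disagreement is modelled as measurement noise *around* those labels,
so the rare all-three-differ adjudications (which resolve to unclassifiable)
perturb the adjudication accounting but not the label pairs used for
accuracy estimation.

Covariates follow the emulated study population: age at death ~ normal(5.9,
6.7) days resampled into 0-28 completed days, gestation ~ normal(33.6, 4.1)
weeks (below 33 weeks for prematurity deaths, so labels stay clinically
coherent), 59.6% male, birth weight ~ normal(2398.6, 1578.4) g.  Covariate
draws are rejected and resampled until they are compatible with the intended
cause's position in the hierarchy (e.g. tetanus needs age >= 3 days,
asphyxia age < 7 days); out-of-range draws are resampled, never clipped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .causes import ASSIGNABLE, SEVERE_INFECTION, Cause
from .hierarchy import (
    GESTATION_BAND_THRESHOLD_WEEKS,
    PREMATURITY_DEFINITION_WEEKS,
    stratum_of,
)

_CAUSE_ORDER = [c for c in Cause if c not in (Cause.UNCLASSIFIABLE,)]

#: Emulated study profile: reference-cause counts over 626 deaths.
STUDY_REFERENCE_COUNTS: dict[Cause, int] = {
    Cause.CONGENITAL_ANOMALIES: 14,
    Cause.PREMATURITY_COMPLICATIONS: 224,
    Cause.BIRTH_ASPHYXIA: 176,
    Cause.TETANUS: 9,
    Cause.PNEUMONIA: 11,
    Cause.MENINGITIS: 1,
    Cause.DIARRHEA: 1,
    Cause.SEPSIS: 162,
    Cause.UNEXPLAINED: 17,
    Cause.OTHER_SPECIFIC: 11,
}
STUDY_N = sum(STUDY_REFERENCE_COUNTS.values())  # 626

#: Per-cause probability the VA diagnosis agrees with the reference
#: diagnosis.  The five validated causes use the study's observed
#: sensitivities (infection members share the composite's rate); the two
#: residual categories get 0.5, a deliberately noisy default.
STUDY_DIAGONAL: dict[Cause, float] = {
    Cause.CONGENITAL_ANOMALIES: 8 / 14,
    Cause.PREMATURITY_COMPLICATIONS: 209 / 224,
    Cause.BIRTH_ASPHYXIA: 147 / 176,
    Cause.TETANUS: 6 / 9,
    Cause.SEPSIS: 138 / 175,
    Cause.MENINGITIS: 138 / 175,
    Cause.PNEUMONIA: 138 / 175,
    Cause.DIARRHEA: 138 / 175,
    Cause.UNEXPLAINED: 0.5,
    Cause.OTHER_SPECIFIC: 0.5,
}

#: Observed reviewer pairwise agreement and arbiter agreement rates.
STUDY_REVIEWER_AGREEMENT = {"hospital": 494 / 626, "verbal_autopsy": 461 / 626}
STUDY_ARBITER_MATCH = {"hospital": 127 / 132, "verbal_autopsy": 146 / 165}


class ConfigError(ValueError):
    """A simulation-config field failed validation."""


@dataclass
class CovariateModel:
    """Distributional assumptions for demographics and timing."""

    age_mean_days: float = 5.9
    age_sd_days: float = 6.7
    gestation_mean_weeks: float = 33.6
    gestation_sd_weeks: float = 4.1
    gestation_range_weeks: tuple[float, float] = (22.0, 44.0)
    p_male: float = 0.596
    birth_weight_mean_g: float = 2398.6
    birth_weight_sd_g: float = 1578.4
    birth_weight_range_g: tuple[float, float] = (300.0, 6000.0)


@dataclass
class SimulationConfig:
    """Full specification of a synthetic paired cohort."""

    n_cases: int
    csmf: Mapping[Cause, float]
    confusion: pd.DataFrame
    reviewer_agreement: Mapping[str, float]
    arbiter_match_prob: Mapping[str, float]
    covariates: CovariateModel = field(default_factory=CovariateModel)
    extra_flag_prob: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ConfigError(f"n_cases must be positive, got {self.n_cases}")
        if abs(sum(self.csmf.values()) - 1.0) > 1e-8:
            raise ConfigError(f"csmf must sum to 1, got {sum(self.csmf.values()):.6f}")
        for cause, p in self.csmf.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"csmf[{cause}] = {p} outside [0, 1]")
        rows = self.confusion.to_numpy(dtype=float)
        if (rows < -1e-12).any() or (rows > 1 + 1e-12).any():
            raise ConfigError("confusion entries must lie in [0, 1]")
        bad = np.where(np.abs(rows.sum(axis=1) - 1.0) > 1e-8)[0]
        if bad.size:
            name = self.confusion.index[bad[0]]
            raise ConfigError(f"confusion row {name!r} does not sum to 1")
        for name, mapping in (
            ("reviewer_agreement", self.reviewer_agreement),
            ("arbiter_match_prob", self.arbiter_match_prob),
        ):
            for src in ("hospital", "verbal_autopsy"):
                if src not in mapping:
                    raise ConfigError(f"{name} missing source {src!r}")
                if not 0 <= mapping[src] <= 1:
                    raise ConfigError(f"{name}[{src}] = {mapping[src]} outside [0, 1]")
        if not 0 <= self.extra_flag_prob <= 1:
            raise ConfigError(f"extra_flag_prob = {self.extra_flag_prob} outside [0, 1]")


def confusion_from_diagonal(
    diagonal: Mapping[Cause, float], csmf: Mapping[Cause, float]
) -> pd.DataFrame:
    """Build a row-stochastic confusion matrix from per-cause agreement rates.

    Row ``c`` puts ``diagonal[c]`` on ``c`` and spreads the remaining mass
    over the other causes proportionally to their CSMF (a misdiagnosis is
    more likely to land on a common cause than a rare one).
    """
    causes = [c for c in _CAUSE_ORDER if c in csmf]
    mat = pd.DataFrame(
        0.0, index=[c.value for c in causes], columns=[c.value for c in causes]
    )
    for c in causes:
        d = float(diagonal[c])
        if not 0 <= d <= 1:
            raise ConfigError(f"diagonal[{c}] = {d} outside [0, 1]")
        others = [j for j in causes if j is not c]
        weight = sum(csmf[j] for j in others)
        mat.loc[c.value, c.value] = d
        for j in others:
            mat.loc[c.value, j.value] = (1 - d) * csmf[j] / weight
    return mat


def default_study_config(n_cases: int = STUDY_N, seed: int = 0) -> SimulationConfig:
    """The emulated study conditions: CSMF, confusion structure, reviewer
    agreement and covariate distributions of the validation cohort."""
    csmf = {c: n / STUDY_N for c, n in STUDY_REFERENCE_COUNTS.items()}
    cfg = SimulationConfig(
        n_cases=n_cases,
        csmf=csmf,
        confusion=confusion_from_diagonal(STUDY_DIAGONAL, csmf),
        reviewer_agreement=dict(STUDY_REVIEWER_AGREEMENT),
        arbiter_match_prob=dict(STUDY_ARBITER_MATCH),
        seed=seed,
    )
    cfg.validate()
    return cfg


_CONFIG_KEYS = {
    "n_cases", "seed", "csmf", "confusion", "reviewer_agreement",
    "arbiter_match_prob", "covariates", "extra_flag_prob",
}


def config_from_dict(data: Mapping, *, seed: Optional[int] = None) -> SimulationConfig:
    """Build a config from a plain mapping (parsed YAML/JSON).

    Unspecified fields fall back to the default study profile.  ``confusion``
    may be given either as ``{"diagonal": {cause: p, ...}}`` (off-diagonal
    mass spread by CSMF) or as a full nested ``{ref: {va: p}}`` matrix.
    ``seed`` passed here overrides one in the mapping.
    """
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    base = default_study_config()

    csmf = base.csmf
    if "csmf" in data:
        csmf = {Cause.parse(k): float(v) for k, v in data["csmf"].items()}

    if "confusion" in data:
        spec = data["confusion"]
        if "diagonal" in spec:
            diagonal = {Cause.parse(k): float(v) for k, v in spec["diagonal"].items()}
            missing = set(csmf) - set(diagonal)
            if missing:
                raise ConfigError(
                    f"confusion.diagonal missing cause(s): {sorted(c.value for c in missing)}"
                )
            confusion = confusion_from_diagonal(diagonal, csmf)
        else:
            names = [c.value for c in csmf]
            confusion = pd.DataFrame(
                [[float(spec[r].get(c, 0.0)) for c in names] for r in names],
                index=names, columns=names,
            )
    elif "csmf" in data:
        confusion = confusion_from_diagonal(STUDY_DIAGONAL, csmf)
    else:
        confusion = base.confusion

    cov_data = dict(data.get("covariates", {}))
    unknown_cov = set(cov_data) - {f.name for f in CovariateModel.__dataclass_fields__.values()}
    if unknown_cov:
        raise ConfigError(f"unknown covariates field(s): {sorted(unknown_cov)}")
    for key in ("gestation_range_weeks", "birth_weight_range_g"):
        if key in cov_data:
            cov_data[key] = tuple(cov_data[key])

    cfg = SimulationConfig(
        n_cases=int(data.get("n_cases", base.n_cases)),
        csmf=csmf,
        confusion=confusion,
        reviewer_agreement=dict(data.get("reviewer_agreement", base.reviewer_agreement)),
        arbiter_match_prob=dict(data.get("arbiter_match_prob", base.arbiter_match_prob)),
        covariates=CovariateModel(**cov_data),
        extra_flag_prob=float(data.get("extra_flag_prob", base.extra_flag_prob)),
        seed=int(seed if seed is not None else data.get("seed", 0)),
    )
    cfg.validate()
    return cfg


@dataclass
class SimulatedCohort:
    """Output tables of one simulation run."""

    cases: pd.DataFrame  # case records with elig_* flag columns
    hospital_reviews: pd.DataFrame  # long format: case_id, reviewer_id, round, cause
    va_reviews: pd.DataFrame
    labels: pd.DataFrame  # case_id, reference_cause, va_cause (analysis labels)


def _covariates_ok(cause: Cause, age_days: int, gestation: float) -> bool:
    """Is the intended cause reachable in the stratum these covariates select?"""
    if cause is Cause.BIRTH_ASPHYXIA and age_days >= 7:
        return False
    if cause is Cause.TETANUS and age_days < 3:
        return False
    if cause in SEVERE_INFECTION and (
        age_days < 3 and gestation < GESTATION_BAND_THRESHOLD_WEEKS
    ):
        return False
    if cause is Cause.OTHER_SPECIFIC and gestation < GESTATION_BAND_THRESHOLD_WEEKS:
        return False
    if (
        cause is Cause.PREMATURITY_COMPLICATIONS
        and gestation >= PREMATURITY_DEFINITION_WEEKS
    ):
        return False
    return True


def _draw_covariates(
    rng: np.random.Generator, cov: CovariateModel, cause: Cause
) -> tuple[int, float]:
    """Rejection-sample (age in completed days, gestation in weeks)."""
    g_lo, g_hi = cov.gestation_range_weeks
    for _ in range(100_000):
        age_cont = rng.normal(cov.age_mean_days, cov.age_sd_days)
        if not 0 <= age_cont < 29:
            continue
        age = int(age_cont)
        gestation = round(
            float(rng.normal(cov.gestation_mean_weeks, cov.gestation_sd_weeks)), 1
        )
        if not g_lo <= gestation <= g_hi:
            continue
        if _covariates_ok(cause, age, gestation):
            return age, gestation
    raise RuntimeError(f"covariate rejection sampling failed for {cause}")


def _eligibility_flags(
    rng: np.random.Generator,
    cause: Cause,
    age_days: int,
    gestation: float,
    extra_flag_prob: float,
) -> dict[Cause, bool]:
    """Flags that make the hierarchy yield exactly ``cause``.

    The intended cause's flag is true, every higher-priority flag in the
    case's stratum is false, and lower-priority flags are set true at random
    (they cannot change the first match).  An unexplained death has no flag
    set at all.
    """
    flags = {c: False for c in ASSIGNABLE}
    if cause is Cause.UNEXPLAINED:
        return flags
    stratum = stratum_of(age_days, gestation)
    idx = None
    for i, entry in enumerate(stratum.ordered_causes):
        if entry.cause is cause and (
            entry.max_age_days is None or age_days < entry.max_age_days
        ):
            idx = i
            break
    if idx is None:  # guarded against by _covariates_ok
        raise RuntimeError(f"{cause} unreachable in stratum {stratum.age_band}")
    flags[cause] = True
    for entry in stratum.ordered_causes[idx + 1 :]:
        if rng.random() < extra_flag_prob:
            flags[entry.cause] = True
    return flags


def _draw_other(
    rng: np.random.Generator,
    causes: list[Cause],
    probs: np.ndarray,
    exclude: set[Cause],
) -> Cause:
    mask = np.array([c not in exclude for c in causes], dtype=float)
    w = probs * mask
    if w.sum() <= 0:
        w = mask
    return causes[rng.choice(len(causes), p=w / w.sum())]


def _reviews_for(
    rng: np.random.Generator,
    case_id: str,
    label: Cause,
    agreement: float,
    arbiter_match: float,
    causes: list[Cause],
    probs: np.ndarray,
    reviewer_prefix: str,
) -> list[dict]:
    """Review rows consistent with the case's final label.

    With probability ``agreement`` both primary reviewers call the label.
    Otherwise one reviewer (chosen at random) carries the label and the other
    calls a different cause; the arbiter then sides with the label-carrier
    with probability ``arbiter_match`` and otherwise calls a third cause,
    which adjudicates to unclassifiable.
    """
    r1 = f"{reviewer_prefix}1"
    r2 = f"{reviewer_prefix}2"
    arb = f"{reviewer_prefix}3"
    rows = []
    if rng.random() < agreement:
        rows.append({"case_id": case_id, "reviewer_id": r1, "round": "primary", "cause": label.value})
        rows.append({"case_id": case_id, "reviewer_id": r2, "round": "primary", "cause": label.value})
        return rows
    other = _draw_other(rng, causes, probs, {label})
    carrier_first = rng.random() < 0.5
    c1, c2 = (label, other) if carrier_first else (other, label)
    rows.append({"case_id": case_id, "reviewer_id": r1, "round": "primary", "cause": c1.value})
    rows.append({"case_id": case_id, "reviewer_id": r2, "round": "primary", "cause": c2.value})
    if rng.random() < arbiter_match:
        arb_cause = label
    else:
        arb_cause = _draw_other(rng, causes, probs, {label, other})
    rows.append({"case_id": case_id, "reviewer_id": arb, "round": "arbiter", "cause": arb_cause.value})
    return rows


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one reproducible paired cohort from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    causes = [c for c in _CAUSE_ORDER if c in config.csmf]
    p_ref = np.array([config.csmf[c] for c in causes])
    conf = config.confusion.loc[[c.value for c in causes], [c.value for c in causes]]
    conf_rows = conf.to_numpy(dtype=float)
    cov = config.covariates

    width = len(str(config.n_cases))
    case_rows, hosp_rows, va_rows, label_rows = [], [], [], []
    for i in range(config.n_cases):
        case_id = f"case-{i + 1:0{width}d}"
        ref_cause = causes[rng.choice(len(causes), p=p_ref)]
        va_cause = causes[rng.choice(len(causes), p=conf_rows[causes.index(ref_cause)])]
        age, gestation = _draw_covariates(rng, cov, ref_cause)
        sex = "male" if rng.random() < cov.p_male else "female"
        bw_lo, bw_hi = cov.birth_weight_range_g
        while True:
            bw = rng.normal(cov.birth_weight_mean_g, cov.birth_weight_sd_g)
            if bw_lo <= bw <= bw_hi:
                break
        flags = _eligibility_flags(rng, ref_cause, age, gestation, config.extra_flag_prob)
        row = {
            "case_id": case_id,
            "age_at_death_days": age,
            "gestation_weeks": gestation,
            "sex": sex,
            "birth_weight_g": round(float(bw), 1),
            "source": "hospital",
        }
        row.update({f"elig_{c.value}": flags[c] for c in ASSIGNABLE})
        case_rows.append(row)
        hosp_rows.extend(
            _reviews_for(
                rng, case_id, ref_cause,
                config.reviewer_agreement["hospital"],
                config.arbiter_match_prob["hospital"],
                causes, p_ref, "HR",
            )
        )
        va_rows.extend(
            _reviews_for(
                rng, case_id, va_cause,
                config.reviewer_agreement["verbal_autopsy"],
                config.arbiter_match_prob["verbal_autopsy"],
                causes, p_ref, "VA",
            )
        )
        label_rows.append(
            {"case_id": case_id, "reference_cause": ref_cause.value, "va_cause": va_cause.value}
        )

    return SimulatedCohort(
        cases=pd.DataFrame(case_rows),
        hospital_reviews=pd.DataFrame(hosp_rows),
        va_reviews=pd.DataFrame(va_rows),
        labels=pd.DataFrame(label_rows),
    )
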