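"""Synthetic mixed-type cohorts with latent fit/frail structure.

Generates binary, ordinal, and continuous health variables whose
distributions differ between two latent classes, diagnosis labels from a
multinomial logit on the latent class and FI, and right-censored conversion
times whose log-hazard is linear in FI x 100.  All randomness derives from a
single master seed fanned out to named per-component PCG64 streams, so adding
one deficit type never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deficits import Codebook, DeficitSpec, ReferenceRange, compute_fi

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "simulate_survival", "make_codebook"]

_STREAMS = ("class", "binary", "ordinal", "continuous", "covariates", "diagnosis", "survival", "missing")

#: ordinal level -> deficit score used for generated four-level items
ORDINAL_SCORES = {0: 0.0, 1: 0.25, 2: 0.5, 3: 1.0}


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 600
    mix: float = 0.5
    n_binary: int = 20
    n_ordinal: int = 5
    n_continuous: int = 10
    informative_fraction: float = 0.4
    effect_binary: float = 1.5
    effect_continuous: float = 1.0
    base_prevalence: float | None = None  # fixed binary base prevalence; random in (0.05, 0.4) when None
    ordinal_levels: int = 4
    diag_model: dict = field(
        default_factory=lambda: {
            # multinomial logit vs HC baseline: intercept, latent-class weight, FI weight
            "mci": (0.3, 1.6, 2.0),
            "ad": (-2.2, 4.4, 3.0),
        }
    )
    surv_shape: float = 1.2
    surv_scale: float = 1800.0   # days
    beta_fi: float = np.log(1.04)  # per unit of FI x 100
    censor_rate: float = 0.3
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0 < self.mix < 1:
            raise ValueError("mix must lie in (0, 1)")
        for fld in ("informative_fraction", "censor_rate", "missing_rate"):
            v = getattr(self, fld)
            if not 0 <= v <= 1:
                raise ValueError(f"{fld} must lie in [0, 1]")
        if min(self.n_binary, self.n_ordinal, self.n_continuous) < 0:
            raise ValueError("deficit counts must be >= 0")
        if self.surv_shape <= 0 or self.surv_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        if self.ordinal_levels < 2:
            raise ValueError("ordinal_levels must be >= 2")
        if self.base_prevalence is not None and not 0 < self.base_prevalence < 1:
            raise ValueError("base_prevalence must lie in (0, 1)")


@dataclass
class GroundTruth:
    latent_label: np.ndarray          # "fit" / "frail" per subject
    informative_set: list[str]
    true_beta_fi: float

    def to_dict(self) -> dict:
        return {
            "latent_label": self.latent_label.tolist(),
            "informative_set": list(self.informative_set),
            "true_beta_fi": float(self.true_beta_fi),
        }


@dataclass
class SurvivalData:
    time: np.ndarray
    event: np.ndarray


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.Generator(np.random.PCG64(ss)) for name, ss in zip(_STREAMS, children)}


def _informative_flags(n_items: int, fraction: float) -> np.ndarray:
    # deterministic: the first ceil(fraction * n) items of each block are informative
    k = int(np.ceil(fraction * n_items)) if n_items else 0
    flags = np.zeros(n_items, dtype=bool)
    flags[:k] = True
    return flags


def make_codebook(config: SimConfig) -> Codebook:
    """Codebook describing the simulated columns (coding + covariate names)."""
    deficits: list[DeficitSpec] = []
    for j in range(config.n_binary):
        deficits.append(DeficitSpec(name=f"bin{j:02d}", kind="binary", coding={0: 0.0, 1: 1.0}))
    L = config.ordinal_levels
    if L == 4:
        coding = dict(ORDINAL_SCORES)
    else:
        coding = {lv: lv / (L - 1) for lv in range(L)}
    for j in range(config.n_ordinal):
        deficits.append(DeficitSpec(name=f"ord{j:02d}", kind="ordinal", coding=dict(coding)))
    for j in range(config.n_continuous):
        # generating distribution for the fit class is N(0, 1): +-2 SD reference range
        deficits.append(
            DeficitSpec(name=f"con{j:02d}", kind="continuous", ranges=(ReferenceRange(-2.0, 2.0),))
        )
    covariates = {
        "age": "age", "sex": "sex", "education": "education", "diagnosis": "diagnosis",
        "cdrsb": "cdrsb", "mmse": "mmse", "time": "time", "event": "event",
    }
    return Codebook(deficits=deficits, covariates=covariates)


def simulate_survival(fi: np.ndarray, config: SimConfig, rng: np.random.Generator | None = None) -> SurvivalData:
    """Right-censored Weibull conversion times with log-hazard beta_fi * (100 * FI).

    Event times follow a Weibull proportional-hazards model with baseline
    shape/scale from the config; censoring is independent (same-shape Weibull
    with scale solved so the marginal censoring fraction approximates
    ``censor_rate`` when beta_fi is small).
    """
    fi = np.asarray(fi, dtype=float)
    if np.any((fi < 0) | (fi > 1)):
        raise ValueError("fi values must lie in [0, 1]")
    if rng is None:
        rng = _streams(config.seed)["survival"]
    n = fi.size
    k, scale = config.surv_shape, config.surv_scale
    eta = config.beta_fi * 100.0 * fi
    u = rng.uniform(size=n)
    times = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / k)

    r = config.censor_rate
    if r <= 0:
        return SurvivalData(time=times, event=np.ones(n, dtype=int))
    if r >= 1:
        return SurvivalData(time=rng.uniform(0, scale, size=n), event=np.zeros(n, dtype=int))
    scale_c = scale * ((1 - r) / r) ** (1.0 / k)
    censor = scale_c * (-np.log(rng.uniform(size=n))) ** (1.0 / k)
    event = (times <= censor).astype(int)
    return SurvivalData(time=np.minimum(times, censor), event=event)


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a cohort table plus its generating ground truth.

    Binary deficits are Bernoulli with a class-dependent log-odds shift on
    informative items; ordinal items follow a proportional-odds latent
    logistic with a class shift; continuous items are Gaussian with a
    class-dependent mean.  Diagnosis comes from a multinomial logit on the
    latent class and provisional FI; time/event from :func:`simulate_survival`.
    """
    rng = _streams(config.seed)
    n = config.n_subjects
    frail = rng["class"].uniform(size=n) < config.mix
    latent = np.where(frail, "frail", "fit")

    columns: dict[str, np.ndarray] = {}
    informative: list[str] = []

    flags_b = _informative_flags(config.n_binary, config.informative_fraction)
    if config.base_prevalence is not None:
        base_prev = np.full(config.n_binary, config.base_prevalence)
    else:
        base_prev = 0.05 + 0.35 * rng["binary"].uniform(size=config.n_binary) if config.n_binary else np.empty(0)
    for j in range(config.n_binary):
        logit0 = np.log(base_prev[j] / (1 - base_prev[j]))
        shift = config.effect_binary if flags_b[j] else 0.0
        p = 1.0 / (1.0 + np.exp(-(logit0 + shift * frail)))
        columns[f"bin{j:02d}"] = (rng["binary"].uniform(size=n) < p).astype(int)
        if flags_b[j] and config.effect_binary != 0:
            informative.append(f"bin{j:02d}")

    L = config.ordinal_levels
    flags_o = _informative_flags(config.n_ordinal, config.informative_fraction)
    # proportional-odds cutpoints put most mass at level 0 for the fit class
    qs = np.linspace(0.6, 0.95, L - 1)
    cutpoints = np.log(qs / (1 - qs))
    for j in range(config.n_ordinal):
        shift = config.effect_binary if flags_o[j] else 0.0
        latent_score = rng["ordinal"].logistic(size=n) + shift * frail
        levels = (latent_score[:, None] > cutpoints[None, :]).sum(axis=1)
        columns[f"ord{j:02d}"] = levels.astype(int)
        if flags_o[j] and config.effect_binary != 0:
            informative.append(f"ord{j:02d}")

    flags_c = _informative_flags(config.n_continuous, config.informative_fraction)
    for j in range(config.n_continuous):
        shift = config.effect_continuous if flags_c[j] else 0.0
        columns[f"con{j:02d}"] = rng["continuous"].normal(size=n) + shift * frail
        if flags_c[j] and config.effect_continuous != 0:
            informative.append(f"con{j:02d}")

    cohort = pd.DataFrame(columns)
    codebook = make_codebook(config)

    # provisional FI on the complete coded deficits drives diagnosis + survival
    from .deficits import build_deficit_matrix

    matrix = build_deficit_matrix(cohort, codebook, items=codebook.names)
    fi = compute_fi(matrix, codebook.names).to_numpy()
    fi = np.clip(np.nan_to_num(fi), 0.0, 1.0)

    cov_rng = rng["covariates"]
    cohort["age"] = np.round(cov_rng.normal(74, 7, size=n), 1)
    cohort["sex"] = np.where(cov_rng.uniform(size=n) < 0.55, "male", "female")
    cohort["education"] = np.clip(np.round(cov_rng.normal(16, 2.7, size=n)), 6, 20).astype(int)

    fi_centered = fi - fi.mean()
    diag_rng = rng["diagnosis"]
    eta_mci = config.diag_model["mci"][0] + config.diag_model["mci"][1] * frail + config.diag_model["mci"][2] * fi_centered
    eta_ad = config.diag_model["ad"][0] + config.diag_model["ad"][1] * frail + config.diag_model["ad"][2] * fi_centered
    expo = np.column_stack([np.zeros(n), eta_mci, eta_ad])
    probs = np.exp(expo - expo.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    draws = diag_rng.uniform(size=n)
    cum = probs.cumsum(axis=1)
    diag_idx = (draws[:, None] > cum).sum(axis=1)
    diagnosis = np.array(["HC", "MCI", "AD"])[diag_idx]
    cohort["diagnosis"] = diagnosis

    cdrsb_mean = np.select([diagnosis == "HC", diagnosis == "MCI"], [0.0, 1.5], default=4.5)
    cdrsb = np.clip(cov_rng.normal(cdrsb_mean, 0.8), 0, 18)
    cdrsb = np.round(cdrsb * 2) / 2
    cdrsb[diagnosis == "HC"] = 0.0
    cohort["cdrsb"] = cdrsb
    mmse_mean = np.select([diagnosis == "HC", diagnosis == "MCI"], [29.0, 27.0], default=23.0)
    cohort["mmse"] = np.clip(np.round(cov_rng.normal(mmse_mean, 1.5)), 0, 30).astype(int)

    surv = simulate_survival(fi, config, rng=rng["survival"])
    cohort["time"] = np.round(surv.time, 1)
    cohort["event"] = surv.event

    if config.missing_rate > 0:
        deficit_cols = codebook.names
        mask = rng["missing"].uniform(size=(n, len(deficit_cols))) < config.missing_rate
        block = cohort[deficit_cols].astype(object)
        block = block.mask(pd.DataFrame(mask, index=cohort.index, columns=deficit_cols))
        cohort[deficit_cols] = block

    truth = GroundTruth(latent_label=latent, informative_set=informative, true_beta_fi=config.beta_fi)
    return cohort, truth
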