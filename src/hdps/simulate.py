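"""Synthetic claims-data generator with a known confounding structure.

Emulates the setting the HDPS is designed for: a treatment cohort drawn from
a coded healthcare database where confounding operates through latent
patient-level constructs (frailty, disease severity, health-seeking
behaviour) that are never observed directly but leave noisy proxy codes in
several data dimensions (e.g. clinical, referral, therapy streams recorded
in the year before cohort entry).

Generative model
----------------
* Latent confounders ``Z_1..Z_K`` are independent standard normals; an
  additional exposure-only latent ``U`` (also standard normal) drives the
  planted near-instrument codes.
* Exposure is Bernoulli with
  ``logit P(X=1) = b0 + confounding_log_hr * (Z_1+..+Z_K) + iv_exposure_log_or * U``.
* The event time is exponential with hazard
  ``baseline_hazard * exp(true_log_hr * X + confounding_log_hr * (Z_1+..+Z_K)
  + small age/sex effects)``, administratively censored at
  ``admin_censor_time``. The pre-defined covariates (``age_std``, ``sex``)
  predict the outcome only, so all confounding of the exposure effect is
  routed through the latent constructs.
* Each code ``j`` has a base Poisson rate ``r_j``; a confounder-proxy code
  assigned to latent ``k`` has per-patient rate ``r_j * exp(proxy_loading * Z_k)``,
  an iv_like code has rate ``r_j * exp(iv_code_loading * U)``, and a noise
  code has constant rate ``r_j``. Counts are expanded to dated event records
  uniform within the lookback window before each patient's index date.

Because ``U`` never enters the hazard, iv_like codes have a true
covariate-outcome risk ratio of 1: they are near-instruments by
construction. Two small pre-defined covariates (``age_std``, ``sex``) are
included so that predefined-only and HDPS-augmented analyses differ.

The default parameters define the package's reference scenario: true hazard
ratio 1.0 with latent confounding strong enough to push the crude hazard
ratio to roughly 1.2, mirroring the classic pattern of a spurious harm
signal that proxy adjustment removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hdps.io import CodeHierarchy, CohortTable, DimensionTable, ValidationError

_ROLES = ("confounder_proxy", "iv_like", "noise")
_DIM_NAMES = ("clinical", "referral", "therapy")

# Pre-defined covariate effects (log-odds on exposure, log-hazard on outcome).
_AGE_BETA = 0.15
_SEX_BETA = 0.10


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Counts must be >= 1; ``n_iv_codes + n_noise_codes`` must leave at least
    one confounder-proxy code per dimension. Rates are per day; times in
    days.
    """

    n_patients: int = 5000
    n_dimensions: int = 3
    codes_per_dimension: int = 40
    n_latent_confounders: int = 2
    proxy_loading: float = 1.5
    n_iv_codes: int = 6
    n_noise_codes: int = 40
    true_log_hr: float = 0.0
    confounding_log_hr: float = 0.35
    baseline_hazard: float = 5e-4
    admin_censor_time: float = 365.0
    lookback_days: int = 365
    seed: int = 0
    # Strength parameters of the planted near-instrument mechanism: the
    # exposure-only latent's log-odds effect on treatment and the code
    # loading on that latent. Chosen so planted codes are strongly
    # exposure-associated (empirical near-IVs) at default sample sizes.
    iv_exposure_log_or: float = 1.5
    iv_code_loading: float = 2.0
    exposure_logit_intercept: float = 0.0

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_dimensions": self.n_dimensions,
            "codes_per_dimension": self.codes_per_dimension,
            "n_latent_confounders": self.n_latent_confounders,
            "n_iv_codes": self.n_iv_codes,
            "n_noise_codes": self.n_noise_codes,
            "lookback_days": self.lookback_days,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValidationError(f"{name} must be an integer >= 1, got {value!r}")
        if self.proxy_loading < 0:
            raise ValidationError("proxy_loading must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValidationError("admin_censor_time must be > 0")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        total = self.n_dimensions * self.codes_per_dimension
        if self.n_iv_codes + self.n_noise_codes >= total:
            raise ValidationError(
                "n_iv_codes + n_noise_codes must leave at least one "
                f"confounder-proxy code (total codes = {total})"
            )


@dataclass
class TruthRecord:
    """Ground truth of a simulated study, for validating downstream stages."""

    true_log_hr: float
    latent_confounder_values: pd.DataFrame  # per-patient Z columns + U
    code_roles: dict[str, str]  # code -> confounder_proxy | iv_like | noise
    crude_expected_direction: int  # sign of the confounding bias
    config: SimulationConfig = field(repr=False, default=None)
    code_base_rates: dict[str, float] | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.code_roles:
            raise ValidationError("code_roles must not be empty")
        bad = {c: r for c, r in self.code_roles.items() if r not in _ROLES}
        if bad:
            raise ValidationError(f"unknown code role(s): {bad}")

    def codes_with_role(self, role: str) -> list[str]:
        if role not in _ROLES:
            raise ValidationError(f"unknown role {role!r}")
        return [c for c, r in self.code_roles.items() if r == role]


def _code_name(dim_idx: int, j: int) -> str:
    return f"{_DIM_NAMES[dim_idx % len(_DIM_NAMES)][:2].upper()}{dim_idx}_{j:03d}"


def _dimension_name(i: int) -> str:
    base = _DIM_NAMES[i % len(_DIM_NAMES)]
    return base if i < len(_DIM_NAMES) else f"{base}_{i // len(_DIM_NAMES)}"


def _assign_roles(config: SimulationConfig, rng: np.random.Generator):
    """Spread iv_like and noise codes across dimensions; the rest are proxies.

    Each proxy code is attached to one latent confounder round-robin.
    """
    codes, dims = [], []
    for d in range(config.n_dimensions):
        for j in range(config.codes_per_dimension):
            codes.append(_code_name(d, j))
            dims.append(d)
    codes = np.asarray(codes)
    total = len(codes)
    roles = np.full(total, "confounder_proxy", dtype=object)
    # Deterministic interleaved placement keeps every dimension a mix of roles.
    special = np.arange(total)
    stride = max(total // (config.n_iv_codes + config.n_noise_codes), 1)
    picked = special[:: stride][: config.n_iv_codes + config.n_noise_codes]
    if len(picked) < config.n_iv_codes + config.n_noise_codes:
        picked = special[: config.n_iv_codes + config.n_noise_codes]
    roles[picked[: config.n_iv_codes]] = "iv_like"
    roles[picked[config.n_iv_codes :]] = "noise"
    proxy_idx = np.flatnonzero(roles == "confounder_proxy")
    latent_of = np.full(total, -1)
    latent_of[proxy_idx] = np.arange(len(proxy_idx)) % config.n_latent_confounders
    return codes, np.asarray(dims), roles, latent_of


def _base_rates(config: SimulationConfig, roles: np.ndarray, rng: np.random.Generator):
    """Log-uniform base Poisson rates; iv_like codes kept low-prevalence.

    Low base prevalence keeps the prevalence ratio of instrument codes close
    to their rate ratio, so their planted exposure association survives the
    binary-indicator transformation.
    """
    total = len(roles)
    rates = np.exp(rng.uniform(np.log(0.05), np.log(0.8), size=total))
    iv = roles == "iv_like"
    rates[iv] = np.exp(rng.uniform(np.log(0.03), np.log(0.08), size=iv.sum()))
    return rates


def generate_study(
    config: SimulationConfig,
) -> tuple[CohortTable, list[DimensionTable], TruthRecord]:
    """Simulate a cohort plus multi-dimension coded event streams.

    Returns the cohort table (with pre-defined covariates ``age_std`` and
    ``sex``), one :class:`~hdps.io.DimensionTable` per declared dimension,
    and the :class:`TruthRecord` describing what was planted. Identical
    configs (including seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    K = config.n_latent_confounders

    z = rng.standard_normal((n, K))
    u = rng.standard_normal(n)
    age = rng.standard_normal(n)
    sex = rng.integers(0, 2, size=n)

    z_sum = z.sum(axis=1)
    # age/sex predict the outcome only: all confounding is routed through
    # the latent Z's, so confounding_log_hr=0 means an unbiased crude HR.
    logit = (
        config.exposure_logit_intercept
        + config.confounding_log_hr * z_sum
        + config.iv_exposure_log_or * u
    )
    exposure = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    log_hazard = (
        np.log(config.baseline_hazard)
        + config.true_log_hr * exposure
        + config.confounding_log_hr * z_sum
        + _AGE_BETA * age
        + _SEX_BETA * sex
    )
    t_event = rng.exponential(1.0 / np.exp(log_hazard))
    followup = np.minimum(t_event, config.admin_censor_time)
    event = (t_event <= config.admin_censor_time).astype(int)
    followup = np.maximum(followup, 1e-9)

    index_date = pd.Timestamp("2019-01-01") + pd.to_timedelta(
        rng.integers(0, 365, size=n), unit="D"
    )
    patient_id = np.array([f"P{i:06d}" for i in range(n)])

    cohort = CohortTable(
        pd.DataFrame(
            {
                "patient_id": patient_id,
                "index_date": index_date,
                "exposure": exposure,
                "event": event,
                "followup_time": followup,
                "age_std": age,
                "sex": sex,
            }
        ),
        predefined=["age_std", "sex"],
    )

    codes, dims_of, roles, latent_of = _assign_roles(config, rng)
    rates = _base_rates(config, roles, rng)

    # Per-patient Poisson rates, role-dependent.
    log_mult = np.zeros((n, len(codes)))
    proxy = roles == "confounder_proxy"
    log_mult[:, proxy] = config.proxy_loading * z[:, latent_of[proxy]]
    iv = roles == "iv_like"
    log_mult[:, iv] = config.iv_code_loading * u[:, None]
    counts = rng.poisson(rates[None, :] * np.exp(log_mult))

    dimensions: list[DimensionTable] = []
    for d in range(config.n_dimensions):
        cols = np.flatnonzero(dims_of == d)
        sub = counts[:, cols]
        pat_idx, code_idx = np.nonzero(sub)
        reps = sub[pat_idx, code_idx]
        pat_rep = np.repeat(pat_idx, reps)
        code_rep = np.repeat(cols[code_idx], reps)
        offsets = rng.integers(1, config.lookback_days + 1, size=len(pat_rep))
        dates = index_date.values[pat_rep] - offsets.astype("timedelta64[D]")
        records = pd.DataFrame(
            {
                "patient_id": patient_id[pat_rep],
                "code": codes[code_rep],
                "date": dates,
            }
        ).sort_values(["patient_id", "code", "date"], kind="stable")
        dimensions.append(DimensionTable(_dimension_name(d), records))

    latent = pd.DataFrame(z, columns=[f"Z{k}" for k in range(K)])
    latent["U"] = u
    latent.insert(0, "patient_id", patient_id)

    truth = TruthRecord(
        true_log_hr=config.true_log_hr,
        latent_confounder_values=latent,
        code_roles=dict(zip(codes.tolist(), roles.tolist())),
        crude_expected_direction=int(np.sign(config.confounding_log_hr)),
        config=config,
        code_base_rates=dict(zip(codes.tolist(), rates.tolist())),
    )
    return cohort, dimensions, truth


def truth_summary(truth: TruthRecord) -> pd.DataFrame:
    """Tabulate planted code roles and effect parameters.

    One row per role with its code count; the count column sums to the
    total number of generated codes.
    """
    counts = pd.Series(truth.code_roles).value_counts()
    rows = [
        {"item": f"codes_{role}", "value": int(counts.get(role, 0))} for role in _ROLES
    ]
    rows.append({"item": "codes_total", "value": len(truth.code_roles)})
    rows.append({"item": "true_log_hr", "value": truth.true_log_hr})
    rows.append(
        {"item": "crude_expected_direction", "value": truth.crude_expected_direction}
    )
    return pd.DataFrame(rows)


def simulated_code_hierarchy(truth: TruthRecord, codes_per_chapter: int = 10) -> CodeHierarchy:
    """Synthetic chapter map for simulated codes (blocks of consecutive codes).

    Stands in for an ICD/BNF chapter hierarchy so concept summaries can be
    exercised on simulated data.
    """
    mapping = {}
    for code in truth.code_roles:
        j = int(code.rsplit("_", 1)[1])
        mapping[code] = f"chapter_{j // codes_per_chapter:02d}"
    return CodeHierarchy(mapping)


def null_config(**overrides) -> SimulationConfig:
    """Reference scenario with confounding switched off (unbiased crude HR)."""
    return SimulationConfig(confounding_log_hr=0.0, **overrides)


def small_config(**overrides) -> SimulationConfig:
    """Scaled-down scenario for replicated simulation studies."""
    defaults = dict(
        n_patients=3000,
        codes_per_dimension=20,
        n_iv_codes=4,
        n_noise_codes=20,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
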