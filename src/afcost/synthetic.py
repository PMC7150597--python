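"""Synthetic linked administrative records with known ground truth.

The generator emulates the statistical structure the cost analysis assumes:
a patient-year panel in which the probability of any health or care resource
use follows a probit index Φ(xβ) and positive annual costs follow a gamma
distribution with log-link mean exp(xγ), over covariates (age band, sex,
deprivation quintile, eightfold urban–rural class, 14 health boards, 3-level
comorbidity, admission year, 5-year mortality) drawn at configurable
marginals.  Annual totals are split across four sectors (inpatient,
outpatient, prescribing, care home) and materialised as raw record streams —
hospital episodes with tariffed specialties and ICD-10 diagnosis positions,
outpatient attendances, prescription dispensing rows whose price arithmetic
recovers the assigned amount, care-home stays priced per day — so that every
downstream stage (cleaning, cohort identification, costing, modelling) is
testable end-to-end against a closed-form oracle.

Ground truth (β, γ, gamma shape, sector split) lives in :class:`DGPParams`
and is configuration, not a claim about any real population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .costing import TariffTable
from .design import (
    AGE_BANDS,
    COMORBIDITY_LEVELS,
    GEOGRAPHIES,
    HEALTH_BOARDS,
    SEXES,
    SIMD_QUINTILES,
    DesignSpec,
    design_columns,
    encode_covariates,
)

_DAYS_PER_YEAR = 365

#: Age-band upper bounds (inclusive) used when drawing an integer age within a band.
_AGE_BAND_RANGES = {
    "0-49": (0, 49),
    "50-54": (50, 54),
    "55-59": (55, 59),
    "60-64": (60, 64),
    "65-69": (65, 69),
    "70-74": (70, 74),
    "75-79": (75, 79),
    "80-84": (80, 84),
    "85-89": (85, 89),
    "90-max": (90, 108),
}

# ICD-10 codes used to materialise comorbidity levels on the index admission:
# distinct Charlson condition groups (heart failure, chronic pulmonary disease,
# diabetes) and a non-Charlson filler.
_CHARLSON_CODES = ("I50", "J44", "E11")
_FILLER_CODE = "R69"

_CARE_HOME_WEEKLY = {True: 700.0, False: 350.0}  # nursing / residential, GBP


def _age_band_marginals(mean: float = 74.0, sd: float = 12.5) -> dict[str, float]:
    """Age-band probabilities from a truncated normal age distribution."""
    lo, hi = 0.0, 109.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    tn = stats.truncnorm(a, b, loc=mean, scale=sd)
    probs = {}
    for band, (lo_b, hi_b) in _AGE_BAND_RANGES.items():
        probs[band] = tn.cdf(hi_b + 1) - tn.cdf(lo_b)
    s = sum(probs.values())
    return {k: v / s for k, v in probs.items()}


def _normalised(d: dict) -> dict:
    s = sum(d.values())
    return {k: v / s for k, v in d.items()}


def default_marginals() -> dict[str, dict]:
    """Default covariate marginals for the synthetic population.

    Category probabilities follow the published baseline characteristics of
    the Scottish incident-AF cohort (proportions of sex, health board,
    urban–rural class, SIMD quintile, comorbidity level and 5-year mortality);
    ages follow a truncated normal (mean 74, SD 12.5, range 0–108) discretised
    into the model's ten bands; admission years are uniform over 2005–2012.
    """
    return {
        "sex": {"male": 0.503, "female": 0.497},
        "health_board": _normalised(
            dict(
                zip(
                    HEALTH_BOARDS,
                    [0.222, 0.148, 0.112, 0.093, 0.079, 0.090, 0.065,
                     0.069, 0.049, 0.035, 0.026, 0.007, 0.004, 0.004],
                )
            )
        ),
        "geography": _normalised(
            dict(
                zip(
                    GEOGRAPHIES,
                    [0.384, 0.297, 0.090, 0.030, 0.014, 0.111, 0.037, 0.036],
                )
            )
        ),
        "simd": _normalised(dict(zip(SIMD_QUINTILES, [0.225, 0.225, 0.201, 0.182, 0.166]))),
        "comorbidity": _normalised(dict(zip(COMORBIDITY_LEVELS, [0.146, 0.193, 0.662]))),
        "died_within_5y": {False: 0.736, True: 0.264},
        "age_group": _age_band_marginals(),
        "admission_year": {y: 1.0 / 8.0 for y in range(2005, 2013)},
    }


def _default_coefs(spec: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Default (β, γ) aligned to ``design_columns(spec)``.

    Signs and magnitudes loosely follow the published regression table for
    the Scottish AF cohort; the intercepts are set so the reference patient
    has moderate use probability and a baseline conditional cost near £1100.
    Interaction coefficients (if the spec declares them) default to zero.
    """
    beta = {
        "intercept": -1.0,
        **dict(zip([f"age_{b}" for b in AGE_BANDS[1:]],
                   [0.329, 0.388, 0.464, 0.486, 0.479, 0.536, 0.431, 0.378, 0.150])),
        "female": 0.045,
        "year_c": 0.169,
        "simd_2": 0.027, "simd_3": -0.041, "simd_4": -0.046, "simd_5": -0.072,
        **dict(zip([f"geo_{g}" for g in GEOGRAPHIES[1:]],
                   [-0.130, -0.153, -0.145, -0.380, -0.197, -0.288, -0.346])),
        **dict(zip([f"hb_{h}" for h in HEALTH_BOARDS[1:]],
                   [-0.044, -0.005, 0.017, -0.358, -0.402, -0.059, -0.175,
                    -0.477, -0.303, -0.501, -1.072, -0.495, -0.362])),
        "died": 0.418,
        "como_2": 0.666, "como_3": 1.205,
    }
    gamma = {
        "intercept": 7.0,
        **dict(zip([f"age_{b}" for b in AGE_BANDS[1:]],
                   [0.036, 0.081, 0.124, 0.157, 0.213, 0.222, 0.286, 0.375, 0.516])),
        "female": 0.054,
        "year_c": -0.024,
        "simd_2": -0.055, "simd_3": -0.080, "simd_4": -0.116, "simd_5": -0.147,
        **dict(zip([f"geo_{g}" for g in GEOGRAPHIES[1:]],
                   [-0.023, -0.041, 0.009, -0.057, -0.043, -0.036, -0.061])),
        **dict(zip([f"hb_{h}" for h in HEALTH_BOARDS[1:]],
                   [-0.033, -0.063, -0.059, -0.046, -0.083, -0.009, -0.046,
                    -0.109, -0.134, -0.086, 0.457, -0.076, -0.029])),
        "died": 0.652,
        "como_2": 0.374, "como_3": 0.990,
    }
    cols = design_columns(spec)
    return (
        np.array([beta.get(c, 0.0) for c in cols]),
        np.array([gamma.get(c, 0.0) for c in cols]),
    )


@dataclass(frozen=True)
class DGPParams:
    """Ground-truth parameters of the synthetic data-generating process."""

    beta: np.ndarray
    gamma_coef: np.ndarray
    gamma_shape: float
    sector_split: tuple[float, float, float, float]
    marginals: dict[str, dict]
    seed: int
    design: DesignSpec = field(default_factory=lambda: DesignSpec(
        age_comorbidity_interaction=False,
        mortality_simd_interaction=False,
        year_center=2005,
    ))
    #: Strength of the optional age–comorbidity tilt (0 = independent draws).
    age_comorbidity_assoc: float = 0.0

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        gamma = np.asarray(self.gamma_coef, dtype=float)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "gamma_coef", gamma)
        width = len(design_columns(self.design))
        if beta.shape != (width,) or gamma.shape != (width,):
            raise ValueError(
                f"beta/gamma_coef must both have length {width} "
                f"(design width), got {beta.shape} and {gamma.shape}"
            )
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        split = np.asarray(self.sector_split, dtype=float)
        if split.shape != (4,) or (split < 0).any():
            raise ValueError("sector_split must be four non-negative proportions")
        if abs(split.sum() - 1.0) > 1e-12:
            raise ValueError("sector_split must sum to 1 within 1e-12")
        for name, m in self.marginals.items():
            tot = sum(m.values())
            if abs(tot - 1.0) > 1e-12:
                raise ValueError(f"marginals[{name!r}] sum to {tot}, not 1")
        if "year" in self.design.blocks and self.design.year_center is None:
            raise ValueError("DGP design must fix year_center explicitly")


def default_dgp_params(seed: int = 0, **overrides) -> DGPParams:
    """The package's default data-generating process.

    The defaults emulate the study conditions of the published analysis:
    covariate marginals at the cohort's baseline table, β/γ patterned on the
    published coefficient signs and magnitudes, gamma shape 1.2 (right-skewed
    annual costs), and a sector split of 79/8/7/6% (inpatient / outpatient /
    prescribing / care home).
    """
    spec = overrides.pop(
        "design",
        DesignSpec(
            age_comorbidity_interaction=False,
            mortality_simd_interaction=False,
            year_center=2005,
        ),
    )
    beta, gamma = _default_coefs(spec)
    kwargs = dict(
        beta=beta,
        gamma_coef=gamma,
        gamma_shape=1.2,
        sector_split=(0.79, 0.08, 0.07, 0.06),
        marginals=default_marginals(),
        seed=seed,
        design=spec,
    )
    kwargs.update(overrides)
    return DGPParams(**kwargs)


@dataclass
class RecordBundle:
    """The five linked raw-record streams plus the generating truth.

    Every patient id in any stream appears in the episode stream (all
    patients carry an index admission), and no death date precedes a
    patient's first admission.
    """

    episodes: pd.DataFrame
    outpatient: pd.DataFrame
    prescriptions: pd.DataFrame
    care_home: pd.DataFrame
    deaths: pd.DataFrame
    truth: DGPParams
    tariffs: TariffTable
    truth_panel: pd.DataFrame | None = None
    index_events: pd.DataFrame | None = None
    injected_duplicates: pd.DataFrame | None = None


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def generate_population(n: int, params: DGPParams) -> pd.DataFrame:
    """Draw ``n`` patients' covariates independently from the marginals.

    Deterministic given ``params.seed``.  Ages are integers in 0–108 drawn
    uniformly within the drawn age band.
    """
    if n < 1:
        raise ValueError(f"population size must be positive, got {n}")
    rng = _rng(params.seed, 1)
    m = params.marginals

    def draw(name: str) -> np.ndarray:
        cats = list(m[name].keys())
        probs = np.array(list(m[name].values()), dtype=float)
        idx = rng.choice(len(cats), size=n, p=probs / probs.sum())
        return np.array(cats, dtype=object)[idx]

    age_group = draw("age_group")
    lo = np.array([_AGE_BAND_RANGES[b][0] for b in age_group])
    hi = np.array([_AGE_BAND_RANGES[b][1] for b in age_group])
    age = rng.integers(lo, hi + 1)

    pop = pd.DataFrame(
        {
            "patient_id": [f"P{i:07d}" for i in range(n)],
            "age": age.astype(int),
            "age_group": age_group,
            "sex": draw("sex"),
            "simd": draw("simd").astype(int),
            "geography": draw("geography"),
            "health_board": draw("health_board"),
            "comorbidity": draw("comorbidity").astype(int),
            "died_within_5y": draw("died_within_5y").astype(bool),
            "admission_year": draw("admission_year").astype(int),
        }
    )

    if params.age_comorbidity_assoc != 0.0:
        # Re-draw comorbidity with probabilities tilted by the age z-score so
        # interaction terms have power on synthetic data.
        z = (pop["age"] - pop["age"].mean()) / max(pop["age"].std(ddof=0), 1e-9)
        base = np.array([m["comorbidity"][c] for c in COMORBIDITY_LEVELS])
        w = base[None, :] * np.exp(
            params.age_comorbidity_assoc * z.to_numpy()[:, None] * np.array([0.0, 1.0, 2.0])
        )
        w = w / w.sum(axis=1, keepdims=True)
        u = rng.random(n)
        cum = np.cumsum(w, axis=1)
        pop["comorbidity"] = np.array(COMORBIDITY_LEVELS)[
            (u[:, None] > cum).sum(axis=1)
        ]
    return pop


def dgp_expected_mean(x, params: DGPParams):
    """Closed-form expected annual cost Φ(x·β)·exp(x·γ) for design row(s) x."""
    x = np.asarray(x, dtype=float)
    width = len(params.beta)
    if x.shape[-1] != width:
        raise ValueError(f"design row has width {x.shape[-1]}, expected {width}")
    xb = x @ params.beta
    xg = x @ params.gamma_coef
    return stats.norm.cdf(xb) * np.exp(xg)


def _draw_death_years(pop: pd.DataFrame, followup_years: int, rng) -> np.ndarray:
    """Follow-up year (1-based) containing death, 0 for survivors.

    Mortality is generated as a 5-year flag first; the death time is then
    uniform within the follow-up window.
    """
    died = pop["died_within_5y"].to_numpy()
    years = np.zeros(len(pop), dtype=int)
    years[died] = rng.integers(1, followup_years + 1, size=died.sum())
    return years


def generate_panel(
    population: pd.DataFrame, params: DGPParams, followup_years: int = 5
) -> pd.DataFrame:
    """Draw the ground-truth patient-year panel directly (no raw records).

    One row per patient per follow-up year up to (and including) the year of
    death; ``any_use`` ~ Bernoulli(Φ(xβ)) and, when positive, ``total`` ~
    Gamma(shape, mean exp(xγ)).  Follow-up years are conditionally
    independent given covariates.  Deterministic given ``params.seed``.
    """
    if followup_years < 1:
        raise ValueError("followup_years must be >= 1")
    X = encode_covariates(population, params.design)
    p_use = stats.norm.cdf(X.to_numpy() @ params.beta)
    mu = np.exp(X.to_numpy() @ params.gamma_coef)

    rng = _rng(params.seed, 2)
    death_year = _draw_death_years(population, followup_years, rng)
    n_years = np.where(death_year > 0, death_year, followup_years)

    rows = np.repeat(np.arange(len(population)), n_years)
    year_index = np.concatenate([np.arange(1, k + 1) for k in n_years])
    m = len(rows)
    any_use = rng.random(m) < p_use[rows]
    total = np.zeros(m)
    k = params.gamma_shape
    pos = any_use.nonzero()[0]
    total[pos] = rng.gamma(shape=k, scale=mu[rows[pos]] / k)
    total = np.round(total, 2)
    # a positive draw rounding to 0.00 would break any_use <=> total > 0
    total[pos] = np.maximum(total[pos], 0.01)

    panel = population.iloc[rows].reset_index(drop=True)
    panel["year_index"] = year_index
    panel["death_year"] = death_year[rows]
    panel["any_use"] = any_use
    panel["total"] = total
    return panel


def _split_pennies(total_pennies: int, split: np.ndarray) -> np.ndarray:
    """Split pennies across sectors; the rounding residual goes to the largest."""
    parts = np.floor(total_pennies * split + 0.5).astype(np.int64)
    residual = total_pennies - parts.sum()
    parts[int(np.argmax(parts))] += residual
    if (parts < 0).any():  # pathological split; clamp and rebalance
        parts = np.maximum(parts, 0)
        parts[int(np.argmax(parts))] += total_pennies - parts.sum()
    return parts


def generate_linked_records(
    population: pd.DataFrame, params: DGPParams, followup_years: int = 5
) -> RecordBundle:
    """Materialise the panel as five linked raw-record streams.

    Each patient receives an index admission carrying ICD-10 code I48 in a
    random diagnostic position 1–6 and secondary codes realising the drawn
    comorbidity level.  Each positive patient-year's total is split across
    sectors and emitted as hospital episodes (amount-coded specialty
    tariffs, chained into one continuous stay, occasionally with a
    same-specialty duplicate episode that the per-specialty-max rule must
    zero out), one outpatient attendance, one prescription row and a
    care-home stay priced per day.  Sub-day care-home remainders fold into
    the prescription so materialised sector costs sum to the drawn total
    penny-exactly.  A burn-in window of non-AF episodes precedes some index
    admissions so the incident lookback is evaluable.
    """
    panel = generate_panel(population, params, followup_years)
    rng = _rng(params.seed, 3)
    split = np.asarray(params.sector_split, dtype=float)

    pop = population.set_index("patient_id")
    # index admission date: uniform day within the admission year
    years = pop["admission_year"].to_numpy()
    day_offset = rng.integers(0, 365, size=len(pop))
    index_dates = pd.to_datetime(
        {"year": years, "month": 1, "day": 1}
    ) + pd.to_timedelta(day_offset, unit="D")
    index_date_map = dict(zip(pop.index, index_dates))

    i48_position = rng.integers(1, 7, size=len(pop))
    i48_pos_map = dict(zip(pop.index, i48_position))

    episodes: list[dict] = []
    outpatient: list[dict] = []
    prescriptions: list[dict] = []
    care_home: list[dict] = []
    deaths: list[dict] = []
    ip_tariffs: dict[str, float] = {"NOCOST": 0.0, "PRIOR": 120.0}
    op_tariffs: dict[tuple[str, str], float] = {}

    def diag_slots(pid: str, with_af: bool, comorbidity: int) -> dict:
        """Six diagnosis slots; I48 at its drawn position on AF admissions."""
        slots = [""] * 6
        codes: list[str] = []
        if comorbidity >= 2:
            codes.append(_CHARLSON_CODES[0])
        if comorbidity >= 3:
            codes.extend(_CHARLSON_CODES[1:])
        if with_af:
            p = i48_pos_map[pid] - 1
            slots[p] = "I48"
            free = [i for i in range(6) if i != p]
        else:
            free = list(range(6))
        if not with_af:
            slots[free.pop(0)] = _FILLER_CODE
        for c in codes:
            if free:
                slots[free.pop(0)] = c
        if with_af and slots[0] == "":
            slots[0] = _FILLER_CODE
        return {f"diag_{i+1}": slots[i] for i in range(6)}

    def ip_code(pennies: int) -> str:
        code = f"IP{pennies}"
        ip_tariffs[code] = pennies / 100.0
        return code

    specialty_pool = (
        "cardiology",
        "geriatric_medicine",
        "general_medicine",
        "respiratory_medicine",
        "orthopaedics",
        "general_surgery",
    )

    def emit_inpatient(pid, year_start, pennies, is_index_year, comorbidity):
        """One CIS summing to ``pennies`` under the per-specialty-max rule.

        Episodes within the CIS take distinct clinical specialties so each
        contributes its tariff; with probability 0.3 a same-specialty
        transfer episode with a lower-priced tariff code is appended, which
        the per-specialty maximum rule must zero out.
        """
        n_ep = int(rng.integers(1, 4)) if pennies >= 300 else 1
        cuts = np.sort(rng.integers(1, pennies, size=n_ep - 1)) if n_ep > 1 else np.array([], int)
        parts = np.diff(np.concatenate([[0], cuts, [pennies]])).astype(int)
        parts = parts[parts > 0]
        specs = list(rng.choice(specialty_pool, size=len(parts), replace=False))
        admit = year_start if is_index_year else year_start + pd.Timedelta(
            days=int(rng.integers(0, 300))
        )
        cur = admit
        first = True
        cis_rows = []
        for p, spec_name in zip(parts, specs):
            stay_len = int(rng.integers(1, 15))
            row = {
                "patient_id": pid,
                "admit_date": cur,
                "discharge_date": cur + pd.Timedelta(days=stay_len),
                "specialty": spec_name,
                "tariff_code": ip_code(int(p)),
                **diag_slots(pid, with_af=first and is_index_year, comorbidity=comorbidity),
            }
            cis_rows.append(row)
            cur = row["discharge_date"]
            first = False
        if rng.random() < 0.3:
            # same-specialty transfer episode priced at or below the original:
            # zero additional cost under the per-specialty maximum rule
            dup_of = cis_rows[int(rng.integers(0, len(cis_rows)))]
            orig = int(round(ip_tariffs[dup_of["tariff_code"]] * 100))
            cis_rows.append(
                {
                    **{k: dup_of[k] for k in dup_of},
                    "admit_date": cur,
                    "discharge_date": cur + pd.Timedelta(days=int(rng.integers(1, 5))),
                    "tariff_code": ip_code(max(1, orig // 2)),
                }
            )
        episodes.extend(cis_rows)

    for pid, grp in panel.groupby("patient_id", sort=True):
        comorbidity = int(pop.loc[pid, "comorbidity"])
        index_date = index_date_map[pid]
        death_year = int(grp["death_year"].iloc[0])

        # burn-in: occasional pre-index, non-AF admission within the lookback
        if rng.random() < 0.2:
            back = int(rng.integers(60, 5 * _DAYS_PER_YEAR))
            admit = index_date - pd.Timedelta(days=back)
            episodes.append(
                {
                    "patient_id": pid,
                    "admit_date": admit,
                    "discharge_date": admit + pd.Timedelta(days=int(rng.integers(1, 8))),
                    "specialty": "PRIOR",
                    "tariff_code": "",
                    **diag_slots(pid, with_af=False, comorbidity=comorbidity),
                }
            )

        year1 = grp[grp["year_index"] == 1].iloc[0]
        year1_pennies = int(round(year1["total"] * 100))
        year1_ip = (
            _split_pennies(year1_pennies, split)[0] if year1["any_use"] else 0
        )
        if year1_ip == 0:
            # index admission still exists but carries no tariffable cost
            episodes.append(
                {
                    "patient_id": pid,
                    "admit_date": index_date,
                    "discharge_date": index_date + pd.Timedelta(days=1),
                    "specialty": "NOCOST",
                    "tariff_code": "",
                    **diag_slots(pid, with_af=True, comorbidity=comorbidity),
                }
            )

        last_activity = index_date
        for _, row in grp.iterrows():
            if not row["any_use"]:
                continue
            y = int(row["year_index"])
            year_start = index_date + pd.DateOffset(years=y - 1)
            year_end = index_date + pd.DateOffset(years=y)
            days_in_year = (year_end - year_start).days
            pennies = int(round(row["total"] * 100))
            ip_p, op_p, rx_p, ch_p = (int(v) for v in _split_pennies(pennies, split))

            if ip_p > 0:
                emit_inpatient(pid, year_start, ip_p, y == 1, comorbidity)
            if op_p > 0:
                code = f"OP{op_p}"
                clinic = "consultant" if rng.random() < 0.7 else "nurse"
                op_tariffs[(code, clinic)] = op_p / 100.0
                date = year_start + pd.Timedelta(days=int(rng.integers(0, days_in_year)))
                outpatient.append(
                    {"patient_id": pid, "date": date, "specialty": code, "clinic_type": clinic}
                )
                last_activity = max(last_activity, date) if y == death_year else last_activity
            if ch_p > 0:
                nursing = bool(rng.random() < 0.5)
                daily_p = int(round(_CARE_HOME_WEEKLY[nursing] / 7.0 * 100))
                days = min(ch_p // daily_p, days_in_year - 1)
                rx_p += ch_p - days * daily_p  # sub-day remainder -> prescribing
                if days > 0:
                    start_off = int(rng.integers(0, days_in_year - days))
                    entry = year_start + pd.Timedelta(days=start_off)
                    care_home.append(
                        {
                            "patient_id": pid,
                            "entry_date": entry,
                            "exit_date": entry + pd.Timedelta(days=int(days)),
                            "nursing": nursing,
                        }
                    )
                    if y == death_year:
                        last_activity = max(last_activity, entry + pd.Timedelta(days=int(days)))
            if rx_p > 0:
                k = int(rng.choice([1, 2, 4]))
                date = year_start + pd.Timedelta(days=int(rng.integers(0, days_in_year)))
                prescriptions.append(
                    {
                        "patient_id": pid,
                        "date": date,
                        "item_price": rx_p / 100.0,
                        "pack_size": k,
                        "quantity": k,
                        "instalments": 1,
                    }
                )
                if y == death_year:
                    last_activity = max(last_activity, date)

        if death_year > 0:
            dy_start = index_date + pd.DateOffset(years=death_year - 1)
            dy_end = index_date + pd.DateOffset(years=death_year)
            lo = max(dy_start, last_activity)
            span = max((dy_end - lo).days, 1)
            death_date = lo + pd.Timedelta(days=int(rng.integers(0, span)))
            deaths.append({"patient_id": pid, "death_date": death_date})

    ep_df = pd.DataFrame(episodes)
    # episode admit dates in the death year may postdate the drawn activity;
    # clamp the death date to the last inpatient discharge where needed
    deaths_df = pd.DataFrame(deaths, columns=["patient_id", "death_date"])
    if not deaths_df.empty and not ep_df.empty:
        last_dis = ep_df.groupby("patient_id")["discharge_date"].max()
        merged = deaths_df.set_index("patient_id")
        common = merged.index.intersection(last_dis.index)
        clamped = np.maximum(
            merged.loc[common, "death_date"].to_numpy(),
            last_dis.loc[common].to_numpy(),
        )
        merged.loc[common, "death_date"] = clamped
        deaths_df = merged.reset_index()

    tariffs = TariffTable(
        inpatient=ip_tariffs,
        outpatient=op_tariffs,
        care_home_weekly=dict(_CARE_HOME_WEEKLY),
    )
    index_events = pd.DataFrame(
        {
            "patient_id": list(index_date_map),
            "index_date": [index_date_map[p] for p in index_date_map],
        }
    ).sort_values("patient_id", ignore_index=True)

    return RecordBundle(
        episodes=ep_df.sort_values(["patient_id", "admit_date"], ignore_index=True),
        outpatient=pd.DataFrame(
            outpatient, columns=["patient_id", "date", "specialty", "clinic_type"]
        ),
        prescriptions=pd.DataFrame(
            prescriptions,
            columns=["patient_id", "date", "item_price", "pack_size", "quantity", "instalments"],
        ),
        care_home=pd.DataFrame(
            care_home, columns=["patient_id", "entry_date", "exit_date", "nursing"]
        ),
        deaths=deaths_df,
        truth=params,
        tariffs=tariffs,
        truth_panel=panel,
        index_events=index_events,
    )


def inject_data_errors(bundle: RecordBundle, dup_rate: float, seed: int) -> RecordBundle:
    """Insert exact-duplicate episode rows at ``dup_rate`` with a manifest.

    ``round(dup_rate * n_episodes)`` existing rows are sampled without
    replacement and appended verbatim, so a cleaner's duplicate recall is
    measurable.  ``dup_rate`` = 0 returns the bundle unchanged.
    """
    if not 0 <= dup_rate < 1:
        raise ValueError(f"dup_rate must be in [0, 1), got {dup_rate}")
    if dup_rate == 0:
        return bundle
    rng = _rng(seed, 4)
    n = len(bundle.episodes)
    n_dup = int(round(dup_rate * n))
    idx = rng.choice(n, size=min(n_dup, n), replace=False)
    dups = bundle.episodes.iloc[idx].copy()
    episodes = pd.concat([bundle.episodes, dups], ignore_index=True)
    return replace(bundle, episodes=episodes, injected_duplicates=dups.reset_index(drop=True))


def write_streams(bundle: RecordBundle, directory) -> None:
    """Write the five record streams (and tariffs) as headered CSV files."""
    from pathlib import Path

    from .costing import write_tariff_files

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.episodes.to_csv(d / "episodes.csv", index=False)
    bundle.outpatient.to_csv(d / "outpatient.csv", index=False)
    bundle.prescriptions.to_csv(d / "prescriptions.csv", index=False)
    bundle.care_home.to_csv(d / "care_home.csv", index=False)
    bundle.deaths.to_csv(d / "deaths.csv", index=False)
    write_tariff_files(bundle.tariffs, d)
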