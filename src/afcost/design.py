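"""Covariate codings and design-matrix construction for the two-part cost model.

The model adjusts for eight covariate blocks — age group, sex, calendar year of
the index admission, deprivation quintile (SIMD), eightfold urban–rural class,
health board of residence, Charlson comorbidity level and 5-year vital status —
plus two interactions (age group × comorbidity, mortality × SIMD).  All
categorical blocks are reference-coded; the reference levels are the youngest
age band, male sex, the most deprived SIMD quintile, large urban areas, the
Greater Glasgow and Clyde health board, no comorbidity and alive at five years.
The admission year enters as a centred continuous term.

The same encoding is used by the synthetic data generator (so that ground-truth
coefficients align with fitted ones column-for-column) and by the model fitters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_BANDS = (
    "0-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85-89",
    "90-max",
)

SEXES = ("male", "female")

SIMD_QUINTILES = (1, 2, 3, 4, 5)

# Eightfold Scottish Government urban–rural classification.
GEOGRAPHIES = (
    "large_urban",
    "other_urban",
    "accessible_small_towns",
    "remote_small_towns",
    "very_remote_small_towns",
    "accessible_rural",
    "remote_rural",
    "very_remote_rural",
)

# The 14 territorial NHS Scotland health boards.
HEALTH_BOARDS = (
    "greater_glasgow_and_clyde",
    "lothian",
    "lanarkshire",
    "grampian",
    "ayrshire_and_arran",
    "tayside",
    "fife",
    "highland",
    "forth_valley",
    "dumfries_and_galloway",
    "borders",
    "western_isles",
    "shetland",
    "orkney",
)

# Collapsed Charlson level: 1 = no comorbidity, 2 = exactly one, 3 = more than one.
COMORBIDITY_LEVELS = (1, 2, 3)

#: Columns a panel DataFrame must carry to be encodable.
COVARIATE_COLUMNS = (
    "age_group",
    "sex",
    "admission_year",
    "simd",
    "geography",
    "health_board",
    "comorbidity",
    "died_within_5y",
)


class UnseenCategoryError(ValueError):
    """A covariate value falls outside the declared category list."""


#: The eight covariate blocks of the full model design.
ALL_BLOCKS = (
    "age_group",
    "sex",
    "year",
    "simd",
    "geography",
    "health_board",
    "mortality",
    "comorbidity",
)


@dataclass(frozen=True)
class DesignSpec:
    """Specification of the regression design shared by both model parts.

    Parameters
    ----------
    blocks
        The covariate blocks (term list) entering the design; defaults to all
        eight.  Reduced designs are useful for small samples and simulation
        studies.
    include_mortality
        Whether the 5-year vital-status indicator enters the design.  The
        alive/dead sensitivity refits set this to ``False``, which also drops
        the mortality × SIMD interaction.
    age_comorbidity_interaction, mortality_simd_interaction
        Toggles for the two declared interactions; only available when their
        main-effect blocks are in the design.
    year_center
        Calendar year at which the continuous admission-year term is centred.
        ``None`` centres at the earliest year observed in the panel.
    """

    blocks: tuple[str, ...] = ALL_BLOCKS
    include_mortality: bool = True
    age_comorbidity_interaction: bool = True
    mortality_simd_interaction: bool = True
    year_center: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.blocks) - set(ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown design block(s): {sorted(unknown)}")
        # interactions only among declared main terms; excluding mortality
        # forces exclusion of its interaction
        if self.age_comorbidity_interaction and not (
            "age_group" in self.blocks and "comorbidity" in self.blocks
        ):
            object.__setattr__(self, "age_comorbidity_interaction", False)
        if self.mortality_simd_interaction and not (
            self.has_mortality and "simd" in self.blocks
        ):
            object.__setattr__(self, "mortality_simd_interaction", False)

    @property
    def has_mortality(self) -> bool:
        return self.include_mortality and "mortality" in self.blocks


def main_effect_columns(spec: DesignSpec) -> list[str]:
    cols: list[str] = []
    if "age_group" in spec.blocks:
        cols += [f"age_{b}" for b in AGE_BANDS[1:]]
    if "sex" in spec.blocks:
        cols.append("female")
    if "year" in spec.blocks:
        cols.append("year_c")
    if "simd" in spec.blocks:
        cols += [f"simd_{q}" for q in SIMD_QUINTILES[1:]]
    if "geography" in spec.blocks:
        cols += [f"geo_{g}" for g in GEOGRAPHIES[1:]]
    if "health_board" in spec.blocks:
        cols += [f"hb_{h}" for h in HEALTH_BOARDS[1:]]
    if spec.has_mortality:
        cols.append("died")
    if "comorbidity" in spec.blocks:
        cols += [f"como_{c}" for c in COMORBIDITY_LEVELS[1:]]
    return cols


def design_columns(spec: DesignSpec) -> list[str]:
    """Ordered names of all design columns (intercept first)."""
    cols = ["intercept"] + main_effect_columns(spec)
    if spec.age_comorbidity_interaction:
        for b in AGE_BANDS[1:]:
            for c in COMORBIDITY_LEVELS[1:]:
                cols.append(f"age_{b}:como_{c}")
    if spec.mortality_simd_interaction:
        for q in SIMD_QUINTILES[1:]:
            cols.append(f"died:simd_{q}")
    return cols


def _check_levels(values: pd.Series, allowed: tuple, name: str) -> None:
    bad = set(values.unique()) - set(allowed)
    if bad:
        raise UnseenCategoryError(f"unseen {name} level(s): {sorted(map(str, bad))}")


def encode_covariates(df: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Reference-code covariates into the model design matrix.

    Parameters
    ----------
    df
        One row per observation, carrying :data:`COVARIATE_COLUMNS`.
    spec
        Design specification.

    Returns
    -------
    DataFrame with columns :func:`design_columns` in order, float dtype.
    """
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"panel is missing covariate column(s): {missing}")

    _check_levels(df["age_group"], AGE_BANDS, "age_group")
    _check_levels(df["sex"], SEXES, "sex")
    _check_levels(df["simd"], SIMD_QUINTILES, "simd")
    _check_levels(df["geography"], GEOGRAPHIES, "geography")
    _check_levels(df["health_board"], HEALTH_BOARDS, "health_board")
    _check_levels(df["comorbidity"], COMORBIDITY_LEVELS, "comorbidity")

    n = len(df)
    center = spec.year_center
    if center is None:
        center = int(df["admission_year"].min())

    X = pd.DataFrame(index=df.index, dtype=float)
    X["intercept"] = 1.0
    if "age_group" in spec.blocks:
        for b in AGE_BANDS[1:]:
            X[f"age_{b}"] = (df["age_group"] == b).astype(float)
    if "sex" in spec.blocks:
        X["female"] = (df["sex"] == "female").astype(float)
    if "year" in spec.blocks:
        X["year_c"] = df["admission_year"].astype(float) - float(center)
    if "simd" in spec.blocks:
        for q in SIMD_QUINTILES[1:]:
            X[f"simd_{q}"] = (df["simd"] == q).astype(float)
    if "geography" in spec.blocks:
        for g in GEOGRAPHIES[1:]:
            X[f"geo_{g}"] = (df["geography"] == g).astype(float)
    if "health_board" in spec.blocks:
        for h in HEALTH_BOARDS[1:]:
            X[f"hb_{h}"] = (df["health_board"] == h).astype(float)
    died = df["died_within_5y"].astype(bool).astype(float)
    if spec.has_mortality:
        X["died"] = died
    if "comorbidity" in spec.blocks:
        for c in COMORBIDITY_LEVELS[1:]:
            X[f"como_{c}"] = (df["comorbidity"] == c).astype(float)

    if spec.age_comorbidity_interaction:
        for b in AGE_BANDS[1:]:
            for c in COMORBIDITY_LEVELS[1:]:
                X[f"age_{b}:como_{c}"] = X[f"age_{b}"] * X[f"como_{c}"]
    if spec.mortality_simd_interaction:
        for q in SIMD_QUINTILES[1:]:
            X[f"died:simd_{q}"] = died * X[f"simd_{q}"]

    assert list(X.columns) == design_columns(spec)
    assert len(X) == n
    return X


def build_design(
    panel: pd.DataFrame, spec: DesignSpec
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Build the design matrix and the two responses of the two-part model.

    Returns
    -------
    (X, any_use, total)
        ``X`` — reference-coded design over all panel rows; ``any_use`` —
        binary indicator of any resource use; ``total`` — total annual cost
        (the second model part subsets to ``total > 0`` itself).
    """
    X = encode_covariates(panel, spec)
    any_use = panel["any_use"].astype(bool).astype(int)
    total = panel["total"].astype(float)
    return X, any_use, total
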