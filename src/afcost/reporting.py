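"""Cohort summary tables, stratified cost tables and sector shares.

Percentages in the cohort summary are 100·count/n rounded to one decimal;
sector shares in the stratified cost tables are each sector mean divided by
the stratum total, computed from unrounded means and reported to two
decimals.  Totals equal the sum of sector means to the penny.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SECTOR_COLUMNS = ("cost_inpatient", "cost_outpatient", "cost_prescribing", "cost_care_home")
SECTOR_LABELS = {
    "cost_inpatient": "inpatient",
    "cost_outpatient": "outpatient",
    "cost_prescribing": "prescribing",
    "cost_care_home": "care_home",
}


def percentage(count: float, n: float, decimals: int = 1) -> float:
    """100·count/n rounded half-up to ``decimals`` places."""
    scale = 10**decimals
    return float(np.floor(100.0 * count / n * scale + 0.5) / scale)


def percentages_from_counts(counts: dict, n: int, decimals: int = 1) -> dict:
    """Category percentages from raw counts (the published-table arithmetic)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return {k: percentage(v, n, decimals) for k, v in counts.items()}


def cohort_summary(cohort: pd.DataFrame) -> dict:
    """Counts and percentages per baseline-characteristics block.

    One row per patient expected.  Returns a dict of blocks: each categorical
    block maps category -> (count, pct); the age block reports mean/SD/range
    of age at first admission.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    n = len(cohort)
    out: dict = {"n": n}
    if "age" in cohort.columns:
        age = cohort["age"].astype(float)
        out["age"] = {
            "mean": float(age.mean()),
            "sd": float(age.std(ddof=1)) if n > 1 else 0.0,
            "range": (float(age.min()), float(age.max())),
        }
    for block in ("sex", "health_board", "geography", "simd", "comorbidity", "died_within_5y"):
        if block not in cohort.columns:
            continue
        counts = cohort[block].value_counts()
        out[block] = {
            k: (int(v), percentage(v, n)) for k, v in counts.items()
        }
    return out


def cost_shares(
    sector_means: dict[str, float], total: float | None = None, decimals: int = 2
) -> pd.DataFrame:
    """Sector means, total and percentage shares for one stratum.

    ``sector_means`` maps sector name -> mean cost (GBP).  Shares are computed
    from the unrounded means against the unrounded total.  ``total`` defaults
    to the sum of the sector means; pass it explicitly when re-deriving shares
    from a published table whose rounded means do not sum to its printed total.
    """
    if total is None:
        total = float(sum(sector_means.values()))
    if total <= 0:
        raise ValueError("stratum total must be positive to compute shares")
    scale = 10**decimals
    rows = [
        {
            "sector": k,
            "mean_cost": round(v, 2),
            "share_pct": float(np.floor(100.0 * v / total * scale + 0.5) / scale),
        }
        for k, v in sector_means.items()
    ]
    rows.append({"sector": "total", "mean_cost": round(total, 2), "share_pct": 100.0})
    return pd.DataFrame(rows)


def stratified_cost_table(panel: pd.DataFrame, by: str) -> pd.DataFrame:
    """Per-stratum sector means, totals and shares over patient-year rows.

    ``by`` is one of sex, age_group, comorbidity or died_within_5y (vital
    status).  Shares are derived from this table's own unrounded means, never
    copied from elsewhere.
    """
    if by not in panel.columns:
        raise ValueError(f"stratum variable {by!r} not in panel")
    records = []
    for stratum, grp in panel.groupby(by, sort=True):
        means = {SECTOR_LABELS[c]: float(grp[c].mean()) for c in SECTOR_COLUMNS}
        total = sum(means.values())
        rec = {"stratum": stratum, "n_patient_years": len(grp)}
        for k, v in means.items():
            rec[f"{k}_mean"] = round(v, 2)
            rec[f"{k}_share_pct"] = (
                float(np.floor(100.0 * v / total * 100 + 0.5) / 100) if total > 0 else np.nan
            )
        rec["total_mean"] = round(total, 2)
        records.append(rec)
    return pd.DataFrame(records)


def plot_stratified_costs(table: pd.DataFrame, path) -> None:
    """Stacked-bar chart of sector means by stratum (data table is primary)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sectors = [SECTOR_LABELS[c] for c in SECTOR_COLUMNS]
    fig, ax = plt.subplots(figsize=(8, 5))
    bottom = np.zeros(len(table))
    for s in sectors:
        vals = table[f"{s}_mean"].to_numpy()
        ax.bar(table["stratum"].astype(str), vals, bottom=bottom, label=s)
        bottom += vals
    ax.set_ylabel("mean annual cost per patient (GBP)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
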