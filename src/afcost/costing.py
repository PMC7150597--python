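"""Sector costing: inpatient stays, outpatient visits, prescriptions, care homes.

Costing rules
-------------
* Inpatient episodes are chained into continuous inpatient stays (CIS): an
  uninterrupted hospital stay from admission to final discharge, possibly
  spanning several specialty episodes.  Each episode carries a specialty /
  HRG-like tariff code priced per spell.  Within a CIS, when two or more
  episodes share a specialty only the highest-cost episode is counted and the
  rest contribute zero; the CIS cost is the sum over distinct specialties of
  the maximum episode cost.
* Outpatient attendances are priced per (specialty, clinic type) pair, with
  separate tariffs for consultant-led and nurse-led clinics.
* Prescription cost = (item price ÷ pack size) × (quantity dispensed ×
  instalments), rounded to the penny (half-up).
* Care-home residency is priced per day at the weekly charge ÷ 7, counting
  only days actually spent in the home that fall inside the costing window
  (half-open day intervals: the exit day is not counted).

All currency arithmetic rounds half-up to the penny at the item level;
aggregation then conserves pennies exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def round_penny(x: float) -> float:
    """Round to 2 decimals with half-up tie-breaking (0.005 -> 0.01)."""
    return float(np.floor(x * 100 + 0.5) / 100)


class UnknownTariffError(KeyError):
    """A specialty / clinic-type code has no tariff entry."""


@dataclass(frozen=True)
class TariffTable:
    """Unit-cost lookup tables.

    ``inpatient`` maps a specialty/HRG-like code to a cost per spell,
    ``outpatient`` maps (specialty, clinic_type) with clinic_type in
    {"consultant", "nurse"} to a cost per attendance, and
    ``care_home_weekly`` maps the nursing-care flag to a weekly charge.
    Lookups are total functions: a missing code raises, it is never zero.
    """

    inpatient: dict[str, float]
    outpatient: dict[tuple[str, str], float]
    care_home_weekly: dict[bool, float]

    def __post_init__(self) -> None:
        for name, table in (
            ("inpatient", self.inpatient),
            ("outpatient", self.outpatient),
            ("care_home_weekly", self.care_home_weekly),
        ):
            for k, v in table.items():
                if v < 0:
                    raise ValueError(f"negative {name} tariff for {k!r}: {v}")

    def inpatient_cost(self, specialty: str) -> float:
        try:
            return self.inpatient[specialty]
        except KeyError:
            raise UnknownTariffError(f"no inpatient tariff for specialty {specialty!r}")

    def outpatient_cost(self, specialty: str, clinic_type: str) -> float:
        try:
            return self.outpatient[(specialty, clinic_type)]
        except KeyError:
            raise UnknownTariffError(
                f"no outpatient tariff for ({specialty!r}, {clinic_type!r})"
            )

    def care_home_daily(self, nursing: bool) -> float:
        try:
            return self.care_home_weekly[bool(nursing)] / 7.0
        except KeyError:
            raise UnknownTariffError(f"no weekly care-home charge for nursing={nursing}")


@dataclass
class ContinuousInpatientStay:
    """One continuous inpatient stay: a chain of contiguous episodes."""

    patient_id: str
    episodes: pd.DataFrame  # rows of the episode table, date-sorted
    start: pd.Timestamp
    end: pd.Timestamp


def build_cis(
    episodes: pd.DataFrame, transfer_tolerance_days: int = 0
) -> list[ContinuousInpatientStay]:
    """Chain one patient's date-sorted episodes into continuous inpatient stays.

    An episode continues the current CIS when its admission date is within
    ``transfer_tolerance_days`` of the running discharge date (default 0:
    same-day transfer); otherwise a new CIS starts.
    """
    if episodes.empty:
        return []
    pid = episodes["patient_id"].iloc[0]
    if (episodes["patient_id"] != pid).any():
        raise ValueError("build_cis expects episodes of a single patient")
    admits = pd.to_datetime(episodes["admit_date"])
    if not admits.is_monotonic_increasing:
        raise ValueError("episodes must be sorted by admission date")

    discharges = pd.to_datetime(episodes["discharge_date"])
    tol = pd.Timedelta(days=transfer_tolerance_days)

    stays: list[ContinuousInpatientStay] = []
    block_start = 0
    running_end = discharges.iloc[0]
    for i in range(1, len(episodes)):
        if admits.iloc[i] <= running_end + tol:
            running_end = max(running_end, discharges.iloc[i])
        else:
            chunk = episodes.iloc[block_start:i]
            stays.append(
                ContinuousInpatientStay(
                    patient_id=pid,
                    episodes=chunk,
                    start=admits.iloc[block_start],
                    end=running_end,
                )
            )
            block_start = i
            running_end = discharges.iloc[i]
    chunk = episodes.iloc[block_start:]
    stays.append(
        ContinuousInpatientStay(
            patient_id=pid,
            episodes=chunk,
            start=admits.iloc[block_start],
            end=running_end,
        )
    )
    return stays


def cost_inpatient_cis(cis: ContinuousInpatientStay, tariffs: TariffTable) -> float:
    """Cost one CIS: per distinct specialty, keep only the maximum episode cost.

    Each episode is priced by its HRG-like ``tariff_code`` (falling back to
    the specialty code when no separate tariff code is recorded); episodes are
    then grouped by clinical specialty and, within the CIS, all but the
    highest-cost episode of each specialty are replaced with zero.  Ties keep
    a single episode (identical contribution either way).  Invariant under
    permutation of episode order; never exceeds the plain sum of episode
    tariffs, with equality iff all specialties are distinct.
    """
    ep = cis.episodes
    has_code = "tariff_code" in ep.columns
    costs: dict[str, float] = {}
    for _, row in ep.iterrows():
        code = row["tariff_code"] if has_code and pd.notna(row["tariff_code"]) and row["tariff_code"] != "" else row["specialty"]
        c = tariffs.inpatient_cost(code)
        spec_code = row["specialty"]
        if spec_code not in costs or c > costs[spec_code]:
            costs[spec_code] = c
    return round_penny(sum(costs.values()))


def cost_outpatient(visit, tariffs: TariffTable) -> float:
    """Tariff for one outpatient attendance (consultant- vs nurse-led)."""
    return round_penny(tariffs.outpatient_cost(visit["specialty"], visit["clinic_type"]))


def cost_prescription(record) -> float:
    """Dispensing cost: (item price / pack size) x (quantity x instalments)."""
    pack = record["pack_size"]
    if pack <= 0:
        raise ValueError(f"pack_size must be positive, got {pack}")
    qty = record["quantity"]
    inst = record["instalments"]
    if qty < 0 or inst < 0:
        raise ValueError("quantity and instalments must be non-negative")
    unit = record["item_price"] / pack
    return round_penny(unit * (qty * inst))


def _overlap_days(
    start_a: pd.Timestamp, end_a: pd.Timestamp, start_b: pd.Timestamp, end_b: pd.Timestamp
) -> int:
    """Day count of the intersection of two half-open [start, end) intervals."""
    lo = max(start_a, start_b)
    hi = min(end_a, end_b)
    return max((hi - lo).days, 0)


def cost_care_home(
    stay, tariffs: TariffTable, window: tuple[pd.Timestamp, pd.Timestamp]
) -> float:
    """Cost of the days of a care-home stay that fall inside ``window``.

    Both the stay and the window are half-open day intervals; daily rate is
    the weekly charge / 7.
    """
    entry = pd.Timestamp(stay["entry_date"])
    exit_ = pd.Timestamp(stay["exit_date"])
    if exit_ < entry:
        raise ValueError(f"negative-length care-home stay: {entry} .. {exit_}")
    days = _overlap_days(entry, exit_, pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    return round_penny(tariffs.care_home_daily(stay["nursing"]) * days)


def _year_bounds(index_date: pd.Timestamp, year_index: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    start = index_date + pd.DateOffset(years=year_index - 1)
    end = index_date + pd.DateOffset(years=year_index)
    return start, end


def aggregate_to_panel(
    panel: pd.DataFrame,
    bundle,
    tariffs: TariffTable,
    transfer_tolerance_days: int = 0,
) -> pd.DataFrame:
    """Cost all raw records and pour them into the patient-year panel.

    ``panel`` holds the skeleton rows (patient_id, year_index, index_date,
    zeroed sector columns).  A CIS is assigned wholly to the follow-up year of
    its admission date; outpatient visits and prescriptions by their own date;
    care-home stays are apportioned day-by-day across the years they straddle.
    Items outside a patient's follow-up window (or for unknown patients) are
    dropped and counted in the log.
    """
    out = panel.copy()
    for col in ("cost_inpatient", "cost_outpatient", "cost_prescribing", "cost_care_home"):
        if col not in out.columns:
            out[col] = 0.0
    key_to_row = {
        (pid, int(y)): i
        for i, (pid, y) in enumerate(zip(out["patient_id"], out["year_index"]))
    }
    index_dates = (
        out.drop_duplicates("patient_id").set_index("patient_id")["index_date"].to_dict()
    )
    max_year = out.groupby("patient_id")["year_index"].max().to_dict()

    inpat = np.zeros(len(out))
    outp = np.zeros(len(out))
    rx = np.zeros(len(out))
    ch = np.zeros(len(out))
    dropped = {"unknown_patient": 0, "out_of_window": 0}

    def year_of(pid: str, date: pd.Timestamp) -> int | None:
        """Follow-up year (1-based) containing ``date``, or None if outside."""
        idx = index_dates.get(pid)
        if idx is None:
            dropped["unknown_patient"] += 1
            return None
        if date < idx:
            dropped["out_of_window"] += 1
            return None
        y = 1
        while date >= idx + pd.DateOffset(years=y):
            y += 1
        if y > max_year.get(pid, 0):
            dropped["out_of_window"] += 1
            return None
        return y

    episodes = bundle.episodes
    for pid, grp in episodes.sort_values(["patient_id", "admit_date"]).groupby(
        "patient_id", sort=False
    ):
        for cis in build_cis(grp, transfer_tolerance_days):
            y = year_of(pid, pd.Timestamp(cis.start))
            if y is None:
                continue
            inpat[key_to_row[(pid, y)]] += cost_inpatient_cis(cis, tariffs)

    for _, visit in bundle.outpatient.iterrows():
        y = year_of(visit["patient_id"], pd.Timestamp(visit["date"]))
        if y is None:
            continue
        outp[key_to_row[(visit["patient_id"], y)]] += cost_outpatient(visit, tariffs)

    for _, rec in bundle.prescriptions.iterrows():
        y = year_of(rec["patient_id"], pd.Timestamp(rec["date"]))
        if y is None:
            continue
        rx[key_to_row[(rec["patient_id"], y)]] += cost_prescription(rec)

    for _, stay in bundle.care_home.iterrows():
        pid = stay["patient_id"]
        idx = index_dates.get(pid)
        if idx is None:
            dropped["unknown_patient"] += 1
            continue
        touched = False
        for y in range(1, int(max_year.get(pid, 0)) + 1):
            window = _year_bounds(pd.Timestamp(idx), y)
            c = cost_care_home(stay, tariffs, window)
            if c > 0:
                ch[key_to_row[(pid, y)]] += c
                touched = True
        if not touched:
            dropped["out_of_window"] += 1

    out["cost_inpatient"] = np.round(inpat, 2)
    out["cost_outpatient"] = np.round(outp, 2)
    out["cost_prescribing"] = np.round(rx, 2)
    out["cost_care_home"] = np.round(ch, 2)
    out["total"] = np.round(
        out["cost_inpatient"]
        + out["cost_outpatient"]
        + out["cost_prescribing"]
        + out["cost_care_home"],
        2,
    )
    out["any_use"] = out["total"] > 0
    if dropped["unknown_patient"] or dropped["out_of_window"]:
        logger.info(
            "aggregate_to_panel dropped items: %d unknown patient, %d outside window",
            dropped["unknown_patient"],
            dropped["out_of_window"],
        )
    out.attrs["dropped_items"] = dropped
    return out


def read_tariff_files(
    inpatient_path, outpatient_path, care_home_path
) -> TariffTable:
    """Read the three tariff tables from headered CSV files.

    ``inpatient.csv``: specialty,cost — ``outpatient.csv``:
    specialty,clinic_type,cost — ``care_home.csv``: nursing,weekly_charge
    (nursing in {true,false}).
    """
    ip = pd.read_csv(inpatient_path)
    op = pd.read_csv(outpatient_path)
    chw = pd.read_csv(care_home_path)
    return TariffTable(
        inpatient=dict(zip(ip["specialty"].astype(str), ip["cost"].astype(float))),
        outpatient={
            (str(r["specialty"]), str(r["clinic_type"])): float(r["cost"])
            for _, r in op.iterrows()
        },
        care_home_weekly={
            bool(r["nursing"]) if isinstance(r["nursing"], (bool, np.bool_))
            else str(r["nursing"]).strip().lower() in ("true", "1", "yes"):
            float(r["weekly_charge"])
            for _, r in chw.iterrows()
        },
    )


def write_tariff_files(tariffs: TariffTable, directory) -> None:
    """Write the three tariff tables as CSV files under ``directory``."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"specialty": list(tariffs.inpatient), "cost": list(tariffs.inpatient.values())}
    ).to_csv(d / "tariff_inpatient.csv", index=False)
    pd.DataFrame(
        [
            {"specialty": s, "clinic_type": c, "cost": v}
            for (s, c), v in tariffs.outpatient.items()
        ]
    ).to_csv(d / "tariff_outpatient.csv", index=False)
    pd.DataFrame(
        [
            {"nursing": k, "weekly_charge": v}
            for k, v in tariffs.care_home_weekly.items()
        ]
    ).to_csv(d / "tariff_care_home.csv", index=False)
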