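"""The sector costing rules on hand-checkable inputs.

Shows continuous-inpatient-stay (CIS) chaining, the per-specialty maximum
rule, prescription dispensing arithmetic, and per-day care-home pricing.
"""

import pandas as pd

from afcost.costing import (
    ContinuousInpatientStay,
    TariffTable,
    build_cis,
    cost_care_home,
    cost_inpatient_cis,
    cost_prescription,
)

tariffs = TariffTable(
    inpatient={"T50": 50.0, "T100": 100.0, "T200": 200.0},
    outpatient={("cardiology", "consultant"): 150.0},
    care_home_weekly={True: 700.0, False: 707.70},
)

# Three episodes forming one continuous stay: two in cardiology (priced 100
# and 200 by their HRG-like tariff codes), one in general surgery (50).
episodes = pd.DataFrame(
    [
        {"patient_id": "A", "admit_date": pd.Timestamp("2010-01-01"),
         "discharge_date": pd.Timestamp("2010-01-03"),
         "specialty": "cardiology", "tariff_code": "T100"},
        {"patient_id": "A", "admit_date": pd.Timestamp("2010-01-03"),
         "discharge_date": pd.Timestamp("2010-01-05"),
         "specialty": "cardiology", "tariff_code": "T200"},
        {"patient_id": "A", "admit_date": pd.Timestamp("2010-01-05"),
         "discharge_date": pd.Timestamp("2010-01-06"),
         "specialty": "general_surgery", "tariff_code": "T50"},
    ]
)
stays = build_cis(episodes)
print(f"{len(episodes)} episodes chain into {len(stays)} continuous stay(s)")
cost = cost_inpatient_cis(stays[0], tariffs)
print(f"CIS cost = £{cost:.2f}")
print("  (per specialty only the highest episode cost counts: "
      "max(100, 200) + 50 = 250)")

rx = {"item_price": 28.0, "pack_size": 28, "quantity": 56, "instalments": 2}
print(f"\nprescription cost = £{cost_prescription(rx):.2f}")
print("  ((28 / 28 per unit) x (56 x 2 units) = 112.00)")

stay = {"entry_date": "2010-03-01", "exit_date": "2010-03-04", "nursing": False}
window = (pd.Timestamp("2010-01-01"), pd.Timestamp("2011-01-01"))
print(f"\ncare-home cost = £{cost_care_home(stay, tariffs, window):.2f}")
print("  (707.70 weekly / 7 = 101.10 daily x 3 days = 303.30; "
      "the exit day is not counted)")
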