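"""Small built-in fixture tables.

``remance_foods`` carries the edible-crop concentrations from the
Remance (Panama) abandoned gold-mine survey: rice and corn grain,
cassava tuber and two locally used tea-leaf samples.  Cu/Zn/As/Sb/Ba
values were reconstructed at full precision from the survey's printed
per-food daily-intake table (DIR × BW / IR), which is why some carry
one more decimal than the survey's coarser comparative table (e.g.
rice As 0.15 rather than 0.2 mg kg⁻¹).  Hg in grain and tuber was
below the 0.1 ng g⁻¹ detection limit; the tea Hg values are likewise
back-derived from the intake table.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .risk import FoodItem

_REMANCE_FOODS_CSV = """\
food_label,ir_label,Cu,Zn,As,Sb,Ba,Hg_ng_g
rice,rice,5.2,17.9,0.15,4.35,12.1,<0.1
corn,corn,4.25,21.95,0.15,4.65,11.7,<0.1
cassava,cassava,7.45,8.95,<0.1,4.05,18.5,<0.1
tea_pm1,tea,13.0,51.85,0.65,4.70,29.28,5.01
tea_pm4,tea,25.45,125.55,0.50,4.60,41.68,17.98
"""

#: published mean BCR step percentages (S1, S2, S3) of the pseudo-total
REMANCE_BCR_STEP_MEANS_PCT = {
    "Cu": (4.45, 9.15, 4.34),
    "As": (0.04, 0.40, 1.39),
}

#: published mean leaf concentrations (mg kg⁻¹) for the forage screen
REMANCE_FORAGE_MEANS = {
    "grass": {"Cu": 18.3, "Zn": 27.3},
    "all_plants": {"Cu": 16.9, "Zn": 31.1},
}


def remance_foods_frame() -> pd.DataFrame:
    """The food-concentration table as a raw frame (``<DL`` dialect)."""
    return pd.read_csv(_io.StringIO(_REMANCE_FOODS_CSV), dtype=str)


def remance_foods() -> list[FoodItem]:
    """The five edible-crop samples as parsed food items."""
    from .core import CensoredMeasurement, Element
    from .io import ELEMENT_TO_COLUMN

    items = []
    for _, row in remance_foods_frame().iterrows():
        ms = {
            e: CensoredMeasurement.parse(e, row[col])
            for e, col in ELEMENT_TO_COLUMN.items()
        }
        items.append(
            FoodItem.from_measurements(
                label=row["food_label"], measurements=ms, ir_label=row["ir_label"]
            )
        )
    return items
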