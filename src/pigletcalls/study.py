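"""Canonical study design: the 11 recording situations.

Eleven behavioural situations in which pre-weaning piglet calls were
recorded, grouped into three gross biological categories (life-threatening,
nursing-related, general social), with the number of analysed calls,
piglets and litters per situation.
"""

from __future__ import annotations

import pandas as pd

LIFE_THREAT = "life_threat"
NURSING = "nursing"
OTHER = "other"

#: (code, description tag, gross category, n_calls, n_piglets, n_litters)
_SITUATION_ROWS = [
    ("CA", "castration", LIFE_THREAT, 171, 7, 5),
    ("CR", "crushing", LIFE_THREAT, 159, 10, 10),
    ("AR", "arms_of_person", LIFE_THREAT, 209, 6, 4),
    ("FI", "fighting", LIFE_THREAT, 115, 5, 4),
    ("BN", "before_nursing", NURSING, 61, 5, 5),
    ("AN", "after_nursing", NURSING, 128, 14, 9),
    ("MN", "missed_nursing", NURSING, 70, 6, 4),
    ("HU", "huddling", OTHER, 81, 10, 3),
    ("IS", "isolation", OTHER, 222, 5, 5),
    ("RE", "reunion", OTHER, 279, 15, 5),
    ("SU", "surprise", OTHER, 18, 10, 6),
]

SITUATION_CODES = tuple(r[0] for r in _SITUATION_ROWS)

GROSS_CATEGORY = {r[0]: r[2] for r in _SITUATION_ROWS}


def load_study_fixture() -> pd.DataFrame:
    """Return the study-design table (one row per situation).

    Columns: ``situation``, ``description``, ``gross_category``,
    ``n_calls``, ``n_piglets``, ``n_litters``.
    """
    return pd.DataFrame(
        _SITUATION_ROWS,
        columns=[
            "situation",
            "description",
            "gross_category",
            "n_calls",
            "n_piglets",
            "n_litters",
        ],
    )
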