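"""Questionnaire battery configuration.

Nine psychiatric instruments totalling 209 analysis items (the Liebowitz
social-anxiety scale contributes its 24 items once, after averaging the fear
and avoidance answers of each item), plus the 44-item Big Five Inventory.
Each entry records the item count, the ordinal response range used for
simulation and totalling, the reverse-keyed items (1-based indices within the
instrument), and the transdiagnostic factor on which the instrument's items
load most heavily (used only by the synthetic generator).
"""

from __future__ import annotations

FACTOR_NAMES = ("AD", "CIT", "SW")

#: name -> (n_items, min_response, max_response, dominant_factor, reverse_items)
PSYCHIATRIC_INSTRUMENTS: dict[str, dict] = {
    "zung":  {"n_items": 20, "min": 1, "max": 4, "factor": "AD",
              "reverse": [2, 5, 6, 11, 12, 14, 16, 17, 18, 20]},
    "stai":  {"n_items": 20, "min": 1, "max": 4, "factor": "AD", "reverse": []},
    "aes":   {"n_items": 18, "min": 1, "max": 4, "factor": "AD", "reverse": []},
    "bis":   {"n_items": 30, "min": 1, "max": 4, "factor": "AD", "reverse": []},
    "oci":   {"n_items": 18, "min": 0, "max": 4, "factor": "CIT", "reverse": []},
    "eat":   {"n_items": 26, "min": 0, "max": 3, "factor": "CIT", "reverse": []},
    "audit": {"n_items": 10, "min": 0, "max": 4, "factor": "CIT", "reverse": []},
    "ssms":  {"n_items": 43, "min": 0, "max": 1, "factor": "CIT", "reverse": []},
    "lsas":  {"n_items": 24, "min": 0, "max": 3, "factor": "SW", "reverse": []},
}

N_PSYCHIATRIC_ITEMS = sum(v["n_items"] for v in PSYCHIATRIC_INSTRUMENTS.values())
assert N_PSYCHIATRIC_ITEMS == 209

BIG5_SUBSCALES: dict[str, int] = {
    "extraversion": 8,
    "agreeableness": 9,
    "conscientiousness": 9,
    "neuroticism": 8,
    "openness": 10,
}
BIG5_RANGE = (1, 5)

#: default attention-check: embedded in the depression scale, correct answer
#: is the response option "Good part of the time" (coded as its scale value).
CATCH_ITEM = {"instrument": "zung", "required_response": "Good part of the time"}


def item_ids(instrument: str) -> list[str]:
    n = PSYCHIATRIC_INSTRUMENTS[instrument]["n_items"]
    return [f"{instrument}_{i:02d}" for i in range(1, n + 1)]


def all_item_ids() -> list[str]:
    out: list[str] = []
    for name in PSYCHIATRIC_INSTRUMENTS:
        out.extend(item_ids(name))
    return out
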