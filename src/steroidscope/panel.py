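"""The 24-h urinary steroid metabolite panel.

Seventeen steroid metabolites quantified by LC-MS/MS from 24-h urine
collections, covering glucocorticoids and their tetrahydro-metabolites,
glucocorticoid and mineralocorticoid-pathway precursors, classic androgen
metabolites, and the major urinary metabolite of the adrenal 11-oxygenated
androgens (11beta-hydroxyandrosterone, 11b-OHAn).

Canonical short names are ASCII; common unicode spellings (5α-THF,
11β-OHAn) are accepted as aliases on input.
"""

from __future__ import annotations

# canonical name -> (full name, functional class)
PANEL: dict[str, tuple[str, str]] = {
    "F": ("cortisol", "glucocorticoid"),
    "E": ("cortisone", "glucocorticoid"),
    "THF": ("tetrahydrocortisol", "glucocorticoid"),
    "5a-THF": ("5alpha-tetrahydrocortisol", "glucocorticoid"),
    "THE": ("tetrahydrocortisone", "glucocorticoid"),
    "a-cortol": ("alpha-cortol", "glucocorticoid"),
    "b-cortol": ("beta-cortol", "glucocorticoid"),
    "a-cortolone": ("alpha-cortolone", "glucocorticoid"),
    "b-cortolone": ("beta-cortolone", "glucocorticoid"),
    "THS": ("tetrahydro-11-deoxycortisol", "precursor"),
    "PD": ("pregnanediol", "precursor"),
    "PT": ("pregnanetriol", "precursor"),
    "5-PT": ("pregnenetriol", "precursor"),
    "An": ("androsterone", "classic_androgen"),
    "Etio": ("etiocholanolone", "classic_androgen"),
    "DHEA": ("dehydroepiandrosterone", "classic_androgen"),
    "11b-OHAn": ("11beta-hydroxyandrosterone", "11oxy_androgen"),
}

STEROIDS: tuple[str, ...] = tuple(PANEL)

GLUCOCORTICOIDS = tuple(k for k, (_, c) in PANEL.items() if c == "glucocorticoid")
PRECURSORS = tuple(k for k, (_, c) in PANEL.items() if c == "precursor")
CLASSIC_ANDROGENS = tuple(k for k, (_, c) in PANEL.items() if c == "classic_androgen")
OXY_ANDROGEN = "11b-OHAn"

_ALIASES = {
    "5α-thf": "5a-THF",
    "5alpha-thf": "5a-THF",
    "11β-ohan": "11b-OHAn",
    "11beta-ohan": "11b-OHAn",
    "11b-ohan": "11b-OHAn",
    "α-cortol": "a-cortol",
    "β-cortol": "b-cortol",
    "α-cortolone": "a-cortolone",
    "β-cortolone": "b-cortolone",
    "cortisol": "F",
    "cortisone": "E",
    "tetrahydrocortisone": "THE",
    "tetrahydrocortisol": "THF",
    "androsterone": "An",
    "etiocholanolone": "Etio",
    "pregnanediol": "PD",
    "pregnanetriol": "PT",
    "pregnenetriol": "5-PT",
}
_CANON = {k.lower(): k for k in PANEL}


def canonical_steroid(name: str) -> str:
    """Map a steroid column name to its canonical panel short name.

    Raises ``KeyError`` for names outside the 17-metabolite panel so that
    column drift is caught at read time rather than propagating silently.
    """
    key = name.strip()
    low = key.lower()
    if low in _CANON:
        return _CANON[low]
    if low in _ALIASES:
        return _ALIASES[low]
    raise KeyError(f"unknown steroid metabolite name: {name!r}")
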