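"""Published reference inputs used in worked examples and cross-checks.

``VACCINE_TOTALS_2019`` holds published national (or province) 2019
annual totals of infant vaccine doses reported through the routine
systems of four countries, keyed by antigen role.  Antigens absent from
a country's routine extract (rotavirus in Lao PDR and Nepal, oral polio
in the South Africa extract) are omitted, never zero-filled.  The
percentages derived from these totals are always recomputed from the
counts at run time.
"""

from __future__ import annotations

VACCINE_TOTALS_2019: dict[str, dict[str, int]] = {
    "Ethiopia": {
        "penta3": 5_962_794,
        "bcg": 6_070_807,
        "pneumococcal3": 5_922_534,
        "oral_polio3": 5_877_936,
        "rotavirus2": 5_886_793,
    },
    "South Africa (KZN)": {
        "penta3": 421_784,
        "bcg": 385_619,
        "pneumococcal3": 464_272,
        "rotavirus2": 413_308,
    },
    "Lao PDR": {
        "penta3": 270_512,
        "bcg": 263_755,
        "pneumococcal3": 266_734,
        "oral_polio3": 253_542,
    },
    "Nepal": {
        "penta3": 1_026_692,
        "bcg": 1_102_239,
        "pneumococcal3": 982_775,
        "oral_polio3": 1_000_842,
    },
}
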