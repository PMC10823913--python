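"""Published parameter sets of the diameter-height mixed model.

Three fitted parameterisations ship with the package, keyed by study
area: Bauges (French Prealps), Milicz (Poland) and Sneznik (Slovenia).
Species codes abbreviate Latin names (``Fa.sy.`` = Fagus sylvatica, ...);
``OtherSp`` pools species with too few observations. At Sneznik only
dominant trees carried height measurements, so the within-stand shape
parameters (species approach rates ``beta_sp`` and the exponent
``gamma``) are borrowed from the Bauges fit, which is flagged on the
parameter object.
"""

from __future__ import annotations

BAUGES = {
    "site": "bauges",
    "alpha_sp": {
        "Fa.sy.": 41.05595,
        "Pi.ab.": 55.11821,
        "Ab.al.": 48.46640,
        "Fr.ex.": 40.94293,
        "Ac.ps.": 37.95001,
        "Qu.pe.": 36.64676,
        "OtherSp": 36.87834,
    },
    "alpha1": 0.01594,
    "alpha2": 1.26326,
    "beta_sp": {
        "Fa.sy.": 1.71474,
        "Pi.ab.": 0.99226,
        "Ab.al.": 1.17894,
        "Fr.ex.": 2.01951,
        "Ac.ps.": 2.08068,
        "Qu.pe.": 1.56216,
        "OtherSp": 1.84067,
    },
    "gamma": 1.42595,
    "variance_power": 0.51,
    "random_sd": 0.14,
    "resid_sd": 0.59,
    "borrowed_from": None,
}

MILICZ = {
    "site": "milicz",
    "alpha_sp": {
        "Pi.sy.": 48.55802,
        "Fa.sy.": 48.01692,
        "Pi.ab.": 60.35196,
        "Qu.un.": 52.24210,
        "Be.pe.": 51.60844,
        "Al.gl.": 49.34039,
        "Ca.be.": 36.73985,
        "La.de.": 52.06992,
        "Ti.co.": 45.25535,
        "Qu.ru.": 45.74754,
        "Ac.ps.": 41.50894,
        "Pr.se.": 36.18532,
        "OtherSp": 54.94652,
    },
    "alpha1": 0.01958,
    "alpha2": 1.13831,
    "beta_sp": {
        "Pi.sy.": 2.73192,
        "Fa.sy.": 1.98085,
        "Pi.ab.": 1.20700,
        "Qu.un.": 1.62943,
        "Be.pe.": 2.11097,
        "Al.gl.": 2.04760,
        "Ca.be.": 2.86677,
        "La.de.": 2.33369,
        "Ti.co.": 1.89682,
        "Qu.ru.": 2.38748,
        "Ac.ps.": 2.56340,
        "Pr.se.": 2.04373,
        "OtherSp": 1.50792,
    },
    "gamma": 1.55264,
    "variance_power": 0.16,
    "random_sd": 0.09,
    "resid_sd": 1.09,
    "borrowed_from": None,
}

# beta_sp and gamma taken from the Bauges fit (dominant-tree-only heights
# at Sneznik preclude estimating the within-stand curve shape).
SNEZNIK = {
    "site": "sneznik",
    "alpha_sp": {
        "Ab.al.": 66.17413,
        "Fa.sy.": 53.81402,
        "Pi.ab.": 76.82544,
    },
    "alpha1": 0.0251,
    "alpha2": 1.00672,
    "beta_sp": {
        "Ab.al.": 1.17894,
        "Fa.sy.": 1.71474,
        "Pi.ab.": 0.99226,
    },
    "gamma": 1.42595,
    "variance_power": -0.56,
    "random_sd": 0.077,
    "resid_sd": 15.8,
    "borrowed_from": "bauges",
}

PUBLISHED = {"bauges": BAUGES, "milicz": MILICZ, "sneznik": SNEZNIK}
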