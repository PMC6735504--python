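"""Bundled example group-summary data and headline treatment ratios.

These are published group-level summary statistics from a preclinical
study of microbubble-enhanced focused-ultrasound carboplatin delivery in
the rat F98 glioma model: gadolinium (Gadavist) tissue concentrations
estimated from R1 maps, intact-carboplatin concentrations by LC-MS/MS
(geometric mean, geometric %CV), tumor-volume doubling times, and median
survival per treatment group. They serve as worked-example inputs for the
ratio, dose-conversion, and survival utilities; the per-animal raw data
were not released, so only summary-level arithmetic is possible on them.
"""

from __future__ import annotations

from .outcomes import human_equivalent_dose, increase_in_survival_time, per_target_prf
from .plant import power_to_pressure

__all__ = [
    "GADAVIST_UG_PER_G",
    "CARBOPLATIN",
    "DOUBLING_TIME_DAYS",
    "MEDIAN_SURVIVAL_DAYS",
    "headline_ratios",
]

#: Estimated Gadavist concentration (ug/g), sonicated vs control tumors.
GADAVIST_UG_PER_G = {
    "tumor_core": {"sonicated": 11.6, "control": 6.9},
    "tumor_rim": {"sonicated": 19.3, "control": 5.6},
}

#: Intact carboplatin, geometric mean (geometric %CV), by compartment and
#: time after sonication. Tissue in ug/g, plasma in ug/mL.
CARBOPLATIN = {
    "1h": {
        "tumor": {"sonicated": (21.6, 20.0), "control": (7.4, 43.0)},
        "brain": {"sonicated": (11.1, 34.0), "control": (1.5, 11.0)},
        "plasma": (26.9, 23.9),
    },
    "4h": {
        "tumor": {"sonicated": (6.4, 11.0), "control": (2.7, 16.0)},
        "brain": {"sonicated": (5.1, 11.0), "control": (1.2, 17.0)},
        "plasma": (0.61, 19.6),
    },
}

#: Tumor doubling time (days, group mean) for the hypointense core and the
#: surrounding hyperintense volume (HIV), per treatment group.
DOUBLING_TIME_DAYS = {
    "control": {"core": 3.1, "hiv": 3.9},
    "drug_only": {"core": 3.6, "hiv": 4.3},
    "fus_drug": {"core": 7.0, "hiv": 7.5},
}

#: Kaplan-Meier median survival (days) per treatment group.
MEDIAN_SURVIVAL_DAYS = {"control": 25.0, "drug_only": 28.0, "fus_drug": 41.5}

#: Treatment exposure parameters.
CARBOPLATIN_DOSE_MG_PER_KG = 50.0
RAT_KM_FACTOR = 6.0
N_TARGETS = 9
BURST_INTERVAL_S = 0.1016
POWER_RANGE_W = (0.16, 0.39)
PRESSURE_ANCHOR = (0.16, 119.0)


def headline_ratios() -> dict:
    """Recompute the study's headline delivery and outcome ratios.

    All values are exact arithmetic on the bundled group summaries:
    sonicated/control concentration ratios, plasma clearance fold-change,
    tissue-to-plasma factors at 4 h, doubling-time and median-survival
    increases, per-target PRF, human-equivalent dose, and the peak
    pressure at the power cap from square-root scaling.
    """
    carb_1h = CARBOPLATIN["1h"]
    carb_4h = CARBOPLATIN["4h"]
    return {
        "gadavist_core_ratio": (
            GADAVIST_UG_PER_G["tumor_core"]["sonicated"] / GADAVIST_UG_PER_G["tumor_core"]["control"]
        ),
        "gadavist_rim_ratio": (
            GADAVIST_UG_PER_G["tumor_rim"]["sonicated"] / GADAVIST_UG_PER_G["tumor_rim"]["control"]
        ),
        "carboplatin_tumor_ratio_1h": carb_1h["tumor"]["sonicated"][0] / carb_1h["tumor"]["control"][0],
        "carboplatin_brain_ratio_1h": carb_1h["brain"]["sonicated"][0] / carb_1h["brain"]["control"][0],
        "carboplatin_tumor_ratio_4h": carb_4h["tumor"]["sonicated"][0] / carb_4h["tumor"]["control"][0],
        "carboplatin_brain_ratio_4h": carb_4h["brain"]["sonicated"][0] / carb_4h["brain"]["control"][0],
        "plasma_fold_decrease": carb_1h["plasma"][0] / carb_4h["plasma"][0],
        "tumor_to_plasma_4h": carb_4h["tumor"]["sonicated"][0] / carb_4h["plasma"][0],
        "brain_to_plasma_4h": carb_4h["brain"]["sonicated"][0] / carb_4h["plasma"][0],
        "doubling_increase_vs_drug_only_pct": 100.0
        * (DOUBLING_TIME_DAYS["fus_drug"]["core"] / DOUBLING_TIME_DAYS["drug_only"]["core"] - 1.0),
        "doubling_increase_vs_control_pct": 100.0
        * (DOUBLING_TIME_DAYS["fus_drug"]["core"] / DOUBLING_TIME_DAYS["control"]["core"] - 1.0),
        "ist_vs_control_pct": increase_in_survival_time(
            MEDIAN_SURVIVAL_DAYS["fus_drug"], MEDIAN_SURVIVAL_DAYS["control"]
        ),
        "ist_vs_drug_only_pct": increase_in_survival_time(
            MEDIAN_SURVIVAL_DAYS["fus_drug"], MEDIAN_SURVIVAL_DAYS["drug_only"]
        ),
        "per_target_prf_hz": per_target_prf(N_TARGETS, BURST_INTERVAL_S),
        "human_equivalent_dose_mg_per_m2": human_equivalent_dose(
            CARBOPLATIN_DOSE_MG_PER_KG, RAT_KM_FACTOR
        ),
        "pressure_at_power_cap_kpa": power_to_pressure(POWER_RANGE_W[1], PRESSURE_ANCHOR),
    }
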