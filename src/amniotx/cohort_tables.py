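"""Published clinical characteristics of the 38-sample amniocentesis cohort.

Categorical findings from the clinical table of the preterm-labor
amniocentesis study the pipeline is designed around: 38 women sampled
after an episode of preterm labor, 10 delivering within 24 hours of the
procedure and 28 later.  Each entry is a 2x2 count table
((present, absent) in the imminent-delivery group,
 (present, absent) in the later-delivery group); denominators smaller
than 10/28 reflect assessments missing for some women.  These counts are
the inputs to the Fisher's exact comparisons of the clinical table and
serve as a reference fixture for the clinical-statistics module.
"""

from __future__ import annotations

CATEGORICAL_COUNTS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "nulliparity": ((3, 7), (4, 24)),
    "history_of_preterm_birth": ((4, 6), (10, 18)),
    "african_american": ((9, 1), (24, 4)),
    "af_il6_ge_2.6_ng_ml": ((8, 2), (8, 20)),
    "positive_af_culture": ((2, 7), (2, 26)),
    "af_wbc_ge_50_per_mm3": ((5, 5), (0, 28)),
    "af_glucose_lt_14_mg_dl": ((6, 3), (1, 27)),
    "cesarean_section": ((2, 8), (3, 25)),
    "antenatal_corticosteroids": ((7, 3), (26, 2)),
    "tocolytic_agents": ((4, 6), (13, 15)),
    "composite_neonatal_morbidity": ((7, 3), (11, 17)),
    "acute_chorioamnionitis": ((5, 4), (9, 15)),
    "chronic_chorioamnionitis": ((4, 5), (7, 17)),
}

#: Published two-sided Fisher's exact p-values for the same rows, as
#: printed (3 decimals; "<0.001" entries are recorded as the bound).
PUBLISHED_FISHER_P: dict[str, float] = {
    "nulliparity": 0.351,
    "history_of_preterm_birth": 1.0,
    "african_american": 1.0,
    "af_il6_ge_2.6_ng_ml": 0.008,
    "positive_af_culture": 0.244,
    "af_wbc_ge_50_per_mm3": 0.001,
    "af_glucose_lt_14_mg_dl": 0.001,
    "cesarean_section": 0.592,
    "antenatal_corticosteroids": 0.103,
    "tocolytic_agents": 1.0,
    "composite_neonatal_morbidity": 0.144,
    "acute_chorioamnionitis": 0.442,
    "chronic_chorioamnionitis": 0.438,
}

#: Rows printed as an upper bound rather than an exact value.
UPPER_BOUND_ROWS = frozenset({"af_wbc_ge_50_per_mm3", "af_glucose_lt_14_mg_dl"})
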