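"""Published statewide reference counts (Georgia deliveries, 2017-2022).

Cell counts from the published characteristics table of a 774,639-delivery
statewide cohort, by transport status.  Each 2x2 entry is
(a, b, c, d) = (level transported, level not transported,
reference transported, reference not transported); these are the inputs from
which the published unadjusted odds ratios recompute in closed form.
"""

from __future__ import annotations

from .association import TwoByTwo

#: Total deliveries, transported deliveries, and the network-eligible subset
#: after excluding missing-endpoint and non-obstetric-facility transports.
TOTAL_DELIVERIES = 774_639
TOTAL_TRANSPORTED = 3_285
NETWORK_ELIGIBLE_TRANSPORTS = 2_757

#: (covariate, level, reference) -> 2x2 transport contingency cells.
GEORGIA_TWO_BY_TWO: dict[str, TwoByTwo] = {
    "rural_vs_urban": TwoByTwo(431, 30514, 1573, 629466),
    "suburban_vs_urban": TwoByTwo(1158, 90063, 1573, 629466),
    "black_vs_white": TwoByTwo(1617, 275801, 1531, 437472),
    "preterm_vs_term": TwoByTwo(2529, 87860, 755, 683461),
    "medicaid_vs_commercial": TwoByTwo(2026, 353994, 738, 311055),
    "tricare_vs_commercial": TwoByTwo(274, 30385, 738, 311055),
    "plurality2plus_vs_singleton": TwoByTwo(502, 26603, 2783, 744751),
    "tobacco_vs_none": TwoByTwo(320, 30104, 2945, 737690),
    "medrisk2plus_vs_none": TwoByTwo(553, 39268, 1587, 554204),
    "nicu_vs_none": TwoByTwo(2302, 71909, 983, 699444),
}

#: Published unadjusted odds ratios for the same contrasts (display scale).
GEORGIA_PUBLISHED_OR: dict[str, float] = {
    "rural_vs_urban": 5.652,
    "suburban_vs_urban": 5.145,
    "black_vs_white": 1.675,
    "preterm_vs_term": 26.057,
    "medicaid_vs_commercial": 2.412,
    "tricare_vs_commercial": 3.801,
    "plurality2plus_vs_singleton": 5.050,
    "tobacco_vs_none": 2.663,
    "medrisk2plus_vs_none": 4.918,
    "nicu_vs_none": 22.778,
}

#: Published Woolf-style interval for the rural-vs-urban contrast.
GEORGIA_RURAL_CI = (5.078, 6.292)
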