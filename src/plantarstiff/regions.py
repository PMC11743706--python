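"""Plantar region conventions and reference calibration values.

The feature space everywhere in this package is the ten anatomical plantar
regions produced by pressure-plate zoning software, in a fixed order:
region 1 is the hallux, region 2 the second-to-fifth toes, regions 3-7 the
first-to-fifth metatarsals, region 8 the midfoot, region 9 the medial heel
and region 10 the lateral heel.

The reference constants below calibrate the synthetic cohort generator to a
healthy young-adult walking population measured with a handheld
damped-oscillation stiffness meter: plantar-aponeurosis stiffness of
476.99 +/- 15.26 N/m, and per-region contribution rates (in percent, with
their reported effect direction) of regional mean stance-phase pressure to
that stiffness.
"""

from __future__ import annotations

REGION_LABELS: tuple[str, ...] = (
    "hallux",
    "toes_2_5",
    "metatarsal_1",
    "metatarsal_2",
    "metatarsal_3",
    "metatarsal_4",
    "metatarsal_5",
    "midfoot",
    "medial_heel",
    "lateral_heel",
)

N_REGIONS = len(REGION_LABELS)

REGION_INDEX: dict[str, int] = {label: i for i, label in enumerate(REGION_LABELS)}

#: Reference contribution rates (%) of each region's mean pressure to
#: soft-tissue stiffness in the calibration population.  They sum to 100.
REFERENCE_CONTRIBUTION_RATES: dict[str, float] = {
    "hallux": 6.41,
    "toes_2_5": 5.78,
    "metatarsal_1": 9.44,
    "metatarsal_2": 9.17,
    "metatarsal_3": 13.58,
    "metatarsal_4": 14.71,
    "metatarsal_5": 8.15,
    "midfoot": 12.43,
    "medial_heel": 12.58,
    "lateral_heel": 7.75,
}

#: Reported direction of each region's influence on stiffness (+1 / -1).
REFERENCE_EFFECT_SIGNS: dict[str, int] = {
    "hallux": -1,
    "toes_2_5": -1,
    "metatarsal_1": -1,
    "metatarsal_2": +1,
    "metatarsal_3": +1,
    "metatarsal_4": +1,
    "metatarsal_5": +1,
    "midfoot": -1,
    "medial_heel": +1,
    "lateral_heel": +1,
}

#: Calibration cohort plantar soft-tissue stiffness, N/m.
REFERENCE_STIFFNESS_MEAN = 476.99
REFERENCE_STIFFNESS_SD = 15.26

#: Valid measurement range of the handheld stiffness meter, N/m.
MYOTON_STIFFNESS_RANGE = (70.0, 1900.0)
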