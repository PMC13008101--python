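"""Health-state space of the liver-fibrosis Markov model.

The cohort moves through the natural history of metabolic
dysfunction-associated steatotic liver disease (MASLD): a disease-free state,
fibrosis stages F0-F3, compensated cirrhosis (F4/CC), decompensated cirrhosis
(DC), hepatocellular carcinoma (HCC), the transplant year (LT), the
post-transplant state, and three absorbing cause-specific death states
(cardiovascular, liver-related, other).
"""

from __future__ import annotations

from enum import IntEnum


class HealthState(IntEnum):
    NO_MASLD = 0
    F0 = 1
    F1 = 2
    F2 = 3
    F3 = 4
    F4_CC = 5
    DC = 6
    HCC = 7
    LT = 8
    POST_LT = 9
    DEATH_CVD = 10
    DEATH_LIVER = 11
    DEATH_OTHER = 12


N_STATES = len(HealthState)

DEATH_STATES = (HealthState.DEATH_CVD, HealthState.DEATH_LIVER, HealthState.DEATH_OTHER)
ALIVE_STATES = tuple(s for s in HealthState if s not in DEATH_STATES)

#: states in which a lifestyle-modification programme can run (pre-decompensation)
PRE_DC_STATES = (
    HealthState.NO_MASLD,
    HealthState.F0,
    HealthState.F1,
    HealthState.F2,
    HealthState.F3,
    HealthState.F4_CC,
)

#: non-cirrhotic MASLD states (all-cause mortality hazard ratio 1.29)
NONCIRRHOTIC_MASLD = (HealthState.F0, HealthState.F1, HealthState.F2, HealthState.F3)

#: cirrhotic states (all-cause mortality hazard ratio 3.13)
CIRRHOTIC_STATES = (HealthState.F4_CC, HealthState.DC, HealthState.HCC)

#: states whose occupants hold significant fibrosis (stage >= 2), the screening target
SIGNIFICANT_FIBROSIS = (
    HealthState.F2,
    HealthState.F3,
    HealthState.F4_CC,
)

#: advanced-disease states billed at the higher clinic-visit frequency
ADVANCED_STATES = (HealthState.DC, HealthState.HCC, HealthState.LT, HealthState.POST_LT)
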