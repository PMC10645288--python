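"""Reference coefficient sets for the three taxonomic range-filling models.

Point estimates (logit scale, standardized covariates) of the selected
plants, birds, and mammals models linking range filling to introduction
history, dispersal, recording effort, and the contagion of climatically
suitable areas.  They serve as generating values for the package's
parameter-recovery demonstrations: simulate establishment events from the
hierarchical beta-logit model with these coefficients, refit, and compare
posterior means with the generating values.
"""

from __future__ import annotations

#: per-taxon generating models: intercept and slope map (logit scale)
TAXON_MODELS = {
    "plants": {
        "intercept": -2.30,
        "coefs": {
            "years_since_introduction": 0.35,
            "days_till_flowering": -0.13,
            "local_recording_effort": -0.30,
        },
    },
    "birds": {
        "intercept": -2.79,
        "coefs": {
            "years_since_introduction": 0.35,
            "dispersal_distance": 0.37,
            "contagion": 0.61,
        },
    },
    "mammals": {
        "intercept": -1.83,
        "coefs": {
            "dispersal_distance": -0.28,
            "contagion": 0.64,
        },
    },
}

#: simulation conditions for the recovery demonstrations
RECOVERY_N = 5000
RECOVERY_N_REALMS = 6
RECOVERY_REALM_SD = 0.3
RECOVERY_PHI = 15.0
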