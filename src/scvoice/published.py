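"""Reference coefficient sets of the deployed voice-based Sasang
constitution classifier, one per sex.

``SCORE_COEFFICIENTS`` holds, for each sex and constitution type
(TE, SE, SY), the intercept and the sparse L1-selected coefficients of
the per-class score over the 21 standardized vocal features; features
absent from a class's dictionary were shrunk exactly to zero.

``MLR_COEFFICIENTS`` holds the multinomial-logistic stage: for the TE
and SE logits (SY is the reference class) an intercept plus
coefficients on [age in years, eta1, eta2, eta3], where eta_k are the
three per-class scores.
"""

from __future__ import annotations

SCORE_COEFFICIENTS: dict[str, dict[str, dict]] = {
    "male": {
        "TE": {
            "intercept": 0.310,
            "coefficients": {
                "sF0": 0.081,
                "sISTD": 0.107,
                "sSPD": -0.004,
                "sLPR2": 0.197,
                "sMFCC1": -0.213,
                "sMFCC3": 0.238,
                "sMFCC4": 0.124,
                "sMFCC11": 0.109,
            },
        },
        "SE": {
            "intercept": -0.309,
            "coefficients": {
                "sFSTD": -0.209,
                "sI0": 0.159,
                "sLPR3": -0.031,
                "sMFCC0": -0.007,
                "sMFCC1": 0.065,
                "sMFCC2": -0.068,
                "sMFCC5": 0.096,
                "sMFCC6": 0.170,
                "sMFCC7": 0.126,
                "sMFCC8": 0.032,
                "sMFCC9": -0.119,
                "sMFCC10": -0.099,
                "sMFCC11": -0.074,
            },
        },
        "SY": {
            "intercept": 0.000,
            "coefficients": {
                "sFSTD": 0.168,
                "sI0": -0.212,
                "sISTD": -0.019,
                "sSPD": 0.081,
                "sLPR1": 0.060,
                "sLPR2": -0.126,
                "sMFCC0": 0.207,
                "sMFCC2": 0.218,
                "sMFCC3": -0.127,
                "sMFCC5": -0.105,
                "sMFCC6": -0.028,
                "sMFCC7": -0.067,
                "sMFCC10": 0.146,
                "sMFCC12": 0.046,
            },
        },
    },
    "female": {
        "TE": {
            "intercept": 0.042,
            "coefficients": {
                "sF0": -0.112,
                "sI0": -0.071,
                "sSPD": 0.048,
                "sLPR2": 0.049,
                "sMFCC1": -0.027,
                "sMFCC2": -0.071,
                "sMFCC3": -0.083,
                "sMFCC5": 0.012,
                "sMFCC6": -0.035,
                "sMFCC7": -0.126,
                "sMFCC8": 0.263,
                "sMFCC9": 0.215,
                "sMFCC11": -0.032,
                "sMFCC12": -0.099,
            },
        },
        "SE": {
            "intercept": -0.157,
            "coefficients": {
                "sF0": 0.015,
                "sFSTD": -0.048,
                "sI0": 0.062,
                "sLPR1": 0.017,
                "sMFCC2": 0.001,
                "sMFCC3": 0.032,
                "sMFCC5": -0.010,
                "sMFCC7": 0.016,
                "sMFCC9": -0.038,
            },
        },
        "SY": {
            "intercept": 0.116,
            "coefficients": {
                "sISTD": -0.040,
                "sSPD": -0.015,
                "sLPR1": -0.004,
                "sLPR2": -0.067,
                "sLPR3": -0.012,
                "sMFCC1": 0.081,
                "sMFCC4": 0.020,
                "sMFCC11": 0.027,
                "sMFCC12": 0.126,
            },
        },
    },
}

# TE and SE logits relative to the SY reference; coefficient order is
# (intercept, age, eta1, eta2, eta3).
MLR_COEFFICIENTS: dict[str, dict[str, dict[str, float]]] = {
    "male": {
        "TE": {
            "intercept": -0.284,
            "age": 0.004,
            "eta1": 1.254,
            "eta2": 0.001,
            "eta3": -1.222,
        },
        "SE": {
            "intercept": 0.754,
            "age": -0.017,
            "eta1": 0.241,
            "eta2": 1.078,
            "eta3": -1.176,
        },
    },
    "female": {
        "TE": {
            "intercept": -0.498,
            "age": 0.011,
            "eta1": 1.116,
            "eta2": 0.105,
            "eta3": -1.297,
        },
        "SE": {
            "intercept": 0.251,
            "age": -0.003,
            "eta1": -0.087,
            "eta2": 1.453,
            "eta3": -1.464,
        },
    },
}
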