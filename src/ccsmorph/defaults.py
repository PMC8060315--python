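"""Published cohort statistics used as package defaults.

All values come from the 23-heart cadaveric morphometry cohort the package
models: marginal means/SDs of the cardiac and conduction-component
projection angles, the eight fitted cardiac-to-CCS inclination regressions,
and the component dimension distributions (mean, SD, observed range, mm).

Where the source's summary table and its running text disagree (beta_sgt,
beta_frt, delta), the defaults use the text values because only those
satisfy the ordinary-least-squares identity that a fitted line passes
through the sample mean point.  The table variants are retained below in
comments; the package does not guess which the authors intended.
"""

from __future__ import annotations

__all__ = [
    "CARDIAC_ANGLE_STATS",
    "CCS_ANGLE_STATS",
    "PRINTED_REGRESSION_COEFFS",
    "PAIR_TO_CARDIAC",
    "PAIR_IDS",
    "TABLE_DIMS",
    "INCONSISTENT_PAIRS",
]

#: Cardiac-axis projection angles: column -> (mean, SD) in degrees.
CARDIAC_ANGLE_STATS: dict[str, tuple[float, float]] = {
    "X_sgt": (99.8, 12.1),
    "X_frt": (46.8, 8.1),
    "X_hzt": (61.5, 13.4),
}

#: Conduction-component projection angles: pair id -> (mean, SD) in degrees.
#: Text-version means (see module docstring).  Summary-table variants:
#:   beta_sgt 31.9 +- 13.2, beta_frt 32.9 +- 17.6, delta 117.1 +- 15.1.
CCS_ANGLE_STATS: dict[str, tuple[float, float]] = {
    "alpha_sgt": (87.8, 18.6),
    "alpha_frt": (49.4, 10.4),
    "alpha_hzt": (272.4, 13.6),
    "beta_sgt": (34.5, 12.9),
    "beta_frt": (147.2, 17.6),
    "beta_hzt": (30.2, 12.4),
    "gamma": (41.5, 15.7),
    "delta": (120.2, 14.6),
}

#: The eight published regression equations: pair id -> (slope, intercept),
#: CCS angle = slope * cardiac angle + intercept, both in degrees.
PRINTED_REGRESSION_COEFFS: dict[str, tuple[float, float]] = {
    "alpha_sgt": (1.165, -28.50),
    "alpha_frt": (0.913, 6.687),
    "alpha_hzt": (0.481, -244.2),
    "beta_sgt": (0.239, 10.67),
    "beta_frt": (-0.733, 181.5),
    "beta_hzt": (0.643, -9.341),
    "gamma": (0.710, -2.145),
    "delta": (0.809, 70.27),
}

#: Which cardiac angle each CCS angle regresses on.  The bundle-branch
#: angles (gamma, delta) exist in the horizontal plane only.
PAIR_TO_CARDIAC: dict[str, str] = {
    "alpha_sgt": "X_sgt",
    "alpha_frt": "X_frt",
    "alpha_hzt": "X_hzt",
    "beta_sgt": "X_sgt",
    "beta_frt": "X_frt",
    "beta_hzt": "X_hzt",
    "gamma": "X_hzt",
    "delta": "X_hzt",
}

PAIR_IDS = tuple(PAIR_TO_CARDIAC)

#: Pairs whose printed equation does not pass through the printed means:
#: pair id -> absolute through-the-means gap in degrees.  alpha_hzt misses
#: by far more than any 360-degree branch can absorb (0.481*61.5 - 244.2 is
#: 127 degrees short of 272.4 modulo 360); delta misses by 0.2 degrees,
#: attributable to coefficient rounding.
INCONSISTENT_PAIRS: dict[str, float] = {"alpha_hzt": 126.98, "delta": 0.18}

#: Component dimensions: component -> measure -> (mean, sd, min, max) in mm,
#: or None where the source prints NA.
TABLE_DIMS: dict[str, dict[str, tuple[float, float, float, float] | None]] = {
    "sinus_node": {
        "length": (33.9, 7.8, 20.5, 53.5),
        "width": (7.4, 1.9, 4.0, 12.3),
        "thickness": (1.6, 0.4, 1.0, 2.4),
    },
    "compact_node": {
        "length": (8.7, 1.7, 5.0, 11.7),
        "width": (4.4, 1.2, 2.4, 6.9),
        "thickness": (2.2, 0.6, 1.4, 4.0),
    },
    "pbh": {
        "length": (4.7, 1.6, 1.7, 7.7),
        "width": (1.4, 0.4, 0.7, 2.2),
        "thickness": (1.2, 0.3, 0.7, 1.9),
    },
    "bbh": {
        "length": (9.6, 2.7, 5.3, 14.9),
        "width": (1.2, 0.3, 0.7, 1.7),
        "thickness": (1.3, 0.3, 0.9, 2.2),
    },
    "lbb_origin": {
        "length": None,
        "width": (9.3, 2.6, 5.1, 14.5),
        "thickness": (0.4, 0.1, 0.3, 0.7),
    },
    "lbb_bending": {
        "length": None,
        "width": (11.4, 2.7, 5.3, 15.5),
        "thickness": (0.4, 0.1, 0.3, 0.6),
    },
    "rbb_proximal": {
        "length": None,
        "width": (1.1, 0.2, 0.8, 1.7),
        "thickness": (1.1, 0.3, 0.3, 1.6),
    },
    "rbb_distal": {
        "length": None,
        "width": (1.0, 0.2, 0.6, 1.5),
        "thickness": (0.9, 0.2, 0.6, 1.2),
    },
}
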