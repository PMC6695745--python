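"""Published reference values shipped with the package.

These are the reference cut-point tables and free-living time-use summaries
for the hip/thigh placements and the three calibration age groups, as
printed in the source calibration study. They are used for arithmetic
consistency checks and as a realism anchor for the synthetic generator;
they are *not* used to fit or tune anything at run time.
"""

from __future__ import annotations

#: Net-VO2 cut-points (mL/min/kg) translated from adult MET values.
PUBLISHED_VO2NET_CUTPOINTS = {"LPA": 1.1, "MPA": 5.5, "VPA": 14.2, "VVPA": 22.9}

#: Standard MET cut-points.
PUBLISHED_MET_CUTPOINTS = {"LPA": 1.5, "MPA": 3.0, "VPA": 6.0, "VVPA": 9.0}

#: mg cut-points: (placement, group, method) -> level -> mg.
PUBLISHED_MG_CUTPOINTS = {
    ("hip", "children", "vo2net"): {"LPA": 29, "MPA": 124, "VPA": 368, "VVPA": 695},
    ("hip", "children", "met"): {"LPA": 52, "MPA": 214, "VPA": 704, "VVPA": 1075},
    ("hip", "adolescents", "vo2net"): {"LPA": 32, "MPA": 157, "VPA": 482, "VVPA": 830},
    ("hip", "adolescents", "met"): {"LPA": 50, "MPA": 219, "VPA": 753, "VVPA": 1062},
    ("hip", "adults", "vo2net"): {"LPA": 39, "MPA": 167, "VPA": 582, "VVPA": 994},
    ("hip", "adults", "met"): {"LPA": 39, "MPA": 167, "VPA": 582, "VVPA": 994},
    ("thigh", "children", "vo2net"): {"LPA": 60, "MPA": 234, "VPA": 603, "VVPA": 964},
    ("thigh", "children", "met"): {"LPA": 99, "MPA": 380, "VPA": 987, "VVPA": 1312},
    ("thigh", "adolescents", "vo2net"): {"LPA": 63, "MPA": 274, "VPA": 700, "VVPA": 1034},
    ("thigh", "adolescents", "met"): {"LPA": 90, "MPA": 368, "VPA": 964, "VVPA": 1272},
    ("thigh", "adults", "vo2net"): {"LPA": 67, "MPA": 273, "VPA": 782, "VVPA": 1181},
    ("thigh", "adults", "met"): {"LPA": 67, "MPA": 273, "VPA": 782, "VVPA": 1181},
}

#: Free-living daily summary (hip placement): method -> category -> level ->
#: (mean minutes, mean % of wear time).
PUBLISHED_DAILY_SUMMARY = {
    "vo2net": {
        "children": {"SED": (661, 64.8), "LPA": (142, 14.0), "MPA": (154, 15.1),
                     "VPA": (47, 4.6), "VVPA": (15, 1.5)},
        "adolescents": {"SED": (786, 77.1), "LPA": (119, 11.7), "MPA": (99, 9.7),
                        "VPA": (12, 1.1), "VVPA": (4, 0.4)},
        "adults_lt50": {"SED": (826, 81.0), "LPA": (119, 11.7), "MPA": (71, 7.0),
                        "VPA": (2, 0.2), "VVPA": (1, 0.1)},
        "adults_ge50": {"SED": (821, 80.5), "LPA": (128, 12.5), "MPA": (69, 6.8),
                        "VPA": (2, 0.2), "VVPA": (0, 0.0)},
    },
    "met": {
        "children": {"SED": (710, 69.6), "LPA": (170, 16.7), "MPA": (125, 12.3),
                     "VPA": (10, 1.0), "VVPA": (5, 0.5)},
        "adolescents": {"SED": (814, 77.8), "LPA": (123, 12.0), "MPA": (78, 7.6),
                        "VPA": (3, 0.3), "VVPA": (2, 0.2)},
        "adults_lt50": {"SED": (826, 81.0), "LPA": (119, 11.7), "MPA": (71, 7.0),
                        "VPA": (2, 0.2), "VVPA": (1, 0.1)},
        "adults_ge50": {"SED": (821, 80.5), "LPA": (128, 12.5), "MPA": (69, 6.8),
                        "VPA": (2, 0.2), "VVPA": (0, 0.0)},
    },
}
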