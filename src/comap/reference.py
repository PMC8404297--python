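"""Published summary inputs for the Danish 2014-15 cardiovascular cohorts.

These are aggregated, openly published characteristics of the nationwide
cohorts of incident acute myocardial infarction (AMI), stroke and atrial
fibrillation (AF) among Danish adults aged 30+ followed 2014-2015: case
counts and person-years by total, sex, age group and income group, and the
range of smoothed municipality-level standardized incidence ratios.  The
underlying individual-level register data are access-restricted; these
margins serve as aggregated inputs for crude-rate computations and for
presentation checks.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cohort_margins", "SIR_RANGE", "PRINTED_IR_PER_10K"]

# (margin, level) -> {disease: (cases, person_years)}
_MARGINS = [
    ("Total", "", (18_349, 6_868_414), (28_006, 6_817_459), (39_040, 6_790_503)),
    ("Sex", "female", (6_791, 3_561_742), (13_391, 3_506_561), (17_754, 3_506_072)),
    ("Sex", "male", (11_558, 3_306_672), (14_615, 3_310_898), (21_286, 3_284_431)),
    ("Age", "30-59", (4_895, 4_256_183), (5_775, 4_238_191), (4_805, 4_256_227)),
    ("Age", "60-69", (4_470, 1_321_559), (5_991, 1_313_460), (8_412, 1_312_313)),
    ("Age", "70-79", (4_595, 859_414), (7_676, 848_137), (12_345, 831_006)),
    ("Age", "80+", (4_389, 431_258), (8_564, 416_943), (13_478, 390_956)),
    ("Income", "Low", (4_572, 1_367_521), (6_991, 1_357_075), (8_600, 1_351_987)),
    ("Income", "Medium", (11_017, 4_124_208), (16_448, 4_093_957), (23_295, 4_077_683)),
    ("Income", "High", (2_760, 1_376_685), (4_567, 1_366_427), (7_145, 1_360_833)),
]

#: crude incidence rates per 10,000 person-years as published (one decimal),
#: in the row order of ``cohort_margins()``
PRINTED_IR_PER_10K = {
    "AMI": (26.7, 19.1, 35.0, 11.5, 33.8, 53.5, 101.8, 33.4, 26.7, 20.0),
    "stroke": (41.1, 38.2, 44.1, 13.6, 45.6, 90.5, 205.4, 51.5, 40.2, 33.4),
    "AF": (57.5, 50.6, 64.8, 11.3, 64.1, 148.6, 344.7, 63.6, 57.1, 52.5),
}

#: published range of smoothed municipality-specific SIRs per disease
SIR_RANGE = {"AMI": (0.76, 1.35), "stroke": (0.79, 1.38), "AF": (0.85, 1.24)}


def cohort_margins() -> pd.DataFrame:
    """Aggregated (cases, person_years) margins as a tidy frame with columns
    disease, margin, level, cases, person_years."""
    rows = []
    for margin, level, ami, stroke, af in _MARGINS:
        for disease, (cases, py) in zip(("AMI", "stroke", "AF"), (ami, stroke, af)):
            rows.append((disease, margin, level, cases, py))
    return pd.DataFrame(
        rows, columns=["disease", "margin", "level", "cases", "person_years"]
    )
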