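"""Published reference values from the Tangkoko crested macaque study.

These are the printed per-locus diversity statistics (pooled column) and
the per-group-year skew table from the original field study of the
population this package's synthetic generator emulates.  They serve as
fixed inputs for reproduction checks of the reporting arithmetic —
column means and SDs, the F_IS identity, the sex-ratio/skew correlation
— not as outputs of this package.
"""

from __future__ import annotations

import pandas as pd

#: Pooled per-locus marker statistics: allele count, observed and
#: expected heterozygosity, polymorphic information content, inbreeding
#: coefficient (one row per microsatellite locus).
TANGKOKO_DIVERSITY = pd.DataFrame(
    [
        ("D1S548", 6, 0.784, 0.736, 0.697, -0.065),
        ("D3S1768", 7, 0.851, 0.781, 0.744, -0.089),
        ("D5S1457", 6, 0.727, 0.649, 0.589, -0.121),
        ("D6S493", 5, 0.688, 0.643, 0.579, -0.070),
        ("D6S501", 5, 0.727, 0.682, 0.614, -0.067),
        ("D7S2204", 6, 0.805, 0.724, 0.674, -0.112),
        ("D10S1432", 4, 0.710, 0.613, 0.538, -0.159),
        ("D11S925", 9, 0.792, 0.748, 0.725, -0.059),
        ("D12S67", 9, 0.856, 0.818, 0.790, -0.047),
        ("D13S765", 7, 0.795, 0.727, 0.693, -0.095),
        ("D14S255", 3, 0.665, 0.651, 0.575, -0.021),
        ("D18S536", 6, 0.787, 0.723, 0.672, -0.089),
    ],
    columns=["locus", "k", "Ho", "He", "PIC", "FIS"],
).set_index("locus")

#: Annual reproductive-skew records per group-year: number of potential
#: sires (males with residency days), observed sires, adult females,
#: determined paternities, alpha male's share of those paternities (%),
#: the modal alpha's tenure share of the year (%), the observed Nonacs B
#: with its null p-value and 95% CI.
TANGKOKO_SKEW = pd.DataFrame(
    [
        ("R1", 2007, 15, 4, 20, 9, 55.56, 73.15, 0.179, 0.001, 0.033, 0.455),
        ("R1", 2008, 20, 2, 21, 3, 33.33, 73.42, 0.139, 0.165, -0.303, 0.562),
        ("R1", 2009, 21, 5, 25, 7, 28.57, 97.26, 0.021, 0.250, -0.133, 0.289),
        ("R2", 2007, 14, 3, 18, 9, 77.78, 18.38, 0.527, 0.000, 0.192, 0.865),
        ("R2", 2008, 7, 1, 19, 7, 100.00, 100.00, 0.672, 0.000, 0.214, 0.672),
        ("R2", 2009, 10, 1, 20, 9, 100.00, 100.00, 0.621, 0.000, 0.251, 0.621),
        ("PB", 2009, 16, 3, 17, 7, 57.14, 31.51, 0.153, 0.016, 0.016, 0.506),
    ],
    columns=[
        "group", "year", "potential_sires", "sires_observed", "adult_females",
        "K", "alpha_paternity_pct", "alpha_tenure_pct", "B", "p_value",
        "ci_low", "ci_high",
    ],
)

#: Inter-laboratory concordance check: alleles compared and mismatching
#: between the two labs that typed the same five individuals.
TANGKOKO_CONCORDANCE = {"n_alleles_compared": 118, "n_mismatches": 2}
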