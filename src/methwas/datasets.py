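"""Bundled summary datasets.

``replication_summary`` returns the published-style per-MVP summary
statistics of the bisulfite-amplicon replication cohort (171 cases, 177
controls): group mean methylation with its standard error at each tested
MVP, the discovery-cohort methylation difference and adjusted p-value.
These summaries are inputs for the summary-mode Welch comparison and the
worked examples; "±" values are standard errors of the mean.
"""

from __future__ import annotations

import pandas as pd

REPLICATION_N_CASE = 171
REPLICATION_N_CONTROL = 177

_ROWS = [
    # site, probe, coordinate, discovery diff, discovery adj p,
    # case mean, case sem, control mean, control sem, printed diff, printed p
    ("FAT1", "cg00405769", "chr4:187539852", -0.075, 4.66e-09, 0.9244, 0.002172, 0.9331, 0.0007216, -0.00871, 0.0002),
    ("MYC", "cg00611675", "chr8:128748464", -0.02626, 1.52e-09, 0.003672, 0.0003027, 0.009375, 0.0008236, -0.0057, 0.0001),
    ("WHSC1", "cg03150409", "chr4:1892317", 0.07564, 1.02e-08, 0.3055, 0.009068, 0.3302, 0.008440, -0.02473, 0.04),
    ("PVRL1", "cg06391300", "chr11:119600292", -0.0419, 3.01e-13, 0.001697, 0.0001290, 0.001795, 0.0001241, -0.0001, 0.58),
    ("chr17", "cg09319020", "chr17:7304467", -0.11844, 2.05e-09, 0.8406, 0.001630, 0.8428, 0.0007958, -0.00216, 0.23),
    ("C11orf58", "cg10633981", "chr11:16779768", 0.12801, 1.85e-16, 0.8587, 0.005899, 0.8683, 0.007230, -0.00963, 0.3),
    ("FGF8", "cg11706469", "chr10:103535362", -0.04486, 6.4e-08, 0.007407, 0.0002551, 0.007412, 0.0002048, -0.00001, 0.98),
    ("WNT2B", "cg11806528", "chr1:113051977", 0.0321, 4.58e-08, 0.005564, 0.0001993, 0.005658, 0.0003072, -0.00009, 0.79),
    ("WNT7A", "cg13602813", "chr3:13920840", -0.03251, 9.88e-08, 0.01223, 0.0004003, 0.01312, 0.0004133, -0.00088, 0.12),
    ("chr1", "cg15897635", "chr1:220697615", 0.10364, 1.82e-14, 0.7349, 0.003714, 0.7450, 0.003034, -0.0101, 0.03),
    ("FGFR1", "cg20913106", "chr8:38324522", 0.0243, 2.95e-12, 0.004360, 0.0002625, 0.004482, 0.0002628, -0.00012, 0.74),
]


def replication_summary() -> pd.DataFrame:
    """Per-MVP replication-cohort summaries (case/control mean ± SEM).

    ``printed_p`` for MYC is an upper bound (reported as < 0.0001).
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "site",
            "probe_id",
            "coordinate",
            "discovery_diff",
            "discovery_p_adj",
            "mean_case",
            "sem_case",
            "mean_control",
            "sem_control",
            "printed_diff",
            "printed_p",
        ],
    )
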