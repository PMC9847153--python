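"""Bundled benchmark cohort: a published screen of 28 Indonesian cassava
cultivars assessed for PPD with the longitudinal-cut protocol.

The table carries, per cultivar, the reported mean +/- SD grayscale PPD
score at the four assessment timepoints (baseline 0-or-1, 2, 4 and 7 days
post-harvest), the contamination percentage at 7 dph, the reported average
PPD score, and the k-means cluster (1-7) and shelf-life status the cohort
was assigned.  It is shipped for validation and worked examples: the
pipeline's aggregation, averaging and status-calling can be re-run against
the reported columns.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

_REFERENCE_CSV = """\
cultivar,mean_0dph,sd_0dph,mean_2dph,sd_2dph,mean_4dph,sd_4dph,mean_7dph,sd_7dph,contamination_pct_7dph,average_ppd_score,status,cluster
Manggu,0.15,0.02,0.15,0.06,0.18,0.06,0.21,0.07,11,0.17,delayed,1
MentegaII,0.13,0.02,0.16,0.03,0.21,0.08,0.22,0.07,0,0.18,delayed,1
Kristal Merah,0.14,0.01,0.18,0.09,0.25,0.10,0.27,0.13,0,0.21,delayed,1
Valenca,0.12,0.02,0.21,0.10,0.28,0.09,0.24,0.06,0,0.21,delayed,1
Baros Kencana,0.20,0.02,0.23,0.06,0.23,0.02,0.22,0.04,0,0.22,delayed,2
Gebang,0.19,0.03,0.21,0.06,0.24,0.03,0.28,0.05,0,0.23,delayed,2
AdiraIV,0.18,0.01,0.20,0.02,0.27,0.12,0.28,0.06,0,0.23,delayed,2
Apuy,0.18,0.02,0.22,0.02,0.29,0.08,0.27,0.07,0,0.24,delayed,2
Roti,0.17,0.01,0.18,0.01,0.33,0.15,0.28,0.09,0,0.24,delayed,2
Darul Hidayah,0.19,0.03,0.26,0.09,0.28,0.04,0.31,0.07,17,0.26,delayed,2
Lokal Nguneng,0.13,0.02,0.24,0.19,0.33,0.08,0.18,0.05,50,0.22,intermediate,3
Randu,0.11,0.01,0.20,0.10,0.35,0.15,0.30,0.14,33,0.24,intermediate,3
Lelen,0.14,0.02,0.26,0.10,0.41,0.13,0.20,0.11,50,0.25,intermediate,3
Menti,0.16,0.01,0.16,0.02,0.37,0.11,0.33,0.11,17,0.26,intermediate,4
Ubi Kuning,0.15,0.02,0.21,0.07,0.34,0.08,0.34,0.12,0,0.26,intermediate,4
AdiraI,0.13,0.03,0.14,0.01,0.28,0.15,0.50,0.17,0,0.26,intermediate,4
Malang II,0.12,0.00,0.25,0.12,0.32,0.09,0.40,0.09,40,0.27,intermediate,4
Rengganis,0.14,0.02,0.27,0.13,0.36,0.21,0.42,0.11,20,0.30,early,5
Kristal Putih,0.14,0.01,0.34,0.04,0.38,0.16,0.40,0.17,0,0.32,early,5
Gempol,0.17,0.01,0.33,0.11,0.41,0.13,0.36,0.10,0,0.32,early,5
Malang VI,0.17,0.01,0.40,0.12,0.40,0.10,0.37,0.06,33,0.34,early,5
Sentul,0.17,0.03,0.33,0.10,0.47,0.14,0.39,0.10,33,0.34,early,5
MentegaI,0.14,0.02,0.24,0.09,0.44,0.12,0.32,0.19,0,0.29,early,6
Baturaja,0.16,0.05,0.24,0.13,0.40,0.07,0.40,0.11,10,0.30,early,6
BIC302,0.14,0.01,0.27,0.13,0.46,0.06,0.46,0.06,0,0.33,early,7
Tali,0.15,0.02,0.30,0.07,0.52,0.11,0.50,0.09,33,0.37,early,7
Ubi Putih,0.15,0.01,0.40,0.07,0.49,0.07,0.45,0.13,0,0.37,early,7
Vandemir,0.14,0.01,0.47,0.11,0.49,0.14,0.55,0.05,11,0.41,early,7
"""


def load_reference_cohort() -> pd.DataFrame:
    """Return the 28-cultivar benchmark summary table as a DataFrame."""
    return pd.read_csv(StringIO(_REFERENCE_CSV))
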