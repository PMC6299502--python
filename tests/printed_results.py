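"""Published sensitivity-analysis results of the Enhanced Quit & Win trial.

Frozen expected values the grids must reproduce from the packaged
aggregated counts alone.  Each row carries, for both factorial contrasts
(counseling vs no counseling; multiple vs single contests): exposed and
control abstinence rates in percent (1 decimal), the odds ratio for
abstinence (2 decimals) and the chi-square p-value (3 decimals).

``INF`` marks the missing = smoking limit; ``"CC"`` the complete-case row.
"""

import math

INF = math.inf

# (or1, couns_exp%, couns_ctl%, couns_or, couns_p, cont_exp%, cont_ctl%, cont_or, cont_p)
SELF_REPORT_GRID_PUBLISHED = [
    ("CC", 29.7, 24.4, 1.31, 0.058, 28.4, 25.4, 1.16, 0.291),
    (1, 29.8, 24.4, 1.31, 0.034, 28.6, 25.4, 1.18, 0.212),
    (2, 27.0, 22.7, 1.26, 0.086, 26.2, 23.4, 1.16, 0.251),
    (3, 25.8, 22.0, 1.23, 0.125, 25.2, 22.5, 1.16, 0.275),
    (4, 25.1, 21.7, 1.21, 0.154, 24.7, 22.1, 1.15, 0.290),
    (5, 24.7, 21.5, 1.20, 0.175, 24.3, 21.8, 1.15, 0.301),
    (INF, 22.9, 20.5, 1.15, 0.303, 22.8, 20.6, 1.14, 0.359),
]

# (or1, or2, couns_exp%, couns_ctl%, couns_or, couns_p,
#            cont_exp%, cont_ctl%, cont_or, cont_p), lambda = eta = 1
VERIFIED_GRID_PUBLISHED = [
    (1, 1, 25.8, 20.9, 1.31, 0.046, 24.8, 21.8, 1.18, 0.212),
    (1, 2, 24.8, 20.1, 1.32, 0.046, 23.9, 20.9, 1.19, 0.204),
    (1, 3, 24.1, 19.4, 1.32, 0.047, 23.3, 20.2, 1.20, 0.200),
    (1, 4, 23.6, 18.9, 1.32, 0.047, 22.7, 19.7, 1.20, 0.197),
    (1, 5, 23.1, 18.5, 1.32, 0.047, 22.2, 19.2, 1.20, 0.195),
    (1, INF, 18.1, 14.1, 1.35, 0.058, 17.4, 14.8, 1.22, 0.209),
    (2, 1, 23.3, 19.5, 1.26, 0.102, 22.7, 20.0, 1.18, 0.249),
    (2, 2, 22.5, 18.7, 1.26, 0.101, 21.9, 19.2, 1.18, 0.241),
    (2, 3, 21.9, 18.1, 1.27, 0.100, 21.3, 18.6, 1.19, 0.236),
    (2, 4, 21.3, 17.6, 1.27, 0.100, 20.8, 18.1, 1.19, 0.233),
    (2, 5, 20.9, 17.2, 1.27, 0.100, 20.4, 17.7, 1.19, 0.231),
    (2, INF, 16.4, 13.1, 1.30, 0.109, 15.9, 13.6, 1.21, 0.244),
    (3, 1, 22.3, 18.9, 1.23, 0.143, 21.9, 19.3, 1.17, 0.272),
    (3, 2, 21.5, 18.2, 1.24, 0.140, 21.1, 18.5, 1.17, 0.264),
    (3, 3, 20.9, 17.6, 1.24, 0.139, 20.5, 17.9, 1.18, 0.258),
    (3, 4, 20.4, 17.1, 1.24, 0.137, 20.0, 17.4, 1.18, 0.255),
    (3, 5, 20.0, 16.7, 1.25, 0.137, 19.6, 17.0, 1.19, 0.253),
    (3, INF, 15.7, 12.8, 1.27, 0.143, 15.3, 13.1, 1.20, 0.264),
    (4, 1, 21.8, 18.6, 1.22, 0.171, 21.4, 18.9, 1.16, 0.287),
    (4, 2, 21.0, 17.9, 1.22, 0.168, 20.6, 18.2, 1.17, 0.278),
    (4, 3, 20.4, 17.3, 1.23, 0.165, 20.0, 17.6, 1.17, 0.272),
    (4, 4, 19.9, 16.8, 1.23, 0.164, 19.6, 17.1, 1.18, 0.269),
    (4, 5, 19.5, 16.4, 1.23, 0.163, 19.2, 16.7, 1.18, 0.266),
    (4, INF, 15.3, 12.6, 1.26, 0.166, 15.0, 12.8, 1.20, 0.277),
    (5, 1, 21.4, 18.4, 1.21, 0.192, 21.1, 18.7, 1.16, 0.297),
    (5, 2, 20.7, 17.7, 1.21, 0.188, 20.3, 17.9, 1.17, 0.288),
    (5, 3, 20.1, 17.1, 1.22, 0.185, 19.8, 17.4, 1.17, 0.282),
    (5, 4, 19.6, 16.6, 1.22, 0.183, 19.3, 16.9, 1.18, 0.279),
    (5, 5, 19.2, 16.3, 1.22, 0.181, 18.9, 16.5, 1.18, 0.276),
    (5, INF, 15.1, 12.4, 1.25, 0.183, 14.8, 12.7, 1.20, 0.285),
    (INF, 1, 19.8, 17.6, 1.16, 0.315, 19.7, 17.7, 1.15, 0.352),
    (INF, 2, 19.1, 16.9, 1.17, 0.306, 19.0, 16.9, 1.15, 0.342),
    (INF, 3, 18.6, 16.3, 1.17, 0.300, 18.5, 16.4, 1.16, 0.335),
    (INF, 4, 18.1, 15.9, 1.17, 0.295, 18.0, 15.9, 1.16, 0.331),
    (INF, 5, 17.8, 15.5, 1.18, 0.292, 17.7, 15.6, 1.16, 0.328),
    (INF, INF, 14.0, 11.9, 1.20, 0.278, 13.8, 12.0, 1.18, 0.333),
]
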