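"""Full sensitivity analysis of the packaged Enhanced Quit & Win counts.

Sweeps the assumed survey-missingness odds ratio OR1 (self-report
outcome) and the OR1 x OR2 grid (urine-verified outcome, with
lambda = eta = 1) and prints the two tables.  Each cell shows the pooled
abstinence rates of the exposed and control arms, the odds ratio for
abstinence, and the chi-square p-value.  OR = 1 is the MAR /
complete-case-equivalent analysis; OR = inf treats every missing outcome
as a failure (missing = smoking).
"""

from cessmiss import enhanced_quit_win_fixture, run_self_report_grid, run_verified_grid

trial = enhanced_quit_win_fixture()

print("Self-report abstinence (rows: assumed OR1; CC = complete case)\n")
print(run_self_report_grid(trial).render())

print("\nUrine-verified abstinence (rows: OR1 x OR2, lambda = eta = 1)\n")
print(run_verified_grid(trial, include_complete_case=False).render())

print(
    "\nReading the counseling columns: the effect is significant only when "
    "both missingness odds ratios are small - the conclusion is sensitive "
    "to the assumed missing-data mechanism."
)
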