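"""Anatomy of the two-stage imputation on one treatment arm.

Walks arm Tx1 of the Enhanced Quit & Win trial (306 randomized, 65
self-reported abstinent, 47 survey non-respondents; 38 urine-verified
abstinent, 21 urine-missing) through both stages under a chosen scenario
and prints every imputed quantity.
"""

from cessmiss import SensitivityParams, enhanced_quit_win_fixture, impute_arm

arm = enhanced_quit_win_fixture().arm("Tx1")
params = SensitivityParams(or1=2.0, or2=2.0, lam=1.0, eta=1.0)
ia = impute_arm(arm, params)
s1, s2 = ia.stage1, ia.stage2

print(f"Arm {arm.arm_label}: n={arm.n_total}, observed self-report "
      f"{arm.sr_abstinent}/{arm.sr_failure}, survey missing {arm.survey_missing}")
print(f"Stage 1 (OR1={params.or1:g}): pi={s1.pi:.4f} -> "
      f"n21={s1.n21:.3f} imputed abstinent, n22={s1.n22:.3f} imputed failures")
print(f"  self-report abstinent total n.1 = {s1.sr_abstinent_total:.3f}")
print(f"Stage 2 (lambda={params.lam:g}): u_imp={s2.u_imp:.3f} would-be urine "
      f"samples, v_imp={s2.v_imp:.3f} would-be missing")
print(f"  (eta={params.eta:g}): f11_imp={s2.f11_imp:.3f}, f12_imp={s2.f12_imp:.3f}")
print(f"  (OR2={params.or2:g}): pi'={s2.pi_prime:.4f} over v={s2.v_total:.3f} -> "
      f"f21={s2.f21:.3f}, f22={s2.f22:.3f}")
print(f"Verified abstinent total = f11. + f21 = {s2.f11_dot:.3f} + {s2.f21:.3f} "
      f"= {s2.verified_abstinent_total:.3f} of {arm.n_total}")
print("\nEvery allocation preserves its pool: n21+n22 = survey missing, "
      "u_imp+v_imp = n21, f21+f22 = total missing urine.")
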