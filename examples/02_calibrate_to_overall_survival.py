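"""Calibrate per-cycle death probabilities to an overall-survival target.

Progression probabilities come straight from the PFS curve; death
probabilities are back-solved so modeled OS (progression-free + progressive
disease) matches the target at every cycle it structurally can.
"""
import nsclc_cea as m

pfs = m.WeibullSurvival(1.25, 30.0)
os_curve = m.WeibullSurvival(1.15, 85.0)
cycles, dt = 100, 6.0

p_prog = m.pfs_to_progression_probs(pfs, cycles, dt)
schedule = m.calibrate_death_probs(p_prog, os_curve, cycles, dt)
report = m.validate_calibration(schedule, os_curve, dt)

print(f"cycles calibrated:        {schedule.n_cycles}")
print(f"deferred early cycles:    {len(schedule.deferred_cycles)}")
print(f"max |OS dev| (all):       {report.max_abs_deviation:.3e}")
print(f"max |OS dev| (unclamped): {report.unclamped_max_abs_deviation:.3e}")
# The overall maximum sits at the first cycle: the target OS drops before
# anyone has progressed, and deaths require prior progression, so that drop
# is deferred one cycle.  Everywhere else the match is exact to machine
# precision.
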