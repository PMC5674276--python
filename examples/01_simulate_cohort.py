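"""Simulate a small bargaining cohort and look at one buyer's record.

Builds three buyers (one per strategy group), prints their bargaining
behavior summary and the shape of their ROI series.
"""

from gcsdn import (
    CohortDesign,
    GroupDesign,
    behavioral_profile,
    default_cohort_design,
    simulate_cohort,
    write_subject,
)

design = default_cohort_design()
small = CohortDesign(groups=tuple(
    GroupDesign(g.spec, g.net, 1, g.scan_params) for g in design.groups
))
cohort = simulate_cohort(small, seed=42)

for s in cohort:
    prof = behavioral_profile(s.trials, last_n=30, subject_id=s.subject_id)
    print(f"{s.subject_id} ({s.group_truth:>14s}): "
          f"{s.n_scans} scans x {len(s.regions)} ROIs, "
          f"IR = {prof.ir:+.2f}, R^2 = {prof.r2:.2f}")
    # IR is the slope of suggested price on private value over the last 30
    # trials: near 1 for truth-anchoring incrementalists, near 0 for
    # uninformative conservatives, negative for deceptive strategists.

paths = write_subject(cohort[-1], "scratch/example_subject")
print("wrote", *[p.name for p in paths.values()])
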