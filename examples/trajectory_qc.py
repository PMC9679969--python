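"""Admission filtering of production runs.

Only trajectories whose ligand stays bound in every frame — and whose
partially bound ligand never self-stacks into a hairpin — enter the
binding-mode statistics.
"""

import ligmodes as lm

runs, truth = lm.make_qc_ensemble(n_runs=20, n_bound=8, frames=60, seed=0)
reports = [lm.qc_trajectory(t, ["PTE"]) for t in runs]
admitted = [r.admitted for r in reports]
print(f"admitted {sum(admitted)} of {len(runs)} runs (planted bound: {sum(truth)})")
print(f"planted flags recovered exactly: {admitted == truth}")

hairpin = lm.make_self_stacking_trajectory(n_contact_residues=1)
report = lm.qc_trajectory(hairpin, ["PTE"])
print(
    f"hairpin pose touching 1 residue: self-stacking frames {report.self_stacking_frames}, "
    f"admitted = {report.admitted}"
)
print()
print("A ligand that leaves the pocket, or collapses onto itself while")
print("barely bound, would contaminate contact statistics; such runs are")
print("rejected whole.")
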