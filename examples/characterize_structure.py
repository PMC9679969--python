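"""Characterize a crystal structure: disulfides, catalytic triad, ion sites
and inter-chain RMSD.

Runs on the generated synthetic stand-in for a three-chain asymmetric unit
(use `ligmodes.read_structure` on any PDB file for real data).
"""

import numpy as np

import ligmodes as lm

structure = lm.make_synthetic_asymmetric_unit(seed=0)
report = lm.structure_report(structure)

print(f"protein chains: {report['protein_chains']}")
print("disulfide bonds (chain, residues, S-S distance):")
for d in report["disulfides"]:
    if d["chain_a"] == "A":
        print(f"  {d['chain_a']} {d['resseq_a']:>3d}-{d['resseq_b']:<3d} {d['ss_distance']:.2f} A")
triad = report["catalytic_triads"]["A"]
print(
    f"catalytic triad chain A: Ser{triad['ser']} His{triad['his']} Asp{triad['asp']}"
    f"  (Og-Ne2 {triad['d_ser_his']:.2f} A, Nd1-Od {triad['d_his_asp']:.2f} A)"
)
for site in report["ion_sites"][:2]:
    partners = sorted({c["resseq"] for c in site["coordinating_atoms"]})
    print(
        f"{site['element']}+ site: carbonyl O of residues {partners}, "
        f"{site['water_count']} waters -> coordination number {site['coordination_number']}"
    )
rmsd = np.array(report["chain_rmsd"]["matrix"])
print(f"pairwise chain RMSD (A): {sorted(round(float(v), 3) for v in rmsd[np.triu_indices(3, 1)])}")
print()
print("Three near-identical chains, three disulfides each, a Ser-His-Asp")
print("triad in hydrogen-bond geometry and octahedral Na+ sites: the")
print("structural signature this package extracts from a PETase crystal.")
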