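"""Elastic-network normal-mode flexibility profiling.

Builds a hinged two-helix hairpin (a structure with one obvious soft
degree of freedom), computes the anisotropic-network normal modes with the
standard 10 A cutoff, and reports the per-residue fluctuation profile of the
low-frequency internal modes 7-11, the most flexible residue window, and the
contact-map deviation between conformers displaced along mode 7.
"""

import numpy as np

from xlassist import enm, synth
from xlassist.structmap import structure_to_pdb

model = synth.make_structure(40, "hairpin", seed=2)
params = enm.ENMParameters(cutoff=10.0, n_modes=15)
modes = enm.compute_modes(model, params)

print(f"nodes: {modes.n_nodes}, near-zero (rigid-body) modes: {modes.n_near_zero}")
print(f"first internal eigenvalues (modes 7-11): "
      f"{np.array2string(modes.eigenvalues[6:11], precision=4)}")

profile = enm.mode_fluctuations(modes, list(range(7, 12)),
                                residue_numbers=model.residue_numbers())
interval, peaks = enm.flexible_region(profile, window=7)
print(f"most flexible window: residues {interval[0]}-{interval[1]}, "
      f"peak at residue {peaks}")

plus, minus = enm.displaced_conformers(model, modes, mode_number=7, amplitude=3.0)
dev = enm.contact_deviation(plus, minus)
rowsum = dev.sum(axis=1)
print(f"largest contact-deviation row sums at residues "
      f"{np.argsort(rowsum)[-3:][::-1] + 1}")
trajectory = structure_to_pdb([minus, model, plus])
print(f"mode-7 trajectory: {trajectory.count('MODEL')} PDB models, "
      "ready for animation in any viewer")
print("Free helix ends swing the most in the softest modes; the same residues")
print("dominate both the fluctuation profile and the contact-change map.")
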