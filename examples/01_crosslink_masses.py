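"""Monoisotopic mass arithmetic for crosslinked peptides.

Builds two tryptic peptides of the DNAJB6 N-terminal domain, bridges them
with BS3, and prints the neutral masses, the m/z a 4+ precursor would show,
and the mass shifts produced by 15N metabolic labelling.  The 15N shift is
exactly 0.997035 Da per nitrogen atom, which is what makes hybrid
(14N-peptide x 15N-peptide) crosslinks recognizable in a mixed-isotope
experiment.
"""

from xlassist.chem import (
    BS3,
    CrosslinkedPair,
    PeptideSpec,
    mass_to_mz,
    pair_mass,
    peptide_mass,
    peptide_nitrogens,
)

# HASPEDIKKAYR = DNAJB6 residues 13-24, KLALK = residues 25-29
a = PeptideSpec("HASPEDIKKAYR", "DNAJB6", start=13)
b = PeptideSpec("KLALK", "DNAJB6", start=25)
pair = CrosslinkedPair(a, b, link_pos_a=20, link_pos_b=25, linker=BS3)

print(f"peptide A {a.sequence}: {peptide_mass(a):.4f} Da, {peptide_nitrogens(a)} N")
print(f"peptide B {b.sequence}: {peptide_mass(b):.4f} Da, {peptide_nitrogens(b)} N")
print(f"BS3 bridge adds {BS3.bridge_mass:.5f} Da (spans up to {BS3.span:g} A)")
print(f"crosslinked pair K20xK25: {pair_mass(pair):.4f} Da")
print(f"  as 4+ precursor: m/z {mass_to_mz(pair_mass(pair), 4):.4f}")

hybrid = CrosslinkedPair(a, b.with_label("15N"), 20, 25, BS3)
full15 = CrosslinkedPair(a.with_label("15N"), b.with_label("15N"), 20, 25, BS3)
print(f"hybrid 14N/15N pair: +{pair_mass(hybrid) - pair_mass(pair):.4f} Da "
      f"(= {peptide_nitrogens(b)} N x 0.997035)")
print(f"fully 15N pair:      +{pair_mass(full15) - pair_mass(pair):.4f} Da")
print("The four isotope states are resolvable at 10 ppm, so a search can tell")
print("which subunit pool each peptide of a crosslink came from.")
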