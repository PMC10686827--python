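"""Tessellate an asymmetric unit into exactly symmetric assemblies.

The symmetry conditioner replicates a subunit through every element of a
point group (Cn, Dn, T, O, I) and projects onto the G-invariant subspace, so
the assembled complex is symmetric to machine precision.  An icosahedral
tessellation of a 1,000-residue unit gives a capsid-scale complex.
"""

from bbdiff import (make_symmetry_group, make_synthetic_set,
                    symmetry_deviation, tessellate, write_pdb)

au_small = make_synthetic_set(1, (50, 50), seed=0)[0]
for name in ("C4", "D3", "O"):
    group = make_symmetry_group(name)
    complex_ = tessellate(au_small, group)
    print(f"{name:3s}: {group.order:3d} subunits, {complex_.n_residues:6d} "
          f"residues, max symmetry deviation "
          f"{symmetry_deviation(complex_, group):.2e} Å")

au_big = make_synthetic_set(1, (1000, 1000), seed=1)[0]
ico = tessellate(au_big, make_symmetry_group("I"))
n_atoms = ico.coords.shape[0] * ico.coords.shape[1]
print(f"I  :  60 subunits, {ico.n_residues} residues, {n_atoms} backbone atoms")
write_pdb(ico, "icosahedral_complex.pdb")

print("\nEvery complex is exactly invariant under its group (deviations at")
print("float rounding), and the icosahedral assembly reaches 60,000 residues")
print("and 240,000 backbone atoms; written to icosahedral_complex.pdb.")
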