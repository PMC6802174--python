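"""Build the coarse-grained models and derive the binding cutoff.

Spermidine (SPD) and norspermidine (NSPD) are rigid rods of 0.39 nm
beads with +1 charges on the ammonium beads; DNA is ten pairs of −1
phosphate spheres on a 1 nm cylinder.  The ammonium-phosphate contact
distance follows from ionic radii and the N-H···O hydrogen-bond length
via the law of cosines; the 105° value is used as the binding cutoff.
"""

import polyamine_dna as pdna

for species in ("SPD", "NSPD"):
    pa = pdna.build_polyamine(species)
    print(
        f"{species}: {pa.n_beads} beads, ammoniums at {pa.charged_indices}, "
        f"rod length {pa.rod_length:.2f} nm, total charge +{pa.total_charge:.0f}"
    )

dna = pdna.build_dna()
print(
    f"DNA: {dna.n_phosphates} phosphates (charge {dna.total_charge:.0f}) on a "
    f"{dna.R_DNA} nm cylinder, axial span {dna.axial_span:.1f} nm"
)

print("\nN-to-P contact distance vs hydrogen-bond angle:")
for angle in (90, 105, 180):
    d = pdna.hbond_contact_distance(angle)
    note = "  <- binding cutoff" if angle == 105 else ""
    print(f"  {angle:3d} deg : {d:.3f} nm{note}")

pdna.write_xyz("model_SPD.xyz", pdna.build_polyamine("SPD"), dna,
               comment="SPD rod (body frame) + DNA phosphate ladder")
print("\nwrote model_SPD.xyz (N = ammonium, C = methylene, P = phosphate)")
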