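"""Estimate scaled assembly parameters for real capsids from AFM mechanics.

For each virus: 2-D Young's modulus Y = E h, capsomer diameter from the
T number, scaled line tension lam = Lambda/(Y R) with a 10 kT contact
energy, and FvK number gamma = 12(1 - nu_p^2)(R/h)^2.  A large gamma
(bacteriophage lambda's mature capsid) means the shell cannot
self-assemble directly as a sphere and needs a soft procapsid first.
"""

from capshell import CapsidDescriptor, capsid_descriptor_to_scaled

CAPSIDS = [
    ("CCMV", CapsidDescriptor(T_number=3, diameter=28, h=3.8, E=0.14)),
    ("lambda procapsid", CapsidDescriptor(T_number=7, diameter=50, h=4.0, E=0.16)),
    ("lambda capsid", CapsidDescriptor(T_number=7, diameter=63, h=1.8, E=1.0)),
    ("SV40", CapsidDescriptor(T_number=7, diameter=45, h=6.0, E=0.033)),
]

print(f"{'virus':18s} {'Y (N/m)':>8s} {'sigma (nm)':>10s} "
      f"{'lam':>10s} {'gamma':>6s}")
for name, cd in CAPSIDS:
    est = capsid_descriptor_to_scaled(cd)
    print(f"{name:18s} {est['Y']:8.2f} {est['sigma']:10.1f} "
          f"{est['lam']:10.6f} {est['gamma']:6.0f}")

print("\ngamma above ~250 puts a capsid outside the self-assembly window "
      "for spheres: only belts and cylinders are stable end states.")
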