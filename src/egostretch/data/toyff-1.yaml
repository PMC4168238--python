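# Toy molecular-mechanics defaults, version 1.
#
# Energies in Hartree, lengths in Å, angles in degrees.  The ring-torsion
# profile is a two-term cosine series whose three-fold term creates the
# staggered (chair-like) wells and whose one-fold term penalises eclipsed
# arrangements, so that ring inversion proceeds through the twist-boat
# band rather than a planar transit.
version: 1
toy_ff:
  bond_k:            # Hartree / Å^2, by element pair (order 2 -> "=")
    C-C: 1.00
    C-O: 1.10
    C=O: 1.90
    C-H: 0.75
    H-O: 1.10
  bond_r0:           # Å
    C-C: 1.52
    C-O: 1.43
    C=O: 1.21
    C-H: 1.10
    H-O: 0.97
  angle_k: 0.30      # Hartree / rad^2
  theta0:            # degrees, by centre element + coordination number
    C4: 109.47122
    C3: 120.0
    C2: 109.47122
    O2: 109.47122
  torsion_k: 0.0015  # Hartree, generic three-fold barrier term
  ring_torsion:      # Hartree, endocyclic profile c3*(1+cos 3t) + c1*(1+cos t)
    c3: 0.002
    c1: 0.001
  nonbonded:
    epsilon: 0.01    # Hartree
    sigma: 2.5       # Å, soft-repulsion onset
    min_path: 4      # pairs >= this many bonds apart interact
builder:
  ring_amplitude_chair: 0.57
  ring_amplitude_equator: 0.75
  glycosidic_phi: 20.0
  glycosidic_psi: -20.0
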