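"""Secondary structure and solvent exposure for an ideal helix.

An ideal poly-Ala alpha helix (phi = -57, psi = -47) is built, its
Kabsch-Sander secondary structure assigned, and each residue's
solvent-accessible surface area converted to relative accessibility
(SASA over the residue type's theoretical maximum) and classified as
buried (< 9%), intermediate (9-36%) or exposed (> 36%).
"""

from thermofold import compute_environment, parse_structure
from thermofold.synthetic import make_ideal_helix

structure = parse_structure(make_ideal_helix(12), structure_id="helix12")
envs = compute_environment(structure, n_points=960)

print("res  ss8  ss3     sasa(A^2)  rel_acc  class")
for e in envs:
    chain, seq_id, aa = e.residue
    print(f"{aa}{seq_id:<4} {e.ss8!r:>4} {e.ss3:<7} {e.sasa:8.1f}  "
          f"{e.rel_acc:7.3f}  {e.acc_class}")
helix_frac = sum(e.ss3 == "helix" for e in envs) / len(envs)
print(f"\nhelix fraction: {helix_frac:.2f} "
      "(interior residues are 'H'; chain ends lack the hydrogen-bond pattern)")
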