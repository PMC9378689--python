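"""Measure the swivel angle between two elongation-complex models.

Builds a synthetic two-module RNAP stand-in with a known 2.5-degree
swivel applied about a bridge-helix-parallel axis, writes it to PDB,
reads it back, and measures the rotation the way the real structures
are compared: core-module alignment, then the residual rotation of the
swivel module.
"""

import tempfile
from pathlib import Path

import putec

fixture = putec.make_two_module_model(angle=2.5, noise_sigma=0.1, seed=7)
with tempfile.TemporaryDirectory() as td:
    paths = putec.write_fixture(fixture, Path(td))
    reference = putec.read_structure(paths["reference"])
    target = putec.read_structure(paths["target"])

report = putec.swivel_angle(reference, target, fixture.domain_set)

print(f"applied swivel angle : {fixture.true_angle:.3f} deg")
print(f"measured swivel angle: {report.angle_deg:.3f} deg")
print(f"axis vs bridge helix : {report.bridge_helix_axis_angle:.2f} deg")
for dom, rmsd in sorted(report.per_domain_rmsd.items()):
    print(f"  {dom:<16s} Calpha RMSD after core alignment: {rmsd:.3f} A")
print()
print("The measured angle recovers the applied rotation despite 0.1 A of")
print("coordinate noise; the core RMSD stays near zero (it is the alignment")
print("frame) while every swivel-module domain moves coherently.")
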