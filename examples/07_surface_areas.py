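"""Solvent-accessible and polar surface areas by sphere sampling.

Computes SASA with a 1.4 A water probe on deterministic golden-spiral
points, and the polar subset (N, O and their hydrogens) that the PSA
descriptor counts.
"""

from mmkit.fixtures import make_polyala
from mmkit.molsys import read_xyz
from mmkit.structure_tools import place_missing_hydrogens, polar_surface_area, sasa

methane = read_xyz("1\n\nC 0 0 0\n")
place_missing_hydrogens(methane)
print(f"methane: SASA = {sasa(methane).sum():7.2f} A^2, "
      f"PSA = {polar_surface_area(methane):6.2f} A^2 (no polar atoms)")

water = read_xyz("3\n\nO 0 0 0\nH 0.96 0 0\nH -0.24 0.93 0\n")
print(f"water:   SASA = {sasa(water).sum():7.2f} A^2, "
      f"PSA = {polar_surface_area(water):6.2f} A^2 (entirely polar)")

peptide = make_polyala(5)
total = sasa(peptide).sum()
polar = polar_surface_area(peptide)
print(f"penta-alanine: SASA = {total:.1f} A^2, PSA = {polar:.1f} A^2 "
      f"({100 * polar / total:.0f}% polar)")
# PSA is always a subset of the total accessible area; for drug-likeness
# screens it correlates with membrane permeability.
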