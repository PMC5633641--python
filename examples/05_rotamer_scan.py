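"""Scan the rotamer space of two mutated residues and keep the best ten.

A residue in a polyalanine host is mutated to serine and methionine
(3 x 27 = 81 chi combinations); each combination is applied and scored
against the rest of the structure with a statistical pair potential, and
the best combinations are rescored with the force field.
"""

import numpy as np

from mmkit.fixtures import make_polyala, make_toy_paramset
from mmkit.internal_coords import mutate_residue
from mmkit.scoring import DistanceHistogram, pmf_from_histogram, type_by_element
from mmkit.structure_tools import (RotamerScanOptions, enumerate_rotamers,
                                   rotamer_scan)

system = make_polyala(4)
mutate_residue(system, 1, "SER")
mutate_residue(system, 2, "MET")
print(f"SER rotamers: {len(enumerate_rotamers('SER'))}, "
      f"MET rotamers: {len(enumerate_rotamers('MET'))}")

rng = np.random.default_rng(0)
tables = {}
for t1 in sorted(set(type_by_element(system))):
    for t2 in sorted(set(type_by_element(system))):
        if (t2, t1) not in tables:
            hist = DistanceHistogram((t1, t2), np.linspace(0.2, 12.0, 60),
                                     rng.uniform(0.5, 2.0, 59))
            tables[(t1, t2)] = pmf_from_histogram(hist,
                                                  distance_scaled_exponent=1.61)

options = RotamerScanOptions(residues=[1, 2], top_k=10, scorer="dfire",
                             rescore=True)
result = rotamer_scan(system, options, tables=tables,
                      params=make_toy_paramset())

print("\nrank  chi(SER)  chi(MET)            score    rescore")
for rank, (combo, score, rescore) in enumerate(result.ranked, start=1):
    ser = ",".join(f"{c:.0f}" for c in combo[0])
    met = ",".join(f"{c:.0f}" for c in combo[1])
    print(f"{rank:4d}  {ser:>8s}  {met:>18s}  {score:8.3f}  {rescore:9.3f}")
# The primary ranking (ascending statistical score) is fixed before the
# force-field rescore is appended, matching the two-stage scan protocol.
# The tables here are random demonstration potentials, so the two columns
# disagree: enormous rescore values flag rotamers the force field rejects
# as steric clashes even when the (random) statistical score likes them.
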