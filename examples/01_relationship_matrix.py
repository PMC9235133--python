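"""Build the numerator relationship matrix A from a small pedigree.

A holds the expected additive-genetic relationships between animals:
Var(breeding values) = A * sigma2_a.  Offspring of a full-sib mating are
inbred, which shows up as a diagonal entry above 1.
"""

import numpy as np

import microherit as mh

records = mh.sort_pedigree([
    mh.PedigreeRecord("sire", None, None),
    mh.PedigreeRecord("dam", None, None),
    mh.PedigreeRecord("kit1", "sire", "dam"),
    mh.PedigreeRecord("kit2", "sire", "dam"),
    mh.PedigreeRecord("inbred", "kit1", "kit2"),
])
A = mh.build_relationship_matrix(records)

np.set_printoptions(precision=3, suppress=True)
print("animals:", A.animals)
print(A.values)
print("inbreeding coefficients:", A.inbreeding())
# full sibs are related 0.5; the full-sib-mating offspring has F = 0.25,
# so its diagonal entry is 1.25
print("kernel for the observed pair (kit1, inbred):")
print(mh.observation_kernel(A, ["kit1", "inbred"]))
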