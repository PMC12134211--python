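"""Design chromosomal barcodes and a padlock probe.

Draws random 30-mers, filters them on composition (GC 40-60%, no
homopolymer of 4+, G/C at both ends) and mutual Hamming distance > 7,
then builds the padlock hybridisation arms for the first survivor.
"""

from poolscreen.barcodes import (
    DesignParams,
    design_padlock,
    generate_candidates,
    select_barcodes,
)

params = DesignParams(n_candidates=10_000, k=30, seed=0)
candidates = generate_candidates(params)
selected = select_barcodes(candidates, params)
print(f"selected {len(selected)} of {params.n_candidates} random 30-mers")
print("first barcode:", selected[0].seq)

plp = design_padlock(selected[0], scaffold="TCGTCGGCAGCGTC")
print("5' arm:", plp.arm5, "| scaffold:", plp.scaffold, "| 3' arm:", plp.arm3)
print("arms joined reconstruct the reverse complement of the barcode;")
print("the scaffold carries the round-readout and RCA-primer sites.")
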