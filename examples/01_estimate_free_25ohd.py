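"""Estimate free 25(OH)D for one participant with all four equations.

Builds a record at the cohort's central biomarker values and prints the
three regression-based estimates and the binding-equilibrium (Bikle)
estimate. All four should sit near the cohort's central measured free
25(OH)D of ~5.3 pg/mL.
"""

from freevitd import (
    ParticipantRecord,
    estimate_bikle,
    estimate_eq1,
    estimate_eq2,
    estimate_eq3,
    vmr,
)

record = ParticipantRecord(
    albumin=4.3,       # g/dL
    d25_3=20.3,        # 25(OH)D3, ng/mL
    d25_2=0.33,        # 25(OH)D2, ng/mL
    vdbp=253.3,        # vitamin D binding protein, µg/mL
    d1_25_3=40.2,      # 1,25(OH)2D3, pg/mL
    d24_25_3=1.7,      # 24,25(OH)2D3, ng/mL
    ipth=34.0,         # intact PTH, pg/mL
    phenotype="Gc1s/Gc2",  # normalized to Gc2/Gc1s
)

print(f"equation 1 (full panel):        {estimate_eq1(record):6.2f} pg/mL")
print(f"equation 2 (+ Gc diplotype):    {estimate_eq2(record):6.2f} pg/mL")
print(f"equation 3 (clinical panel):    {estimate_eq3(record):6.2f} pg/mL")
print(f"Bikle binding equilibrium:      {estimate_bikle(record):6.2f} pg/mL")
print(f"vitamin D metabolite ratio:     {vmr(record.d24_25_3, record.d25_3):6.2f}")
print()
print("All estimates are the free (non-protein-bound) 25(OH)D fraction;")
print("the VMR (24,25(OH)2D3 / 25(OH)D3 x 100) indexes catabolism.")
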