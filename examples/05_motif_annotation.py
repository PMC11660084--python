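"""Promoter HRPE scanning and N-degron census.

Scans 1000-bp upstream windows for the hypoxia-responsive promoter
element (GCCVCYGGTTTY, both strands) and translates TF coding sequences
to find N-terminal MCGGAI/V degrons — the signature of ERF VII oxygen
sensing. Uses the synthetic stand-ins for the published apple PCO and
ERF VII sequences.
"""

import hypoxnet as hx
from hypoxnet.motifs import HRPE, degron_census, presence_table
from hypoxnet.synthetic_refs import (
    PCO_A_TYPE, PCO_B_TYPE, synthetic_erfvii_cds, synthetic_pco_upstream,
)

upstream = synthetic_pco_upstream(seed=0)
table = presence_table(upstream, HRPE).set_index("seq_id")
print("HRPE presence in PCO promoters (B-type = hypoxia-inducible):")
for gid in PCO_B_TYPE + PCO_A_TYPE:
    kind = "B" if gid in PCO_B_TYPE else "A"
    print(f"  {gid} ({kind}-type): {int(table.loc[gid, 'n_hits'])} hit(s)")

cds = synthetic_erfvii_cds(seed=0)
with_degron = degron_census(cds)
print(f"\nERF VII CDS with an N-terminal MCGGAI/V degron: "
      f"{len(with_degron)}/{len(cds)}")
first = next(iter(cds.values()))
print(f"example N-terminus: {hx.translate_cds(first)[:10]}...")
# B-type promoters all carry the HRPE; A-type none — the expected split
# for hypoxia-inducible vs constitutive plant cysteine oxidases.
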