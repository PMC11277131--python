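"""Simulate a three-species cryptic complex and run the full pipeline.

The default configuration has a high-count species (n=90), a variable-count
sister (n=77-79, same marker-bivalent structure) and a third species
distinguished by structure alone; two species fly together at one site.
Enabling introgression copies the first species' barcode into the second,
reproducing the classic barcode-identity-despite-karyotype-divergence trap —
which the combined analysis resolves and flags.
"""

import tempfile
from pathlib import Path

import karyodelim as kd

for introgression in (False, True):
    pairs = (("sp1", "sp2"),) if introgression else ()
    config = kd.SimulationConfig(seed=42, introgression_pairs=pairs)
    dataset = kd.simulate(config)
    with tempfile.TemporaryDirectory() as td:
        paths = kd.write_dataset(dataset, Path(td))
        result = kd.run_pipeline(paths["karyotypes"], paths["alignment"],
                                 paths["localities"], kd.RunConfig(seed=42))
    label = "with introgression" if introgression else "no introgression"
    print(f"--- {label} ---")
    for v in result.verdicts:
        p = f", p={v.evidence.association_p:.4f}" if v.evidence.sympatric else ""
        flag = " [mitochondrial introgression suspected]" if v.introgression_flag else ""
        print(f"{v.group_a} vs {v.group_b}: {v.decision.value} "
              f"({v.rule_fired}{p}){flag}")
    print()

print("R1 = sympatric stable combinations; R3 = allopatric fixed karyotype "
      "difference.\nUnder introgression the sp1/sp2 pair shares barcodes but "
      "keeps its fixed count gap,\nso it is still called distinct and the "
      "shared barcode is attributed to introgression.")
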