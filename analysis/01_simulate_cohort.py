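#!/usr/bin/env python
"""Generate the synthetic study materials.

Produces the toy sphingolipid network (SBML), the simulated longitudinal
PBMC metabolomics cohort (10 CTRL / 27 P1Ab / 34 PT1D children sampled at
12/24/36 months), the PBMC expression matrix over the network's genes, the
pathway definitions and the planted-effect registry, under
results/data/.
"""

import json
from pathlib import Path

from immunogem import synthetic_data as syn

SEED = 1
OUT = Path("results/data")


def main():
    paths = syn.write_cohort(OUT, seed=SEED)
    registry = json.loads(paths["ground_truth"].read_text())
    print(f"wrote {len(paths)} files to {OUT}/")
    print(f"  planted metabolomics effects: {len(registry['metabolomics'])}")
    print(f"  planted expression effects:   {len(registry['expression'])}"
          f" (glycoceramide-synthase program x2 in PT1D)")
    named = [e for e in registry["metabolomics"]
             if e["feature"].startswith(("Cer(", "HexCer("))]
    for e in named:
        age = "all ages" if e["age"] is None else f"{e['age']} months"
        print(f"  {e['feature']}: {e['log2_effect']:+.1f} log2 in {e['group']} at {age}")


if __name__ == "__main__":
    main()
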