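#!/usr/bin/env python
"""Glycoceramide production flux across the extracted group models.

Optimises the glucosylceramide and digalactosylceramide objectives in each
context model (re-adding a pruned demand where needed) and summarises
per-subsystem flux changes between the control and progressor optima.
"""

from pathlib import Path

from immunogem.pipeline import RunConfig, run_pipeline

SEED = 1
OUT = Path("results/pipeline")


def main():
    import pandas as pd

    run_pipeline(RunConfig(outdir=str(OUT), seed=SEED))
    flux = pd.read_csv(OUT / "glycoceramide_flux.tsv", sep="\t")
    print("glycoceramide production optima:")
    print(flux.round(3).to_string(index=False))
    deltas_path = OUT / "subsystem_deltas.tsv"
    if deltas_path.exists():
        deltas = pd.read_csv(deltas_path, sep="\t")
        print("\nsubsystem flux change (CTRL -> PT1D, glucosylceramide objective):")
        print(deltas.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
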