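#!/usr/bin/env python
"""Reporter-metabolite analysis on the toy network.

Aggregates differential-expression significance (PT1D vs P1Ab, and vs CTRL)
onto network metabolites with Monte-Carlo background correction, separately
for up- and down-regulation, and prints the top up-reporters — the
glycoceramide species in a recovered run.
"""

from pathlib import Path

from immunogem.pipeline import RunConfig, run_pipeline

SEED = 1
OUT = Path("results/pipeline")


def main():
    import pandas as pd

    run_pipeline(RunConfig(outdir=str(OUT), seed=SEED), upto="reporters")
    t = pd.read_csv(OUT / "reporters_PT1D_vs_P1Ab_up.tsv", sep="\t")
    print("top up-reporters, PT1D vs P1Ab:")
    print(t.head(8)[["metabolite", "k", "z_corrected", "p", "fdr"]]
          .round(4).to_string(index=False))


if __name__ == "__main__":
    main()
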