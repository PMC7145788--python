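#!/usr/bin/env python
"""Pathway over-representation with impact scores.

For each contrast's selected features, tests every pathway set against the
measured universe (one-sided hypergeometric, BH FDR) and computes the
centrality-based pathway impact score.  Prints the 36-month progressor
comparison, where sphingolipid metabolism should surface.
"""

from pathlib import Path

from immunogem.pipeline import RunConfig, run_pipeline

SEED = 1
OUT = Path("results/pipeline")


def main():
    import pandas as pd

    run_pipeline(RunConfig(outdir=str(OUT), seed=SEED), upto="ora")
    t = pd.read_csv(OUT / "ora_PT1D_vs_P1Ab_36m.tsv", sep="\t")
    print("over-representation, PT1D vs P1Ab at 36 months:")
    cols = ["pathway", "hits_k", "size_K", "p", "fdr", "pis", "significant"]
    print(t[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
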