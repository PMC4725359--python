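#!/usr/bin/env python
"""Bootstrapped differential-abundance analysis of the synthetic dataset,
plus a side-by-side comparison with the packaged 27-OTU reference table.

The procedure: 40 repetitions of (draw 50% of each class's samples, record
per-taxon median abundance), a rank-sum test between the two 40-vectors of
medians, BH correction at FDR 1e-4 — all bootstrapped 1000 times, keeping
taxa marked in >= 99.5% of iterations.  Outputs under results/diffabund/.
"""

from pathlib import Path

from dysbiome import (
    BootDiffParams,
    bootstrapped_diff,
    read_abundance_table,
    summarize_against_fixture,
    to_relative,
)
from dysbiome.tables import read_sample_meta

IN = Path("results/synthetic")
OUT = Path("results/diffabund")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rel = to_relative(read_abundance_table(IN / "abundance_counts.tsv", unit="counts"))
    meta = read_sample_meta(IN / "sample_metadata.tsv")
    res = bootstrapped_diff(rel, meta, BootDiffParams(n_bootstraps=1000, seed=1))
    res.frame.sort_index().to_csv(
        OUT / "differential_abundance.tsv", sep="\t", float_format="%.10g"
    )
    sig = res.significant_taxa
    print(f"{len(sig)} taxa retained at 99.5% over 1000 bootstraps "
          f"(no effects are planted in this dataset, so 0 is the correct answer)")
    if sig:
        print(res.frame.loc[sig, ["retention", "direction"]].to_string())
    cmp = summarize_against_fixture(res.frame)
    cmp.to_csv(OUT / "fixture_comparison.tsv", sep="\t")
    print("\nrun vs packaged 27-OTU reference table:")
    print(cmp.to_string())


if __name__ == "__main__":
    main()
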