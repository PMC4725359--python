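#!/usr/bin/env python
"""Core-microbiome comparison: taxa at >= 0.1% abundance in >= 80% of a
class's samples, per class, with the common / exclusive breakdown.
Outputs under results/core/."""

from pathlib import Path

import pandas as pd

from dysbiome import compare_cores, core_taxa, read_abundance_table, to_relative
from dysbiome.tables import LESIONAL, NON_LESIONAL, read_sample_meta

IN = Path("results/synthetic")
OUT = Path("results/core")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rel = to_relative(read_abundance_table(IN / "abundance_counts.tsv", unit="counts"))
    meta = read_sample_meta(IN / "sample_metadata.tsv")
    cores = {kl: core_taxa(rel, meta, kl) for kl in (LESIONAL, NON_LESIONAL)}
    common, ex_l, ex_n = compare_cores(cores[LESIONAL], cores[NON_LESIONAL])
    rows = [
        (t, t in cores[LESIONAL].members, t in cores[NON_LESIONAL].members)
        for t in sorted(cores[LESIONAL].members | cores[NON_LESIONAL].members)
    ]
    pd.DataFrame(rows, columns=["taxon_id", "core_lesional", "core_non_lesional"]).to_csv(
        OUT / "core_taxa.tsv", sep="\t", index=False
    )
    print(f"core taxa: {len(cores[NON_LESIONAL].members)} non-lesional, "
          f"{len(cores[LESIONAL].members)} lesional, {len(common)} common")
    print(f"exclusive to lesional: {sorted(ex_l)[:5]}{'...' if len(ex_l) > 5 else ''}")
    print(f"exclusive to non-lesional: {sorted(ex_n)[:5]}{'...' if len(ex_n) > 5 else ''}")


if __name__ == "__main__":
    main()
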