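#!/usr/bin/env python
"""Generate the study-like synthetic dataset all downstream analyses use.

10 subjects, one lesional (V) and one non-lesional (N) sample each, 220
genus-level taxa, 40,000 reads per sample.  Writes the counts table, sample
metadata, lineage (phylum) annotations and the (empty, by default) planted
truth under results/synthetic/.
"""

from pathlib import Path

import pandas as pd

from dysbiome import default_skinlike_spec, generate, write_abundance_table
from dysbiome.tables import write_sample_meta

OUT = Path("results/synthetic")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = default_skinlike_spec(SEED)
    ds = generate(spec)
    write_abundance_table(ds.table, OUT / "abundance_counts.tsv")
    write_sample_meta(ds.meta, OUT / "sample_metadata.tsv")
    pd.DataFrame(
        [(t, spec.phylum_assignment[t]) for t in spec.taxa],
        columns=["taxon_id", "phylum"],
    ).to_csv(OUT / "lineage.tsv", sep="\t", index=False)
    pd.Series(ds.truth, name="higher_in", dtype=object).rename_axis("taxon_id").to_csv(
        OUT / "planted_truth.tsv", sep="\t"
    )
    comp = spec.expected_composition()
    by_phylum = comp.groupby(spec.phylum_assignment.__getitem__).sum().sort_values(
        ascending=False
    )
    print(f"wrote {len(ds.table.taxa)} taxa x {len(ds.table.samples)} samples "
          f"(seed {SEED}) to {OUT}")
    print("expected phylum mass (top 4):")
    print((by_phylum.head(4) * 100).round(1).to_string())


if __name__ == "__main__":
    main()
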