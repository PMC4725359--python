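"""Packaged worked-example fixture: the 27 differentially abundant OTUs.

The TSV carries, per OTU, its phylum, the class-pooled relative contribution
(percent) in non-lesional ("normal") and lesional ("vitiligo") skin, the
median and range of per-sample abundance for both classes, and which class
has the higher median.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .tables import ValidationError

_FIXTURE_NAME = "differential_otus_reference.tsv"

_REQUIRED = [
    "otu_id",
    "phylum",
    "rel_contrib_non_lesional",
    "rel_contrib_lesional",
    "median_non_lesional",
    "min_non_lesional",
    "max_non_lesional",
    "median_lesional",
    "min_lesional",
    "max_lesional",
    "higher_in",
]


def fixture_path():
    """Filesystem path of the packaged differential-OTU table."""
    return resources.files("dysbiome.data") / _FIXTURE_NAME


def load_differential_otus(path=None) -> pd.DataFrame:
    """Load (and validate) the differential-OTU fixture, or a same-layout TSV."""
    src = fixture_path() if path is None else path
    df = pd.read_csv(src, sep="\t", comment="#")
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise ValidationError(f"fixture missing columns {sorted(missing)}")
    if df["otu_id"].duplicated().any():
        raise ValidationError("fixture has duplicate otu_id rows")
    bad = ~df["higher_in"].isin(["lesional", "non_lesional"])
    if bad.any():
        raise ValidationError(
            f"fixture higher_in values invalid: {df.loc[bad, 'higher_in'].tolist()}"
        )
    return df.set_index("otu_id")
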