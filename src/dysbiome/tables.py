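"""Abundance-table data model, TSV I/O and normalisation utilities.

The central container is :class:`AbundanceTable`, a taxa x samples matrix of
counts or relative percentages, accompanied by per-sample metadata
(:class:`SampleMeta`) and per-taxon lineage/phenotype annotations
(:class:`TaxonRecord`).  Sample identifiers follow the paired-site naming
scheme ``<subject><N|V><site>`` (e.g. ``A1N1`` = non-lesional site 1 of
subject A1, ``A1V1`` its lesional counterpart).

All tables are tab-separated UTF-8 text; lines starting with ``#`` are
comments; taxon ids sit in the first column, sample ids in the header.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

LESIONAL = "lesional"
NON_LESIONAL = "non_lesional"
CLASSES = (LESIONAL, NON_LESIONAL)

LINEAGE_RANKS = ("phylum", "class", "order", "family", "genus")
PHENOTYPE_KEYS = ("gram_nature", "sporulation", "oxygen_requirement", "cell_shape")

#: Closed vocabularies for phenotype annotations.  Configurable: pass an
#: alternative mapping to :func:`read_lineage`.
DEFAULT_PHENOTYPE_VOCAB: dict[str, frozenset[str]] = {
    "gram_nature": frozenset({"positive", "negative", "variable"}),
    "sporulation": frozenset({"sporulating", "non_sporulating"}),
    "oxygen_requirement": frozenset(
        {"aerobic", "anaerobic", "facultative", "microaerophilic"}
    ),
    "cell_shape": frozenset(
        {"coccus", "rod", "coccobacillus", "filamentous", "spiral", "pleomorphic"}
    ),
}


class ValidationError(ValueError):
    """Raised when an input table or metadata record violates its contract."""


_SAMPLE_ID_RE = re.compile(r"^(?P<subject>[A-Za-z]+\d*)(?P<cls>[NV])(?P<site>\d+)$")


@dataclass(frozen=True)
class SampleMeta:
    """One sample: id, owning subject, site tag and lesional status."""

    sample_id: str
    subject_id: str
    site_tag: str
    klass: str

    def __post_init__(self):
        if self.klass not in CLASSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: class must be one of {CLASSES}, "
                f"got {self.klass!r}"
            )


def parse_sample_id(sample_id: str) -> SampleMeta:
    """Decode a ``<subject><N|V><site>`` token (N = non-lesional, V = lesional)."""
    m = _SAMPLE_ID_RE.match(sample_id)
    if m is None:
        raise ValidationError(
            f"sample id {sample_id!r} does not follow the <subject><N|V><site> scheme"
        )
    klass = NON_LESIONAL if m.group("cls") == "N" else LESIONAL
    return SampleMeta(sample_id, m.group("subject"), m.group("site"), klass)


@dataclass(frozen=True)
class TaxonRecord:
    """Taxon id plus lineage (phylum..genus) and optional phenotype labels."""

    taxon_id: str
    lineage: dict = field(default_factory=dict)
    phenotypes: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = set(self.lineage) - set(LINEAGE_RANKS)
        if bad:
            raise ValidationError(f"taxon {self.taxon_id!r}: unknown ranks {sorted(bad)}")
        bad = set(self.phenotypes) - set(PHENOTYPE_KEYS)
        if bad:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: unknown phenotype keys {sorted(bad)}"
            )


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by taxon id with sample ids as columns.  All values
        must be finite and non-negative.
    unit:
        ``"counts"`` or ``"percent"``.  Percent tables must have column sums
        of 100 within ``1e-6``.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self):
        if self.unit not in ("counts", "percent"):
            raise ValidationError(f"unit must be 'counts' or 'percent', got {self.unit!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at taxon {idx[r]!r}, sample {cols[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value at taxon {idx[r]!r}, sample {cols[c]!r}"
            )
        if self.unit == "percent" and len(idx):
            sums = vals.sum(axis=0)
            off = np.abs(sums - 100.0) > 1e-6
            if off.any():
                j = int(np.argmax(off))
                raise ValidationError(
                    f"percent column {cols[j]!r} sums to {sums[j]!r}, expected 100"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown samples: {missing}")
        return AbundanceTable(self.data[list(sample_ids)].copy(), self.unit)


@dataclass
class RankMatrix:
    """Per-taxon normalised ranks across samples, values in (0, 1].

    Row *i* holds the within-row average ranks of taxon *i*'s abundances
    across samples, divided by the number of samples.  Tied abundances get
    equal (fractional) ranks.
    """

    data: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    """Read a TSV with duplicate-header detection and numeric validation."""
    with open(path, "r", encoding="utf-8") as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            header = line.rstrip("\n").split("\t")
            break
    if header is None:
        raise ValidationError(f"{path}: empty table")
    sample_ids = header[1:]
    seen, dups = set(), []
    for s in sample_ids:
        if s in seen:
            dups.append(s)
        seen.add(s)
    if dups:
        raise ValidationError(f"{path}: duplicate sample columns {sorted(set(dups))}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    out = {}
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            raise ValidationError(
                f"{path}: non-numeric cell at taxon {bad[0]!r}, sample {col!r}"
            ) from None
    return pd.DataFrame(out, index=df.index)


def read_abundance_table(path, unit: str) -> AbundanceTable:
    """Read a taxa x samples TSV and validate it as an :class:`AbundanceTable`.

    Percent tables whose column sums are within 0.5 of 100 are renormalised
    to sum exactly 100; larger deviations raise :class:`ValidationError`.
    """
    df = _read_tsv(path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate taxon rows {dup}")
    if unit == "percent":
        sums = df.to_numpy(dtype=float).sum(axis=0)
        off = np.abs(sums - 100.0) > 0.5
        if off.any():
            j = int(np.argmax(off))
            raise ValidationError(
                f"{path}: column {df.columns[j]!r} sums to {sums[j]:.4f}, "
                "not within 0.5 of 100"
            )
        df = df * (100.0 / sums)
    return AbundanceTable(df, unit)


def write_abundance_table(table: AbundanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon_id", float_format="%.10g")


def read_sample_meta(path) -> list[SampleMeta]:
    """Read sample metadata TSV with columns sample_id, subject_id, site_tag, class."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "subject_id", "site_tag", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    metas = []
    seen = set()
    for _, row in df.iterrows():
        if row["sample_id"] in seen:
            raise ValidationError(f"{path}: duplicate sample_id {row['sample_id']!r}")
        seen.add(row["sample_id"])
        metas.append(
            SampleMeta(row["sample_id"], row["subject_id"], str(row["site_tag"]),
                       row["class"])
        )
    return metas


def write_sample_meta(metas: list[SampleMeta], path) -> None:
    pd.DataFrame(
        [(m.sample_id, m.subject_id, m.site_tag, m.klass) for m in metas],
        columns=["sample_id", "subject_id", "site_tag", "class"],
    ).to_csv(path, sep="\t", index=False)


def meta_from_sample_ids(sample_ids) -> list[SampleMeta]:
    """Decode metadata straight from scheme-following sample ids."""
    return [parse_sample_id(s) for s in sample_ids]


def read_lineage(path, phenotype_vocab=None) -> dict[str, TaxonRecord]:
    """Read a lineage/phenotype TSV keyed by taxon_id.

    Recognised columns: the five lineage ranks (phylum..genus) and the four
    phenotype keys; empty cells mean "absent".  Phenotype values are checked
    against the closed vocabularies (``DEFAULT_PHENOTYPE_VOCAB`` unless
    overridden).
    """
    vocab = DEFAULT_PHENOTYPE_VOCAB if phenotype_vocab is None else phenotype_vocab
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "taxon_id" not in df.columns:
        raise ValidationError(f"{path}: missing 'taxon_id' column")
    records = {}
    for _, row in df.iterrows():
        tid = row["taxon_id"]
        if tid in records:
            raise ValidationError(f"{path}: duplicate taxon_id {tid!r}")
        lineage = {
            rank: row[rank]
            for rank in LINEAGE_RANKS
            if rank in df.columns and pd.notna(row[rank]) and row[rank] != ""
        }
        phen = {}
        for key in PHENOTYPE_KEYS:
            if key in df.columns and pd.notna(row[key]) and row[key] != "":
                val = row[key]
                if key in vocab and val not in vocab[key]:
                    raise ValidationError(
                        f"{path}: taxon {tid!r}: {key}={val!r} not in vocabulary "
                        f"{sorted(vocab[key])}"
                    )
                phen[key] = val
        records[tid] = TaxonRecord(tid, lineage, phen)
    return records


# ---------------------------------------------------------------------------
# normalisation


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert a counts table to per-sample relative percentages (sum 100)."""
    if table.unit != "counts":
        raise ValidationError("to_relative expects a counts table")
    vals = table.values
    sums = vals.sum(axis=0)
    zero = sums == 0
    if zero.any():
        j = int(np.argmax(zero))
        raise ValidationError(f"sample {table.samples[j]!r} has zero total count")
    rel = vals * (100.0 / sums)
    return AbundanceTable(
        pd.DataFrame(rel, index=table.data.index, columns=table.data.columns),
        "percent",
    )


def rank_normalize(table: AbundanceTable) -> RankMatrix:
    """Rank each taxon's abundances across samples (average ranks for ties),
    divided by the sample count so values lie in (0, 1]."""
    n = len(table.samples)
    if n < 2:
        raise ValidationError("rank normalisation needs at least 2 samples")
    ranks = rankdata(table.values, axis=1, method="average") / n
    return RankMatrix(
        pd.DataFrame(ranks, index=table.data.index, columns=table.data.columns)
    )


def relative_contribution(table: AbundanceTable, meta, klass: str) -> pd.Series:
    """Class-pooled percentage of assignments per taxon.

    For counts the pool is the literal sum of counts over the class's samples
    divided by the class total; for percent tables each sample contributes
    equally (unweighted mean of its percentages).  Either way the result sums
    to 100 over taxa.
    """
    if klass not in CLASSES:
        raise ValidationError(f"unknown class {klass!r}")
    ids = [m.sample_id for m in meta if m.klass == klass and m.sample_id in table.data.columns]
    if not ids:
        raise ValidationError(f"no samples of class {klass!r} in table")
    sub = table.data[ids].to_numpy(dtype=float)
    if table.unit == "counts":
        total = sub.sum()
        if total == 0:
            raise ValidationError(f"class {klass!r} has zero total count")
        contrib = sub.sum(axis=1) * (100.0 / total)
    else:
        contrib = sub.mean(axis=1)
    return pd.Series(contrib, index=table.data.index, name=klass)
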