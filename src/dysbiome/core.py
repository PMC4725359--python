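"""Core-microbiome identification and comparison between sample classes.

A taxon is "core" for a class when its per-sample relative abundance reaches
a minimum percentage (default 0.1%) in at least a minimum fraction (default
80%, ceiling on fractional counts) of that class's samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tables import CLASSES, AbundanceTable, ValidationError


@dataclass(frozen=True)
class CoreSet:
    klass: str
    members: frozenset
    min_pct: float
    min_prev: float


def core_taxa(
    table: AbundanceTable,
    meta,
    klass: str,
    min_pct: float = 0.1,
    min_prev: float = 0.8,
) -> CoreSet:
    """Taxa at >= *min_pct* percent in >= ceil(min_prev * n) samples of *klass*."""
    if table.unit != "percent":
        raise ValidationError("core_taxa expects a percent table")
    if klass not in CLASSES:
        raise ValidationError(f"unknown class {klass!r}")
    if not (0 < min_prev <= 1):
        raise ValidationError("min_prev must be in (0, 1]")
    ids = [m.sample_id for m in meta
           if m.klass == klass and m.sample_id in table.data.columns]
    if not ids:
        raise ValidationError(f"no samples of class {klass!r}")
    sub = table.data[ids].to_numpy(dtype=float)
    # guard against float fuzz in e.g. 0.8 * 15
    need = math.ceil(min_prev * len(ids) - 1e-9)
    hits = (sub >= min_pct).sum(axis=1)
    members = frozenset(np.asarray(table.taxa)[hits >= need].tolist())
    return CoreSet(klass, members, min_pct, min_prev)


def compare_cores(a: CoreSet, b: CoreSet):
    """(common, exclusive to a, exclusive to b) taxon sets."""
    common = a.members & b.members
    return common, a.members - common, b.members - common
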