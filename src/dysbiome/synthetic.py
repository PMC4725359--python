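"""Synthetic paired lesional/non-lesional abundance datasets.

The generator emulates the statistical structure the downstream analyses
assume: a long-tailed genus abundance distribution dominated by four phyla
(Actinobacteria, Proteobacteria, Firmicutes, Bacteroidetes), per-subject
community signatures shared by both of a subject's paired samples and
stronger than any class signature, and a sparse, configurable set of planted
class-differential taxa.

Per sample, counts are drawn as:

1. a per-subject log-normal perturbation of the base log-mean vector
   (standard deviation ``subject_effect_sd``), shared by the subject's
   lesional and non-lesional sample;
2. the planted log-fold-changes added to lesional samples only;
3. softmax to a composition;
4. a Dirichlet-multinomial draw at ``sequencing_depth`` with total
   concentration ``overdispersion`` (``inf`` = plain multinomial).

Randomness: the master seed spawns one independent substream per subject
effect and per sample, so per-sample draws do not depend on generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    LESIONAL,
    NON_LESIONAL,
    AbundanceTable,
    SampleMeta,
    TaxonRecord,
    ValidationError,
)

MAJOR_PHYLA = ("Actinobacteria", "Proteobacteria", "Firmicutes", "Bacteroidetes")
MINOR_PHYLA = (
    "Cyanobacteria",
    "Fusobacteria",
    "Acidobacteria",
    "Verrucomicrobia",
    "Planctomycetes",
    "Chloroflexi",
    "Deinococcus-Thermus",
    "TM7",
)

# Target expected phylum mass of the skin-like default: the four majors carry
# ~85% of assignments with Actinobacteria alone above 45%.
_PHYLUM_TARGETS = {
    "Actinobacteria": 0.50,
    "Proteobacteria": 0.18,
    "Firmicutes": 0.11,
    "Bacteroidetes": 0.06,
}


@dataclass
class SyntheticSpec:
    """Full parameterisation of the generator."""

    n_subjects: int
    n_taxa: int
    sequencing_depth: int
    base_log_mean: np.ndarray
    subject_effect_sd: float
    class_effect: dict[str, float] = field(default_factory=dict)
    overdispersion: float = math.inf
    phylum_assignment: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.base_log_mean = np.asarray(self.base_log_mean, dtype=float)
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if self.n_taxa < 10:
            raise ValidationError("n_taxa must be >= 10")
        if self.sequencing_depth <= 0:
            raise ValidationError("sequencing_depth must be positive")
        if self.base_log_mean.shape != (self.n_taxa,):
            raise ValidationError(
                f"base_log_mean must have length n_taxa={self.n_taxa}"
            )
        if self.subject_effect_sd < 0:
            raise ValidationError("subject_effect_sd must be non-negative")
        if not (self.overdispersion > 0):
            raise ValidationError("overdispersion must be positive (inf allowed)")
        taxa = set(self.taxa)
        unknown = set(self.class_effect) - taxa
        if unknown:
            raise ValidationError(f"class_effect names unknown taxa: {sorted(unknown)}")
        unknown = set(self.phylum_assignment) - taxa
        if unknown:
            raise ValidationError(
                f"phylum_assignment names unknown taxa: {sorted(unknown)}"
            )

    @property
    def taxa(self) -> list[str]:
        return [f"genus_{i + 1:04d}" for i in range(self.n_taxa)]

    def expected_composition(self) -> pd.Series:
        """Population-level composition softmax(base_log_mean), before
        subject effects and counting noise."""
        w = np.exp(self.base_log_mean - self.base_log_mean.max())
        return pd.Series(w / w.sum(), index=self.taxa)

    def taxon_records(self) -> dict[str, TaxonRecord]:
        return {
            t: TaxonRecord(t, {"phylum": self.phylum_assignment.get(t, "Unclassified")})
            for t in self.taxa
        }


@dataclass
class SyntheticDataset:
    """Generated counts table + metadata + planted ground truth."""

    table: AbundanceTable
    meta: list[SampleMeta]
    truth: dict[str, str]  # taxon -> direction ("lesional"/"non_lesional" = higher in)
    spec: SyntheticSpec


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one paired dataset (two samples per subject, one per class)."""
    taxa = spec.taxa
    root = np.random.SeedSequence(spec.seed)
    # one child per subject; each subject spawns (effect, sample N, sample V)
    subject_seeds = root.spawn(spec.n_subjects)

    effect = np.zeros(spec.n_taxa)
    for t, lfc in spec.class_effect.items():
        effect[taxa.index(t)] = lfc

    columns, metas, ids = {}, [], []
    for j, sseed in enumerate(subject_seeds):
        eff_ss, n_ss, v_ss = sseed.spawn(3)
        subj = f"S{j + 1}"
        subject_shift = (
            np.random.default_rng(eff_ss).normal(0.0, spec.subject_effect_sd, spec.n_taxa)
            if spec.subject_effect_sd > 0
            else np.zeros(spec.n_taxa)
        )
        for klass, ss, tag in (
            (NON_LESIONAL, n_ss, "N1"),
            (LESIONAL, v_ss, "V1"),
        ):
            logit = spec.base_log_mean + subject_shift
            if klass == LESIONAL:
                logit = logit + effect
            w = np.exp(logit - logit.max())
            p = w / w.sum()
            rng = np.random.default_rng(ss)
            if math.isfinite(spec.overdispersion):
                alpha = p * spec.overdispersion
                # Dirichlet with possibly tiny alphas: gamma draws, renormalise
                g = rng.gamma(shape=alpha, scale=1.0)
                tot = g.sum()
                q = g / tot if tot > 0 else p
            else:
                q = p
            counts = rng.multinomial(spec.sequencing_depth, q)
            sid = f"{subj}{tag}"
            ids.append(sid)
            columns[sid] = counts
            metas.append(SampleMeta(sid, subj, tag[1:], klass))

    df = pd.DataFrame(columns, index=taxa, columns=ids)
    truth = {
        t: (LESIONAL if lfc > 0 else NON_LESIONAL)
        for t, lfc in spec.class_effect.items()
        if lfc != 0
    }
    return SyntheticDataset(AbundanceTable(df, "counts"), metas, truth, spec)


def _greedy_phylum_assignment(masses: np.ndarray, taxa: list[str]) -> dict[str, str]:
    """Assign taxa to phyla so expected phylum masses track the skin targets.

    Taxa are visited in descending expected mass; each goes to the phylum with
    the largest remaining absolute deficit, which makes the realised expected
    masses match the targets to within the mass of a single tail taxon.
    """
    targets = dict(_PHYLUM_TARGETS)
    minor_share = (1.0 - sum(targets.values())) / len(MINOR_PHYLA)
    for ph in MINOR_PHYLA:
        targets[ph] = minor_share
    acc = {ph: 0.0 for ph in targets}
    assignment = {}
    for i in np.argsort(-masses):
        ph = max(targets, key=lambda k: targets[k] - acc[k])
        assignment[taxa[i]] = ph
        acc[ph] += masses[i]
    return assignment


def default_skinlike_spec(
    seed: int,
    n_subjects: int = 10,
    n_taxa: int = 220,
    sequencing_depth: int = 40_000,
    subject_effect_sd: float = 1.3,
    overdispersion: float = math.inf,
) -> SyntheticSpec:
    """Skin-like defaults: 10 subjects, 220 genus-level taxa with power-law
    base abundances (exponent 0.9 plus per-seed jitter, putting roughly 40%
    of expected mass on the top eight genera), phyla assigned so the four
    major phyla carry ~85% of expected mass with Actinobacteria above 45%,
    and subject effects (log-sd 1.3, shared by a subject's paired samples)
    strong enough to dominate any sparse class effect.  Counting noise is
    multinomial by default (biological variation is carried by the subject
    effect); pass a finite ``overdispersion`` to add a Dirichlet technical
    layer.  No class effects are planted by default."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    ranks = np.arange(1, n_taxa + 1, dtype=float)
    base = -0.9 * np.log(ranks) + rng.normal(0.0, 0.25, n_taxa)
    spec = SyntheticSpec(
        n_subjects=n_subjects,
        n_taxa=n_taxa,
        sequencing_depth=sequencing_depth,
        base_log_mean=base,
        subject_effect_sd=subject_effect_sd,
        overdispersion=overdispersion,
        seed=int(seed),
    )
    comp = spec.expected_composition().to_numpy()
    spec.phylum_assignment = _greedy_phylum_assignment(comp, spec.taxa)
    return spec


def plant_effects(
    spec: SyntheticSpec,
    log_fold_change: float,
    n_taxa: int = 1,
    min_base_pct: float = 1.0,
    max_base_pct: float = 10.0,
) -> SyntheticSpec:
    """Return a copy of *spec* with *n_taxa* class effects planted on taxa
    whose expected base relative abundance lies in [min_base_pct, max_base_pct]
    percent.  Deterministic: eligible taxa are taken in descending abundance."""
    comp = spec.expected_composition() * 100.0
    eligible = [
        t for t in comp.sort_values(ascending=False).index
        if min_base_pct <= comp[t] <= max_base_pct and t not in spec.class_effect
    ]
    if len(eligible) < n_taxa:
        raise ValidationError(
            f"only {len(eligible)} taxa with base abundance in "
            f"[{min_base_pct}, {max_base_pct}]%, need {n_taxa}"
        )
    effects = dict(spec.class_effect)
    for t in eligible[:n_taxa]:
        effects[t] = log_fold_change
    return SyntheticSpec(
        n_subjects=spec.n_subjects,
        n_taxa=spec.n_taxa,
        sequencing_depth=spec.sequencing_depth,
        base_log_mean=spec.base_log_mean.copy(),
        subject_effect_sd=spec.subject_effect_sd,
        class_effect=effects,
        overdispersion=spec.overdispersion,
        phylum_assignment=dict(spec.phylum_assignment),
        seed=spec.seed,
    )
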