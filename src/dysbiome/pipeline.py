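"""End-to-end orchestration: one config in, a reproducible report bundle out.

A :class:`PipelineConfig` names either input TSVs (abundance counts +
metadata + optional lineage) or a synthetic-data block, plus per-stage
parameters.  :func:`run_pipeline` then sequences the analyses — diversity
panel, evenness curves, taxa-at-threshold counts, core-taxa comparison,
bootstrapped differential abundance, per-class co-occurrence networks with
hub analysis and core interactions — writing text artifacts and a manifest
into the output directory.  One master seed drives named substreams per
stage, so outputs are byte-identical for a fixed config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import compare_cores, core_taxa
from .diffabund import BootDiffParams, bootstrapped_diff
from .diversity import (
    compare_indices_by_class,
    diversity_report,
    successive_contribution_differences,
    taxa_at_thresholds,
)
from .fixtures import load_differential_otus
from .network import (
    build_network,
    core_interactions,
    edge_table,
    hub_analysis,
    summarize_network,
    write_graphml,
)
from .synthetic import SyntheticSpec, default_skinlike_spec, generate, plant_effects
from .tables import (
    CLASSES,
    LESIONAL,
    NON_LESIONAL,
    ValidationError,
    meta_from_sample_ids,
    rank_normalize,
    read_abundance_table,
    read_lineage,
    read_sample_meta,
    relative_contribution,
    to_relative,
    write_abundance_table,
    write_sample_meta,
)

logger = logging.getLogger("dysbiome")

# stage offsets mixed into the master seed so toggling one stage leaves the
# other stages' substreams untouched
_STAGE_SEEDS = {"synthetic": 11, "diffabund": 23, "network": 37, "rarefaction": 53}


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one of (abundance_path) or
    (synthetic) must be given."""

    out_dir: str
    seed: int = 0
    abundance_path: str | None = None
    metadata_path: str | None = None
    lineage_path: str | None = None
    synthetic: dict | None = None  # kwargs of default_skinlike_spec (+ planted)
    evenness_min_pct: float = 1.0
    contribution_thresholds: tuple = (0.01, 0.1, 1.0)
    core_min_pct: float = 0.1
    core_min_prev: float = 0.8
    diff: BootDiffParams = field(default_factory=BootDiffParams)
    network_confidence: float = 0.99
    network_method: str = "t_approx"
    hub_thresholds: tuple = (60, 70, 80, 90)

    def __post_init__(self):
        has_paths = self.abundance_path is not None
        has_synth = self.synthetic is not None
        if has_paths == has_synth:
            raise ValidationError(
                "config must provide exactly one of abundance_path or synthetic"
            )
        if isinstance(self.diff, dict):
            self.diff = BootDiffParams(**self.diff)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_dataset(config: PipelineConfig):
    if config.synthetic is not None:
        synth = dict(config.synthetic)
        planted = synth.pop("planted", None)
        spec = default_skinlike_spec(
            seed=synth.pop("seed", config.seed + _STAGE_SEEDS["synthetic"]), **synth
        )
        if planted:
            spec = plant_effects(spec, **planted)
        ds = generate(spec)
        return ds.table, ds.meta, ds.spec.taxon_records(), ds.truth
    table = read_abundance_table(config.abundance_path, unit="counts")
    if config.metadata_path:
        meta = read_sample_meta(config.metadata_path)
    else:
        meta = meta_from_sample_ids(table.samples)
    annotations = read_lineage(config.lineage_path) if config.lineage_path else {}
    return table, meta, annotations, {}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of in-memory results and writes the
    report bundle (TSV/JSON artifacts + manifest) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        counts, meta, annotations, truth = _load_dataset(config)
        rel = to_relative(counts)
        write_abundance_table(counts, out / "abundance_counts.tsv")
        write_sample_meta(meta, out / "sample_metadata.tsv")
        if truth:
            pd.Series(truth, name="higher_in").rename_axis("taxon_id").to_csv(
                out / "planted_truth.tsv", sep="\t"
            )

        stage = "diversity"
        report = diversity_report(counts, meta)
        report.to_csv(out / "diversity_report.tsv", sep="\t", float_format="%.10g")
        compare_indices_by_class(report, meta).to_csv(
            out / "diversity_class_comparison.tsv", sep="\t", float_format="%.10g"
        )
        contrib = {kl: relative_contribution(rel, meta, kl) for kl in CLASSES}
        even_rows, thresh_rows = [], []
        for kl in CLASSES:
            try:
                curve = successive_contribution_differences(
                    contrib[kl], config.evenness_min_pct
                )
                for i, d in enumerate(curve.differences, start=1):
                    even_rows.append((kl, i, d, curve.slope))
            except ValidationError:
                logger.warning("evenness curve skipped for %s (too few genera)", kl)
            for t, c in taxa_at_thresholds(
                contrib[kl], config.contribution_thresholds
            ).items():
                thresh_rows.append((kl, t, c))
        pd.DataFrame(
            even_rows, columns=["class", "position", "difference", "log_trend_slope"]
        ).to_csv(out / "evenness_curves.tsv", sep="\t", index=False,
                 float_format="%.10g")
        pd.DataFrame(
            thresh_rows, columns=["class", "threshold_pct", "n_taxa"]
        ).to_csv(out / "taxa_at_thresholds.tsv", sep="\t", index=False,
                 float_format="%.10g")

        stage = "core"
        cores = {
            kl: core_taxa(rel, meta, kl, config.core_min_pct, config.core_min_prev)
            for kl in CLASSES
        }
        common, ex_l, ex_n = compare_cores(cores[LESIONAL], cores[NON_LESIONAL])
        core_rows = [
            (t, t in cores[LESIONAL].members, t in cores[NON_LESIONAL].members)
            for t in sorted(cores[LESIONAL].members | cores[NON_LESIONAL].members)
        ]
        pd.DataFrame(
            core_rows, columns=["taxon_id", "core_lesional", "core_non_lesional"]
        ).to_csv(out / "core_taxa.tsv", sep="\t", index=False)

        stage = "diffabund"
        diff_params = BootDiffParams(**{**asdict(config.diff),
                                        "seed": config.seed + _STAGE_SEEDS["diffabund"]})
        diff = bootstrapped_diff(rel, meta, diff_params)
        diff.frame.sort_index().to_csv(
            out / "differential_abundance.tsv", sep="\t", float_format="%.10g"
        )

        stage = "network"
        nets, summaries = {}, {}
        for kl in CLASSES:
            ids = sorted(m.sample_id for m in meta if m.klass == kl)
            ranks = rank_normalize(rel.subset_samples(ids))
            nets[kl] = build_network(
                ranks,
                annotations,
                confidence=config.network_confidence,
                klass=kl,
                method=config.network_method,
                seed=config.seed + _STAGE_SEEDS["network"],
            )
            edge_table(nets[kl]).to_csv(
                out / f"network_edges_{kl}.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
            write_graphml(nets[kl], out / f"network_{kl}.graphml")
            s = summarize_network(nets[kl])
            summaries[kl] = {
                "n_nodes": s.n_nodes,
                "n_edges": s.n_edges,
                "density": s.density,
                "diameter": s.diameter,
                "max_degree": max(s.degree.values()) if s.degree else 0,
                "critical_r": nets[kl].critical_r,
            }
        hub_rows = []
        for kl in CLASSES:
            if nets[kl].graph.number_of_edges():
                for rep in hub_analysis(nets[kl], config.hub_thresholds):
                    for ph, cnt in sorted(rep.phylum_composition.items()):
                        hub_rows.append((kl, rep.threshold_pct, ph, cnt,
                                         len(rep.hubs)))
        pd.DataFrame(
            hub_rows,
            columns=["class", "threshold_pct", "phylum", "n_hubs_in_phylum",
                     "n_hubs_total"],
        ).to_csv(out / "hub_composition.tsv", sep="\t", index=False)
        shared = core_interactions(nets[LESIONAL], nets[NON_LESIONAL])
        pd.DataFrame(
            sorted((min(p), max(p), sign) for p, sign in shared),
            columns=["taxon_a", "taxon_b", "sign"],
        ).to_csv(out / "core_interactions.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "dysbiome_version": __version__,
            "seed": config.seed,
            "config": _jsonable(asdict(config)),
            "n_samples": len(counts.samples),
            "n_taxa": len(counts.taxa),
            "network_summaries": summaries,
            "n_core": {kl: len(cores[kl].members) for kl in CLASSES},
            "n_core_common": len(common),
            "n_significant": int(diff.frame["significant"].sum()),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except ValidationError as err:
        raise ValidationError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "table": counts,
        "meta": meta,
        "diversity": report,
        "cores": cores,
        "core_comparison": (common, ex_l, ex_n),
        "diff": diff,
        "networks": nets,
        "network_summaries": summaries,
        "core_interactions": shared,
        "truth": truth,
        "manifest": manifest,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def summarize_against_fixture(diff_frame: pd.DataFrame, fixture_path=None) -> pd.DataFrame:
    """Side-by-side counts for a run's differential table vs the packaged
    27-OTU fixture: records, per-direction counts, counts above contribution
    thresholds."""
    fix = load_differential_otus(fixture_path)

    def counts_of(records, contrib_cols, higher_col_is_direction):
        n = len(records)
        if higher_col_is_direction:
            hi_l = int((records["direction"] == "higher_in_lesional").sum())
            hi_n = int((records["direction"] == "higher_in_non_lesional").sum())
        else:
            hi_l = int((records["higher_in"] == "lesional").sum())
            hi_n = int((records["higher_in"] == "non_lesional").sum())
        best = records[contrib_cols].max(axis=1)
        return {
            "n_significant": n,
            "n_higher_in_lesional": hi_l,
            "n_higher_in_non_lesional": hi_n,
            "n_contrib_gt_0.1pct": int((best > 0.1).sum()),
            "n_contrib_ge_1pct": int((best >= 1.0).sum()),
        }

    run_records = diff_frame[diff_frame.get("significant", False) == True]  # noqa: E712
    run = counts_of(
        run_records,
        ["rel_contrib_non_lesional", "rel_contrib_lesional"],
        higher_col_is_direction=True,
    )
    ref = counts_of(
        fix, ["rel_contrib_non_lesional", "rel_contrib_lesional"],
        higher_col_is_direction=False,
    )
    return pd.DataFrame({"run": run, "fixture": ref})
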