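"""Stage orchestration: simulate/ingest → filter → features → fidelity →
cross-validation → baseline → report.

Each stage reads/writes the package's interchange formats and the whole
run is captured in a :class:`RunManifest` (config echo, seeds, input
digests, stage timings, output paths) so every published number is
traceable to a config and a seed.

The host-fidelity stage runs on event-level visitation records (taxon-
and species-eligibility filtered, before duplicate collapse): the
duplicate rule exists to collapse double-entered rows in aggregated
compilations, and applying it to event-level records would discard true
repeat visits. Feature construction uses the fully filtered dataset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .features import build_feature_table
from .fidelity import fidelity_size_correlation, host_fidelity, sex_fidelity_comparison
from .filtering import (
    dedupe_occurrences,
    filter_visitation,
    remove_geographic_outliers,
)
from .model import (
    BLOCKINGS,
    CVConfig,
    DietBreadthModel,
    aggregate_cv_importance,
    baseline_cv,
)
from .synth import SyntheticConfig, generate_bundle, write_bundle


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: Dict[str, str] = field(default_factory=dict)
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_all(
    out_dir,
    seed: int = 0,
    synthetic_config: Optional[SyntheticConfig] = None,
    cv_config: Optional[CVConfig] = None,
    blockings: Optional[List[str]] = None,
) -> RunManifest:
    """Run every stage on a synthetic bundle and write all reports.

    Returns the populated manifest; raises on the first failing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = synthetic_config or SyntheticConfig(seed=seed)
    cv = cv_config or CVConfig(seed=seed, n_repeats=1)
    blockings = list(blockings or BLOCKINGS)

    manifest = RunManifest(
        config={
            "synthetic": dataclasses.asdict(syn),
            "cv": dataclasses.asdict(cv),
            "blockings": blockings,
        },
        seed=seed,
    )

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.time()

            def __exit__(self, *exc):
                manifest.stage_seconds[name] = round(time.time() - self.t0, 2)
                return False

        return _T()

    with stage("simulate"):
        bundle = generate_bundle(syn)
        paths = write_bundle(bundle, out / "inputs")
        manifest.outputs.update({f"input_{k}": v for k, v in paths.items()})
        manifest.input_digests = {k: _digest(v) for k, v in paths.items()}

    with stage("filter"):
        labeled = {l.bee_species for l in bundle.labels}
        vis, vis_report = filter_visitation(
            bundle.visitation,
            us_species=bundle.us_species,
            cleptoparasites=bundle.cleptoparasites,
            nonnatives=bundle.nonnatives,
            labeled_species=labeled,
        )
        occ, dd_report = dedupe_occurrences(bundle.occurrences)
        occ, out_report = remove_geographic_outliers(occ)
        with open(out / "filter_report.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "visitation": vis_report.as_dict(),
                    "occurrence_dedupe": dd_report.as_dict(),
                    "occurrence_outliers": out_report.as_dict(),
                },
                fh,
                indent=2,
            )
        manifest.outputs["filter_report"] = str(out / "filter_report.json")

    with stage("fidelity"):
        # event-level records: eligibility filters only (see module docstring)
        event_vis = [
            r
            for r in bundle.visitation
            if r.plant_genus
            and r.bee_species in bundle.us_species
            and r.bee_species not in bundle.cleptoparasites
            and r.bee_species not in bundle.nonnatives
        ]
        summary = host_fidelity(event_vis, bundle.labels)
        sex_cmp = sex_fidelity_comparison(event_vis, bundle.labels)
        per_species = pd.DataFrame(
            [
                {
                    "bee_species": r.bee_species,
                    "n_records": r.n_records,
                    "n_host_visits": r.n_host_visits,
                    "proportion_host": r.proportion_host,
                }
                for r in summary.results
            ]
        )
        per_species.to_csv(out / "fidelity_per_species.csv", index=False)
        fid_json = {
            "n_species": summary.n_species,
            "mean_proportion_host": summary.mean,
            "median_proportion_host": summary.median,
            "histogram_bins_0.1": summary.histogram,
            "pearson_r_vs_sample_size": fidelity_size_correlation(summary.results),
            "sex_comparison": {
                "n_species": sex_cmp.n_species,
                "wilcoxon_v": sex_cmp.wilcoxon.v,
                "p_value": sex_cmp.wilcoxon.p_value,
                "mean_female": sex_cmp.mean_female,
                "mean_male": sex_cmp.mean_male,
            },
        }
        with open(out / "fidelity_summary.json", "w", encoding="utf-8") as fh:
            json.dump(fid_json, fh, indent=2)
        manifest.outputs["fidelity_summary"] = str(out / "fidelity_summary.json")

    with stage("features"):
        table, screen = build_feature_table(
            vis, occ, bundle.labels, bundle.bee_tree, bundle.plant_tree, seed=seed
        )
        table.to_csv(out / "features.csv")
        with open(out / "features_provenance.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": seed,
                    "n_species": len(table),
                    "collinearity_flagged": screen.flagged_pairs,
                    "collinearity_dropped": screen.dropped,
                },
                fh,
                indent=2,
            )
        manifest.outputs["features"] = str(out / "features.csv")

    cv_metrics = {}
    runs = {}
    with stage("cv"):
        model = DietBreadthModel(table)
        for blocking in blockings:
            cfg = dataclasses.replace(cv, blocking=blocking)
            run = model.cross_validate(cfg)
            runs[blocking] = run
            cv_metrics[blocking] = run.metrics()
            run.fold_frame().to_csv(out / f"cv_folds_{blocking}.csv", index=False)
        agg = aggregate_cv_importance(runs)
        agg.to_csv(out / "importance_aggregate.csv")
        manifest.outputs["importance_aggregate"] = str(out / "importance_aggregate.csv")

    with stage("baseline"):
        base_cfg = dataclasses.replace(cv, blocking="spatial", compute_importance=False)
        base_run = baseline_cv(table, base_cfg)
        cv_metrics["phylo_baseline"] = {
            k: v for k, v in base_run.metrics().items() if k != "blocking"
        }

    with stage("report"):
        report = {
            "seed": seed,
            "n_species": len(table),
            "class_counts": table["label"].value_counts().to_dict(),
            "fidelity": fid_json,
            "cv": cv_metrics,
            "top10_importance": agg.head(10)["mean_importance"].to_dict(),
        }
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, default=float)
        lines = ["# beelecty run report", "", f"- species: {len(table)}"]
        for blocking, m in cv_metrics.items():
            lines.append(
                f"- {blocking}: AUC={m.get('mean_auc', float('nan')):.3f} "
                f"balanced={m['mean_balanced_accuracy']:.3f} "
                f"spec={m['mean_specialist_accuracy']:.3f} "
                f"gen={m['mean_generalist_accuracy']:.3f}"
            )
        (out / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
        manifest.outputs["report"] = str(out / "report.json")

    manifest.write(out / "manifest.json")
    return manifest
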