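"""End-to-end study pipeline.

Stages, in order: eligibility filter -> baseline network + centrality +
bootstrap -> anxiety-augmented network -> anxiety split -> pre-matching
comparison (network permutation test + demographics report) -> propensity
matching -> post-matching comparison.  A JSON manifest records counts at
every stage and the paths of all artifacts; the run log echoes every
default so a run is auditable.  One master seed drives every stochastic
stage through stable per-stage derivation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import association_matrix
from .centrality import centrality_table
from .comparison import nct
from .data_io import CohortConfig, CohortTable, apply_eligibility, read_cohort, split_by_anxiety
from .group_stats import StatsConfig, table2_report
from .matching import MatchConfig, match_cohort, matched_tables
from .network import GlassoConfig, fit_network
from .resampling import bootstrap_edges
from .synthetic import cluster_tags_for

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort_path: str = ""
    cohort: CohortConfig = field(default_factory=CohortConfig)
    glasso: GlassoConfig = field(default_factory=GlassoConfig)
    matching: MatchConfig = field(default_factory=MatchConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    n_boot: int = 1000
    n_perm: int = 1000
    include_anxiety_node: bool = True
    seed: int = 0
    output_dir: str = "lldnet_results"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        kw = {}
        for key, sub in (("cohort", CohortConfig), ("glasso", GlassoConfig),
                         ("matching", MatchConfig), ("stats", StatsConfig)):
            if key in raw:
                kw[key] = sub(**raw.pop(key))
        kw.update(raw)
        return cls(**kw)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _comparisons_json(comps):
    return [
        {"variable": c.variable, "test": c.test_kind, "statistic": c.statistic,
         "df": c.df, "p_value": c.p_value}
        for c in comps
    ]


def run_study(config: PipelineConfig, cohort: CohortTable | None = None) -> dict:
    """Run the full pipeline; returns the manifest dict (also written to
    output_dir/manifest.json).  `cohort` overrides reading cohort_path."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "counts": {}, "artifacts": {}, "seed": config.seed}
    logger.info("config: %s", config)

    def done(stage, **info):
        manifest["stages"].append(stage)
        manifest["counts"].update(info)
        _write_manifest(manifest, out)

    try:
        if cohort is None:
            cohort = read_cohort(config.cohort_path)
        done("read", input=cohort.n)

        eligible = apply_eligibility(cohort, config.cohort)
        done("eligibility", **{f"eligibility_{k}": v for k, v in eligible.filter_log.items()},
             eligible=eligible.n)

        tags = cluster_tags_for([f"m{i}" for i in range(1, 11)] + ["anxiety"])
        assoc = association_matrix(eligible)
        baseline = fit_network(assoc, eligible.n, config.glasso, cluster_tags=tags)
        baseline.write(str(out / "baseline_network"))
        cent = centrality_table(baseline)
        cent.to_dataframe().to_csv(out / "baseline_centrality.csv", index=False)
        manifest["artifacts"]["baseline_network"] = str(out / "baseline_network.json")
        manifest["artifacts"]["baseline_centrality"] = str(out / "baseline_centrality.csv")
        done("baseline_network", baseline_edges=baseline.n_edges)

        boot = bootstrap_edges(eligible, config.glasso, n_boot=config.n_boot,
                               seed=stage_seed(config.seed, "bootstrap"))
        pd.DataFrame({
            "edge": [f"{a}--{b}" for a, b in
                     (tuple(baseline.labels[k] for k in ij) for ij in boot.edge_index())],
            "weight": boot.point_weights,
            "ci_low": boot.edge_ci_low,
            "ci_high": boot.edge_ci_high,
        }).to_csv(out / "baseline_bootstrap.csv", index=False)
        manifest["artifacts"]["baseline_bootstrap"] = str(out / "baseline_bootstrap.csv")
        done("bootstrap", bootstrap_failed=boot.n_failed)

        if config.include_anxiety_node:
            assoc_anx = association_matrix(eligible, include_anxiety_node=True)
            anx_net = fit_network(assoc_anx, eligible.n, config.glasso, cluster_tags=tags)
            anx_net.write(str(out / "anxiety_network"))
            manifest["artifacts"]["anxiety_network"] = str(out / "anxiety_network.json")
            done("anxiety_network", anxiety_edges=anx_net.n_edges)

        low, high = split_by_anxiety(eligible, config.cohort)
        done("split", low=low.n, high=high.n)

        pre_nct = nct(low, high, config.glasso, n_perm=config.n_perm,
                      seed=stage_seed(config.seed, "nct_pre"))
        pre_table = table2_report(low, high)
        manifest["pre_matching"] = {
            "p_strength": pre_nct.p_strength, "p_structure": pre_nct.p_structure,
            "s_observed": pre_nct.s_observed, "m_observed": pre_nct.m_observed,
            "table2": _comparisons_json(pre_table),
        }
        done("pre_matching_comparison")

        labeled = CohortTable(pd.concat([low.df, high.df], ignore_index=True))
        mres = match_cohort(labeled, config.matching)
        pd.DataFrame(mres.pairs, columns=["high_anxiety_id", "low_anxiety_id"]).to_csv(
            out / "matched_pairs.csv", index=False)
        mres.balance.to_csv(out / "balance.csv", index=False)
        manifest["artifacts"]["matched_pairs"] = str(out / "matched_pairs.csv")
        done("matching", matched_pairs=mres.n_matched)

        mlow, mhigh = matched_tables(labeled, mres)
        post_nct = nct(mlow, mhigh, config.glasso, n_perm=config.n_perm,
                       seed=stage_seed(config.seed, "nct_post"))
        post_table = table2_report(low, high, matched=mres, cohort=labeled)
        manifest["post_matching"] = {
            "p_strength": post_nct.p_strength, "p_structure": post_nct.p_structure,
            "s_observed": post_nct.s_observed, "m_observed": post_nct.m_observed,
            "table2": _comparisons_json([c for c in post_table if c.variable.endswith("_after")]),
        }
        done("post_matching_comparison", post_low=mlow.n, post_high=mhigh.n)
    except Exception as e:
        manifest["error"] = str(e)
        _write_manifest(manifest, out)
        raise

    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
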