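"""End-to-end analysis: per-metric pipeline plus cross-metric correction.

For every trait metric the pipeline (i) restricts the trait table to species
present in the tree, (ii) prunes the tree to those species, (iii) Box-Cox
transforms and standardizes the pooled values, (iv) grafts population
replicates as virtual sister-taxa, (v) decomposes the diversity among nodes,
and (vi) runs the conservation (S_c), skewness-to-root (S_3) and
phylogenetic-signal (C_mean) permutation tests.  Across metrics, p-values
are Hochberg-adjusted within each statistic family (one family per
statistic, never pooled across statistics).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import traits as traits_mod
from .decomp import decompose_diversity, s3_statistic, sc_statistic
from .inference import (
    InferenceError,
    TestResult,
    abouheif_test,
    conservation_test,
    hochberg_adjust,
    skewness_to_root_test,
)
from .phylo import (
    Tree,
    depth_ranks,
    enlarge_with_replicates,
    prune_to_taxa,
    read_newick_file,
)
from .traits import TraitTable, TraitValidationError, prepare_metric

__all__ = ["AnalysisConfig", "run_analysis", "analyze_metric"]

log = logging.getLogger("phylodiv")

HYPOTHESES = {
    "C_mean": "Phylogenetic signal",
    "S_c": "Intra-specific conservation",
    "S_3": "Skewness to root",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs and knobs for a full run.

    ``n_perm`` defaults to 1000 permutations; the seed is mandatory so every
    permutation test is reproducible.
    """

    tree_path: str
    traits_path: str
    output_dir: str
    seed: int
    metrics: Sequence[str] | str = "all"
    n_perm: int = 1000
    boxcox: bool = True

    def __post_init__(self):
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        if self.seed is None:
            raise ValueError("a seed is required")


def _subseed(seed: int, metric: str, test: str) -> int:
    """Stable per-(metric, test) seed derived from the master seed."""
    digest = np.random.SeedSequence(
        [seed, abs(hash_str(metric)), abs(hash_str(test))]
    ).generate_state(1)[0]
    return int(digest % (2**31))


def hash_str(s: str) -> int:
    # deterministic across processes (unlike built-in hash)
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


@dataclass
class MetricResult:
    metric: str
    n_species: int
    decomposition: pd.DataFrame
    tests: dict[str, TestResult] = field(default_factory=dict)


def analyze_metric(
    reference: Tree,
    table: TraitTable,
    metric: str,
    n_perm: int,
    seed: int,
    boxcox: bool = True,
) -> MetricResult | None:
    """Run the full pipeline for one metric; None if it must be skipped."""
    sub = table.for_metric(metric)
    tree_species = set(reference.tip_label.values())
    present = [sp for sp in sub["species"].unique() if sp in tree_species]
    dropped = sorted(set(sub["species"]) - set(present))
    if dropped:
        log.warning("%s: species absent from tree dropped: %s", metric, dropped)
    if len(present) < 2:
        log.warning("%s: fewer than 2 species in the tree; metric skipped", metric)
        return None

    sub = sub[sub["species"].isin(present)]
    restricted = traits_mod.from_records(sub)
    pruned = prune_to_taxa(reference, present)
    log.info("%s: %d species, %d measurements", metric, len(present), len(sub))

    prepared = prepare_metric(restricted, metric, boxcox=boxcox)
    design = restricted.replicate_design(metric)
    replicates = {sp: pops for sp, pops in design.items() if len(pops) >= 2}
    enlarged = enlarge_with_replicates(pruned, replicates)
    ranks = depth_ranks(reference, enlarged)

    dec = decompose_diversity(enlarged, prepared.tip_values)
    result = MetricResult(
        metric=metric,
        n_species=len(present),
        decomposition=dec.to_frame(enlarged.artificial_nodes, ranks),
    )

    # species means of the transformed, standardized values, on the pruned tree
    labels = pd.Series(prepared.tip_values)
    species_of = {
        enlarged.tree.tip_label[t]: sp
        for t, sp in enlarged.virtual_tip_species.items()
    }
    means = labels.groupby(labels.index.map(species_of)).mean().to_dict()

    if len(present) >= 3:
        result.tests["C_mean"] = abouheif_test(
            pruned, means, n_perm=n_perm, seed=_subseed(seed, metric, "C_mean")
        )
    else:
        log.warning("%s: fewer than 3 species; C_mean skipped", metric)

    if replicates:
        result.tests["S_c"] = conservation_test(
            enlarged, prepared.tip_values, n_perm=n_perm,
            seed=_subseed(seed, metric, "S_c"),
        )
    else:
        log.warning("%s: no replicated species; conservation test skipped", metric)

    result.tests["S_3"] = skewness_to_root_test(
        enlarged, prepared.tip_values, ranks, n_perm=n_perm,
        seed=_subseed(seed, metric, "S_3"),
    )
    return result


def run_analysis(config: AnalysisConfig) -> pd.DataFrame:
    """Run every requested metric and write reports to the output directory.

    Writes, per metric, a decomposition TSV and one JSON per test, and a
    cross-metric ``summary.tsv`` with Hochberg-adjusted p-values (adjusted
    within each statistic family across metrics).  Returns the summary table.
    """
    reference = read_newick_file(config.tree_path)
    table = traits_mod.read_trait_table(config.traits_path)
    metrics = (
        list(table.metrics) if config.metrics == "all" else list(config.metrics)
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    results: list[MetricResult] = []
    for metric in metrics:
        res = analyze_metric(
            reference, table, metric, config.n_perm, config.seed,
            boxcox=config.boxcox,
        )
        if res is not None:
            results.append(res)

    rows = []
    for res in results:
        mdir = outdir / res.metric
        mdir.mkdir(exist_ok=True)
        res.decomposition.to_csv(mdir / "decomposition.tsv", sep="\t",
                                 index=False, float_format="%.10g")
        for name, tr in res.tests.items():
            rows.append(
                {
                    "metric": res.metric,
                    "statistic": name,
                    "hypothesis": HYPOTHESES[name],
                    "alternative": tr.alternative,
                    "n_species": res.n_species,
                    "observed": tr.observed,
                    "p_value": tr.p_value,
                }
            )
    summary = pd.DataFrame(rows)

    if not summary.empty:
        summary["p_adjusted"] = np.nan
        for name in summary["statistic"].unique():
            mask = summary["statistic"] == name
            summary.loc[mask, "p_adjusted"] = hochberg_adjust(
                summary.loc[mask, "p_value"].to_numpy()
            )

    for res in results:
        mdir = outdir / res.metric
        for name, tr in res.tests.items():
            payload = tr.to_dict()
            hit = summary[
                (summary["metric"] == res.metric) & (summary["statistic"] == name)
            ]
            if not hit.empty:
                payload["p_adjusted"] = float(hit["p_adjusted"].iloc[0])
            fname = {"C_mean": "cmean", "S_c": "sc", "S_3": "s3"}[name]
            with open(mdir / f"{fname}.json", "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")

    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False,
                   float_format="%.10g")
    return summary
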