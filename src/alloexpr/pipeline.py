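"""Full-pipeline orchestration: simulate or load, analyse, report.

``run_all`` executes the complete analysis sequence for every polyploid
individual — differential expression against each parent, the 12-category
classification, mid-parent non-additivity, homoeolog bias transitions and
activation/silencing — followed by the cross-individual set report and the
optional trait dendrogram. Every intermediate table is written as TSV under
the output directory, together with a machine-readable run manifest
(parameters, seed, package version, input checksums). Reruns under one
configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import bias_summary, hybrid_bias, parental_bias, transition_table
from .de import de_table, size_factors_median_of_ratios
from .eld import classify_individual, pair_level_matrix, pattern_summary
from .io import (
    CountMatrix,
    HomoeologPairTable,
    SampleSheet,
    TraitMatrix,
    PARENT_A,
    PARENT_C,
    POLYPLOID,
    read_counts,
    read_pairs,
    read_sample_sheet,
    read_traits,
    write_table,
)
from .mpv import build_mpv, test_nonadditive
from .sets import derive_pattern_sets, family_from_lists, set_report, trait_cluster
from .silencing import SILENCED, NOVEL, silencing_calls, silencing_summary
from .simulate import SimConfig, simulate

log = logging.getLogger("alloexpr")


@dataclass
class RunConfig:
    """Pipeline configuration (paths to inputs, or a simulation block)."""

    counts: str | None = None
    samples: str | None = None
    pairs: str | None = None
    traits: str | None = None
    simulate: dict | None = None
    alpha: float = 0.05
    cpm_threshold: float = 10.0
    outdir: str = "results/run"
    seed: int = 0
    run_silencing: bool = True
    run_bias: bool = True
    run_mpv: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.cpm_threshold <= 0:
            raise ValueError("cpm_threshold must be positive")


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _load_inputs(
    config: RunConfig,
) -> tuple[CountMatrix, SampleSheet, HomoeologPairTable, TraitMatrix | None, dict]:
    meta: dict = {}
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim = simulate(SimConfig(**sim_kwargs))
        meta["inputs"] = {"simulated": sim_kwargs}
        traits = None
        if config.traits:
            traits = read_traits(config.traits)
        return sim.counts, sim.sheet, sim.pairs, traits, meta
    if not (config.counts and config.samples and config.pairs):
        raise ValueError("need counts, samples and pairs paths (or a simulate block)")
    sheet = read_sample_sheet(config.samples)
    counts = read_counts(config.counts, sheet)
    pairs = read_pairs(config.pairs)
    traits = read_traits(config.traits) if config.traits else None
    meta["inputs"] = {
        "counts": {"path": str(config.counts), "sha256": _checksum(config.counts)},
        "samples": {"path": str(config.samples), "sha256": _checksum(config.samples)},
        "pairs": {"path": str(config.pairs), "sha256": _checksum(config.pairs)},
    }
    return counts, sheet, pairs, traits, meta


def run_all(
    config: RunConfig,
    counts: CountMatrix | None = None,
    sheet: SampleSheet | None = None,
    pairs: HomoeologPairTable | None = None,
    traits: TraitMatrix | None = None,
    write: bool = True,
) -> dict:
    """Run every analysis stage; return (and optionally write) all tables.

    In-memory inputs may be passed directly, bypassing the paths in
    ``config``. Any stage error aborts with the stage name in the message.
    """
    outdir = Path(config.outdir)
    meta: dict = {}
    alpha = config.alpha
    results: dict = {}

    def stage(name: str):
        log.info("stage: %s", name)
        return name

    try:
        stage("load_inputs")
        if counts is None or sheet is None or pairs is None:
            counts, sheet, pairs, traits_loaded, meta = _load_inputs(config)
            traits = traits if traits is not None else traits_loaded
        stage("pair_matrix")
        pm = pair_level_matrix(counts, pairs, sheet)
        sf = size_factors_median_of_ratios(pm)
        n_pairs = len(pairs)

        stage("parent_vs_parent")
        cols_a = pm.sample_cols(sheet.samples_of(PARENT_A))
        cols_c = pm.sample_cols(sheet.samples_of(PARENT_C))
        de_ac = de_table(
            pm.gene_ids, pm.counts[:, cols_a], pm.counts[:, cols_c],
            sf[cols_a], sf[cols_c], alpha,
        )
        results["de_parents"] = de_ac.frame
        if config.run_mpv:
            mpv = build_mpv(pm, sheet, sf)
        if config.run_bias:
            stage("parental_bias")
            _, parent_states = parental_bias(counts, pairs, sheet, alpha, sf)

        assignments: dict[str, pd.DataFrame] = {}
        nonadd_sets: dict[str, set] = {}
        sil_sets: dict[str, set] = {}
        nov_sets: dict[str, set] = {}
        all_sil_calls = []
        summary_rows = []
        for individual in sheet.individuals:
            stage(f"individual {individual}")
            cols_t = pm.sample_cols(sheet.samples_of(POLYPLOID, individual))
            de_ta = de_table(
                pm.gene_ids, pm.counts[:, cols_a], pm.counts[:, cols_t],
                sf[cols_a], sf[cols_t], alpha,
            )
            de_tc = de_table(
                pm.gene_ids, pm.counts[:, cols_c], pm.counts[:, cols_t],
                sf[cols_c], sf[cols_t], alpha,
            )
            results[f"de_vs_A_{individual}"] = de_ta.frame
            results[f"de_vs_C_{individual}"] = de_tc.frame
            assign = classify_individual(de_ta, de_tc, de_ac, individual)
            assignments[individual] = assign
            results[f"eld_{individual}"] = assign
            results[f"eld_summary_{individual}"] = pattern_summary(assign, n_pairs)
            row = {
                "individual": individual,
                "deg_up_vs_A": int((de_ta.frame["call"] == "UP_B").sum()),
                "deg_down_vs_A": int((de_ta.frame["call"] == "UP_A").sum()),
                "deg_up_vs_C": int((de_tc.frame["call"] == "UP_B").sum()),
                "deg_down_vs_C": int((de_tc.frame["call"] == "UP_A").sum()),
            }
            if config.run_mpv:
                nonadd_table, frac = test_nonadditive(
                    pm, sheet, individual, alpha, sf, mpv
                )
                results[f"nonadditive_{individual}"] = nonadd_table.frame
                row["nonadditive_fraction"] = frac
                nonadd_sets[individual] = set(
                    nonadd_table.frame.loc[nonadd_table.frame["nonadditive"], "unit_id"]
                )
            if config.run_bias:
                _, hyb_states = hybrid_bias(counts, pairs, sheet, individual, alpha, sf)
                trans = transition_table(parent_states, hyb_states)
                results[f"bias_{individual}"] = trans
                results[f"bias_summary_{individual}"] = bias_summary(trans)
                row["hybrid_A_bias"] = int((hyb_states == "A_BIAS").sum())
                row["hybrid_C_bias"] = int((hyb_states == "C_BIAS").sum())
            if config.run_silencing:
                calls = silencing_calls(
                    counts, pairs, sheet, individual, config.cpm_threshold
                )
                all_sil_calls.append(calls)
                sil = calls[calls["status"] == SILENCED]
                nov = calls[calls["status"] == NOVEL]
                sil_sets[individual] = set(sil["gene_id"])
                nov_sets[individual] = set(nov["gene_id"])
                for sg in ("A", "C"):
                    row[f"silenced_{sg}"] = int((sil["subgenome"] == sg).sum())
                    row[f"novel_{sg}"] = int((nov["subgenome"] == sg).sum())
            summary_rows.append(row)

        results["individual_summary"] = pd.DataFrame(summary_rows)
        if config.run_silencing and all_sil_calls:
            calls = pd.concat(all_sil_calls, ignore_index=True)
            results["silencing_calls"] = calls[calls["status"] != "NEITHER"]
            results["silencing_summary"] = silencing_summary(calls)

        stage("cross_individual_sets")
        families = derive_pattern_sets(assignments)
        if nonadd_sets:
            families["NONADDITIVE"] = family_from_lists("NONADDITIVE", nonadd_sets)
        if sil_sets:
            families["SILENCED"] = family_from_lists("SILENCED", sil_sets)
            families["NOVEL"] = family_from_lists("NOVEL", nov_sets)
        results["set_report"] = pd.concat(
            [set_report(f) for f in families.values()], ignore_index=True
        )

        if traits is not None:
            stage("trait_cluster")
            merges, leaf_order = trait_cluster(traits)
            results["trait_dendrogram"] = merges
            results["trait_leaf_order"] = pd.DataFrame({"leaf": leaf_order})
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in results.items():
            write_table(table, outdir / f"{name}.tsv")
        manifest = {
            "package_version": __version__,
            "alpha": alpha,
            "cpm_threshold": config.cpm_threshold,
            "seed": config.seed,
            "n_pairs": len(pairs),
            "individuals": sheet.individuals,
            **meta,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return results
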