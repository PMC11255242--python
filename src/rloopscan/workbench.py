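"""End-to-end orchestration of the synthetic experiment.

simulate -> call peaks -> compare conditions -> context -> sequence
features -> classifier -> genome scan -> differential expression ->
association -> two-species contrast, with one report per run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expr_assoc, peakcall, rloopclf, seqfeat, simgen
from .genome import GenomeBundle

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "rloopscan_run"
    profile_a: simgen.SpeciesProfile = field(
        default_factory=lambda: replace(simgen.HUMAN_LIKE)
    )
    profile_b: simgen.SpeciesProfile = field(
        default_factory=lambda: replace(simgen.MOUSE_LIKE)
    )
    sim: simgen.SimulationConfig = field(default_factory=simgen.SimulationConfig)
    motif_law: simgen.MotifLaw = field(default_factory=simgen.MotifLaw)
    peaks: peakcall.PeakParams = field(default_factory=peakcall.PeakParams)
    tss_window: int = 1000
    tts_window: int = 1000
    min_trun: int = 5
    lfc_thresh: float = 1.0
    q_thresh: float = 0.05
    scan_window: int = 150
    scan_step: int = 50
    scan_min_trun: int = 8  # stricter than min_trun: screens scan windows
    metaprofile_flank: int = 500
    write_files: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, replace(current, **value))
            else:
                setattr(cfg, key, value)
        return cfg


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema/range checks; returns a list of violations (empty when valid)."""
    problems: list[str] = []
    problems.extend(config.sim.validate())
    for profile in (config.profile_a, config.profile_b):
        problems.extend(f"{profile.name}: {p}" for p in profile.validate())
    if config.peaks.min_width < 1:
        problems.append("peaks.min_width must be >= 1")
    if config.peaks.pval_cut <= 0 or config.peaks.pval_cut >= 1:
        problems.append("peaks.pval_cut must lie in (0, 1)")
    if config.scan_window < config.peaks.min_width:
        problems.append("scan_window must be >= peaks.min_width")
    if config.scan_step < 1:
        problems.append("scan_step must be >= 1")
    if config.sim.n_replicates < 2:
        problems.append("n_replicates must be >= 2 for differential testing")
    if config.min_trun < 1:
        problems.append("min_trun must be >= 1")
    return problems


def _context_fraction(labelled: list, label: str) -> float:
    if not labelled:
        return float("nan")
    return sum(1 for _, lab in labelled if lab == label) / len(labelled)


def run_species(
    profile: simgen.SpeciesProfile, config: PipelineConfig, out: Path | None
) -> dict:
    """All single-species stages; returns a result dict with tables."""
    sim_cfg = replace(config.sim, seed=stage_seed(config.seed, f"sim:{profile.name}"))
    dataset = simgen.simulate_dataset(profile, sim_cfg, config.motif_law)
    bundle, truth = dataset.bundle, dataset.truth
    if out is not None:
        simgen.write_dataset(dataset, out)

    peaks = {
        cond: peakcall.call_peaks(dataset.coverage[cond], config.peaks)
        for cond in ("control", "kd")
    }
    comparison = peakcall.compare_peak_sets(peaks["control"], peaks["kd"])
    length_stats = (
        peakcall.peak_length_stats(peaks["control"], peaks["kd"])
        if peaks["control"] and peaks["kd"]
        else None
    )

    labelled_common, _ = peakcall.annotate_context(
        [b for _, b in comparison.common], bundle, config.tss_window, config.tts_window
    )
    labelled_gained, _ = peakcall.annotate_context(
        comparison.gained, bundle, config.tss_window, config.tts_window
    )

    kd_assoc, _ = seqfeat.associate_t_runs(peaks["kd"], bundle, config.min_trun)
    ctrl_assoc, _ = seqfeat.associate_t_runs(peaks["control"], bundle, config.min_trun)

    anchors = [(p.chrom, p.summit, p.strand) for p in peaks["kd"]]
    profile_vec, n_used, n_dropped = (
        peakcall.metaprofile(
            dataset.coverage["kd"], anchors, config.metaprofile_flank
        )
        if anchors
        else (np.array([]), 0, 0)
    )

    labelled_assoc, _ = peakcall.annotate_context(
        kd_assoc, bundle, config.tss_window, config.tts_window
    )
    gb_assoc = [p for p, lab in labelled_assoc if lab == "GB"]

    # G% vs T-run-length trend on genebody T-run-associated peaks
    trun_feats = [
        f
        for f in (
            seqfeat.region_features(p, bundle, config.min_trun) for p in gb_assoc
        )
        if f.max_trun >= config.min_trun
    ]
    gbins = (
        seqfeat.gpct_by_trun_bins(trun_feats) if len(trun_feats) > 2 else None
    )

    model = None
    scan_counts = pd.Series(0, index=[g.gene_id for g in bundle.genes])
    hits = []
    if len(gb_assoc) >= 20:
        # positives: scan-window-sized sequences centered on the summits of
        # genebody T-run-associated peaks, so training and scanning share one
        # feature definition; negatives: length-matched random gene regions
        w = config.scan_window
        pos_rows = []
        for p in gb_assoc:
            chrom_len = bundle.chrom_length(p.chrom)
            start = min(max(0, p.summit - w // 2), max(0, chrom_len - w))
            seq = bundle.fetch(p.chrom, start, min(chrom_len, start + w), p.strand)
            pos_rows.append(rloopclf.window_features(seq))
        pos = np.array(pos_rows)
        rand = seqfeat.sample_random_regions(
            bundle,
            n=len(gb_assoc),
            lengths=[w] * len(gb_assoc),
            seed=stage_seed(config.seed, f"rand:{profile.name}"),
        )
        neg = np.array(
            [
                rloopclf.window_features(seqfeat.extract_sense_sequence(p, bundle))
                for p in rand
            ]
        )
        model = rloopclf.train_classifier(
            pos, neg, seed=stage_seed(config.seed, f"clf:{profile.name}")
        )
        hits = rloopclf.scan_genome(
            model,
            bundle,
            window=config.scan_window,
            step=config.scan_step,
            min_trun=config.scan_min_trun,
        )
        scan_counts = rloopclf.count_hits_per_gene(hits, bundle)

    labels = ["control"] * sim_cfg.n_replicates + ["kd"] * sim_cfg.n_replicates
    de = expr_assoc.de_test(
        dataset.counts, labels, config.lfc_thresh, config.q_thresh
    )
    truth_idx = truth.genes.set_index("gene_id")
    assoc = expr_assoc.association_report(
        de.classes(),
        truth_idx["length"],
        truth_idx["motif_count"],
    )

    return {
        "profile": profile,
        "dataset": dataset,
        "bundle": bundle,
        "truth": truth,
        "peaks": peaks,
        "comparison": comparison,
        "length_stats": length_stats,
        "labelled_common": labelled_common,
        "labelled_gained": labelled_gained,
        "t_run_associated": {"control": ctrl_assoc, "kd": kd_assoc},
        "metaprofile": {
            "profile": profile_vec,
            "n_used": n_used,
            "n_dropped": n_dropped,
        },
        "gpct_bins": gbins,
        "model": model,
        "scan_hits": hits,
        "scan_counts": scan_counts,
        "de": de,
        "association": assoc,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run both species profiles plus the cross-species contrast.

    Writes the report (JSON + TSV tables) under ``config.out_dir`` when
    ``config.write_files`` is set; always returns the in-memory report.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))
    out = Path(config.out_dir) if config.write_files else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    results = {}
    for profile in (config.profile_a, config.profile_b):
        logger.info("running species profile %s", profile.name)
        species_out = out / profile.name if out is not None else None
        try:
            results[profile.name] = run_species(profile, config, species_out)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for species {profile.name}: {exc}"
            ) from exc

    name_a, name_b = config.profile_a.name, config.profile_b.name
    res_a, res_b = results[name_a], results[name_b]
    truth_a = res_a["truth"].genes.set_index("gene_id")
    truth_b = res_b["truth"].genes.set_index("gene_id")
    n_orth = min(len(truth_a), len(truth_b))
    ortholog_map = pd.DataFrame(
        {"gene_a": truth_a.index[:n_orth], "gene_b": truth_b.index[:n_orth]}
    )
    species = expr_assoc.cross_species_compare(
        res_a["association"],
        res_b["association"],
        truth_a["length"],
        truth_b["length"],
        ortholog_map,
    )

    report = build_report(config, results, species)
    if out is not None:
        write_report(report, results, out)
    return {"report": report, "results": results, "species_contrast": species}


def build_report(config: PipelineConfig, results: dict, species: dict) -> dict:
    report: dict = {"seed": config.seed, "species": {}}
    for name, res in results.items():
        comp = res["comparison"]
        de_classes = res["de"].table["class"].value_counts().to_dict()
        entry = {
            "n_genes": len(res["bundle"].genes),
            "n_motifs": len(res["truth"].motifs),
            "n_peaks_control": len(res["peaks"]["control"]),
            "n_peaks_kd": len(res["peaks"]["kd"]),
            "n_common": len(comp.common),
            "n_gained": len(comp.gained),
            "n_lost": len(comp.lost),
            "gb_fraction_common": _context_fraction(res["labelled_common"], "GB"),
            "gb_fraction_gained": _context_fraction(res["labelled_gained"], "GB"),
            "n_trun_associated_control": len(res["t_run_associated"]["control"]),
            "n_trun_associated_kd": len(res["t_run_associated"]["kd"]),
            "de_classes": de_classes,
            "n_scan_hits": len(res["scan_hits"]),
        }
        if res["length_stats"]:
            entry["median_width_control"] = res["length_stats"]["median_a"]
            entry["median_width_kd"] = res["length_stats"]["median_b"]
            entry["width_mwu_p"] = res["length_stats"]["p_value"]
        if res["model"] is not None:
            entry["cv_accuracy"] = res["model"].cv_accuracy
            entry["auc"] = res["model"].auc
        if res["gpct_bins"] is not None:
            entry["gpct_trun_spearman"] = res["gpct_bins"].attrs["spearman_rho"]
        tests = res["association"].tests
        for _, row in tests.iterrows():
            entry[f"assoc_{row.comparison}_{row.covariate}_p"] = (
                None if row.skipped else float(row.p_value)
            )
        report["species"][name] = entry
    report["cross_species"] = {
        "affected_ratio_a_over_b": species["affected_ratio_a_over_b"],
        "median_length_a": species["median_length_a"],
        "median_length_b": species["median_length_b"],
        "species_a": {
            k: v for k, v in species["species_a"].items() if k != "length_effect"
        }
        | {"length_effect_p": species["species_a"]["length_effect"]["p_value"]},
        "species_b": {
            k: v for k, v in species["species_b"].items() if k != "length_effect"
        }
        | {"length_effect_p": species["species_b"]["length_effect"]["p_value"]},
    }
    return report


def write_report(report: dict, results: dict, out: Path) -> None:
    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=default, allow_nan=True)
    for name, res in results.items():
        species_out = out / name
        species_out.mkdir(parents=True, exist_ok=True)
        res["de"].table.to_csv(species_out / "de.tsv", sep="\t", index=False)
        res["association"].summary.to_csv(
            species_out / "association_summary.tsv", sep="\t", index=False
        )
        res["association"].tests.to_csv(
            species_out / "association_tests.tsv", sep="\t", index=False
        )
        res["scan_counts"].rename_axis("gene_id").to_csv(
            species_out / "scan_counts.tsv", sep="\t"
        )
        for cond in ("control", "kd"):
            peakcall.write_bed(
                res["peaks"][cond], species_out / f"peaks.{cond}.bed"
            )
        if res["model"] is not None:
            res["model"].save(species_out / "model.txt")
        if res["gpct_bins"] is not None:
            res["gpct_bins"].to_csv(
                species_out / "gpct_by_trun.tsv", sep="\t", index=False
            )
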