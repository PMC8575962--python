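"""Configuration-driven end-to-end study: simulate -> detect -> network ->
classify -> enrich -> map -> date.

Every stage derives its own child seed from the global seed by a fixed
counter scheme, so stages are individually reproducible. Threshold
applications log input/output counts to make the match funnel auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .age import ClockParams, extract_observation, generations_to_years, posterior_mode
from .ancestry import test_communities, test_ethnicities
from .geomaps import export_map, location_enrichment, small_set_mode
from .ibd import build_match_sets, detect_ibd, write_match_file
from .network import (
    build_network,
    classify_carriers,
    degree_histogram,
    degree_of_sharing,
    evaluate_calls,
    export_calls,
    export_edge_list,
    export_graphml,
    penetrance,  # noqa: F401  (re-exported for report consumers)
)
from .simdata import (
    AnnotationConfig,
    FocalAllele,
    PedigreeExtinctionError,
    annotate_samples,
    drop_haplotypes,
    make_genetic_map,
    plant_focal_allele,
    simulate_background,
    simulate_pedigree,
    write_study,
)

__all__ = ["StudyConfig", "validate_config", "run_study"]

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "carriers", "background", "annotate", "detect", "age")


@dataclass
class StudyConfig:
    seed: int
    # pedigree
    n_generations: int = 8
    mean_offspring: float = 2.5
    max_pedigree_size: int = 3000
    max_ascertainment_attempts: int = 200
    # marker panel / map
    n_chromosomes: int = 3
    chrom_length_cm: float = 150.0
    n_markers_per_chrom: int = 3000
    freq_min: float = 0.05
    freq_max: float = 0.95
    # focal allele
    focal_chrom: str = "chr1"
    focal_cm: float = 75.0
    window_half_cm: float = 2.0
    # cohort
    background_size: int = 2000
    n_known_carriers: int = 5
    known_carrier_min_generation: int = 4
    # detection thresholds
    word_size: int = 64
    detect_min_cm: float = 1.0
    genome_threshold_cm: float = 6.0
    locus_threshold_cm: float = 1.0
    max_hom_mismatches: int = 0
    ibs_filter: bool = False
    genotype_error_rate: float = 0.0
    # enrichment
    ethnicity_alpha: float = 0.05
    community_alpha: float = 0.001
    min_fold: float = 1.5
    null_annotations: bool = False
    # geo
    geo_rounding: int = 0
    geo_min_trees: int = 10
    geo_min_or: float = 4.0
    small_set_min_trees: int = 2
    scatter_sd_deg: float = 0.5
    # clocks
    recomb_rate: float = 1e-8
    mut_rate: float = 1.25e-8
    ne: float = 10_000.0
    generation_time: float = 25.0
    age_clock: str = "recombination"  # no mutation process in the simulator

    def stage_seed(self, stage: str) -> int:
        return self.seed * 1009 + _STAGES.index(stage)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        cfg, errors = validate_config(json.loads(text))
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        return cfg


def validate_config(raw: dict) -> tuple[StudyConfig | None, list[str]]:
    """Validate a raw JSON dict into a StudyConfig; returns (config, errors)."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config must be a JSON object"]
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown fields: {sorted(unknown)}")
    if "seed" not in raw:
        errors.append("missing required field: seed")
    elif not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")
    if errors:
        return None, errors
    cfg = StudyConfig(**{k: v for k, v in raw.items() if k in known})
    for name in ("detect_min_cm", "genome_threshold_cm", "locus_threshold_cm",
                 "chrom_length_cm", "mean_offspring", "ethnicity_alpha",
                 "community_alpha", "recomb_rate", "mut_rate", "ne",
                 "generation_time"):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive")
    if cfg.n_known_carriers < 1:
        errors.append("n_known_carriers must be >= 1")
    if cfg.n_generations < 2:
        errors.append("n_generations must be >= 2")
    if cfg.background_size < 0:
        errors.append("background_size must be >= 0")
    if cfg.word_size < 8:
        errors.append("word_size must be >= 8")
    if cfg.focal_chrom not in {f"chr{i}" for i in range(1, cfg.n_chromosomes + 1)}:
        errors.append(f"focal_chrom {cfg.focal_chrom} not in simulated chromosomes")
    if not 0 <= cfg.focal_cm <= cfg.chrom_length_cm:
        errors.append("focal_cm outside chromosome span")
    if cfg.age_clock not in ("recombination", "mutation", "joint"):
        errors.append("age_clock must be recombination | mutation | joint")
    return (None, errors) if errors else (cfg, [])


def _ascertain_family(config: StudyConfig, gmap, panel):
    """Simulate pedigrees until one is ascertainable: the planted allele must
    segregate in at least ``n_known_carriers`` individuals and the family must
    fit the size cap. Mirrors real-world ascertainment (families enter such a
    study *because* the allele segregates broadly); deterministic in the seed
    via a fixed sub-seed counter.
    """
    base = config.stage_seed("simulate")
    focal_bp = int(round(gmap.cm_to_bp(config.focal_chrom, config.focal_cm)))
    w_lo = int(round(gmap.cm_to_bp(config.focal_chrom, config.focal_cm - config.window_half_cm)))
    w_hi = int(round(gmap.cm_to_bp(config.focal_chrom, config.focal_cm + config.window_half_cm)))
    last_reason = "no attempt made"
    for attempt in range(config.max_ascertainment_attempts):
        sub = base + 7919 * attempt
        try:
            pedigree = simulate_pedigree(
                config.n_generations, config.mean_offspring, sub,
                max_size=config.max_pedigree_size,
            )
        except (PedigreeExtinctionError, ValueError) as exc:
            last_reason = str(exc)
            continue
        hapset = drop_haplotypes(pedigree, gmap, panel, sub)
        founder_hap = f"{sorted(pedigree.founders)[0]}.0"
        focal = FocalAllele(config.focal_chrom, focal_bp, w_lo, w_hi, founder_hap)
        carriers = plant_focal_allele(pedigree, hapset, focal)
        if len(carriers) < config.n_known_carriers:
            last_reason = f"only {len(carriers)} carriers segregate"
            continue
        if attempt:
            logger.info("family ascertained on attempt %d", attempt + 1)
        return pedigree, hapset, focal, carriers
    raise RuntimeError(
        f"no ascertainable family in {config.max_ascertainment_attempts} "
        f"attempts (last: {last_reason})"
    )


def _select_known_carriers(pedigree, carriers: list[str], cfg: StudyConfig) -> list[str]:
    if len(carriers) < cfg.n_known_carriers:
        raise RuntimeError(
            f"only {len(carriers)} carriers segregate; need {cfg.n_known_carriers}"
        )
    eligible = sorted(
        c for c in carriers
        if pedigree[c].generation >= cfg.known_carrier_min_generation
    )
    if len(eligible) < cfg.n_known_carriers:
        eligible = sorted(carriers)
    rng = np.random.default_rng(cfg.stage_seed("carriers"))
    return sorted(rng.choice(eligible, size=cfg.n_known_carriers, replace=False))


def run_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline; returns the report dict (also written as
    ``report.json`` beside all stage files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "study_config.json").write_text(config.to_json())
    report: dict = {"software_version": __version__, "config": json.loads(config.to_json())}

    # --- simulate ------------------------------------------------------
    gmap, panel = make_genetic_map(
        config.n_chromosomes, config.chrom_length_cm, config.n_markers_per_chrom,
        config.stage_seed("simulate"), freq_range=(config.freq_min, config.freq_max),
    )
    pedigree, hapset, focal, carriers = _ascertain_family(config, gmap, panel)
    known_carriers = _select_known_carriers(pedigree, carriers, config)
    background = simulate_background(
        config.background_size, panel, gmap, config.stage_seed("background")
    )
    cohort = hapset.merged_with(background)
    logger.info(
        "simulated pedigree of %d (%d carriers) + %d background",
        len(pedigree), len(carriers), config.background_size,
    )
    report["simulate"] = {
        "pedigree_size": len(pedigree),
        "n_true_carriers": len(carriers),
        "known_carriers": known_carriers,
        "focal": dataclasses.asdict(focal),
    }

    # --- annotate ------------------------------------------------------
    descendants = sorted(pedigree.descendants_of(sorted(pedigree.founders)[0]))
    ann_cfg = AnnotationConfig(
        scatter_sd_deg=config.scatter_sd_deg, null=config.null_annotations
    )
    annotations, birth_records = annotate_samples(
        descendants, background.sample_ids, ann_cfg, config.stage_seed("annotate")
    )

    # --- detect --------------------------------------------------------
    detect_input = cohort
    if config.genotype_error_rate > 0:
        from .simdata import apply_genotype_error

        detect_input = apply_genotype_error(
            cohort, config.genotype_error_rate, config.stage_seed("detect")
        )
    segments = detect_ibd(
        detect_input,
        word_size=config.word_size,
        min_length_cm=config.detect_min_cm,
        max_hom_mismatches=config.max_hom_mismatches,
        ibs_filter=config.ibs_filter,
        target_ids=known_carriers,
    )
    write_match_file(out / "segments.match", segments)
    matches = build_match_sets(
        segments, known_carriers, focal, gmap,
        config.genome_threshold_cm, config.locus_threshold_cm,
    )
    logger.info(
        "threshold funnel: %d segments -> %d genetic matches (> %.1f cM) -> "
        "%d at-locus (> %.1f cM)",
        len(segments), len(matches.genetic_matches), config.genome_threshold_cm,
        len(matches.at_locus_matches), config.locus_threshold_cm,
    )

    # --- network / classify -------------------------------------------
    graph = build_network(segments, matches, total_map_cm=gmap.total_length_cm())
    export_edge_list(graph, out / "network_edges.csv")
    export_graphml(graph, out / "network.graphml")
    profile = degree_of_sharing(matches, known_carriers, config.locus_threshold_cm)
    universe = [s for s in cohort.sample_ids if s not in set(known_carriers)]
    calls = classify_carriers(profile, known_carriers, all_samples=universe)
    export_calls(calls, out / "carrier_calls.csv")
    histogram = degree_histogram(calls)
    putative = [c.sample_id for c in calls if c.label == "putative_carrier"]
    truth = {
        sid: (sid in pedigree and pedigree[sid].carrier) for sid in universe
    }
    metrics = evaluate_calls(calls, truth)
    report["matching"] = {
        "n_segments": len(segments),
        "n_genetic_matches": len(matches.genetic_matches),
        "n_at_locus": len(matches.at_locus_matches),
        "degree_histogram": {str(k): v for k, v in sorted(histogram.items())},
        "n_putative_carriers": len(putative),
        "putative_carriers": sorted(putative),
        "evaluation": metrics,
    }

    # --- enrich --------------------------------------------------------
    in_ids = sorted(set(matches.genetic_matches) & set(annotations))
    report["enrichment"] = {"in_group_size": len(in_ids)}
    if len(in_ids) >= 2:
        in_ann = {s: annotations[s] for s in in_ids}
        bg_ann = {s: a for s, a in annotations.items() if s not in set(in_ids)}
        eth = test_ethnicities(in_ann, bg_ann, config.ethnicity_alpha)
        com = test_communities(
            in_ann, bg_ann, alpha=config.community_alpha, min_fold=config.min_fold
        )
        report["enrichment"]["ethnicity"] = [dataclasses.asdict(r) for r in eth]
        report["enrichment"]["communities"] = [dataclasses.asdict(r) for r in com]
        report["enrichment"]["ethnicity_pass"] = [r.region for r in eth if r.passes]
        report["enrichment"]["community_pass"] = [r.community for r in com if r.passes]

    # --- geomap --------------------------------------------------------
    in_trees = {f"T_{s}" for s in in_ids}
    in_records = [r for r in birth_records if r.tree_id in in_trees]
    bg_records = [r for r in birth_records if r.tree_id not in in_trees]
    cells = location_enrichment(
        in_records, bg_records, rounding=config.geo_rounding,
        min_trees=config.geo_min_trees, min_or=config.geo_min_or,
    )
    export_map(cells, out / "map_cells.geojson", out / "map_cells.csv")
    carrier_trees = {f"T_{s}" for s in putative}
    carrier_records = [r for r in birth_records if r.tree_id in carrier_trees]
    small_cells = small_set_mode(
        carrier_records, bg_records, min_trees=config.small_set_min_trees,
        min_or=config.geo_min_or,
    )
    export_map(small_cells, out / "map_cells_small_set.geojson")
    report["geomap"] = {
        "n_cells": len(cells),
        "n_passing_cells": sum(c.passes for c in cells),
        "n_small_set_passing": sum(c.passes for c in small_cells),
    }

    # --- age -----------------------------------------------------------
    params = ClockParams(config.recomb_rate, config.mut_rate, config.ne,
                         config.generation_time)
    pair = _most_distant_pair(pedigree, known_carriers)
    controls = background.sample_ids[:99]
    obs = extract_observation(cohort, pair[0], pair[1], focal, control_ids=controls)
    est = posterior_mode([obs], params, clock=config.age_clock)
    report["age"] = {
        "pair": list(pair),
        "pair_meioses": pedigree.meioses_between(*pair),
        "observation": dataclasses.asdict(obs),
        "mode_generations": est.mode,
        "interval_generations": [est.lower, est.upper],
        "interval_mass": est.interval_mass,
        "clock": est.clock,
        "mode_years": generations_to_years(est.mode, config.generation_time),
    }

    # --- persist -------------------------------------------------------
    write_study(
        out / "study", gmap=gmap, panel=panel, pedigree=pedigree, hapset=cohort,
        focal=focal, annotations=annotations, birth_records=birth_records,
    )
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _most_distant_pair(pedigree, known_carriers: list[str]) -> tuple[str, str]:
    best, best_m = None, -1
    for i, a in enumerate(known_carriers):
        for b in known_carriers[i + 1:]:
            m = pedigree.meioses_between(a, b)
            if m is not None and m > best_m:
                best, best_m = (a, b), m
    if best is None:
        raise RuntimeError("no related carrier pair for age estimation")
    return best
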