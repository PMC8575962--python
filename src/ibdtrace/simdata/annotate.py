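"""Simulated ancestry annotations and genealogical birth records.

Pedigree-descended samples draw ethnicity proportion vectors with elevated
weight on the planted regions, receive an enriched community label with
elevated probability, and emit birth records clustered around a per-time-bin
migration waypoint. Background samples draw from a diffuse baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AncestryAnnotation",
    "BirthRecord",
    "AnnotationConfig",
    "TIME_BINS",
    "annotate_samples",
]

# half-open on the left two, final bin closed: [1700,1800), [1800,1850), [1850,1910]
TIME_BINS: tuple[tuple[int, int], ...] = ((1700, 1800), (1800, 1850), (1850, 1910))


@dataclass
class AncestryAnnotation:
    sample_id: str
    ethnicity: dict[str, float]  # region -> proportion, sums to 1
    communities: frozenset[str]

    def __post_init__(self) -> None:
        total = sum(self.ethnicity.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: proportions sum to {total}, not 1")
        if any(v < 0 for v in self.ethnicity.values()):
            raise ValueError(f"{self.sample_id}: negative proportion")


@dataclass
class BirthRecord:
    tree_id: str
    ancestor_id: str
    year: int
    lat: float  # rounded to `rounding` decimals at construction
    lon: float

    def __post_init__(self) -> None:
        if not -90 <= self.lat <= 90 or not -180 <= self.lon <= 180:
            raise ValueError("coordinates outside world bounds")


@dataclass
class AnnotationConfig:
    """Planted enrichment structure.

    ``waypoints`` holds one (lat, lon) per time bin; fewer waypoints than
    bins is rejected. Setting ``null=True`` makes the in-group draw from the
    background distributions (no planted signal).
    """

    regions: tuple[str, ...] = ("region_A", "region_B", "region_C", "region_D")
    enriched_regions: tuple[str, ...] = ("region_A", "region_B")
    enriched_weight: float = 6.0  # Dirichlet weight multiplier for planted regions
    concentration: float = 20.0  # total Dirichlet concentration
    communities: tuple[str, ...] = tuple(f"community_{i:02d}" for i in range(20))
    enriched_community: str = "community_00"
    p_community_in: float = 0.8  # P(enriched label | in-group)
    p_community_bg: float = 0.05  # P(any given label | background)
    waypoints: tuple[tuple[float, float], ...] = (
        (56.0, 10.0),
        (42.0, -75.0),
        (40.7, -111.9),
    )
    scatter_sd_deg: float = 1.0
    records_per_tree_per_bin: int = 4
    background_center: tuple[float, float] = (48.0, -30.0)
    background_sd_deg: float = 40.0
    rounding: int = 2
    year_range: tuple[int, int] = (1700, 1910)
    null: bool = False

    def __post_init__(self) -> None:
        if len(self.waypoints) < len(TIME_BINS):
            raise ValueError(
                f"need one waypoint per time bin: got {len(self.waypoints)}, "
                f"need {len(TIME_BINS)}"
            )
        if self.enriched_community not in self.communities:
            raise ValueError("enriched community must be in the community universe")
        unknown = set(self.enriched_regions) - set(self.regions)
        if unknown:
            raise ValueError(f"enriched regions not in universe: {sorted(unknown)}")


def _dirichlet_weights(config: AnnotationConfig, enriched: bool) -> np.ndarray:
    w = np.ones(len(config.regions))
    if enriched:
        for i, r in enumerate(config.regions):
            if r in config.enriched_regions:
                w[i] = config.enriched_weight
    return config.concentration * w / w.sum()


def _clip_latlon(lat: float, lon: float) -> tuple[float, float]:
    return min(max(lat, -90.0), 90.0), ((lon + 180.0) % 360.0) - 180.0


def annotate_samples(
    in_group_ids: list[str],
    background_ids: list[str],
    config: AnnotationConfig,
    seed: int,
) -> tuple[dict[str, AncestryAnnotation], list[BirthRecord]]:
    """Draw annotations for every sample and one family tree per sample.

    Returns (annotations keyed by sample id, birth records for all trees).
    Tree ids are ``T_<sample_id>``; each in-group tree emits
    ``records_per_tree_per_bin`` records per time bin scattered around that
    bin's waypoint, while background trees scatter around the diffuse
    baseline center.
    """
    rng = np.random.default_rng(seed)
    annotations: dict[str, AncestryAnnotation] = {}
    records: list[BirthRecord] = []
    bg_alpha = _dirichlet_weights(config, enriched=False)
    in_alpha = bg_alpha if config.null else _dirichlet_weights(config, enriched=True)

    for ids, alpha, is_in in (
        (in_group_ids, in_alpha, True),
        (background_ids, bg_alpha, False),
    ):
        planted = is_in and not config.null
        for sid in ids:
            props = rng.dirichlet(alpha)
            labels = set()
            for com in config.communities:
                p = config.p_community_bg
                if planted and com == config.enriched_community:
                    p = config.p_community_in
                if rng.random() < p:
                    labels.add(com)
            annotations[sid] = AncestryAnnotation(
                sid,
                dict(zip(config.regions, props / props.sum())),
                frozenset(labels),
            )
            tree = f"T_{sid}"
            k = 0
            for b, (y0, y1) in enumerate(TIME_BINS):
                if planted:
                    center, sd = config.waypoints[b], config.scatter_sd_deg
                else:
                    center, sd = config.background_center, config.background_sd_deg
                for _ in range(config.records_per_tree_per_bin):
                    # final bin is closed on the right
                    hi = y1 + 1 if b == len(TIME_BINS) - 1 else y1
                    year = int(rng.integers(y0, hi))
                    lat, lon = _clip_latlon(
                        center[0] + rng.normal(0, sd), center[1] + rng.normal(0, sd)
                    )
                    k += 1
                    records.append(
                        BirthRecord(
                            tree,
                            f"{tree}_A{k:03d}",
                            year,
                            round(lat, config.rounding),
                            round(lon, config.rounding),
                        )
                    )
    return annotations, records
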