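"""IBD-sharing network, meioses estimation, carrier classification, penetrance."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .ibd import IBDSegment, MatchSets

__all__ = [
    "UNRELATED",
    "CarrierCall",
    "build_network",
    "estimate_meioses",
    "expected_shared_fraction",
    "degree_of_sharing",
    "classify_carriers",
    "degree_histogram",
    "evaluate_calls",
    "penetrance",
    "export_edge_list",
    "export_graphml",
    "export_calls",
]

UNRELATED = "unrelated"  # sentinel for zero sharing (beyond resolution)


@dataclass(frozen=True)
class CarrierCall:
    sample_id: str
    label: str  # putative_carrier | unlikely | not_at_locus
    degree: int


def expected_shared_fraction(meioses: int, n_common_ancestors: int = 2) -> float:
    """Expected diploid-normalized shared genome fraction: ``k * 2**-M``."""
    if meioses < 1 or n_common_ancestors not in (1, 2):
        raise ValueError("need meioses >= 1 and n_common_ancestors in {1, 2}")
    return n_common_ancestors * 2.0 ** (-meioses)


def estimate_meioses(shared_fraction: float, n_common_ancestors: int = 2) -> int | str:
    """Invert the expected-sharing model: ``round(log2(k / f))``.

    Returns the :data:`UNRELATED` sentinel for zero sharing.
    """
    if n_common_ancestors not in (1, 2):
        raise ValueError("n_common_ancestors must be 1 or 2")
    if shared_fraction < 0 or shared_fraction > 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if shared_fraction == 0:
        return UNRELATED
    return round(math.log2(n_common_ancestors / shared_fraction))


def build_network(
    segments: list[IBDSegment],
    matches: MatchSets | None = None,
    total_map_cm: float | None = None,
) -> nx.Graph:
    """Undirected network with per-pair aggregated sharing totals.

    Edge attributes: ``genome_cm`` (summed segment lengths), ``at_locus_cm``
    (from ``matches`` when given, for sample-carrier pairs), and ``meioses``
    (when ``total_map_cm`` is given; shared fraction on the diploid scale).
    """
    g = nx.Graph()
    for seg in segments:
        if seg.id_a == seg.id_b:
            raise ValueError("self-edge in segment list")
        if g.has_edge(*seg.pair):
            g.edges[seg.pair]["genome_cm"] += seg.length_cm
            g.edges[seg.pair]["n_segments"] += 1
        else:
            g.add_edge(seg.id_a, seg.id_b, genome_cm=seg.length_cm, n_segments=1,
                       at_locus_cm=0.0)
    if matches is not None:
        for sample, per_carrier in matches.locus_cm.items():
            for carrier, cm in per_carrier.items():
                if g.has_edge(sample, carrier):
                    g.edges[sample, carrier]["at_locus_cm"] = cm
                else:
                    g.add_edge(sample, carrier, genome_cm=0.0, n_segments=0,
                               at_locus_cm=cm)
    if total_map_cm is not None:
        for u, v, data in g.edges(data=True):
            f = data["genome_cm"] / (2.0 * total_map_cm)
            data["meioses"] = estimate_meioses(f) if f > 0 else UNRELATED
    return g


def degree_of_sharing(
    matches: MatchSets,
    known_carriers: list[str],
    locus_threshold_cm: float = 1.0,
) -> dict[str, frozenset[str]]:
    """Per at-locus sample, the exact subset of known carriers with whom
    summed at-locus overlap strictly exceeds the threshold."""
    carriers = set(known_carriers)
    profile = {}
    for sample in matches.at_locus_matches:
        shared = frozenset(
            c
            for c, cm in matches.locus_cm.get(sample, {}).items()
            if c in carriers and cm > locus_threshold_cm
        )
        if shared:
            profile[sample] = shared
    return profile


def classify_carriers(
    profile: dict[str, frozenset[str]],
    known_carriers: list[str],
    all_samples: list[str] | None = None,
) -> list[CarrierCall]:
    """All-carriers rule: a sample sharing at-locus with EVERY known carrier
    is a putative carrier; any positive but incomplete degree is `unlikely`;
    samples absent from the profile are `not_at_locus` (emitted only when
    ``all_samples`` is given)."""
    n_known = len(set(known_carriers))
    if n_known == 0:
        raise ValueError("need at least one known carrier")
    calls = []
    for sample, shared in profile.items():
        degree = len(shared)
        label = "putative_carrier" if degree == n_known else "unlikely"
        calls.append(CarrierCall(sample, label, degree))
    if all_samples is not None:
        seen = set(profile) | set(known_carriers)
        calls.extend(
            CarrierCall(s, "not_at_locus", 0) for s in all_samples if s not in seen
        )
    return sorted(calls, key=lambda c: c.sample_id)


def degree_histogram(calls: list[CarrierCall]) -> dict[int, int]:
    """Counts of at-locus samples by degree of sharing (degree-0 calls are
    not at locus and excluded)."""
    out: dict[int, int] = {}
    for c in calls:
        if c.degree > 0:
            out[c.degree] = out.get(c.degree, 0) + 1
    return out


def evaluate_calls(
    calls: list[CarrierCall],
    truth: dict[str, bool],
) -> dict[str, float | int | None]:
    """Confusion matrix of the putative-carrier call against truth.

    Undefined ratios (0/0) are reported as None, never as 0.
    """
    tp = fp = fn = tn = 0
    for c in calls:
        positive = c.label == "putative_carrier"
        actual = truth.get(c.sample_id, False)
        tp += positive and actual
        fp += positive and not actual
        fn += (not positive) and actual
        tn += (not positive) and (not actual)
    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "ppv": ratio(tp, tp + fp),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    }


def penetrance(affected_adult_carriers: int, total_adult_carriers: int) -> int:
    """Percent penetrance, rounded half-up to the nearest integer."""
    if total_adult_carriers <= 0:
        raise ValueError("total_adult_carriers must be > 0")
    if not 0 <= affected_adult_carriers <= total_adult_carriers:
        raise ValueError("affected count must lie in [0, total]")
    return int(math.floor(100.0 * affected_adult_carriers / total_adult_carriers + 0.5))


def export_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("idA,idB,genome_cm,at_locus_cm,n_segments,meioses\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(
                f"{u},{v},{d.get('genome_cm', 0.0)!r},{d.get('at_locus_cm', 0.0)!r},"
                f"{d.get('n_segments', 0)},{d.get('meioses', '')}\n"
            )


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def export_calls(calls: list[CarrierCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id,label,degree\n")
        for c in calls:
            fh.write(f"{c.sample_id},{c.label},{c.degree}\n")
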