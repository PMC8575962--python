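"""Unphased IBD segment detection by seeded haplotype matching.

The detector hashes non-overlapping words of each haplotype; a word shared
verbatim between two samples' haplotypes is a seed, which is then extended at
the *genotype* level until a homozygous mismatch (opposite homozygotes) is
reached on each side. Reported segments are therefore unphased. A brute-force
oracle that scans every marker for opposite homozygosity provides the exact
maximal-clean-run reference for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .simdata.genmap import GeneticMap
from .simdata.haplotypes import FocalAllele, HaplotypeSet

__all__ = [
    "IBDSegment",
    "MatchSets",
    "detect_ibd",
    "brute_force_ibd",
    "build_match_sets",
    "locus_overlap",
    "write_match_file",
    "read_match_file",
]

# IBS guard: reported segments must carry at least one marker per this many cM
DEFAULT_IBS_DENSITY_CM = 0.2


@dataclass(frozen=True, order=True)
class IBDSegment:
    """A pairwise shared interval; (id_a, id_b) in canonical (sorted) order."""

    id_a: str
    id_b: str
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    n_markers: int

    def __post_init__(self) -> None:
        if self.id_a > self.id_b:
            raise ValueError("segment ids must be in canonical order")
        if self.end_bp <= self.start_bp or self.end_cm <= self.start_cm:
            raise ValueError("segment end must exceed start")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    @staticmethod
    def make(a: str, b: str, chrom: str, start_bp: int, end_bp: int,
             start_cm: float, end_cm: float, n_markers: int) -> "IBDSegment":
        if b < a:
            a, b = b, a
        return IBDSegment(a, b, chrom, int(start_bp), int(end_bp),
                          float(start_cm), float(end_cm), int(n_markers))


@dataclass
class MatchSets:
    """Threshold-based match sets relative to a panel of known carriers."""

    genetic_matches: set[str]
    at_locus_matches: set[str]
    genome_cm: dict[str, dict[str, float]] = field(default_factory=dict)
    locus_cm: dict[str, dict[str, float]] = field(default_factory=dict)

    def total_locus_cm(self, sample: str) -> float:
        return sum(self.locus_cm.get(sample, {}).values())


def _opp_hom_mask(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    return ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))


def _clean_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of markers free of opposite homozygotes.

    Returns inclusive (start, stop) marker-index pairs for runs of length >= 2
    (a single marker cannot carry positive genetic length).
    """
    opp = np.flatnonzero(mask)
    bounds = np.concatenate(([-1], opp, [len(mask)]))
    runs = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i] + 1, bounds[i + 1] - 1
        if b > a:
            runs.append((int(a), int(b)))
    return runs


def _segment_from_run(
    a: str, b: str, chrom: str, run: tuple[int, int], bp: np.ndarray, cm: np.ndarray
) -> IBDSegment:
    i, j = run
    return IBDSegment.make(a, b, chrom, bp[i], bp[j], cm[i], cm[j], j - i + 1)


def _passes_ibs(seg: IBDSegment, density_cm: float) -> bool:
    return seg.n_markers >= seg.length_cm / density_cm


def detect_ibd(
    hapset: HaplotypeSet,
    word_size: int = 64,
    min_length_cm: float = 6.0,
    max_hom_mismatches: int = 0,
    *,
    ibs_filter: bool = False,
    ibs_density_cm: float = DEFAULT_IBS_DENSITY_CM,
    target_ids: list[str] | None = None,
) -> list[IBDSegment]:
    """Seed-and-extend unphased IBD detection over a sample set.

    Seeds are exact word matches between any two samples' haplotypes;
    extension runs at the genotype level until an opposite-homozygote marker
    (tolerating up to ``max_hom_mismatches`` of them inside a segment).
    Segments shorter than ``min_length_cm`` are dropped. When ``ibs_filter``
    is set, segments with fewer than one marker per ``ibs_density_cm`` are
    also dropped (a stand-in IBS screen). ``target_ids`` restricts reporting
    to pairs involving at least one target sample.
    """
    if word_size < 8:
        raise ValueError("word_size must be >= 8")
    ids = hapset.sample_ids
    if not ids:
        raise ValueError("empty sample set")
    targets = set(target_ids) if target_ids is not None else None
    panel = hapset.panel
    genotypes: dict[str, np.ndarray] = {}
    segments: list[IBDSegment] = []
    for chrom in hapset.gmap.chromosomes:
        sl = panel.chrom_slice(chrom)
        bp, cm = panel.bp[sl], panel.cm[sl]
        m = sl.stop - sl.start
        haps = np.empty((2 * len(ids), m), dtype=np.uint8)
        for k, sid in enumerate(ids):
            h0, h1 = hapset[sid]
            haps[2 * k] = h0.alleles[sl]
            haps[2 * k + 1] = h1.alleles[sl]
        # seed pass: bucket haplotype words, pairs sharing a word are seeds
        pair_windows: dict[tuple[int, int], set[int]] = {}
        for w0 in range(0, m - word_size + 1, word_size):
            buckets: dict[bytes, list[int]] = {}
            words = haps[:, w0 : w0 + word_size]
            for row in range(words.shape[0]):
                buckets.setdefault(words[row].tobytes(), []).append(row // 2)
            for members in buckets.values():
                uniq = sorted(set(members))
                if len(uniq) < 2:
                    continue
                if targets is not None:
                    in_t = [s for s in uniq if ids[s] in targets]
                    out_t = [s for s in uniq if ids[s] not in targets]
                    pairs = itertools.chain(
                        itertools.combinations(in_t, 2),
                        itertools.product(in_t, out_t),
                    )
                else:
                    pairs = itertools.combinations(uniq, 2)
                for sa, sb in pairs:
                    key = (sa, sb) if sa < sb else (sb, sa)
                    pair_windows.setdefault(key, set()).add(w0)
        # extension pass, one pair at a time
        for (sa, sb), windows in pair_windows.items():
            for sid in (ids[sa], ids[sb]):
                if sid not in genotypes:
                    genotypes[sid] = hapset.genotypes(sid)
            mask = _opp_hom_mask(genotypes[ids[sa]][sl], genotypes[ids[sb]][sl])
            runs = _runs_with_budget(mask, sorted(windows), word_size, cm, max_hom_mismatches)
            for run in runs:
                seg = _segment_from_run(ids[sa], ids[sb], chrom, run, bp, cm)
                if seg.length_cm < min_length_cm:
                    continue
                if ibs_filter and not _passes_ibs(seg, ibs_density_cm):
                    continue
                segments.append(seg)
    return sorted(segments)


def _runs_with_budget(
    mask: np.ndarray,
    seed_starts: list[int],
    word_size: int,
    cm: np.ndarray,
    budget: int,
) -> list[tuple[int, int]]:
    """Extend each seed to its maximal run containing <= ``budget`` opposite
    homozygotes, deduplicated."""
    opp = np.flatnonzero(mask)
    n = len(mask)
    bounds = np.concatenate(([-1], opp, [n]))  # gap g spans (bounds[g], bounds[g+1])
    n_gaps = len(bounds) - 1
    out: set[tuple[int, int]] = set()
    for w0 in seed_starts:
        g = int(np.searchsorted(bounds, w0, side="right")) - 1
        if g >= n_gaps:  # seed at chromosome end edge case
            g = n_gaps - 1
        best = None
        for left in range(min(budget, g) + 1):
            right = min(budget - left, n_gaps - 1 - g)
            a = int(bounds[g - left] + 1)
            b = int(bounds[g + right + 1] - 1)
            if b <= a:
                continue
            length = cm[b] - cm[a]
            if best is None or length > best[0]:
                best = (length, (a, b))
        if best is not None:
            out.add(best[1])
    return sorted(out)


def brute_force_ibd(
    hapset: HaplotypeSet,
    min_length_cm: float,
    *,
    max_comparisons: int = 10**7,
) -> list[IBDSegment]:
    """Exhaustive oracle: for every pair, every maximal opposite-homozygote-
    free run of genetic length >= ``min_length_cm``. Guarded to small
    instances (pair-marker comparisons <= ``max_comparisons``)."""
    ids = hapset.sample_ids
    n_pairs = len(ids) * (len(ids) - 1) // 2
    if n_pairs * hapset.panel.n_markers > max_comparisons:
        raise ValueError(
            f"instance too large for brute force: "
            f"{n_pairs * hapset.panel.n_markers} pair-marker comparisons"
        )
    geno = {sid: hapset.genotypes(sid) for sid in ids}
    segments = []
    for a, b in itertools.combinations(ids, 2):
        for chrom in hapset.gmap.chromosomes:
            sl = hapset.panel.chrom_slice(chrom)
            bp, cm = hapset.panel.bp[sl], hapset.panel.cm[sl]
            mask = _opp_hom_mask(geno[a][sl], geno[b][sl])
            for run in _clean_runs(mask):
                seg = _segment_from_run(a, b, chrom, run, bp, cm)
                if seg.length_cm >= min_length_cm:
                    segments.append(seg)
    return sorted(segments)


def locus_overlap(segment: IBDSegment, locus: FocalAllele, gmap: GeneticMap) -> float:
    """Genetic length (cM) of the segment's overlap with the locus window."""
    if segment.chrom != locus.chrom:
        return 0.0
    lo = float(gmap.bp_to_cm(locus.chrom, locus.window_start_bp))
    hi = float(gmap.bp_to_cm(locus.chrom, locus.window_end_bp))
    return max(0.0, min(segment.end_cm, hi) - max(segment.start_cm, lo))


def build_match_sets(
    segments: list[IBDSegment],
    known_carriers: list[str],
    locus: FocalAllele,
    gmap: GeneticMap,
    genome_threshold_cm: float = 6.0,
    locus_threshold_cm: float = 1.0,
) -> MatchSets:
    """Threshold segments into genetic matches and at-locus matches.

    A sample is a genetic match when it shares at least one segment STRICTLY
    longer than ``genome_threshold_cm`` with at least one known carrier; it is
    an at-locus match when, additionally, its summed segment overlap with the
    locus window exceeds ``locus_threshold_cm`` (strictly) for at least one
    carrier. Known carriers themselves are excluded from both sets.
    """
    if genome_threshold_cm <= 0 or locus_threshold_cm <= 0:
        raise ValueError("thresholds must be positive")
    span = gmap.chrom_span_bp(locus.chrom) if locus.chrom in gmap.anchors else None
    if span is None or not (span[0] <= locus.window_start_bp <= locus.window_end_bp <= span[1]):
        raise ValueError("locus window outside map span")
    carriers = set(known_carriers)
    genome_cm: dict[str, dict[str, float]] = {}
    locus_cm: dict[str, dict[str, float]] = {}
    genetic: set[str] = set()
    for seg in segments:
        for sample, carrier in ((seg.id_a, seg.id_b), (seg.id_b, seg.id_a)):
            if carrier not in carriers or sample in carriers:
                continue
            genome_cm.setdefault(sample, {}).setdefault(carrier, 0.0)
            genome_cm[sample][carrier] += seg.length_cm
            if seg.length_cm > genome_threshold_cm:
                genetic.add(sample)
            ov = locus_overlap(seg, locus, gmap)
            if ov > 0:
                locus_cm.setdefault(sample, {}).setdefault(carrier, 0.0)
                locus_cm[sample][carrier] += ov
    at_locus = {
        s
        for s in genetic
        if any(v > locus_threshold_cm for v in locus_cm.get(s, {}).values())
    }
    return MatchSets(genetic, at_locus, genome_cm, locus_cm)


_MATCH_HEADER = "idA\tidB\tchrom\tstart_bp\tend_bp\tstart_cM\tend_cM\tlength_cM\tn_markers\n"


def write_match_file(path: str | Path, segments: list[IBDSegment]) -> None:
    with open(path, "w") as fh:
        fh.write(_MATCH_HEADER)
        for s in segments:
            fh.write(
                f"{s.id_a}\t{s.id_b}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t"
                f"{s.start_cm!r}\t{s.end_cm!r}\t{s.length_cm!r}\t{s.n_markers}\n"
            )


def read_match_file(path: str | Path) -> list[IBDSegment]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            a, b, chrom, sbp, ebp, scm, ecm, _len, nm = line.rstrip("\n").split("\t")
            out.append(
                IBDSegment.make(a, b, chrom, int(sbp), int(ebp), float(scm), float(ecm), int(nm))
            )
    return out
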