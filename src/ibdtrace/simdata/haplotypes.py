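"""Gene dropping: phased haplotype mosaics with founder-segment truth labels.

Recombination follows the Haldane model: crossover counts per transmission are
Poisson with mean equal to the chromosome's map length in Morgans, and
breakpoints are uniform in genetic (cM) position. Every haplotype carries, per
chromosome, an ordered list of labeled intervals ``(start_cM, end_cM,
founder_hap_id)`` that tile the chromosome exactly; pairwise true IBD is
recoverable from these labels without touching the allele data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap, MarkerPanel
from .pedigree import Pedigree

__all__ = [
    "FocalAllele",
    "Haplotype",
    "HaplotypeSet",
    "drop_haplotypes",
    "plant_focal_allele",
    "simulate_background",
    "apply_genotype_error",
    "true_ibd_segments",
    "true_ibd_fraction",
]

# one labeled interval: (start_cM, end_cM, founder_hap_id)
Segment = tuple[float, float, str]


@dataclass
class FocalAllele:
    """Definition of the planted rare dominant allele."""

    chrom: str
    bp: int
    window_start_bp: int
    window_end_bp: int
    founder_hap: str

    def __post_init__(self) -> None:
        if not (self.window_start_bp <= self.bp <= self.window_end_bp):
            raise ValueError("focal position must lie inside its locus window")


@dataclass
class Haplotype:
    alleles: np.ndarray  # uint8 over the global marker index
    segments: dict[str, list[Segment]]  # per chromosome, tiling [0, L]

    def label_at(self, chrom: str, cm: float) -> str:
        """Founder haplotype of origin at genetic position ``cm``."""
        for start, end, label in self.segments[chrom]:
            if start <= cm < end:
                return label
        last = self.segments[chrom][-1]
        if cm == last[1]:  # chromosome end belongs to the final segment
            return last[2]
        raise ValueError(f"position {cm} cM outside chromosome {chrom}")


@dataclass
class HaplotypeSet:
    panel: MarkerPanel
    gmap: GeneticMap
    haps: dict[str, tuple[Haplotype, Haplotype]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.haps)

    def __contains__(self, sid: str) -> bool:
        return sid in self.haps

    def __getitem__(self, sid: str) -> tuple[Haplotype, Haplotype]:
        return self.haps[sid]

    def genotypes(self, sid: str) -> np.ndarray:
        """Unphased genotype vector (0/1/2 alt-allele dosage)."""
        h0, h1 = self.haps[sid]
        return h0.alleles.astype(np.uint8) + h1.alleles

    def genotype_matrix(self, sample_ids: list[str] | None = None) -> np.ndarray:
        ids = sample_ids if sample_ids is not None else self.sample_ids
        return np.stack([self.genotypes(s) for s in ids])

    def merged_with(self, other: "HaplotypeSet") -> "HaplotypeSet":
        if other.panel is not self.panel and other.panel.n_markers != self.panel.n_markers:
            raise ValueError("cannot merge haplotype sets over different panels")
        overlap = set(self.haps) & set(other.haps)
        if overlap:
            raise ValueError(f"duplicate sample ids on merge: {sorted(overlap)[:5]}")
        merged = HaplotypeSet(self.panel, self.gmap, dict(self.haps))
        merged.haps.update(other.haps)
        return merged


def _founder_haplotype(
    founder_id: str, which: int, panel: MarkerPanel, gmap: GeneticMap, rng
) -> Haplotype:
    alleles = (rng.random(panel.n_markers) < panel.freq).astype(np.uint8)
    segments = {
        c: [(0.0, gmap.chrom_length_cm(c), f"{founder_id}.{which}")]
        for c in gmap.chromosomes
    }
    return Haplotype(alleles, segments)


def _clip_segments(segs: list[Segment], lo: float, hi: float) -> list[Segment]:
    out = []
    for s, e, lab in segs:
        a, b = max(s, lo), min(e, hi)
        if a < b:
            out.append((a, b, lab))
    return out


def _meiosis(
    parent: tuple[Haplotype, Haplotype],
    panel: MarkerPanel,
    gmap: GeneticMap,
    rng,
) -> Haplotype:
    """One gamete: crossovers Poisson(L Morgans), breakpoints uniform in cM."""
    alleles = np.empty(panel.n_markers, dtype=np.uint8)
    segments: dict[str, list[Segment]] = {}
    for chrom in gmap.chromosomes:
        length = gmap.chrom_length_cm(chrom)
        n_x = rng.poisson(length / 100.0)
        breaks = np.sort(rng.uniform(0.0, length, size=n_x))
        bounds = np.concatenate(([0.0], breaks, [length]))
        active = int(rng.integers(2))
        sl = panel.chrom_slice(chrom)
        cm = panel.cm[sl]
        out_segs: list[Segment] = []
        for i in range(len(bounds) - 1):
            lo, hi = float(bounds[i]), float(bounds[i + 1])
            hap = parent[(active + i) % 2]
            out_segs.extend(_clip_segments(hap.segments[chrom], lo, hi))
            # markers in [lo, hi); the final piece also takes the chrom end
            j0 = int(np.searchsorted(cm, lo, side="left"))
            j1 = len(cm) if i == len(bounds) - 2 else int(np.searchsorted(cm, hi, side="left"))
            alleles[sl.start + j0 : sl.start + j1] = hap.alleles[sl.start + j0 : sl.start + j1]
        # merge touching pieces with identical origin label
        merged: list[Segment] = []
        for seg in out_segs:
            if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
                merged[-1] = (merged[-1][0], seg[1], seg[2])
            else:
                merged.append(seg)
        segments[chrom] = merged
    return Haplotype(alleles, segments)


def drop_haplotypes(
    pedigree: Pedigree,
    gmap: GeneticMap,
    panel: MarkerPanel,
    seed: int,
) -> HaplotypeSet:
    """Drop founder haplotypes down the pedigree.

    Founder haplotypes draw alleles independently from panel frequencies;
    each non-founder receives one recombinant gamete from each parent
    (haplotype 0 paternal, haplotype 1 maternal).
    """
    rng = np.random.default_rng(seed)
    hapset = HaplotypeSet(panel, gmap)
    order = sorted(pedigree.members.values(), key=lambda m: m.generation)
    for ind in order:
        if ind.is_founder:
            hapset.haps[ind.id] = (
                _founder_haplotype(ind.id, 0, panel, gmap, rng),
                _founder_haplotype(ind.id, 1, panel, gmap, rng),
            )
        else:
            father = hapset.haps[ind.father]
            mother = hapset.haps[ind.mother]
            hapset.haps[ind.id] = (
                _meiosis(father, panel, gmap, rng),
                _meiosis(mother, panel, gmap, rng),
            )
    return hapset


def plant_focal_allele(
    pedigree: Pedigree,
    hapset: HaplotypeSet,
    allele: FocalAllele,
) -> list[str]:
    """Rewrite the focal marker so it is carried exactly by descendants of the
    originating founder haplotype, and set pedigree carrier flags accordingly.

    The panel's founder frequency at the focal marker is zeroed so that any
    background cohort simulated afterwards is allele-free. Returns carrier ids.
    """
    gmap = hapset.gmap
    lo, hi = gmap.chrom_span_bp(allele.chrom)
    if not (lo <= allele.bp <= hi):
        raise ValueError(
            f"focal position {allele.chrom}:{allele.bp} outside map span [{lo}, {hi}]"
        )
    idx = hapset.panel.marker_index(allele.chrom, allele.bp)
    cm = float(hapset.panel.cm[idx])
    carriers = []
    for sid, (h0, h1) in hapset.haps.items():
        hit = False
        for h in (h0, h1):
            is_origin = h.label_at(allele.chrom, cm) == allele.founder_hap
            h.alleles[idx] = 1 if is_origin else 0
            hit = hit or is_origin
        if sid in pedigree:
            pedigree[sid].carrier = hit
        if hit:
            carriers.append(sid)
    hapset.panel.freq[idx] = 0.0
    return carriers


def simulate_background(
    n_samples: int,
    panel: MarkerPanel,
    gmap: GeneticMap,
    seed: int,
    *,
    id_prefix: str = "B",
) -> HaplotypeSet:
    """Unrelated cohort: haplotypes drawn independently from panel frequencies.

    Each sample is its own founder, so true IBD between any two background
    samples (or with the pedigree) is empty by construction.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    rng = np.random.default_rng(seed)
    hapset = HaplotypeSet(panel, gmap)
    for i in range(1, n_samples + 1):
        sid = f"{id_prefix}{i:06d}"
        hapset.haps[sid] = (
            _founder_haplotype(sid, 0, panel, gmap, rng),
            _founder_haplotype(sid, 1, panel, gmap, rng),
        )
    return hapset


def apply_genotype_error(hapset: HaplotypeSet, rate: float, seed: int) -> HaplotypeSet:
    """Symmetric allele flips at ``rate`` per haplotype per marker.

    Returns a new set with flipped alleles; truth labels are shared unchanged
    (error is applied after truth capture).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = HaplotypeSet(hapset.panel, hapset.gmap)
    for sid, (h0, h1) in hapset.haps.items():
        flipped = []
        for h in (h0, h1):
            mask = rng.random(len(h.alleles)) < rate
            flipped.append(Haplotype(np.where(mask, 1 - h.alleles, h.alleles).astype(np.uint8), h.segments))
        out.haps[sid] = (flipped[0], flipped[1])
    return out


def _shared_intervals(a: list[Segment], b: list[Segment]) -> list[tuple[float, float]]:
    """Intervals where two labeled tilings carry the same founder label."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e and a[i][2] == b[j][2]:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _merge_intervals(ivs: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def true_ibd_segments(
    hapset: HaplotypeSet,
    a: str,
    b: str,
    min_cM: float = 0.0,
) -> list[tuple[str, float, float]]:
    """True pairwise IBD from founder labels: per chromosome, the merged union
    over the four haplotype pairings of identically-labeled intervals.

    Returns ``(chrom, start_cM, end_cM)`` records of length >= ``min_cM``.
    """
    out = []
    ha, hb = hapset[a], hapset[b]
    for chrom in hapset.gmap.chromosomes:
        ivs: list[tuple[float, float]] = []
        for x in ha:
            for y in hb:
                ivs.extend(_shared_intervals(x.segments[chrom], y.segments[chrom]))
        for s, e in _merge_intervals(ivs):
            if e - s >= min_cM:
                out.append((chrom, s, e))
    return out


def true_ibd_fraction(hapset: HaplotypeSet, a: str, b: str) -> float:
    """Diploid-normalized true sharing fraction (label truth).

    Sums intersection lengths over all four haplotype pairings (so fully
    shared regions count twice) and divides by twice the map length; this is
    the convention under which full siblings share 0.5 and the expected
    fraction for a pair M meioses apart through k common ancestors is
    ``k * 2**-M``.
    """
    ha, hb = hapset[a], hapset[b]
    shared = 0.0
    for chrom in hapset.gmap.chromosomes:
        for x in ha:
            for y in hb:
                shared += sum(
                    e - s
                    for s, e in _shared_intervals(x.segments[chrom], y.segments[chrom])
                )
    return shared / (2.0 * hapset.gmap.total_length_cm())
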