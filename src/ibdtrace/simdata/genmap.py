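"""Genetic map and marker panel construction.

The genetic map is the coordinate backbone of the whole pipeline: every
segment length, threshold and flank is measured in centimorgans obtained by
linear interpolation between map anchors. Here the anchors *are* the markers,
so interpolation is exact at marker positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "MarkerPanel", "make_genetic_map"]


@dataclass
class GeneticMap:
    """Per-chromosome bp <-> cM lookup with linear interpolation.

    Parameters
    ----------
    anchors : dict mapping chromosome id -> (bp array, cM array), both
        strictly increasing and of equal length >= 2.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.size != cm.size or bp.size < 2:
                raise ValueError(f"chromosome {chrom}: need >= 2 anchors")
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise ValueError(
                    f"chromosome {chrom}: anchor positions must be strictly increasing"
                )
            clean[chrom] = (bp, cm)
        if not clean:
            raise ValueError("empty genetic map")
        self.anchors = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self.anchors)

    def chrom_span_bp(self, chrom: str) -> tuple[int, int]:
        bp, _ = self.anchors[chrom]
        return int(bp[0]), int(bp[-1])

    def chrom_length_cm(self, chrom: str) -> float:
        _, cm = self.anchors[chrom]
        return float(cm[-1] - cm[0])

    def total_length_cm(self) -> float:
        return float(sum(self.chrom_length_cm(c) for c in self.anchors))

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray | float:
        xs, ys = self.anchors[chrom]
        out = np.interp(bp, xs, ys)
        return float(out) if np.isscalar(bp) else out

    def cm_to_bp(self, chrom: str, cm) -> np.ndarray | float:
        xs, ys = self.anchors[chrom]
        out = np.interp(cm, ys, xs)
        return float(out) if np.isscalar(cm) else out


@dataclass
class MarkerPanel:
    """Biallelic markers over one or more chromosomes.

    Arrays are parallel and globally sorted by (chromosome, bp). ``offsets``
    maps a chromosome id to its half-open slice ``[start, stop)`` into the
    global marker index.
    """

    chrom: np.ndarray  # of str
    bp: np.ndarray  # int64
    cm: np.ndarray  # float64
    ref: np.ndarray  # of str
    alt: np.ndarray  # of str
    freq: np.ndarray  # founder alt-allele frequency, float64 in [0, 1]
    offsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.bp)
        for arr in (self.chrom, self.cm, self.ref, self.alt, self.freq):
            if len(arr) != n:
                raise ValueError("marker arrays must have equal length")
        if not self.offsets:
            self.offsets = {}
            start = 0
            for i in range(1, n + 1):
                if i == n or self.chrom[i] != self.chrom[start]:
                    self.offsets[str(self.chrom[start])] = (start, i)
                    start = i
        for chrom, (a, b) in self.offsets.items():
            if np.any(np.diff(self.bp[a:b]) <= 0):
                raise ValueError(f"chromosome {chrom}: markers not sorted by bp")

    @property
    def n_markers(self) -> int:
        return len(self.bp)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.offsets)

    def chrom_slice(self, chrom: str) -> slice:
        a, b = self.offsets[chrom]
        return slice(a, b)

    def marker_index(self, chrom: str, bp: int) -> int:
        """Index of the marker nearest ``bp`` on ``chrom``."""
        a, b = self.offsets[chrom]
        sub = self.bp[a:b]
        i = int(np.searchsorted(sub, bp))
        if i == 0:
            return a
        if i >= len(sub):
            return b - 1
        return a + (i if abs(sub[i] - bp) < abs(sub[i - 1] - bp) else i - 1)


def make_genetic_map(
    n_chromosomes: int,
    chrom_length_cM: float,
    n_markers: int,
    seed: int,
    *,
    bp_per_cm: float = 1_000_000.0,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[GeneticMap, MarkerPanel]:
    """Build a synthetic map with ``n_markers`` per chromosome.

    Markers are uniformly spaced in cM spanning exactly ``chrom_length_cM``;
    bp positions are jittered around a constant bp/cM scale but kept strictly
    increasing. Founder alt-allele frequencies are uniform on ``freq_range``.
    """
    if n_chromosomes < 1 or chrom_length_cM <= 0 or n_markers < 2:
        raise ValueError(
            "need n_chromosomes >= 1, chrom_length_cM > 0, n_markers >= 2"
        )
    rng = np.random.default_rng(seed)
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms, bps, cms, freqs = [], [], [], []
    for c in range(1, n_chromosomes + 1):
        name = f"chr{c}"
        cm = np.linspace(0.0, chrom_length_cM, n_markers)
        spacing_bp = chrom_length_cM * bp_per_cm / (n_markers - 1)
        jitter = rng.uniform(-0.3, 0.3, size=n_markers) * spacing_bp
        bp = np.round(1 + cm * bp_per_cm + jitter).astype(np.int64)
        # enforce strict monotonicity after jitter
        bp = np.maximum.accumulate(bp) + np.arange(n_markers)
        anchors[name] = (bp, cm)
        chroms.append(np.full(n_markers, name, dtype=object))
        bps.append(bp)
        cms.append(cm)
        freqs.append(rng.uniform(*freq_range, size=n_markers))
    alleles = np.array(["A", "C", "G", "T"], dtype=object)
    total = n_chromosomes * n_markers
    ref = rng.choice(alleles, size=total)
    alt = rng.choice(alleles, size=total)
    clash = alt == ref
    while np.any(clash):
        alt[clash] = rng.choice(alleles, size=int(clash.sum()))
        clash = alt == ref
    panel = MarkerPanel(
        chrom=np.concatenate(chroms),
        bp=np.concatenate(bps),
        cm=np.concatenate(cms),
        ref=ref,
        alt=alt,
        freq=np.concatenate(freqs),
    )
    return GeneticMap(anchors), panel
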