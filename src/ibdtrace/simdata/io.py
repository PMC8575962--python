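"""Write a simulated study to disk and read it back losslessly.

All artifacts are plain text: a phased VCF 4.2, tab-separated genetic map and
pedigree tables, CSV annotation/birth-record tables, and JSON truth files
(carrier status, founder-segment labels, true IBD segments). The VCF writer
is a thin formatter; reading goes through :mod:`cyvcf2`.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .annotate import AncestryAnnotation, BirthRecord
from .genmap import GeneticMap, MarkerPanel
from .haplotypes import FocalAllele, Haplotype, HaplotypeSet, true_ibd_segments
from .pedigree import Individual, Pedigree

__all__ = ["write_study", "read_study", "write_vcf", "read_vcf"]

_GT = np.array(["0|0", "0|1", "1|0", "1|1"], dtype=object)


def write_vcf(path: str | Path, hapset: HaplotypeSet) -> None:
    panel = hapset.panel
    ids = hapset.sample_ids
    h0 = np.stack([hapset[s][0].alleles for s in ids])  # samples x markers
    h1 = np.stack([hapset[s][1].alleles for s in ids])
    codes = (2 * h0 + h1).T  # markers x samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ibdtrace-simdata\n")
        for chrom in hapset.gmap.chromosomes:
            _, hi = hapset.gmap.chrom_span_bp(chrom)
            fh.write(f"##contig=<ID={chrom},length={hi + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ids)
            + "\n"
        )
        for m in range(panel.n_markers):
            row = "\t".join(_GT[codes[m]])
            fh.write(
                f"{panel.chrom[m]}\t{panel.bp[m]}\tm{m}\t{panel.ref[m]}\t"
                f"{panel.alt[m]}\t.\tPASS\t.\tGT\t{row}\n"
            )


def read_vcf(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a phased VCF; returns (sample ids, hap0 matrix, hap1 matrix)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    ids = list(vcf.samples)
    a0, a1 = [], []
    for variant in vcf:
        arr = variant.genotype.array()
        a0.append(arr[:, 0])
        a1.append(arr[:, 1])
    vcf.close()
    h0 = np.asarray(a0, dtype=np.uint8).T.copy()
    h1 = np.asarray(a1, dtype=np.uint8).T.copy()
    return ids, h0, h1


def _write_map(path: Path, gmap: GeneticMap) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbp\tcM\n")
        for chrom, (bp, cm) in gmap.anchors.items():
            for b, c in zip(bp, cm):
                fh.write(f"{chrom}\t{b}\t{float(c)!r}\n")


def _read_map(path: Path) -> GeneticMap:
    anchors: dict[str, tuple[list, list]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, bp, cm = line.rstrip("\n").split("\t")
            anchors.setdefault(chrom, ([], []))
            anchors[chrom][0].append(int(bp))
            anchors[chrom][1].append(float(cm))
    return GeneticMap(
        {c: (np.array(b), np.array(g)) for c, (b, g) in anchors.items()}
    )


def _write_markers(path: Path, panel: MarkerPanel) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbp\tcM\tref\talt\tfreq\n")
        for i in range(panel.n_markers):
            fh.write(
                f"{panel.chrom[i]}\t{panel.bp[i]}\t{float(panel.cm[i])!r}\t"
                f"{panel.ref[i]}\t{panel.alt[i]}\t{float(panel.freq[i])!r}\n"
            )


def _read_markers(path: Path) -> MarkerPanel:
    cols: list[list] = [[], [], [], [], [], []]
    with open(path) as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            for c, v in zip(cols, parts):
                c.append(v)
    return MarkerPanel(
        chrom=np.array(cols[0], dtype=object),
        bp=np.array(cols[1], dtype=np.int64),
        cm=np.array(cols[2], dtype=np.float64),
        ref=np.array(cols[3], dtype=object),
        alt=np.array(cols[4], dtype=object),
        freq=np.array(cols[5], dtype=np.float64),
    )


def _write_pedigree(path: Path, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        fh.write("id\tfather\tmother\tgeneration\n")
        for ind in ped.members.values():
            fh.write(
                f"{ind.id}\t{ind.father or '0'}\t{ind.mother or '0'}\t{ind.generation}\n"
            )


def _read_pedigree(path: Path, carriers: set[str]) -> Pedigree:
    ped = Pedigree()
    with open(path) as fh:
        next(fh)
        for line in fh:
            iid, fa, mo, gen = line.rstrip("\n").split("\t")
            ped.add(
                Individual(
                    iid,
                    None if fa == "0" else fa,
                    None if mo == "0" else mo,
                    int(gen),
                    carrier=iid in carriers,
                )
            )
    return ped


def _write_annotations(path: Path, annotations: dict[str, AncestryAnnotation]) -> None:
    regions = sorted({r for a in annotations.values() for r in a.ethnicity})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", *regions, "communities"])
        for sid, ann in annotations.items():
            writer.writerow(
                [sid]
                + [repr(float(ann.ethnicity.get(r, 0.0))) for r in regions]
                + [";".join(sorted(ann.communities))]
            )


def _read_annotations(path: Path) -> dict[str, AncestryAnnotation]:
    out: dict[str, AncestryAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        regions = header[1:-1]
        for row in reader:
            sid = row[0]
            eth = {r: float(v) for r, v in zip(regions, row[1:-1])}
            coms = frozenset(row[-1].split(";")) if row[-1] else frozenset()
            out[sid] = AncestryAnnotation(sid, eth, coms)
    return out


def _write_birth_records(path: Path, records: list[BirthRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tree_id", "ancestor_id", "year", "lat", "lon"])
        for r in records:
            writer.writerow([r.tree_id, r.ancestor_id, r.year, repr(float(r.lat)), repr(float(r.lon))])


def _read_birth_records(path: Path) -> list[BirthRecord]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for tree, anc, year, lat, lon in reader:
            out.append(BirthRecord(tree, anc, int(year), float(lat), float(lon)))
    return out


def _segments_to_json(hapset: HaplotypeSet) -> dict:
    return {
        sid: [
            {c: [[s, e, lab] for s, e, lab in segs] for c, segs in h.segments.items()}
            for h in pair
        ]
        for sid, pair in hapset.haps.items()
    }


def write_study(
    out_dir: str | Path,
    *,
    gmap: GeneticMap,
    panel: MarkerPanel,
    pedigree: Pedigree,
    hapset: HaplotypeSet,
    focal: FocalAllele | None = None,
    annotations: dict[str, AncestryAnnotation] | None = None,
    birth_records: list[BirthRecord] | None = None,
    truth_ibd_pairs: list[tuple[str, str]] | None = None,
) -> Path:
    """Write every study artifact under ``out_dir``; returns the directory.

    ``truth_ibd_pairs`` selects which pairwise true-IBD segment lists to
    materialize (all-vs-all is quadratic; callers choose).
    """
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    _write_map(out / "map.tsv", gmap)
    _write_markers(out / "markers.tsv", panel)
    _write_pedigree(out / "pedigree.tsv", pedigree)
    write_vcf(out / "genotypes.vcf", hapset)
    if focal is not None:
        (out / "focal_allele.json").write_text(json.dumps(vars(focal), indent=1))
    if annotations is not None:
        _write_annotations(out / "annotations.csv", annotations)
    if birth_records is not None:
        _write_birth_records(out / "birth_records.csv", birth_records)
    carriers = {sid for sid in hapset.sample_ids if sid in pedigree and pedigree[sid].carrier}
    (out / "truth" / "carriers.json").write_text(json.dumps(sorted(carriers), indent=1))
    (out / "truth" / "segment_labels.json").write_text(
        json.dumps(_segments_to_json(hapset))
    )
    if truth_ibd_pairs is not None:
        with open(out / "truth" / "true_ibd.tsv", "w") as fh:
            fh.write("idA\tidB\tchrom\tstart_cM\tend_cM\n")
            for a, b in truth_ibd_pairs:
                for chrom, s, e in true_ibd_segments(hapset, a, b):
                    fh.write(f"{a}\t{b}\t{chrom}\t{float(s)!r}\t{float(e)!r}\n")
    return out


def read_study(out_dir: str | Path):
    """Read a study directory back into in-memory structures.

    Returns a dict with keys ``gmap, panel, pedigree, hapset, focal,
    annotations, birth_records`` (missing optional artifacts map to None).
    """
    out = Path(out_dir)
    gmap = _read_map(out / "map.tsv")
    panel = _read_markers(out / "markers.tsv")
    carriers = set(json.loads((out / "truth" / "carriers.json").read_text()))
    ped = _read_pedigree(out / "pedigree.tsv", carriers)
    ids, h0, h1 = read_vcf(out / "genotypes.vcf")
    labels = json.loads((out / "truth" / "segment_labels.json").read_text())
    hapset = HaplotypeSet(panel, gmap)
    for i, sid in enumerate(ids):
        haps = []
        for which, alleles in ((0, h0[i]), (1, h1[i])):
            segs = {
                c: [(float(s), float(e), lab) for s, e, lab in lst]
                for c, lst in labels[sid][which].items()
            }
            haps.append(Haplotype(np.asarray(alleles, dtype=np.uint8), segs))
        hapset.haps[sid] = (haps[0], haps[1])
    focal = None
    if (out / "focal_allele.json").exists():
        focal = FocalAllele(**json.loads((out / "focal_allele.json").read_text()))
    annotations = None
    if (out / "annotations.csv").exists():
        annotations = _read_annotations(out / "annotations.csv")
    birth_records = None
    if (out / "birth_records.csv").exists():
        birth_records = _read_birth_records(out / "birth_records.csv")
    return {
        "gmap": gmap,
        "panel": panel,
        "pedigree": ped,
        "hapset": hapset,
        "focal": focal,
        "annotations": annotations,
        "birth_records": birth_records,
    }
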