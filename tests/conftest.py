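import numpy as np
import pytest

from ibdtrace.simdata import (
    FocalAllele,
    drop_haplotypes,
    make_genetic_map,
    plant_focal_allele,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def small_map_panel():
    """One 100 cM chromosome, 500 markers."""
    return make_genetic_map(1, 100.0, 500, seed=11)


@pytest.fixture(scope="session")
def two_chrom_map_panel():
    return make_genetic_map(2, 80.0, 400, seed=13)


@pytest.fixture(scope="session")
def small_family(two_chrom_map_panel):
    """4-generation pedigree with dropped haplotypes and a planted allele."""
    gmap, panel = two_chrom_map_panel
    ped = simulate_pedigree(4, 2.5, seed=5)
    haps = drop_haplotypes(ped, gmap, panel, seed=7)
    founder = sorted(ped.founders)[0]
    bp = int(round(gmap.cm_to_bp("chr1", 40.0)))
    lo = int(round(gmap.cm_to_bp("chr1", 38.0)))
    hi = int(round(gmap.cm_to_bp("chr1", 42.0)))
    focal = FocalAllele("chr1", bp, lo, hi, f"{founder}.0")
    carriers = plant_focal_allele(ped, haps, focal)
    return {
        "gmap": gmap,
        "panel": panel,
        "pedigree": ped,
        "hapset": haps,
        "focal": focal,
        "carriers": carriers,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
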