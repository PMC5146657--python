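"""Shared fixtures: tiny genotype objects and a survey-shaped synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from salixploidy.ssr_model import AlleleSet, GenotypeMatrix, PedigreeGenotypes
from salixploidy.synthetic import simulate_f1_family, simulate_individual


def aset(marker: str, sample: str, *alleles: int) -> AlleleSet:
    return AlleleSet(marker_id=marker, sample_id=sample, alleles=tuple(alleles))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20161209)


@pytest.fixture
def abxcd_family() -> PedigreeGenotypes:
    """Clean AB x CD family: progeny cover all four genotype classes."""
    mother = aset("M1", "mom", 168, 172)
    father = aset("M1", "dad", 176, 180)
    progeny = [
        aset("M1", "p1", 168, 176),
        aset("M1", "p2", 168, 180),
        aset("M1", "p3", 172, 176),
        aset("M1", "p4", 172, 180),
        aset("M1", "p5", 168, 176),
        aset("M1", "p6", 172, 180),
    ]
    return PedigreeGenotypes("M1", mother, father, tuple(progeny))


def make_survey_matrix() -> tuple[GenotypeMatrix, dict[str, str]]:
    """A small hand-built matrix with known candidates, clones and diploids."""
    records = []
    markers = [f"MK_{i}" for i in range(1, 7)]
    base = {m: (200 + 10 * i, 204 + 10 * i) for i, m in enumerate(markers)}

    def add(sample, per_marker):
        for m in markers:
            records.append(aset(m, sample, *per_marker(m)))

    add("Dip_1", lambda m: base[m])
    add("Dip_2", lambda m: (base[m][0],))
    # clone pair: identical everywhere, distinct from every other sample
    add("Clo_1", lambda m: (base[m][0] + 2, base[m][1] + 6))
    add("Clo_2", lambda m: (base[m][0] + 2, base[m][1] + 6))
    # triploid: 3 alleles at two markers
    add("Tri_1", lambda m: (base[m][0], base[m][1], base[m][1] + 2)
        if m in ("MK_1", "MK_4") else base[m])
    # tetraploid: 4 alleles at one marker
    add("Tet_1", lambda m: (base[m][0], base[m][1], base[m][0] + 2, base[m][1] + 2)
        if m == "MK_2" else base[m])
    matrix = GenotypeMatrix.from_records(records)
    species = {s: s.split("_")[0] for s in matrix.samples}
    return matrix, species


@pytest.fixture
def survey_matrix() -> tuple[GenotypeMatrix, dict[str, str]]:
    return make_survey_matrix()


def make_informative_study(seed: int = 7, n_panel: int = 12,
                           n_markers_high: int = 10):
    """Pedigrees + a diploid panel for 11 informative markers.

    Ten markers carry four equal-frequency alleles (high PIC); the
    eleventh is dominated by one allele (low PIC), mirroring a panel
    where the PIC > 0.5 filter removes exactly one informative marker.
    """
    rng = np.random.default_rng(seed)
    freqs: dict[str, dict[int, float]] = {}
    for i in range(1, n_markers_high + 1):
        a = 160 + 20 * i
        freqs[f"INF_{i:02d}"] = {a: 0.25, a + 4: 0.25, a + 8: 0.25, a + 12: 0.25}
    freqs["INF_11"] = {400: 0.90, 404: 0.05, 408: 0.05}

    pedigrees = {}
    for marker, f in freqs.items():
        alleles = sorted(f)
        mother = AlleleSet(marker, "mom", (alleles[0], alleles[1]))
        father = AlleleSet(marker, "dad", tuple(alleles[2:4])
                           if len(alleles) >= 4 else (alleles[1], alleles[2]))
        ped, _ = simulate_f1_family(mother, father, n_progeny=6,
                                    null_rate=0.0, rng=rng)
        pedigrees[marker] = ped

    records = []
    for j in range(1, n_panel + 1):
        sid = f"Pan_{j}"
        for marker, f in freqs.items():
            ind = simulate_individual(f, ploidy=2, null_rate=0.0, rng=rng,
                                      marker_id=marker)
            records.append(AlleleSet(marker, sid, ind.alleles))
    return pedigrees, GenotypeMatrix.from_records(records), freqs


@pytest.fixture
def informative_study():
    return make_informative_study()
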