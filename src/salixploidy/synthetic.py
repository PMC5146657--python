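"""Synthetic SSR genotypes and cytometry streams with known ground truth.

The generator emulates the data structures of a willow ploidy survey:

* a panel of unlinked SSR markers, each with a handful of distinct
  integer allele sizes in the microsatellite range (150-450 bp; the
  survey's amplicons ran 168-406 bp) and allele frequencies drawn from a
  symmetric Dirichlet;
* dosage-blind genotypes: a P-ploid individual carries P allele draws,
  each independently silenced with the null-allele rate, and only the
  *set* of surviving distinct alleles is observed — never copy numbers;
* F1 full-sib families where every progeny inherits one allele from
  each diploid parent (the substrate of the informativeness test);
* clonal ramets, emitted as extra sample ids sharing one genet's
  genotype;
* fluorescence event streams: a Gaussian G0/G1 peak at
  unit_position * ploidy / reference_ploidy with a chosen CV%, an
  optional G2/M peak at twice that position, and a truncated-exponential
  debris tail.

Everything is reproducible from a single integer seed, and the emitted
truth (ploidies, clone groups, frequencies, peak positions) is returned
alongside the data so every pipeline stage can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fcm import EventStream
from .ssr_model import AlleleSet, GenotypeMatrix, PedigreeGenotypes

__all__ = [
    "FCMSimConfig",
    "SimConfig",
    "SimTruth",
    "StudyData",
    "simulate_marker_panel",
    "simulate_individual",
    "simulate_f1_family",
    "simulate_fcm_stream",
    "simulate_study",
    "default_study_config",
]

_SIZE_RANGE = (150, 450)  # bp window containing the observed 168-406 amplicons


@dataclass(frozen=True)
class FCMSimConfig:
    """Cytometry stream parameters.

    Defaults mirror the survey conditions: diploid G0/G1 near channel
    10739, CV 4.5% (the reported runs spanned 2.61-4.97%), at least
    5,000 particles per run, a small debris tail and a 10% G2/M fraction.
    """

    unit_position: float = 10739.0
    cv_percent: float = 4.5
    n_events: int = 5000
    debris_fraction: float = 0.05
    g2_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.unit_position <= 0:
            raise ValueError("unit_position must be positive")
        if not (0 <= self.debris_fraction < 1 and 0 <= self.g2_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")
        if self.debris_fraction + self.g2_fraction >= 1:
            raise ValueError("debris_fraction + g2_fraction must be < 1")


@dataclass(frozen=True)
class SimConfig:
    """Study-level generator settings (see module docstring)."""

    seed: int = 0
    n_alleles_per_marker: int = 5
    allele_freq_concentration: float = 1.0
    n_markers: int = 10
    ploidy_assignments: Mapping[str, int] = field(default_factory=dict)
    clone_copies: Mapping[str, int] = field(default_factory=dict)
    null_allele_rate: float = 0.0
    fcm: FCMSimConfig = field(default_factory=FCMSimConfig)

    def __post_init__(self) -> None:
        if self.n_alleles_per_marker < 1:
            raise ValueError("need at least one allele per marker")
        if not 0 <= self.null_allele_rate <= 1:
            raise ValueError("null_allele_rate must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated study."""

    ploidy: dict[str, int]
    clone_groups: list[tuple[str, ...]]
    allele_freqs: dict[str, dict[int, float]]
    peak_positions: dict[str, float]


@dataclass
class StudyData:
    """A complete simulated study: genotypes, species labels, FCM runs, truth."""

    matrix: GenotypeMatrix
    species: dict[str, str]
    streams: dict[str, list[EventStream]]
    truth: SimTruth


def simulate_marker_panel(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, dict[int, float]]:
    """Draw marker allele sizes and Dirichlet frequencies.

    Returns marker_id -> {allele size: frequency}.  Allele sizes are
    distinct integers in the microsatellite window; frequencies come
    from a symmetric Dirichlet with the configured concentration (large
    concentration -> near-equal frequencies).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    panel: dict[str, dict[int, float]] = {}
    sizes = np.arange(_SIZE_RANGE[0], _SIZE_RANGE[1] + 1)
    for i in range(cfg.n_markers):
        alleles = np.sort(rng.choice(sizes, size=cfg.n_alleles_per_marker, replace=False))
        freqs = rng.dirichlet(
            np.full(cfg.n_alleles_per_marker, cfg.allele_freq_concentration)
        )
        panel[f"SIM_{i + 1:03d}"] = {
            int(a): float(f) for a, f in zip(alleles, freqs)
        }
    return panel


def simulate_individual(
    freqs: Mapping[int, float],
    ploidy: int,
    null_rate: float,
    rng: np.random.Generator,
    marker_id: str = "SIM_001",
    sample_id: str = "sim",
) -> AlleleSet:
    """Draw one dosage-blind genotype at one marker.

    ``ploidy`` alleles are drawn i.i.d. from the frequency vector; each
    is silenced independently with probability ``null_rate``; the
    observed call is the set of distinct survivors (empty = missing).
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    alleles = np.array(list(freqs), dtype=int)
    probs = np.array([freqs[int(a)] for a in alleles], dtype=float)
    draws = rng.choice(alleles, size=ploidy, p=probs / probs.sum())
    survived = draws[rng.random(ploidy) >= null_rate]
    return AlleleSet(marker_id=marker_id, sample_id=sample_id,
                     alleles=tuple(int(a) for a in survived))


def simulate_f1_family(
    mother: AlleleSet,
    father: AlleleSet,
    n_progeny: int,
    null_rate: float,
    rng: np.random.Generator,
) -> tuple[PedigreeGenotypes, list[tuple[int, int]]]:
    """Simulate Mendelian segregation in a full-sib family of diploids.

    Each progeny inherits one uniformly chosen allele from each parent;
    inherited alleles are then null-silenced independently.  Returns the
    pedigree plus the true (maternal, paternal) gametes per progeny.
    """
    if mother.n_alleles not in (1, 2) or father.n_alleles not in (1, 2):
        raise ValueError("parents must be diploid (1-2 observed alleles)")
    progeny = []
    gametes = []
    for i in range(n_progeny):
        m = int(rng.choice(mother.alleles))
        f = int(rng.choice(father.alleles))
        gametes.append((m, f))
        observed = tuple(a for a in (m, f) if rng.random() >= null_rate)
        progeny.append(
            AlleleSet(marker_id=mother.marker_id, sample_id=f"F1_{i + 1:02d}",
                      alleles=observed)
        )
    ped = PedigreeGenotypes(
        marker_id=mother.marker_id, mother=mother, father=father,
        progeny=tuple(progeny),
    )
    return ped, gametes


def simulate_fcm_stream(
    fcm_cfg: FCMSimConfig,
    ploidy: int,
    reference_ploidy: int = 2,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    replicate: int = 0,
) -> EventStream:
    """Simulate one cytometer run for a sample of the given ploidy.

    Mixture: the G0/G1 peak is Normal(mu, cv/100 * mu) with
    mu = unit_position * ploidy / reference_ploidy; the G2/M fraction
    sits at Normal(2*mu) with the same relative spread; debris follows a
    zero-truncated exponential with mean mu/3.  Events are clipped at 0.
    """
    rng = np.random.default_rng() if rng is None else rng
    mu = fcm_cfg.unit_position * ploidy / reference_ploidy
    sigma = fcm_cfg.cv_percent / 100.0 * mu
    p_debris, p_g2 = fcm_cfg.debris_fraction, fcm_cfg.g2_fraction
    n_g1, n_g2, n_debris = rng.multinomial(
        fcm_cfg.n_events, [1.0 - p_debris - p_g2, p_g2, p_debris]
    )
    parts = [
        rng.normal(mu, sigma, size=n_g1),
        rng.normal(2 * mu, 2 * sigma, size=n_g2),
        rng.exponential(mu / 3.0, size=n_debris),
    ]
    events = np.clip(np.concatenate(parts), 0.0, None)
    rng.shuffle(events)
    return EventStream(sample_id=sample_id, replicate=replicate, events=events)


def _genotype_sample(
    panel: Mapping[str, Mapping[int, float]],
    sample_id: str,
    ploidy: int,
    null_rate: float,
    rng: np.random.Generator,
) -> list[AlleleSet]:
    return [
        replace(
            simulate_individual(freqs, ploidy, null_rate, rng, marker_id=marker),
            sample_id=sample_id,
        )
        for marker, freqs in panel.items()
    ]


def simulate_study(
    cfg: SimConfig,
    species: Mapping[str, str] | None = None,
    n_fcm_replicates: int = 3,
    with_fcm: bool = True,
) -> StudyData:
    """Simulate a full survey: genotypes, clones, and cytometry runs.

    Samples and ploidies come from ``cfg.ploidy_assignments``; a sample
    with ``cfg.clone_copies[sid] = c`` additionally emits ramets
    ``sid_r2 .. sid_rc`` sharing its genotype and ploidy.  Species
    labels default to the prefix of the sample id before the first
    underscore.
    """
    if not cfg.ploidy_assignments:
        raise ValueError("cfg.ploidy_assignments is empty")
    rng = np.random.default_rng(cfg.seed)
    panel = simulate_marker_panel(cfg, rng)
    records: list[AlleleSet] = []
    truth_ploidy: dict[str, int] = {}
    clone_groups: list[tuple[str, ...]] = []
    all_ids: list[str] = []
    for sid, ploidy in cfg.ploidy_assignments.items():
        genotype = _genotype_sample(panel, sid, ploidy, cfg.null_allele_rate, rng)
        copies = int(cfg.clone_copies.get(sid, 1))
        ids = [sid] + [f"{sid}_r{j}" for j in range(2, copies + 1)]
        if copies > 1:
            clone_groups.append(tuple(sorted(ids)))
        for rid in ids:
            truth_ploidy[rid] = ploidy
            all_ids.append(rid)
            records.extend(replace(cell, sample_id=rid) for cell in genotype)
    matrix = GenotypeMatrix.from_records(records)
    species_map = (
        dict(species)
        if species is not None
        else {sid: sid.split("_")[0] for sid in all_ids}
    )

    streams: dict[str, list[EventStream]] = {}
    peak_positions: dict[str, float] = {}
    if with_fcm:
        for sid in all_ids:
            mu = cfg.fcm.unit_position * truth_ploidy[sid] / 2.0
            peak_positions[sid] = mu
            streams[sid] = [
                simulate_fcm_stream(
                    cfg.fcm, truth_ploidy[sid], reference_ploidy=2,
                    rng=rng, sample_id=sid, replicate=rep,
                )
                for rep in range(1, n_fcm_replicates + 1)
            ]
    truth = SimTruth(
        ploidy=truth_ploidy,
        clone_groups=sorted(clone_groups),
        allele_freqs={m: dict(f) for m, f in panel.items()},
        peak_positions=peak_positions,
    )
    return StudyData(matrix=matrix, species=species_map, streams=streams, truth=truth)


def default_study_config(seed: int = 0, **overrides) -> SimConfig:
    """A 48-sample study shaped like the willow survey.

    Four species of 12 stands each: one tree species all tetraploid
    (with a ramet trio), one tree species 8 tetraploid / 4 diploid (with
    a ramet pair), one shrub species 1 tetraploid / 11 diploid, and one
    shrub species 1 triploid / 11 diploid (with a ramet pair).  Ramets
    replace the last stands of their species so each species keeps 12
    sample ids.
    """
    ploidy: dict[str, int] = {}
    clones: dict[str, int] = {}
    # tree species A: 10 genets, all tetraploid; genet A_1 has 3 ramets
    for i in range(1, 11):
        ploidy[f"TreeA_{i}"] = 4
    clones["TreeA_1"] = 3
    # tree species B: 8 tetraploid + 3 diploid genets; diploid B_9 has 2 ramets
    for i in range(1, 9):
        ploidy[f"TreeB_{i}"] = 4
    for i in range(9, 12):
        ploidy[f"TreeB_{i}"] = 2
    clones["TreeB_9"] = 2
    # shrub species C: 1 tetraploid + 11 diploid
    ploidy["ShrubC_1"] = 4
    for i in range(2, 13):
        ploidy[f"ShrubC_{i}"] = 2
    # shrub species D: 1 triploid + 10 diploid genets; diploid D_2 has 2 ramets
    ploidy["ShrubD_1"] = 3
    for i in range(2, 12):
        ploidy[f"ShrubD_{i}"] = 2
    clones["ShrubD_2"] = 2
    defaults = dict(
        seed=seed,
        n_alleles_per_marker=6,
        allele_freq_concentration=5.0,
        n_markers=10,
        ploidy_assignments=ploidy,
        clone_copies=clones,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
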