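"""Polyploid candidate screening and clonal ramet detection.

With single-copy fully informative SSRs, a diploid can show at most two
distinct alleles at a locus, so any sample showing three (four) alleles
at some diagnostic marker is a triploid (tetraploid) candidate.  The
screen is one-sided: a polyploid that happens to carry duplicate alleles
can masquerade as a diploid, but a diploid can never show three alleles
at a single-copy locus, so candidate classes are never over-called.

Clonal ramets — vegetatively propagated copies of one genet — share an
identical multilocus genotype; they are detected by exact allele-set
identity at every co-typed marker, with a minimum marker overlap so that
sparsely typed samples are not grouped on thin evidence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ssr_model import AlleleSet, GenotypeMatrix

__all__ = [
    "GenotypeMatrix",
    "CandidateClass",
    "CandidateCall",
    "CloneGroup",
    "infer_candidate_ploidy",
    "detect_clonal_ramets",
    "summarize_screen",
]


class CandidateClass(str, enum.Enum):
    diploid = "diploid"
    triploid_candidate = "triploid_candidate"
    tetraploid_candidate = "tetraploid_candidate"
    higher_candidate = "higher_candidate"
    unscorable = "unscorable"


_CLASS_BY_MAX = {0: CandidateClass.unscorable, 1: CandidateClass.diploid,
                 2: CandidateClass.diploid, 3: CandidateClass.triploid_candidate,
                 4: CandidateClass.tetraploid_candidate}


def _class_from_max(max_alleles: int) -> CandidateClass:
    return _CLASS_BY_MAX.get(max_alleles, CandidateClass.higher_candidate)


@dataclass(frozen=True)
class CandidateCall:
    """Ploidy candidate class of one sample from its maximum allele count."""

    sample_id: str
    max_alleles: int
    supporting_markers: tuple[str, ...]
    n_markers_typed: int
    candidate_class: CandidateClass


@dataclass(frozen=True)
class CloneGroup:
    """Samples with identical multilocus genotypes (putative ramets)."""

    member_ids: tuple[str, ...]
    n_markers_compared: int


def infer_candidate_ploidy(
    matrix: GenotypeMatrix, diagnostic: Sequence[str]
) -> list[CandidateCall]:
    """Screen every sample by its maximum observed allele count.

    ``max_alleles`` is the maximum of |AlleleSet| over the diagnostic
    markers at which the sample is typed (missing cells skipped).  A
    single reliable three-allele marker is enough to nominate a
    candidate; ``supporting_markers`` lists every marker attaining the
    maximum so callers can require stronger support.  A sample typed at
    no diagnostic marker is ``unscorable``, not an error.
    """
    missing = [m for m in diagnostic if m not in matrix.markers]
    if missing:
        raise KeyError(f"diagnostic markers absent from the matrix: {missing}")
    calls = []
    for sample in matrix.samples:
        counts = {}
        for marker in diagnostic:
            cell = matrix.get(sample, marker)
            if cell is not None:
                counts[marker] = cell.n_alleles
        if counts:
            max_alleles = max(counts.values())
            supporting = tuple(m for m in diagnostic if counts.get(m) == max_alleles)
        else:
            max_alleles = 0
            supporting = ()
        calls.append(
            CandidateCall(
                sample_id=sample,
                max_alleles=max_alleles,
                supporting_markers=supporting,
                n_markers_typed=len(counts),
                candidate_class=_class_from_max(max_alleles),
            )
        )
    return calls


def _identical_where_cotyped(
    matrix: GenotypeMatrix, a: str, b: str, min_shared_markers: int
) -> bool:
    shared = 0
    for marker in matrix.markers:
        ca, cb = matrix.get(a, marker), matrix.get(b, marker)
        if ca is None or cb is None:
            continue
        if ca.alleles != cb.alleles:
            return False
        shared += 1
    return shared >= min_shared_markers


def detect_clonal_ramets(
    matrix: GenotypeMatrix, min_shared_markers: int = 5
) -> list[CloneGroup]:
    """Group samples whose genotypes are identical wherever co-typed.

    The pairwise relation ("identical at every co-typed marker, with at
    least ``min_shared_markers`` markers in common") is closed
    transitively; singleton groups are omitted.  Output is ordered
    lexicographically by first member, and members within a group are
    sorted, so the result is invariant to the sample order of the input.
    """
    if min_shared_markers < 1:
        raise ValueError("min_shared_markers must be >= 1")
    samples = sorted(matrix.samples)
    parent = {s: s for s in samples}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            if find(a) != find(b) and _identical_where_cotyped(
                matrix, a, b, min_shared_markers
            ):
                parent[find(b)] = find(a)

    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(find(s), []).append(s)
    out = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members)
        n_compared = min(
            sum(
                1
                for marker in matrix.markers
                if matrix.get(a, marker) is not None
                and matrix.get(b, marker) is not None
            )
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        out.append(CloneGroup(member_ids=tuple(members), n_markers_compared=n_compared))
    out.sort(key=lambda g: g.member_ids[0])
    return out


def summarize_screen(
    calls: Iterable[CandidateCall], species: Mapping[str, str]
) -> pd.DataFrame:
    """Contingency table of species x candidate class.

    Every sample must carry a species label; rows are species, columns
    the candidate classes (all classes present, zero-filled), and each
    row total equals that species' sample count.
    """
    calls = list(calls)
    labels = []
    for call in calls:
        if call.sample_id not in species:
            raise KeyError(f"sample {call.sample_id!r} has no species label")
        labels.append(species[call.sample_id])
    classes = [c.value for c in CandidateClass]
    table = pd.DataFrame(0, index=sorted(set(labels)), columns=classes, dtype=int)
    for call, label in zip(calls, labels):
        table.loc[label, call.candidate_class.value] += 1
    return table
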