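"""Codominant SSR genotypes and pedigree-based marker informativeness.

Microsatellite (SSR) genotypes are observed *dosage-blind*: fragment
analysis reports which allele sizes are present at a locus, not how many
copies of each a sample carries.  A single-copy locus in a diploid can
therefore show at most two distinct alleles, and a full-sib pedigree
(two parents plus progeny) lets us classify each marker:

* **cross type** — the parental genotype configuration.  With parental
  alleles labelled A, B, C, D, the informative configurations are
  AB x CD (no shared allele) and AB x BC (one shared allele), because
  all four offspring genotype classes can then be told apart.
* **single copy** — every progeny genotype must be explainable as one
  maternal plus one paternal gamete.  Extra alleles betray a multi-copy
  amplicon; a progeny showing a single allele that cannot be a legal
  homozygote betrays a null (non-amplifying) allele.

Markers passing both checks are *single-copy fully informative* and are
the substrate for downstream allele-count ploidy screening.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "AlleleSet",
    "PedigreeGenotypes",
    "CrossType",
    "FailureReason",
    "MarkerVerdict",
    "GenotypeMatrix",
    "PedigreeError",
    "GenotypeParseError",
    "classify_cross_type",
    "enumerate_offspring_genotypes",
    "check_single_copy",
    "read_genotype_table",
    "write_genotype_table",
    "read_pedigree_table",
]


class PedigreeError(ValueError):
    """A pedigree record is unusable (missing parent, marker mismatch...)."""


class GenotypeParseError(ValueError):
    """A genotype table row could not be parsed."""


@dataclass(frozen=True)
class AlleleSet:
    """The distinct allele sizes called for one sample at one marker.

    Alleles are integer fragment sizes in base pairs, stored sorted
    ascending and deduplicated.  An empty allele tuple means the call is
    missing.  Copy number (dosage) is deliberately not represented.
    """

    marker_id: str
    sample_id: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        cleaned = tuple(sorted(set(int(a) for a in self.alleles)))
        if any(a <= 0 for a in cleaned):
            raise ValueError(
                f"allele sizes must be positive integers, got {self.alleles!r} "
                f"for {self.sample_id}@{self.marker_id}"
            )
        object.__setattr__(self, "alleles", cleaned)

    @property
    def missing(self) -> bool:
        return len(self.alleles) == 0

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def __contains__(self, allele: int) -> bool:
        return allele in self.alleles


@dataclass(frozen=True)
class PedigreeGenotypes:
    """Mother/father/progeny allele sets at one marker (full-sib family)."""

    marker_id: str
    mother: AlleleSet
    father: AlleleSet
    progeny: tuple[AlleleSet, ...]

    def __post_init__(self) -> None:
        records = (self.mother, self.father, *self.progeny)
        for rec in records:
            if rec.marker_id != self.marker_id:
                raise PedigreeError(
                    f"marker_id mismatch: pedigree is {self.marker_id!r} but "
                    f"sample {rec.sample_id!r} is typed at {rec.marker_id!r}"
                )
        if not self.progeny:
            raise PedigreeError(f"pedigree for {self.marker_id} has no progeny")
        object.__setattr__(self, "progeny", tuple(self.progeny))


class CrossType(str, enum.Enum):
    """Parental genotype configuration of a marker in a full-sib cross."""

    ABxCD = "ABxCD"          # both parents heterozygous, no shared allele
    ABxBC = "ABxBC"          # both heterozygous, exactly one shared allele
    ABxAB = "ABxAB"          # identical heterozygotes
    uninformative = "uninformative"  # at least one homozygous parent
    invalid = "invalid"      # a parent shows >2 alleles (not single-copy)

    @property
    def fully_informative(self) -> bool:
        """True when all four offspring genotype classes are distinguishable."""
        return self in (CrossType.ABxCD, CrossType.ABxBC)


class FailureReason(str, enum.Enum):
    progeny_extra_allele = "progeny_extra_allele"
    progeny_allele_not_parental = "progeny_allele_not_parental"
    null_allele_signature = "null_allele_signature"
    parent_multiallelic = "parent_multiallelic"
    parent_homozygous = "parent_homozygous"
    identical_parent_genotypes = "identical_parent_genotypes"


@dataclass(frozen=True)
class MarkerVerdict:
    """Outcome of the pedigree segregation test for one marker."""

    marker_id: str
    cross_type: CrossType
    single_copy: bool
    fully_informative: bool
    failure_reasons: tuple[FailureReason, ...]
    n_progeny: int

    def __post_init__(self) -> None:
        if self.fully_informative and (not self.single_copy or self.failure_reasons):
            raise ValueError("fully_informative requires single_copy and no failures")


def classify_cross_type(mother: AlleleSet, father: AlleleSet) -> CrossType:
    """Classify the parental genotype configuration at one marker.

    Raises :class:`PedigreeError` when either parent call is missing.
    A parent showing more than two alleles yields ``invalid`` (the locus
    cannot be single-copy in a diploid parent).
    """
    if mother.missing or father.missing:
        raise PedigreeError(
            f"missing parental genotype at {mother.marker_id}: "
            f"mother={mother.alleles} father={father.alleles}"
        )
    if mother.n_alleles > 2 or father.n_alleles > 2:
        return CrossType.invalid
    if mother.n_alleles == 1 or father.n_alleles == 1:
        return CrossType.uninformative
    shared = len(set(mother.alleles) & set(father.alleles))
    if shared == 0:
        return CrossType.ABxCD
    if shared == 1:
        return CrossType.ABxBC
    return CrossType.ABxAB


def enumerate_offspring_genotypes(
    mother: AlleleSet, father: AlleleSet
) -> dict[tuple[int, int], float]:
    """Expected Mendelian genotype frequencies for a diploid cross.

    Each maternal allele is paired with each paternal allele with
    probability 1/(n_m * n_f); probabilities of identical unordered pairs
    are summed.  Keys are sorted allele pairs (a homozygote is ``(a, a)``).
    """
    if classify_cross_type(mother, father) is CrossType.invalid:
        raise PedigreeError(
            f"cannot enumerate offspring for a >2-allele parent at {mother.marker_id}"
        )
    out: dict[tuple[int, int], float] = {}
    p = 1.0 / (mother.n_alleles * father.n_alleles)
    for m in mother.alleles:
        for f in father.alleles:
            key = (m, f) if m <= f else (f, m)
            out[key] = out.get(key, 0.0) + p
    return out


def _gamete_consistent(progeny: AlleleSet, mother: AlleleSet, father: AlleleSet) -> bool:
    """Can the observed progeny allele set arise as {maternal, paternal} gamete?"""
    observed = set(progeny.alleles)
    return any(
        {m, f} == observed for m in mother.alleles for f in father.alleles
    )


def check_single_copy(ped: PedigreeGenotypes) -> MarkerVerdict:
    """Run the full segregation test and return a :class:`MarkerVerdict`.

    ``single_copy`` requires, for every non-missing progeny: at most two
    alleles, all alleles parental, and the set decomposable as one
    maternal plus one paternal gamete.  A single-allele progeny is legal
    only when that allele can come from both parents (the AB x BC cross
    legitimately yields BB homozygotes); otherwise it carries the
    signature of a null allele.  A parental-allele pair that is not
    gamete-consistent (e.g. {A,B} progeny under AB x CD) is also flagged
    ``null_allele_signature`` — a silenced allele plus a co-migrating
    artefact is the usual cause.

    ``fully_informative`` additionally requires cross type AB x CD or
    AB x BC and no failure of any kind.
    """
    cross = classify_cross_type(ped.mother, ped.father)
    reasons: list[FailureReason] = []
    if cross is CrossType.invalid:
        reasons.append(FailureReason.parent_multiallelic)
    elif cross is CrossType.uninformative:
        reasons.append(FailureReason.parent_homozygous)
    elif cross is CrossType.ABxAB:
        reasons.append(FailureReason.identical_parent_genotypes)

    parental = set(ped.mother.alleles) | set(ped.father.alleles)
    progeny_ok = True
    for child in ped.progeny:
        if child.missing:
            continue
        if child.n_alleles > 2:
            progeny_ok = False
            _append_once(reasons, FailureReason.progeny_extra_allele)
            continue
        if not set(child.alleles) <= parental:
            progeny_ok = False
            _append_once(reasons, FailureReason.progeny_allele_not_parental)
            continue
        if cross is not CrossType.invalid and not _gamete_consistent(
            child, ped.mother, ped.father
        ):
            progeny_ok = False
            _append_once(reasons, FailureReason.null_allele_signature)

    single_copy = progeny_ok and cross is not CrossType.invalid
    fully = single_copy and cross.fully_informative and not reasons
    return MarkerVerdict(
        marker_id=ped.marker_id,
        cross_type=cross,
        single_copy=single_copy,
        fully_informative=fully,
        failure_reasons=tuple(reasons),
        n_progeny=len(ped.progeny),
    )


def _append_once(reasons: list[FailureReason], reason: FailureReason) -> None:
    if reason not in reasons:
        reasons.append(reason)


# ---------------------------------------------------------------------------
# Genotype matrix and tabular I/O
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x markers table of :class:`AlleleSet` cells.

    Cells are stored sparsely; an absent cell is a missing call.
    """

    samples: list[str] = field(default_factory=list)
    markers: list[str] = field(default_factory=list)
    cells: dict[tuple[str, str], AlleleSet] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[AlleleSet]) -> "GenotypeMatrix":
        mat = cls()
        for rec in records:
            mat.add(rec)
        return mat

    def add(self, rec: AlleleSet) -> None:
        key = (rec.sample_id, rec.marker_id)
        if key in self.cells:
            raise GenotypeParseError(
                f"duplicate genotype row for sample {rec.sample_id!r} "
                f"at marker {rec.marker_id!r}"
            )
        if rec.sample_id not in self.samples:
            self.samples.append(rec.sample_id)
        if rec.marker_id not in self.markers:
            self.markers.append(rec.marker_id)
        self.cells[key] = rec

    def get(self, sample_id: str, marker_id: str) -> AlleleSet | None:
        """The cell, or None when the sample was not typed at the marker."""
        cell = self.cells.get((sample_id, marker_id))
        if cell is None or cell.missing:
            return None
        return cell

    def iter_records(self) -> Iterator[AlleleSet]:
        for sample in self.samples:
            for marker in self.markers:
                cell = self.cells.get((sample, marker))
                if cell is not None:
                    yield cell

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers == other.markers
            and self.cells == other.cells
        )


_ALLELE_SEPARATORS = (";", ",")


def _parse_alleles(token: str, lineno: int) -> tuple[int, ...]:
    token = token.strip()
    if not token:
        return ()
    for sep in _ALLELE_SEPARATORS:
        token = token.replace(sep, " ")
    alleles = []
    for piece in token.split():
        try:
            alleles.append(int(piece))
        except ValueError as exc:
            raise GenotypeParseError(
                f"line {lineno}: non-integer allele token {piece!r}"
            ) from exc
    return tuple(alleles)


def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read a long-format genotype TSV (sample_id, marker_id, alleles).

    Alleles are semicolon- or comma-separated integer base-pair sizes; an
    empty field is a missing call.
    """
    path = Path(path)
    mat = GenotypeMatrix()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["sample_id", "marker_id", "alleles"]
        if header[: len(required)] != required:
            raise GenotypeParseError(
                f"{path}: expected header columns {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise GenotypeParseError(f"{path}: line {lineno}: too few columns")
            sample_id, marker_id, allele_token = parts[0], parts[1], parts[2]
            mat.add(
                AlleleSet(
                    marker_id=marker_id,
                    sample_id=sample_id,
                    alleles=_parse_alleles(allele_token, lineno),
                )
            )
    return mat


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix in the canonical long TSV dialect (round-trip stable)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tmarker_id\talleles\n")
        for rec in matrix.iter_records():
            fh.write(
                f"{rec.sample_id}\t{rec.marker_id}\t"
                f"{';'.join(str(a) for a in rec.alleles)}\n"
            )


def read_pedigree_table(path: str | Path) -> dict[str, PedigreeGenotypes]:
    """Read a pedigree TSV (marker_id, role, sample_id, alleles) per marker.

    ``role`` is one of mother/father/progeny.  Returns one
    :class:`PedigreeGenotypes` per marker.
    """
    path = Path(path)
    by_marker: dict[str, dict[str, list[AlleleSet]]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["marker_id", "role", "sample_id", "alleles"]
        if header[: len(required)] != required:
            raise GenotypeParseError(
                f"{path}: expected header columns {required}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            marker_id, role, sample_id, allele_token = line.rstrip("\n").split("\t")[:4]
            if role not in ("mother", "father", "progeny"):
                raise GenotypeParseError(f"{path}: line {lineno}: unknown role {role!r}")
            rec = AlleleSet(marker_id, sample_id, _parse_alleles(allele_token, lineno))
            by_marker.setdefault(marker_id, {"mother": [], "father": [], "progeny": []})[
                role
            ].append(rec)
    out: dict[str, PedigreeGenotypes] = {}
    for marker_id, roles in by_marker.items():
        if len(roles["mother"]) != 1 or len(roles["father"]) != 1:
            raise PedigreeError(
                f"marker {marker_id}: need exactly one mother and one father row"
            )
        out[marker_id] = PedigreeGenotypes(
            marker_id=marker_id,
            mother=roles["mother"][0],
            father=roles["father"][0],
            progeny=tuple(roles["progeny"]),
        )
    return out
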