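"""Per-marker variability statistics on a diploid reference panel.

Allele frequencies are estimated from a panel of diploid, clonally
deduplicated individuals (mixing ploidy levels would bias the counts,
because a triploid's AAB and ABB genotypes are phenotypically the same
dosage-blind {A,B} call).  Each diploid contributes two allele
observations; a single-allele call is the conventional codominant
homozygote and is counted twice.

The marker summary statistic is the polymorphism information content

    PIC = 1 - sum_i p_i^2 - sum_i sum_{j>i} 2 p_i^2 p_j^2

(Botstein convention), and markers with PIC above a threshold (0.5 by
default, the conventional bar for a "highly variable" SSR) on top of a
fully-informative pedigree verdict are selected as diagnostic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .ssr_model import GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "MarkerStats",
    "PanelError",
    "estimate_allele_frequencies",
    "compute_pic",
    "marker_stats_from_frequencies",
    "select_diagnostic_markers",
]


class PanelError(ValueError):
    """The reference panel violates the diploid/deduplicated precondition."""


@dataclass(frozen=True)
class AlleleFrequencies:
    """Estimated allele frequencies for one marker.

    ``n_observations`` is always ``2 * n_samples`` (diploid panel; a
    homozygote contributes its allele twice).
    """

    marker_id: str
    freqs: dict[int, float]
    n_samples: int
    n_observations: int

    def __post_init__(self) -> None:
        if self.freqs:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.marker_id}: frequencies sum to {total}")
            if any(f <= 0 for f in self.freqs.values()):
                raise ValueError(f"{self.marker_id}: non-positive frequency")
        if self.n_observations != 2 * self.n_samples:
            raise ValueError("n_observations must equal 2 * n_samples")


@dataclass(frozen=True)
class MarkerStats:
    marker_id: str
    n_alleles: int
    pic: float
    size_range: tuple[int, int] | None
    diagnostic: bool


def estimate_allele_frequencies(
    matrix: GenotypeMatrix, panel: Sequence[str]
) -> dict[str, AlleleFrequencies]:
    """Estimate per-marker allele frequencies from a diploid panel.

    ``panel`` must list diploid samples with at most one ramet per clone.
    A panel sample showing three or more alleles at any marker raises
    :class:`PanelError`: polyploid candidates must be excluded before
    frequency estimation, as dosage-blind polyploid genotypes make the
    counts unidentifiable.
    """
    panel = list(panel)
    unknown = [s for s in panel if s not in matrix.samples]
    if unknown:
        raise PanelError(f"panel samples absent from the matrix: {unknown}")
    out: dict[str, AlleleFrequencies] = {}
    for marker in matrix.markers:
        counts: Counter[int] = Counter()
        n_samples = 0
        for sample in panel:
            cell = matrix.get(sample, marker)
            if cell is None:
                continue
            if cell.n_alleles > 2:
                raise PanelError(
                    f"panel sample {sample!r} shows {cell.n_alleles} alleles at "
                    f"{marker!r}; exclude polyploid candidates before estimating "
                    "frequencies"
                )
            n_samples += 1
            if cell.n_alleles == 1:
                counts[cell.alleles[0]] += 2
            else:
                counts[cell.alleles[0]] += 1
                counts[cell.alleles[1]] += 1
        n_obs = 2 * n_samples
        freqs = {a: c / n_obs for a, c in sorted(counts.items())} if n_obs else {}
        out[marker] = AlleleFrequencies(
            marker_id=marker, freqs=freqs, n_samples=n_samples, n_observations=n_obs
        )
    return out


def compute_pic(f: AlleleFrequencies | Mapping[int, float]) -> float:
    """Polymorphism information content of one marker.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.  The double sum is
    evaluated in closed form as (sum p^2)^2 - sum p^4.  Monomorphic
    markers return exactly 0.
    """
    freqs = f.freqs if isinstance(f, AlleleFrequencies) else dict(f)
    if not freqs:
        raise ValueError("cannot compute PIC from an empty frequency map")
    if len(freqs) < 2:
        return 0.0
    p2 = sum(p * p for p in freqs.values())
    p4 = sum(p ** 4 for p in freqs.values())
    return 1.0 - p2 - (p2 * p2 - p4)


def marker_stats_from_frequencies(
    f: AlleleFrequencies,
    fully_informative: bool,
    pic_threshold: float = 0.5,
) -> MarkerStats:
    """Bundle frequencies into a MarkerStats row with the diagnostic flag."""
    if f.freqs:
        alleles = sorted(f.freqs)
        size_range: tuple[int, int] | None = (alleles[0], alleles[-1])
        pic = compute_pic(f)
    else:
        size_range = None
        pic = 0.0
    return MarkerStats(
        marker_id=f.marker_id,
        n_alleles=len(f.freqs),
        pic=pic,
        size_range=size_range,
        diagnostic=pic > pic_threshold and fully_informative,
    )


def select_diagnostic_markers(
    stats: Iterable[MarkerStats],
    pic_threshold: float = 0.5,
    exclude: Iterable[str] = (),
) -> list[str]:
    """Markers with PIC strictly above the threshold, best first.

    ``exclude`` is a manual blacklist for markers whose alleles are not
    distinct and easily recordable — a human judgement the statistic
    cannot make.  Ties are broken by marker id for determinism.
    """
    excluded = set(exclude)
    kept = [s for s in stats if s.pic > pic_threshold and s.marker_id not in excluded]
    kept.sort(key=lambda s: (-s.pic, s.marker_id))
    return [s.marker_id for s in kept]
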