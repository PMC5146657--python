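"""Stage orchestration: marker screen, cytometry calling, study report.

The marker stage chains the pedigree informativeness test, clonal
deduplication, allele-frequency / PIC estimation on the diploid panel,
diagnostic-marker selection and the allele-count candidate screen.  The
cytometry stage turns event streams (or precomputed G0/G1 means) into
ratio-based ploidy calls against an internal diploid reference.  The
study report joins both per sample so marker/FCM concordance is
auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import fcm as fcm_mod
from .fcm import (EventStream, PeakConfig, PeakEstimate, PloidyCall, QCFlag,
                  aggregate_replicates, call_ploidy, compute_ratio,
                  find_g0g1_peak)
from .marker_stats import (MarkerStats, estimate_allele_frequencies,
                           marker_stats_from_frequencies,
                           select_diagnostic_markers)
from .ploidy_markers import (CandidateCall, CandidateClass, CloneGroup,
                             detect_clonal_ramets, infer_candidate_ploidy,
                             summarize_screen)
from .ssr_model import (GenotypeMatrix, MarkerVerdict, PedigreeGenotypes,
                        check_single_copy, read_genotype_table,
                        read_pedigree_table)

__all__ = [
    "RunConfig",
    "MarkerStageResult",
    "FCMStageResult",
    "run_marker_stage",
    "run_fcm_stage_from_means",
    "run_fcm_stage_from_streams",
    "build_study_report",
    "species_from_prefix",
]

logger = logging.getLogger("salixploidy")

_CLASS_TO_PLOIDY = {
    CandidateClass.diploid: 2,
    CandidateClass.triploid_candidate: 3,
    CandidateClass.tetraploid_candidate: 4,
}


@dataclass
class RunConfig:
    """Paths and thresholds of a full run; serialisable to flat YAML."""

    genotype_table: str = ""
    pedigree_table: str = ""
    marker_metadata: str = ""
    fcm_events_dir: str = ""
    fcm_means_table: str = ""
    reference_sample: str = ""
    reference_ploidy: int = 2
    pic_threshold: float = 0.5
    cv_threshold: float = 5.0
    min_events: int = 5000
    ploidy_tolerance: float = 0.3
    min_shared_markers: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def species_from_prefix(sample_ids: Sequence[str]) -> dict[str, str]:
    """Default species labelling: the sample-id prefix before '_'."""
    return {sid: sid.split("_")[0] for sid in sample_ids}


@dataclass
class MarkerStageResult:
    verdicts: dict[str, MarkerVerdict]
    clone_groups: list[CloneGroup]
    panel: list[str]
    stats: list[MarkerStats]
    diagnostic: list[str]
    calls: list[CandidateCall]
    summary: pd.DataFrame


def _diploid_panel(
    matrix: GenotypeMatrix,
    markers: Sequence[str],
    clone_groups: Sequence[CloneGroup],
) -> list[str]:
    """Panel = one ramet per clone, excluding >2-allele (polyploid) samples."""
    drop_ramets = {
        member for group in clone_groups for member in group.member_ids[1:]
    }
    panel = []
    for sample in matrix.samples:
        if sample in drop_ramets:
            continue
        cells = [matrix.get(sample, m) for m in markers]
        if any(c is not None and c.n_alleles > 2 for c in cells):
            continue  # polyploid candidate: excluded from frequency estimation
        panel.append(sample)
    return panel


def run_marker_stage(
    matrix: GenotypeMatrix,
    pedigrees: Mapping[str, PedigreeGenotypes] | None = None,
    species: Mapping[str, str] | None = None,
    pic_threshold: float = 0.5,
    min_shared_markers: int = 5,
    exclude_markers: Sequence[str] = (),
    assume_informative: bool = False,
) -> MarkerStageResult:
    """Run the full marker-aided selection stage.

    When ``pedigrees`` is given, markers are first classified by the
    full-sib segregation test and only single-copy fully informative
    ones proceed; with ``assume_informative=True`` (e.g. simulated
    panels built from known single-copy loci) every matrix marker
    proceeds directly.
    """
    if not matrix.samples or not matrix.markers:
        raise ValueError("empty genotype matrix")
    verdicts: dict[str, MarkerVerdict] = {}
    if pedigrees is not None:
        verdicts = {m: check_single_copy(p) for m, p in pedigrees.items()}
        informative = [m for m in matrix.markers
                       if m in verdicts and verdicts[m].fully_informative]
    elif assume_informative:
        informative = list(matrix.markers)
    else:
        raise ValueError("need pedigrees, or assume_informative=True")
    logger.info("markers tested: %d; single-copy fully informative: %d",
                len(matrix.markers), len(informative))

    clone_groups = detect_clonal_ramets(matrix, min_shared_markers=min_shared_markers)
    panel = _diploid_panel(matrix, informative, clone_groups)
    freqs = estimate_allele_frequencies(matrix, panel)
    stats = [
        marker_stats_from_frequencies(freqs[m], fully_informative=True,
                                      pic_threshold=pic_threshold)
        for m in informative
    ]
    diagnostic = select_diagnostic_markers(stats, pic_threshold=pic_threshold,
                                           exclude=exclude_markers)
    logger.info("diagnostic markers (PIC > %.2f): %d", pic_threshold, len(diagnostic))
    calls = infer_candidate_ploidy(matrix, diagnostic)
    species_map = dict(species) if species else species_from_prefix(matrix.samples)
    summary = summarize_screen(calls, species_map)
    return MarkerStageResult(
        verdicts=verdicts, clone_groups=clone_groups, panel=panel, stats=stats,
        diagnostic=diagnostic, calls=calls, summary=summary,
    )


@dataclass
class FCMStageResult:
    calls: list[PloidyCall]
    peaks: dict[str, PeakEstimate]
    replicate_cvs: dict[str, list[float]]
    reference_mean: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _calls_to_table(result: FCMStageResult, species: Mapping[str, str] | None) -> pd.DataFrame:
    rows = []
    for call in result.calls:
        rows.append({
            "sample_id": call.sample_id,
            "species": (species or {}).get(call.sample_id, ""),
            "g0g1_mean": result.peaks[call.sample_id].mean_position,
            "ratio": call.ratio,
            "ploidy_level": f"{call.ploidy}x",
            "cv_percent": ";".join(f"{cv:.2f}" for cv in
                                   result.replicate_cvs.get(call.sample_id, [])),
            "qc_pass": call.qc_pass,
            "flags": ";".join(f.value for f in call.flags),
        })
    return pd.DataFrame(rows)


def run_fcm_stage_from_means(
    means: Mapping[str, float],
    reference_mean: float,
    reference_ploidy: int = 2,
    tolerance: float = 0.3,
    species: Mapping[str, str] | None = None,
) -> FCMStageResult:
    """Ploidy calls from precomputed G0/G1 peak means (published-table mode).

    Ratios are rounded to two decimals before calling, matching the
    semantics of a printed survey table.
    """
    if reference_mean <= 0:
        raise fcm_mod.FCMError("reference mean must be positive")
    calls, peaks = [], {}
    for sid, mean in means.items():
        ratio = compute_ratio(mean, reference_mean)
        call = call_ploidy(ratio, reference_ploidy=reference_ploidy,
                           tolerance=tolerance, sample_id=sid)
        calls.append(call)
        peaks[sid] = PeakEstimate(mean_position=float(mean), sd=float("nan"),
                                  cv_percent=float("nan"), n_gated=0,
                                  gate=(0.0, float(mean) * 2))
    result = FCMStageResult(calls=calls, peaks=peaks, replicate_cvs={},
                            reference_mean=float(reference_mean))
    result.table = _calls_to_table(result, species)
    return result


def run_fcm_stage_from_streams(
    streams: Mapping[str, Sequence[EventStream]],
    reference_sample: str,
    reference_ploidy: int = 2,
    tolerance: float = 0.3,
    cv_threshold: float = 5.0,
    peak_config: PeakConfig = PeakConfig(),
    species: Mapping[str, str] | None = None,
) -> FCMStageResult:
    """Ploidy calls from raw event streams.

    Per sample: estimate the G0/G1 peak in every replicate, pool the
    replicate means, then ratio the pooled mean against the reference
    sample's pooled mean and call ploidy on the raw ratio.  Replicates
    failing CV or event-count QC flag the call but are never dropped.
    """
    if reference_sample not in streams:
        raise fcm_mod.FCMError(
            f"reference sample {reference_sample!r} has no event streams"
        )
    pooled: dict[str, PeakEstimate] = {}
    qc: dict[str, tuple[bool, tuple[QCFlag, ...]]] = {}
    replicate_cvs: dict[str, list[float]] = {}
    min_gate_events = min(peak_config.min_events,
                          min(len(s.events) for ss in streams.values() for s in ss))
    for sid, replicates in streams.items():
        if not replicates:
            raise fcm_mod.FCMError(f"sample {sid!r} has no replicates")
        estimates = [find_g0g1_peak(s, peak_config) for s in replicates]
        replicate_cvs[sid] = [e.cv_percent for e in estimates]
        # gating discards tail events, so the gated-count QC floor is
        # interpreted against the gated fraction, not the raw stream size
        pooled[sid], ok, flags = aggregate_replicates(
            estimates, cv_threshold=cv_threshold,
            min_events=int(0.5 * min_gate_events),
        )
        qc[sid] = (ok, flags)
    ref_mean = pooled[reference_sample].mean_position
    calls = []
    for sid in streams:
        raw_ratio = pooled[sid].mean_position / ref_mean
        call = call_ploidy(raw_ratio, reference_ploidy=reference_ploidy,
                           tolerance=tolerance, sample_id=sid)
        ok, flags = qc[sid]
        call = PloidyCall(
            sample_id=sid,
            ratio=fcm_mod.round_ratio(raw_ratio),
            ploidy_estimate=call.ploidy_estimate,
            ploidy=call.ploidy,
            reference_ploidy=reference_ploidy,
            qc_pass=call.qc_pass and ok,
            flags=tuple(call.flags) + flags,
        )
        calls.append(call)
    result = FCMStageResult(calls=calls, peaks=pooled, replicate_cvs=replicate_cvs,
                            reference_mean=ref_mean)
    result.table = _calls_to_table(result, species)
    return result


def build_study_report(
    marker: MarkerStageResult | None,
    fcm_result: FCMStageResult,
    species: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join marker screen and cytometry calls into the per-sample report.

    The ``concordant`` column compares the marker candidate class's
    implied ploidy with the FCM call; the marker screen is one-sided
    (it can under- but never over-call), so a diploid marker class with
    a higher FCM ploidy is discordant and worth inspecting, while exact
    agreement is the expected outcome for sufficiently heterozygous
    polyploids.
    """
    table = fcm_result.table.copy()
    if marker is not None:
        by_sample = {c.sample_id: c for c in marker.calls}
        clone_of = {}
        for i, group in enumerate(marker.clone_groups, start=1):
            for member in group.member_ids:
                clone_of[member] = f"clone_{i}"
        marker_class, supporting, clone_col, concord = [], [], [], []
        for sid in table["sample_id"]:
            call = by_sample.get(sid)
            if call is None:
                marker_class.append("")
                supporting.append("")
                concord.append("")
            else:
                marker_class.append(call.candidate_class.value)
                supporting.append(";".join(call.supporting_markers))
                implied = _CLASS_TO_PLOIDY.get(call.candidate_class)
                fcm_ploidy = int(table.loc[table["sample_id"] == sid, "ploidy_level"]
                                 .iloc[0].rstrip("x"))
                concord.append("" if implied is None else str(implied == fcm_ploidy))
            clone_col.append(clone_of.get(sid, ""))
        table["marker_class"] = marker_class
        table["supporting_markers"] = supporting
        table["clone_group"] = clone_col
        table["concordant"] = concord
    # internal consistency: per-species counts must equal row counts
    if "species" in table.columns and table["species"].any():
        counts = table.groupby("species").size()
        assert int(counts.sum()) == len(table)
    return table


def write_report(table: pd.DataFrame, tsv_path: str | Path,
                 json_path: str | Path | None = None,
                 config: RunConfig | None = None) -> None:
    """Write the study report as TSV, optionally with a JSON sidecar."""
    table.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "rows": table.to_dict(orient="records"),
            "config": asdict(config) if config is not None else None,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, default=str))
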