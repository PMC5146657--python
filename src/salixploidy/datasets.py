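"""Bundled reference tables from the willow ploidy survey.

Two small TSVs ship with the package:

* ``diagnostic_markers.tsv`` — the ten diagnostic SSR primers (primer
  sequences, parental cross type in the mapping pedigree, PIC in the
  12-stand *S. suchowensis* panel).
* ``fcm_ploidy_survey.tsv`` — the published cytometry survey of 48
  willow stands: per measurement group the G0/G1 peak mean, the ratio
  against the diploid reference, the called ploidy level and the CV%.

Module constants record the survey's scalar inputs: the reference
sample's peak position (channel 10739, diploid *S. suchowensis*), the
primer amplification tally (174 of 192 primers succeeded on all four
species), and the PIC of the eleventh single-copy marker (0.34) that
the PIC > 0.5 filter removed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "REFERENCE_SAMPLE",
    "REFERENCE_G0G1",
    "REFERENCE_PLOIDY",
    "N_PRIMERS_TESTED",
    "N_PRIMERS_AMPLIFIED",
    "NONDIAGNOSTIC_MARKER_PIC",
    "load_diagnostic_markers",
    "load_fcm_survey",
    "expand_survey_accessions",
]

REFERENCE_SAMPLE = "Ssu_2"
REFERENCE_G0G1 = 10739.0
REFERENCE_PLOIDY = 2
N_PRIMERS_TESTED = 192
N_PRIMERS_AMPLIFIED = 174
#: PIC of the one single-copy fully informative marker (of eleven) that
#: fell below the 0.5 diagnostic threshold.
NONDIAGNOSTIC_MARKER_PIC = 0.34


def _data_path(name: str):
    return resources.files("salixploidy.data").joinpath(name)


def load_diagnostic_markers() -> pd.DataFrame:
    """The ten diagnostic SSR markers (marker metadata table)."""
    with resources.as_file(_data_path("diagnostic_markers.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_fcm_survey() -> pd.DataFrame:
    """The cytometry survey, one row per measurement group.

    ``accessions`` holds comma-separated stand ids sharing a
    measurement; ``ploidy_level`` is the printed label (``2x``/``3x``/
    ``4x``).
    """
    with resources.as_file(_data_path("fcm_ploidy_survey.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def expand_survey_accessions(survey: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per accession (stand), repeating its group's measurements."""
    if survey is None:
        survey = load_fcm_survey()
    rows = []
    for _, row in survey.iterrows():
        for accession in str(row["accessions"]).split(","):
            out = row.to_dict()
            out["accession"] = accession.strip()
            rows.append(out)
    return pd.DataFrame(rows).drop(columns=["accessions"])
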