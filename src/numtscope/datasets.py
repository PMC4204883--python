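"""Bundled reference data from the published orthopteran numt survey.

Three small plain-text tables ship with the package:

* ``orthoptera_clone_survey.tsv`` — per-(family, locus) clone counts for
  COI, COII and ND5 across 28 orthopteran families: total clones
  sequenced, clones identical to the mitochondrial ortholog, unique
  numts, and unique numts carrying a stop codon or indel.
* ``orthoptera_numt_classes.tsv`` — per-(family, locus)
  paleonumt/neonumt counts from the per-taxon phylogenetic analyses.
* ``orthoptera_fossil_calibrations.csv`` — fossil age intervals (MY)
  bounding the most recent common ancestor of family sets in which
  shared ancient numts (synaponumts) were recovered.

These are published summary counts, bundled so aggregation and dating
can be exercised and checked without any sequence downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import FossilCalibration
from .report import FamilyLocusSummary

__all__ = [
    "load_clone_survey",
    "load_numt_class_counts",
    "load_fossil_calibrations",
    "clone_survey_rows",
]


def _data_path(name: str):
    return resources.files("numtscope").joinpath("data", name)


def load_clone_survey() -> pd.DataFrame:
    """Per-(family, locus) clone survey counts as a DataFrame."""
    with resources.as_file(_data_path("orthoptera_clone_survey.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def clone_survey_rows(locus: str | None = None) -> list[FamilyLocusSummary]:
    """Clone survey counts as :class:`FamilyLocusSummary` rows."""
    frame = load_clone_survey()
    if locus is not None:
        frame = frame[frame.locus == locus]
    return [
        FamilyLocusSummary(
            taxon=rec.family,
            locus=rec.locus,
            n_total_clones=int(rec.n_total_clones),
            n_identical=int(rec.n_identical),
            n_unique_numts=int(rec.n_unique_numts),
            n_numts_with_stop_or_indel=int(rec.n_numts_with_stop_or_indel),
        )
        for rec in frame.itertuples(index=False)
    ]


def load_numt_class_counts() -> pd.DataFrame:
    """Per-(family, locus) paleonumt/neonumt counts as a DataFrame."""
    with resources.as_file(_data_path("orthoptera_numt_classes.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_fossil_calibrations() -> FossilCalibration:
    """Fossil MRCA age constraints for orthopteran family sets."""
    with resources.as_file(
        _data_path("orthoptera_fossil_calibrations.csv")
    ) as path:
        return FossilCalibration.from_csv(path)
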