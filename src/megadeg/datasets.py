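"""The nine-study atopic-dermatitis microarray catalog used as the default
multi-study design.

These are the published GEO series identifiers with their sample counts,
countries, study ages and platforms; only the metadata is carried here — the
expression matrices themselves are read from files or simulated.
"""

from __future__ import annotations

from .io import DatasetMeta

__all__ = ["example_catalog"]

_DATA_TYPE = "microarray expression profiling"
_COMPARISON = "AD vs healthy controls"

_STUDIES = [
    # (id, n_control, n_case, country, study_age, platform)
    ("GSE5667", 5, 12, "United States", 15, "GPL96"),
    ("GSE6012", 10, 10, "Sweden", 15, "GPL96"),
    ("GSE16161", 9, 9, "United States", 12, "GPL570"),
    ("GSE26952", 7, 5, "United States", 10, "GPL2700"),
    ("GSE32924", 8, 25, "United States", 10, "GPL570"),
    ("GSE60709", 21, 12, "Germany", 7, "GPL6947"),
    ("GSE116486", 18, 28, "United States", 3, "GPL570"),
    ("GSE120721", 22, 30, "United States", 3, "GPL570"),
    ("GSE153007", 5, 24, "United States", 1, "GPL6480"),
]


def example_catalog() -> list[DatasetMeta]:
    """Metadata for the nine case/control studies, in publication order."""
    return [
        DatasetMeta(
            dataset_id=sid,
            n_control=nc,
            n_case=na,
            country=country,
            study_age=age,
            organism="Homo sapiens",
            platform=platform,
            data_type=_DATA_TYPE,
            comparison=_COMPARISON,
            downloadable=True,
        )
        for sid, nc, na, country, age, platform in _STUDIES
    ]
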