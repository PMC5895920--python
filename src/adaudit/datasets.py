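"""Packaged example data.

``us_audience_2016`` is the September-2016 snapshot of published US-wide
audience totals for the study's marker, placebo and baseline interests
(granularity 20; US-wide rows only — the per-state counts behind the
original analyses were never released).  ``us_interest_taxonomy`` carries
the matching role assignments: markers for alcoholism, obesity, diabetes
and food sensitivities, five generic placebos, and the fitness-and-wellness
health baseline.
"""

from __future__ import annotations

from importlib import resources
from typing import List

from .core import AudienceSnapshot, InterestSpec
from .io import read_snapshot, read_taxonomy


def _data_path(name: str):
    return resources.files("adaudit.data") / name


def us_audience_2016() -> AudienceSnapshot:
    """US-wide published audience totals, September 2016."""
    with resources.as_file(_data_path("us_audience_2016.jsonl")) as path:
        return read_snapshot(path)


def us_interest_taxonomy() -> List[InterestSpec]:
    """Role assignments for the 2016 study interests."""
    with resources.as_file(_data_path("us_interests_2016.json")) as path:
        return read_taxonomy(path)
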