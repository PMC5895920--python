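"""Domain types for advertising-audience analysis.

The unit of observation is a *reach estimate*: the number of platform users
matching a targeting selection (a geography, demographic constraints, and a
conjunction of interests), reported rounded to a fixed granularity (20 users
by default) for k-anonymity.  This module defines the query/estimate types,
the granularity rounding rule, the stored-snapshot audience provider, and
the table of regional health statistics the estimates are compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Protocol, runtime_checkable

import pandas as pd

from .errors import (
    InvalidArgumentError,
    MissingEstimateError,
    ValidationError,
)

GENDERS = ("any", "female", "male")
AGE_BRACKETS = ("any", "18-24", "25-44", "45-64", "65+")
ETHNICITIES = (
    "any",
    "african_american",
    "asian_american",
    "hispanic",
    "none_of_above",
)
INTEREST_ROLES = ("marker", "placebo", "baseline", "reference")

#: 50 US state postal codes (no District of Columbia).
US_STATES = (
    "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "FL", "GA",
    "HI", "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME", "MD",
    "MA", "MI", "MN", "MS", "MO", "MT", "NE", "NV", "NH", "NJ",
    "NM", "NY", "NC", "ND", "OH", "OK", "OR", "PA", "RI", "SC",
    "SD", "TN", "TX", "UT", "VT", "VA", "WA", "WV", "WI", "WY",
)

DEFAULT_GRANULARITY = 20


def round_to_granularity(count: float, granularity: int) -> int:
    """Round a non-negative count to the nearest multiple of ``granularity``.

    Exact halves round away from zero, so ``round_to_granularity(30, 20)``
    is 40.  This emulates the coarsening an aggregate-count API applies
    before releasing audience sizes.
    """
    if granularity < 1 or int(granularity) != granularity:
        raise InvalidArgumentError(f"granularity must be a positive integer, got {granularity!r}")
    if not math.isfinite(count) or count < 0:
        raise InvalidArgumentError(f"count must be a finite non-negative number, got {count!r}")
    return int(granularity) * int(math.floor(count / granularity + 0.5))


@dataclass(frozen=True)
class AudienceQuery:
    """A targeting selection: geography x demographics x interest conjunction.

    ``interests`` is an unordered conjunction; an empty set means "no
    interest constraint".  Demographic fields take ``"any"`` to mean no
    constraint on that axis.
    """

    geography: str
    gender: str = "any"
    age_bracket: str = "any"
    ethnic_affinity: str = "any"
    interests: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.geography:
            raise InvalidArgumentError("geography must be non-empty")
        if self.gender not in GENDERS:
            raise InvalidArgumentError(f"gender {self.gender!r} not in {GENDERS}")
        if self.age_bracket not in AGE_BRACKETS:
            raise InvalidArgumentError(f"age_bracket {self.age_bracket!r} not in {AGE_BRACKETS}")
        if self.ethnic_affinity not in ETHNICITIES:
            raise InvalidArgumentError(
                f"ethnic_affinity {self.ethnic_affinity!r} not in {ETHNICITIES}"
            )
        object.__setattr__(self, "interests", frozenset(self.interests))

    def with_interests(self, interests: Iterable[str]) -> "AudienceQuery":
        return AudienceQuery(
            geography=self.geography,
            gender=self.gender,
            age_bracket=self.age_bracket,
            ethnic_affinity=self.ethnic_affinity,
            interests=frozenset(interests),
        )

    def __str__(self) -> str:  # used in error messages
        ints = "+".join(sorted(self.interests)) or "<none>"
        return (
            f"{self.geography}/{self.gender}/{self.age_bracket}/"
            f"{self.ethnic_affinity}/{ints}"
        )


@dataclass(frozen=True)
class AudienceEstimate:
    """A query together with its rounded aggregate audience count."""

    query: AudienceQuery
    count: int

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise InvalidArgumentError(f"count must be a non-negative integer, got {self.count!r}")


@dataclass(frozen=True)
class InterestSpec:
    """An interest and its analysis role.

    A *marker* interest proxies a specific health condition (``condition``
    required); a *placebo* is a popular generic interest with no plausible
    causal link, used to estimate the background correlation level; a
    *baseline* is a broad health interest capturing general health
    awareness; a *reference* interest serves only as a normalization
    denominator.
    """

    name: str
    role: str
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in INTEREST_ROLES:
            raise InvalidArgumentError(f"role {self.role!r} not in {INTEREST_ROLES}")
        if (self.role == "marker") != (self.condition is not None):
            raise InvalidArgumentError(
                f"interest {self.name!r}: condition must be given iff role is 'marker'"
            )


class HealthStatTable:
    """State-level condition prevalences, one row per (state, condition).

    Prevalences are stored as fractions in [0, 1]; any percent conversion is
    a rendering concern.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["state", "condition", "prevalence"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValidationError(f"health table missing columns {missing}")
        frame = frame[required].copy()
        frame["prevalence"] = frame["prevalence"].astype(float)
        dup = frame.duplicated(subset=["state", "condition"])
        if dup.any():
            keys = frame.loc[dup, ["state", "condition"]].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (state, condition) rows: {keys}")
        bad = frame[(frame["prevalence"] < 0) | (frame["prevalence"] > 1)]
        if len(bad):
            raise ValidationError(
                "prevalence outside [0, 1] for "
                + ", ".join(f"({r.state}, {r.condition})={r.prevalence}" for r in bad.itertuples())
            )
        self._frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, rows: Iterable[tuple]) -> "HealthStatTable":
        return cls(pd.DataFrame(rows, columns=["state", "condition", "prevalence"]))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def conditions(self) -> list:
        return sorted(self._frame["condition"].unique())

    @property
    def states(self) -> list:
        return sorted(self._frame["state"].unique())

    def prevalence_series(self, condition: str) -> pd.Series:
        """Prevalence indexed by state for one condition."""
        sub = self._frame[self._frame["condition"] == condition]
        if sub.empty:
            raise ValidationError(f"condition {condition!r} not in health table")
        return sub.set_index("state")["prevalence"].sort_index()

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HealthStatTable):
            return NotImplemented
        a = self._frame.sort_values(["state", "condition"]).reset_index(drop=True)
        b = other._frame.sort_values(["state", "condition"]).reset_index(drop=True)
        return a.equals(b)


@runtime_checkable
class AudienceProvider(Protocol):
    """Anything that answers audience queries with rounded counts."""

    granularity: int

    def audience(self, query: AudienceQuery) -> int: ...


class AudienceSnapshot:
    """A stored collection of audience estimates taken at one point in time.

    This is the only ingestion path for real platform data: an API dump is
    converted to estimates once and analyses run against the frozen
    snapshot.  Counts must be multiples of the snapshot granularity and
    queries must be unique.
    """

    def __init__(
        self,
        estimates: Iterable[AudienceEstimate],
        granularity: int = DEFAULT_GRANULARITY,
        timestamp: str = "",
    ):
        if granularity < 1:
            raise InvalidArgumentError("granularity must be positive")
        self.granularity = int(granularity)
        self.timestamp = timestamp
        self._counts: dict = {}
        self.estimates = list(estimates)
        for est in self.estimates:
            if est.count % self.granularity:
                raise ValidationError(
                    f"count {est.count} for {est.query} is not a multiple of {self.granularity}"
                )
            if est.query in self._counts:
                raise ValidationError(f"duplicate query in snapshot: {est.query}")
            self._counts[est.query] = est.count

    def audience(self, query: AudienceQuery) -> int:
        try:
            return self._counts[query]
        except KeyError:
            raise MissingEstimateError(f"no estimate stored for query {query}") from None

    def __len__(self) -> int:
        return len(self.estimates)

    def __contains__(self, query: AudienceQuery) -> bool:
        return query in self._counts


def snapshot_audience(snapshot: AudienceSnapshot, query: AudienceQuery) -> int:
    """Look up the stored count for ``query`` in ``snapshot``."""
    return snapshot.audience(query)


def taxonomy_by_role(taxonomy: Iterable[InterestSpec]) -> Mapping[str, list]:
    """Group an interest taxonomy by role, preserving order."""
    out: dict = {role: [] for role in INTEREST_ROLES}
    for spec in taxonomy:
        out[spec.role].append(spec)
    return out
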