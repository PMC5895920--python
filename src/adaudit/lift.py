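"""Lift between targeting selections, from aggregate audience counts alone.

For selections A and B with audience counts N_A, N_B, a joint count N_AB
and a base population N_pop,

    lift(A, B) = P(A and B) / (P(A) * P(B)) = (N_AB * N_pop) / (N_A * N_B)

with P(A) = N_A / N_pop.  Lift 1 means the selections co-occur as often as
independence predicts; above 1 they attract, below 1 they repel.  B may be
a second interest selection or a demographic restriction (then N_AB is A's
audience restricted to B and N_B the base audience restricted to B).

Because all four counts are granularity-rounded, lifts computed from small
audiences are imprecise; records whose smallest count is below twice the
granularity carry a low-precision flag rather than being suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .core import AudienceProvider, AudienceQuery
from .errors import InconsistentCountsError, InvalidArgumentError, UndefinedLiftError

#: A selection is an interest name, a set of names, or a demographic mapping
#: such as {"gender": "male"} / {"age_bracket": "65+"}.
Selection = Union[str, Iterable[str], Mapping[str, str]]

#: Default base population: US-wide, no demographic or interest constraint.
US_ADULTS = AudienceQuery(geography="US")


def _is_demographic(sel: Selection) -> bool:
    return isinstance(sel, Mapping)


def _interest_set(sel: Selection) -> frozenset:
    if isinstance(sel, str):
        return frozenset((sel,))
    return frozenset(sel)


def selection_label(sel: Selection) -> str:
    if _is_demographic(sel):
        return ",".join(f"{k}={v}" for k, v in sorted(sel.items()))
    return " + ".join(sorted(_interest_set(sel)))


def _restrict(query: AudienceQuery, demo: Mapping[str, str]) -> AudienceQuery:
    allowed = {"gender", "age_bracket", "ethnic_affinity"}
    bad = set(demo) - allowed
    if bad:
        raise InvalidArgumentError(f"unknown demographic fields {sorted(bad)}")
    fields = {
        "geography": query.geography,
        "gender": query.gender,
        "age_bracket": query.age_bracket,
        "ethnic_affinity": query.ethnic_affinity,
    }
    fields.update(demo)
    return AudienceQuery(interests=query.interests, **fields)


@dataclass(frozen=True)
class LiftRecord:
    """A computed lift with the four counts that produced it."""

    a: str
    b: str
    n_a: int
    n_b: int
    n_ab: int
    n_pop: int
    lift: float
    low_precision: bool


def lift(
    provider: AudienceProvider,
    a: Selection,
    b: Selection,
    base_query: AudienceQuery = US_ADULTS,
) -> LiftRecord:
    """Compute lift(A, B) over ``base_query``'s population.

    A must be an interest selection.  B is either an interest selection
    (the joint audience is the conjunction of both interest sets) or a
    demographic restriction (the joint audience is A's audience within that
    demographic slice of the base).
    """
    if _is_demographic(a):
        raise InvalidArgumentError("selection A must be an interest selection")
    a_set = _interest_set(a)
    n_pop = provider.audience(base_query)
    n_a = provider.audience(base_query.with_interests(base_query.interests | a_set))
    if _is_demographic(b):
        n_b = provider.audience(_restrict(base_query, b))
        n_ab = provider.audience(
            _restrict(base_query.with_interests(base_query.interests | a_set), b)
        )
    else:
        b_set = _interest_set(b)
        n_b = provider.audience(base_query.with_interests(base_query.interests | b_set))
        n_ab = provider.audience(
            base_query.with_interests(base_query.interests | a_set | b_set)
        )
    if 0 in (n_a, n_b, n_pop):
        raise UndefinedLiftError(
            f"lift undefined for A={selection_label(a)!r}, B={selection_label(b)!r}: "
            f"N_A={n_a}, N_B={n_b}, N_pop={n_pop}"
        )
    g = provider.granularity
    if n_ab > min(n_a, n_b) + g:
        raise InconsistentCountsError(
            f"joint count {n_ab} exceeds min marginal {min(n_a, n_b)} beyond "
            f"granularity {g} for A={selection_label(a)!r}, B={selection_label(b)!r}"
        )
    return LiftRecord(
        a=selection_label(a),
        b=selection_label(b),
        n_a=n_a,
        n_b=n_b,
        n_ab=n_ab,
        n_pop=n_pop,
        lift=(n_ab * n_pop) / (n_a * n_b),
        low_precision=min(n_a, n_b, n_ab) < 2 * g,
    )


def lift_from_counts(n_a: int, n_b: int, n_ab: int, n_pop: int) -> float:
    """The bare estimator, for counts obtained elsewhere."""
    if 0 in (n_a, n_b, n_pop):
        raise UndefinedLiftError(f"lift undefined: N_A={n_a}, N_B={n_b}, N_pop={n_pop}")
    return (n_ab * n_pop) / (n_a * n_b)


def rank_lifts(
    records: Sequence[LiftRecord], top_k: int
) -> Tuple[List[LiftRecord], List[LiftRecord]]:
    """Top-k most directly related and most inversely related pairs.

    Sorting is stable with ties broken lexicographically by (A, B) labels;
    a ``top_k`` beyond the record count saturates to full lists.
    """
    if top_k < 1:
        raise InvalidArgumentError(f"top_k must be >= 1, got {top_k}")
    if not records:
        raise InvalidArgumentError("records must be non-empty")
    descending = sorted(records, key=lambda rec: (-rec.lift, rec.a, rec.b))
    ascending = sorted(records, key=lambda rec: (rec.lift, rec.a, rec.b))
    return descending[:top_k], ascending[:top_k]


def lift_frame(records: Iterable[LiftRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "A": r.a,
                "B": r.b,
                "lift": r.lift,
                "N_A": r.n_a,
                "N_B": r.n_b,
                "N_AB": r.n_ab,
                "N_pop": r.n_pop,
                "low_precision": r.low_precision,
            }
            for r in records
        ]
    )


class ComorbidityLiftAnalysis:
    """Model object: lifts for a list of selection pairs over one base."""

    def __init__(
        self,
        provider: AudienceProvider,
        pairs: Sequence[Tuple[Selection, Selection]],
        base_query: AudienceQuery = US_ADULTS,
    ):
        self.provider = provider
        self.pairs = list(pairs)
        self.base_query = base_query

    def fit(self) -> "LiftResults":
        records = [lift(self.provider, a, b, self.base_query) for a, b in self.pairs]
        return LiftResults(model=self, records=records)


class LiftResults:
    def __init__(self, model: ComorbidityLiftAnalysis, records: List[LiftRecord]):
        self.model = model
        self.records = records

    def rank(self, top_k: int) -> Tuple[List[LiftRecord], List[LiftRecord]]:
        return rank_lifts(self.records, top_k)

    def to_frame(self) -> pd.DataFrame:
        return lift_frame(self.records)

    def summary(self, top_k: int = 20) -> str:
        top, bottom = self.rank(top_k)
        lines = ["Lift analysis", "", "Directly related (greatest lift):"]
        lines += [f"  {r.a}  |  {r.b}  |  {r.lift:.2f}" for r in top]
        lines += ["", "Inversely related (smallest lift):"]
        lines += [f"  {r.a}  |  {r.b}  |  {r.lift:.2f}" for r in bottom]
        return "\n".join(lines)

    def to_tsv(self, path, top_k: int = 20) -> None:
        top, bottom = self.rank(top_k)
        with open(path, "w") as fh:
            fh.write("section\tA\tB\tlift\n")
            for section, recs in (("directly related", top), ("inversely related", bottom)):
                for r in recs:
                    fh.write(f"{section}\t{r.a}\t{r.b}\t{r.lift:.4f}\n")
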