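"""Correlation screening of interest shares against health statistics.

Raw audience counts mean little on their own: a state with more platform
users has a larger audience for every interest.  Counts are therefore
normalized into *shares* against a reference population — all platform
users (``FB_pop``), users interested in the platform itself (``FB_int``),
or users holding a broad health baseline interest (``FW_int``).

For every Facebook-style index f (an interest under a normalization) and
health index h (a condition prevalence), the screen computes the Pearson
correlation r_fh across regions with its two-tailed p from
``t = r * sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of freedom, and applies
a Bonferroni threshold alpha/k where k is the number of (interest,
condition, normalization) hypotheses actually tested.

The key confound control is the *placebo envelope*: the largest |r| any
placebo interest attains for a condition.  A marker correlation is only
flagged as exceeding background once it beats that envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import AudienceProvider, AudienceQuery, HealthStatTable, InterestSpec
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidArgumentError,
    UndefinedShareError,
)

logger = logging.getLogger(__name__)

SCREENED_ROLES = ("marker", "placebo", "baseline")


@dataclass(frozen=True)
class NormalizationScheme:
    """Maps a (geography, demographic) cell to its reference query.

    ``reference_interests`` is empty for the all-users reference and
    otherwise names the interest(s) whose audience is the denominator.
    """

    name: str
    reference_interests: frozenset = frozenset()

    def reference_query(self, geo: str, demo: Optional[Mapping[str, str]] = None) -> AudienceQuery:
        demo = dict(demo or {})
        return AudienceQuery(geography=geo, interests=self.reference_interests, **demo)


#: The three standard reference populations.
FB_POP = NormalizationScheme(name="FB_pop")
FB_INT = NormalizationScheme(name="FB_int", reference_interests=frozenset(("Facebook",)))
FW_INT = NormalizationScheme(
    name="FW_int", reference_interests=frozenset(("Fitness and wellness",))
)
STANDARD_SCHEMES: Dict[str, NormalizationScheme] = {
    s.name: s for s in (FB_POP, FB_INT, FW_INT)
}


def normalized_share(
    provider: AudienceProvider,
    interest: str,
    geo: str,
    demo: Optional[Mapping[str, str]] = None,
    scheme: NormalizationScheme = FB_POP,
) -> float:
    """Audience share of ``interest`` relative to the scheme's reference.

    The share may exceed 1 by rounding slack when the numerator audience
    nearly equals the reference; such cells are logged, never clipped.
    """
    demo = dict(demo or {})
    numer = provider.audience(
        AudienceQuery(geography=geo, interests=frozenset((interest,)), **demo)
    )
    denom = provider.audience(scheme.reference_query(geo, demo))
    if denom == 0:
        raise UndefinedShareError(
            f"zero reference count for scheme {scheme.name} in cell geo={geo} demo={demo}"
        )
    share = numer / denom
    if share > 1.0:
        logger.warning(
            "share %.4f > 1 for interest %r under %s in geo=%s (rounding slack)",
            share, interest, scheme.name, geo,
        )
    return share


def pearson_correlation(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Product-moment correlation; rejects short or constant inputs."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise InvalidArgumentError("inputs must be 1-D vectors of equal length")
    if xs.size < 3:
        raise InvalidArgumentError(f"need at least 3 observations, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return float(stats.pearsonr(xs, ys).statistic)


def correlation_p_value(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n (t transform)."""
    if n < 3 or int(n) != n:
        raise InvalidArgumentError(f"n must be an integer >= 3, got {n!r}")
    if abs(r) > 1:
        raise InvalidArgumentError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def significance_tier(p: float) -> str:
    """Display tier with exclusive upper bounds: '<.001', '<.01', '<.05', 'ns'."""
    if not 0.0 <= p <= 1.0:
        raise InvalidArgumentError(f"p must lie in [0, 1], got {p}")
    for bound, label in ((0.001, "<.001"), (0.01, "<.01"), (0.05, "<.05")):
        if p < bound:
            return label
    return "ns"


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise threshold alpha / k."""
    if k < 1:
        raise InvalidArgumentError(f"k must be >= 1, got {k}")
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / k


def format_p(p: float) -> str:
    """Display rounding: 3 decimals below .01, else 2 ('<.001' floor)."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}"[1:] if p < 0.01 else f"{p:.2f}"[1:]


@dataclass(frozen=True)
class CorrelationRecord:
    """One tested hypothesis: an interest-condition pair under one scheme."""

    interest: str
    role: str
    condition: str
    normalization: str
    n: int
    r: float
    p: float
    tier: str
    bonferroni_significant: bool


@dataclass
class AnalysisConfig:
    """Screening options: significance level, correction factor, regions."""

    alpha: float = 0.05
    k_override: Optional[int] = None
    excluded_regions: frozenset = frozenset(("DC",))
    normalizations: Sequence[NormalizationScheme] = (FB_POP,)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must lie in (0, 1)")
        if self.k_override is not None and self.k_override < 1:
            raise InvalidArgumentError("k override must be >= 1")
        self.excluded_regions = frozenset(self.excluded_regions)
        resolved = []
        for scheme in self.normalizations:
            if isinstance(scheme, str):
                if scheme not in STANDARD_SCHEMES:
                    raise InvalidArgumentError(
                        f"unknown normalization {scheme!r}; standard ones: {sorted(STANDARD_SCHEMES)}"
                    )
                scheme = STANDARD_SCHEMES[scheme]
            resolved.append(scheme)
        self.normalizations = tuple(resolved)


def correlation_screen(
    provider: AudienceProvider,
    taxonomy: Iterable[InterestSpec],
    health_table: HealthStatTable,
    config: Optional[AnalysisConfig] = None,
) -> List[CorrelationRecord]:
    """All (interest, condition, normalization) correlations with Bonferroni verdicts.

    Interests with role ``reference`` serve only as denominators and are not
    screened.  A constant share vector aborts only its own record (logged),
    not the whole screen; zero reference counts propagate as errors naming
    the cell.
    """
    config = config or AnalysisConfig()
    regions = [s for s in health_table.states if s not in config.excluded_regions]
    if len(regions) < 3:
        raise InvalidArgumentError(f"need >= 3 regions after exclusions, got {len(regions)}")
    screened = [spec for spec in taxonomy if spec.role in SCREENED_ROLES]

    raw: List[Tuple[InterestSpec, str, str, int, float]] = []
    for scheme in config.normalizations:
        share_cache: Dict[str, np.ndarray] = {}
        for spec in screened:
            share_cache[spec.name] = np.array(
                [normalized_share(provider, spec.name, geo, scheme=scheme) for geo in regions]
            )
        for condition in health_table.conditions:
            prev = health_table.prevalence_series(condition).reindex(regions)
            if prev.isna().any():
                missing = prev.index[prev.isna()].tolist()
                raise InvalidArgumentError(
                    f"condition {condition!r} lacks prevalence for regions {missing}"
                )
            ys = prev.to_numpy()
            for spec in screened:
                try:
                    r = pearson_correlation(share_cache[spec.name], ys)
                except DegenerateInputError:
                    logger.warning(
                        "skipping degenerate cell: constant share vector for interest %r "
                        "(condition %r, normalization %s)",
                        spec.name, condition, scheme.name,
                    )
                    continue
                raw.append((spec, condition, scheme.name, len(regions), r))

    k = config.k_override if config.k_override is not None else max(len(raw), 1)
    threshold = bonferroni_threshold(config.alpha, k)
    records = []
    for spec, condition, norm, n, r in raw:
        p = correlation_p_value(r, n)
        records.append(
            CorrelationRecord(
                interest=spec.name,
                role=spec.role,
                condition=condition,
                normalization=norm,
                n=n,
                r=r,
                p=p,
                tier=significance_tier(p),
                bonferroni_significant=p < threshold,
            )
        )
    return records


@dataclass(frozen=True)
class MarkerVerdict:
    record: CorrelationRecord
    exceeds_placebo: bool


@dataclass(frozen=True)
class PlaceboEnvelope:
    """Per (condition, normalization): the placebo background level."""

    condition: str
    normalization: str
    envelope: float  # max |r| over placebo records
    placebos: Tuple[CorrelationRecord, ...]
    markers: Tuple[MarkerVerdict, ...]
    baselines: Tuple[CorrelationRecord, ...]


def placebo_envelope_report(
    records: Iterable[CorrelationRecord],
) -> Dict[Tuple[str, str], PlaceboEnvelope]:
    """Compare every marker correlation against its placebo envelope."""
    records = list(records)
    groups: Dict[Tuple[str, str], List[CorrelationRecord]] = {}
    for rec in records:
        groups.setdefault((rec.condition, rec.normalization), []).append(rec)
    report = {}
    for key, recs in sorted(groups.items()):
        placebos = tuple(r for r in recs if r.role == "placebo")
        if not placebos:
            raise ConfigurationError(
                f"no placebo records for condition={key[0]!r}, normalization={key[1]!r}; "
                "the placebo envelope is undefined"
            )
        envelope = max(abs(r.r) for r in placebos)
        markers = tuple(
            MarkerVerdict(record=r, exceeds_placebo=abs(r.r) > envelope)
            for r in recs
            if r.role == "marker"
        )
        baselines = tuple(r for r in recs if r.role == "baseline")
        report[key] = PlaceboEnvelope(
            condition=key[0],
            normalization=key[1],
            envelope=envelope,
            placebos=placebos,
            markers=markers,
            baselines=baselines,
        )
    return report


def records_frame(records: Iterable[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "interest": r.interest,
                "role": r.role,
                "condition": r.condition,
                "normalization": r.normalization,
                "n": r.n,
                "r": r.r,
                "p": r.p,
                "tier": r.tier,
                "bonferroni_significant": r.bonferroni_significant,
            }
            for r in records
        ]
    )


class InterestPrevalenceScreen:
    """Model object: interest shares screened against condition prevalences.

    Parameters
    ----------
    provider
        Anything answering audience queries (a snapshot or synthetic world).
    taxonomy
        Interest specs with roles (marker / placebo / baseline / reference).
    health_table
        Regional prevalences per condition.
    config
        Screening options; defaults to FB_pop normalization, alpha=.05,
        DC excluded, k computed from the records tested.
    """

    def __init__(
        self,
        provider: AudienceProvider,
        taxonomy: Iterable[InterestSpec],
        health_table: HealthStatTable,
        config: Optional[AnalysisConfig] = None,
    ):
        self.provider = provider
        self.taxonomy = list(taxonomy)
        self.health_table = health_table
        self.config = config or AnalysisConfig()

    def fit(self) -> "ScreenResults":
        records = correlation_screen(
            self.provider, self.taxonomy, self.health_table, self.config
        )
        return ScreenResults(model=self, records=records)


class ScreenResults:
    """Fitted correlation screen: records, Bonferroni verdicts, envelopes."""

    def __init__(self, model: InterestPrevalenceScreen, records: List[CorrelationRecord]):
        self.model = model
        self.records = records
        cfg = model.config
        self.k = cfg.k_override if cfg.k_override is not None else max(len(records), 1)
        self.alpha = cfg.alpha
        self.threshold = bonferroni_threshold(cfg.alpha, self.k)

    def to_frame(self) -> pd.DataFrame:
        return records_frame(self.records)

    def placebo_envelope(self) -> Dict[Tuple[str, str], PlaceboEnvelope]:
        return placebo_envelope_report(self.records)

    def wide_table(self) -> pd.DataFrame:
        """Interests (grouped by condition) x normalizations, r with tier."""
        frame = self.to_frame()
        frame["display"] = [
            f"{r:.2f}".replace("0.", ".")
            + ("" if tier == "ns" else f" ({tier})")
            for r, tier in zip(frame["r"], frame["tier"])
        ]
        wide = frame.pivot_table(
            index=["condition", "role", "interest"],
            columns="normalization",
            values="display",
            aggfunc="first",
        )
        return wide

    def summary(self) -> str:
        lines = [
            "Interest-prevalence correlation screen",
            f"  regions per record: n = {self.records[0].n if self.records else 0}",
            f"  hypotheses tested:  k = {self.k}",
            f"  Bonferroni threshold: p < {self.threshold:.2e} (alpha = {self.alpha})",
            "",
            self.wide_table().to_string(),
            "",
        ]
        for key, env in self.placebo_envelope().items():
            lines.append(
                f"placebo envelope [{key[0]} / {key[1]}]: max placebo |r| = {env.envelope:.3f}"
            )
            for mv in env.markers:
                verdict = "exceeds" if mv.exceeds_placebo else "within"
                lines.append(
                    f"  marker {mv.record.interest!r}: r = {mv.record.r:+.3f} "
                    f"(p = {format_p(mv.record.p)}) — {verdict} placebo envelope"
                )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_tsv(self, path) -> None:
        self.wide_table().to_csv(path, sep="\t")
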