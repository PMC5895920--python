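"""Synthetic audience universe with planted effects.

Real advertising-audience snapshots are not publicly deposited, so the
package ships a generative stand-in that answers audience queries exactly
like a stored snapshot would.  The model is deliberately simple and
analytically tractable:

* Each region (US state) ``s`` carries two latent factors: a health factor
  ``z_s ~ N(0, 1)`` and a platform-engagement factor
  ``u_s = rho * z_s + sqrt(1 - rho^2) * xi_s``, ``xi_s ~ N(0, 1)``.  The
  correlation ``rho`` between them is the confounding channel that makes
  generic "placebo" interests correlate with health outcomes.
* Condition prevalence in state ``s`` is
  ``h_cs = expit(mu_c + beta_c * z_s + sigma_c * eps_cs)``.
* The propensity of a demographic segment in state ``s`` to hold interest
  ``i`` is ``p_is = expit(theta_i + offset_seg + lambda_i * z_s +
  kappa_i * u_s)``: marker interests load on ``z`` (lambda), engagement-
  driven interests load on ``u`` (kappa).
* Pairs of interests co-occur with a planted lift ``omega_AB``:
  ``P(A and B) = min(omega_AB * p_A * p_B, min(p_A, p_B))`` — capped so the
  joint stays feasible.

Counts are exact expected audiences (population x adoption x segment share
x propensity) rounded to the reporting granularity, so every number the
world emits obeys the same k-anonymity coarsening as the real API.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    AGE_BRACKETS,
    DEFAULT_GRANULARITY,
    ETHNICITIES,
    GENDERS,
    US_STATES,
    AudienceEstimate,
    AudienceQuery,
    AudienceSnapshot,
    HealthStatTable,
    InterestSpec,
    round_to_granularity,
)
from .errors import InvalidArgumentError, MissingInterestError, ValidationError

#: Concrete (non-"any") demographic levels per axis.
SEGMENT_GENDERS = GENDERS[1:]
SEGMENT_AGES = AGE_BRACKETS[1:]
SEGMENT_ETHNICITIES = ETHNICITIES[1:]

SEGMENTS: Tuple[Tuple[str, str, str], ...] = tuple(
    (g, a, e)
    for g in SEGMENT_GENDERS
    for a in SEGMENT_AGES
    for e in SEGMENT_ETHNICITIES
)
N_SEGMENTS = len(SEGMENTS)


@dataclass(frozen=True)
class ConditionConfig:
    """Generative parameters for one health condition.

    ``mu`` is the prevalence intercept on the logit scale, ``beta`` the
    loading on the state health factor z, ``sigma`` the SD of state-level
    idiosyncratic noise.
    """

    name: str
    mu: float = -2.2
    beta: float = 0.15
    sigma: float = 0.0


@dataclass(frozen=True)
class InterestConfig:
    """Generative parameters for one interest.

    ``theta`` is the base propensity on the logit scale; ``lam`` loads on
    the health factor z (marker channel); ``kappa`` loads on the engagement
    factor u (confounding channel); ``tau`` is the SD of idiosyncratic
    state-level propensity noise, independent of both factors.
    """

    name: str
    role: str = "placebo"
    condition: Optional[str] = None
    theta: float = -4.0
    lam: float = 0.0
    kappa: float = 0.0
    tau: float = 0.0

    def spec(self) -> InterestSpec:
        return InterestSpec(name=self.name, role=self.role, condition=self.condition)


@dataclass
class WorldConfig:
    """Full specification of a synthetic audience universe."""

    conditions: Sequence[ConditionConfig]
    interests: Sequence[InterestConfig]
    n_states: int = 50
    state_populations: object = 1_000_000  # int or sequence of ints (adults)
    adoption: float = 0.6
    rho: float = 0.0  # corr(z, u): engagement–health confounding
    segment_shares: Optional[Sequence[float]] = None  # default uniform
    segment_offsets: Optional[Mapping[Tuple[str, str, str], float]] = None
    pairwise_lift: Mapping[frozenset, float] = field(default_factory=dict)
    granularity: int = DEFAULT_GRANULARITY
    seed: int = 0

    def populations(self) -> np.ndarray:
        pops = self.state_populations
        if np.isscalar(pops):
            arr = np.full(self.n_states, float(pops))
        else:
            arr = np.asarray(pops, dtype=float)
            if arr.shape != (self.n_states,):
                raise InvalidArgumentError(
                    f"state_populations length {arr.size} != n_states {self.n_states}"
                )
        if np.any(arr <= 0):
            raise InvalidArgumentError("state populations must be positive")
        return arr

    def validate(self) -> None:
        if self.n_states < 1:
            raise InvalidArgumentError("n_states must be >= 1")
        if not 0.0 <= self.adoption <= 1.0:
            raise InvalidArgumentError("adoption must be a fraction in [0, 1]")
        if not -1.0 <= self.rho <= 1.0:
            raise InvalidArgumentError("rho must lie in [-1, 1]")
        self.populations()
        names = [i.name for i in self.interests]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("interest names must be unique")
        for key, omega in self.pairwise_lift.items():
            if omega < 0:
                raise InvalidArgumentError(f"pairwise lift for {set(key)} must be >= 0")
            if len(key) != 2:
                raise InvalidArgumentError("pairwise_lift keys must be unordered pairs")
        if self.segment_shares is not None:
            shares = np.asarray(self.segment_shares, dtype=float)
            if shares.shape != (N_SEGMENTS,) or np.any(shares < 0):
                raise InvalidArgumentError(
                    f"segment_shares must be {N_SEGMENTS} non-negative fractions"
                )
            if abs(shares.sum() - 1.0) > 1e-9:
                raise InvalidArgumentError("segment_shares must sum to 1")


def state_codes(n_states: int) -> List[str]:
    """Region codes: real state postal codes up to 50, synthetic beyond."""
    if n_states <= len(US_STATES):
        return list(US_STATES[:n_states])
    extra = [f"S{i:03d}" for i in range(n_states - len(US_STATES))]
    return list(US_STATES) + extra


def _stream(seed: int, *keys: int) -> np.random.Generator:
    """Independent substream keyed by integers, stable across config edits."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *keys])


def _name_key(name: str) -> int:
    return zlib.crc32(name.encode("utf8"))


class SyntheticWorld:
    """A realized universe: latent draws, prevalences, and propensities.

    Exposes the same ``audience(query)`` interface as a stored snapshot, so
    every analysis stage runs unchanged against simulated data.
    """

    def __init__(self, config: WorldConfig):
        config.validate()
        self.config = config
        self.granularity = config.granularity
        self.states = state_codes(config.n_states)
        n_s = config.n_states

        # Latent state factors: substreams keyed per state so the draws do
        # not shift when interests or conditions are added to the config.
        z = np.empty(n_s)
        xi = np.empty(n_s)
        for s in range(n_s):
            rng = _stream(config.seed, 1, s)
            z[s], xi[s] = rng.standard_normal(2)
        rho = config.rho
        self.z = z
        self.u = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * xi

        # Realized prevalences h_cs (noise substream keyed per condition).
        rows = []
        self._prevalence: Dict[str, np.ndarray] = {}
        for cond in config.conditions:
            eps = np.empty(n_s)
            for s in range(n_s):
                eps[s] = _stream(config.seed, 2, _name_key(cond.name), s).standard_normal()
            h = expit(cond.mu + cond.beta * z + cond.sigma * eps)
            self._prevalence[cond.name] = h
            rows.extend((self.states[s], cond.name, float(h[s])) for s in range(n_s))
        self._health = HealthStatTable.from_records(rows)

        # Segment propensities p[i, s, seg].
        if config.segment_offsets:
            offsets = np.array(
                [float(config.segment_offsets.get(seg, 0.0)) for seg in SEGMENTS]
            )
        else:
            offsets = np.zeros(N_SEGMENTS)
        self._interest_index = {i.name: k for k, i in enumerate(config.interests)}
        lam = np.array([i.lam for i in config.interests], dtype=float)
        kap = np.array([i.kappa for i in config.interests], dtype=float)
        theta = np.array([i.theta for i in config.interests], dtype=float)
        noise = np.zeros((len(config.interests), n_s))
        for k, interest in enumerate(config.interests):
            if interest.tau:
                key = _name_key(interest.name)
                for s in range(n_s):
                    noise[k, s] = interest.tau * _stream(
                        config.seed, 3, key, s
                    ).standard_normal()
        logit = (
            theta[:, None, None]
            + offsets[None, None, :]
            + lam[:, None, None] * z[None, :, None]
            + kap[:, None, None] * self.u[None, :, None]
            + noise[:, :, None]
        )
        self.propensity = expit(logit)  # (n_interests, n_states, n_segments)

        shares = (
            np.full(N_SEGMENTS, 1.0 / N_SEGMENTS)
            if config.segment_shares is None
            else np.asarray(config.segment_shares, dtype=float)
        )
        self.segment_shares = shares
        #: exact platform users per (state, segment) before any interest filter
        self.base = config.populations()[:, None] * config.adoption * shares[None, :]

        self._lift = {frozenset(k): float(v) for k, v in config.pairwise_lift.items()}

    # ---- query answering -------------------------------------------------

    @property
    def health_table(self) -> HealthStatTable:
        return self._health

    @property
    def taxonomy(self) -> List[InterestSpec]:
        return [i.spec() for i in self.config.interests]

    def planted_lift(self, a: str, b: str) -> float:
        return self._lift.get(frozenset((a, b)), 1.0)

    def _state_indices(self, geography: str) -> np.ndarray:
        if geography == "US":
            return np.arange(len(self.states))
        try:
            return np.array([self.states.index(geography)])
        except ValueError:
            raise InvalidArgumentError(f"unknown geography {geography!r}") from None

    @staticmethod
    def _segment_mask(query: AudienceQuery) -> np.ndarray:
        mask = np.ones(N_SEGMENTS, dtype=bool)
        for axis, want in (
            (0, query.gender),
            (1, query.age_bracket),
            (2, query.ethnic_affinity),
        ):
            if want != "any":
                mask &= np.array([seg[axis] == want for seg in SEGMENTS])
        return mask

    def _joint_propensity(self, interests: Sequence[str]) -> np.ndarray:
        idx = []
        for name in interests:
            if name not in self._interest_index:
                raise MissingInterestError(f"interest {name!r} not in this world")
            idx.append(self._interest_index[name])
        if len(idx) == 0:
            return np.ones_like(self.base)
        if len(idx) == 1:
            return self.propensity[idx[0]]
        if len(idx) > 2:
            raise InvalidArgumentError(
                "conjunctions of 3 or more interests are outside generative scope"
            )
        p_a, p_b = self.propensity[idx[0]], self.propensity[idx[1]]
        omega = self.planted_lift(interests[0], interests[1])
        return np.minimum(omega * p_a * p_b, np.minimum(p_a, p_b))

    def exact_audience(self, query: AudienceQuery) -> float:
        """Expected audience before granularity rounding."""
        s_idx = self._state_indices(query.geography)
        mask = self._segment_mask(query)
        joint = self._joint_propensity(sorted(query.interests))
        cell = self.base[s_idx][:, mask] * joint[np.ix_(s_idx, np.flatnonzero(mask))]
        return float(cell.sum())

    def audience(self, query: AudienceQuery) -> int:
        return round_to_granularity(self.exact_audience(query), self.granularity)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Realize a synthetic universe; deterministic given ``config.seed``."""
    return SyntheticWorld(config)


def world_audience(world: SyntheticWorld, query: AudienceQuery) -> int:
    """Rounded audience count the world reports for ``query``."""
    return world.audience(query)


def _default_queries(world: SyntheticWorld) -> List[AudienceQuery]:
    """Every interest x state x marginal demographic, pairs named in the
    lift matrix, and the no-constraint reference rows, plus US-wide rows."""
    geos = ["US"] + list(world.states)
    marginals: List[dict] = [{}]
    marginals += [{"gender": g} for g in SEGMENT_GENDERS]
    marginals += [{"age_bracket": a} for a in SEGMENT_AGES]
    marginals += [{"ethnic_affinity": e} for e in SEGMENT_ETHNICITIES]
    interest_sets: List[frozenset] = [frozenset()]
    interest_sets += [frozenset((i.name,)) for i in world.config.interests]
    queries = [
        AudienceQuery(geography=geo, interests=ints, **demo)
        for geo in geos
        for ints in interest_sets
        for demo in marginals
    ]
    queries += [
        AudienceQuery(geography=geo, interests=frozenset(pair))
        for geo in geos
        for pair in world._lift
    ]
    return queries


def export_world(
    world: SyntheticWorld,
    queries: Optional[Iterable[AudienceQuery]] = None,
    timestamp: str = "synthetic",
) -> Tuple[AudienceSnapshot, HealthStatTable]:
    """Materialize the world as a validated snapshot plus health table."""
    if queries is None:
        queries = _default_queries(world)
    estimates = [AudienceEstimate(query=q, count=world.audience(q)) for q in queries]
    snapshot = AudienceSnapshot(
        estimates, granularity=world.granularity, timestamp=timestamp
    )
    return snapshot, world.health_table


# ---- config (de)serialization --------------------------------------------


def world_config_from_dict(data: Mapping) -> WorldConfig:
    """Build a :class:`WorldConfig` from a plain mapping (YAML-friendly)."""
    try:
        conditions = [ConditionConfig(**c) for c in data["conditions"]]
        interests = [InterestConfig(**i) for i in data["interests"]]
    except KeyError as exc:
        raise ValidationError(f"world config missing required block: {exc}") from None
    except TypeError as exc:
        raise ValidationError(f"world config field error: {exc}") from None
    pairwise = {
        frozenset((p["a"], p["b"])): float(p["omega"])
        for p in data.get("pairwise_lift", [])
    }
    offsets = None
    if data.get("segment_offsets"):
        offsets = {
            tuple(key.split(",")): float(val)
            for key, val in data["segment_offsets"].items()
        }
    return WorldConfig(
        conditions=conditions,
        interests=interests,
        n_states=int(data.get("n_states", 50)),
        state_populations=data.get("state_populations", 1_000_000),
        adoption=float(data.get("adoption", 0.6)),
        rho=float(data.get("rho", 0.0)),
        segment_shares=data.get("segment_shares"),
        segment_offsets=offsets,
        pairwise_lift=pairwise,
        granularity=int(data.get("granularity", DEFAULT_GRANULARITY)),
        seed=int(data.get("seed", 0)),
    )


def world_config_to_dict(config: WorldConfig) -> dict:
    pops = config.state_populations
    return {
        "conditions": [vars(c) for c in config.conditions],
        "interests": [
            {k: v for k, v in vars(i).items() if v is not None} for i in config.interests
        ],
        "n_states": config.n_states,
        "state_populations": pops if np.isscalar(pops) else list(map(float, pops)),
        "adoption": config.adoption,
        "rho": config.rho,
        "segment_shares": (
            None if config.segment_shares is None else list(map(float, config.segment_shares))
        ),
        "segment_offsets": (
            {",".join(k): v for k, v in config.segment_offsets.items()}
            if config.segment_offsets
            else None
        ),
        "pairwise_lift": [
            {"a": a, "b": b, "omega": omega}
            for (a, b), omega in sorted((tuple(sorted(k)), v) for k, v in config.pairwise_lift.items())
        ],
        "granularity": config.granularity,
        "seed": config.seed,
    }


# ---- study-condition factories ------------------------------------------
#
# These encode the simulation regimes the test-bed exercises.  Loadings are
# chosen analytically: with a noiseless share (a monotone function of z
# alone) and prevalence noise sigma, the model-implied share–prevalence
# correlation is approximately beta / sqrt(beta^2 + sigma^2), and a
# kappa-loaded placebo attains rho times the equally loaded marker's value.


def _sigma_for_target_r(beta: float, r: float) -> float:
    if not 0 < r <= 1:
        raise InvalidArgumentError("target correlation must be in (0, 1]")
    return beta * np.sqrt(1.0 / (r * r) - 1.0)


def marker_recovery_config(
    r_target: float = 0.75,
    n_states: int = 50,
    seed: int = 0,
    population: int = 1_000_000,
    adoption: float = 0.6,
) -> WorldConfig:
    """A world with one marker planted at a known share–prevalence r."""
    beta = 0.15
    return WorldConfig(
        conditions=[
            ConditionConfig(
                name="obesity", mu=-1.1, beta=beta, sigma=_sigma_for_target_r(beta, r_target)
            )
        ],
        interests=[
            InterestConfig(
                name="plus-size clothing",
                role="marker",
                condition="obesity",
                theta=-3.5,
                lam=0.15,
            ),
            # loads engagement only; with rho=0 it is independent of health
            InterestConfig(name="reading", role="placebo", theta=-1.0, kappa=0.1),
        ],
        n_states=n_states,
        state_populations=population,
        adoption=adoption,
        seed=seed,
    )


def confounded_world_config(
    rho: float = 0.7,
    r_marker: float = 0.40,
    n_states: int = 50,
    seed: int = 0,
) -> WorldConfig:
    """Marker loads the health factor, placebo loads engagement only.

    With equal loadings the placebo's expected correlation is ``rho`` times
    the marker's, so the marker target is kept moderate to mirror the
    regime where placebo and marker correlations are comparable.
    """
    beta, lam = 0.15, 0.15
    return WorldConfig(
        conditions=[
            ConditionConfig(
                name="diabetes", mu=-2.2, beta=beta, sigma=_sigma_for_target_r(beta, r_marker)
            )
        ],
        interests=[
            InterestConfig(
                name="diabetic diet", role="marker", condition="diabetes", theta=-4.0, lam=lam
            ),
            InterestConfig(name="technology", role="placebo", theta=-1.5, kappa=lam),
        ],
        n_states=n_states,
        rho=rho,
        seed=seed,
    )


def null_world_config(
    n_interests: int = 4,
    n_conditions: int = 2,
    n_states: int = 50,
    seed: int = 0,
    condition_sigma: float = 0.3,
) -> WorldConfig:
    """No planted effects: shares vary idiosyncratically, loadings are zero."""
    conditions = [
        ConditionConfig(name=f"condition_{c}", mu=-2.0, beta=0.2, sigma=condition_sigma)
        for c in range(n_conditions)
    ]
    interests = [
        InterestConfig(
            name=f"placebo_{i}",
            role="placebo",
            theta=-2.0 - 0.2 * i,
            lam=0.0,
            kappa=0.0,
            tau=0.3,
        )
        for i in range(n_interests)
    ]
    return WorldConfig(
        conditions=conditions, interests=interests, n_states=n_states, seed=seed
    )


def lift_recovery_config(
    omega: float = 2.0,
    p_a: float = 0.05,
    p_b: float = 0.05,
    population: int = 10_000_000,
    seed: int = 0,
) -> WorldConfig:
    """Constant-propensity world with one planted pairwise lift."""
    from scipy.special import logit

    interests = [
        InterestConfig(name="bariatrics", role="marker", condition="obesity", theta=float(logit(p_a))),
        InterestConfig(name="nightlife", role="placebo", theta=float(logit(p_b))),
    ]
    return WorldConfig(
        conditions=[ConditionConfig(name="obesity", mu=-1.1, beta=0.0, sigma=0.0)],
        interests=interests,
        n_states=1,
        state_populations=population,
        pairwise_lift={frozenset(("bariatrics", "nightlife")): omega},
        seed=seed,
    )
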