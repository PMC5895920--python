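"""OLS modelling of prevalence from interest shares with backward-AIC selection.

Regional prevalence of a condition is regressed on normalized interest
shares (optionally plus control covariates such as demographic or economic
statistics).  With only ~50 regions and many candidate features, model
selection is pure backward elimination: at each step the single feature
whose removal yields the lowest AIC is dropped, as long as that AIC is
strictly below the current model's; removed features never re-enter.

The information criterion is the least-squares form

    AIC = n * ln(RSS / n) + 2 * (p + 1)

with p the number of slope features (the intercept counted in the +1) and
the additive likelihood constant dropped — it cancels in comparisons at
fixed n.  RSS is floored at 1e-12 before the log so perfect fits survive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr

from .association import NormalizationScheme, FB_POP, normalized_share
from .core import AudienceProvider, HealthStatTable, InterestSpec
from .errors import CollinearityError, InvalidArgumentError, ValidationError

RSS_FLOOR = 1e-12


@dataclass
class DesignMatrix:
    """Named feature columns and a prevalence response, one row per region."""

    regions: List[str]
    features: pd.DataFrame  # index = regions
    response: pd.Series  # index = regions

    def __post_init__(self) -> None:
        self.features = self.features.loc[self.regions]
        self.response = self.response.loc[self.regions]
        if self.features.isna().any().any() or self.response.isna().any():
            raise ValidationError("design matrix contains missing cells")

    @property
    def n(self) -> int:
        return len(self.regions)

    @property
    def feature_names(self) -> List[str]:
        return list(self.features.columns)

    def standardized(self) -> "DesignMatrix":
        """Z-score every feature column (response untouched)."""
        feats = self.features.copy()
        std = feats.std(ddof=1)
        if (std == 0).any():
            zero = std.index[std == 0].tolist()
            raise ValidationError(f"cannot standardize constant columns {zero}")
        feats = (feats - feats.mean()) / std
        return DesignMatrix(regions=self.regions, features=feats, response=self.response)


def ls_aic(n: int, rss: float, p: int) -> float:
    """Least-squares AIC with the constant dropped; intercept counted."""
    return n * math.log(max(rss, RSS_FLOOR) / n) + 2 * (p + 1)


@dataclass
class RegressionFit:
    """A fitted OLS model, possibly after backward elimination."""

    features: List[str]
    params: pd.Series  # 'intercept' + slopes
    bse: pd.Series
    rss: float
    r_squared: float
    adj_r_squared: float
    aic: float
    n: int
    trace: List[Tuple[str, float]] = field(default_factory=list)
    response_name: str = "prevalence"

    def summary(self) -> str:
        lines = [
            f"OLS prevalence model: {self.response_name} ~ {len(self.features)} feature(s), n = {self.n}",
            f"  R^2 = {self.r_squared:.4f}   adj. R^2 = {self.adj_r_squared:.4f}   AIC = {self.aic:.3f}",
            "",
            f"  {'term':<32} {'coef':>12} {'std err':>12}",
        ]
        for name in self.params.index:
            se = self.bse[name]
            se_str = f"{se:12.4g}" if np.isfinite(se) else "         n/a"
            lines.append(f"  {name:<32} {self.params[name]:12.4g} {se_str}")
        if self.trace:
            lines += ["", "  backward elimination trace (feature removed -> AIC):"]
            lines += [f"    - {name:<30} AIC = {aic:.3f}" for name, aic in self.trace]
        return "\n".join(lines)


def fit_ols(design: DesignMatrix, features: Optional[Sequence[str]] = None) -> RegressionFit:
    """Least-squares fit of the response on a feature subset plus intercept."""
    if features is None:
        features = design.feature_names
    features = list(features)
    unknown = [f for f in features if f not in design.features.columns]
    if unknown:
        raise InvalidArgumentError(f"unknown features {unknown}")
    n, p = design.n, len(features)
    if n <= p + 1:
        raise InvalidArgumentError(f"need n > p + 1 (n={n}, p={p})")
    X = np.column_stack([np.ones(n), design.features[features].to_numpy(dtype=float)])
    y = design.response.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR identifies which columns are linearly dependent
        _, _, piv = _qr(X, mode="economic", pivoting=True)
        dependent = sorted(
            (["intercept"] + features)[j] for j in piv[rank:]
        )
        raise CollinearityError(f"rank-deficient design; dependent columns: {dependent}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    dof = n - p - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof
    sigma2 = rss / dof if dof > 0 else float("nan")
    with np.errstate(invalid="ignore"):
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
    index = ["intercept"] + features
    return RegressionFit(
        features=features,
        params=pd.Series(beta, index=index),
        bse=pd.Series(se, index=index),
        rss=rss,
        r_squared=r2,
        adj_r_squared=adj_r2,
        aic=ls_aic(n, rss, p),
        n=n,
        response_name=str(design.response.name or "prevalence"),
    )


def backward_eliminate(
    design: DesignMatrix, features: Optional[Sequence[str]] = None
) -> RegressionFit:
    """Backward feature elimination minimizing AIC.

    Removes, one at a time, the feature whose removal gives the lowest AIC,
    while that AIC strictly improves on the current model's; ties between
    candidate removals break lexicographically by feature name.  The
    returned fit carries the full elimination trace.
    """
    current_features = sorted(features if features is not None else design.feature_names)
    current = fit_ols(design, current_features)
    trace: List[Tuple[str, float]] = []
    while current_features:
        candidates = []
        for name in current_features:
            reduced = [f for f in current_features if f != name]
            candidates.append((fit_ols(design, reduced).aic, name))
        best_aic, best_name = min(candidates)  # ties: lexicographic name
        if best_aic < current.aic:
            current_features = [f for f in current_features if f != best_name]
            current = fit_ols(design, current_features)
            trace.append((best_name, current.aic))
        else:
            break
    current.trace = trace
    return current


def assemble_design(
    provider: AudienceProvider,
    taxonomy: Iterable[InterestSpec],
    health_table: HealthStatTable,
    condition: str,
    normalization: NormalizationScheme = FB_POP,
    controls: Optional[pd.DataFrame] = None,
    excluded_regions: Iterable[str] = ("DC",),
    roles: Sequence[str] = ("marker", "placebo", "baseline"),
) -> DesignMatrix:
    """Build a region-level design: interest shares (+ controls) vs prevalence.

    Feature names are namespaced ``interest:<name>`` and ``control:<name>``.
    A controls table missing any included region is a validation error.
    """
    excluded = set(excluded_regions)
    regions = [s for s in health_table.states if s not in excluded]
    prev = health_table.prevalence_series(condition).reindex(regions)
    if prev.isna().any():
        raise ValidationError(
            f"missing prevalence for regions {prev.index[prev.isna()].tolist()}"
        )
    cols: Dict[str, list] = {}
    for spec in taxonomy:
        if spec.role not in roles:
            continue
        cols[f"interest:{spec.name}"] = [
            normalized_share(provider, spec.name, geo, scheme=normalization)
            for geo in regions
        ]
    features = pd.DataFrame(cols, index=regions)
    if controls is not None:
        missing = [s for s in regions if s not in controls.index]
        if missing:
            raise ValidationError(f"controls table missing states {missing}")
        ctrl = controls.loc[regions].add_prefix("control:")
        features = pd.concat([features, ctrl], axis=1)
    response = prev.rename(condition)
    return DesignMatrix(regions=regions, features=features, response=response)


class PrevalenceRegression:
    """Model object: a design matrix ready for OLS / backward selection.

    ``fit()`` returns the full-model OLS fit; ``fit(method="backward")``
    runs AIC-guided backward elimination.  ``from_provider`` assembles the
    design from an audience provider, taxonomy, and health table directly.
    """

    def __init__(self, design: DesignMatrix, standardize: bool = False):
        self.design = design.standardized() if standardize else design

    @classmethod
    def from_provider(
        cls,
        provider: AudienceProvider,
        taxonomy: Iterable[InterestSpec],
        health_table: HealthStatTable,
        condition: str,
        normalization: NormalizationScheme = FB_POP,
        controls: Optional[pd.DataFrame] = None,
        standardize: bool = False,
        excluded_regions: Iterable[str] = ("DC",),
    ) -> "PrevalenceRegression":
        design = assemble_design(
            provider,
            taxonomy,
            health_table,
            condition,
            normalization=normalization,
            controls=controls,
            excluded_regions=excluded_regions,
        )
        return cls(design, standardize=standardize)

    def fit(self, method: str = "ols") -> RegressionFit:
        if method == "ols":
            return fit_ols(self.design)
        if method == "backward":
            return backward_eliminate(self.design)
        raise InvalidArgumentError(f"unknown method {method!r} (use 'ols' or 'backward')")
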