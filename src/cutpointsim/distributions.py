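"""Parametric distribution pairs for the two diagnostic categories.

A diagnostic scenario is a pair of positive-support distributions — one for
the "healthy" (non-diseased) category and one for the "diseased" category —
from which fictitious test values are drawn. The point where the two
(optionally prevalence-weighted) densities cross is the theoretical reference
cut-off: below it the healthy density dominates, above it the diseased one
does. Four built-in scenarios cover lognormal, chi-square, inverse-gamma and
mixed chi-square/Weibull shapes with increasing degrees of separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "Family",
    "DistributionSpec",
    "Scenario",
    "CrossingPoint",
    "CrossingError",
    "NoCrossingError",
    "AmbiguousCrossingError",
    "crossing_point",
    "SCENARIOS",
    "get_scenario",
    "scenario_from_config",
]


class Family(str, Enum):
    """Supported positive-support distribution families."""

    LOGNORMAL = "lognormal"
    CHI_SQUARE = "chi_square"
    INVERSE_GAMMA = "inverse_gamma"
    WEIBULL = "weibull"


# parameter names per family, in positional order
_PARAM_NAMES: dict[Family, tuple[str, ...]] = {
    Family.LOGNORMAL: ("mu", "sigma"),
    Family.CHI_SQUARE: ("df",),
    Family.INVERSE_GAMMA: ("shape", "scale"),
    Family.WEIBULL: ("shape", "scale"),
}


class CrossingError(ValueError):
    """Base class for density crossing-point failures."""


class NoCrossingError(CrossingError):
    """The weighted densities do not cross between the two medians."""


class AmbiguousCrossingError(CrossingError):
    """More than one crossing between the two medians."""


@dataclass(frozen=True)
class DistributionSpec:
    """One distribution family plus its parameters for a diagnostic category.

    Parameters
    ----------
    family
        One of :class:`Family` (or its string value).
    params
        Positional parameters: lognormal ``(mu, sigma)`` on the log scale;
        chi_square ``(df,)``; inverse_gamma ``(shape, scale)`` with density
        proportional to ``x**(-shape-1) * exp(-scale/x)``; weibull
        ``(shape, scale)`` with density
        ``(k/lam) * (x/lam)**(k-1) * exp(-(x/lam)**k)``.
    """

    family: Family
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        params = tuple(float(p) for p in np.atleast_1d(self.params))
        object.__setattr__(self, "params", params)
        names = _PARAM_NAMES[fam]
        if len(params) != len(names):
            raise ValueError(
                f"{fam.value} takes {len(names)} parameter(s) {names}, got {params}"
            )
        # all shape/scale/sd parameters must be positive; lognormal mu is free
        for name, value in zip(names, params):
            if name != "mu" and value <= 0:
                raise ValueError(f"{fam.value} parameter {name} must be > 0, got {value}")
            if not np.isfinite(value):
                raise ValueError(f"{fam.value} parameter {name} must be finite")

    @cached_property
    def _frozen(self):
        """The scipy.stats frozen distribution behind this spec."""
        if self.family is Family.LOGNORMAL:
            mu, sigma = self.params
            return stats.lognorm(sigma, scale=np.exp(mu))
        if self.family is Family.CHI_SQUARE:
            (df,) = self.params
            return stats.chi2(df)
        if self.family is Family.INVERSE_GAMMA:
            shape, scale = self.params
            return stats.invgamma(shape, scale=scale)
        shape, scale = self.params
        return stats.weibull_min(shape, scale=scale)

    def pdf(self, x) -> np.ndarray | float:
        """Density f(x); zero for x <= 0 outside the support."""
        return self._frozen.pdf(x)

    def median(self) -> float:
        return float(self._frozen.median())

    def ppf(self, q) -> np.ndarray | float:
        return self._frozen.ppf(q)

    def mean(self) -> float:
        return float(self._frozen.mean())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` independent test values using the given generator."""
        if n < 0:
            raise ValueError("sample size must be >= 0")
        return np.asarray(self._frozen.rvs(size=n, random_state=rng), dtype=float)


def density(spec: DistributionSpec, x) -> np.ndarray | float:
    """Density of ``spec`` at ``x`` (module-level convenience)."""
    return spec.pdf(x)


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent draws from ``spec`` (module-level convenience)."""
    return spec.sample(n, rng)


@dataclass(frozen=True)
class Scenario:
    """A named pair of category distributions.

    The diseased distribution must lie to the right of the healthy one
    (larger median) so that the decision rule "test positive if x >= cut-off"
    is oriented correctly.
    """

    name: str
    healthy: DistributionSpec
    diseased: DistributionSpec

    def __post_init__(self) -> None:
        if self.healthy == self.diseased:
            raise ValueError("healthy and diseased distributions must differ")
        if not self.diseased.median() > self.healthy.median():
            raise ValueError(
                "diseased distribution must have a larger median than the healthy one"
            )


@dataclass(frozen=True)
class CrossingPoint:
    """Solution of w_h * f_h(x) = w_d * f_d(x)."""

    x_star: float
    weight_healthy: float
    weight_diseased: float


def crossing_point(
    healthy: DistributionSpec,
    diseased: DistributionSpec,
    weight_diseased: float = 0.5,
    *,
    xtol: float = 1e-6,
    _n_scan: int = 4096,
) -> CrossingPoint:
    """Solve for the prevalence-weighted density crossing point.

    Finds the root of ``g(x) = (1 - w) f_h(x) - w f_d(x)`` between the two
    distribution medians, where ``w = weight_diseased``. The decision-relevant
    crossing is the one where the dominant category flips, i.e. where ``g``
    changes sign from positive to negative with increasing ``x``; densities of
    different families may cross again in the far tails, which is ignored here.

    Parameters
    ----------
    healthy, diseased
        The two category distributions; the diseased median must exceed the
        healthy median.
    weight_diseased
        Prevalence weight ``w`` in (0, 1) given to the diseased density; the
        healthy density gets ``1 - w``. ``w = 0.5`` gives the unweighted
        (equal-weight) crossing point.
    xtol
        Absolute tolerance of the root refinement.

    Raises
    ------
    NoCrossingError
        If the weighted densities do not cross between the medians.
    AmbiguousCrossingError
        If they cross more than once between the medians.
    """
    if not 0.0 < weight_diseased < 1.0:
        raise ValueError("weight_diseased must be strictly between 0 and 1")
    # validates distinctness and median ordering
    Scenario("_crossing", healthy, diseased)
    w = float(weight_diseased)

    lo, hi = healthy.median(), diseased.median()

    def g(x):
        return (1.0 - w) * healthy.pdf(x) - w * diseased.pdf(x)

    grid = np.linspace(lo, hi, _n_scan + 1)
    values = g(grid)
    signs = np.sign(values)
    # indices i where the sign flips between grid[i] and grid[i+1]
    flips = np.flatnonzero(signs[:-1] * signs[1:] < 0)
    exact_roots = np.flatnonzero(signs[1:-1] == 0)
    n_crossings = len(flips) + len(exact_roots)
    if n_crossings == 0:
        raise NoCrossingError(
            f"no crossing in decision region [{lo:.6g}, {hi:.6g}] "
            f"for weight_diseased={w}"
        )
    if n_crossings > 1:
        raise AmbiguousCrossingError(
            f"{n_crossings} crossings between the medians; decision region ambiguous"
        )
    if exact_roots.size:
        root = float(grid[exact_roots[0] + 1])
    else:
        i = flips[0]
        root = float(brentq(g, grid[i], grid[i + 1], xtol=xtol))
    # the crossing must flip from healthy-dominant to diseased-dominant
    if not (g(root - 10 * xtol) >= 0 >= g(root + 10 * xtol)):
        raise NoCrossingError(
            "crossing does not flip from healthy-dominant to diseased-dominant"
        )
    return CrossingPoint(x_star=root, weight_healthy=1.0 - w, weight_diseased=w)


#: The four built-in simulation scenarios.
SCENARIOS: dict[str, Scenario] = {
    "scenario1": Scenario(
        "scenario1",
        DistributionSpec(Family.LOGNORMAL, (2.0, 0.4)),
        DistributionSpec(Family.LOGNORMAL, (2.5, 0.3)),
    ),
    "scenario2": Scenario(
        "scenario2",
        DistributionSpec(Family.CHI_SQUARE, (7.0,)),
        DistributionSpec(Family.CHI_SQUARE, (10.0,)),
    ),
    "scenario3": Scenario(
        "scenario3",
        DistributionSpec(Family.INVERSE_GAMMA, (6.0, 20.0)),
        DistributionSpec(Family.INVERSE_GAMMA, (3.0, 20.0)),
    ),
    "scenario4": Scenario(
        "scenario4",
        DistributionSpec(Family.CHI_SQUARE, (6.0,)),
        DistributionSpec(Family.WEIBULL, (10.0, 20.0)),
    ),
}


def get_scenario(name: str) -> Scenario:
    """Look up a built-in scenario by name ("scenario1" .. "scenario4")."""
    try:
        return SCENARIOS[name]
    except KeyError:
        known = ", ".join(sorted(SCENARIOS))
        raise KeyError(f"unknown scenario {name!r}; known scenarios: {known}") from None


def _spec_from_mapping(entry: Mapping) -> DistributionSpec:
    family = Family(str(entry["family"]))
    params = entry["params"]
    if isinstance(params, Mapping):
        names = _PARAM_NAMES[family]
        params = [params[name] for name in names]
    return DistributionSpec(family, tuple(float(p) for p in params))


def scenario_from_config(path: str | Path) -> Scenario:
    """Build a :class:`Scenario` from a flat YAML config file.

    Expected keys::

        name: my_scenario            # optional, defaults to the file stem
        healthy: {family: lognormal, params: [2.0, 0.4]}
        diseased: {family: lognormal, params: [2.5, 0.3]}

    ``params`` may also be a mapping using the per-family parameter names
    (mu/sigma, df, shape/scale).
    """
    path = Path(path)
    with path.open() as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, Mapping):
        raise ValueError(f"scenario config {path} must be a mapping")
    missing = {"healthy", "diseased"} - set(raw)
    if missing:
        raise ValueError(f"scenario config {path} is missing keys: {sorted(missing)}")
    return Scenario(
        name=str(raw.get("name", path.stem)),
        healthy=_spec_from_mapping(raw["healthy"]),
        diseased=_spec_from_mapping(raw["diseased"]),
    )
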