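"""Smooth age-specific penetrance curves and the conditional CBC model.

Penetrance — the cumulative probability that a carrier (or a member of the
general population) develops a given cancer by age ``t`` — is modelled as a
scaled truncated-normal distribution,

    F(t) = r * F_norm(t; mu, sigma),    t >= 0,

where ``r`` is the lifetime cumulative risk, ``mu`` the mean age of onset
and ``sigma`` its standard deviation; the normal is truncated at age 0 and
renormalized on [0, inf).  The corresponding survival, density and hazard
are S = 1 - F, f = r * f_norm and h = f / S.  Parameters are fitted to
5-year age-specific incidence-rate tables by least squares on the hazard.

Contralateral breast cancer (CBC) is modelled conditionally on the first
breast cancer with a constant hazard: the time from first BC to CBC is
exponential, f_cbc(u) = lambda * exp(-lambda * u).

Carrier incidence tables are built by multiplying general-population
incidence rates by published age-specific relative risks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .pedigree import CancerType, Sex

__all__ = [
    "IncidenceTable",
    "PenetranceParams",
    "CbcModel",
    "PenetranceSet",
    "CARRIER",
    "GENERAL",
    "carrier_incidence",
    "fit_penetrance",
    "fit_cbc",
    "load_penetrance_set",
    "available_populations",
]

#: carrier-status labels used throughout the parameter sets
CARRIER = "carrier"
GENERAL = "general"   # general-population (benign-hypothesis) curve

_POPULATION_FILES = {
    "UK": "penetrance_uk_synthetic.yaml",
    "NL": "penetrance_nl_synthetic.yaml",
    "US": "penetrance_us_synthetic.yaml",
    "LEGACY-NL": "penetrance_legacy_nl_synthetic.yaml",
}


def available_populations() -> list[str]:
    return ["UK", "NL", "US", "legacy-NL"]


# ---------------------------------------------------------------------------
# Incidence tables
# ---------------------------------------------------------------------------

@dataclass
class IncidenceTable:
    """Piecewise-constant incidence rates on contiguous age intervals.

    ``age_start``/``age_end`` delimit [start, end) intervals in years
    (typically 5-year registry bins); ``rates`` are events per person-year.
    """

    age_start: np.ndarray
    age_end: np.ndarray
    rates: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.age_start = np.asarray(self.age_start, dtype=float)
        self.age_end = np.asarray(self.age_end, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if not (len(self.age_start) == len(self.age_end) == len(self.rates)):
            raise ValueError("age_start, age_end, rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("incidence rates must be non-negative")
        if np.any(self.age_end <= self.age_start):
            raise ValueError("intervals must have positive width")
        if np.any(self.age_start[1:] != self.age_end[:-1]):
            raise ValueError("intervals must be contiguous and ordered")
        if self.age_start[0] < 0 or self.age_end[-1] > 130:
            raise ValueError("ages must lie within [0, 130]")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.age_start + self.age_end)

    @property
    def widths(self) -> np.ndarray:
        return self.age_end - self.age_start

    @classmethod
    def from_csv(cls, path, **meta) -> "IncidenceTable":
        """Read a delimited table with columns age_start, age_end, rate."""
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower().strip(): c for c in df.columns}
        try:
            return cls(df[cols["age_start"]].to_numpy(),
                       df[cols["age_end"]].to_numpy(),
                       df[cols["rate"]].to_numpy(), meta=meta)
        except KeyError as e:
            raise ValueError(f"incidence file lacks column {e}") from None

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_start": self.age_start, "age_end": self.age_end,
                      "rate": self.rates}).to_csv(path, index=False)


def carrier_incidence(population_rates: IncidenceTable,
                      relative_risks: IncidenceTable) -> IncidenceTable:
    """Carrier incidence = population incidence × age-specific relative risk.

    The product is taken on the union grid of both tables' interval
    boundaries over the population table's range; outside the range covered
    by the relative-risk table the relative risk defaults to 1.
    """
    if (relative_risks.age_end[-1] <= population_rates.age_start[0]
            or relative_risks.age_start[0] >= population_rates.age_end[-1]):
        raise ValueError("population and relative-risk tables cover disjoint age ranges")

    bounds = np.union1d(
        np.concatenate([population_rates.age_start, population_rates.age_end]),
        np.concatenate([relative_risks.age_start, relative_risks.age_end]))
    lo, hi = population_rates.age_start[0], population_rates.age_end[-1]
    bounds = bounds[(bounds >= lo) & (bounds <= hi)]

    starts, ends, rates = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (a + b)
        i = np.searchsorted(population_rates.age_end, mid, side="right")
        pop = population_rates.rates[i]
        j = np.searchsorted(relative_risks.age_end, mid, side="right")
        rr = relative_risks.rates[j] if (
            j < len(relative_risks.rates) and relative_risks.age_start[j] <= mid
        ) else 1.0
        starts.append(a); ends.append(b); rates.append(pop * rr)

    meta = dict(population_rates.meta)
    meta["carrier_status"] = CARRIER
    return IncidenceTable(np.array(starts), np.array(ends), np.array(rates), meta=meta)


# ---------------------------------------------------------------------------
# Scaled truncated-normal penetrance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PenetranceParams:
    """(r, mu, sigma) of the scaled truncated-normal penetrance curve.

    ``r`` is the lifetime cumulative risk in (0, 1); ``mu`` and ``sigma``
    (years) locate and spread the age-of-onset distribution, truncated at
    age 0.
    """

    r: float
    mu: float
    sigma: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not (0 < self.r < 1):
            raise ValueError(f"lifetime risk r={self.r} must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.mu < 130):
            raise ValueError("mu must lie in (0, 130)")

    def _dist(self):
        return stats.truncnorm(-self.mu / self.sigma, np.inf,
                               loc=self.mu, scale=self.sigma)

    def cdf(self, t):
        """Penetrance F(t) = r * F_norm(t); F(0) = 0, F(inf) = r."""
        t = np.asarray(t, dtype=float)
        return self.r * np.where(t <= 0, 0.0, self._dist().cdf(np.maximum(t, 0.0)))

    def sf(self, t):
        """Survival S(t) = 1 - F(t): probability cancer-free at age t."""
        return 1.0 - self.cdf(t)

    def pdf(self, t):
        """Density f(t) = r * f_norm(t)."""
        t = np.asarray(t, dtype=float)
        return self.r * np.where(t < 0, 0.0, self._dist().pdf(np.maximum(t, 0.0)))

    def hazard(self, t):
        """Hazard h(t) = f(t) / S(t): instantaneous rate among the unaffected."""
        return self.pdf(t) / self.sf(t)

    def evaluate(self, t) -> dict:
        """All four survival quantities at age(s) ``t``: {F, S, f, h}."""
        F = self.cdf(t)
        f = self.pdf(t)
        return {"F": F, "S": 1.0 - F, "f": f, "h": f / (1.0 - F)}

    def logpdf(self, t) -> float:
        return math.log(self.pdf(t))

    def logsf(self, t) -> float:
        return math.log(self.sf(t))


_FIT_BOUNDS = {"r": (1e-4, 0.999), "mu": (20.0, 100.0), "sigma": (2.0, 40.0)}
# 8 deterministic starts on a coarse (r, mu, sigma) grid
_FIT_STARTS = [(r0, m0, s0) for r0 in (0.05, 0.45)
               for m0 in (45.0, 70.0) for s0 in (8.0, 20.0)]


def fit_penetrance(table: IncidenceTable,
                   init: Optional[tuple] = None,
                   bounds: Optional[dict] = None) -> PenetranceParams:
    """Fit (r, mu, sigma) to an incidence table by least squares on the hazard.

    Minimizes the width-weighted sum of squared differences between the
    observed rates ``y_i`` (at interval midpoints ``t_i``) and the model
    hazard ``h(t_i) = r f_norm / (1 - r F_norm)``.  Multi-start bounded
    optimization (8 deterministic starts, or a single user-supplied
    ``init``) makes the result start-independent within tolerance.  A fit
    pinned at a parameter bound is flagged in ``meta['warnings']``.
    """
    if len(table.rates) < 4:
        raise ValueError("need at least 4 intervals to fit (r, mu, sigma)")
    if not np.any(table.rates > 0):
        raise ValueError("no events to fit: all incidence rates are zero")

    b = dict(_FIT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b["r"][0], b["mu"][0], b["sigma"][0]])
    hi = np.array([b["r"][1], b["mu"][1], b["sigma"][1]])
    t, y, w = table.midpoints, table.rates, np.sqrt(table.widths)

    def residuals(theta):
        r, mu, sigma = theta
        d = stats.truncnorm(-mu / sigma, np.inf, loc=mu, scale=sigma)
        h = r * d.pdf(t) / (1.0 - r * d.cdf(t))
        return w * (h - y)

    best = None
    for start in ([init] if init is not None else _FIT_STARTS):
        x0 = np.clip(np.asarray(start, dtype=float), lo, hi)
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("penetrance fit failed from every start")

    r, mu, sigma = best.x
    meta = dict(table.meta)
    meta["sum_of_squares"] = float(2 * best.cost)
    pinned = [name for name, v, (a, c) in
              zip(("r", "mu", "sigma"), best.x, (b["r"], b["mu"], b["sigma"]))
              if abs(v - a) < 1e-8 or abs(v - c) < 1e-8]
    if pinned:
        meta["warnings"] = [f"fit pinned at bound for {', '.join(pinned)}"]
    return PenetranceParams(float(r), float(mu), float(sigma), meta=meta)


# ---------------------------------------------------------------------------
# Contralateral breast cancer: constant conditional hazard
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CbcModel:
    """Constant hazard of CBC per year since the first breast cancer."""

    rate: float
    lifetime_cap: Optional[float] = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("CBC hazard must be positive")
        if self.lifetime_cap is not None and not (0 < self.lifetime_cap <= 1):
            raise ValueError("lifetime_cap must lie in (0, 1]")

    def pdf(self, u):
        """f_cbc(u) = lambda * exp(-lambda u), u = years since first BC."""
        return self.rate * np.exp(-self.rate * np.asarray(u, dtype=float))

    def sf(self, u):
        return np.exp(-self.rate * np.asarray(u, dtype=float))

    def logpdf(self, u) -> float:
        return math.log(self.rate) - self.rate * u

    def logsf(self, u) -> float:
        return -self.rate * u


def fit_cbc(conditional_rates: IncidenceTable) -> CbcModel:
    """Fit the constant CBC hazard by least squares.

    For a piecewise-constant rate table the least-squares constant is the
    width-weighted mean of the observed conditional rates.
    """
    if not np.any(conditional_rates.rates > 0):
        raise ValueError("no events to fit: all CBC rates are zero")
    lam = float(np.average(conditional_rates.rates, weights=conditional_rates.widths))
    return CbcModel(rate=lam, meta=dict(conditional_rates.meta))


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

@dataclass
class PenetranceSet:
    """All curves needed to analyse one gene in one reference population.

    ``curves`` maps (cancer_type, carrier_status) → PenetranceParams, with
    the applicable sex recorded in each curve's ``meta['sex']`` ('F', 'M' or
    'both'); ``cbc`` maps carrier_status → CbcModel.  For every carrier
    curve the matching general-population curve must be present — the
    benign hypothesis needs it.
    """

    gene: str
    population: str
    curves: dict[tuple[CancerType, str], PenetranceParams]
    cbc: dict[str, CbcModel]
    provenance: str = ""

    def __post_init__(self):
        for (cancer, status) in self.curves:
            if status == CARRIER and (cancer, GENERAL) not in self.curves:
                raise ValueError(
                    f"incomplete set: {self.gene} {cancer.value} has a carrier "
                    "curve but no general-population curve")
        if self.cbc and CARRIER in self.cbc and GENERAL not in self.cbc:
            raise ValueError("incomplete set: carrier CBC model without a "
                             "general-population CBC model")

    def curve(self, cancer: CancerType, status: str) -> PenetranceParams:
        try:
            return self.curves[(cancer, status)]
        except KeyError:
            raise KeyError(
                f"no {status} curve for {self.gene} {cancer.value} in "
                f"population {self.population!r}") from None

    def cbc_model(self, status: str) -> CbcModel:
        try:
            return self.cbc[status]
        except KeyError:
            raise KeyError(f"no {status} CBC model for {self.gene} in "
                           f"population {self.population!r}") from None

    def processes_for(self, sex: Sex) -> list[CancerType]:
        """Cancer processes modelled for an individual of the given sex.

        CBC is not listed: it is handled conditionally on the first BC.
        """
        out = []
        for (cancer, status), params in self.curves.items():
            if status != CARRIER or cancer == CancerType.CBC:
                continue
            applies = params.meta.get("sex", "both")
            if applies == "both" or applies == sex.value:
                out.append(cancer)
        return sorted(out, key=lambda c: c.value)

    @property
    def models_cbc(self) -> bool:
        return bool(self.cbc)


def load_penetrance_set(population: str, gene: str,
                        source_config=None) -> PenetranceSet:
    """Load a bundled (or user-supplied) penetrance parameter set.

    ``population`` is one of UK, NL, US or legacy-NL (case-insensitive), or
    'custom' with ``source_config`` pointing at a YAML file of the same
    schema as the bundled ones.  The bundled sets are synthetic
    representative parameter files (see each file's provenance field).
    """
    if source_config is not None:
        with open(source_config) as fh:
            doc = yaml.safe_load(fh)
    else:
        key = population.upper()
        if key not in _POPULATION_FILES:
            raise ValueError(
                f"unknown population {population!r}; available: "
                f"{', '.join(available_populations())} (or pass source_config)")
        doc = yaml.safe_load(
            resources.files("coseg.data").joinpath(_POPULATION_FILES[key]).read_text())

    genes = doc.get("genes", {})
    if gene not in genes:
        raise ValueError(
            f"no penetrance curves for gene {gene!r} in population "
            f"{doc.get('population', population)!r}; available genes: "
            f"{', '.join(sorted(genes))}")

    gdoc = genes[gene]
    curves = {}
    for c in gdoc.get("curves", []):
        cancer = CancerType(c["cancer"])
        params = PenetranceParams(
            float(c["r"]), float(c["mu"]), float(c["sigma"]),
            meta={"sex": c.get("sex", "both"), "gene": gene, "cancer": cancer.value,
                  "status": c["status"]})
        curves[(cancer, c["status"])] = params
    cbc = {status: CbcModel(rate=float(rate), meta={"gene": gene, "status": status})
           for status, rate in gdoc.get("cbc", {}).items()}
    return PenetranceSet(gene=gene, population=str(doc.get("population", population)),
                         curves=curves, cbc=cbc,
                         provenance=str(doc.get("provenance", "")))
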