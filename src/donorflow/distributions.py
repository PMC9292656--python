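"""Process-time distributions for the donation-centre simulator.

Every activity a donor undergoes (registration, consultation, haemoglobin
testing, phlebotomy setup, phlebotomy itself, resting, refreshment) is
modelled with a parametric service-time distribution in decimal minutes.
Five families are supported:

``normal``      mean, sd — draws at or below zero are resampled so that
                service times stay strictly positive.
``lognormal``   mean, sd of the distribution itself (not of the log); the
                underlying log-scale parameters are derived internally.
``triangular``  min a, max b, mode c.
``uniform``     min m, max M.
``weibull3``    scale, shape, location — a three-parameter Weibull, i.e. a
                standard Weibull shifted right by the location.

The defaults in :func:`default_catalog` describe a whole-blood collection
centre: short registrations (longer for walk-ins, whose data must be typed
into the database), a consultation of roughly 18 minutes, a quick
haemoglobin finger-prick, a Weibull-shaped phlebotomy bounded below by the
time the bag physically needs to fill, a mandated post-donation rest and a
self-paced canteen refreshment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "DistributionSpec",
    "ProcessTimeCatalog",
    "ACTIVITIES",
    "default_catalog",
    "sample",
    "expected_value",
    "bernoulli",
]

_FAMILIES = {"normal", "lognormal", "triangular", "uniform", "weibull3"}

#: Activities the engine draws service times for. ``registration_booked`` /
#: ``registration_unbooked`` are selected by donor type; everything else is
#: shared.
ACTIVITIES = (
    "registration_booked",
    "registration_unbooked",
    "consultation",
    "haemoglobin",
    "pre_setup",
    "phlebotomy",
    "post_setup",
    "resting",
    "refreshment",
)


class ConfigurationError(ValueError):
    """Raised for an invalid distribution family or parameter set."""


@dataclass(frozen=True)
class DistributionSpec:
    """One parametric service-time distribution, in minutes.

    Parameters
    ----------
    family
        One of ``normal``, ``lognormal``, ``triangular``, ``uniform``,
        ``weibull3``.
    params
        Family-specific tuple: normal ``(mean, sd)``; lognormal
        ``(mean, sd)`` of the distribution itself; triangular
        ``(a, b, c)`` as (min, max, mode); uniform ``(m, M)``;
        weibull3 ``(scale, shape, location)``.
    """

    family: str
    params: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise ConfigurationError(f"normal requires (mean, sd>0), got {p}")
        elif self.family == "lognormal":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ConfigurationError(f"lognormal requires (mean>0, sd>0), got {p}")
        elif self.family == "triangular":
            if len(p) != 3:
                raise ConfigurationError(f"triangular requires (a, b, c), got {p}")
            a, b, c = p
            if not (a <= c <= b):
                raise ConfigurationError(f"triangular requires a <= c <= b, got {p}")
        elif self.family == "uniform":
            if len(p) != 2 or not p[0] < p[1]:
                raise ConfigurationError(f"uniform requires (m < M), got {p}")
        elif self.family == "weibull3":
            if len(p) != 3 or p[0] <= 0 or p[1] <= 0:
                raise ConfigurationError(
                    f"weibull3 requires (scale>0, shape>0, location), got {p}"
                )

    # -- convenience constructors ------------------------------------
    @classmethod
    def normal(cls, mean: float, sd: float) -> "DistributionSpec":
        return cls("normal", (mean, sd))

    @classmethod
    def lognormal(cls, mean: float, sd: float) -> "DistributionSpec":
        return cls("lognormal", (mean, sd))

    @classmethod
    def triangular(cls, a: float, b: float, c: float) -> "DistributionSpec":
        return cls("triangular", (a, b, c))

    @classmethod
    def uniform(cls, m: float, M: float) -> "DistributionSpec":
        return cls("uniform", (m, M))

    @classmethod
    def weibull3(cls, scale: float, shape: float, location: float) -> "DistributionSpec":
        return cls("weibull3", (scale, shape, location))

    @classmethod
    def degenerate(cls, value: float) -> "DistributionSpec":
        """A point mass at ``value`` (triangular with zero-width support)."""
        return cls("triangular", (value, value, value))


def _lognormal_log_params(mean: float, sd: float) -> Tuple[float, float]:
    """Convert (mean, sd) of a lognormal to its log-scale (mu, sigma)."""
    var = sd * sd
    sigma2 = math.log(1.0 + var / (mean * mean))
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample(spec: DistributionSpec, stream: np.random.Generator) -> float:
    """Draw one service time (minutes) from ``spec`` using ``stream``.

    Normal draws at or below zero are resampled, preserving the nominal
    mean approximately (the truncated mass is negligible at the default
    parameter values, e.g. P(X<=0) ~ 2e-3 for mean 1.77, sd 0.612).
    """
    fam, p = spec.family, spec.params
    if fam == "normal":
        x = stream.normal(p[0], p[1])
        while x <= 0.0:
            x = stream.normal(p[0], p[1])
        return float(x)
    if fam == "lognormal":
        mu, sigma = _lognormal_log_params(*p)
        return float(stream.lognormal(mu, sigma))
    if fam == "triangular":
        a, b, c = p
        if a == b:  # degenerate point mass; numpy rejects left==right
            return float(a)
        return float(stream.triangular(a, c, b))
    if fam == "uniform":
        return float(stream.uniform(p[0], p[1]))
    if fam == "weibull3":
        scale, shape, loc = p
        return float(loc + scale * stream.weibull(shape))
    raise ConfigurationError(f"unknown distribution family {fam!r}")  # pragma: no cover


def expected_value(spec: DistributionSpec) -> float:
    """Closed-form mean of ``spec`` in minutes.

    weibull3 uses ``location + scale * Gamma(1 + 1/shape)``; the normal
    mean ignores the positive-truncation resampling, whose bias is
    negligible at realistic service-time parameters.
    """
    fam, p = spec.family, spec.params
    if fam == "normal" or fam == "lognormal":
        return float(p[0])
    if fam == "triangular":
        return float((p[0] + p[1] + p[2]) / 3.0)
    if fam == "uniform":
        return float((p[0] + p[1]) / 2.0)
    if fam == "weibull3":
        scale, shape, loc = p
        return float(loc + scale * math.gamma(1.0 + 1.0 / shape))
    raise ConfigurationError(f"unknown distribution family {fam!r}")  # pragma: no cover


def bernoulli(p: float, stream: np.random.Generator) -> bool:
    """One Bernoulli(p) draw. Used for slot filling, no-shows and deferrals."""
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"Bernoulli probability must be in [0, 1], got {p}")
    return bool(stream.uniform() < p)


@dataclass
class ProcessTimeCatalog:
    """Mapping from activity name to its service-time distribution.

    Every activity in :data:`ACTIVITIES` must be present exactly once.
    """

    specs: Dict[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [a for a in ACTIVITIES if a not in self.specs]
        extra = [a for a in self.specs if a not in ACTIVITIES]
        if missing or extra:
            raise ConfigurationError(
                f"catalog must cover exactly {ACTIVITIES}; "
                f"missing={missing}, unknown={extra}"
            )

    def __getitem__(self, activity: str) -> DistributionSpec:
        return self.specs[activity]

    def replace(self, **overrides: DistributionSpec) -> "ProcessTimeCatalog":
        """A copy of the catalog with some activities swapped out."""
        specs = dict(self.specs)
        specs.update(overrides)
        return ProcessTimeCatalog(specs)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> Dict[str, dict]:
        return {
            a: {"family": s.family, "params": list(s.params)}
            for a, s in self.specs.items()
        }

    @classmethod
    def from_dict(cls, data: Dict[str, dict]) -> "ProcessTimeCatalog":
        try:
            specs = {
                a: DistributionSpec(d["family"], tuple(float(x) for x in d["params"]))
                for a, d in data.items()
            }
        except KeyError as exc:
            raise ConfigurationError(f"catalog entry missing field {exc}") from exc
        return cls(specs)


def default_catalog() -> ProcessTimeCatalog:
    """The default process-time catalog (minutes).

    Values describe a Western fixed-site whole-blood centre: registration
    normal(1.77, 0.612) for booked donors and lognormal(2.4, 0.82) for
    walk-ins; consultation triangular(16.5, 20, mode 18.33); haemoglobin
    test uniform(1.34, 2) — consultation and haemoglobin are calibrated so
    their combined expectation equals the 20-minute standard consultation
    slot the upstream scheduler plans with; machine pre-setup
    normal(1.6, 0.284); phlebotomy Weibull(scale 4.23, shape 1.82) shifted
    by 9.5 min; post-setup uniform(1, 2); resting triangular(4, 10, mode 5);
    refreshment lognormal(14.22, 7.11).
    """
    return ProcessTimeCatalog(
        {
            "registration_booked": DistributionSpec.normal(1.77, 0.612),
            "registration_unbooked": DistributionSpec.lognormal(2.4, 0.82),
            "consultation": DistributionSpec.triangular(16.5, 20.0, 18.33),
            "haemoglobin": DistributionSpec.uniform(1.34, 2.0),
            "pre_setup": DistributionSpec.normal(1.6, 0.284),
            "phlebotomy": DistributionSpec.weibull3(4.23, 1.82, 9.5),
            "post_setup": DistributionSpec.uniform(1.0, 2.0),
            "resting": DistributionSpec.triangular(4.0, 10.0, 5.0),
            "refreshment": DistributionSpec.lognormal(14.22, 7.11),
        }
    )
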