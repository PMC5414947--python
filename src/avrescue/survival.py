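"""Probability curves consumed by the rescue scenarios.

Two curves drive every trade-off in this package:

* :class:`SurvivalCurve` — probability that a completely buried subject is
  alive as a function of burial time.  It is monotone non-increasing: the
  buried subject only loses survival chance as time passes.  The shipped
  default is a piecewise-linear digitization of the Swiss avalanche
  survival curve; since that curve is published graphically only, the knot
  set is versioned configuration, not ground truth.

* :class:`RoscModel` — probability that CPR on a normothermic pulseless
  patient has achieved return of spontaneous circulation (ROSC) after
  ``t`` minutes of resuscitation::

      p1(t) = a * (1 - exp(-0.07 * t**1.3))

  ``a`` is the success ceiling: the fraction of such patients who are
  resuscitable at all.  ``a`` shrinks with the duration of burial before
  extrication (the hypoxic insult), tabulated in
  :class:`TriageParameterTable`: 0.62 after 12 min of burial, 0.25 after
  20 min, 0 from 35 min on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "SurvivalCurve",
    "RoscModel",
    "TriageParameterTable",
    "default_survival_curve",
    "default_triage_table",
]

DEFAULT_CURVE_RESOURCE = "survival_curve_v1.yaml"
DEFAULT_TRIAGE_RESOURCE = "triage_a_v1.yaml"


@dataclass(frozen=True)
class SurvivalCurve:
    """Monotone non-increasing map from burial time [min] to survival probability.

    Evaluation interpolates linearly between knots (which cannot overshoot
    the knot values, so monotonicity is preserved exactly); beyond the last
    knot the last probability holds.
    """

    times_min: np.ndarray
    probabilities: np.ndarray
    version: str = "unversioned"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "probabilities", p)
        if t.ndim != 1 or t.size < 1 or t.size != p.size:
            raise ValueError("knots must be two equal-length 1-D arrays")
        if t[0] != 0:
            raise ValueError("knot times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(p) > 0):
            raise ValueError("survival probabilities must be non-increasing")

    def __call__(self, t_min):
        return self.survival_at(t_min)

    def survival_at(self, t_min):
        """Survival probability at burial time ``t_min`` (scalar or array)."""
        t = np.asarray(t_min, dtype=float)
        if np.any(t < 0):
            raise ValueError("burial time must be >= 0")
        out = np.interp(t, self.times_min, self.probabilities)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(t_min) else out

    @classmethod
    def from_knots(cls, knots, version: str = "unversioned") -> "SurvivalCurve":
        arr = np.asarray(knots, dtype=float)
        return cls(arr[:, 0], arr[:, 1], version=version)

    @classmethod
    def from_yaml(cls, path) -> "SurvivalCurve":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_knots(doc["knots"], version=str(doc.get("version", "file")))

    def to_yaml(self, path) -> None:
        doc = {
            "name": "survival-curve",
            "version": self.version,
            "units": {"time": "min", "survival": "probability"},
            "knots": [[float(t), float(p)]
                      for t, p in zip(self.times_min, self.probabilities)],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class RoscModel:
    """Saturating-exponential ROSC probability, p1(t) = a·(1 − e^(−rate·t^exponent))."""

    a: float
    rate: float = 0.07
    exponent: float = 1.3

    def __post_init__(self) -> None:
        if not 0 <= self.a <= 1:
            raise ValueError("ceiling a must lie in [0, 1]")
        if self.rate < 0 or self.exponent <= 0:
            raise ValueError("rate must be >= 0 and exponent > 0")

    def probability(self, t_cpr_min):
        """P(ROSC achieved) after ``t_cpr_min`` minutes of CPR."""
        t = np.asarray(t_cpr_min, dtype=float)
        if np.any(t < 0):
            raise ValueError("CPR duration must be >= 0")
        out = self.a * (1.0 - np.exp(-self.rate * t**self.exponent))
        return float(out) if np.isscalar(t_cpr_min) else out

    def mean_over_grid(self, grid_min) -> float:
        """Arithmetic mean of the ROSC probability over a duration grid."""
        grid = np.asarray(grid_min, dtype=float)
        if grid.size == 0:
            raise ValueError("grid must be non-empty")
        return float(np.mean(self.probability(grid)))


@dataclass(frozen=True)
class TriageParameterTable:
    """Success ceiling ``a`` by initial burial time of the extricated patient."""

    entries: tuple[tuple[float, float], ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.entries]
        avals = [a for _, a in self.entries]
        if len(ts) < 1 or sorted(ts) != ts:
            raise ValueError("entries must be sorted by burial time")
        if any(np.diff(avals) > 0):
            raise ValueError("a must be non-increasing in burial time")

    def a_for(self, t_burial_min: float) -> float:
        """Exact-match lookup; burial times past the last entry give its a."""
        for t, a in self.entries:
            if t == t_burial_min:
                return a
        if t_burial_min > self.entries[-1][0]:
            return self.entries[-1][1]
        raise KeyError(
            f"no ceiling tabulated for burial time {t_burial_min} min; "
            f"known: {[t for t, _ in self.entries]}"
        )

    @classmethod
    def from_yaml(cls, path) -> "TriageParameterTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            tuple((float(t), float(a)) for t, a in doc["entries"]),
            version=str(doc.get("version", "file")),
        )


def _default_resource(name: str):
    return resources.files("avrescue").joinpath("defaults", name)


def default_survival_curve() -> SurvivalCurve:
    """The package's shipped (versioned, approximate) survival-curve digitization."""
    with resources.as_file(_default_resource(DEFAULT_CURVE_RESOURCE)) as p:
        return SurvivalCurve.from_yaml(p)


def default_triage_table() -> TriageParameterTable:
    """The shipped burial-time → ROSC-ceiling table (12→0.62, 20→0.25, 35→0)."""
    with resources.as_file(_default_resource(DEFAULT_TRIAGE_RESOURCE)) as p:
        return TriageParameterTable.from_yaml(p)
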