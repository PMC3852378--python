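"""Deterministic population-size histories ``N(t)``.

A :class:`DemographicModel` maps an integer generation ``t`` in ``[0, T]`` to a
diploid census size ``N(t) >= 2``.  Three shapes are supported:

``constant``
    ``N(t) = N`` for all ``t``.
``exponential``
    ``N(t) = round(N_start * (N_end / N_start) ** (t / T))``, i.e. geometric
    interpolation between the endpoints, rounded to the nearest integer per
    generation so that binomial reproduction always has an integer number of
    gene copies.
``piecewise``
    A step function given as ordered segments ``(f0, f1, N)`` with the
    fractions ``f0 < f1`` of the total duration ``T``.  A generation ``t``
    belongs to the segment with ``f0 * T <= t < f1 * T`` (the last segment is
    closed at ``T``), so fractional boundaries need no rounding.

Five canonical demographic scenarios used throughout the test-calibration
experiments (constant size, slow and rapid exponential growth, moderate and
severe bottlenecks) plus their small-population variants are available through
:func:`builtin_model`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DemographyError",
    "DemographicModel",
    "population_size",
    "builtin_model",
    "BUILTIN_MODELS",
]


class DemographyError(ValueError):
    """Invalid demographic parameters or an out-of-range evaluation time."""


@dataclass(frozen=True)
class DemographicModel:
    """A deterministic diploid population-size function on ``[0, T]``.

    Parameters
    ----------
    kind
        One of ``{"constant", "exponential", "piecewise"}``.
    T
        Total duration in generations (``T >= 1``).
    N
        Census size for the ``constant`` kind.
    N_start, N_end
        Endpoint sizes for the ``exponential`` kind.
    segments
        Ordered ``(start_fraction, end_fraction, N)`` triples covering
        ``[0, 1]`` for the ``piecewise`` kind.
    """

    kind: str
    T: int
    N: int | None = None
    N_start: int | None = None
    N_end: int | None = None
    segments: tuple[tuple[float, float, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "exponential", "piecewise"):
            raise DemographyError(f"unknown model kind {self.kind!r}")
        if self.T < 1:
            raise DemographyError(f"duration T must be >= 1, got {self.T}")
        if self.kind == "constant":
            if self.N is None or self.N < 2:
                raise DemographyError("constant model needs N >= 2")
        elif self.kind == "exponential":
            if self.N_start is None or self.N_end is None:
                raise DemographyError("exponential model needs N_start and N_end")
            if self.N_start < 2 or self.N_end < 2:
                raise DemographyError("exponential endpoints must be >= 2")
        else:
            segs = self.segments
            if not segs:
                raise DemographyError("piecewise model needs segments")
            if not math.isclose(segs[0][0], 0.0) or not math.isclose(segs[-1][1], 1.0):
                raise DemographyError("piecewise segments must cover [0, 1]")
            for (a0, a1, n), prev in zip(segs, (None,) + segs[:-1]):
                if not (0.0 <= a0 < a1 <= 1.0):
                    raise DemographyError(f"bad segment bounds ({a0}, {a1})")
                if n < 2:
                    raise DemographyError("segment sizes must be >= 2")
                if prev is not None and not math.isclose(prev[1], a0):
                    raise DemographyError("piecewise segments must be contiguous")

    def size(self, t: int) -> int:
        """``N(t)`` for an integer generation ``0 <= t <= T``."""
        return population_size(self, t)

    def sizes(self) -> np.ndarray:
        """``N(t)`` for every generation ``t = 0 .. T`` as an integer array."""
        return np.array([population_size(self, t) for t in range(self.T + 1)])


def population_size(model: DemographicModel, t: int) -> int:
    """Evaluate ``N(t)`` of `model` at generation `t`.

    Raises
    ------
    DemographyError
        If ``t`` lies outside ``[0, model.T]``.
    """
    if not 0 <= t <= model.T:
        raise DemographyError(f"t={t} outside [0, {model.T}]")
    if model.kind == "constant":
        return int(model.N)
    if model.kind == "exponential":
        n = round(model.N_start * (model.N_end / model.N_start) ** (t / model.T))
        return max(2, int(n))
    # piecewise: segment j holds on (f0*T, f1*T], evaluated directly on the
    # fractional boundaries (first segment closed at 0).  The left-open
    # convention ties each generation's drift to the epoch that produced it,
    # so an epoch change at a sampling time does not leak into the earlier
    # sampling interval.
    for j, (f0, f1, n) in enumerate(model.segments):
        if (f0 * model.T < t <= f1 * model.T) or (j == 0 and t == 0):
            return int(n)
    raise DemographyError(f"no segment contains t={t}")  # pragma: no cover


def _bottleneck(n_out: int, n_in: int) -> tuple[tuple[float, float, int], ...]:
    return ((0.0, 0.5, n_out), (0.5, 0.75, n_in), (0.75, 1.0, n_out))


BUILTIN_MODELS = (
    "model1",
    "model2",
    "model3",
    "model4",
    "model5",
    "model1p",
    "model5p",
)


def builtin_model(name: str, T: int) -> DemographicModel:
    """Construct one of the canonical demographic scenarios with duration `T`.

    ``model1``  constant ``N = 10^4``;
    ``model2``  slow exponential growth ``10^4 -> 10^5``;
    ``model3``  moderate bottleneck ``5x10^4 / 10^4 / 5x10^4`` (bottleneck on
    ``[0.5 T, 0.75 T)``);
    ``model4``  rapid exponential growth ``10^4 -> 10^8``;
    ``model5``  severe bottleneck ``10^6 / 10^4 / 10^6``;
    ``model1p`` constant ``N = 100``;
    ``model5p`` model5 with every size divided by 200 (``5000 / 50 / 5000``).
    """
    if name == "model1":
        return DemographicModel("constant", T, N=10_000)
    if name == "model2":
        return DemographicModel("exponential", T, N_start=10_000, N_end=100_000)
    if name == "model3":
        return DemographicModel("piecewise", T, segments=_bottleneck(50_000, 10_000))
    if name == "model4":
        return DemographicModel("exponential", T, N_start=10_000, N_end=100_000_000)
    if name == "model5":
        return DemographicModel(
            "piecewise", T, segments=_bottleneck(1_000_000, 10_000)
        )
    if name == "model1p":
        return DemographicModel("constant", T, N=100)
    if name == "model5p":
        return DemographicModel("piecewise", T, segments=_bottleneck(5_000, 50))
    raise DemographyError(
        f"unknown builtin model {name!r}; choose from {', '.join(BUILTIN_MODELS)}"
    )
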