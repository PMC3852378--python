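"""The frequency increment test (FIT) and its reference-locus extension (FITR).

Both tests ask whether the trajectory of an allele frequency ``x_0, .., x_L``
observed at times ``t_0 < .. < t_L`` drifts farther and more directionally
than neutral genetic drift allows.

**FIT.**  The standardized increments

    Y_i = (x_i - x_{i-1}) / sqrt(2 x_{i-1} (1 - x_{i-1}) (t_i - t_{i-1}))

are, for short intervals and moderate frequencies, approximately i.i.d.
normal with mean 0 and variance 1/(2N) under neutrality in a Wright-Fisher
population of constant diploid size N.  Since N is unknown, the one-sample
location statistic ``t_FIT = Ybar / sqrt(S^2 / L)`` is referred to a
Student-t distribution with ``L - 1`` degrees of freedom.  The construction
assumes every interval has the *same* variance, so a fluctuating population
size makes the FIT conservative.

**FITR.**  With ``R`` independent neutral reference loci observed at the same
times, the per-interval drift scale can be cancelled instead of pooled.  With
``dx_{h,i} = (x_{h,i} - x_{h,i-1}) / sqrt(x_{h,i-1} (1 - x_{h,i-1}))``, the
per-interval statistic

    t^(i) = dx_{0,i} / sqrt( (1/R) * sum_h dx_{h,i}^2 )

is a standard-normal numerator over an independent chi/sqrt(df) denominator —
the interval's unknown variance effective size and interval length cancel —
so ``t^(i)`` is Student-t with ``R`` degrees of freedom whatever ``N(t)``
does.  The summary statistic ``t_FITR = (1/sqrt(L)) * sum_i t^(i)`` is
referred to an empirical null built by summing ``L`` independent Student-t(R)
draws (the exact null for ``L = 1`` is analytic).

Reference loci whose frequency reaches 0 or 1 at any sampled time have
ill-defined (or degenerate) increments and are removed before computing
``t_FITR``; the number of surviving references sets the degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "DegenerateInputError",
    "DegenerateFocalError",
    "NoReferenceError",
    "ZeroDenominatorError",
    "IncrementMatrix",
    "TestResult",
    "fit_increments",
    "fit_test",
    "fit_test_batch",
    "fitr_increments",
    "filter_reference_loci",
    "fitr_component",
    "fitr_statistic",
    "fitr_null",
    "fitr_test",
    "fitr_test_batch",
]


class DegenerateInputError(ValueError):
    """A frequency of exactly 0 or 1 makes a required increment undefined."""


class DegenerateFocalError(DegenerateInputError):
    """The focal locus is fixed or lost where an increment is required."""


class NoReferenceError(ValueError):
    """No reference locus survives filtering; the FITR is undefined."""


class ZeroDenominatorError(ValueError):
    """All reference increments are zero at some interval."""


@dataclass
class IncrementMatrix:
    """Standardized increments ``dx[h, i]`` for loci ``h = 0..R``, steps ``i = 1..L``.

    ``valid[h]`` marks loci whose increments are all well defined and usable;
    a locus is invalid if its frequency is exactly 0 or 1 at any sampled
    time.  ``removed`` records the indices of reference loci dropped by
    :func:`filter_reference_loci` (indices refer to the original locus order).
    """

    d: np.ndarray
    dt: np.ndarray
    valid: np.ndarray
    locus_index: np.ndarray = None
    removed: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.locus_index is None:
            self.locus_index = np.arange(self.d.shape[0])

    @property
    def L(self) -> int:
        return self.d.shape[1]

    @property
    def R(self) -> int:
        return self.d.shape[0] - 1


@dataclass
class TestResult:
    """Outcome of a FIT or FITR application to one trajectory set."""

    statistic: float
    test: str
    p_value: float
    df: int | None = None
    null: tuple | None = None  # (L, R_used, M) for the empirical FITR null
    R_used: int | None = None
    removed_loci: tuple[int, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"{self.test}: statistic={self.statistic:.6g}",
                 f"p={self.p_value:.4g}"]
        if self.df is not None:
            parts.append(f"df={self.df}")
        if self.R_used is not None:
            parts.append(f"references_used={self.R_used}")
        if self.removed_loci:
            parts.append(f"removed={list(self.removed_loci)}")
        return "  ".join(parts)


# ---------------------------------------------------------------------------
# FIT
# ---------------------------------------------------------------------------

def fit_increments(x, times) -> np.ndarray:
    """Standardized increments ``Y_1 .. Y_L`` of a single frequency series."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.ndim != 1 or x.size != t.size or x.size < 2:
        raise ValueError("need one frequency per time, at least two times")
    bad = (x[:-1] <= 0.0) | (x[:-1] >= 1.0)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise DegenerateInputError(
            f"frequency {x[i]} at time {t[i]} makes increment {i + 1} undefined"
        )
    dt = np.diff(t)
    return np.diff(x) / np.sqrt(2.0 * x[:-1] * (1.0 - x[:-1]) * dt)


def fit_test(x, times) -> TestResult:
    """Frequency increment test of neutrality on a single locus.

    ``t_FIT = Ybar / sqrt(S^2 / L)`` with the unbiased (``L - 1``) variance,
    compared two-sided against Student-t with ``L - 1`` degrees of freedom.
    """
    y = fit_increments(x, times)
    L = y.size
    if L < 2:
        raise ValueError("FIT needs at least two increments (L >= 2)")
    s2 = y.var(ddof=1)
    if s2 == 0.0:
        raise DegenerateInputError("all increments identical: zero variance")
    stat = y.mean() / np.sqrt(s2 / L)
    p = 2.0 * sps.t.sf(abs(stat), L - 1)
    return TestResult(statistic=float(stat), test="FIT", p_value=float(p), df=L - 1)


def fit_test_batch(freqs, times):
    """Vectorised FIT over replicates.

    Parameters
    ----------
    freqs
        Array ``(n_rep, L + 1)`` of focal-locus frequencies.
    times
        The shared sampling times.

    Returns
    -------
    stat, p, degenerate
        Statistics and two-sided p-values (NaN where degenerate) and the
        boolean mask of replicates whose series makes the test undefined
        (fixation before the last interval, or zero increment variance).
    """
    x = np.asarray(freqs, dtype=float)
    t = np.asarray(times, dtype=float)
    dt = np.diff(t)
    prev = x[:, :-1]
    degenerate = np.any((prev <= 0.0) | (prev >= 1.0), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.diff(x, axis=1) / np.sqrt(2.0 * prev * (1.0 - prev) * dt)
    L = dt.size
    # degenerate rows are masked with zeros here and overwritten with NaN below
    y_safe = np.where(np.isfinite(y), y, 0.0)
    mean = y_safe.mean(axis=1)
    s2 = y_safe.var(axis=1, ddof=1)
    degenerate |= ~np.isfinite(s2) | (s2 == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = mean / np.sqrt(s2 / L)
    stat = np.where(degenerate, np.nan, stat)
    p = 2.0 * sps.t.sf(np.abs(stat), L - 1)
    return stat, p, degenerate


# ---------------------------------------------------------------------------
# FITR
# ---------------------------------------------------------------------------

def _standardized_increments(freqs: np.ndarray) -> np.ndarray:
    """``dx[..., i] = (x_i - x_{i-1}) / sqrt(x_{i-1} (1 - x_{i-1}))`` along the last axis."""
    prev = freqs[..., :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.diff(freqs, axis=-1) / np.sqrt(prev * (1.0 - prev))


def fitr_increments(trajset) -> IncrementMatrix:
    """Standardized increment matrix of a trajectory set, with validity flags.

    A locus is flagged invalid when its frequency is exactly 0 or 1 at any
    sampled time, which makes the increments (or the per-interval variance
    they are meant to represent) degenerate.  An invalid *focal* locus is an
    error; invalid references are left for :func:`filter_reference_loci`.
    """
    x = np.atleast_2d(np.asarray(trajset.freqs, dtype=float))
    times = np.asarray(trajset.times)
    d = _standardized_increments(x)
    fixed = (x <= 0.0) | (x >= 1.0)
    valid = ~np.any(fixed, axis=1)
    if np.any(fixed[0, :-1]):
        i = int(np.argmax(fixed[0]))
        raise DegenerateFocalError(
            f"focal locus fixed at time {times[i]}: FIT/FITR increments undefined"
        )
    valid[0] = True  # focal fixed only at t_L still has defined increments
    d[~np.isfinite(d)] = np.nan
    return IncrementMatrix(d=d, dt=np.diff(times), valid=valid)


def filter_reference_loci(inc: IncrementMatrix) -> IncrementMatrix:
    """Drop reference loci flagged invalid (frequency hit 0 or 1).

    Removal is all-or-nothing per locus.  Raises :class:`NoReferenceError`
    when no reference survives.
    """
    if inc.R < 1:
        raise NoReferenceError("FITR needs at least one reference locus")
    keep = inc.valid.copy()
    keep[0] = True
    removed = tuple(int(h) for h in inc.locus_index[~keep])
    if int(keep[1:].sum()) == 0:
        raise NoReferenceError("all reference loci hit frequency 0 or 1")
    return IncrementMatrix(
        d=inc.d[keep],
        dt=inc.dt,
        valid=inc.valid[keep],
        locus_index=inc.locus_index[keep],
        removed=removed,
    )


def fitr_component(d0, dref) -> float:
    """Per-interval statistic ``t^(i) = d0 / sqrt(mean(dref^2))``.

    The unknown variance effective size and the interval length divide out of
    the ratio, so the component is Student-t with ``R = len(dref)`` degrees of
    freedom under neutrality of the focal locus.
    """
    dref = np.asarray(dref, dtype=float)
    denom2 = np.mean(dref**2)
    if denom2 == 0.0:
        raise ZeroDenominatorError("all reference increments are zero")
    return float(d0 / np.sqrt(denom2))


def fitr_statistic(inc: IncrementMatrix) -> float:
    """``t_FITR = (1 / sqrt(L)) * sum_i t^(i)`` of a filtered increment matrix."""
    comps = [fitr_component(inc.d[0, i], inc.d[1:, i]) for i in range(inc.L)]
    return float(np.sum(comps) / np.sqrt(inc.L))


_NULL_CACHE: dict[tuple, np.ndarray] = {}


def fitr_null(L: int, R: int, M: int = 100_000, rng=None, seed=None) -> np.ndarray:
    """`M` draws from the null distribution of ``t_FITR`` for given ``(L, R)``.

    Each draw is ``(1/sqrt(L)) * sum of L independent Student-t(R)`` random
    variables.  When built from an integer `seed` the sample is cached in
    memory keyed by ``(L, R, M, seed)`` so repeated tests on the same design
    reuse one null.
    """
    if L < 1 or R < 1:
        raise ValueError("need L >= 1 and R >= 1")
    key = (L, R, M, seed)
    if seed is not None and key in _NULL_CACHE:
        return _NULL_CACHE[key]
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.standard_t(R, size=(M, L)).sum(axis=1) / np.sqrt(L)
    if seed is not None:
        _NULL_CACHE[key] = draws
    return draws


def empirical_p(stat: float, null: np.ndarray) -> float:
    """Two-sided Monte-Carlo p-value with the add-one estimator."""
    k = int(np.count_nonzero(np.abs(null) >= abs(stat)))
    return (1 + k) / (null.size + 1)


def fitr_test(trajset, M: int = 100_000, rng=None, seed=None,
              null: np.ndarray | None = None) -> TestResult:
    """Frequency increment test with reference loci on one trajectory set.

    Pipeline: standardized increments -> removal of fixed references ->
    ``t_FITR`` -> two-sided p-value against the empirical null for
    ``(L, R_used)`` (analytic Student-t(R_used) when ``L = 1``).  A
    precomputed `null` sample overrides `M`/`rng`/`seed`.
    """
    inc = filter_reference_loci(fitr_increments(trajset))
    stat = fitr_statistic(inc)
    L, r_used = inc.L, inc.R
    if L == 1:
        p = 2.0 * sps.t.sf(abs(stat), r_used)
        desc = (L, r_used, "analytic")
    else:
        if null is None:
            null = fitr_null(L, r_used, M=M, rng=rng, seed=seed)
        p = empirical_p(stat, null)
        desc = (L, r_used, null.size)
    return TestResult(
        statistic=stat,
        test="FITR",
        p_value=float(p),
        null=desc,
        R_used=r_used,
        removed_loci=inc.removed,
    )


def fitr_test_batch(freqs, M: int = 100_000, null_rng=None):
    """Vectorised FITR over replicates sharing one design.

    Parameters
    ----------
    freqs
        Array ``(n_rep, n_loci, L + 1)``; locus 0 is focal.
    M
        Empirical-null size per distinct surviving reference count.
    null_rng
        Generator for the null draws (a fresh default generator if omitted).

    Returns
    -------
    stat, p, r_used, degenerate
        Per-replicate statistic, two-sided p-value, surviving reference
        count, and the mask of degenerate replicates (focal fixed before the
        last interval, no surviving reference, or a zero denominator); their
        statistic and p are NaN.
    """
    x = np.asarray(freqs, dtype=float)
    n_rep, n_loci, n_times = x.shape
    L = n_times - 1
    if null_rng is None:
        null_rng = np.random.default_rng()

    d = _standardized_increments(x)
    fixed = (x <= 0.0) | (x >= 1.0)
    degenerate = np.any(fixed[:, 0, :-1], axis=1)  # focal fixed pre-t_L
    ref_ok = ~np.any(fixed[:, 1:, :], axis=2)      # (n_rep, R)
    r_used = ref_ok.sum(axis=1)

    dref = np.where(ref_ok[:, :, None], d[:, 1:, :], 0.0)
    dref = np.nan_to_num(dref)
    ss = np.einsum("rhl,rhl->rl", dref, dref)      # (n_rep, L)
    degenerate |= (r_used == 0) | np.any(ss == 0.0, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        comps = d[:, 0, :] / np.sqrt(ss / np.maximum(r_used, 1)[:, None])
        stat = comps.sum(axis=1) / np.sqrt(L)
    stat = np.where(degenerate, np.nan, stat)

    p = np.full(n_rep, np.nan)
    for r in np.unique(r_used[~degenerate]):
        sel = (~degenerate) & (r_used == r)
        if L == 1:
            p[sel] = 2.0 * sps.t.sf(np.abs(stat[sel]), int(r))
            continue
        null_abs = np.sort(np.abs(fitr_null(L, int(r), M=M, rng=null_rng)))
        k = null_abs.size - np.searchsorted(null_abs, np.abs(stat[sel]), side="left")
        p[sel] = (1 + k) / (null_abs.size + 1)
    return stat, p, r_used, degenerate
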