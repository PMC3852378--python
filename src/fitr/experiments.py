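"""Replicate-level Monte-Carlo drivers: type-I error, power, table grids.

Each driver simulates many independent trajectory sets under one parameter
cell, applies the FIT or FITR, and reports the rejection rate at a nominal
level together with its binomial Monte-Carlo standard error.  Replicates on
which the test is undefined (focal locus fixed before the last interval, all
references removed, zero denominator) are excluded from the denominator and
counted separately.

The four built-in table grids reproduce the package's calibration study:

1. FIT type-I error across the five demographic scenarios;
2. FITR type-I error across the same scenarios;
3. validation of pseudo-sampling against exact binomial reproduction and of
   free vs. limited recombination (small-population scenarios);
4. the effect of low-frequency reference loci (removal of fixed references)
   on type-I error and power, with the mean surviving reference count.

Per-cell seeds are derived from the master seed by stable hashing of the
cell, so any cell is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .demography import DemographicModel, builtin_model
from .wf import SimulationConfig, simulate_batch, simulate_linked
from .stats import fit_test_batch, fitr_test_batch

__all__ = [
    "ExperimentCell",
    "RejectionResult",
    "rejection_rate",
    "run_table",
    "power_curve",
]


@dataclass(frozen=True)
class ExperimentCell:
    """One grid cell of a simulation experiment.

    ``model`` is a builtin name or an explicit :class:`DemographicModel`.
    ``L`` intervals of length ``dt`` (default ``T // L``) define the sampling
    times ``0, dt, .., L*dt``.  ``R`` reference loci share ``x0_ref`` and
    ``s_ref``; the focal locus uses ``x0_focal`` and ``s0``.
    """

    test: str
    model: str | DemographicModel
    T: int
    L: int
    dt: int | None = None
    R: int = 0
    s0: float = 0.0
    s_ref: float = 0.0
    x0_focal: float = 0.5
    x0_ref: float = 0.5
    method: str = "pseudo"
    r: float | str = "free"
    sample_n: int | None = None

    def __post_init__(self) -> None:
        if self.test not in ("FIT", "FITR"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.test == "FITR" and self.R < 1:
            raise ValueError("FITR needs at least one reference locus")
        if self.dt is None:
            if self.T % self.L:
                raise ValueError(
                    f"T={self.T} not divisible by L={self.L}; give dt explicitly"
                )
            object.__setattr__(self, "dt", self.T // self.L)
        if self.L * self.dt > self.T:
            raise ValueError("sampling times exceed the duration T")

    def demographic_model(self) -> DemographicModel:
        if isinstance(self.model, DemographicModel):
            return self.model
        return builtin_model(self.model, self.T)

    def sample_times(self) -> tuple[int, ...]:
        return tuple(range(0, self.L * self.dt + 1, self.dt))

    def config(self) -> SimulationConfig:
        x0 = (self.x0_focal,) + (self.x0_ref,) * self.R
        s = (self.s0,) + (self.s_ref,) * self.R
        return SimulationConfig(
            model=self.demographic_model(),
            sample_times=self.sample_times(),
            x0=x0,
            s=s,
            n_loci=self.R + 1,
            method=self.method,
            recombination=self.r,
            sample_n=self.sample_n,
        )


@dataclass
class RejectionResult:
    """Monte-Carlo rejection rate of one cell, in percent."""

    rate: float
    se: float
    n_tested: int
    n_degenerate: int
    mean_R_used: float | None = None
    alpha: float = 0.05


def _cell_seed(master_seed: int, cell, tag: str = "") -> np.random.SeedSequence:
    digest = hashlib.sha256(f"{cell!r}|{tag}".encode()).digest()
    cell_key = int.from_bytes(digest[:4], "big") >> 1  # stable 31-bit cell hash
    return np.random.SeedSequence([int(master_seed), cell_key])


def _simulate_cell(cell: ExperimentCell, replicates: int, rng) -> np.ndarray:
    config = cell.config()
    if cell.r == "free":
        return simulate_batch(config, replicates, rng)
    return np.stack(
        [simulate_linked(config, rng).freqs for _ in range(replicates)]
    )


def rejection_rate(
    cell: ExperimentCell,
    replicates: int,
    seed: int = 0,
    alpha: float = 0.05,
    null_draws: int = 100_000,
) -> RejectionResult:
    """Fraction of `replicates` on which the cell's test rejects at `alpha`.

    Returns the rate and its binomial standard error (both in percent), the
    number of testable replicates, the number excluded as degenerate, and —
    for the FITR — the mean number of reference loci surviving removal.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(_cell_seed(seed, cell, "sim"))
    freqs = _simulate_cell(cell, replicates, rng)
    mean_r = None
    if cell.test == "FIT":
        _, p, degenerate = fit_test_batch(freqs[:, 0, :], cell.sample_times())
    else:
        null_rng = np.random.default_rng(_cell_seed(seed, cell, "null"))
        _, p, r_used, degenerate = fitr_test_batch(
            freqs, M=null_draws, null_rng=null_rng
        )
        if np.any(~degenerate):
            mean_r = float(r_used[~degenerate].mean())
    ok = ~degenerate
    n = int(ok.sum())
    if n == 0:
        raise RuntimeError("all replicates degenerate: test never defined")
    rate = float(np.mean(p[ok] < alpha))
    se = float(np.sqrt(rate * (1.0 - rate) / n))
    return RejectionResult(
        rate=100.0 * rate,
        se=100.0 * se,
        n_tested=n,
        n_degenerate=int(degenerate.sum()),
        mean_R_used=mean_r,
        alpha=alpha,
    )


# (T, L) rows shared by the two type-I error tables
_TYPE1_ROWS = [(10, 2), (100, 20), (1000, 200), (10, 5), (100, 5), (1000, 5)]
# reference-locus counts paired with each demographic scenario in table 2
_TABLE2_R = {"model1": 5, "model2": 2, "model3": 20, "model4": 1, "model5": 10}


def _collect(cells, replicates, seed, alpha, null_draws, progress=None):
    rows = []
    for cell in cells:
        res = rejection_rate(cell, replicates, seed=seed, alpha=alpha,
                             null_draws=null_draws)
        row = asdict(cell) | {
            "rate": res.rate,
            "se": res.se,
            "n_tested": res.n_tested,
            "n_degenerate": res.n_degenerate,
            "mean_R_used": res.mean_R_used,
        }
        row["model"] = cell.model if isinstance(cell.model, str) else cell.model.kind
        rows.append(row)
        if progress is not None:
            progress(cell, res)
    return pd.DataFrame(rows)


def run_table(
    table: int,
    replicates: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    null_draws: int = 100_000,
    progress=None,
) -> pd.DataFrame:
    """Run every cell of one of the four built-in table grids.

    Returns a tidy DataFrame with one row per cell (parameters, rejection
    rate in percent, binomial SE, counts of tested and degenerate
    replicates, and the mean surviving reference count for FITR cells).
    """
    cells: list[ExperimentCell] = []
    if table == 1:
        for T, L in _TYPE1_ROWS:
            for m in ("model1", "model2", "model3", "model4", "model5"):
                cells.append(ExperimentCell("FIT", m, T, L))
    elif table == 2:
        for T, L in _TYPE1_ROWS:
            for m, R in _TABLE2_R.items():
                cells.append(ExperimentCell("FITR", m, T, L, R=R))
    elif table == 3:
        grid = [("model1p", 10, 2), ("model1p", 20, 5),
                ("model5p", 5, 1), ("model5p", 10, 5)]
        for m, T, L in grid:
            for s0 in (0.0, 0.05):
                for r in ("free", 0.1, 0.01, 0.0):
                    cells.append(ExperimentCell(
                        "FITR", m, T, L, R=10, s0=s0, method="binomial", r=r))
                cells.append(ExperimentCell(
                    "FITR", m, T, L, R=10, s0=s0, method="pseudo"))
    elif table == 4:
        for m, s_sel in (("model1", 0.002), ("model5", 0.0005)):
            for L in (2, 10):
                for x0_ref in (0.5, 0.1, 0.05, 0.01):
                    for s0 in (0.0, s_sel):
                        cells.append(ExperimentCell(
                            "FITR", m, 1000, L, R=10, s0=s0, x0_ref=x0_ref))
    else:
        raise ValueError(f"unknown table {table}; choose 1-4")
    return _collect(cells, replicates, seed, alpha, null_draws, progress)


def power_curve(
    cell: ExperimentCell,
    s_grid,
    replicates: int,
    seed: int = 0,
    alpha: float = 0.05,
    null_draws: int = 100_000,
) -> pd.DataFrame:
    """Rejection rate of `cell`'s test as a function of the focal selection
    coefficient, over `s_grid`.  The ``s = 0`` point is the type-I error."""
    from dataclasses import replace

    rows = []
    for s0 in s_grid:
        res = rejection_rate(replace(cell, s0=float(s0)), replicates,
                             seed=seed, alpha=alpha, null_draws=null_draws)
        rows.append({"s0": float(s0), "rate": res.rate, "se": res.se,
                     "n_tested": res.n_tested,
                     "n_degenerate": res.n_degenerate})
    return pd.DataFrame(rows)
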