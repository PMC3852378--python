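"""Wright-Fisher forward simulation of allele-frequency trajectories.

The population is diploid: ``N`` individuals carry ``2N`` gene copies, and
reproduction draws the next generation's allele count binomially from the
post-selection expected frequency.  Selection is genic (no dominance): with
selection coefficient ``s`` the three genotypes have fitnesses ``1``,
``1 + s/2`` and ``1 + s``, giving the deterministic update

    x' = x * (1 + 0.5 * s * (1 + x)) / (1 + s * x).

Two reproduction engines are provided.  ``binomial`` is the exact model;
``pseudo`` is the pseudo-sampling diffusion approximation, which replaces the
binomial draw by a normal draw with matched mean and variance at moderate
frequencies and by a Poisson draw of the minor-allele count when the expected
minor count is at most 5 copies.  Pseudo-sampling makes census sizes of
``10^6``-``10^8`` tractable; at small sizes it is moment-matched to the exact
binomial engine.

Loci are simulated independently under free recombination (the default); an
individual-based simulator with per-adjacent-pair recombination fraction ``r``
and linkage-equilibrium initialisation is available for linked loci.  Exact
0 and 1 are absorbing everywhere (no mutation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .demography import DemographicModel

__all__ = [
    "TrajectorySet",
    "SimulationConfig",
    "selection_update",
    "step_binomial",
    "step_pseudo",
    "simulate_batch",
    "simulate_replicate",
    "simulate_linked",
    "sample_individuals",
]

#: expected minor-allele copies at or below which the pseudo-sampling engine
#: switches from the normal to the Poisson branch
MINOR_COUNT_THRESHOLD = 5

#: refuse individual-based (linked) simulation above this census size
LINKED_N_GUARD = 100_000


@dataclass
class TrajectorySet:
    """Allele frequencies at ``R + 1`` loci observed at ``L + 1`` times.

    ``freqs[h, i]`` is the frequency of the tracked allele at locus ``h`` and
    sampling time ``times[i]``; locus 0 is the focal locus, loci ``1 .. R``
    are references.
    """

    times: np.ndarray
    freqs: np.ndarray
    s: np.ndarray | None = None
    model: DemographicModel | None = None
    seed: int | None = None
    locus_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.freqs = np.atleast_2d(np.asarray(self.freqs, dtype=float))
        if self.times.ndim != 1 or self.freqs.shape[1] != self.times.size:
            raise ValueError("freqs must be (n_loci, len(times))")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.freqs < 0) | (self.freqs > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if self.s is not None:
            self.s = np.broadcast_to(
                np.asarray(self.s, dtype=float), (self.n_loci,)
            ).copy()
        if self.locus_names is None:
            self.locus_names = tuple(f"locus_{h}" for h in range(self.n_loci))

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[0]

    @property
    def R(self) -> int:
        """Number of reference loci (loci beyond the focal one)."""
        return self.n_loci - 1

    @property
    def L(self) -> int:
        """Number of sampling intervals (one less than sampled times)."""
        return self.times.size - 1


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one simulated experiment of ``n_loci`` diallelic loci.

    ``x0`` and ``s`` broadcast across loci; locus 0 is focal.  ``sample_times``
    must start at 0 and end at or before ``model.T``.  ``recombination`` is
    ``"free"`` (independent loci) or a per-adjacent-pair crossover fraction in
    ``[0, 0.5]`` for the individual-based simulator.  ``sample_n`` adds
    binomial sampling noise of ``n`` diploid individuals per time point
    (``None`` records population frequencies exactly).
    """

    model: DemographicModel
    sample_times: tuple[int, ...]
    x0: float | tuple[float, ...] = 0.5
    s: float | tuple[float, ...] = 0.0
    n_loci: int = 1
    method: str = "pseudo"
    recombination: float | str = "free"
    sample_n: int | None = None
    replicates: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("binomial", "pseudo"):
            raise ValueError(f"unknown method {self.method!r}")
        times = np.asarray(self.sample_times)
        if times[0] != 0 or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing from 0")
        if times[-1] > self.model.T:
            raise ValueError("sample_times exceed the model duration")
        if self.recombination != "free":
            r = float(self.recombination)
            if not 0.0 <= r <= 0.5:
                raise ValueError("recombination fraction must be in [0, 0.5]")

    def x0_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.x0, float), (self.n_loci,)).copy()

    def s_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.s, float), (self.n_loci,)).copy()


def selection_update(x, s):
    """Deterministic post-selection expected frequency under genic selection.

    Accepts scalars or arrays (broadcasting).  Raises for pathological
    ``s < -1`` that would make the mean fitness non-positive.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    wbar = 1.0 + s * x
    if np.any(wbar <= 0):
        raise ValueError("mean fitness <= 0: selection coefficient below -1")
    out = x * (1.0 + 0.5 * s * (1.0 + x)) / wbar
    return np.clip(out, 0.0, 1.0)


def step_binomial(x, N_next, s, rng):
    """One exact Wright-Fisher generation: binomial(2 N_next, x') / (2 N_next)."""
    p = selection_update(x, s)
    two_n = 2 * int(N_next)
    k = rng.binomial(two_n, p)
    return k / two_n


def step_pseudo(x, N_next, s, rng, minor_count_threshold=MINOR_COUNT_THRESHOLD):
    """One generation by pseudo-sampling (normal / Poisson approximation).

    After the deterministic selection update to ``p'``, the next frequency is
    drawn from a normal with mean ``p'`` and variance ``p'(1-p')/(2N)``,
    clipped to ``[0, 1]`` — unless the expected minor-allele count
    ``2N * min(p', 1-p')`` is at most `minor_count_threshold`, in which case
    the minor-allele count is drawn from a Poisson with that mean (capped at
    ``2N``).  Exact 0 and 1 are absorbing.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    p = np.atleast_1d(selection_update(x, s))
    two_n = 2 * int(N_next)

    out = p.copy()
    absorbed = (x == 0.0) | (x == 1.0)
    minor = np.minimum(p, 1.0 - p)
    lam = two_n * minor
    pois = (~absorbed) & (lam <= minor_count_threshold)
    norm = (~absorbed) & (~pois)

    if np.any(pois):
        k = np.minimum(rng.poisson(lam[pois]), two_n)
        f = k / two_n
        out[pois] = np.where(p[pois] <= 0.5, f, 1.0 - f)
    if np.any(norm):
        pn = p[norm]
        sd = np.sqrt(pn * (1.0 - pn) / two_n)
        out[norm] = np.clip(rng.normal(pn, sd), 0.0, 1.0)
    out[absorbed] = x[absorbed]
    return out[0] if scalar else out


def _step(x, N_next, s, rng, method):
    if method == "binomial":
        # absorption is automatic (p' is exactly 0 or 1) but keep exact values
        return step_binomial(x, N_next, s, rng)
    return step_pseudo(x, N_next, s, rng)


def simulate_batch(config: SimulationConfig, n_rep: int, rng) -> np.ndarray:
    """Simulate `n_rep` independent replicates of independently evolving loci.

    Returns an array of shape ``(n_rep, n_loci, L + 1)`` with the population
    frequencies at ``config.sample_times``.  All replicates and loci advance
    in lock-step through one vectorised draw per generation, which is what
    makes Monte-Carlo calibration at ``10^4``-``10^5`` replicates cheap.
    """
    if config.recombination != "free":
        raise ValueError("simulate_batch requires free recombination; "
                         "use simulate_linked for linked loci")
    times = np.asarray(config.sample_times)
    sizes = config.model.sizes()
    sample_at = {int(t): i for i, t in enumerate(times)}

    x = np.broadcast_to(config.x0_array(), (n_rep, config.n_loci)).copy()
    s = config.s_array()
    out = np.empty((n_rep, config.n_loci, times.size))
    if 0 in sample_at:
        out[:, :, sample_at[0]] = x
    for t in range(1, int(times[-1]) + 1):
        x = _step(x, sizes[t], s, rng, config.method)
        if t in sample_at:
            out[:, :, sample_at[t]] = x
    if config.sample_n is not None:
        two_n = 2 * int(config.sample_n)
        out = rng.binomial(two_n, out) / two_n
    return out


def simulate_replicate(config: SimulationConfig, rng) -> TrajectorySet:
    """Simulate a single replicate under free recombination."""
    freqs = simulate_batch(config, 1, rng)[0]
    return TrajectorySet(
        times=np.asarray(config.sample_times),
        freqs=freqs,
        s=config.s_array(),
        model=config.model,
    )


def simulate(config: SimulationConfig) -> list[TrajectorySet]:
    """Simulate ``config.replicates`` trajectory sets from ``config.seed``.

    Replicate streams are spawned from a single seed sequence, so replicate
    ``j`` is reproducible from ``(seed, j)`` alone.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    sim = simulate_linked if config.recombination != "free" else simulate_replicate
    return [sim(config, np.random.default_rng(c)) for c in children]


def simulate_linked(config: SimulationConfig, rng) -> TrajectorySet:
    """Individual-based simulation of ``n_loci`` ordered linked loci.

    The population is kept as ``N(t)`` diploids, each a pair of haplotypes
    over the ordered loci.  At ``t = 0`` haplotypes are assembled by
    independent per-locus Bernoulli draws at the initial frequencies (linkage
    equilibrium).  Each offspring picks two parents with probability
    proportional to fitness (multiplicative across loci, genic within a
    locus); each parent transmits a gamete with crossovers between adjacent
    loci occurring independently with probability ``r``.  ``r = 0.5`` is free
    recombination and matches the independent-loci engine distributionally.
    """
    if config.method != "binomial":
        raise ValueError("linked simulation is individual-based (method='binomial')")
    r = 0.5 if config.recombination == "free" else float(config.recombination)
    sizes = config.model.sizes()
    if sizes.max() > LINKED_N_GUARD:
        raise ValueError(
            f"census size {sizes.max()} exceeds the individual-based guard "
            f"({LINKED_N_GUARD}); use recombination='free' with simulate_replicate"
        )
    times = np.asarray(config.sample_times)
    sample_at = {int(t): i for i, t in enumerate(times)}
    x0 = config.x0_array()
    s = config.s_array()
    n_loci = config.n_loci

    n = int(sizes[0])
    pop = (rng.random((n, 2, n_loci)) < x0).astype(np.int8)  # LE at t = 0
    out = np.empty((n_loci, times.size))
    if 0 in sample_at:
        out[:, sample_at[0]] = pop.mean(axis=(0, 1))

    idx = np.arange(n_loci)
    for t in range(1, int(times[-1]) + 1):
        n_next = int(sizes[t])
        g = pop.sum(axis=1)  # genotype allele counts, (n, n_loci)
        w = np.prod(1.0 + 0.5 * s * g, axis=1)
        parents = rng.choice(pop.shape[0], size=(n_next, 2), p=w / w.sum())
        gametes = np.empty((n_next, 2, n_loci), dtype=np.int8)
        for side in (0, 1):
            hp = pop[parents[:, side]]  # (n_next, 2, n_loci)
            start = rng.integers(0, 2, n_next)
            cross = rng.random((n_next, n_loci - 1)) < r
            strand = (start[:, None] + np.pad(np.cumsum(cross, axis=1),
                                              ((0, 0), (1, 0)))) % 2
            gametes[:, side] = hp[np.arange(n_next)[:, None], strand, idx]
        pop = gametes
        if t in sample_at:
            out[:, sample_at[t]] = pop.mean(axis=(0, 1))

    traj = TrajectorySet(times=times, freqs=out, s=s, model=config.model)
    if config.sample_n is not None:
        traj = sample_individuals(traj, config.sample_n, rng)
    return traj


def sample_individuals(traj: TrajectorySet, n, rng) -> TrajectorySet:
    """Binomial sampling noise of `n` diploids at every locus and time point.

    Each population frequency ``x`` is replaced by ``k / (2n)`` with
    ``k ~ Binomial(2n, x)``.  ``n in (None, "all")`` returns the input
    unchanged.
    """
    if n is None or n == "all":
        return traj
    two_n = 2 * int(n)
    freqs = rng.binomial(two_n, traj.freqs) / two_n
    return replace(traj, freqs=freqs)
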