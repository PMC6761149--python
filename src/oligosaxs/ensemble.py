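"""Flexible-conformer pools and genetic-algorithm sub-ensemble selection.

Disordered termini or loops make a single rigid model unable to fit the
data; instead a large pool of conformers with random-coil-like flexible
segments is generated and a small sub-ensemble whose mixed curve fits
the data is selected with a genetic algorithm (population of candidate
subsets, elitist selection, single-point crossover, member-swap
mutation), run over several independently seeded rounds with the best
round returned.

Flexible segments are grown as self-avoiding random walks with the
canonical Calpha-Calpha step of 3.8 A and a hard-sphere clash cutoff of
3.0 A to all previously placed sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConformerGenerationError
from .guinier import guinier_fit
from .mixture import Mixture
from .profiles import CoordinateModel, ScatteringProfile

__all__ = ["EnsembleResult", "generate_pool", "select_ensemble",
           "EnsembleSelector"]

CA_STEP = 3.8          # A, Calpha-Calpha virtual bond
CLASH_CUTOFF = 3.0     # A, hard-sphere self-avoidance
_STEP_RETRIES = 100    # directions tried per step before a segment restart
_SEGMENT_RESTARTS = 50


@dataclass(frozen=True)
class EnsembleResult:
    """Selected sub-ensemble and its mixture fit."""

    member_ids: tuple[int, ...]
    weights: np.ndarray
    chi: float
    rg_distribution: np.ndarray   # Rg of the selected members, A (nan if n/a)
    seed: int
    chi_history: np.ndarray = field(default=None, repr=False)

    def summary(self) -> str:
        rows = ", ".join(f"#{m}:{w:.3f}" for m, w in
                         zip(self.member_ids, self.weights))
        return (f"ensemble chi = {self.chi:.4g}  members [{rows}]  "
                f"Rg = {np.array2string(self.rg_distribution, precision=1)} A "
                f"(seed {self.seed})")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_segment(anchor: np.ndarray, n_res: int, occupied: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding walk of ``n_res`` sites starting 3.8 A from anchor."""
    for _ in range(_SEGMENT_RESTARTS):
        pts: list[np.ndarray] = []
        prev = anchor
        failed = False
        for _step in range(n_res):
            placed = False
            for _try in range(_STEP_RETRIES):
                cand = prev + CA_STEP * _random_unit(rng)
                blocked = occupied if not pts else np.vstack([occupied, pts])
                # the walk's own previous site sits exactly one bond away
                d = np.linalg.norm(blocked - cand, axis=1)
                d = d[d > 1e-9]
                if np.all(d >= CLASH_CUTOFF - 1e-9):
                    pts.append(cand)
                    prev = cand
                    placed = True
                    break
            if not placed:
                failed = True
                break
        if not failed:
            return np.asarray(pts)
    raise ConformerGenerationError(
        f"self-avoiding walk of {n_res} residues failed after "
        f"{_SEGMENT_RESTARTS} restarts")


def generate_pool(core: CoordinateModel,
                  flexible_segments: list[tuple[int, int]],
                  n_conformers: int, seed: int) -> list[CoordinateModel]:
    """Generate conformers: rigid core plus random-coil flexible segments.

    Each segment is specified as ``(attachment_site_index, residue_count)``
    and grown as a self-avoiding walk (3.8 A steps, 3.0 A clash cutoff to
    every previously placed site).  Deterministic for a fixed seed.
    """
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    n_core = len(core)
    for attach, n_res in flexible_segments:
        if not 0 <= attach < n_core:
            raise ValueError(f"attachment site {attach} not in core")
        if n_res < 1:
            raise ValueError("segment residue count must be >= 1")
    rng = np.random.default_rng(seed)
    pool = []
    for ic in range(n_conformers):
        sites = [core.positions]
        for attach, n_res in flexible_segments:
            occupied = np.vstack(sites)
            seg = _grow_segment(core.positions[attach], n_res, occupied, rng)
            sites.append(seg)
        pos = np.vstack(sites)
        n_extra = pos.shape[0] - n_core
        weights = np.concatenate([core.weights, np.ones(n_extra)])
        labels = core.site_labels + tuple(
            f"flex{k}" for k in range(n_extra))
        pool.append(CoordinateModel(positions=pos, weights=weights,
                                    site_labels=labels,
                                    label=f"{core.label}/conf{ic}"))
    return pool


class EnsembleSelector:
    """Genetic-algorithm selection of a fixed-size sub-ensemble.

    The fitness of a candidate subset is the chi of its non-negative
    mixture fit to the data.  Elitism makes the best-so-far chi
    non-increasing across generations; the initial population is seeded
    with the best single members so the final ensemble can never fit
    worse than the best individual curve.
    """

    def __init__(self, pool_curves: list[ScatteringProfile],
                 data: ScatteringProfile,
                 population: int = 50, mutation_rate: float = 0.1,
                 n_elite: int = 5):
        if not pool_curves:
            raise ValueError("pool must be non-empty")
        self.data = data
        self.pool = pool_curves
        self.population = population
        self.mutation_rate = mutation_rate
        self.n_elite = n_elite
        self._cache: dict[tuple[int, ...], tuple[float, np.ndarray]] = {}

    def _fitness(self, members: tuple[int, ...]) -> tuple[float, np.ndarray]:
        if members not in self._cache:
            res = Mixture(self.data, [self.pool[i] for i in members]).fit()
            self._cache[members] = (res.chi, res.fractions)
        return self._cache[members]

    def _offspring(self, a: tuple[int, ...], b: tuple[int, ...],
                   rng: np.random.Generator) -> tuple[int, ...]:
        k = len(a)
        if k == 1:
            child = list(a if rng.random() < 0.5 else b)
        else:
            cut = int(rng.integers(1, k))
            child = list(a[:cut]) + [m for m in b if m not in a[:cut]]
            child = child[:k]
            while len(child) < k:  # repair duplicates
                m = int(rng.integers(len(self.pool)))
                if m not in child:
                    child.append(m)
        for g in range(k):  # member-swap mutation
            if rng.random() < self.mutation_rate:
                m = int(rng.integers(len(self.pool)))
                if m not in child:
                    child[g] = m
        return tuple(sorted(child))

    def run_round(self, ensemble_size: int, n_generations: int,
                  seed: int) -> tuple[tuple[int, ...], float, np.ndarray]:
        rng = np.random.default_rng(seed)
        npool = len(self.pool)
        pop: list[tuple[int, ...]] = []
        # seed one individual with the best single members
        singles = sorted(range(npool), key=lambda i: self._fitness((i,))[0])
        pop.append(tuple(sorted(singles[:ensemble_size])))
        while len(pop) < self.population:
            pop.append(tuple(sorted(
                rng.choice(npool, size=ensemble_size, replace=False).tolist())))
        history = []
        for _gen in range(n_generations):
            pop.sort(key=lambda m: self._fitness(m)[0])
            history.append(self._fitness(pop[0])[0])
            elite = pop[:self.n_elite]
            parents = pop[:max(len(pop) // 2, 2)]
            children = []
            while len(children) < self.population - len(elite):
                ia, ib = rng.integers(len(parents), size=2)
                children.append(self._offspring(parents[ia], parents[ib], rng))
            pop = elite + children
        pop.sort(key=lambda m: self._fitness(m)[0])
        best = pop[0]
        chi, fr = self._fitness(best)
        history.append(chi)
        return best, chi, np.asarray(history)

    def fit(self, ensemble_size: int, n_generations: int = 200,
            n_rounds: int = 3, seed: int = 0) -> EnsembleResult:
        if ensemble_size > len(self.pool):
            raise ValueError("ensemble_size exceeds pool size")
        if ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        best = None
        for r in range(n_rounds):
            members, chi, hist = self.run_round(
                ensemble_size, n_generations, seed=seed + 7919 * r)
            if best is None or chi < best[1]:
                best = (members, chi, hist)
        members, chi, hist = best
        _, fractions = self._fitness(members)
        rgs = []
        for m in members:
            try:
                rgs.append(guinier_fit(self.pool[m]).Rg)
            except Exception:
                rgs.append(np.nan)
        return EnsembleResult(member_ids=members, weights=fractions,
                              chi=chi, rg_distribution=np.asarray(rgs),
                              seed=seed, chi_history=hist)


def select_ensemble(pool_curves: list[ScatteringProfile],
                    data: ScatteringProfile, ensemble_size: int,
                    n_generations: int = 200, n_rounds: int = 3,
                    seed: int = 0, population: int = 50,
                    mutation_rate: float = 0.1) -> EnsembleResult:
    """Functional wrapper around :class:`EnsembleSelector`."""
    sel = EnsembleSelector(pool_curves, data, population=population,
                           mutation_rate=mutation_rate)
    return sel.fit(ensemble_size, n_generations=n_generations,
                   n_rounds=n_rounds, seed=seed)
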