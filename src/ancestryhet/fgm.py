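"""Fisher geometric model: adaptive walk, F2 hybrids and trait mismatch.

A monomorphic population with phenotype z (a vector of m traits) adapts
toward an optimum o under Gaussian fitness w = exp(-sigma * ||z - o||^2).
Mutations arise one at a time with additive effect vectors drawn from
N(0, alpha^2) per trait and fix with the diffusion probability
pi = (1 - exp(-2*N*s*p)) / (1 - exp(-2*N*s)) given their selection
coefficient s = w_mut/w_wt - 1 (origin-fixation regime: no standing
variation, free recombination, unique loci).

After the walk, F2 hybrids between the derived population and the
unchanged ancestor inherit ancestral-homozygous / heterozygous /
derived-homozygous genotypes at each fixed locus with probabilities
0.25 : 0.5 : 0.25.  A hybrid's "mismatch" is the perpendicular distance
of its phenotype from the line connecting the two parent phenotypes;
more heterozygous hybrids sit closer to that axis, which is the
mechanistic link between ancestry heterozygosity and ecological hybrid
incompatibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SimulationError, ValidationError

DEFAULT_ALPHA = 0.15
DEFAULT_SIGMA = 10.0
DEFAULT_POP_SIZE = 1000


@dataclass(frozen=True)
class FgmConfig:
    """Parameters of the adaptive walk and hybrid cohort.

    ``m`` traits; mutation effect sd ``alpha``; selection strength
    ``sigma``; population size ``n_pop`` (initial mutant frequency
    ``p0 = 1/n_pop`` unless given); ``n_mutations`` proposals;
    ``n_hybrids`` F2s.  The ancestor sits at the origin; the optimum
    defaults to [1, 1] for m = 2 and to 1 on the first trait (0
    elsewhere) for m > 2, mirroring a single selected trait among
    otherwise stabilized traits.
    """

    m: int = 2
    alpha: float = DEFAULT_ALPHA
    sigma: float = DEFAULT_SIGMA
    n_pop: int = DEFAULT_POP_SIZE
    n_mutations: int = 1000
    n_hybrids: int = 500
    p0: float | None = None
    z0: tuple[float, ...] | None = None
    z_opt: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or self.alpha <= 0 or self.sigma < 0 or self.n_pop < 2:
            raise ValidationError("invalid FGM configuration")
        if self.n_hybrids < 1 or self.n_mutations < 1:
            raise ValidationError("invalid FGM configuration")

    def ancestral_phenotype(self) -> np.ndarray:
        z0 = np.zeros(self.m) if self.z0 is None else np.asarray(self.z0, float)
        if z0.shape != (self.m,):
            raise ValidationError("z0 length must equal m")
        return z0

    def optimum(self) -> np.ndarray:
        if self.z_opt is not None:
            o = np.asarray(self.z_opt, float)
            if o.shape != (self.m,):
                raise ValidationError("z_opt length must equal m")
            return o
        if self.m == 2:
            return np.ones(2)
        o = np.zeros(self.m)
        o[0] = 1.0
        return o

    @property
    def initial_frequency(self) -> float:
        return self.p0 if self.p0 is not None else 1.0 / self.n_pop


def fitness(z: np.ndarray, o: np.ndarray, sigma: float) -> float | np.ndarray:
    """Gaussian fitness w = exp(-sigma * ||z - o||^2); 1 at the optimum."""
    z = np.asarray(z, float)
    o = np.asarray(o, float)
    if z.shape[-1] != o.shape[-1]:
        raise ValidationError("phenotype and optimum have different lengths")
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    d2 = np.sum((z - o) ** 2, axis=-1)
    return np.exp(-sigma * d2)


_NEUTRAL_TOL = 1e-8


def fixation_probability(n_pop: int, s: float, p: float) -> float:
    """Diffusion fixation probability of a mutation at frequency p.

    pi = (1 - exp(-2*N*s*p)) / (1 - exp(-2*N*s)); the s -> 0 limit is p.
    Evaluated in a numerically stable form (no overflow for strongly
    deleterious s) and clamped to [0, 1].
    """
    if n_pop < 2:
        raise ValidationError("n_pop must be >= 2")
    if not 0.0 < p <= 1.0:
        raise ValidationError("p must be in (0, 1]")
    a = 2.0 * n_pop * s * p
    b = 2.0 * n_pop * s
    if abs(b) < _NEUTRAL_TOL:
        return p
    if b > 0 or -b <= 500:
        pi = np.expm1(-a) / np.expm1(-b)
    else:
        # strongly deleterious: factor out exp(-a+b) to avoid overflow in expm1
        pi = np.exp(-a + b) * np.expm1(a) / np.expm1(b)
    return float(min(1.0, max(0.0, pi)))


@dataclass
class AdaptiveWalk:
    """Record of an origin-fixation adaptive walk."""

    effects: np.ndarray          # (n_fixed, m) accepted mutation vectors, in order
    proposals: pd.DataFrame      # per proposal: s, pi, accepted
    z_ancestor: np.ndarray
    z_parent: np.ndarray
    config: FgmConfig

    @property
    def n_fixed(self) -> int:
        return self.effects.shape[0]


def adaptive_walk(
    config: FgmConfig, rng: np.random.Generator | None = None
) -> AdaptiveWalk:
    """Run the origin-fixation walk toward the optimum.

    Each of ``n_mutations`` proposals has iid N(0, alpha^2) effects per
    trait; the selection coefficient is the fitness ratio minus one, and
    the proposal fixes with its diffusion fixation probability.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z = config.ancestral_phenotype().copy()
    z_a = z.copy()
    o = config.optimum()
    effects = []
    recs = []
    for _ in range(config.n_mutations):
        delta = rng.normal(0.0, config.alpha, size=config.m)
        w_wt = fitness(z, o, config.sigma)
        w_mut = fitness(z + delta, o, config.sigma)
        s = w_mut / w_wt - 1.0
        pi = fixation_probability(config.n_pop, s, config.initial_frequency)
        accepted = rng.random() < pi
        if accepted:
            z = z + delta
            effects.append(delta)
        recs.append((s, pi, accepted))
    proposals = pd.DataFrame(recs, columns=["s", "pi", "accepted"])
    eff = np.array(effects).reshape(len(effects), config.m)
    return AdaptiveWalk(eff, proposals, z_a, z, config)


@dataclass
class HybridCohort:
    """Simulated F2 hybrids between the derived and ancestral parents."""

    dosage: np.ndarray        # (n_hybrids, n_loci) derived-allele counts in {0,1,2}
    phenotype: np.ndarray     # (n_hybrids, m)
    hybrid_index: np.ndarray
    heterozygosity: np.ndarray
    excess_het: np.ndarray
    mismatch: np.ndarray
    walk: AdaptiveWalk

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "hybrid_index": self.hybrid_index,
                "heterozygosity": self.heterozygosity,
                "excess_het": self.excess_het,
                "mismatch": self.mismatch,
            }
        )
        for j in range(self.phenotype.shape[1]):
            df[f"z{j + 1}"] = self.phenotype[:, j]
        return df


def perpendicular_distance(
    z: np.ndarray, z_a: np.ndarray, z_p: np.ndarray
) -> np.ndarray:
    """Distance from point(s) z to the infinite line through z_a and z_p."""
    z = np.atleast_2d(np.asarray(z, float))
    v = np.asarray(z_p, float) - np.asarray(z_a, float)
    norm2 = float(v @ v)
    if norm2 == 0.0:
        raise SimulationError("parent phenotypes coincide; mismatch axis undefined")
    u = z - z_a
    # residual of the orthogonal projection, computed componentwise to
    # avoid the catastrophic cancellation of ||u||^2 - proj^2 on-axis
    vhat = v / np.sqrt(norm2)
    resid = u - np.outer(u @ vhat, vhat)
    return np.sqrt(np.sum(resid * resid, axis=1))


def mismatch(z: np.ndarray, walk: AdaptiveWalk, mode: str = "perpendicular") -> np.ndarray:
    """Trait mismatch of phenotype(s) ``z`` relative to the parents.

    ``perpendicular``: shortest distance to the line connecting the
    realized parent phenotypes.  ``nonselected_distance`` (m > 2 only):
    Euclidean norm over the non-selected trait components (2..m), i.e.
    distance from the shared optimum of the stabilized traits.
    """
    z = np.atleast_2d(np.asarray(z, float))
    if mode == "perpendicular":
        return perpendicular_distance(z, walk.z_ancestor, walk.z_parent)
    if mode == "nonselected_distance":
        if walk.config.m <= 2:
            raise ValidationError("nonselected_distance requires m > 2")
        return np.sqrt(np.sum(z[:, 1:] ** 2, axis=1))
    raise ValidationError(f"unknown mismatch mode {mode!r}")


def make_f2_cohort(
    walk: AdaptiveWalk,
    n_hybrids: int | None = None,
    seed: int | np.random.Generator | None = None,
    mode: str = "perpendicular",
) -> HybridCohort:
    """Draw an F2 cohort over the walk's fixed loci.

    Dosages are iid per locus with probabilities 0.25/0.5/0.25 (free
    recombination); phenotypes are additive: z = z_A + sum_i dosage_i/2
    * effect_i.
    """
    if walk.n_fixed == 0:
        raise SimulationError("adaptive walk fixed no mutations; no loci to segregate")
    n = walk.config.n_hybrids if n_hybrids is None else n_hybrids
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = walk.n_fixed
    dosage = rng.choice([0, 1, 2], size=(n, L), p=[0.25, 0.5, 0.25])
    phenotype = walk.z_ancestor + (dosage / 2.0) @ walk.effects
    h = dosage.sum(axis=1) / (2.0 * L)
    het = (dosage == 1).mean(axis=1)
    excess = het - 2.0 * h * (1.0 - h)
    mm = mismatch(phenotype, walk, mode=mode)
    return HybridCohort(dosage, phenotype, h, het, excess, mm, walk)


def simulate_hybridization(
    config: FgmConfig, mode: str = "perpendicular"
) -> HybridCohort:
    """One full simulation run: adaptive walk, then its F2 cohort.

    A single random stream seeded by ``config.seed`` drives both stages,
    so one integer reproduces the whole run.
    """
    rng = np.random.default_rng(config.seed)
    walk = adaptive_walk(config, rng=rng)
    return make_f2_cohort(walk, seed=rng, mode=mode)


def cohort_relation(cohort: HybridCohort) -> tuple[float, float, int]:
    """Spearman correlation between excess heterozygosity and mismatch.

    Under the model, more heterozygous hybrids lie nearer the
    inter-parent axis, so the correlation is expected negative.
    """
    n = len(cohort.mismatch)
    if n < 3:
        raise ValidationError("need at least 3 hybrids")
    if np.ptp(cohort.mismatch) == 0 or np.ptp(cohort.excess_het) == 0:
        raise SimulationError("degenerate cohort: constant mismatch or heterozygosity")
    rho, p = stats.spearmanr(cohort.excess_het, cohort.mismatch)
    return float(rho), float(p), n
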