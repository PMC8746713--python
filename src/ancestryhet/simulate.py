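"""Synthetic pedigreed-cross genotype bundles.

Generates long-format genotype tables with the statistical structure of
a multi-study hybrid-cross compilation: several datasets per environment
(lab aquaria vs field ponds), two cross types (benthic x limnetic and
marine x freshwater), microsatellite / SNP-array / GBS genotyping
platforms, F2 and optionally F3 generations, platform-specific
missingness and per-call sequencing depth, and optional viability
selection in pond datasets that elevates ancestry heterozygosity among
survivors.

Ancestry segregates neutrally 1:2:1 per diagnostic marker (markers are
unlinked by default: the heterozygosity statistics and their null
expectations do not depend on linkage).  All randomness is reproducible
from the bundle seed plus structural indices, so any family or dataset
can be regenerated in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import AncestryMatrix, CrossGenotypes, GENOTYPE_COLUMNS
from .errors import SimulationError, ValidationError
from .fgm import DEFAULT_ALPHA, perpendicular_distance

logger = logging.getLogger(__name__)

PLATFORMS = ("microsatellite", "snp_array", "gbs")
ARCHITECTURES = ("heterozygote_advantage", "pairwise_dmi", "fgm_mismatch")

# stream codes for per-purpose random generators
_S_MARKERS, _S_TRUTH, _S_NOISE, _S_SELECT, _S_F3, _S_LENGTH = 901, 1, 2, 3, 4, 5

_NUCLEOTIDES = np.array(["A", "C", "G", "T"])


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


@dataclass(frozen=True)
class SelectionSpec:
    """Viability-selection architecture applied to recombinant cohorts.

    ``heterozygote_advantage``: fitness (1-s)^(# ancestry-homozygous loci
    among the first ``k_loci`` markers; ``k_loci=None`` selects on all).
    ``pairwise_dmi``: fitness (1-s)^(# of ``k_pairs`` designated marker
    pairs homozygous for opposite ancestries).
    ``fgm_mismatch``: each marker gets a random additive effect vector
    over ``m_traits`` traits; fitness exp(-sigma_scale * d_perp^2) where
    d_perp is the phenotype's perpendicular distance from the
    inter-parent axis.  More traits mean more mismatch dimensions: with
    very few traits the attainable excess heterozygosity saturates near
    1% no matter how strong the penalty, because a single orthogonal
    direction can be zeroed by balanced homozygous ancestry.

    Survival probability is fitness rescaled by the cohort maximum, which
    leaves the survivor distribution (proportional to fitness) unchanged
    while keeping yields workable.
    """

    architecture: str
    s: float = 0.0
    k_loci: int | None = None
    k_pairs: int = 1
    sigma_scale: float = 1.0
    m_traits: int = 20
    target_environment: str = "pond"

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValidationError(f"unknown selection architecture {self.architecture!r}")
        if self.s < 0 or self.sigma_scale < 0:
            raise ValidationError("selection strength must be >= 0")
        if self.k_loci is not None and self.k_loci < 1:
            raise ValidationError("k_loci must be >= 1")
        if self.k_pairs < 1:
            raise ValidationError("k_pairs must be >= 1")
        if self.m_traits < 2:
            raise ValidationError("m_traits must be >= 2")
        if self.target_environment not in ("pond", "lab", "both"):
            raise ValidationError("target_environment must be pond, lab or both")

    def targets(self, environment: str) -> bool:
        return self.target_environment in (environment, "both")

    @property
    def strength(self) -> float:
        return self.sigma_scale if self.architecture == "fgm_mismatch" else self.s

    def with_strength(self, value: float) -> "SelectionSpec":
        if self.architecture == "fgm_mismatch":
            return replace(self, sigma_scale=value)
        return replace(self, s=value)


@dataclass(frozen=True)
class DatasetSpec:
    """Structure of one simulated dataset (one study/pond/aquarium)."""

    dataset_id: str
    environment: str                  # lab | pond
    cross_type: str = "BxL"           # BxL | MxF
    lake: str | None = "Paxton"       # Paxton | Priest for BxL; None for MxF
    platform: str = "snp_array"
    n_families: int = 1
    n_f1_per_family: int = 2
    n_f2_per_family: int = 100
    n_f3_per_family: int = 0
    n_markers: int = 60

    def __post_init__(self) -> None:
        if self.environment not in ("lab", "pond"):
            raise ValidationError(f"unknown environment {self.environment!r}")
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.cross_type not in ("BxL", "MxF"):
            raise ValidationError(f"unknown cross type {self.cross_type!r}")
        if min(self.n_families, self.n_f1_per_family, self.n_f2_per_family,
               self.n_markers) < 1 or self.n_f3_per_family < 0:
            raise ValidationError("dataset counts must be >= 1 (n_f3 >= 0)")


@dataclass(frozen=True)
class SimBundleConfig:
    """Full recipe for a simulated multi-dataset bundle.

    ``sex_chromosome='auto'`` labels chromosome 19 as the sex chromosome
    when at least 19 chromosomes exist, otherwise the last chromosome
    (none for single-chromosome toys).  GBS depth is negative-binomial
    with mean ``coverage_mean`` and shape ``coverage_shape``; calls at
    depth <= 20 are masked downstream by the coverage filter.
    """

    datasets: tuple[DatasetSpec, ...]
    n_chromosomes: int = 20
    sex_chromosome: str | None = "auto"
    missing_rate: float = 0.02
    error_rate: float = 0.0
    coverage_mean: float = 60.0
    coverage_shape: float = 3.0
    selection: SelectionSpec | None = None
    linkage: str = "none"             # none | chromosome (shared dosage per chromosome)
    simulate_length: bool = True
    selection_max_oversample: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValidationError("bundle needs at least one dataset")
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate dataset ids")
        if self.n_chromosomes < 1:
            raise ValidationError("n_chromosomes must be >= 1")
        for p in (self.missing_rate, self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.linkage not in ("none", "chromosome"):
            raise ValidationError("linkage must be 'none' or 'chromosome'")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")

    @property
    def chromosome_labels(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def sex_chromosome_label(self) -> str | None:
        if self.sex_chromosome != "auto":
            return self.sex_chromosome
        if self.n_chromosomes >= 19:
            return "19"
        if self.n_chromosomes >= 2:
            return str(self.n_chromosomes)
        return None

    @classmethod
    def from_counts(
        cls,
        n_datasets_lab: int,
        n_datasets_pond: int,
        cross_type: str = "BxL",
        lake: str = "Paxton",
        n_families: int = 1,
        f2_per_family: int = 100,
        n_markers: int = 60,
        lab_platform: str = "microsatellite",
        pond_platform: str = "snp_array",
        **kwargs,
    ) -> "SimBundleConfig":
        """Bundle of structurally identical lab and pond datasets."""
        specs = []
        for i in range(n_datasets_lab):
            specs.append(DatasetSpec(
                dataset_id=f"lab{i + 1}", environment="lab", cross_type=cross_type,
                lake=lake if cross_type == "BxL" else None, platform=lab_platform,
                n_families=n_families, n_f2_per_family=f2_per_family,
                n_markers=n_markers,
            ))
        for i in range(n_datasets_pond):
            specs.append(DatasetSpec(
                dataset_id=f"pond{i + 1}", environment="pond", cross_type=cross_type,
                lake=lake if cross_type == "BxL" else None, platform=pond_platform,
                n_families=n_families, n_f2_per_family=f2_per_family,
                n_markers=n_markers,
            ))
        return cls(datasets=tuple(specs), **kwargs)


def study_bundle_config(seed: int = 0, scale: float = 1.0, **kwargs) -> SimBundleConfig:
    """Config emulating the empirical compilation of nine datasets.

    Two cross types (benthic x limnetic from two lakes; marine x
    freshwater), three lab aquarium datasets genotyped at microsatellites
    and six pond datasets on SNP arrays or GBS, with fish counts of
    86-723 per dataset and marker counts of ~23-183.  ``scale``
    multiplies per-family fish counts for quicker runs.
    """

    def n(x: int) -> int:
        return max(2, round(x * scale))

    specs = (
        DatasetSpec("bxl_priest_lab", "lab", "BxL", "Priest", "microsatellite",
                    n_families=1, n_f2_per_family=n(90), n_markers=23),
        DatasetSpec("bxl_priest_pond", "pond", "BxL", "Priest", "snp_array",
                    n_families=1, n_f2_per_family=n(412), n_markers=89),
        DatasetSpec("bxl_paxton_lab", "lab", "BxL", "Paxton", "microsatellite",
                    n_families=1, n_f2_per_family=n(89), n_markers=97),
        DatasetSpec("bxl_paxton_pond_a", "pond", "BxL", "Paxton", "snp_array",
                    n_families=4, n_f2_per_family=n(154), n_markers=63),
        DatasetSpec("bxl_paxton_pond_b", "pond", "BxL", "Paxton", "snp_array",
                    n_families=1, n_f2_per_family=n(636), n_markers=62),
        DatasetSpec("bxl_paxton_pond_c", "pond", "BxL", "Paxton", "snp_array",
                    n_families=2, n_f2_per_family=n(151), n_markers=183),
        DatasetSpec("bxl_paxton_pond_gbs", "pond", "BxL", "Paxton", "gbs",
                    n_families=4, n_f2_per_family=n(81), n_f3_per_family=n(81),
                    n_markers=120),
        DatasetSpec("mxf_lab", "lab", "MxF", None, "microsatellite",
                    n_families=4, n_f2_per_family=n(94), n_markers=59),
        DatasetSpec("mxf_pond", "pond", "MxF", None, "snp_array",
                    n_families=6, n_f2_per_family=n(37), n_f3_per_family=n(83),
                    n_markers=120),
    )
    return SimBundleConfig(datasets=specs, seed=seed, **kwargs)


# ----------------------------------------------------------------------
# marker panels and allele pools


def _dataset_markers(config: SimBundleConfig, dataset_index: int):
    """Marker table and per-side allele pools for one dataset.

    Markers are assigned round-robin to chromosomes.  Microsatellite
    pools are two fragment-size-like integer tokens per side; SNP/GBS
    pools are single nucleotides, distinct between sides.
    """
    spec = config.datasets[dataset_index]
    rng = _rng(config.seed, dataset_index, _S_MARKERS)
    chroms = config.chromosome_labels
    ids, chrom_col, pools_a, pools_b = [], [], [], []
    for i in range(spec.n_markers):
        ids.append(f"{spec.dataset_id}_m{i + 1:04d}")
        chrom_col.append(chroms[i % len(chroms)])
        if spec.platform == "microsatellite":
            a = 100 + 2 * rng.integers(0, 20, size=2)
            b = 200 + 2 * rng.integers(0, 20, size=2)
            pools_a.append(tuple(str(x) for x in sorted(set(a))))
            pools_b.append(tuple(str(x) for x in sorted(set(b))))
        else:
            ref, alt = rng.choice(4, size=2, replace=False)
            pools_a.append((_NUCLEOTIDES[ref],))
            pools_b.append((_NUCLEOTIDES[alt],))
    markers = pd.DataFrame({"marker_id": ids, "chromosome": chrom_col}).set_index("marker_id")
    return markers, pools_a, pools_b


def _segregate(rng: np.random.Generator, n: int, markers: pd.DataFrame,
               linkage: str) -> np.ndarray:
    """Neutral F2 ancestry dosages, 1:2:1 per marker."""
    L = len(markers)
    if linkage == "chromosome":
        chroms = markers["chromosome"].to_numpy()
        labels, inverse = np.unique(chroms, return_inverse=True)
        per_chrom = rng.choice([0, 1, 2], size=(n, len(labels)), p=[0.25, 0.5, 0.25])
        return per_chrom[:, inverse]
    return rng.choice([0, 1, 2], size=(n, L), p=[0.25, 0.5, 0.25])


def _materialize_matrix(rng, dosage, pools_a, pools_b):
    """Turn an (n, L) dosage matrix into two (n, L) allele-token arrays.

    Dosage 0 draws both alleles from the side-A pool, 2 from side B, 1
    one from each (A first).  Token choice within a pool is uniform.
    """
    n, L = dosage.shape
    a1 = np.empty((n, L), dtype=object)
    a2 = np.empty((n, L), dtype=object)
    for j in range(L):
        pa = np.asarray(pools_a[j], dtype=object)
        pb = np.asarray(pools_b[j], dtype=object)
        d = dosage[:, j]
        ta1 = pa[rng.integers(len(pa), size=n)]
        ta2 = pa[rng.integers(len(pa), size=n)]
        tb1 = pb[rng.integers(len(pb), size=n)]
        tb2 = pb[rng.integers(len(pb), size=n)]
        a1[:, j] = np.where(d == 2, tb1, ta1)
        a2[:, j] = np.where(d == 0, ta2, tb2)
    return a1, a2


# ----------------------------------------------------------------------
# viability selection


def _selection_fitness(
    dosage: np.ndarray, spec: SelectionSpec, seed_key: tuple[int, ...]
) -> np.ndarray:
    """Fitness of each row of a dosage matrix under the architecture."""
    n, L = dosage.shape
    if spec.architecture == "heterozygote_advantage":
        k = L if spec.k_loci is None else spec.k_loci
        if k > L:
            raise SimulationError(f"k_loci={k} exceeds available loci ({L})")
        sel = dosage[:, :k]
        n_hom = np.nansum((sel == 0) | (sel == 2), axis=1)
        return (1.0 - spec.s) ** n_hom
    if spec.architecture == "pairwise_dmi":
        if 2 * spec.k_pairs > L:
            raise SimulationError(f"k_pairs={spec.k_pairs} needs {2 * spec.k_pairs} loci; have {L}")
        left = dosage[:, 0:2 * spec.k_pairs:2]
        right = dosage[:, 1:2 * spec.k_pairs:2]
        opposite = ((left == 0) & (right == 2)) | ((left == 2) & (right == 0))
        return (1.0 - spec.s) ** np.nansum(opposite, axis=1)
    # fgm_mismatch: per-marker additive multi-trait effects, penalty on
    # the perpendicular deviation of the additive phenotype from the
    # inter-parent axis
    rng = _rng(*seed_key, 7)
    effects = rng.normal(0.0, DEFAULT_ALPHA, size=(L, spec.m_traits))
    filled = np.where(np.isnan(dosage), 1.0, dosage)
    phenotype = (filled / 2.0) @ effects
    z_a = np.zeros(spec.m_traits)
    z_p = effects.sum(axis=0)
    d_perp = perpendicular_distance(phenotype, z_a, z_p)
    return np.exp(-spec.sigma_scale * d_perp**2)


def apply_viability_selection(
    matrix: AncestryMatrix, spec: SelectionSpec, seed: int
) -> AncestryMatrix:
    """Subset a cohort to viability-selection survivors.

    Recombinant individuals survive with probability fitness / max
    fitness (survivor genotypes are untouched; only membership changes).
    Founder and F1 rows always survive.  With zero selection strength
    the input is returned unchanged.
    """
    if matrix.dosage.size == 0:
        raise ValidationError("empty matrix")
    if spec.strength == 0.0:
        return matrix
    recomb = matrix.recombinant_mask.to_numpy()
    d = matrix.dosage.to_numpy(dtype=float)[recomb]
    w = _selection_fitness(d, spec, (seed,))
    w_max = w.max()
    if w_max <= 0:
        raise SimulationError("all fitness values are zero; selection too strong")
    rng = _rng(seed, _S_SELECT)
    survive_rec = rng.random(len(w)) < (w / w_max)
    keep = np.ones(len(recomb), dtype=bool)
    keep[recomb] = survive_rec
    return matrix.subset(matrix.dosage.index[keep])


def _select_dosages(
    dosage: np.ndarray, spec: SelectionSpec, rng: np.random.Generator, seed_key
) -> np.ndarray:
    """Boolean survivor mask for a raw dosage block (internal fast path)."""
    if spec.strength == 0.0:
        return np.ones(dosage.shape[0], dtype=bool)
    w = _selection_fitness(dosage, spec, seed_key)
    w_max = w.max()
    if w_max <= 0:
        raise SimulationError("all fitness values are zero; selection too strong")
    return rng.random(len(w)) < (w / w_max)


# ----------------------------------------------------------------------
# genotyping error


def inject_genotyping_error(
    cross: CrossGenotypes, e: float, seed: int
) -> CrossGenotypes:
    """Convert ancestry-homozygous recombinant calls to heterozygotes.

    The conservative error model: each non-missing F2/F3 call whose two
    alleles both belong to one founder side is independently replaced by
    a cross-side heterozygous call with probability ``e``.  Heterozygous,
    missing, founder and F1 calls are untouched.
    """
    if not 0.0 <= e <= 1.0:
        raise ValidationError("error rate must lie in [0, 1]")
    if e == 0.0:
        return cross
    df = cross.data.copy()
    founders = df[df["generation"].isin(("F0A", "F0B")) & df["allele_1"].notna()]
    side_of: dict[tuple[str, str], dict[str, int]] = {}
    rep: dict[tuple[str, str], list[str | None]] = {}
    for (ds, marker), sub in founders.groupby(["dataset_id", "marker_id"], sort=False):
        gen = sub["generation"]
        a = set(sub.loc[gen == "F0A", "allele_1"]) | set(sub.loc[gen == "F0A", "allele_2"])
        b = set(sub.loc[gen == "F0B", "allele_1"]) | set(sub.loc[gen == "F0B", "allele_2"])
        if not a or not b or (a & b):
            continue  # sides not defined/diagnostic: leave calls alone
        side_of[(ds, marker)] = {**{t: 0 for t in a}, **{t: 1 for t in b}}
        rep[(ds, marker)] = [sorted(a)[0], sorted(b)[0]]

    rng = _rng(seed, _S_NOISE)
    recomb = df["generation"].isin(("F2", "F3")).to_numpy()
    called = df["allele_1"].notna().to_numpy()
    keys = list(zip(df["dataset_id"], df["marker_id"]))
    a1 = df["allele_1"].to_numpy(object)
    a2 = df["allele_2"].to_numpy(object)
    flip = rng.random(len(df)) < e
    for i in np.nonzero(recomb & called & flip)[0]:
        mapping = side_of.get(keys[i])
        if mapping is None:
            continue
        s1, s2 = mapping.get(a1[i]), mapping.get(a2[i])
        if s1 is None or s2 is None or s1 != s2:
            continue  # unknown token or already heterozygous
        a2[i] = rep[keys[i]][1 - s1]
    df["allele_1"] = a1
    df["allele_2"] = a2
    return CrossGenotypes(df)


# ----------------------------------------------------------------------
# family and bundle generation


def _f3_dosages(rng, parent_dosage: np.ndarray, n_f3: int) -> np.ndarray:
    """F3 dosages by random union of gametes from distinct F2 parents."""
    n_par, L = parent_dosage.shape
    if n_par < 2:
        raise SimulationError("need at least 2 surviving F2s to produce F3s")
    dams = rng.integers(n_par, size=n_f3)
    sires = (dams + 1 + rng.integers(n_par - 1, size=n_f3)) % n_par
    g1 = rng.random((n_f3, L)) < (parent_dosage[dams] / 2.0)
    g2 = rng.random((n_f3, L)) < (parent_dosage[sires] / 2.0)
    return (g1.astype(int) + g2.astype(int))


def _family_pedigree_rows(config, dataset_index, family_index, markers,
                          pools_a, pools_b):
    """F0 and F1 ids, generations and dosage rows for one family."""
    spec = config.datasets[dataset_index]
    fam = f"{spec.dataset_id}_f{family_index + 1}"
    L = len(markers)
    ids = [f"{fam}_F0A", f"{fam}_F0B"]
    gens = ["F0A", "F0B"]
    dosage = [np.zeros(L, int), np.full(L, 2)]
    for i in range(spec.n_f1_per_family):
        ids.append(f"{fam}_F1_{i + 1}")
        gens.append("F1")
        dosage.append(np.ones(L, int))
    return fam, ids, gens, np.array(dosage)


def _assemble_dataset(config, dataset_index, markers, pools_a, pools_b,
                      ped_ids, ped_gens, ped_fams, ped_dosage,
                      recomb_ids, recomb_gen, recomb_fam,
                      recomb_dosage, noise_key) -> CrossGenotypes:
    """Materialize calls, apply missingness/error/coverage, and emit the
    long-format table for one dataset."""
    spec = config.datasets[dataset_index]
    rng = _rng(*noise_key)
    L = len(markers)
    marker_ids = markers.index.to_numpy()
    chroms = markers["chromosome"].to_numpy()

    # genotyping error at the ancestry level: hom -> het with prob e
    dosage = recomb_dosage.copy()
    if config.error_rate > 0:
        hom = (dosage == 0) | (dosage == 2)
        dosage[hom & (rng.random(dosage.shape) < config.error_rate)] = 1

    ped_a1, ped_a2 = _materialize_matrix(rng, ped_dosage, pools_a, pools_b)
    # founders carry their side's full allele pool so that every F1/F2
    # allele draw is consistent with inheritance from the F0 pair
    for r, gen in enumerate(ped_gens):
        if gen == "F0A":
            ped_a1[r, :] = [p[0] for p in pools_a]
            ped_a2[r, :] = [p[-1] for p in pools_a]
        elif gen == "F0B":
            ped_a1[r, :] = [p[0] for p in pools_b]
            ped_a2[r, :] = [p[-1] for p in pools_b]
    rec_a1, rec_a2 = _materialize_matrix(rng, dosage, pools_a, pools_b)
    miss = rng.random(dosage.shape) < config.missing_rate
    rec_a1[miss] = None
    rec_a2[miss] = None

    all_ids = np.array(list(ped_ids) + list(recomb_ids), dtype=object)
    all_gens = np.array(list(ped_gens) + list(recomb_gen), dtype=object)
    all_fams = np.array(list(ped_fams) + list(recomb_fam), dtype=object)
    a1 = np.vstack([ped_a1, rec_a1])
    a2 = np.vstack([ped_a2, rec_a2])
    n = len(all_ids)
    df = pd.DataFrame(
        {
            "dataset_id": spec.dataset_id,
            "family_id": np.repeat(all_fams, L),
            "individual_id": np.repeat(all_ids, L),
            "generation": np.repeat(all_gens, L),
            "environment": spec.environment,
            "marker_id": np.tile(marker_ids, n),
            "chromosome": np.tile(chroms, n),
            "allele_1": a1.ravel(),
            "allele_2": a2.ravel(),
        }
    )
    if spec.platform == "gbs":
        shape = config.coverage_shape
        p = shape / (shape + config.coverage_mean)
        df["coverage"] = rng.negative_binomial(shape, p, size=len(df)).astype(float)
        df.loc[df["allele_1"].isna(), "coverage"] = 0.0
    else:
        df["coverage"] = np.nan
    if config.simulate_length:
        lrng = _rng(config.seed, dataset_index, _S_LENGTH)
        fams = sorted(set(recomb_fam))
        offsets = dict(zip(fams, lrng.normal(0.0, 3.0, size=len(fams))))
        lengths = {
            ind: 45.0 + offsets[f] + lrng.normal(0.0, 5.0)
            for ind, f in zip(recomb_ids, recomb_fam)
        }
        df["length_mm"] = df["individual_id"].map(lengths)
    else:
        df["length_mm"] = np.nan
    return CrossGenotypes(df)


def generate_f2_family(
    config: SimBundleConfig, dataset_index: int, family_index: int
) -> CrossGenotypes:
    """One family's genotype table: F0 pair, F1s, F2s (and F3s if asked).

    No viability selection is applied here (see
    :func:`generate_study_bundle`); dosages segregate 1:2:1 iid per
    marker, then missingness, genotyping error and (for GBS) per-call
    depth are overlaid.  Deterministic in (seed, dataset, family).
    """
    if not 0 <= dataset_index < len(config.datasets):
        raise ValidationError("dataset_index out of range")
    spec = config.datasets[dataset_index]
    if not 0 <= family_index < spec.n_families:
        raise ValidationError("family_index out of range")
    markers, pools_a, pools_b = _dataset_markers(config, dataset_index)
    fam, ped_ids, ped_gens, ped_dosage = _family_pedigree_rows(
        config, dataset_index, family_index, markers, pools_a, pools_b)
    rng = _rng(config.seed, dataset_index, family_index, _S_TRUTH, 99)
    f2 = _segregate(rng, spec.n_f2_per_family, markers, config.linkage)
    ids = [f"{fam}_F2_{i + 1}" for i in range(spec.n_f2_per_family)]
    gens = ["F2"] * spec.n_f2_per_family
    fams = [fam] * spec.n_f2_per_family
    dosage = f2
    if spec.n_f3_per_family:
        f3 = _f3_dosages(rng, f2, spec.n_f3_per_family)
        ids += [f"{fam}_F3_{i + 1}" for i in range(spec.n_f3_per_family)]
        gens += ["F3"] * spec.n_f3_per_family
        fams += [fam] * spec.n_f3_per_family
        dosage = np.vstack([f2, f3])
    return _assemble_dataset(
        config, dataset_index, markers, pools_a, pools_b,
        ped_ids, ped_gens, [fam] * len(ped_ids), ped_dosage,
        ids, gens, fams, dosage,
        noise_key=(config.seed, dataset_index, family_index, _S_NOISE))


@dataclass
class Bundle:
    """A generated study bundle: per-dataset tables plus a manifest."""

    datasets: dict[str, CrossGenotypes]
    manifest: pd.DataFrame
    config: SimBundleConfig

    def concat(self) -> CrossGenotypes:
        return CrossGenotypes(
            pd.concat([c.data for c in self.datasets.values()], ignore_index=True)
        )


def _generate_selected_cohort(config, dataset_index, spec, markers, sel_spec,
                              rng, generation: str, n_target: int,
                              parent_dosage: np.ndarray | None):
    """Generate recombinant dosages under viability selection.

    Candidates are produced in batches (F2: fresh 1:2:1 draws; F3:
    gametes from the surviving F2 pool) and filtered by survival until
    ``n_target`` survivors accumulate or the oversampling cap is hit.
    """
    survivors: list[np.ndarray] = []
    n_have = 0
    batch = max(n_target, 100)
    total_drawn = 0
    cap = config.selection_max_oversample * max(n_target, 1) + batch
    while n_have < n_target and total_drawn < cap:
        if generation == "F2":
            cand = _segregate(rng, batch, markers, config.linkage)
        else:
            cand = _f3_dosages(rng, parent_dosage, batch)
        total_drawn += batch
        mask = _select_dosages(cand, sel_spec, rng,
                               (config.seed, dataset_index, _S_SELECT))
        kept = cand[mask]
        survivors.append(kept)
        n_have += len(kept)
    out = np.vstack(survivors) if survivors else np.empty((0, len(markers)), int)
    if n_have < n_target:
        logger.warning(
            "dataset %s %s: only %d of %d survivors generated under selection",
            spec.dataset_id, generation, n_have, n_target,
        )
    return out[:n_target]


def generate_study_bundle(config: SimBundleConfig) -> Bundle:
    """Generate every dataset of the bundle plus a manifest table.

    Pond (or otherwise targeted) datasets pass their recombinant cohorts
    through viability selection *before* genotyping noise is overlaid:
    selection acts on true genotypes, genotyping happens at sampling.
    """
    datasets: dict[str, CrossGenotypes] = {}
    manifest_rows = []
    sel = config.selection
    for ds_idx, spec in enumerate(config.datasets):
        markers, pools_a, pools_b = _dataset_markers(config, ds_idx)
        ped_ids: list[str] = []
        ped_gens: list[str] = []
        ped_fams: list[str] = []
        ped_blocks: list[np.ndarray] = []
        ids: list[str] = []
        gens: list[str] = []
        fams: list[str] = []
        blocks: list[np.ndarray] = []
        selected = sel is not None and sel.targets(spec.environment)
        for fam_idx in range(spec.n_families):
            fam, p_ids, p_gens, p_dosage = _family_pedigree_rows(
                config, ds_idx, fam_idx, markers, pools_a, pools_b)
            ped_ids += p_ids
            ped_gens += p_gens
            ped_fams += [fam] * len(p_ids)
            ped_blocks.append(p_dosage)
            rng = _rng(config.seed, ds_idx, fam_idx, _S_TRUTH, 99)
            if selected:
                f2 = _generate_selected_cohort(
                    config, ds_idx, spec, markers, sel, rng, "F2",
                    spec.n_f2_per_family, None)
            else:
                f2 = _segregate(rng, spec.n_f2_per_family, markers, config.linkage)
            n_f2 = len(f2)
            ids += [f"{fam}_F2_{i + 1}" for i in range(n_f2)]
            gens += ["F2"] * n_f2
            fams += [fam] * n_f2
            blocks.append(f2)
            if spec.n_f3_per_family:
                if selected:
                    f3 = _generate_selected_cohort(
                        config, ds_idx, spec, markers, sel, rng, "F3",
                        spec.n_f3_per_family, f2)
                else:
                    f3 = _f3_dosages(rng, f2, spec.n_f3_per_family)
                ids += [f"{fam}_F3_{i + 1}" for i in range(len(f3))]
                gens += ["F3"] * len(f3)
                fams += [fam] * len(f3)
                blocks.append(f3)
        dosage = np.vstack(blocks)
        cross = _assemble_dataset(
            config, ds_idx, markers, pools_a, pools_b,
            ped_ids, ped_gens, ped_fams, np.vstack(ped_blocks),
            ids, gens, fams, dosage,
            noise_key=(config.seed, ds_idx, _S_NOISE))
        datasets[spec.dataset_id] = cross
        manifest_rows.append({
            "dataset_id": spec.dataset_id,
            "environment": spec.environment,
            "cross_type": spec.cross_type,
            "lake": spec.lake if spec.lake is not None else "none",
            "platform": spec.platform,
            "n_fish": len(ids),
            "n_markers": spec.n_markers,
        })
    manifest = pd.DataFrame(manifest_rows)
    return Bundle(datasets, manifest, config)
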