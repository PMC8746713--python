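"""Statistical layer: environment contrasts, robustness analyses, simulations.

The headline analysis is a linear mixed model for individual excess
ancestry heterozygosity with environment (lab vs pond), cross type,
their interaction and lake as fixed effects and data source (dataset)
as a random intercept; the quantity of interest is the model-implied
pond - lab contrast within each cross, with Wald inference.

Around it sit the robustness analyses: the hybrid-index-deviation
correlation (incompatibility vs single-locus heterosis), bootstrap
comparison of correlations, one-way group-mean comparisons (inbred vs
outbred, F2 vs F3, among-study homogeneity), within-family body-size
regression, single-marker-per-chromosome resampling, and the
genotyping-error and selection-strength simulation studies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .ancestry import summarize_individuals
from .containers import AncestryMatrix
from .errors import ModelError, SimulationError, ValidationError
from .simulate import SelectionSpec, _selection_fitness

logger = logging.getLogger(__name__)


def attach_manifest(summaries: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Join cross_type/lake/platform metadata onto a summary table."""
    cols = [c for c in ("dataset_id", "cross_type", "lake", "platform") if c in manifest.columns]
    out = summaries.merge(manifest[cols], on="dataset_id", how="left", validate="m:1")
    if out["cross_type"].isna().any():
        missing = sorted(out.loc[out["cross_type"].isna(), "dataset_id"].unique())
        raise ValidationError(f"datasets absent from manifest: {missing}")
    return out


# ----------------------------------------------------------------------
# mixed model


@dataclass
class LmmResult:
    """Fitted environment model and per-cross pond - lab contrasts."""

    contrasts: pd.DataFrame        # cross, estimate, se, z, p
    params: pd.Series
    bse: pd.Series
    group_var: float
    resid_var: float
    n_obs: int
    used_fixed_effects_fallback: bool
    note: str
    formula: str
    result: object = field(repr=False, default=None)

    def contrast(self, cross: str) -> pd.Series:
        sub = self.contrasts[self.contrasts["cross"] == cross]
        if sub.empty:
            raise KeyError(f"no contrast for cross {cross!r}")
        return sub.iloc[0]


def _prepare_model_frame(summaries: pd.DataFrame, response: str) -> pd.DataFrame:
    required = {response, "environment", "dataset_id"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValidationError(f"summary table lacks columns: {sorted(missing)}")
    df = summaries.copy()
    if "cross_type" not in df.columns:
        df["cross_type"] = "all"
    df["lake"] = df.get("lake", pd.Series("none", index=df.index))
    df["lake"] = df["lake"].fillna("none").replace("", "none")
    envs = sorted(df["environment"].unique())
    if len(envs) < 2:
        raise ModelError(f"need both environments; found only {envs}")
    return df


def _build_formula(df: pd.DataFrame, response: str) -> str:
    terms = ["C(environment)"]
    crosses = sorted(df["cross_type"].unique())
    if len(crosses) > 1:
        terms += ["C(cross_type)", "C(environment):C(cross_type)"]
    # lake is a fixed factor for the benthic x limnetic stratum; a single
    # observed level (or pure MxF data) makes it inestimable and it is dropped
    if df["lake"].nunique() > 1:
        terms.append("C(lake)")
    return f"{response} ~ " + " + ".join(terms)


def _contrast_rows(df, exog_names, beta, cov):
    """Pond - lab contrast per cross from the fixed effects."""
    crosses = sorted(df["cross_type"].unique())
    reference = crosses[0]
    env_name = "C(environment)[T.pond]"
    rows = []
    for cross in crosses:
        L = np.zeros(len(exog_names))
        L[exog_names.index(env_name)] = 1.0
        if cross != reference:
            inter = f"C(environment)[T.pond]:C(cross_type)[T.{cross}]"
            L[exog_names.index(inter)] = 1.0
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"cross": cross, "estimate": est, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows)


def fit_environment_model(
    summaries: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    response: str = "value",
) -> LmmResult:
    """Fit the lab-vs-pond model and report per-cross contrasts.

    REML linear mixed model with a random intercept per data source.
    When the random-intercept variance is estimated at the boundary
    (zero) or the optimizer fails, the fit degrades gracefully to the
    ordinary fixed-effects model, with a note recorded.
    """
    if manifest is not None:
        summaries = attach_manifest(summaries, manifest)
    df = _prepare_model_frame(summaries, response)
    formula = _build_formula(df, response)
    note = ""
    fallback = False
    mixed = None
    group_var = 0.0
    if df["dataset_id"].nunique() > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups=df["dataset_id"])
                mixed = model.fit(reml=True)
            group_var = float(np.squeeze(mixed.cov_re.to_numpy()))
            if not mixed.converged or group_var < 1e-10:
                note = "random-intercept variance at boundary; using fixed-effects fit"
                mixed = None
        except Exception as exc:  # noqa: BLE001 - optimizer failures vary
            note = f"mixed model failed ({exc}); using fixed-effects fit"
            mixed = None
    else:
        note = "single data source; random intercept inestimable"

    if mixed is not None:
        exog_names = list(mixed.model.exog_names)
        beta = np.asarray(mixed.fe_params)
        cov = np.asarray(mixed.cov_params())[: len(exog_names), : len(exog_names)]
        contrasts = _contrast_rows(df, exog_names, beta, cov)
        params = mixed.fe_params
        bse = mixed.bse_fe
        resid_var = float(mixed.scale)
        result_obj = mixed
    else:
        fallback = True
        ols = smf.ols(formula, df).fit()
        exog_names = list(ols.model.exog_names)
        beta = np.asarray(ols.params)
        cov = np.asarray(ols.cov_params())
        contrasts = _contrast_rows(df, exog_names, beta, cov)
        params = ols.params
        bse = ols.bse
        group_var = 0.0
        resid_var = float(ols.mse_resid)
        result_obj = ols
        if note:
            logger.info(note)
    return LmmResult(
        contrasts=contrasts, params=params, bse=bse, group_var=group_var,
        resid_var=resid_var, n_obs=len(df), used_fixed_effects_fallback=fallback,
        note=note, formula=formula, result=result_obj,
    )


# ----------------------------------------------------------------------
# correlations and group comparisons


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def hybrid_index_deviation_correlation(
    summaries: pd.DataFrame, group: str | None = None
) -> CorrelationResult:
    """Spearman correlation of excess het with |hybrid index - 0.5|.

    A negative correlation (heterozygosity pays off less as the genome
    becomes more parent-like) is the signature of between-locus
    incompatibilities rather than single-locus heterosis, for which no
    relationship is expected.
    """
    df = summaries
    if group is not None:
        df = df[df["environment"] == group]
    if len(df) < 3:
        raise ValidationError("need at least 3 individuals")
    x = np.abs(df["hybrid_index"].to_numpy() - 0.5)
    y = df["value"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ModelError("constant input vector; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), len(df))


@dataclass
class BootstrapResult:
    delta_rho: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int
    n_skipped: int


def bootstrap_correlation_difference(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap test for a difference between two deviation correlations.

    Individuals are resampled with replacement within each group; the
    two-sided P uses the (k+1)/(B+1) continuity convention so it is
    never exactly zero.  Degenerate resamples (constant ranks) are
    skipped and counted.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("both groups need at least 3 individuals")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals", stacklevel=2)
    rng = np.random.default_rng(seed)

    def _xy(df):
        return np.abs(df["hybrid_index"].to_numpy() - 0.5), df["value"].to_numpy()

    xa, ya = _xy(group_a)
    xb, yb = _xy(group_b)
    rho_a = stats.spearmanr(xa, ya).statistic
    rho_b = stats.spearmanr(xb, yb).statistic
    deltas = []
    skipped = 0
    for _ in range(n_boot):
        ia = rng.integers(len(xa), size=len(xa))
        ib = rng.integers(len(xb), size=len(xb))
        if np.ptp(xa[ia]) == 0 or np.ptp(ya[ia]) == 0 or np.ptp(xb[ib]) == 0 or np.ptp(yb[ib]) == 0:
            skipped += 1
            continue
        ra = stats.spearmanr(xa[ia], ya[ia]).statistic
        rb = stats.spearmanr(xb[ib], yb[ib]).statistic
        deltas.append(ra - rb)
    deltas = np.asarray(deltas)
    if deltas.size == 0:
        raise ModelError("all bootstrap replicates degenerate")
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    b = deltas.size
    p = 2.0 * min((1 + np.sum(deltas <= 0)) / (b + 1), (1 + np.sum(deltas >= 0)) / (b + 1))
    return BootstrapResult(float(rho_a - rho_b), float(lo), float(hi),
                           float(min(p, 1.0)), b, skipped)


@dataclass
class GroupComparison:
    levels: list
    means: pd.Series
    difference: float | None    # level[1] - level[0] for two groups
    difference_se: float | None
    f: float
    df_between: int
    df_within: int
    p: float


def compare_group_means(summaries: pd.DataFrame, grouping: str) -> GroupComparison:
    """One-way fixed-effects comparison of mean excess heterozygosity.

    Serves the inbred-vs-outbred, F2-vs-F3, among-study and a-priori
    phenotype-group analyses through the ``grouping`` column.
    """
    if grouping not in summaries.columns:
        raise ValidationError(f"no column {grouping!r} in summaries")
    groups = {k: v["value"].to_numpy() for k, v in summaries.groupby(grouping, observed=True)}
    if len(groups) < 2:
        raise ModelError(f"grouping {grouping!r} has fewer than 2 levels")
    small = [k for k, v in groups.items() if len(v) < 2]
    if small:
        raise ModelError(f"grouping level(s) with n < 2: {small}")
    levels = sorted(groups)
    arrays = [groups[k] for k in levels]
    f, p = stats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    df_b, df_w = len(arrays) - 1, n_total - len(arrays)
    diff = se = None
    if len(arrays) == 2:
        a, b = arrays
        diff = float(b.mean() - a.mean())
        s2p = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df_w
        se = float(np.sqrt(s2p * (1 / len(a) + 1 / len(b))))
    means = pd.Series({k: groups[k].mean() for k in levels})
    return GroupComparison(levels, means, diff, se, float(f), df_b, df_w, float(p))


@dataclass
class RegressionResult:
    slope: float
    slope_se: float
    f: float
    p: float
    r_squared: float
    n: int
    n_families_excluded: int


def within_family_size_regression(summaries: pd.DataFrame) -> RegressionResult:
    """Regression of within-family standardized body length on heterozygosity.

    Standard length is z-scored within family (families with fewer than
    3 measured fish or zero length variance are excluded with a
    warning), then regressed on observed ancestry heterozygosity.  Under
    a heterosis-through-vigor mechanism the slope would be positive; no
    relationship is the incompatibility-model expectation in the lab.
    """
    df = summaries.dropna(subset=["length_mm"]).copy()
    keep = []
    excluded = 0
    for fam, sub in df.groupby("family_id"):
        if len(sub) < 3 or sub["length_mm"].std(ddof=1) == 0:
            excluded += 1
            warnings.warn(f"family {fam!r} excluded from size regression", stacklevel=2)
            continue
        z = (sub["length_mm"] - sub["length_mm"].mean()) / sub["length_mm"].std(ddof=1)
        keep.append(pd.DataFrame({"z_length": z, "observed_het": sub["observed_het"]}))
    if not keep:
        raise ModelError("no family with usable length data")
    data = pd.concat(keep)
    X = sm.add_constant(data["observed_het"])
    fit = sm.OLS(data["z_length"], X).fit()
    slope = float(fit.params["observed_het"])
    se = float(fit.bse["observed_het"])
    t = slope / se
    return RegressionResult(slope, se, float(t**2), float(fit.pvalues["observed_het"]),
                            float(fit.rsquared), len(data), excluded)


# ----------------------------------------------------------------------
# single-marker resampling


@dataclass
class ResamplingResult:
    fraction_same_direction: float
    se: float
    full_effect: float
    n_reps: int
    n_effective: int


def _excess_rows(d: np.ndarray) -> np.ndarray:
    """Per-row excess heterozygosity of a dosage matrix (NaN-aware)."""
    n_loci = np.sum(~np.isnan(d), axis=1).astype(float)
    n_loci[n_loci == 0] = np.nan
    h = np.nansum(d, axis=1) / (2.0 * n_loci)
    obs = np.nansum(d == 1, axis=1) / n_loci
    return obs - 2.0 * h * (1.0 - h)


def _environment_design(meta: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Additive design matrix (intercept, pond, cross/lake dummies).

    Returns the matrix and the column index of the pond indicator, whose
    coefficient is the environment main effect tracked by the
    resampling analysis.
    """
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    cols.append((meta["environment"] == "pond").to_numpy(float))
    names.append("pond")
    for col in ("cross_type", "lake"):
        if col in meta.columns:
            levels = sorted(meta[col].fillna("none").unique())
            for lev in levels[1:]:
                cols.append((meta[col].fillna("none") == lev).to_numpy(float))
                names.append(f"{col}={lev}")
    return np.column_stack(cols), names.index("pond")


def single_marker_resampling(
    matrices: dict[str, AncestryMatrix],
    manifest: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
) -> ResamplingResult:
    """Sign-stability of the environment effect under marker thinning.

    Each replicate keeps one uniformly chosen marker per chromosome per
    dataset, recomputes individual excess heterozygosity, refits the
    additive environment model and records whether the environment
    effect has the same sign as in the full data.  Chromosomes without
    markers in a dataset are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    meta_parts, dosages, chrom_cols = [], [], []
    manifest_idx = manifest.set_index("dataset_id")
    for ds, matrix in matrices.items():
        recomb = matrix.recombinant_mask.to_numpy()
        d = matrix.dosage.to_numpy(float)[recomb]
        meta = matrix.individuals.loc[recomb].copy()
        meta["dataset_id"] = ds
        meta["cross_type"] = manifest_idx.loc[ds, "cross_type"]
        meta["lake"] = manifest_idx.loc[ds, "lake"]
        meta_parts.append(meta[["environment", "cross_type", "lake"]])
        dosages.append(d)
        chroms = matrix.markers["chromosome"].to_numpy()
        groups = {}
        for j, c in enumerate(chroms):
            groups.setdefault(c, []).append(j)
        chrom_cols.append({c: np.asarray(idx) for c, idx in groups.items()})
    meta = pd.concat(meta_parts, ignore_index=True)
    X, pond_col = _environment_design(meta)

    def _effect(y: np.ndarray) -> float:
        ok = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        return float(beta[pond_col])

    y_full = np.concatenate([_excess_rows(d) for d in dosages])
    full_effect = _effect(y_full)
    agree = 0
    effective = 0
    for _ in range(n_reps):
        ys = []
        for d, groups in zip(dosages, chrom_cols):
            cols = [idx[rng.integers(len(idx))] for idx in groups.values()]
            ys.append(_excess_rows(d[:, cols]))
        eff = _effect(np.concatenate(ys))
        effective += 1
        if np.sign(eff) == np.sign(full_effect):
            agree += 1
    frac = agree / effective
    se = float(np.sqrt(frac * (1 - frac) / effective))
    return ResamplingResult(frac, se, full_effect, n_reps, effective)


# ----------------------------------------------------------------------
# simulation studies


@dataclass
class SimulationReport:
    """Grid (or search trace) of a simulation study with its threshold."""

    parameter: str
    table: pd.DataFrame          # parameter value, mean_excess, mc_se, n_reps
    target_excess: float
    threshold: float | None
    bracket: tuple[float, float] | None
    seed: int
    architecture: str | None = None


def _neutral_cohort(rng: np.random.Generator, n_fish: int, n_loci: int) -> np.ndarray:
    return rng.choice([0.0, 1.0, 2.0], size=(n_fish, n_loci), p=[0.25, 0.5, 0.25])


def genotyping_error_threshold(
    n_fish: int = 500,
    n_loci: int = 100,
    n_reps: int = 20,
    target_excess: float = 0.03,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> SimulationReport:
    """Error rate needed for hom->het miscalls to mimic the pond signal.

    Simulates neutral F2 cohorts, converts each true-homozygote call to
    a heterozygote with probability e (the conservative error model:
    errors only ever inflate heterozygosity) and locates the smallest
    grid rate whose mean individual excess heterozygosity reaches the
    target.  Common uniforms across the grid make the response
    monotone within each replicate.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 0.1001, 0.005), 4)
    grid = np.asarray(grid, float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValidationError("error-rate grid must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    means = np.zeros((len(grid), n_reps))
    for r in range(n_reps):
        base = _neutral_cohort(rng, n_fish, n_loci)
        hom = (base == 0) | (base == 2)
        u = rng.random(base.shape)
        for i, e in enumerate(grid):
            d = base.copy()
            d[hom & (u < e)] = 1.0
            means[i, r] = float(np.mean(_excess_rows(d)))
    mean_excess = means.mean(axis=1)
    mc_se = means.std(axis=1, ddof=1) / np.sqrt(n_reps)
    table = pd.DataFrame({
        "error_rate": grid, "mean_excess": mean_excess,
        "mc_se": mc_se, "n_reps": n_reps,
    })
    reach = np.nonzero(mean_excess >= target_excess)[0]
    threshold = bracket = None
    if reach.size:
        k = reach[0]
        threshold = float(grid[k])
        bracket = (float(grid[k - 1]) if k else 0.0, float(grid[k]))
    return SimulationReport("error_rate", table, target_excess, threshold,
                            bracket, seed)


def selection_strength_required(
    architecture: str,
    target_excess: float = 0.03,
    n_fish: int = 20000,
    n_loci: int = 100,
    k_loci: int | None = None,
    k_pairs: int | None = None,
    m_traits: int = 20,
    tol: float = 0.002,
    seed: int = 0,
    max_strength: float | None = None,
) -> SimulationReport:
    """Selection strength needed for survivors to show the target excess.

    Bisection on the architecture's strength parameter (s for the
    locus-count architectures, the mismatch penalty scale for the
    phenotypic one), evaluating survivor mean excess heterozygosity on a
    common simulated cohort with common survival draws.  The initial
    interval is expanded automatically; an unattainable target raises a
    structured error.
    """
    spec0 = SelectionSpec(
        architecture=architecture,
        k_loci=k_loci,
        k_pairs=k_pairs if k_pairs is not None else 1,
        m_traits=m_traits,
    )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    cohort = _neutral_cohort(rng, n_fish, n_loci)
    u = rng.random(n_fish)
    trace = []

    def survivor_excess(strength: float) -> float:
        spec = spec0.with_strength(strength)
        if strength == 0.0:
            surv = np.ones(n_fish, bool)
        else:
            w = _selection_fitness(cohort, spec, (seed, 17))
            w_max = w.max()
            if w_max <= 0:
                raise SimulationError("all fitness values are zero")
            surv = u < (w / w_max)
        if surv.sum() < 30:
            raise SimulationError(
                f"fewer than 30 survivors at strength {strength:g}")
        val = float(np.mean(_excess_rows(cohort[surv])))
        trace.append((strength, val, int(surv.sum())))
        return val

    bounded = architecture in ("heterozygote_advantage", "pairwise_dmi")
    hi_cap = 1.0 - 1e-9 if bounded else 1e6
    lo, f_lo = 0.0, survivor_excess(0.0)
    if f_lo >= target_excess:
        raise SimulationError("target excess already reached without selection")
    hi = min(0.25 if bounded else 1.0, hi_cap) if max_strength is None else max_strength
    f_hi = survivor_excess(hi)
    expansions = 0
    while f_hi < target_excess and hi < hi_cap * (1 - 1e-12) and expansions < 60:
        hi = min(hi * 2.0 if not bounded else (hi + hi_cap) / 2.0, hi_cap)
        f_hi = survivor_excess(hi)
        expansions += 1
    if f_hi < target_excess:
        raise SimulationError(
            f"target excess {target_excess} unattainable for {architecture} "
            f"(max observed {f_hi:.4f} at strength {hi:g})")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = survivor_excess(mid)
        if abs(f_mid - target_excess) <= tol:
            lo = hi = mid
            break
        if f_mid < target_excess:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(1.0, hi):
            break
    s_star = 0.5 * (lo + hi)
    table = pd.DataFrame(trace, columns=["strength", "mean_excess", "n_survivors"])
    param = "sigma_scale" if architecture == "fgm_mismatch" else "s"
    return SimulationReport(param, table, target_excess, float(s_star),
                            (float(lo), float(hi)), seed, architecture=architecture)


def tune_selection_to_target(
    architecture: str,
    target_excess: float = 0.03,
    seed: int = 0,
    **kwargs,
) -> SelectionSpec:
    """SelectionSpec whose strength yields the target survivor excess."""
    report = selection_strength_required(
        architecture, target_excess=target_excess, seed=seed, **kwargs)
    spec = SelectionSpec(
        architecture=architecture,
        k_loci=kwargs.get("k_loci"),
        k_pairs=kwargs.get("k_pairs") or 1,
        m_traits=kwargs.get("m_traits", 20),
    )
    return spec.with_strength(report.threshold)
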