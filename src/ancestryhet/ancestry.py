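"""Marker filtering, ancestry polarization and heterozygosity statistics.

The analysis restricts attention to *diagnostic* (ancestry-informative)
markers: loci at which the two founder lineages of a cross share no
alleles and at which every genotyped F1 hybrid carries one allele from
each side.  At such loci every allele's ancestry is unambiguous, so each
recombinant genotype can be written as a dosage of "side B" ancestry.

The central statistic is excess ancestry heterozygosity: observed
ancestry heterozygosity (p_AB, the fraction of heterozygous-for-ancestry
loci) minus the Hardy-Weinberg expectation 2*p_A*p_B computed from the
individual's (or locus's) own ancestry frequencies.  Under neutral 1:2:1
F2 segregation its expectation is zero; viability selection against
mismatched homozygous ancestry combinations pushes it positive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    AncestryMatrix,
    CrossGenotypes,
    MarkerPanel,
    RECOMBINANT_GENERATIONS,
)
from .errors import FilterError, PedigreeError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SEX_CHROMOSOME = "19"
DEFAULT_MIN_COVERAGE = 20
DEFAULT_MIN_LOCI = 20
DEFAULT_MIN_INDIVIDUALS = 20


def _mask_low_coverage(df: pd.DataFrame, min_coverage: int) -> pd.DataFrame:
    """Treat calls with coverage <= min_coverage as missing (strict '>' rule)."""
    cov = pd.to_numeric(df["coverage"], errors="coerce")
    low = cov.notna() & (cov <= min_coverage)
    if low.any():
        df = df.copy()
        df.loc[low, ["allele_1", "allele_2"]] = np.nan
    return df


def select_diagnostic_markers(
    cross: CrossGenotypes,
    sex_chrom_label: str = DEFAULT_SEX_CHROMOSOME,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> MarkerPanel:
    """Flag markers that are diagnostic for ancestry.

    A marker is diagnostic iff (a) the union of side-A founder alleles is
    disjoint from the union of side-B founder alleles, (b) every genotyped
    F1 carries exactly one allele from each side, and (c) it is not on the
    sex chromosome.  ``rejection_reason`` records the first failed rule
    (``shared_allele``, ``f1_not_heterozygous``, ``sex_chromosome``;
    ``no_founder_calls`` when a side has no genotyped founder call).
    Low-coverage calls are masked as missing before rules are evaluated.
    """
    df = cross.data
    if not (df["generation"] == "F1").any():
        raise PedigreeError("cross has no F1 individuals")
    if not ((df["generation"] == "F0A").any() and (df["generation"] == "F0B").any()):
        raise PedigreeError("cross lacks F0 founders on one or both sides")
    df = _mask_low_coverage(df, min_coverage)

    called = df[df["allele_1"].notna()]
    rows = []
    n_f1_het = 0
    n_f1_checked = 0
    for marker_id, sub in called.groupby("marker_id", sort=False):
        chrom = sub["chromosome"].iloc[0]
        gen = sub["generation"]
        a_alleles = frozenset(
            pd.concat([sub.loc[gen == "F0A", "allele_1"], sub.loc[gen == "F0A", "allele_2"]])
        )
        b_alleles = frozenset(
            pd.concat([sub.loc[gen == "F0B", "allele_1"], sub.loc[gen == "F0B", "allele_2"]])
        )
        reason = None
        if not a_alleles or not b_alleles:
            reason = "no_founder_calls"
        elif a_alleles & b_alleles:
            reason = "shared_allele"
        else:
            f1 = sub[gen == "F1"]
            het = (
                f1["allele_1"].isin(a_alleles) & f1["allele_2"].isin(b_alleles)
            ) | (
                f1["allele_1"].isin(b_alleles) & f1["allele_2"].isin(a_alleles)
            )
            n_f1_checked += len(f1)
            n_f1_het += int(het.sum())
            if not het.all():
                reason = "f1_not_heterozygous"
            elif str(chrom) == str(sex_chrom_label):
                reason = "sex_chromosome"
        rows.append(
            {
                "marker_id": marker_id,
                "chromosome": chrom,
                "side_a_alleles": a_alleles,
                "side_b_alleles": b_alleles,
                "diagnostic": reason is None,
                "rejection_reason": reason,
            }
        )
    table = pd.DataFrame(rows).set_index("marker_id")
    rate = n_f1_het / n_f1_checked if n_f1_checked else float("nan")
    panel = MarkerPanel(table, f1_validation_rate=rate, n_f1_calls_checked=n_f1_checked)
    if not table["diagnostic"].any():
        logger.warning("no diagnostic markers retained (all rejected)")
    return panel


def polarize_to_ancestry(cross: CrossGenotypes, panel: MarkerPanel) -> AncestryMatrix:
    """Convert raw calls at diagnostic markers into side-B ancestry dosages.

    Dosage is the number of alleles from the side-B set (0, 1 or 2).
    Calls containing a token seen in neither founder side (novel alleles,
    genotyping artifacts) become missing and are tallied in
    ``n_unpolarized_calls``.
    """
    diag = panel.table[panel.table["diagnostic"]]
    missing_markers = set(diag.index) - set(cross.data["marker_id"])
    if missing_markers:
        raise ValidationError(
            f"panel markers absent from cross: {sorted(missing_markers)[:5]}"
        )
    # token -> side lookup, exploded to one row per (marker, token)
    map_rows = []
    for marker_id, row in diag.iterrows():
        for tok in row["side_a_alleles"]:
            map_rows.append((marker_id, tok, 0.0))
        for tok in row["side_b_alleles"]:
            map_rows.append((marker_id, tok, 1.0))
    side_map = pd.DataFrame(map_rows, columns=["marker_id", "token", "side_b"])

    df = cross.data[cross.data["marker_id"].isin(diag.index)].copy()
    for i in (1, 2):
        df = df.merge(
            side_map.rename(columns={"token": f"allele_{i}", "side_b": f"side_{i}"}),
            on=["marker_id", f"allele_{i}"],
            how="left",
        )
    called = df["allele_1"].notna()
    unknown = called & (df["side_1"].isna() | df["side_2"].isna())
    n_unpolarized = int(unknown.sum())
    if n_unpolarized:
        logger.info("%d calls carried novel alleles and were set missing", n_unpolarized)
    df["dosage"] = df["side_1"] + df["side_2"]
    df.loc[unknown, "dosage"] = np.nan

    dosage = df.pivot_table(
        index="individual_id", columns="marker_id", values="dosage",
        aggfunc="first", dropna=False,
    )
    # preserve input orderings
    ind_meta = cross.individuals().set_index("individual_id")
    dosage = dosage.reindex(index=ind_meta.index, columns=diag.index)
    markers = diag[["chromosome"]].copy()
    return AncestryMatrix(dosage, ind_meta, markers, n_unpolarized_calls=n_unpolarized)


def apply_matrix_filters(
    matrix: AncestryMatrix,
    min_loci: int = DEFAULT_MIN_LOCI,
    min_individuals: int = DEFAULT_MIN_INDIVIDUALS,
) -> AncestryMatrix:
    """Drop under-genotyped recombinants and under-genotyped markers.

    Recombinant (F2/F3) individuals need at least ``min_loci`` non-missing
    dosages and markers need at least ``min_individuals`` non-missing
    recombinant dosages.  The two rules are iterated to a fixed point so
    the result does not depend on application order.  Founder and F1 rows
    are retained regardless and never counted.
    """
    if matrix.dosage.size == 0:
        raise FilterError("empty ancestry matrix")
    dosage = matrix.dosage
    recomb = matrix.recombinant_mask.to_numpy()
    keep_rows = np.ones(dosage.shape[0], dtype=bool)
    keep_cols = np.ones(dosage.shape[1], dtype=bool)
    present = dosage.notna().to_numpy()
    while True:
        loci_per_ind = (present[:, keep_cols]).sum(axis=1)
        new_rows = keep_rows & (~recomb | (loci_per_ind >= min_loci))
        inds_per_marker = present[new_rows & recomb].sum(axis=0)
        new_cols = keep_cols & (inds_per_marker >= min_individuals)
        if new_rows.sum() == keep_rows.sum() and new_cols.sum() == keep_cols.sum():
            break
        keep_rows, keep_cols = new_rows, new_cols
        if not (keep_rows & recomb).any():
            raise FilterError(
                f"all recombinant individuals dropped (min_loci={min_loci})",
                binding_constraint="min_loci",
            )
        if not keep_cols.any():
            raise FilterError(
                f"all markers dropped (min_individuals={min_individuals})",
                binding_constraint="min_individuals",
            )
    if not (keep_rows & recomb).any():
        raise FilterError(
            f"all recombinant individuals dropped (min_loci={min_loci})",
            binding_constraint="min_loci",
        )
    if not keep_cols.any():
        raise FilterError(
            f"all markers dropped (min_individuals={min_individuals})",
            binding_constraint="min_individuals",
        )
    return matrix.subset(dosage.index[keep_rows], dosage.columns[keep_cols])


def _small_sample_factor(n: np.ndarray, correction: str) -> np.ndarray:
    if correction == "none":
        return np.ones_like(n, dtype=float)
    if correction == "small_sample":
        return (2.0 * n) / (2.0 * n - 1.0)
    raise ValidationError(f"unknown correction {correction!r}")


def summarize_individuals(
    matrix: AncestryMatrix,
    statistic: str = "excess",
    correction: str = "none",
) -> pd.DataFrame:
    """Per-recombinant-individual heterozygosity summary.

    Returns one row per F2/F3 individual with ``n_loci``, the hybrid
    index ``h`` (fraction of side-B alleles), ``observed_het`` (p_AB),
    ``expected_het`` (2*h*(1-h), optionally scaled by 2N/(2N-1) with
    N = n_loci), ``excess_het`` and an analysis column ``value`` that is
    the excess (default) or the raw observed heterozygosity.
    """
    if statistic not in ("excess", "observed"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    sub = matrix.recombinant_dosage()
    d = sub.to_numpy(dtype=float)
    n_loci = np.sum(~np.isnan(d), axis=1)
    if np.any(n_loci == 0):
        bad = sub.index[n_loci == 0].tolist()[:5]
        raise ValidationError(f"individual(s) with zero genotyped loci: {bad}")
    h = np.nansum(d, axis=1) / (2.0 * n_loci)
    observed = np.nansum(d == 1, axis=1) / n_loci
    expected = 2.0 * h * (1.0 - h) * _small_sample_factor(n_loci, correction)
    excess = observed - expected
    out = pd.DataFrame(
        {
            "individual_id": sub.index,
            "n_loci": n_loci.astype(int),
            "hybrid_index": h,
            "observed_het": observed,
            "expected_het": expected,
            "excess_het": excess,
        }
    )
    meta = matrix.individuals.loc[sub.index].reset_index(drop=True)
    out = pd.concat(
        [out, meta[["dataset_id", "family_id", "generation", "environment", "length_mm"]]],
        axis=1,
    )
    out["value"] = out["excess_het"] if statistic == "excess" else out["observed_het"]
    return out


def summarize_loci(
    matrix: AncestryMatrix,
    statistic: str = "excess",
    correction: str = "none",
) -> pd.DataFrame:
    """Per-marker heterozygosity summary over recombinant individuals."""
    if statistic not in ("excess", "observed"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    sub = matrix.recombinant_dosage()
    d = sub.to_numpy(dtype=float)
    n_ind = np.sum(~np.isnan(d), axis=0)
    if np.any(n_ind == 0):
        bad = sub.columns[n_ind == 0].tolist()[:5]
        raise ValidationError(f"marker(s) with zero genotyped individuals: {bad}")
    p_b = np.nansum(d, axis=0) / (2.0 * n_ind)
    observed = np.nansum(d == 1, axis=0) / n_ind
    expected = 2.0 * p_b * (1.0 - p_b) * _small_sample_factor(n_ind, correction)
    excess = observed - expected
    out = pd.DataFrame(
        {
            "marker_id": sub.columns,
            "chromosome": matrix.markers.loc[sub.columns, "chromosome"].to_numpy(),
            "n_individuals": n_ind.astype(int),
            "ancestry_freq": p_b,
            "observed_het": observed,
            "expected_het": expected,
            "excess_het": excess,
        }
    )
    out["value"] = out["excess_het"] if statistic == "excess" else out["observed_het"]
    return out


def chromosome_means(loci: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-chromosome mean of locus excess heterozygosity.

    SE is the standard deviation over loci divided by sqrt(n_loci); it is
    reported as NaN for single-locus chromosomes.
    """
    if loci.empty:
        raise ValidationError("empty locus summary")
    g = loci.groupby("chromosome")["excess_het"]
    out = g.agg(mean_excess_het="mean", sd="std", n_loci="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n_loci"])
    return out[["chromosome", "mean_excess_het", "se", "n_loci"]]
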