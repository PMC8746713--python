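"""In-memory containers for pedigreed cross genotypes and ancestry dosages.

The canonical unit of raw data is a long-format table of genotype calls
(one row per individual x marker) for a pedigreed hybrid cross: F0
founders from each side, F1 hybrids, and recombinant F2/F3 individuals.
Downstream of marker filtering, genotypes are re-expressed as ancestry
dosages (0, 1 or 2 copies of "side B" ancestry) in an individuals x
markers matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PedigreeError, ValidationError

#: Column order of the canonical long-format genotype table.
GENOTYPE_COLUMNS = [
    "dataset_id",
    "family_id",
    "individual_id",
    "generation",
    "environment",
    "marker_id",
    "chromosome",
    "allele_1",
    "allele_2",
    "coverage",
    "length_mm",
]

GENERATIONS = ("F0A", "F0B", "F1", "F2", "F3")
RECOMBINANT_GENERATIONS = ("F2", "F3")
ENVIRONMENTS = ("lab", "pond")


@dataclass
class CrossGenotypes:
    """Long-format genotype calls for one or more pedigreed crosses.

    ``data`` holds one row per (individual, marker) call with the columns
    in :data:`GENOTYPE_COLUMNS`.  Allele tokens are opaque strings
    (microsatellite fragment sizes, nucleotides, ...); a call is missing
    when both allele columns are null.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in GENOTYPE_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ValidationError(f"genotype table lacks columns: {missing_cols}")
        self.data = self.data[GENOTYPE_COLUMNS].reset_index(drop=True)

    # -- validation ----------------------------------------------------

    def validate(self, require_founders: bool = True) -> "CrossGenotypes":
        """Check structural invariants; return self on success."""
        df = self.data
        bad_gen = ~df["generation"].isin(GENERATIONS)
        if bad_gen.any():
            lines = (df.index[bad_gen] + 2).tolist()[:5]  # +2: header + 1-based
            labels = sorted(df.loc[bad_gen, "generation"].unique())
            raise ValidationError(
                f"unknown generation label(s) {labels} at line(s) {lines}"
            )
        bad_env = ~df["environment"].isin(ENVIRONMENTS)
        if bad_env.any():
            lines = (df.index[bad_env] + 2).tolist()[:5]
            raise ValidationError(f"unknown environment label at line(s) {lines}")
        half = df["allele_1"].isna() != df["allele_2"].isna()
        if half.any():
            lines = (df.index[half] + 2).tolist()[:5]
            raise ValidationError(
                f"half-missing genotype (one allele null) at line(s) {lines}"
            )
        dup = df.duplicated(subset=["dataset_id", "individual_id", "marker_id"])
        if dup.any():
            lines = (df.index[dup] + 2).tolist()[:5]
            raise ValidationError(
                f"duplicate (individual, marker) call within dataset at line(s) {lines}"
            )
        if require_founders:
            for ds, sub in df.groupby("dataset_id", sort=False):
                present = set(sub["generation"].unique())
                for role in ("F0A", "F0B", "F1"):
                    if role not in present:
                        raise PedigreeError(
                            f"dataset {ds!r} has no {role} individuals"
                        )
        return self

    # -- convenience ---------------------------------------------------

    @property
    def datasets(self) -> list[str]:
        return list(pd.unique(self.data["dataset_id"]))

    def individuals(self) -> pd.DataFrame:
        """Per-individual metadata (first call's values)."""
        cols = ["dataset_id", "family_id", "individual_id", "generation",
                "environment", "length_mm"]
        return (
            self.data[cols]
            .drop_duplicates(subset=["dataset_id", "individual_id"])
            .reset_index(drop=True)
        )

    def is_missing(self) -> pd.Series:
        return self.data["allele_1"].isna()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MarkerPanel:
    """Per-marker diagnostic status derived from founders and F1s.

    ``table`` is indexed by marker_id with columns ``chromosome``,
    ``side_a_alleles`` / ``side_b_alleles`` (frozensets of tokens),
    ``diagnostic`` (bool) and ``rejection_reason`` (None for diagnostic
    markers; otherwise the first failed rule).  ``f1_validation_rate``
    is the fraction of non-missing F1 calls, at markers whose founder
    allele sets are disjoint, that are heterozygous for ancestry.
    """

    table: pd.DataFrame
    f1_validation_rate: float
    n_f1_calls_checked: int

    @property
    def diagnostic_markers(self) -> list[str]:
        return self.table.index[self.table["diagnostic"]].tolist()

    def rejection_counts(self) -> pd.Series:
        return self.table.loc[~self.table["diagnostic"], "rejection_reason"].value_counts()


@dataclass
class AncestryMatrix:
    """Individuals x diagnostic markers ancestry-dosage matrix.

    ``dosage`` is a float DataFrame (rows: individual ids, columns:
    marker ids) holding the number of side-B ancestry alleles (0, 1, 2)
    with NaN for missing calls.  ``individuals`` is indexed by
    individual_id (dataset_id, family_id, generation, environment,
    length_mm); ``markers`` by marker_id (chromosome).
    """

    dosage: pd.DataFrame
    individuals: pd.DataFrame
    markers: pd.DataFrame
    n_unpolarized_calls: int = 0

    def __post_init__(self) -> None:
        if not self.dosage.index.equals(self.individuals.index):
            raise ValidationError("dosage rows and individual metadata disagree")
        if not self.dosage.columns.equals(self.markers.index):
            raise ValidationError("dosage columns and marker metadata disagree")

    @property
    def recombinant_mask(self) -> pd.Series:
        return self.individuals["generation"].isin(RECOMBINANT_GENERATIONS)

    def recombinant_dosage(self) -> pd.DataFrame:
        return self.dosage.loc[self.recombinant_mask.to_numpy()]

    def subset(
        self,
        individual_ids: pd.Index | np.ndarray | list | None = None,
        marker_ids: pd.Index | np.ndarray | list | None = None,
    ) -> "AncestryMatrix":
        dosage = self.dosage
        individuals = self.individuals
        markers = self.markers
        if individual_ids is not None:
            dosage = dosage.loc[individual_ids]
            individuals = individuals.loc[individual_ids]
        if marker_ids is not None:
            dosage = dosage[marker_ids]
            markers = markers.loc[marker_ids]
        return AncestryMatrix(dosage, individuals, markers, self.n_unpolarized_calls)

    def concat(self, other: "AncestryMatrix") -> "AncestryMatrix":
        """Stack two matrices over individuals (outer join on markers)."""
        dosage = pd.concat([self.dosage, other.dosage], axis=0)
        individuals = pd.concat([self.individuals, other.individuals], axis=0)
        markers = pd.concat(
            [self.markers, other.markers.loc[~other.markers.index.isin(self.markers.index)]]
        )
        dosage = dosage.reindex(columns=markers.index)
        return AncestryMatrix(
            dosage, individuals, markers,
            self.n_unpolarized_calls + other.n_unpolarized_calls,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape
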