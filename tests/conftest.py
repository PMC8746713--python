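import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ancestryhet.containers import CrossGenotypes, GENOTYPE_COLUMNS

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_cross(calls, environment="lab", dataset_id="ds1", family_id="f1",
               chromosomes=None, coverage=None, lengths=None) -> CrossGenotypes:
    """Build a CrossGenotypes from {individual_id: (generation, [(a1, a2), ...])}.

    ``calls`` maps individual -> (generation, list of allele pairs, one per
    marker m1..mK in order); None entries are missing calls.
    """
    n_markers = len(next(iter(calls.values()))[1])
    marker_ids = [f"m{j + 1}" for j in range(n_markers)]
    chromosomes = chromosomes or ["1"] * n_markers
    rows = []
    for ind, (gen, pairs) in calls.items():
        for j, pair in enumerate(pairs):
            a1, a2 = (None, None) if pair is None else pair
            cov = coverage.get((ind, marker_ids[j])) if coverage else None
            rows.append({
                "dataset_id": dataset_id, "family_id": family_id,
                "individual_id": ind, "generation": gen,
                "environment": environment, "marker_id": marker_ids[j],
                "chromosome": chromosomes[j], "allele_1": a1, "allele_2": a2,
                "coverage": cov,
                "length_mm": lengths.get(ind) if lengths else None,
            })
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    df["coverage"] = pd.to_numeric(df["coverage"])
    df["length_mm"] = pd.to_numeric(df["length_mm"])
    return CrossGenotypes(df)


@pytest.fixture
def toy_cross():
    """Five-marker cross: founders share an allele at m3, one F1 is
    ancestry-homozygous at m5, so only m1, m2, m4 are diagnostic."""
    A, B = ("A", "A"), ("G", "G")
    het = ("A", "G")
    return make_cross({
        "f0a": ("F0A", [A, A, ("A", "C"), A, A]),
        "f0b": ("F0B", [B, B, ("C", "G"), B, B]),   # shares C at m3
        "f1x": ("F1", [het, het, het, het, het]),
        "f1y": ("F1", [het, het, het, het, ("G", "G")]),  # hom at m5
        "f2a": ("F2", [A, het, het, B, het]),
        "f2b": ("F2", [het, B, A, het, A]),
    })


@pytest.fixture(scope="session")
def neutral_bundle():
    """Small neutral lab+pond bundle shared across read-only tests."""
    from ancestryhet.simulate import SimBundleConfig, generate_study_bundle

    config = SimBundleConfig.from_counts(
        2, 2, f2_per_family=120, n_markers=44, seed=101, missing_rate=0.02)
    return generate_study_bundle(config)


def random_ancestry_matrix(n, n_loci, seed=0, generation="F2", environment="pond"):
    """Neutral 1:2:1 dosage matrix wrapped as an AncestryMatrix."""
    from ancestryhet.containers import AncestryMatrix

    rng = np.random.default_rng(seed)
    d = rng.choice([0.0, 1.0, 2.0], size=(n, n_loci), p=[0.25, 0.5, 0.25])
    dosage = pd.DataFrame(d, index=[f"i{k}" for k in range(n)],
                          columns=[f"m{j}" for j in range(n_loci)])
    individuals = pd.DataFrame({
        "dataset_id": "d1", "family_id": "f1", "generation": generation,
        "environment": environment, "length_mm": np.nan,
    }, index=dosage.index)
    markers = pd.DataFrame({"chromosome": [str(j % 20 + 1) for j in range(n_loci)]},
                           index=dosage.columns)
    return AncestryMatrix(dosage, individuals, markers)


def summarize_bundle(bundle, min_loci=20, min_individuals=20, **kwargs):
    """Full-pipeline individual summaries for every dataset of a bundle."""
    from ancestryhet import (apply_matrix_filters, polarize_to_ancestry,
                             select_diagnostic_markers, summarize_individuals)

    parts = []
    matrices = {}
    for ds, cross in bundle.datasets.items():
        panel = select_diagnostic_markers(cross)
        matrix = apply_matrix_filters(
            polarize_to_ancestry(cross, panel),
            min_loci=min_loci, min_individuals=min_individuals)
        matrices[ds] = matrix
        parts.append(summarize_individuals(matrix, **kwargs))
    return pd.concat(parts, ignore_index=True), matrices
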