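"""Reading and writing the canonical genotype TSV, VCF import, sidecars.

Canonical genotype dialect: UTF-8, tab-separated, mandatory header, one
row per individual x marker with columns dataset_id, family_id,
individual_id, generation (F0A|F0B|F1|F2|F3), environment (lab|pond),
marker_id, chromosome, allele_1, allele_2, coverage, length_mm; missing
values are written "NA".  Lines starting with '#' are metadata comments
(the pipeline stamps a config hash there).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CrossGenotypes, GENOTYPE_COLUMNS
from .errors import ValidationError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"


def write_genotype_tsv(
    cross: CrossGenotypes, path: str | Path, config_hash: str | None = None
) -> Path:
    """Write a genotype table in the canonical dialect."""
    path = Path(path)
    df = cross.data.copy()
    cov = pd.to_numeric(df["coverage"], errors="coerce")
    df["coverage"] = cov.map(lambda v: MISSING_TOKEN if pd.isna(v) else str(int(v)))
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING_TOKEN)
    return path


def read_genotype_tsv(path: str | Path) -> CrossGenotypes:
    """Read and validate a canonical genotype TSV.

    Raises a structured error naming offending line numbers for missing
    columns, half-missing allele pairs or unknown generation labels; an
    empty body with a valid header yields an empty table with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(
        path, sep="\t", dtype=str, comment="#",
        na_values=[MISSING_TOKEN], keep_default_na=False,
    )
    missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing_cols}")
    extra = [c for c in df.columns if c not in GENOTYPE_COLUMNS]
    if extra:
        logger.info("%s: preserving %d unknown column(s) as metadata", path, len(extra))
    df["coverage"] = pd.to_numeric(df["coverage"], errors="coerce")
    df["length_mm"] = pd.to_numeric(df["length_mm"], errors="coerce")
    cross = CrossGenotypes(df)
    if df.empty:
        logger.warning("%s: empty genotype table", path)
        return cross
    return cross.validate()


# ----------------------------------------------------------------------
# VCF import


def import_vcf(path: str | Path, pedigree_map: pd.DataFrame) -> CrossGenotypes:
    """Convert a VCF (GT fields) into the canonical long format.

    ``pedigree_map`` has one row per sample with columns sample_id,
    dataset_id, family_id, generation, environment (and optionally
    length_mm).  REF/ALT become the allele tokens; per-sample DP maps to
    coverage; multiallelic sites and half-missing genotypes become
    missing calls (counts logged).
    """
    from cyvcf2 import VCF

    required = {"sample_id", "dataset_id", "family_id", "generation", "environment"}
    missing_cols = required - set(pedigree_map.columns)
    if missing_cols:
        raise ValidationError(f"pedigree map lacks columns: {sorted(missing_cols)}")
    ped = pedigree_map.set_index("sample_id")
    vcf = VCF(str(path))
    samples = vcf.samples
    absent = [s for s in samples if s not in ped.index]
    if absent:
        raise ValidationError(f"samples absent from pedigree map: {absent}")

    rows = []
    n_multiallelic = n_halfmissing = 0
    for variant in vcf:
        tokens = [variant.REF] + list(variant.ALT)
        marker_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        multi = len(variant.ALT) > 1
        if multi:
            n_multiallelic += 1
        try:
            depths = variant.format("DP")
        except Exception:  # noqa: BLE001 - format field absent
            depths = None
        if depths is None:
            depths = variant.gt_depths
        genotypes = variant.genotypes  # [allele1, allele2, phased]
        for i, sample in enumerate(samples):
            a1 = a2 = None
            cov = None
            if depths is not None:
                d = int(np.ravel(depths[i])[0])
                cov = d if d >= 0 else None
            if not multi:
                g = genotypes[i]
                i1, i2 = int(g[0]), int(g[1])
                if i1 >= 0 and i2 >= 0:
                    a1, a2 = tokens[i1], tokens[i2]
                elif (i1 >= 0) != (i2 >= 0):
                    n_halfmissing += 1
            meta = ped.loc[sample]
            rows.append((
                meta["dataset_id"], meta["family_id"], sample,
                meta["generation"], meta["environment"], marker_id,
                str(variant.CHROM), a1, a2, cov,
                meta.get("length_mm", np.nan),
            ))
    if n_multiallelic or n_halfmissing:
        logger.info(
            "VCF import: %d multiallelic site(s) and %d half-missing genotype(s) set missing",
            n_multiallelic, n_halfmissing,
        )
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    df["coverage"] = pd.to_numeric(df["coverage"], errors="coerce")
    df["length_mm"] = pd.to_numeric(df["length_mm"], errors="coerce")
    return CrossGenotypes(df).validate()


# ----------------------------------------------------------------------
# bundles, manifests, sidecars


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass) configuration."""
    if is_dataclass(obj) and not isinstance(obj, type):
        payload = asdict(obj)
    else:
        payload = obj
    text = yaml.safe_dump(_yaml_ready(payload), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _yaml_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_bundle(bundle, outdir: str | Path) -> dict[str, Path]:
    """Write per-dataset genotype TSVs, the manifest and a config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config_hash(bundle.config)
    paths = {}
    for ds, cross in bundle.datasets.items():
        paths[ds] = write_genotype_tsv(cross, outdir / f"{ds}.genotypes.tsv", h)
    bundle.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    paths["manifest"] = outdir / "manifest.tsv"
    sidecar = {
        "config": _yaml_ready(asdict(bundle.config)),
        "config_hash": h,
        "seed": int(bundle.config.seed),
    }
    with open(outdir / "bundle.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    paths["sidecar"] = outdir / "bundle.yaml"
    return paths


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"dataset_id": str, "lake": str})
    required = {"dataset_id", "environment", "cross_type"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise ValidationError(f"manifest lacks columns: {sorted(missing_cols)}")
    return manifest
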