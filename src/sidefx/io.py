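"""Readers for the pipeline's delimited-text interchange files."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .genevectors import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "read_subjects",
    "read_medis",
    "read_scale_scores",
    "read_weights",
    "read_gene_vectors",
]


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Load ``genotypes.tsv`` + ``snp_map.tsv`` from a cohort directory."""
    path = Path(path)
    values = pd.read_csv(path / "genotypes.tsv", sep="\t", index_col="subject_id",
                         na_values="NA")
    snp_map = pd.read_csv(path / "snp_map.tsv", sep="\t", index_col="snp_id")
    return GenotypeMatrix(values, snp_map)


def read_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "subjects.tsv", sep="\t")


def read_medis(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "medis_long.tsv", sep="\t")


def read_scale_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "scale_scores.tsv", sep="\t")


def read_weights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "weights.tsv", sep="\t")


def read_gene_vectors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path) / "gene_vectors.tsv", sep="\t",
                       index_col="subject_id", na_values="NA")
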