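"""End-to-end orchestration of the two-stage genotype-phenotype analysis.

Chains the modules into the study's workflow: simulate (or load) a cohort,
score side-effect profiles at an assessment day, QC and encode gene vectors,
report genetic diversity, screen genes for phenotype-characteristic patterns,
and cross-validate the neural-net classifier on the screened inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortConfig, SyntheticCohort, simulate_cohort
from .genevectors import diversity_report, encode_gene_vectors, qc_filter
from .nn import CVReport, NNConfig, cross_validate, prepare_inputs
from .phenotypes import (
    build_outcomes,
    default_registry,
    score_profiles,
    severity_case,
    stratify_cluster,
)
from .screen import ScreenConfig, ScreenResult, screen_all

__all__ = ["PipelineResult", "run_pipeline", "phenotype_labels"]


def phenotype_labels(profiles: pd.DataFrame, phenotype: str = "GSIDE") -> pd.Series:
    """Binary case labels (moderate-to-severe vs none/mild) for a phenotype.

    ``phenotype`` is "S" (global), "GSIDE", a specific component (SEX, AUTO,
    NEURO, CARDIO) or any cluster name; component/cluster scores are rescaled
    to the full instrument before applying the severity cutpoints.
    """
    registry = default_registry()
    if phenotype == "S":
        strata = profiles["stratum"]
        return pd.Series(severity_case(strata.to_numpy()), index=profiles.index)
    if phenotype == "GSIDE":
        n_items = len(registry.general_items)
    elif phenotype in ("SEX", "AUTO", "NEURO", "CARDIO"):
        cluster = {v: k for k, v in
                   {"sexuality": "SEX", "autonomic": "AUTO",
                    "neurological": "NEURO", "cardio_vascular": "CARDIO"}.items()}[phenotype]
        n_items = len(registry.items_for(cluster))
    elif phenotype in registry.clusters:
        n_items = len(registry.items_for(phenotype))
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    strata = stratify_cluster(profiles[phenotype].to_numpy(), n_items)
    return pd.Series(severity_case(strata), index=profiles.index)


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    profiles: pd.DataFrame
    outcomes: pd.DataFrame
    vectors: pd.DataFrame
    diversity: pd.DataFrame
    screen: ScreenResult
    cv: CVReport
    labels: pd.Series
    qc_log: object = None


def run_pipeline(
    config: CohortConfig,
    phenotype: str = "GSIDE",
    day: float = 10,
    screen_config: ScreenConfig | None = None,
    nn_config: NNConfig | None = None,
    nn_inputs: str = "indicators",
    apply_qc: bool = True,
) -> PipelineResult:
    """Run the full synthetic-cohort analysis and return every intermediate.

    Seeds for screening and the network are derived from the cohort seed when
    not supplied explicitly.
    """
    cohort = simulate_cohort(config)
    profiles = score_profiles(cohort.medis, day=day)
    outcomes = build_outcomes(cohort.subjects, cohort.scale_scores, cohort.weights)

    gmat, qc_log = (
        qc_filter(cohort.genotypes) if apply_qc else (cohort.genotypes, None)
    )
    vectors = encode_gene_vectors(gmat)
    diversity = diversity_report(vectors, gmat)

    # align labels with the (possibly QC-reduced) subject set
    labels = phenotype_labels(profiles, phenotype).reindex(vectors.index)
    keep = labels.notna()
    vectors = vectors.loc[keep]
    labels = labels[keep].astype(bool)

    screen_config = screen_config or ScreenConfig(seed=config.seed)
    scr = screen_all(vectors, labels.to_numpy(), screen_config)

    nn_config = nn_config or NNConfig(seed=config.seed)
    if nn_inputs == "indicators" and (scr.table["patterns"].map(len) > 0).any():
        X = prepare_inputs(vectors, scr.gene_weights, mode="indicators",
                           screen_table=scr.table)
    else:
        m_per_gene = gmat.snp_map.groupby("gene_id")["k"].max()
        X = prepare_inputs(vectors, scr.gene_weights, mode="normalized",
                           snps_per_gene=m_per_gene)
    cv = cross_validate(X.to_numpy(), labels.to_numpy(), nn_config)

    return PipelineResult(
        cohort=cohort, profiles=profiles, outcomes=outcomes, vectors=vectors,
        diversity=diversity, screen=scr, cv=cv, labels=labels, qc_log=qc_log,
    )
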