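"""Clinical phenotype scoring for side-effect and outcome data.

Implements the quantitative side-effect model used throughout the pipeline:
the 46-item side-effect inventory is grouped into 9 named clusters; five of
them (25 items) form the unspecific *general* component, summarised by the
single sum score ``GSIDE``; the remaining four (21 items) are the
treatment-specific components ``SEX``, ``AUTO``, ``NEURO`` and ``CARDIO``.
The global score ``S`` (sum over all items) is stratified into five severity
bands, and the same cutpoints are applied to rescaled cluster scores.

Also provided: sustained-reduction response/onset classification on HAMD17 or
PANSSP series, baseline severity categories, and 3-week weight-change
classification with last-observation-carried-forward (LOCF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusterRegistry",
    "default_registry",
    "GENERAL_CLUSTERS",
    "SPECIFIC_CLUSTERS",
    "STRATA",
    "score_profiles",
    "stratify_severity",
    "stratify_cluster",
    "severity_case",
    "classify_response",
    "classify_baseline_severity",
    "weight_change",
    "build_outcomes",
    "locf_ratings",
]

#: cluster name -> number of inventory items
_CLUSTER_SIZES = {
    "sleep": 5,
    "appetite": 3,
    "sexuality": 3,
    "gastro_intestinal": 7,
    "cardiac_respiratory": 4,
    "autonomic": 5,
    "psychosomatic": 6,
    "neurological": 9,
    "cardio_vascular": 4,
}

#: clusters forming the unspecific general component (25 items, GSIDE)
GENERAL_CLUSTERS = (
    "sleep",
    "appetite",
    "gastro_intestinal",
    "cardiac_respiratory",
    "psychosomatic",
)

#: treatment-specific clusters (21 items) and their component names
SPECIFIC_CLUSTERS = {
    "sexuality": "SEX",
    "autonomic": "AUTO",
    "neurological": "NEURO",
    "cardio_vascular": "CARDIO",
}

#: severity strata in increasing order of severity
STRATA = ("none", "mild", "moderate", "severe", "very_severe")

#: global-score cutpoints: none <=10 < mild <=30 < moderate <=40 < severe <=50 < very_severe
_CUTPOINTS = (10.0, 30.0, 40.0, 50.0)

#: ratings are ordinal 0..4 (absent, mild, moderate, severe, very severe)
MAX_RATING = 4


@dataclass(frozen=True)
class ClusterRegistry:
    """Ordered mapping from cluster name to its item identifiers.

    The default registry names items ``<cluster>_<i>``; any registry with the
    stated per-cluster item counts is accepted.
    """

    clusters: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.clusters) != set(_CLUSTER_SIZES):
            raise ValueError("registry must define exactly the 9 named clusters")
        for name, items in self.clusters.items():
            if len(items) != _CLUSTER_SIZES[name]:
                raise ValueError(
                    f"cluster {name!r} must have {_CLUSTER_SIZES[name]} items, "
                    f"got {len(items)}"
                )
        all_items = [i for items in self.clusters.values() for i in items]
        if len(all_items) != len(set(all_items)):
            raise ValueError("items must partition the instrument (no duplicates)")

    @property
    def all_items(self) -> tuple[str, ...]:
        return tuple(i for items in self.clusters.values() for i in items)

    @property
    def n_items(self) -> int:
        return len(self.all_items)

    def items_for(self, cluster: str) -> tuple[str, ...]:
        return self.clusters[cluster]

    @property
    def general_items(self) -> tuple[str, ...]:
        return tuple(i for c in GENERAL_CLUSTERS for i in self.clusters[c])

    @property
    def specific_items(self) -> tuple[str, ...]:
        return tuple(i for c in SPECIFIC_CLUSTERS for i in self.clusters[c])

    def cluster_of(self, item: str) -> str:
        for name, items in self.clusters.items():
            if item in items:
                return name
        raise KeyError(f"unknown item id {item!r}")


def default_registry() -> ClusterRegistry:
    """Registry with systematically named items, e.g. ``sleep_1`` .. ``sleep_5``."""
    return ClusterRegistry(
        {
            name: tuple(f"{name}_{i}" for i in range(1, size + 1))
            for name, size in _CLUSTER_SIZES.items()
        }
    )


# ---------------------------------------------------------------------------
# severity stratification


def stratify_severity(s: float | np.ndarray) -> str | np.ndarray:
    """Map a global side-effect score S to its severity stratum.

    Cutpoints: S<=10 none; 10<S<=30 mild; 30<S<=40 moderate; 40<S<=50 severe;
    S>50 very severe. Vectorised over arrays.
    """
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0):
        raise ValueError("global score S must be non-negative")
    if arr.ndim == 0:
        return STRATA[int(np.searchsorted(np.asarray(_CUTPOINTS), float(arr), side="left"))]
    idx = np.searchsorted(np.asarray(_CUTPOINTS), arr, side="left")
    return np.asarray(STRATA, dtype=object)[idx]


def stratify_cluster(score: float | np.ndarray, n_items: int, n_total: int = 46) -> str | np.ndarray:
    """Stratify a cluster (or component) score with the global cutpoints.

    The printed cutpoints are calibrated to the full 46-item instrument, so a
    cluster score is rescaled by ``n_total / n_items`` before stratification.
    """
    if not 0 < n_items <= n_total:
        raise ValueError("n_items must be in (0, n_total]")
    return stratify_severity(np.asarray(score, dtype=float) * (n_total / n_items))


def severity_case(stratum: str | np.ndarray) -> bool | np.ndarray:
    """Moderate-to-severe dichotomy: True for {moderate, severe, very_severe}."""
    ranks = {name: i for i, name in enumerate(STRATA)}
    if isinstance(stratum, str):
        return ranks[stratum] >= ranks["moderate"]
    vec = np.vectorize(lambda s: ranks[s] >= ranks["moderate"])
    return vec(np.asarray(stratum, dtype=object))


# ---------------------------------------------------------------------------
# profile scoring


def locf_ratings(panel: pd.DataFrame, day: float) -> pd.DataFrame:
    """Return a subject x item rating table at ``day`` with LOCF fill-in.

    ``panel`` is long-format with columns ``subject_id, day, item_id, rating``.
    For each (subject, item) the rating at the largest observed day <= ``day``
    is used. Subjects with no assessment on or before ``day`` are dropped
    (callers may treat that as a missing-data error).
    """
    required = {"subject_id", "day", "item_id", "rating"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel needs columns {sorted(required)}")
    upto = panel[panel["day"] <= day]
    if upto.empty:
        raise ValueError(f"no assessments on or before day {day}")
    upto = upto.sort_values("day", kind="stable")
    last = upto.groupby(["subject_id", "item_id"], sort=False)["rating"].last()
    return last.unstack("item_id")


def score_profiles(
    panel: pd.DataFrame,
    registry: ClusterRegistry | None = None,
    day: float = 10,
) -> pd.DataFrame:
    """Compute per-subject side-effect profiles at an assessment day.

    Returns a DataFrame indexed by subject with one column per cluster score,
    plus ``S`` (global sum), ``GSIDE`` (general component, 25 items), the four
    specific components ``SEX, AUTO, NEURO, CARDIO``, and the global severity
    ``stratum``.

    Raises a schema error for unknown item ids and a ValueError for ratings
    outside the 0..4 ordinal scale.
    """
    registry = registry or default_registry()
    wide = locf_ratings(panel, day)
    unknown = set(wide.columns) - set(registry.all_items)
    if unknown:
        raise KeyError(f"unknown item ids in panel: {sorted(unknown)[:5]}")
    missing_items = set(registry.all_items) - set(wide.columns)
    if missing_items:
        raise ValueError(f"panel lacks items: {sorted(missing_items)[:5]}")
    wide = wide[list(registry.all_items)]
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)]
        raise ValueError(f"missing ratings after LOCF for subjects {list(bad)[:5]}")
    vals = wide.to_numpy()
    if ((vals < 0) | (vals > MAX_RATING)).any():
        raise ValueError("ratings must lie on the 0..4 ordinal scale")

    out = pd.DataFrame(index=wide.index)
    for name in _CLUSTER_SIZES:
        out[name] = wide[list(registry.items_for(name))].sum(axis=1).astype(int)
    out["S"] = out[list(_CLUSTER_SIZES)].sum(axis=1)
    out["GSIDE"] = out[list(GENERAL_CLUSTERS)].sum(axis=1)
    for cluster, comp in SPECIFIC_CLUSTERS.items():
        out[comp] = out[cluster]
    out["stratum"] = stratify_severity(out["S"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# response / onset classification

#: sustained fractional baseline reduction defining response, per scale
RESPONSE_FRACTION = {"HAMD17": 0.50, "PANSSP": 0.40}
ONSET_FRACTION = 0.20

#: study entry minima on the baseline scales
ENTRY_MINIMUM = {"HAMD17": 15, "PANSSG": 21}


def _sustained_day(days: np.ndarray, reductions: np.ndarray, threshold: float):
    """First day from which the reduction criterion holds through the last
    available assessment, or None."""
    ok = reductions >= threshold
    # last False blocks everything before it
    sustained_from = None
    for i in range(len(ok) - 1, -1, -1):
        if not ok[i]:
            break
        sustained_from = days[i]
    return sustained_from


@dataclass
class ResponseRecord:
    responder: bool
    onset: bool
    onset_day: float | None
    response_day: float | None
    baseline: float
    scale: str


def classify_response(
    days: Sequence[float],
    scores: Sequence[float],
    scale: str,
) -> ResponseRecord:
    """Classify response and onset of improvement from a score series.

    ``responder``: the scale-specific reduction (50% HAMD17 / 40% PANSSP of the
    baseline, the first assessment) is reached at some assessment and *sustained*,
    i.e. holds at every subsequent available assessment through the last one.
    ``onset``: same with a 20% reduction. A responder is always an onset case.
    """
    if scale not in RESPONSE_FRACTION:
        raise ValueError(f"scale must be one of {sorted(RESPONSE_FRACTION)}")
    days_a = np.asarray(days, dtype=float)
    scores_a = np.asarray(scores, dtype=float)
    if days_a.shape != scores_a.shape or days_a.size < 2:
        raise ValueError("need matching days/scores with baseline plus >=1 follow-up")
    if np.any(np.diff(days_a) <= 0):
        raise ValueError("days must be strictly increasing")
    baseline = scores_a[0]
    if baseline <= 0:
        raise ValueError("baseline score must be positive for relative reduction")
    red = (baseline - scores_a[1:]) / baseline
    follow_days = days_a[1:]
    resp_day = _sustained_day(follow_days, red, RESPONSE_FRACTION[scale])
    onset_day = _sustained_day(follow_days, red, ONSET_FRACTION)
    return ResponseRecord(
        responder=resp_day is not None,
        onset=onset_day is not None,
        onset_day=onset_day,
        response_day=resp_day,
        baseline=float(baseline),
        scale=scale,
    )


def classify_baseline_severity(score: float, scale: str) -> tuple[str, bool]:
    """Baseline severity category and an entry-criterion flag.

    HAMD17 (depression): <20 mild, 20-24 moderate, >24 severe; entry minimum 15.
    PANSSG (schizophrenia, general scale): <30 mild, 30-40 moderate, >40 severe;
    entry minimum 21. Scores below the entry minimum are categorised anyway and
    flagged rather than excluded.
    """
    if scale == "HAMD17":
        cat = "mild" if score < 20 else ("moderate" if score <= 24 else "severe")
    elif scale == "PANSSG":
        cat = "mild" if score < 30 else ("moderate" if score <= 40 else "severe")
    else:
        raise ValueError("scale must be 'HAMD17' or 'PANSSG'")
    return cat, bool(score >= ENTRY_MINIMUM[scale])


# ---------------------------------------------------------------------------
# weight change

WEIGHT_CLASSES = ("loss_ge_2", "stable", "gain_2_4", "gain_4_7.5", "gain_gt_7.5")


@dataclass
class WeightRecord:
    delta_kg: float
    weight_class: str
    locf_used: bool


def _classify_delta(delta: float) -> str:
    if delta <= -2:
        return "loss_ge_2"
    if abs(delta) < 2:
        return "stable"
    if delta <= 4:
        return "gain_2_4"
    if delta <= 7.5:
        return "gain_4_7.5"
    return "gain_gt_7.5"


def weight_change(
    days: Sequence[float],
    weights: Sequence[float],
    locf: bool = True,
) -> WeightRecord | None:
    """Weight change after 3 weeks with optional LOCF for early dropouts.

    ``delta`` = week-3 weight minus baseline (day 0). If week 3 (day 21) is
    missing and ``locf`` is set, the week-2 (day 14) weight is carried forward.
    Changes of >=2 kg in magnitude count as significant gain/loss; gains are
    binned [2,4], (4,7.5], >7.5 kg. Returns None when no usable post-baseline
    weight exists (caller logs the exclusion).
    """
    series = dict(zip(np.asarray(days, dtype=float), np.asarray(weights, dtype=float)))
    series = {d: w for d, w in series.items() if np.isfinite(w)}
    if 0 not in series:
        raise ValueError("baseline (day 0) weight required")
    baseline = series[0]
    if 21 in series:
        delta = series[21] - baseline
        used_locf = False
    elif locf and 14 in series:
        delta = series[14] - baseline
        used_locf = True
    else:
        return None
    return WeightRecord(float(delta), _classify_delta(delta), used_locf)


# ---------------------------------------------------------------------------
# cohort-level outcome assembly


def build_outcomes(
    subjects: pd.DataFrame,
    scale_scores: pd.DataFrame,
    weights: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-subject outcome table.

    ``subjects`` needs ``subject_id, diagnosis`` (F2/F3); ``scale_scores`` is
    long-format ``subject_id, day, score`` on the diagnosis-specific scale
    (PANSSP for F2, HAMD17 for F3); ``weights`` is long ``subject_id, day,
    weight_kg``. Subjects without a usable weight series get NaN weight fields;
    the exclusion reason is recorded.
    """
    rows = []
    scores_by_subj = dict(tuple(scale_scores.groupby("subject_id", sort=False)))
    weights_by_subj = dict(tuple(weights.groupby("subject_id", sort=False)))
    for rec in subjects.itertuples(index=False):
        sid = rec.subject_id
        scale = "PANSSP" if rec.diagnosis == "F2" else "HAMD17"
        base_scale = "PANSSG" if rec.diagnosis == "F2" else "HAMD17"
        row: dict = {"subject_id": sid, "scale": scale}
        grp = scores_by_subj.get(sid)
        if grp is not None and len(grp) >= 2:
            grp = grp.sort_values("day")
            resp = classify_response(grp["day"].to_numpy(), grp["score"].to_numpy(), scale)
            row.update(
                responder=resp.responder,
                onset=resp.onset,
                onset_day=resp.onset_day,
            )
            cat, entry_ok = classify_baseline_severity(resp.baseline, base_scale)
            row.update(baseline_severity=cat, entry_ok=entry_ok)
        else:
            row.update(
                responder=np.nan, onset=np.nan, onset_day=np.nan,
                baseline_severity=np.nan, entry_ok=np.nan,
            )
        wgrp = weights_by_subj.get(sid)
        wrec = None
        if wgrp is not None and (wgrp["day"] == 0).any():
            wrec = weight_change(wgrp["day"].to_numpy(), wgrp["weight_kg"].to_numpy())
        if wrec is None:
            row.update(
                weight_delta_kg=np.nan, weight_class=np.nan, weight_locf=np.nan,
                weight_excluded_reason="no post-baseline weight" if wgrp is not None else "no weights",
            )
        else:
            row.update(
                weight_delta_kg=wrec.delta_kg,
                weight_class=wrec.weight_class,
                weight_locf=wrec.locf_used,
                weight_excluded_reason="",
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
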