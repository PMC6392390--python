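"""Best-close-match species identification.

Every barcode in the dataset serves once as a query against all the others.
A query can only be identified when its nearest neighbour lies within a
threshold T — by default the empirical 95th percentile of all intraspecific
distances ("auto"). The species composition of the set of nearest matches
(ties resolved with a relative tolerance) yields a four-way verdict:

* correct       — every nearest match is conspecific with the query
* ambiguous     — the nearest matches include the query's species and others
* incorrect     — no nearest match is conspecific
* unidentified  — no database barcode lies within [0, T]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_model import TaxonLabel
from .distances import DistanceMatrix, DivergencePartition

CATEGORIES = ("correct", "ambiguous", "incorrect", "unidentified")


@dataclass(frozen=True)
class BCMConfig:
    threshold_T: float | str = "auto"
    percentile: float = 0.95
    tie_rel_tol: float = 1e-9

    def __post_init__(self) -> None:
        if isinstance(self.threshold_T, str) and self.threshold_T != "auto":
            raise ValueError("threshold_T must be a number or 'auto'")
        if not isinstance(self.threshold_T, str) and self.threshold_T < 0:
            raise ValueError("explicit threshold_T must be >= 0")
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")


@dataclass
class BCMRecordResult:
    query_id: str
    category: str
    min_distance: float | None
    match_ids: list[str] = field(default_factory=list)
    match_species: set[str] = field(default_factory=set)


@dataclass
class BCMSummary:
    counts: dict[str, int]
    percentages: dict[str, float]
    threshold_T: float
    n_queries: int


def _species_of(labels: Mapping[str, TaxonLabel | str], sid: str) -> str:
    lab = labels.get(sid)
    sp = lab.species if isinstance(lab, TaxonLabel) else lab
    if not sp:
        raise ValueError(f"specimen {sid!r} has no species label")
    return sp


def compute_threshold(p: DivergencePartition, percentile: float = 0.95) -> float:
    """Empirical intraspecific-distance quantile, no interpolation.

    T is the smallest intraspecific distance x such that at least
    ceil(percentile * n) of the n intraspecific distances are <= x.
    """
    values = sorted(v for _, v in p.intra)
    if not values:
        raise ValueError("no intraspecific distances: cannot derive a threshold")
    if not 0 < percentile <= 1:
        raise ValueError("percentile must be in (0, 1]")
    k = math.ceil(percentile * len(values))
    return values[k - 1]


def classify_query(
    query_id: str,
    m: DistanceMatrix,
    labels: Mapping[str, TaxonLabel | str],
    T: float,
    tie_rel_tol: float = 1e-9,
) -> BCMRecordResult:
    """Classify one query against every other barcode in the matrix."""
    qi = m.index(query_id)
    q_species = _species_of(labels, query_id)
    row = m.d[qi].copy()
    row[qi] = np.nan  # the query is not part of its own database
    defined = ~np.isnan(row)
    if not defined.any():
        return BCMRecordResult(query_id, "unidentified", None)
    d_min = float(row[defined].min())
    if d_min > T:
        return BCMRecordResult(query_id, "unidentified", d_min)
    cutoff = d_min * (1.0 + tie_rel_tol)
    match_idx = [j for j in np.nonzero(defined)[0] if row[j] <= cutoff]
    match_ids = [m.ids[j] for j in match_idx]
    match_species = {_species_of(labels, sid) for sid in match_ids}
    if match_species == {q_species}:
        category = "correct"
    elif q_species in match_species:
        category = "ambiguous"
    else:
        category = "incorrect"
    return BCMRecordResult(query_id, category, d_min, match_ids, match_species)


def best_close_match(
    m: DistanceMatrix,
    labels: Mapping[str, TaxonLabel | str],
    cfg: BCMConfig = BCMConfig(),
    partition: DivergencePartition | None = None,
) -> tuple[list[BCMRecordResult], BCMSummary]:
    """Run the identification test with every barcode as query.

    The dataset is expected to be pre-filtered to species with >= 2
    representatives (otherwise conspecific matches cannot exist). When
    ``cfg.threshold_T`` is "auto" the threshold is the intraspecific-distance
    percentile of this matrix's own partition (computed here unless supplied).
    """
    if cfg.threshold_T == "auto":
        if partition is None:
            from .distances import partition_divergences

            partition = partition_divergences(m, labels)
        T = compute_threshold(partition, cfg.percentile)
    else:
        T = float(cfg.threshold_T)  # type: ignore[arg-type]
    results = [
        classify_query(sid, m, labels, T, cfg.tie_rel_tol) for sid in m.ids
    ]
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.category] += 1
    n = len(results)
    percentages = {c: 100.0 * counts[c] / n for c in CATEGORIES} if n else {}
    return results, BCMSummary(counts, percentages, T, n)
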