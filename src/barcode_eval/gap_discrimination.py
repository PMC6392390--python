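"""Barcoding-gap analysis and per-species discrimination scoring.

A (global) barcoding gap exists when the minimum interspecific divergence
exceeds the maximum intraspecific divergence. Discrimination is scored per
species with the analogous local criterion: a species is discriminated when
its largest conspecific distance is strictly smaller than the smallest
distance from any of its members to any heterospecific member. A species
sharing an identical barcode with another species necessarily fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import TaxonLabel
from .distances import DistanceMatrix, DivergencePartition


@dataclass
class GapReport:
    max_intra: float
    min_inter: float
    gap_present: bool
    overlap_interval: tuple[float, float] | None  # (min_inter, max_intra) when no gap
    mean_intra: float
    mean_inter: float
    range_intra: tuple[float, float]
    range_inter: tuple[float, float]


@dataclass
class DiscriminationReport:
    per_species: dict[str, bool]
    unassessable: list[str] = field(default_factory=list)

    @property
    def n_discriminated(self) -> int:
        return sum(self.per_species.values())

    @property
    def n_assessed(self) -> int:
        return len(self.per_species)

    @property
    def percent(self) -> float:
        return 100.0 * self.n_discriminated / self.n_assessed if self.per_species else 0.0


def divergence_histogram(p: DivergencePartition, bin_width: float = 0.01) -> pd.DataFrame:
    """Frequency (%) distribution of intra- and interspecific divergences.

    Half-open bins [k*w, (k+1)*w) on a grid shared by both classes;
    frequencies are normalized to percent within each class. Returns columns
    (class, bin_low, bin_high, percent).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    intra, inter = p.intra_values, p.inter_values
    if intra.size == 0 and inter.size == 0:
        raise ValueError("empty divergence partition")
    top = max(intra.max(initial=0.0), inter.max(initial=0.0))
    n_bins = int(math.floor(top / bin_width)) + 1
    rows = []
    for cls, values in (("intra", intra), ("inter", inter)):
        if values.size == 0:
            continue
        idx = np.floor(values / bin_width).astype(int)
        counts = np.bincount(idx, minlength=n_bins)
        for k in range(n_bins):
            rows.append(
                {
                    "class": cls,
                    "bin_low": k * bin_width,
                    "bin_high": (k + 1) * bin_width,
                    "percent": 100.0 * counts[k] / values.size,
                }
            )
    return pd.DataFrame(rows, columns=["class", "bin_low", "bin_high", "percent"])


def barcoding_gap_test(p: DivergencePartition) -> GapReport:
    """Global gap test plus the class summaries used in the gap narrative."""
    intra, inter = p.intra_values, p.inter_values
    if intra.size == 0 or inter.size == 0:
        raise ValueError("both intra- and interspecific distances are required")
    max_intra, min_inter = float(intra.max()), float(inter.min())
    gap = min_inter > max_intra
    return GapReport(
        max_intra=max_intra,
        min_inter=min_inter,
        gap_present=gap,
        overlap_interval=None if gap else (min_inter, max_intra),
        mean_intra=float(intra.mean()),
        mean_inter=float(inter.mean()),
        range_intra=(float(intra.min()), max_intra),
        range_inter=(min_inter, float(inter.max())),
    )


def species_discrimination(
    m: DistanceMatrix, labels: Mapping[str, TaxonLabel | str]
) -> DiscriminationReport:
    """Local-gap discrimination verdict for every species in the matrix.

    Requires every species to have >= 2 specimens (filter first). Undefined
    distances are ignored; a species with no defined heterospecific distance
    is reported unassessable and excluded from the percentage denominator.
    """
    species: list[str] = []
    for sid in m.ids:
        lab = labels.get(sid)
        sp = lab.species if isinstance(lab, TaxonLabel) else lab
        if not sp:
            raise ValueError(f"specimen {sid!r} has no species label")
        species.append(sp)
    sp_arr = np.array(species)
    uniq, counts = np.unique(sp_arr, return_counts=True)
    singletons = uniq[counts < 2]
    if singletons.size:
        raise ValueError(
            f"singleton species present (e.g. {singletons[0]!r}); "
            "apply filter_min_representatives(k=2) first"
        )
    per_species: dict[str, bool] = {}
    unassessable: list[str] = []
    for sp in uniq:
        mask = sp_arr == sp
        intra_block = m.d[np.ix_(mask, mask)]
        iu = np.triu_indices(int(mask.sum()), k=1)
        intra_vals = intra_block[iu]
        intra_vals = intra_vals[~np.isnan(intra_vals)]
        inter_block = m.d[np.ix_(mask, ~mask)].ravel()
        inter_vals = inter_block[~np.isnan(inter_block)]
        if inter_vals.size == 0 or intra_vals.size == 0:
            unassessable.append(str(sp))
            continue
        per_species[str(sp)] = bool(intra_vals.max() < inter_vals.min())
    return DiscriminationReport(per_species=per_species, unassessable=unassessable)
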