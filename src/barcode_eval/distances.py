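"""Pairwise divergence engine.

Implements the p-distance and the Tamura-Nei (1993) distance with an optional
continuous-gamma rate correction, assembled into symmetric specimen-by-specimen
matrices under pairwise deletion of gap/missing sites, plus the partition of
distances into intra- and interspecific sets and the two significance tests
used downstream (Welch's unpaired t-test, one-way ANOVA).

The TN93 estimator distinguishes purine transitions (A<->G, proportion P1),
pyrimidine transitions (C<->T, proportion P2) and transversions (Q), with base
frequencies estimated empirically from the two sequences of each pair:

    d = k1 * h(w1) + k2 * h(w2) + k3 * h(w3)

where, with pi_R = pi_A + pi_G and pi_Y = pi_C + pi_T,

    k1 = 2 pi_A pi_G / pi_R
    k2 = 2 pi_C pi_T / pi_Y
    k3 = 2 (pi_R pi_Y - pi_A pi_G pi_Y / pi_R - pi_C pi_T pi_R / pi_Y)
    w1 = 1 - P1/k1 - Q/(2 pi_R)
    w2 = 1 - P2/k2 - Q/(2 pi_Y)
    w3 = 1 - Q/(2 pi_R pi_Y)

and h(w) = -ln(w) without rate variation, or h(w) = a (w^(-1/a) - 1) under a
gamma(a) distribution of relative rates across sites. Any non-positive
logarithm/power argument makes the estimator undefined for that pair; such
pairs are flagged, never truncated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import LocusAlignment, TaxonLabel

# Encoding: A=0, C=1, G=2, T=3, anything gap/missing = 255.
_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a gapped nucleotide string to uint8 codes (255 = excluded site)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairCounts:
    """Site-pattern summary for one sequence pair after pairwise deletion."""

    n_sites: int
    P1: float  # purine transitions A<->G, fraction of n_sites
    P2: float  # pyrimidine transitions C<->T
    Q: float  # transversions
    freqs: tuple[float, float, float, float]  # pi_A, pi_C, pi_G, pi_T


@dataclass(frozen=True)
class DistanceModelParams:
    model: str = "tn93"  # "p" or "tn93"
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        if self.model not in ("p", "tn93"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.gamma_shape is not None:
            if self.model != "tn93":
                raise ValueError("gamma_shape is only meaningful for tn93")
            if self.gamma_shape <= 0:
                raise ValueError("gamma_shape must be positive")


def pair_counts(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> PairCounts:
    """Count transition/transversion fractions for one pair.

    Sites where either sequence has a gap ('-') or missing character ('N','?')
    are excluded (pairwise deletion). Base frequencies are pooled over both
    sequences at the included sites.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError("sequences have unequal length")
    ok = (a != 255) & (b != 255)
    n = int(ok.sum())
    if n == 0:
        return PairCounts(0, 0.0, 0.0, 0.0, (0.25, 0.25, 0.25, 0.25))
    av, bv = a[ok], b[ok]
    diff = av != bv
    # purines {A=0, G=2}, pyrimidines {C=1, T=3}: codes differ by 2 for
    # transitions, and parity distinguishes the two transition types.
    pur_a, pur_b = av % 2 == 0, bv % 2 == 0
    trans = diff & (pur_a == pur_b)
    p1 = int((trans & pur_a).sum())
    p2 = int((trans & ~pur_a).sum())
    q = int(diff.sum()) - p1 - p2
    counts = np.bincount(av, minlength=4)[:4] + np.bincount(bv, minlength=4)[:4]
    freqs = tuple((counts / (2 * n)).tolist())
    return PairCounts(n, p1 / n, p2 / n, q / n, freqs)  # type: ignore[arg-type]


def _h(w: float, gamma_shape: float | None) -> float:
    """-ln(w), or its gamma-rates analogue a*(w^(-1/a) - 1)."""
    if gamma_shape is None:
        return -math.log(w)
    a = gamma_shape
    return a * (w ** (-1.0 / a) - 1.0)


def p_distance(c: PairCounts) -> float | None:
    if c.n_sites == 0:
        return None
    return c.P1 + c.P2 + c.Q


def tn93_distance(c: PairCounts, params: DistanceModelParams | None = None) -> float | None:
    """Tamura-Nei (1993) distance from pair counts; None when undefined.

    Undefined means an out-of-range estimator argument (saturation) or a
    degenerate base composition incompatible with the observed differences.
    """
    params = params or DistanceModelParams()
    if c.n_sites == 0:
        return None
    if c.P1 == 0.0 and c.P2 == 0.0 and c.Q == 0.0:
        return 0.0
    pa, pc, pg, pt = c.freqs
    pr, py = pa + pg, pc + pt
    g = params.gamma_shape
    d = 0.0

    k1 = 2.0 * pa * pg / pr if pr > 0 else 0.0
    k2 = 2.0 * pc * pt / py if py > 0 else 0.0
    if k1 > 0:
        w1 = 1.0 - c.P1 / k1 - c.Q / (2.0 * pr)
        if w1 <= 0:
            return None
        d += k1 * _h(w1, g)
    elif c.P1 > 0:
        return None
    if k2 > 0:
        w2 = 1.0 - c.P2 / k2 - c.Q / (2.0 * py)
        if w2 <= 0:
            return None
        d += k2 * _h(w2, g)
    elif c.P2 > 0:
        return None
    if pr > 0 and py > 0:
        k3 = 2.0 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
        w3 = 1.0 - c.Q / (2.0 * pr * py)
        if w3 <= 0:
            return None
        d += k3 * _h(w3, g)
    elif c.Q > 0:
        return None
    return d


def pairwise_distance(
    seq_a: str | np.ndarray, seq_b: str | np.ndarray, params: DistanceModelParams
) -> float | None:
    c = pair_counts(seq_a, seq_b)
    return p_distance(c) if params.model == "p" else tn93_distance(c, params)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise divergence matrix; NaN marks undefined entries."""

    ids: list[str]
    d: np.ndarray  # (n, n) float64, zero diagonal, NaN where undefined
    params: DistanceModelParams

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, specimen_id: str) -> int:
        try:
            return self.ids.index(specimen_id)
        except ValueError:
            raise KeyError(f"specimen {specimen_id!r} not in distance matrix") from None

    def get(self, id_a: str, id_b: str) -> float:
        """Distance between two specimens (NaN when undefined)."""
        return float(self.d[self.index(id_a), self.index(id_b)])

    def n_undefined(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.d[iu]).sum())

    def submatrix(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in keep_ids]
        return DistanceMatrix(list(keep_ids), self.d[np.ix_(idx, idx)].copy(), self.params)

    def to_long_table(self):
        import pandas as pd

        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                v = self.d[i, j]
                rows.append(
                    {
                        "id_a": self.ids[i],
                        "id_b": self.ids[j],
                        "distance": v if not np.isnan(v) else "",
                        "defined": int(not np.isnan(v)),
                    }
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "distance", "defined"])

    def to_phylip(self) -> str:
        """Lower-triangular PHYLIP-style text (undefined entries as 'NA')."""
        lines = [f"{self.n}"]
        for i, sid in enumerate(self.ids):
            vals = []
            for j in range(i):
                v = self.d[i, j]
                vals.append("NA" if np.isnan(v) else f"{v:.8f}")
            lines.append("\t".join([sid] + vals))
        return "\n".join(lines) + "\n"


def _tn93_vectorized(
    n_sites: np.ndarray,
    P1: np.ndarray,
    P2: np.ndarray,
    Q: np.ndarray,
    freqs: np.ndarray,
    params: DistanceModelParams,
) -> np.ndarray:
    """Vectorized TN93 over arrays of pair counts; NaN where undefined.

    Mirrors :func:`tn93_distance` exactly (same guards, same gamma form).
    """
    pa, pc, pg, pt = (freqs[..., k] for k in range(4))
    pr, py = pa + pg, pc + pt
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = np.where(pr > 0, 2 * pa * pg / pr, 0.0)
        k2 = np.where(py > 0, 2 * pc * pt / py, 0.0)
        k3 = np.where(
            (pr > 0) & (py > 0),
            2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py),
            0.0,
        )
        w1 = np.where(k1 > 0, 1.0 - P1 / np.where(k1 > 0, k1, 1.0) - Q / (2 * pr), 1.0)
        w2 = np.where(k2 > 0, 1.0 - P2 / np.where(k2 > 0, k2, 1.0) - Q / (2 * py), 1.0)
        prpy = pr * py
        w3 = np.where(prpy > 0, 1.0 - Q / (2 * np.where(prpy > 0, prpy, 1.0)), 1.0)
        g = params.gamma_shape
        if g is None:
            h1, h2, h3 = -np.log(w1), -np.log(w2), -np.log(w3)
        else:
            h1 = g * (w1 ** (-1.0 / g) - 1.0)
            h2 = g * (w2 ** (-1.0 / g) - 1.0)
            h3 = g * (w3 ** (-1.0 / g) - 1.0)
        d = k1 * h1 + k2 * h2 + k3 * h3
    bad = (
        (n_sites == 0)
        | ((k1 > 0) & (w1 <= 0))
        | ((k1 == 0) & (P1 > 0))
        | ((k2 > 0) & (w2 <= 0))
        | ((k2 == 0) & (P2 > 0))
        | ((prpy > 0) & (w3 <= 0))
        | ((prpy == 0) & (Q > 0))
    )
    d = np.where(bad, np.nan, d)
    return np.where((P1 == 0) & (P2 == 0) & (Q == 0) & (n_sites > 0), 0.0, d)


def distance_matrix_from_codes(codes: np.ndarray, ids: Sequence[str], params: DistanceModelParams) -> DistanceMatrix:
    """All-pairs distances from an (n, L) uint8 code matrix (255 = excluded)."""
    n = codes.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    d = np.zeros((n, n))
    for i in range(n - 1):
        a = codes[i]
        B = codes[i + 1:]
        ok = (a != 255) & (B != 255)
        ns = ok.sum(axis=1)
        diff = (a != B) & ok
        pur_a = a % 2 == 0
        trans = diff & ((pur_a[None, :]) == (B % 2 == 0))
        p1 = (trans & pur_a[None, :]).sum(axis=1)
        p2 = trans.sum(axis=1) - p1
        q = diff.sum(axis=1) - p1 - p2
        base_counts = np.stack(
            [((a == k) & ok).sum(axis=1) + ((B == k) & ok).sum(axis=1) for k in range(4)],
            axis=-1,
        ).astype(float)
        denom = np.where(ns > 0, 2.0 * ns, 1.0)
        freqs = base_counts / denom[:, None]
        safe_ns = np.where(ns > 0, ns, 1)
        if params.model == "p":
            row = np.where(ns > 0, diff.sum(axis=1) / safe_ns, np.nan)
        else:
            row = _tn93_vectorized(
                ns, p1 / safe_ns, p2 / safe_ns, q / safe_ns, freqs, params
            )
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return DistanceMatrix(ids=list(ids), d=d, params=params)


def distance_matrix(aln: LocusAlignment, params: DistanceModelParams) -> DistanceMatrix:
    """All-pairs distances for an alignment under ``params``."""
    if len(aln.members) < 2:
        raise ValueError("need at least 2 sequences")
    codes = np.vstack([encode_sequence(seq) for _, seq in aln.members])
    return distance_matrix_from_codes(codes, aln.ids, params)


@dataclass
class DivergencePartition:
    """Intra- vs interspecific split of the defined off-diagonal distances."""

    intra: list[tuple[str, float]]  # (species, distance)
    inter: list[tuple[str, str, float]]  # (species_i, species_j, distance)

    @property
    def intra_values(self) -> np.ndarray:
        return np.array([v for _, v in self.intra], dtype=float)

    @property
    def inter_values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.inter], dtype=float)


def partition_divergences(
    m: DistanceMatrix, labels: Mapping[str, TaxonLabel | str]
) -> DivergencePartition:
    """Split defined pairwise distances into intra- and interspecific sets."""
    species: list[str] = []
    for sid in m.ids:
        lab = labels.get(sid)
        sp = lab.species if isinstance(lab, TaxonLabel) else lab
        if not sp:
            raise ValueError(f"specimen {sid!r} has no species label")
        species.append(sp)
    intra: list[tuple[str, float]] = []
    inter: list[tuple[str, str, float]] = []
    for i in range(m.n):
        for j in range(i + 1, m.n):
            v = m.d[i, j]
            if np.isnan(v):
                continue
            if species[i] == species[j]:
                intra.append((species[i], float(v)))
            else:
                inter.append((species[i], species[j], float(v)))
    return DivergencePartition(intra=intra, inter=inter)


# ---------------------------------------------------------------------------
# Significance tests
# ---------------------------------------------------------------------------

def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: (F, df_between, df_within, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    if all(g.var(ddof=1) == 0 for g in arrays):
        raise ValueError("all within-group variances are zero")
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    return float(f), k - 1, n - k, float(p)
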