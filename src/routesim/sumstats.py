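"""Summary statistics of population lineage-frequency samples.

Twelve statistics summarise a set of population samples: mean/SD of the
lineage count, mean/SD of gene diversity overall and separately in the
northern (NEA) and southern (SEA) groups, the Pearson correlation of gene
diversity with latitude, and the three hierarchical F-statistics of an
allele-identity AMOVA (F_ST, F_CT, F_SC) with NEA/SEA as the grouping.
An optional 13th statistic is the absolute correlation between the first
principal coordinate of the pairwise-F_ST matrix and latitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PopulationSample",
    "StatVector",
    "STAT_NAMES",
    "gene_diversity",
    "lineage_count",
    "amova",
    "pairwise_fst",
    "pcoa_first_coordinate",
    "compute_stats",
]

STAT_NAMES = [
    "M_A", "SD_A", "M_H", "SD_H",
    "M_H_north", "SD_H_north", "M_H_south", "SD_H_south",
    "R_H_lat", "F_ST", "F_CT", "F_SC",
]
PCOA_STAT = "R_coord1_lat"


@dataclass
class PopulationSample:
    """Gene-copy counts per lineage for one sampled population."""

    id: str
    latitude: float
    group: str  # "NEA" or "SEA"
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError(f"population {self.id!r}: negative counts")
        if self.n_copies < 2:
            raise ValueError(f"population {self.id!r}: fewer than 2 gene copies")
        if self.group not in ("NEA", "SEA"):
            raise ValueError(f"population {self.id!r}: group must be NEA or SEA")

    @property
    def n_copies(self) -> int:
        return int(self.counts.sum())


@dataclass
class StatVector:
    """Named summary-statistic vector in fixed column order."""

    values: dict[str, float] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or self.names
        return np.array([self.values[n] for n in names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def gene_diversity(counts) -> float:
    """Nei's unbiased gene diversity H = n/(n-1) * (1 - sum p_i^2)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("gene diversity needs at least 2 gene copies")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.square(p).sum()))


def lineage_count(counts) -> int:
    """Number of lineages observed at least once."""
    return int((np.asarray(counts) > 0).sum())


def _ssd(pooled_counts: np.ndarray) -> float:
    """Sum of squared deviations of a pool of gene copies under the
    0/1 allele-identity distance: SSD = (n - sum c_i^2 / n) / 2."""
    n = pooled_counts.sum()
    if n == 0:
        return 0.0
    return float(n - np.square(pooled_counts).sum() / n) / 2.0


def amova(samples: list[PopulationSample], floor_negative: bool = True):
    """Hierarchical allele-identity AMOVA with the NEA/SEA grouping.

    Partitions the total variance of the 0/1 identity distance between
    gene copies into among-group (sigma_a), among-population-within-group
    (sigma_b) and within-population (sigma_c) components, with the
    standard unequal-sample-size coefficients, and returns

    ``F_CT = sigma_a / total``, ``F_SC = sigma_b / (sigma_b + sigma_c)``,
    ``F_ST = (sigma_a + sigma_b) / total``

    as ``(F_ST, F_CT, F_SC)``.  Negative variance components are floored
    at zero before the ratios (so 1-F_ST = (1-F_CT)(1-F_SC) holds exactly).
    """
    groups: dict[str, list[PopulationSample]] = {}
    for s in samples:
        groups.setdefault(s.group, []).append(s)
    if len(groups) != 2:
        raise ValueError("AMOVA needs exactly 2 groups (NEA and SEA)")
    for gname, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {gname!r} has fewer than 2 populations")
    L = max(len(s.counts) for s in samples)
    X = np.zeros((len(samples), L))
    sizes = np.zeros(len(samples))
    glabel = []
    for i, s in enumerate(samples):
        X[i, : len(s.counts)] = s.counts
        sizes[i] = s.n_copies
        glabel.append(s.group)
    glabel = np.array(glabel)
    gnames = sorted(groups)
    N = sizes.sum()
    P = len(samples)
    G = len(gnames)

    ssd_wp = sum(_ssd(X[i]) for i in range(P))
    ssd_wg = 0.0
    group_sizes = {}
    sum_nsq_over_group = 0.0
    for g in gnames:
        mask = glabel == g
        group_sizes[g] = sizes[mask].sum()
        sum_nsq_over_group += np.square(sizes[mask]).sum() / group_sizes[g]
        ssd_wg += _ssd(X[mask].sum(axis=0))
    ssd_total = _ssd(X.sum(axis=0))
    ssd_ag = ssd_total - ssd_wg
    ssd_ap_wg = ssd_wg - ssd_wp

    df_c, df_b, df_a = N - P, P - G, G - 1
    ms_c = ssd_wp / df_c
    ms_b = ssd_ap_wg / df_b
    ms_a = ssd_ag / df_a

    n1 = (N - sum_nsq_over_group) / df_b
    n2 = (sum_nsq_over_group - np.square(sizes).sum() / N) / df_a
    n3 = (N - sum(v * v for v in group_sizes.values()) / N) / df_a

    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / n1
    sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    if floor_negative:
        sigma_a, sigma_b, sigma_c = (max(0.0, v) for v in (sigma_a, sigma_b, sigma_c))
    total = sigma_a + sigma_b + sigma_c
    if total == 0:
        return 0.0, 0.0, 0.0
    f_ct = sigma_a / total
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0
    f_st = (sigma_a + sigma_b) / total
    return float(f_st), float(f_ct), float(f_sc)


def _two_level_fst(counts_a: np.ndarray, counts_b: np.ndarray, n_a: float, n_b: float) -> float:
    """Two-population allele-identity AMOVA F_ST, floored at zero."""
    N = n_a + n_b
    ssd_wp = _ssd(counts_a) + _ssd(counts_b)
    ssd_total = _ssd(counts_a + counts_b)
    df_w = N - 2
    if df_w <= 0:
        return 0.0
    ms_w = ssd_wp / df_w
    ms_a = (ssd_total - ssd_wp) / 1.0
    n_c = (N - (n_a * n_a + n_b * n_b) / N) / 1.0
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_c
    if sigma_a < 0:
        sigma_a = 0.0
    tot = sigma_a + sigma_w
    return float(sigma_a / tot) if tot > 0 else 0.0


def pairwise_fst(samples: list[PopulationSample]) -> np.ndarray:
    """Symmetric matrix of two-population AMOVA F_ST values (zero diagonal)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 populations")
    L = max(len(s.counts) for s in samples)
    X = np.zeros((len(samples), L))
    for i, s in enumerate(samples):
        X[i, : len(s.counts)] = s.counts
    n = X.sum(axis=1)
    P = len(samples)
    D = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            D[i, j] = D[j, i] = _two_level_fst(X[i], X[j], n[i], n[j])
    return D


def pcoa_first_coordinate(D: np.ndarray) -> np.ndarray:
    """First principal coordinate of a distance matrix.

    Classical metric scaling: double-center ``-0.5 * D*D``, take the
    leading eigenvector scaled by the square root of its eigenvalue.  The
    sign is arbitrary; an all-zero matrix yields the zero vector.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    B = -0.5 * D * D
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ B @ J
    evals, evecs = np.linalg.eigh(B)
    lead = evals[-1]
    if lead <= 0:
        return np.zeros(n)
    return evecs[:, -1] * math.sqrt(lead)


def compute_stats(samples: list[PopulationSample], include_pcoa: bool = False) -> StatVector:
    """Compute the 12 named summary statistics (optionally + PCoA one).

    Means and SDs are the arithmetic mean and the sample standard
    deviation (ddof=1); the diversity-latitude statistic is the Pearson
    correlation.  If gene diversity has zero variance across populations
    the correlation is undefined and recorded as NaN.
    """
    if len(samples) < 4:
        raise ValueError("need at least 2 populations per group")
    a = np.array([lineage_count(s.counts) for s in samples], dtype=float)
    h = np.array([gene_diversity(s.counts) for s in samples])
    lat = np.array([s.latitude for s in samples])
    north = np.array([s.group == "NEA" for s in samples])
    if north.sum() < 2 or (~north).sum() < 2:
        raise ValueError("need at least 2 populations per group")

    if np.ptp(h) > 0 and np.ptp(lat) > 0:
        r_h_lat = float(sps.pearsonr(h, lat)[0])
    else:
        r_h_lat = math.nan
    f_st, f_ct, f_sc = amova(samples)
    vals = {
        "M_A": float(a.mean()),
        "SD_A": float(a.std(ddof=1)),
        "M_H": float(h.mean()),
        "SD_H": float(h.std(ddof=1)),
        "M_H_north": float(h[north].mean()),
        "SD_H_north": float(h[north].std(ddof=1)),
        "M_H_south": float(h[~north].mean()),
        "SD_H_south": float(h[~north].std(ddof=1)),
        "R_H_lat": r_h_lat,
        "F_ST": f_st,
        "F_CT": f_ct,
        "F_SC": f_sc,
    }
    if include_pcoa:
        coord1 = pcoa_first_coordinate(pairwise_fst(samples))
        if np.ptp(coord1) > 0 and np.ptp(lat) > 0:
            vals[PCOA_STAT] = abs(float(sps.pearsonr(coord1, lat)[0]))
        else:
            vals[PCOA_STAT] = math.nan
    return StatVector(vals)
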