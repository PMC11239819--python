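"""Cell-type-specificity analysis of the merged allele-frequency table.

Two complementary strategies identify variants over-represented in the
manufactured cell stages (iPS cells and/or iSCs) relative to the parental
fibroblasts:

1. **k-means on AF vectors.**  Every variant X is encoded as the triple
   AF_X = (AF_fibro, AF_ipsc, AF_isc) and clustered with Lloyd's algorithm
   (seeded, max 1000 iterations).  Clusters whose centroid shows low
   fibroblast AF but elevated iPSC *and* iSC AF carry the
   manufacturing-associated pattern; scanning k = 3..9 and taking the
   smallest k exhibiting such a cluster mirrors the published protocol.

2. **AF/odds-ratio cutoff filtering.**  The odds ratio
   OR(a, b) = a(1-b) / (b(1-a)) measures over-representation of the mutant
   allele in one cell type versus another; fixed AF (0.25) and OR (2.0)
   cutoffs, applied as three conjunctive filter blocks, label each variant
   SHARED_IPSC_ISC, IPSC_ONLY, ISC_ONLY or NONE.

Concordance between the two strategies, and cross-patient overlap of the
specific variants, are the safety readouts: high concordance plus absent
cross-patient sharing argues against positive selection of
manufacturing-induced variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import VariantKey, table_keys

SHARED_IPSC_ISC = "SHARED_IPSC_ISC"
IPSC_ONLY = "IPSC_ONLY"
ISC_ONLY = "ISC_ONLY"
NONE = "NONE"

DEFAULT_AF_THRESHOLD = 0.25
DEFAULT_OR_THRESHOLD = 2.0
DEFAULT_EPSILON = 1e-3


@dataclass
class ClusteringConfig:
    k: int
    seed: int = 0
    max_iter: int = 1000
    k_scan_range: tuple[int, int] = (3, 9)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ClusteringResult:
    k: int
    assignments: np.ndarray          # (n,) cluster index per variant
    centroids: np.ndarray            # (k, 3)
    sizes: np.ndarray                # (k,)
    flagged_clusters: set[int] = field(default_factory=set)
    inertia_history: list[float] = field(default_factory=list)

    @property
    def inertia(self) -> float:
        return self.inertia_history[-1] if self.inertia_history else float("nan")


@dataclass
class SpecificityCall:
    key: VariantKey
    label: str
    odds_ratios: dict[str, float]
    af_threshold: float = DEFAULT_AF_THRESHOLD
    or_threshold: float = DEFAULT_OR_THRESHOLD


def build_af_matrix(table: pd.DataFrame) -> np.ndarray:
    """The n x 3 AF matrix (fibro, iPSC, iSC) in merged-table row order."""
    mat = table[["af_fibro", "af_ipsc", "af_isc"]].to_numpy(dtype=float)
    if mat.size and ((mat < 0) | (mat > 1)).any():
        bad = int(np.argwhere((mat < 0) | (mat > 1))[0][0])
        row = table.iloc[bad]
        raise ValueError(
            f"AF out of [0,1] for variant {row.chrom}:{row.pos} {row.ref}>{row.alt}")
    return mat.reshape(-1, 3)


def kmeans_af(matrix: np.ndarray, config: ClusteringConfig) -> ClusteringResult:
    """Lloyd k-means on AF vectors with seeded random-partition initiation.

    Each row starts in a uniformly random cluster, then Lloyd iterations
    alternate centroid means and nearest-centroid (Euclidean) reassignment
    until a fixpoint or ``max_iter``.  Nearest-centroid ties break to the
    lowest cluster index; an emptied cluster is repaired by moving in the
    point currently farthest from its own centroid.  Deterministic for a
    fixed seed.
    """
    n = matrix.shape[0]
    k = config.k
    if n == 0:
        raise ValueError("cannot cluster an empty AF matrix")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")

    rng = np.random.default_rng(config.seed)
    assignments = rng.integers(0, k, size=n)
    centroids = np.zeros((k, 3))
    history: list[float] = []

    for _ in range(config.max_iter):
        for j in range(k):
            members = assignments == j
            if members.any():
                centroids[j] = matrix[members].mean(axis=0)
            # an initially empty cluster keeps its previous centroid and is
            # repaired after reassignment below
        d2 = ((matrix[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assignments = d2.argmin(axis=1)  # argmin takes the lowest index on ties

        for j in range(k):
            if not (new_assignments == j).any():
                own = d2[np.arange(n), new_assignments]
                donor = int(own.argmax())
                new_assignments[donor] = j
                d2[donor] = np.inf  # exclude from further donation this round
                d2[donor, j] = float(((matrix[donor] - centroids[j]) ** 2).sum())

        history.append(float(d2[np.arange(n), new_assignments].sum()))
        if (new_assignments == assignments).all():
            assignments = new_assignments
            break
        assignments = new_assignments

    for j in range(k):
        members = assignments == j
        if members.any():
            centroids[j] = matrix[members].mean(axis=0)
    sizes = np.bincount(assignments, minlength=k)
    inertia = float(((matrix - centroids[assignments]) ** 2).sum())
    history.append(inertia)
    return ClusteringResult(k=k, assignments=assignments, centroids=centroids,
                            sizes=sizes, inertia_history=history)


def flag_specific_clusters(result: ClusteringResult,
                           af_threshold: float = DEFAULT_AF_THRESHOLD) -> set[int]:
    """Clusters with the shared iPSC/iSC-specific centroid pattern.

    Flagged iff centroid fibro AF < threshold while both iPSC and iSC AF
    exceed it — the pattern the published analysis identifies visually,
    aligned here with the filter-block cutoffs.
    """
    flagged = {
        j for j in range(result.k)
        if result.sizes[j] > 0
        and result.centroids[j, 0] < af_threshold
        and result.centroids[j, 1] > af_threshold
        and result.centroids[j, 2] > af_threshold
    }
    result.flagged_clusters = flagged
    return flagged


def scan_k(matrix: np.ndarray, seed: int = 0,
           k_range: tuple[int, int] = (3, 9),
           af_threshold: float = DEFAULT_AF_THRESHOLD,
           max_iter: int = 1000) -> ClusteringResult | None:
    """Scan k over ``k_range`` and return the smallest-k clustering with a
    flagged shared-specific cluster, or None if no k exhibits the pattern."""
    lo, hi = k_range
    for k in range(lo, hi + 1):
        if k > matrix.shape[0]:
            break
        result = kmeans_af(matrix, ClusteringConfig(k=k, seed=seed, max_iter=max_iter))
        if flag_specific_clusters(result, af_threshold):
            return result
    return None


def odds_ratio(af_num: float, af_den: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Over-representation odds ratio a(1-b) / (b(1-a)) with AFs clamped into
    [epsilon, 1-epsilon] so boundary frequencies stay finite and directional."""
    if not (0 < epsilon < 0.5):
        raise ValueError(f"epsilon must lie in (0, 0.5), got {epsilon}")
    a = min(max(af_num, epsilon), 1.0 - epsilon)
    b = min(max(af_den, epsilon), 1.0 - epsilon)
    return (a * (1.0 - b)) / (b * (1.0 - a))


def classify_specificity(af_fibro: float, af_ipsc: float, af_isc: float,
                         af_threshold: float = DEFAULT_AF_THRESHOLD,
                         or_threshold: float = DEFAULT_OR_THRESHOLD,
                         epsilon: float = DEFAULT_EPSILON) -> tuple[str, dict[str, float]]:
    """Apply the three conjunctive filter blocks to one AF triple.

    All inequalities are strict.  Returns the label and the odds ratios
    evaluated for the decision.
    """
    t, u = af_threshold, or_threshold
    ors = {
        "ipsc_vs_fibro": odds_ratio(af_ipsc, af_fibro, epsilon),
        "isc_vs_fibro": odds_ratio(af_isc, af_fibro, epsilon),
        "ipsc_vs_isc": odds_ratio(af_ipsc, af_isc, epsilon),
        "isc_vs_ipsc": odds_ratio(af_isc, af_ipsc, epsilon),
    }
    if af_fibro < t and af_ipsc > t and af_isc > t \
            and ors["ipsc_vs_fibro"] > u and ors["isc_vs_fibro"] > u:
        return SHARED_IPSC_ISC, ors
    if af_fibro < t and af_ipsc > t and af_isc < t \
            and ors["ipsc_vs_fibro"] > u and ors["ipsc_vs_isc"] > u:
        return IPSC_ONLY, ors
    if af_fibro < t and af_ipsc < t and af_isc > t \
            and ors["isc_vs_fibro"] > u and ors["isc_vs_ipsc"] > u:
        return ISC_ONLY, ors
    return NONE, ors


def classify_table(table: pd.DataFrame,
                   af_threshold: float = DEFAULT_AF_THRESHOLD,
                   or_threshold: float = DEFAULT_OR_THRESHOLD,
                   epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Filter-block labels for every merged-table row.

    Returns the table plus ``label`` and the four odds-ratio columns, in the
    original row order.
    """
    out = table.copy()
    labels, or_cols = [], {k: [] for k in
                           ("or_ipsc_vs_fibro", "or_isc_vs_fibro",
                            "or_ipsc_vs_isc", "or_isc_vs_ipsc")}
    for r in table.itertuples():
        label, ors = classify_specificity(r.af_fibro, r.af_ipsc, r.af_isc,
                                          af_threshold, or_threshold, epsilon)
        labels.append(label)
        or_cols["or_ipsc_vs_fibro"].append(ors["ipsc_vs_fibro"])
        or_cols["or_isc_vs_fibro"].append(ors["isc_vs_fibro"])
        or_cols["or_ipsc_vs_isc"].append(ors["ipsc_vs_isc"])
        or_cols["or_isc_vs_ipsc"].append(ors["isc_vs_ipsc"])
    out["label"] = labels
    for col, vals in or_cols.items():
        out[col] = vals
    return out


def keys_in_flagged_clusters(table: pd.DataFrame, result: ClusteringResult) -> set[VariantKey]:
    """Variant keys belonging to the flagged clusters of a clustering result."""
    keys = table_keys(table)
    return {keys[i] for i in range(len(keys))
            if int(result.assignments[i]) in result.flagged_clusters}


def keys_with_label(calls: pd.DataFrame, label: str = SHARED_IPSC_ISC) -> set[VariantKey]:
    mask = calls["label"] == label
    return set(table_keys(calls.loc[mask]))


def concordance(kmeans_set: set[VariantKey], filter_set: set[VariantKey]) -> float:
    """Fraction of k-means-flagged variants also labelled shared-specific by
    the cutoff filter (denominator: the k-means set)."""
    if not kmeans_set:
        raise ValueError("k-means set is empty; concordance undefined")
    return len(kmeans_set & filter_set) / len(kmeans_set)


def cross_patient_overlap(
    patient_sets: dict[str, set[VariantKey]],
) -> dict[VariantKey, set[str]]:
    """Exact-key sharing of specific variants across patient lines.

    Returns only keys found in >= 2 patients; an empty map is the expected
    no-positive-selection outcome.
    """
    if len(patient_sets) < 2:
        raise ValueError("need at least two patient call sets")
    seen: dict[VariantKey, set[str]] = {}
    for name, keys in patient_sets.items():
        for key in keys:
            seen.setdefault(key, set()).add(name)
    return {k: names for k, names in seen.items() if len(names) >= 2}


def cluster_summary(result: ClusteringResult) -> pd.DataFrame:
    """One row per cluster: centroid triple, size, flagged indicator."""
    rows = [{
        "k": result.k, "cluster": j,
        "centroid_fibro": result.centroids[j, 0],
        "centroid_ipsc": result.centroids[j, 1],
        "centroid_isc": result.centroids[j, 2],
        "size": int(result.sizes[j]),
        "flagged": j in result.flagged_clusters,
    } for j in range(result.k)]
    return pd.DataFrame(rows)
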