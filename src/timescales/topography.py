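"""Cortical parcellation handling and topographic similarity.

Topographic similarity asks how uniformly a metric (ACW or MF) is laid out
over the cortical surface: for a given scope (one of the seven functional
networks, or the whole cortex) each parcel contributes its across-subject
profile of the metric, and the parcels' profiles are correlated pairwise
(Pearson).  The matrix is summarised by the median of its strictly-upper-
triangle entries, and two states are compared by a paired t test over the
Fisher r-to-Z transformed upper-triangle entries.

The parcellation convention is the Schaefer-Yeo 1000-parcel atlas grouped
into the seven Yeo networks with the canonical parcel counts (visual 162,
somatomotor 194, dorsal attention 122, ventral attention 121, limbic 60,
frontoparietal 129, default-mode 212).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Canonical seven-network parcel counts of the 1000-parcel scheme.
NETWORK_SIZES: dict[str, int] = {
    "visual": 162,
    "somatomotor": 194,
    "dorsal_attention": 122,
    "ventral_attention": 121,
    "limbic": 60,
    "frontoparietal": 129,
    "default_mode": 212,
}

NETWORKS = tuple(NETWORK_SIZES)
CORTEX = "cortex"


@dataclass
class ParcellationScheme:
    """Mapping of integer-labelled parcels onto named networks.

    ``parcel_ids`` are the positive integer labels (as found in a label
    volume); ``network_of[i]`` names the network of ``parcel_ids[i]``.  The
    cortex is the union of all networks.
    """

    parcel_ids: np.ndarray
    network_of: np.ndarray

    def __post_init__(self) -> None:
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        self.network_of = np.asarray(self.network_of, dtype=object)
        if self.parcel_ids.size != self.network_of.size:
            raise ValueError("parcel_ids and network_of must have equal length")
        if len(set(self.parcel_ids.tolist())) != self.parcel_ids.size:
            raise ValueError("parcel ids must be unique (every parcel mapped exactly once)")

    @classmethod
    def default(cls) -> "ParcellationScheme":
        """The canonical 1000-parcel / seven-network scheme.

        Parcels are numbered 1..1000 in contiguous network blocks in the
        order of :data:`NETWORK_SIZES`.
        """

        networks = np.concatenate(
            [np.full(n, name, dtype=object) for name, n in NETWORK_SIZES.items()]
        )
        scheme = cls(parcel_ids=np.arange(1, networks.size + 1), network_of=networks)
        scheme.validate_canonical()
        return scheme

    def validate_canonical(self) -> None:
        """Check the seven-network counts of the study parcellation."""

        counts = {name: int((self.network_of == name).sum()) for name in NETWORKS}
        if counts != NETWORK_SIZES:
            raise ValueError(f"network parcel counts {counts} differ from the canonical layout")
        if self.parcel_ids.size != sum(NETWORK_SIZES.values()):
            raise ValueError("parcel count must total 1000")

    @property
    def n_parcels(self) -> int:
        return self.parcel_ids.size

    @property
    def networks(self) -> tuple[str, ...]:
        seen: list[str] = []
        for name in self.network_of:
            if name not in seen:
                seen.append(name)
        return tuple(seen)

    def parcels_in(self, scope: str) -> np.ndarray:
        """Column indices of the parcels in ``scope`` (a network or "cortex")."""

        if scope == CORTEX:
            return np.arange(self.n_parcels)
        idx = np.flatnonzero(self.network_of == scope)
        if idx.size == 0:
            raise KeyError(f"unknown network {scope!r}")
        return idx

    @classmethod
    def from_table(cls, path) -> "ParcellationScheme":
        """Read a parcel -> network lookup table (columns parcel_id, network)."""

        table = pd.read_csv(path, sep=None, engine="python")
        return cls(
            parcel_ids=table["parcel_id"].to_numpy(),
            network_of=table["network"].to_numpy(),
        )

    def to_table(self, path) -> None:
        pd.DataFrame(
            {"parcel_id": self.parcel_ids, "network": self.network_of}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ParcelMetricTable:
    """Subjects x parcels matrix of one metric in one state."""

    values: np.ndarray
    metric: str = ""
    state: str = ""
    subject_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x parcels")
        if not self.subject_ids:
            self.subject_ids = list(range(self.values.shape[0]))


@dataclass
class SimilarityMatrix:
    """Pairwise Pearson matrix of parcel profiles plus its summaries."""

    r: np.ndarray
    z: np.ndarray
    median_r: float
    state: str = ""
    metric: str = ""
    scope: str = ""

    def upper_triangle(self, which: str = "z") -> np.ndarray:
        m = self.z if which == "z" else self.r
        iu = np.triu_indices_from(m, k=1)
        return m[iu]


@dataclass
class SimilarityComparison:
    """Paired t test between two states' similarity matrices."""

    t: float
    p: float
    median_a: float
    median_b: float
    n_pairs: int
    scale: str = "z"


def parcel_means(voxel_values: np.ndarray, voxel_labels: np.ndarray,
                 parcel_ids: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean metric per parcel from voxel-level values.

    ``voxel_labels[i]`` is the integer parcel label of voxel ``i``.  NaN
    sentinels are excluded from the mean; a parcel whose voxels are all
    sentinels yields a NaN with a logged warning.  Returns
    ``(parcel_ids, means)`` in ascending label order unless ``parcel_ids``
    is given.
    """

    voxel_values = np.asarray(voxel_values, dtype=float).ravel()
    voxel_labels = np.asarray(voxel_labels).ravel()
    if voxel_values.size != voxel_labels.size:
        raise ValueError("voxel metric vector and label vector lengths differ")
    if parcel_ids is None:
        parcel_ids = np.unique(voxel_labels)
    means = np.full(len(parcel_ids), np.nan)
    for k, pid in enumerate(parcel_ids):
        vals = voxel_values[voxel_labels == pid]
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            logger.warning("parcel %s has no finite voxel values", pid)
            continue
        means[k] = finite.mean()
    return np.asarray(parcel_ids), means


def similarity_matrix(
    table: ParcelMetricTable | np.ndarray,
    scheme: ParcellationScheme | None = None,
    scope: str = CORTEX,
) -> SimilarityMatrix:
    """Pairwise Pearson correlation of parcel profiles within ``scope``.

    Entry ``(i, j)`` is the Pearson correlation between parcel ``i``'s and
    parcel ``j``'s across-subject metric vectors.  The Fisher transform
    ``z = atanh(r)`` is applied off-diagonal, with ``|r| = 1`` entries
    clipped to ``1 - 1e-12`` to keep z finite (clipping is logged).
    ``median_r`` is the median of the strictly-upper-triangle entries,
    excluding parcels with zero across-subject variance (their rows and
    columns become NaN sentinels).
    """

    if isinstance(table, ParcelMetricTable):
        values, state, metric = table.values, table.state, table.metric
    else:
        values, state, metric = np.asarray(table, dtype=float), "", ""
    if scheme is not None and scope != CORTEX:
        values = values[:, scheme.parcels_in(scope)]
    elif scheme is not None:
        values = values[:, scheme.parcels_in(CORTEX)]
    n_subjects, n_parcels = values.shape
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for parcel-profile correlations")
    sd = np.nanstd(values, axis=0)
    good = np.isfinite(sd) & (sd > 0) & np.isfinite(values).all(axis=0)
    r = np.full((n_parcels, n_parcels), np.nan)
    if good.sum() >= 2:
        r_good = np.corrcoef(values[:, good], rowvar=False)
        r[np.ix_(good, good)] = r_good
    if (~good).any():
        logger.warning(
            "similarity_matrix: %d parcel(s) with zero variance excluded", int((~good).sum())
        )
    np.fill_diagonal(r, 1.0)
    clip = 1.0 - 1e-12
    off = ~np.eye(n_parcels, dtype=bool)
    n_clipped = int((np.abs(r[off]) >= 1.0).sum())
    if n_clipped:
        logger.info("similarity_matrix: %d off-diagonal |r| = 1 entries clipped before atanh", n_clipped)
    z = r.copy()
    z[off] = np.arctanh(np.clip(r[off], -clip, clip))
    iu = np.triu_indices(n_parcels, k=1)
    upper = r[iu]
    median_r = float(np.nanmedian(upper)) if np.isfinite(upper).any() else float("nan")
    return SimilarityMatrix(r=r, z=z, median_r=median_r, state=state, metric=metric, scope=scope)


def compare_similarity(
    a: SimilarityMatrix, b: SimilarityMatrix, scale: str = "z"
) -> SimilarityComparison:
    """Paired t test of two states' pairwise-correlation distributions.

    Pairs are the aligned upper-triangle entries; the test runs on the
    Fisher-transformed values by default (``scale="r"`` is available).
    Each parcel pair is treated as one observation, which reproduces the
    field's convention but ignores the pairs' mutual dependence - t values
    can therefore be enormous; interpret them as descriptive.
    """

    if a.r.shape != b.r.shape:
        raise ValueError("similarity matrices have different shapes")
    ua, ub = a.upper_triangle(scale), b.upper_triangle(scale)
    mask = np.isfinite(ua) & np.isfinite(ub)
    ua, ub = ua[mask], ub[mask]
    if ua.size < 2:
        raise ValueError("too few finite aligned pairs")
    logger.info(
        "compare_similarity: %d parcel pairs treated as observations; "
        "pairs are not independent, t values are descriptive",
        ua.size,
    )
    d = ua - ub
    if np.all(d == 0):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(ua, ub)
    return SimilarityComparison(
        t=float(t), p=float(p), median_a=a.median_r, median_b=b.median_r,
        n_pairs=int(ua.size), scale=scale,
    )
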