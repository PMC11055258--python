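"""Lead-graph structure: entropy, mutual information, and adjacency variants.

Each 12-lead ECG is viewed as a 12-variable time series.  Pairwise statistical
dependence between leads is measured with mutual information (MI), estimated
by the plug-in (maximum-likelihood) estimator on an equal-width discretization
of each lead, in bits.  The weighted variant (WMI) doubles the MI between
leads that share an electrical pole cluster:

    A(i, j) = MI(i, j) * (1 + r(Q_i, Q_j)),   r(Q_i, Q_j) = 1 iff Q_i = Q_j

where the three clusters are the bipolar limb leads (I, II, III), the
augmented unipolar limb leads (aVR, aVL, aVF) and the precordial leads
(V1..V6).  The identity adjacency ignores inter-lead structure entirely and
serves as the ablation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .io import ECGRecord, LEAD_ORDER, N_LEADS

DEFAULT_N_BINS = 16


class Cluster(str, Enum):
    BIPOLAR_LIMB = "BIPOLAR_LIMB"
    UNIPOLAR_LIMB = "UNIPOLAR_LIMB"
    PRECORDIAL = "PRECORDIAL"


class Variant(str, Enum):
    WMI = "wmi"
    MI = "mi"
    IDENTITY = "identity"


class Normalization(str, Enum):
    NONE = "none"
    SPECTRAL = "spectral"  # per-matrix: divide by own spectral radius
    DATASET = "dataset"  # shared constant fitted on a record collection


#: Standard assignment of the 12 leads to the three pole clusters.
DEFAULT_CLUSTER_MAP: dict[str, Cluster] = {
    "I": Cluster.BIPOLAR_LIMB,
    "II": Cluster.BIPOLAR_LIMB,
    "III": Cluster.BIPOLAR_LIMB,
    "aVR": Cluster.UNIPOLAR_LIMB,
    "aVL": Cluster.UNIPOLAR_LIMB,
    "aVF": Cluster.UNIPOLAR_LIMB,
    **{f"V{i}": Cluster.PRECORDIAL for i in range(1, 7)},
}


@dataclass
class DiscretizedSeries:
    """An integer-symbol rendering of a real series over equal-width bins."""

    symbols: np.ndarray
    n_bins: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.symbols.size and (
            self.symbols.min() < 0 or self.symbols.max() >= self.n_bins
        ):
            raise ValueError("symbols out of range [0, n_bins)")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class MIMatrix:
    """Pairwise mutual information between the 12 leads, in bits.

    The diagonal holds the marginal entropies H(X_i) = I(X_i; X_i).
    """

    values: np.ndarray
    n_bins: int
    estimator_id: str = "plugin-equalwidth"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_LEADS, N_LEADS):
            raise ValueError(f"expected 12x12, got {v.shape}")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("MI matrix must be symmetric")
        if v.min() < 0:
            raise ValueError("MI matrix must be non-negative")
        self.values = v


@dataclass
class AdjacencyMatrix:
    """Symmetric non-negative 12x12 edge-weight matrix over the lead nodes."""

    values: np.ndarray
    variant: Variant
    normalization: Normalization = Normalization.NONE

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_LEADS, N_LEADS):
            raise ValueError(f"expected 12x12, got {v.shape}")
        if np.abs(v - v.T).max() > 1e-9:
            raise ValueError("adjacency must be symmetric")
        if v.min() < -1e-12:
            raise ValueError("adjacency must be non-negative")
        if self.variant == Variant.IDENTITY and not np.array_equal(v, np.eye(N_LEADS)):
            raise ValueError("IDENTITY variant must be the exact identity matrix")
        self.values = v


def discretize(x: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> DiscretizedSeries:
    """Equal-width binning of ``x`` over [min(x), max(x)].

    The maximum lands in bin ``n_bins - 1``; a constant series maps to all
    zeros.
    """
    x = np.asarray(x, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    lo, hi = x.min(), x.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    if lo == hi:
        symbols = np.zeros(x.shape, dtype=np.int64)
    else:
        # right-open bins except the last, which absorbs the maximum
        symbols = np.minimum(
            ((x - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1
        )
    return DiscretizedSeries(symbols=symbols, n_bins=n_bins, bin_edges=edges)


def _plugin_entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy(d: DiscretizedSeries) -> float:
    """Plug-in Shannon entropy H(X) in bits over observed symbol frequencies."""
    if len(d) == 0:
        raise ValueError("empty series")
    return _plugin_entropy(np.bincount(d.symbols, minlength=d.n_bins))


def joint_entropy(dx: DiscretizedSeries, dy: DiscretizedSeries) -> float:
    """Plug-in joint entropy H(X, Y) in bits over the observed pair table."""
    if len(dx) != len(dy):
        raise ValueError("length mismatch between the two series")
    joint = np.bincount(
        dx.symbols * dy.n_bins + dy.symbols, minlength=dx.n_bins * dy.n_bins
    )
    return _plugin_entropy(joint)


def mutual_information(dx: DiscretizedSeries, dy: DiscretizedSeries) -> float:
    """I(X; Y) = H(X) + H(Y) - H(X, Y), clamped at zero from below."""
    mi = entropy(dx) + entropy(dy) - joint_entropy(dx, dy)
    return max(mi, 0.0)


def mi_matrix(rec: ECGRecord, n_bins: int = DEFAULT_N_BINS) -> MIMatrix:
    """Pairwise MI between all leads of a record, in canonical lead order.

    The upper triangle is computed and mirrored; the diagonal is the marginal
    entropy of each lead (I(X; X) = H(X)).
    """
    rec = rec.reordered()
    discs = [discretize(rec.signal[i], n_bins) for i in range(N_LEADS)]
    ents = np.array([entropy(d) for d in discs])
    v = np.zeros((N_LEADS, N_LEADS))
    for i in range(N_LEADS):
        v[i, i] = ents[i]
        for j in range(i + 1, N_LEADS):
            mi = ents[i] + ents[j] - joint_entropy(discs[i], discs[j])
            v[i, j] = v[j, i] = max(mi, 0.0)
    return MIMatrix(values=v, n_bins=n_bins)


def cluster_indicator(q_i: Cluster, q_j: Cluster) -> int:
    """r(Q_i, Q_j): 1 if the two leads share a pole cluster, else 0."""
    return int(Cluster(q_i) == Cluster(q_j))


def cluster_indicator_matrix(
    clusters: Optional[dict[str, Cluster]] = None,
) -> np.ndarray:
    clusters = clusters or DEFAULT_CLUSTER_MAP
    q = [clusters[name] for name in LEAD_ORDER]
    return np.array(
        [[cluster_indicator(qi, qj) for qj in q] for qi in q], dtype=float
    )


def wmi_matrix(
    mi: MIMatrix,
    clusters: Optional[dict[str, Cluster]] = None,
    zero_diagonal: bool = False,
) -> AdjacencyMatrix:
    """Weight the MI matrix by pole clusters: same-cluster entries double."""
    r = cluster_indicator_matrix(clusters)
    a = mi.values * (1.0 + r)
    if zero_diagonal:
        np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(values=a, variant=Variant.WMI)


def mi_adjacency(mi: MIMatrix, zero_diagonal: bool = False) -> AdjacencyMatrix:
    """Use the raw MI matrix itself as the adjacency (unweighted variant)."""
    a = mi.values.copy()
    if zero_diagonal:
        np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(values=a, variant=Variant.MI)


def identity_adjacency() -> AdjacencyMatrix:
    """The structure-blind baseline: every lead connected only to itself."""
    return AdjacencyMatrix(values=np.eye(N_LEADS), variant=Variant.IDENTITY)


def normalize_adjacency(a: AdjacencyMatrix) -> AdjacencyMatrix:
    """Divide by the spectral radius so polynomial filter powers stay bounded.

    A no-op on the zero matrix; the identity maps to itself.
    """
    lam = float(np.abs(np.linalg.eigvalsh(a.values)).max())
    values = a.values if lam == 0 else a.values / lam
    return AdjacencyMatrix(
        values=values, variant=a.variant, normalization=Normalization.SPECTRAL
    )


def spectral_radius(a: AdjacencyMatrix | np.ndarray) -> float:
    values = a.values if isinstance(a, AdjacencyMatrix) else np.asarray(a, float)
    return float(np.abs(np.linalg.eigvalsh(values)).max())


def dataset_scale(adjacencies: list[AdjacencyMatrix]) -> float:
    """Shared normalization constant: mean spectral radius over a collection.

    Dividing every matrix by this one constant bounds the polynomial filter
    powers like per-matrix spectral normalization does, but keeps the
    between-record magnitude differences that per-matrix normalization
    erases — and those differences carry class information when coupling
    strength varies by rhythm.
    """
    if not adjacencies:
        raise ValueError("need at least one adjacency")
    return float(np.mean([spectral_radius(a) for a in adjacencies]))


def apply_dataset_scale(
    adjacencies: list[AdjacencyMatrix], scale: Optional[float] = None
) -> list[AdjacencyMatrix]:
    """Divide every adjacency by one shared constant (default: fitted mean)."""
    scale = dataset_scale(adjacencies) if scale is None else float(scale)
    if scale <= 0:
        return list(adjacencies)
    return [
        AdjacencyMatrix(
            values=a.values / scale,
            variant=a.variant,
            normalization=Normalization.DATASET,
        )
        for a in adjacencies
    ]


def record_adjacency(
    rec: ECGRecord,
    variant: Variant | str = Variant.WMI,
    n_bins: int = DEFAULT_N_BINS,
    normalize: bool = True,
    zero_diagonal: bool = False,
    mi: Optional[MIMatrix] = None,
) -> AdjacencyMatrix:
    """Per-record adjacency of the requested variant.

    Each record yields its own graph; an already-computed ``mi`` matrix may be
    passed to avoid re-estimation when several variants are built from the
    same record.
    """
    variant = Variant(variant)
    if variant == Variant.IDENTITY:
        return identity_adjacency()
    if mi is None:
        mi = mi_matrix(rec, n_bins)
    if variant == Variant.WMI:
        a = wmi_matrix(mi, zero_diagonal=zero_diagonal)
    else:
        a = mi_adjacency(mi, zero_diagonal=zero_diagonal)
    return normalize_adjacency(a) if normalize else a
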