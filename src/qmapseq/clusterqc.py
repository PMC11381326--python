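"""Quality-control flags and trajectory clustering across a titration.

Constructs whose probing behaviour contradicts the two-state docking model
are flagged rather than fitted: a reactive tetraloop closing pair means the
loop context itself is perturbed, and a probe that stays reactive at
saturating Mg2+ with a weak fitted amplitude suggests an alternative
structure rather than a weak contact.  Per-nucleotide reactivity
trajectories (reactivity as a function of Mg2+) are clustered
agglomeratively to surface recurring behavioural classes across a mutant
family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .titration import STATUS_BELOW_DETECTION, HillFitResult, TitrationSeries

FLAG_CLOSING_PAIR = "closing_pair_reactive"
FLAG_ALT_STRUCTURE = "alternative_structure"
FLAG_BELOW_DETECTION = "below_detection"


def qc_flags(
    series: TitrationSeries,
    closing_pair_positions: Sequence[int],
    tetraloop_positions: Sequence[int] | None = None,
    fit: HillFitResult | None = None,
    closing_pair_threshold: float = 0.02,
    alt_structure_residual: float = 0.5,
    alt_structure_amplitude: float = 0.5,
) -> list[str]:
    """QC flags for one construct's titration.

    - ``closing_pair_reactive``: mutation fraction above threshold in the
      tetraloop closing pair at the highest Mg2+ point.
    - ``alternative_structure``: probe reactivity at the highest Mg2+ stays
      above ``alt_structure_residual`` of its 0-Mg2+ value while the fitted
      amplitude is below ``alt_structure_amplitude``.
    - ``below_detection``: passed through from the Hill fit.
    """
    flags: list[str] = []
    pts = series.unmasked
    top = max(pts, key=lambda p: p.mg)
    bottom = min(pts, key=lambda p: p.mg)
    probes = list(tetraloop_positions or series.probe_positions)

    closing = top.profile.mean_reactivity(closing_pair_positions)
    if np.isfinite(closing) and closing > closing_pair_threshold:
        flags.append(FLAG_CLOSING_PAIR)

    r_top = top.profile.mean_reactivity(probes)
    r_bottom = bottom.profile.mean_reactivity(probes)
    amplitude = fit.amplitude_A if fit is not None else np.nan
    if (
        np.isfinite(r_top)
        and np.isfinite(r_bottom)
        and r_bottom > 0
        and r_top > alt_structure_residual * r_bottom
        and (not np.isfinite(amplitude) or amplitude < alt_structure_amplitude)
    ):
        flags.append(FLAG_ALT_STRUCTURE)

    if fit is not None and fit.status == STATUS_BELOW_DETECTION:
        flags.append(FLAG_BELOW_DETECTION)
    return flags


# ---------------------------------------------------------------------------
# Trajectory clustering
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryMatrix:
    """Reactivity-vs-Mg2+ trajectories for selected (construct, position) rows."""

    row_labels: list[tuple[str, int]]
    mg: np.ndarray
    values: np.ndarray  # shape (rows, len(mg))
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.mg)):
            raise ValueError("trajectory matrix shape mismatch")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("trajectory matrix contains missing cells")

    def max_normalized(self) -> "TrajectoryMatrix":
        """Scale each row by its maximum (rows with max 0 are left as-is)."""
        rowmax = self.values.max(axis=1, keepdims=True)
        scaled = np.where(rowmax > 0, self.values / np.where(rowmax > 0, rowmax, 1), self.values)
        return TrajectoryMatrix(
            row_labels=list(self.row_labels),
            mg=self.mg.copy(),
            values=scaled,
            normalization="row_max",
        )


def trajectory_matrix(
    series_list: Sequence[TitrationSeries],
    positions: dict[str, Sequence[int]] | None = None,
) -> TrajectoryMatrix:
    """Build a trajectory matrix from titration series on a common Mg2+ grid.

    ``positions`` maps construct name to the reference positions to include
    (default: the series' probe positions).
    """
    if not series_list:
        raise ValueError("no series supplied")
    mg = np.array([p.mg for p in series_list[0].unmasked])
    labels: list[tuple[str, int]] = []
    rows: list[np.ndarray] = []
    for series in series_list:
        this_mg = np.array([p.mg for p in series.unmasked])
        if len(this_mg) != len(mg) or np.any(this_mg != mg):
            raise ValueError(
                f"{series.construct}: Mg2+ grid differs from the common grid"
            )
        pos = (positions or {}).get(series.construct, series.probe_positions)
        for p in pos:
            labels.append((series.construct, p))
            rows.append(
                np.array(
                    [pt.profile.mut_fraction[p] for pt in series.unmasked]
                )
            )
    return TrajectoryMatrix(row_labels=labels, mg=mg, values=np.vstack(rows))


@dataclass
class ClusterResult:
    labels: np.ndarray  # 1-based cluster ids, scipy fcluster convention
    linkage_matrix: np.ndarray
    k: int
    method: str
    metric: str

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def cluster_trajectories(
    matrix: TrajectoryMatrix,
    k: int,
    method: str = "ward",
    metric: str = "euclidean",
    normalize: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of reactivity trajectories.

    Defaults to Ward linkage on Euclidean distances of row-max-normalized
    trajectories, which groups rows by the *shape* of their Mg2+ response
    rather than its absolute magnitude.  Deterministic given inputs; labels
    are stable under row permutation up to relabeling.
    """
    n_rows = matrix.values.shape[0]
    if n_rows < 2:
        raise ValueError("clustering needs at least 2 rows")
    if k > n_rows:
        raise ValueError(f"k={k} exceeds number of rows {n_rows}")
    data = matrix.max_normalized().values if normalize else matrix.values
    Z = linkage(data, method=method, metric=metric)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        labels=labels, linkage_matrix=Z, k=int(labels.max()),
        method=method, metric=metric,
    )


def cluster_labels_frame(matrix: TrajectoryMatrix, result: ClusterResult):
    """Labels as a DataFrame (construct, position, cluster) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "construct": [c for c, _ in matrix.row_labels],
            "position": [p for _, p in matrix.row_labels],
            "cluster": result.labels,
        }
    )


def plot_dendrogram(result: ClusterResult, path=None, ax=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(result.linkage_matrix, ax=ax, no_labels=True)
    ax.set_ylabel("distance")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_cluster_means(matrix: TrajectoryMatrix, result: ClusterResult, path=None):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    data = matrix.max_normalized().values
    for cid in range(1, result.k + 1):
        members = result.members(cid)
        if len(members) == 0:
            continue
        ax.plot(
            matrix.mg, data[members].mean(axis=0),
            marker="o", label=f"cluster {cid} (n={len(members)})",
        )
    ax.set_xscale("symlog", linthresh=0.05)
    ax.set_xlabel("[Mg2+] (mM)")
    ax.set_ylabel("normalized reactivity")
    ax.legend(fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax
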