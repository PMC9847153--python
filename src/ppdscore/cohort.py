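"""Cultivar-level aggregation and shelf-life classification.

Root-level PPD scores are aggregated into per-cultivar time-courses
(mean +/- sample SD per days-post-harvest timepoint), contaminated roots are
excluded beforehand (microbial discoloration is indistinguishable from PPD
in grayscale), and the cultivar trajectories are clustered with k-means.
Each cluster is then called *delayed*, *intermediate* or *early* PPD from
its centroid statistics:

- early        if the cluster mean of the members' average PPD scores
               is >= ``early_threshold`` (default 0.29);
- delayed      if the cluster's post-baseline peak (max of the member-mean
               trajectory over 2, 4, 7 dph) is < ``peak_threshold`` (0.33);
- intermediate otherwise: a low average but a trajectory shape (mid-course
               peak or late jump) that is not a delayed pattern.

The *average PPD score* of a cultivar is the arithmetic mean of its
time-point mean scores over the assessment course {0-or-1, 2, 4, 7} dph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ClusteringError, MissingTimepointError

logger = logging.getLogger(__name__)

#: Assessment timepoints (dph) entering the average PPD score.
ASSESSMENT_TIMEPOINTS = (0, 2, 4, 7)

#: Timepoints over which the post-baseline trajectory peak is taken.
PEAK_TIMEPOINTS = (2, 4, 7)

DEFAULT_EARLY_THRESHOLD = 0.29
DEFAULT_PEAK_THRESHOLD = 0.33

STATUSES = ("delayed", "intermediate", "early")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as in the reported score tables.

    Applied only in report output; full precision is kept internally.
    """
    if np.isnan(x):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def canonical_dph(dph: int) -> int:
    """Map the baseline assessments at 0 or 1 dph onto a single 0 timepoint."""
    return 0 if dph in (0, 1) else int(dph)


# ---------------------------------------------------------------------------
# filtering and aggregation
# ---------------------------------------------------------------------------

def filter_contaminated(
    assessments: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop contaminated roots and tabulate contamination per cultivar x dph.

    Parameters
    ----------
    assessments
        Long-format table with columns ``cultivar``, ``root_id``, ``dph``,
        ``root_score``, ``contaminated`` (0/1 or bool).

    Returns
    -------
    retained, contamination
        ``retained`` holds only uncontaminated roots.  ``contamination`` has
        one row per cultivar x dph with ``n_total``, ``n_contaminated`` and
        ``contamination_pct`` (100 * flagged / total, rounded to the nearest
        integer for reporting).  Cells where every root is flagged are
        logged as warnings; their downstream means become missing.
    """
    df = assessments.copy()
    df["contaminated"] = df["contaminated"].astype(bool)
    grouped = df.groupby(["cultivar", "dph"], sort=True)["contaminated"]
    contamination = grouped.agg(n_total="size", n_contaminated="sum").reset_index()
    contamination["contamination_pct"] = [
        int(round_half_up(100.0 * c / t, 0))
        for c, t in zip(contamination["n_contaminated"], contamination["n_total"])
    ]
    for _, row in contamination[
        contamination["n_contaminated"] == contamination["n_total"]
    ].iterrows():
        logger.warning(
            "all %d roots of %s at %s dph are contaminated; "
            "no score can be reported for this cell",
            row["n_total"], row["cultivar"], row["dph"],
        )
    return df[~df["contaminated"]].copy(), contamination


def contamination_percent(n_total: int, n_contaminated: int) -> int:
    """Reported contamination percentage for one cultivar x dph cell."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(round_half_up(100.0 * n_contaminated / n_total, 0))


def aggregate_timepoint(scores: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and count of retained root scores.

    With a single score the SD is undefined and returned as NaN; with no
    scores the mean itself is missing (NaN), never silently zero.
    """
    values = np.asarray([s for s in scores if not np.isnan(s)], dtype=float)
    n = values.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else float("nan")
    return mean, sd, n


@dataclass
class CultivarTrajectory:
    """Per-cultivar PPD time-course: mean +/- SD and counts per timepoint."""

    cultivar: str
    mean: dict[int, float]
    sd: dict[int, float] = field(default_factory=dict)
    n_roots: dict[int, int] = field(default_factory=dict)
    contamination_pct: dict[int, int] = field(default_factory=dict)

    @property
    def timepoints(self) -> tuple[int, ...]:
        return tuple(sorted(self.mean))

    def has_timepoints(self, timepoints: Iterable[int]) -> bool:
        return all(
            t in self.mean and not np.isnan(self.mean[t]) for t in timepoints
        )


def average_ppd_score(
    traj: CultivarTrajectory,
    timepoints: Sequence[int] = ASSESSMENT_TIMEPOINTS,
) -> float:
    """Mean of the time-point mean scores over the assessment course."""
    missing = [t for t in timepoints if t not in traj.mean or np.isnan(traj.mean[t])]
    if missing:
        raise MissingTimepointError(
            f"cultivar {traj.cultivar!r} lacks mean scores at dph {missing}"
        )
    return float(np.mean([traj.mean[t] for t in timepoints]))


def build_trajectories(
    assessments: pd.DataFrame,
    *,
    filter_contamination: bool = True,
) -> list[CultivarTrajectory]:
    """Aggregate a long-format root-score table into cultivar trajectories.

    Baseline assessments at 0 and 1 dph are pooled into the 0 dph timepoint.
    Contaminated roots are excluded before aggregation (default).
    """
    df = assessments.copy()
    if filter_contamination and "contaminated" in df.columns:
        retained, contamination = filter_contaminated(df)
    else:
        retained = df
        contamination = None
    retained = retained.copy()
    retained["dph"] = retained["dph"].map(canonical_dph)

    trajectories: dict[str, CultivarTrajectory] = {}
    for cultivar, sub in retained.groupby("cultivar", sort=True):
        traj = CultivarTrajectory(cultivar=str(cultivar), mean={})
        for dph, cell in sub.groupby("dph"):
            mean, sd, n = aggregate_timepoint(cell["root_score"].to_numpy())
            traj.mean[int(dph)] = mean
            traj.sd[int(dph)] = sd
            traj.n_roots[int(dph)] = n
        trajectories[str(cultivar)] = traj

    if contamination is not None:
        contamination = contamination.copy()
        contamination["dph"] = contamination["dph"].map(canonical_dph)
        for (cultivar, dph), cell in contamination.groupby(["cultivar", "dph"]):
            traj = trajectories.setdefault(
                str(cultivar), CultivarTrajectory(cultivar=str(cultivar), mean={})
            )
            traj.contamination_pct[int(dph)] = contamination_percent(
                int(cell["n_total"].sum()), int(cell["n_contaminated"].sum())
            )
            # A fully contaminated cell produced no retained roots: record it
            # as a missing mean rather than dropping the timepoint key.
            if int(dph) not in traj.mean:
                traj.mean[int(dph)] = float("nan")
                traj.sd[int(dph)] = float("nan")
                traj.n_roots[int(dph)] = 0
    return list(trajectories.values())


def trajectories_from_means(
    means: pd.DataFrame,
    *,
    cultivar_col: str = "cultivar",
) -> list[CultivarTrajectory]:
    """Build trajectories from a wide table of time-point means.

    Expected columns: ``cultivar`` plus ``mean_<dph>dph`` (e.g. ``mean_0dph``)
    and optionally ``sd_<dph>dph`` and ``contamination_pct_7dph``.  This is
    the entry point for published summary tables where per-root scores are
    not available.
    """
    mean_cols = {
        int(c.removeprefix("mean_").removesuffix("dph")): c
        for c in means.columns
        if c.startswith("mean_") and c.endswith("dph")
    }
    if not mean_cols:
        raise ValueError("no mean_<t>dph columns found")
    out = []
    for _, row in means.iterrows():
        traj = CultivarTrajectory(
            cultivar=str(row[cultivar_col]),
            mean={canonical_dph(t): float(row[c]) for t, c in mean_cols.items()},
        )
        for t in list(mean_cols):
            sd_col = f"sd_{t}dph"
            if sd_col in means.columns:
                traj.sd[canonical_dph(t)] = float(row[sd_col])
        if "contamination_pct_7dph" in means.columns:
            traj.contamination_pct[7] = int(row["contamination_pct_7dph"])
        out.append(traj)
    return out


# ---------------------------------------------------------------------------
# k-means clustering of trajectories
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Fitted k-means model over cultivar trajectory vectors.

    Cluster ids are 1..k, renumbered so that cluster 1 has the lowest
    centroid mean (most delayed) and cluster k the highest — the physical
    ordering used when naming clusters "1-2 delayed ... 5-7 early".
    """

    k: int
    feature_timepoints: tuple[int, ...]
    cultivars: tuple[str, ...]
    centroids: np.ndarray
    labels: np.ndarray  # cluster id (1..k) per cultivar
    wcss: float
    restart_wcss: tuple[float, ...]
    seed: int
    restarts: int
    standardized: bool = False

    @property
    def membership(self) -> dict[str, int]:
        return {c: int(l) for c, l in zip(self.cultivars, self.labels)}


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    centers = _kmeans_pp_init(X, k, rng)
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for j in range(k):
            members = new_labels == j
            if members.any():
                centers[j] = X[members].mean(axis=0)
            else:
                # Re-seed an empty cluster from the point farthest from its
                # current centroid.
                farthest = d2[np.arange(len(new_labels)), new_labels].argmax()
                centers[j] = X[farthest]
                new_labels[farthest] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(labels)), labels].sum())
    return labels, centers, wcss


def kmeans_cluster(
    trajectories: Sequence[CultivarTrajectory],
    k: int = 7,
    *,
    feature_timepoints: Sequence[int] = PEAK_TIMEPOINTS,
    restarts: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    standardize: bool = False,
) -> ClusterModel:
    """Cluster cultivar trajectories with seeded, restarted k-means.

    Lloyd's algorithm with k-means++ initialization; ``restarts``
    independent starts are drawn from a generator seeded with ``seed`` and
    the lowest-WCSS fit is returned, so the result is deterministic for
    fixed inputs.  Features are the per-cultivar mean scores at
    ``feature_timepoints`` (default 2, 4, 7 dph), optionally standardized.
    """
    cultivars = [t.cultivar for t in trajectories]
    if len(set(cultivars)) != len(cultivars):
        raise ClusteringError("duplicate cultivar ids in clustering input")
    if k > len(cultivars):
        raise ClusteringError(f"k={k} exceeds the {len(cultivars)} cultivars")
    if k < 1:
        raise ClusteringError("k must be >= 1")
    feature_timepoints = tuple(int(t) for t in feature_timepoints)
    incomplete = [
        t.cultivar for t in trajectories if not t.has_timepoints(feature_timepoints)
    ]
    if incomplete:
        raise ClusteringError(
            f"cultivars missing feature timepoints {feature_timepoints}: {incomplete}"
        )

    X = np.array(
        [[t.mean[tp] for tp in feature_timepoints] for t in trajectories],
        dtype=float,
    )
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ClusteringError("cannot standardize a constant feature")
        X = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    restart_wcss = []
    for _ in range(max(1, restarts)):
        labels, centers, wcss = _lloyd(X, k, rng, max_iter)
        restart_wcss.append(wcss)
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss)
    labels, centers, wcss = best

    # Renumber clusters by ascending centroid mean so ids are reproducible.
    order = np.argsort(centers.mean(axis=1), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return ClusterModel(
        k=k,
        feature_timepoints=feature_timepoints,
        cultivars=tuple(cultivars),
        centroids=centers[order],
        labels=remap[labels],
        wcss=wcss,
        restart_wcss=tuple(restart_wcss),
        seed=seed,
        restarts=restarts,
        standardized=standardize,
    )


# ---------------------------------------------------------------------------
# cluster -> PPD status
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatusCall:
    """Shelf-life class of one cultivar, inherited from its cluster."""

    cultivar: str
    cluster: int
    status: str
    cluster_centroid_average: float
    cluster_centroid_peak: float


def status_from_membership(
    trajectories: Sequence[CultivarTrajectory],
    membership: Mapping[str, int],
    *,
    early_threshold: float = DEFAULT_EARLY_THRESHOLD,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
    peak_timepoints: Sequence[int] = PEAK_TIMEPOINTS,
    average_timepoints: Sequence[int] = ASSESSMENT_TIMEPOINTS,
) -> list[StatusCall]:
    """Call delayed/intermediate/early per cluster given fixed memberships.

    Cluster-level statistics (unrounded):

    - ``centroid_average``: mean over member cultivars of their average PPD
      score over ``average_timepoints``;
    - ``centroid_peak``: max over ``peak_timepoints`` of the member-mean
      trajectory.

    Status: early if centroid_average >= early_threshold, else delayed if
    centroid_peak < peak_threshold, else intermediate.  All members of a
    cluster share its status.
    """
    by_cultivar = {t.cultivar: t for t in trajectories}
    missing = set(membership) - set(by_cultivar)
    if missing:
        raise ClusteringError(f"membership names unknown cultivars: {sorted(missing)}")

    clusters: dict[int, list[CultivarTrajectory]] = {}
    for cultivar, cluster in membership.items():
        clusters.setdefault(int(cluster), []).append(by_cultivar[cultivar])

    cluster_stats: dict[int, tuple[float, float]] = {}
    for cluster, members in clusters.items():
        avg = float(
            np.mean([average_ppd_score(t, average_timepoints) for t in members])
        )
        peak = float(
            max(np.mean([t.mean[tp] for t in members]) for tp in peak_timepoints)
        )
        cluster_stats[cluster] = (avg, peak)

    calls = []
    for cultivar in membership:
        cluster = int(membership[cultivar])
        avg, peak = cluster_stats[cluster]
        if avg >= early_threshold:
            status = "early"
        elif peak < peak_threshold:
            status = "delayed"
        else:
            status = "intermediate"
        calls.append(
            StatusCall(
                cultivar=cultivar,
                cluster=cluster,
                status=status,
                cluster_centroid_average=avg,
                cluster_centroid_peak=peak,
            )
        )
    return calls


def assign_status(
    model: ClusterModel,
    trajectories: Sequence[CultivarTrajectory],
    *,
    early_threshold: float = DEFAULT_EARLY_THRESHOLD,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> list[StatusCall]:
    """Call PPD status for every cultivar of a fitted cluster model."""
    if model.centroids is None or len(model.cultivars) == 0:
        raise ClusteringError("cluster model is not fitted")
    return status_from_membership(
        trajectories,
        model.membership,
        early_threshold=early_threshold,
        peak_threshold=peak_threshold,
    )


# ---------------------------------------------------------------------------
# report table
# ---------------------------------------------------------------------------

def summary_table(
    trajectories: Sequence[CultivarTrajectory],
    calls: Sequence[StatusCall] | None = None,
    *,
    timepoints: Sequence[int] = ASSESSMENT_TIMEPOINTS,
) -> pd.DataFrame:
    """Cohort report: mean +/- SD per timepoint, contamination, average
    score, cluster and status — one row per cultivar, sorted by average
    score.  Score cells are rounded half-up to 2 decimals (report only).
    """
    call_by_cultivar = {c.cultivar: c for c in (calls or [])}
    rows = []
    for traj in trajectories:
        row: dict[str, object] = {"cultivar": traj.cultivar}
        for t in timepoints:
            mean = traj.mean.get(t, float("nan"))
            sd = traj.sd.get(t, float("nan"))
            row[f"mean_{t}dph"] = round_half_up(mean) if not np.isnan(mean) else np.nan
            row[f"sd_{t}dph"] = round_half_up(sd) if not np.isnan(sd) else np.nan
            if traj.n_roots:
                row[f"n_{t}dph"] = traj.n_roots.get(t, 0)
        row["contamination_pct_7dph"] = traj.contamination_pct.get(7, np.nan)
        try:
            row["average_ppd_score"] = round_half_up(
                average_ppd_score(traj, timepoints)
            )
        except MissingTimepointError:
            row["average_ppd_score"] = np.nan
        call = call_by_cultivar.get(traj.cultivar)
        if call is not None:
            row["cluster"] = call.cluster
            row["status"] = call.status
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["average_ppd_score", "cultivar"], na_position="last"
    ).reset_index(drop=True)
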