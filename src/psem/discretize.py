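"""Optimal 1-D discretization of continuous variables into ordered categories.

Two discretizers are provided, both solved exactly by the same Fisher
dynamic program over contiguous partitions of the sorted values:

* :func:`r2_optimal_discretize` — picks the smallest number of bins whose
  optimal partition explains at least ``r2_target`` of the variance
  (R² between the values and their bin means); used for log relative
  abundances and latent-construct scores.
* :func:`kmeans_discretize` — fixed-``k`` minimum within-class SSE
  partition (exact 1-D k-means); used for body weights.

Zeros of a relative-abundance vector are not numbers on the log scale;
they are carried as NaN ("zero marks") and routed to a dedicated ordered
category below all others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Binning",
    "optimal_partition",
    "kmeans_discretize",
    "r2_optimal_discretize",
    "apply_binning",
]


@dataclass
class Binning:
    """Ordered interval thresholds for one variable.

    Non-zero bins are left-open/right-closed intervals delimited by
    ``thresholds``; category indices start at 1 when ``has_zero_class``
    (index 0 is the zero class), at 0 otherwise.
    """

    variable: str
    thresholds: list[float]           # t_1 < ... < t_{k-1}
    representatives: list[float]      # per-bin training mean, increasing
    has_zero_class: bool = False
    zero_representative: float | None = None
    occupancy: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        """Number of non-zero bins."""
        return len(self.representatives)

    @property
    def n_categories(self) -> int:
        return self.k + (1 if self.has_zero_class else 0)

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")
        r = np.asarray(self.representatives, float)
        if r.size > 1 and not np.all(np.diff(r) > 0):
            raise ValueError("bin representatives must be strictly increasing")
        if len(self.thresholds) != max(0, len(self.representatives) - 1):
            raise ValueError("need exactly k-1 thresholds for k bins")

    # -- numeric representatives for every category index, zero class first
    def category_representatives(self) -> np.ndarray:
        reps = list(self.representatives)
        if self.has_zero_class:
            zr = self.zero_representative
            if zr is None:
                zr = (reps[0] - 1.0) if reps else -1.0
            reps = [zr] + reps
        return np.asarray(reps, float)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variable": self.variable,
                "thresholds": self.thresholds,
                "representatives": self.representatives,
                "has_zero_class": self.has_zero_class,
                "zero_representative": self.zero_representative,
                "occupancy": self.occupancy,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Binning":
        d = json.loads(text)
        return cls(**d)


def optimal_partition(values: np.ndarray, k: int) -> tuple[list[np.ndarray], float]:
    """Exact minimum within-bin SSE contiguous partition of 1-D data.

    Fisher's dynamic program on the sorted values: O(k n^2) with prefix
    sums. Returns the list of k sorted value-groups and the optimal SSE.
    """
    x = np.sort(np.asarray(values, float))
    n = x.size
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for n={n} values")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse_vec(i: np.ndarray, j: int) -> np.ndarray:
        # SSE of x[i:j] (j exclusive) for a vector of starts i < j
        m = j - i
        s = s1[j] - s1[i]
        return np.maximum(0.0, (s2[j] - s2[i]) - s * s / m)

    # cost[c][j]: best SSE of first j points in c+1 bins
    cost = np.full((k, n + 1), np.inf)
    back = np.zeros((k, n + 1), dtype=int)
    # first row: SSE of each prefix x[0:j]
    m = np.arange(1, n + 1)
    cost[0, 1:] = np.maximum(0.0, s2[1:] - s1[1:] ** 2 / m)
    for c in range(1, k):
        for j in range(c + 1, n + 1):
            i = np.arange(c, j)
            v = cost[c - 1, i] + sse_vec(i, j)
            arg = int(np.argmin(v))
            cost[c, j] = v[arg]
            back[c, j] = c + arg
    cuts = []
    j = n
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        cuts.append(i)
        j = i
    cuts = sorted(cuts)
    groups = np.split(x, cuts)
    return groups, float(cost[k - 1, n])


def _binning_from_groups(
    variable: str,
    groups: list[np.ndarray],
    boundary: str,
    has_zero_class: bool = False,
    zero_representative: float | None = None,
    n_zero: int = 0,
) -> Binning:
    reps = [float(g.mean()) for g in groups]
    if boundary == "centers":
        thr = [(reps[i] + reps[i + 1]) / 2 for i in range(len(groups) - 1)]
    else:  # midpoint between adjacent extreme training values
        thr = [
            float((groups[i][-1] + groups[i + 1][0]) / 2)
            for i in range(len(groups) - 1)
        ]
    total = sum(g.size for g in groups) + n_zero
    occ = [g.size / total for g in groups]
    if has_zero_class:
        occ = [n_zero / total] + occ
    return Binning(
        variable=variable,
        thresholds=thr,
        representatives=reps,
        has_zero_class=has_zero_class,
        zero_representative=zero_representative,
        occupancy=occ,
    )


def kmeans_discretize(
    values, k: int, seed: int = 0, variable: str = "value"
) -> Binning:
    """Exact 1-D k-means binning (bins bounded by midpoints of adjacent centers).

    The one-dimensional SSE objective is solved globally by dynamic
    programming, so the ``seed`` has no influence on the optimum; it is
    accepted for interface stability only.
    """
    x = np.asarray(values, float)
    if np.isnan(x).any():
        raise ValueError("kmeans_discretize does not accept zero-marked values")
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct values, got {np.unique(x).size}")
    groups, _ = optimal_partition(x, k)
    return _binning_from_groups(variable, groups, boundary="centers")


def r2_optimal_discretize(
    values,
    k_candidates=(2, 3, 4, 5),
    r2_target: float = 0.95,
    variable: str = "value",
    zero_class: bool | None = None,
) -> Binning:
    """Pick the smallest k whose exact partition reaches R² >= ``r2_target``.

    ``values`` may contain NaN zero-marks; these bypass the partition and
    are given a dedicated category below the lowest bin (its numeric
    representative is one unit below the observed minimum). If every value
    is zero-marked a zero-class-only binning is returned.
    """
    if not 0 < r2_target < 1:
        raise ValueError("r2_target must be in (0,1)")
    x = np.asarray(values, float)
    nz = x[~np.isnan(x)]
    n_zero = int(np.isnan(x).sum())
    if zero_class is None:
        zero_class = n_zero > 0
    if nz.size == 0:
        import warnings

        warnings.warn(f"{variable}: all values zero-marked; zero class only")
        return Binning(variable, [], [], has_zero_class=True, zero_representative=0.0,
                       occupancy=[1.0])
    zero_rep = float(nz.min() - 1.0) if zero_class else None
    tss = float(((nz - nz.mean()) ** 2).sum())
    n_distinct = np.unique(nz).size
    if tss == 0.0:  # constant: one bin suffices
        groups = [np.sort(nz)]
        return _binning_from_groups(variable, groups, "extremes", zero_class,
                                    zero_rep, n_zero)
    best_groups, best_r2 = None, -np.inf
    for k in sorted(set(int(k) for k in k_candidates)):
        if k > n_distinct:
            break
        groups, sse = optimal_partition(nz, k)
        r2 = 1.0 - sse / tss
        if r2 > best_r2 + 1e-12:
            best_groups, best_r2 = groups, r2
        if r2 >= r2_target:
            best_groups, best_r2 = groups, r2
            break
    return _binning_from_groups(variable, best_groups, "extremes", zero_class,
                                zero_rep, n_zero)


def apply_binning(values, binning: Binning) -> np.ndarray:
    """Map values (NaN = zero mark) to ordered category indices.

    Intervals are right-closed: a value equal to a threshold falls in the
    lower bin. Values outside the training range clamp to the extreme
    bins. With a zero class, zero marks map to category 0 and the
    non-zero bins are shifted up by one.
    """
    x = np.asarray(values, float)
    thr = np.asarray(binning.thresholds, float)
    # side='left' on -x trick not needed: searchsorted with side='left'
    # puts v == t in the lower bin for right-closed intervals.
    cats = np.searchsorted(thr, x, side="left")
    cats = np.clip(cats, 0, max(binning.k - 1, 0))
    if binning.has_zero_class:
        cats = cats + 1
        cats[np.isnan(x)] = 0
    elif np.isnan(x).any():
        raise ValueError(f"{binning.variable}: zero-marked values but no zero class")
    return cats.astype(int)
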