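"""Strength and significance of learned arcs.

Each arc parent -> child is scored by its Kullback–Leibler force: the
divergence, in bits per sample, between the fitted network and the same
network with the arc removed and its CPTs refit, the expectation taken
under the empirical distribution. Under maximum likelihood this equals
the empirical conditional mutual information of parent and child given
the child's other parents, and removing the arc raises the network's
description length by exactly N times the force. Significance uses the
G-test (the likelihood-ratio chi-square, G = 2 N ln2 MI_bits), and a
Pearson correlation on the underlying continuous values completes the
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayesnet import DiscreteBN

__all__ = ["ArcReport", "mutual_information", "arc_force_kl", "g_test",
           "arc_report"]


@dataclass
class ArcReport:
    parent: str
    child: str
    kl_force: float
    g_stat: float
    df: int
    p_value: float
    pearson_r: float


def _contingency(x: np.ndarray, y: np.ndarray,
                 ax: int | None = None, ay: int | None = None) -> np.ndarray:
    ax = ax or int(x.max()) + 1
    ay = ay or int(y.max()) + 1
    t = np.zeros((ax, ay))
    np.add.at(t, (x, y), 1.0)
    return t


def _mi_from_table(t: np.ndarray) -> float:
    n = t.sum()
    if n == 0:
        return 0.0
    p = t / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def mutual_information(x, y, z=None) -> float:
    """Empirical (conditional) mutual information in bits.

    With conditioning variables ``z`` (an array or list of arrays), the
    per-stratum MI values are averaged with empirical stratum weights.
    """
    x = np.asarray(x, int)
    y = np.asarray(y, int)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be equal-length, non-empty")
    if z is None:
        return max(0.0, _mi_from_table(_contingency(x, y)))
    z = np.asarray(z, int)
    if z.ndim == 1:
        z = z[:, None]
    # encode strata
    code = np.zeros(len(x), dtype=np.int64)
    for j in range(z.shape[1]):
        code = code * (z[:, j].max() + 1) + z[:, j]
    total = 0.0
    ax, ay = int(x.max()) + 1, int(y.max()) + 1
    for s in np.unique(code):
        m = code == s
        total += m.sum() / len(x) * _mi_from_table(
            _contingency(x[m], y[m], ax, ay))
    return max(0.0, float(total))


def arc_force_kl(bn: DiscreteBN, arc: tuple[str, str],
                 data: pd.DataFrame) -> float:
    """KL force of one arc in bits: conditional MI of parent and child
    given the child's other parents (the MLE likelihood-ratio per sample)."""
    parent, child = arc
    if parent not in bn.structure.parents[child]:
        raise ValueError(f"arc {parent}->{child} not in network")
    others = [p for p in bn.structure.parents[child] if p != parent]
    z = data[others].to_numpy() if others else None
    return mutual_information(data[parent].to_numpy(), data[child].to_numpy(), z)


def g_test(x, y, z=None) -> tuple[float, int, float]:
    """Likelihood-ratio test of (conditional) independence.

    G = 2 N ln(2) MI_bits; df = (a_x - 1)(a_y - 1) * prod(a_z); p from the
    chi-square upper tail.
    """
    x = np.asarray(x, int)
    y = np.asarray(y, int)
    n = len(x)
    mi = mutual_information(x, y, z)
    ax, ay = int(x.max()) + 1, int(y.max()) + 1
    df = (ax - 1) * (ay - 1)
    if z is not None:
        z = np.asarray(z, int)
        if z.ndim == 1:
            z = z[:, None]
        for j in range(z.shape[1]):
            df *= int(z[:, j].max()) + 1
    if df == 0:
        raise ValueError("degenerate single-category variable (df = 0)")
    g = 2.0 * n * np.log(2.0) * mi
    return float(g), int(df), float(stats.chi2.sf(g, df))


def _pearson_pairwise(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r with NaN (zero-marked) entries excluded pairwise."""
    m = ~(np.isnan(a) | np.isnan(b))
    if m.sum() < 3 or np.std(a[m]) == 0 or np.std(b[m]) == 0:
        return float("nan")
    return float(stats.pearsonr(a[m], b[m])[0])


def arc_report(bn: DiscreteBN, data: pd.DataFrame,
               raw_values: pd.DataFrame | None = None,
               alpha: float = 0.05) -> pd.DataFrame:
    """Per-arc KL force, G-test (conditioned on the child's other parents)
    and Pearson r on the continuous values, sorted by descending KL.

    ``raw_values`` holds the continuous (e.g. log relative abundance)
    columns aligned with ``data``; zero-marked entries are NaN and are
    excluded pairwise from the correlation. Arcs failing the G-test at
    ``alpha`` are flagged, not removed.
    """
    rows = []
    for parent, child in bn.structure.arcs:
        kl = arc_force_kl(bn, (parent, child), data)
        others = [p for p in bn.structure.parents[child] if p != parent]
        z = data[others].to_numpy() if others else None
        g, df, p = g_test(data[parent].to_numpy(), data[child].to_numpy(), z)
        if raw_values is not None and parent in raw_values and child in raw_values:
            r = _pearson_pairwise(raw_values[parent].to_numpy(float),
                                  raw_values[child].to_numpy(float))
        else:
            r = float("nan")
        rows.append({"parent": parent, "child": child, "KL": kl, "G": g,
                     "df": df, "p": p, "r": r, "significant": p < alpha})
    out = pd.DataFrame(rows, columns=["parent", "child", "KL", "G", "df", "p",
                                      "r", "significant"])
    return out.sort_values("KL", ascending=False, kind="mergesort").reset_index(
        drop=True)
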