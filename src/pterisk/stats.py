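"""Descriptive statistics, Pearson correlations and Ward clustering.

Summaries are computed on DL/2-substituted values in each element's
reporting unit (Hg in ng g⁻¹), so they are directly comparable to the
published range/mean/SD tables.  Correlations use Pearson's r with
two-sided p-values from the t distribution on n−2 degrees of freedom.
Element association structure is explored with Ward's-method
agglomerative clustering on z-score-standardised concentration
profiles (standardisation is essential because Hg in ng g⁻¹ and Ba in
mg kg⁻¹ differ by orders of magnitude); set ``standardize=False`` to
cluster raw values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr

from .core import (
    ELEMENTS,
    Element,
    PlantSample,
    SoilSample,
    substitute_censored_reporting,
)

@dataclass(frozen=True)
class ElementSummary:
    """Range/mean/SD of one element over a sample set (reporting units)."""

    element: Element
    n: int
    n_censored: int
    min: float
    max: float
    mean: float
    sd: float


def summarize(values_or_samples, element: Element) -> ElementSummary:
    """Descriptive statistics for one element.

    Accepts a sequence of plant/soil samples (measurements are DL/2
    substituted, kept in the reporting unit) or a plain sequence of
    numbers.  Sample SD (ddof=1); 0 for a single value.
    """
    values: list[float] = []
    n_censored = 0
    for item in values_or_samples:
        if isinstance(item, (PlantSample, SoilSample)):
            m = item.measurements.get(element)
            if m is None:
                continue
            values.append(substitute_censored_reporting(m))
            n_censored += int(m.censored)
        else:
            values.append(float(item))
    if not values:
        raise ValueError(f"no measurements for {element.value}")
    arr = np.asarray(values, dtype=float)
    return ElementSummary(
        element=element,
        n=len(arr),
        n_censored=n_censored,
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    )


def element_summaries(
    pairs: list[tuple[PlantSample, Optional[SoilSample]]]
) -> pd.DataFrame:
    """Range/mean/SD table for plants and (where present) soils."""
    records = []
    plants = [p for p, _ in pairs]
    soils = [s for _, s in pairs if s is not None]
    for element in ELEMENTS:
        for kind, samples in (("plant", plants), ("soil", soils)):
            has = [s for s in samples if element in s.measurements]
            if not has:
                continue
            s = summarize(has, element)
            records.append(
                {
                    "element": element.value,
                    "kind": kind,
                    "unit": element.reporting_unit.value,
                    "n": s.n,
                    "n_censored": s.n_censored,
                    "min": s.min,
                    "max": s.max,
                    "mean": s.mean,
                    "sd": s.sd,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["element", "kind", "unit", "n", "n_censored", "min", "max", "mean", "sd"],
    )


def concentration_frame(
    pairs: list[tuple[PlantSample, Optional[SoilSample]]], kind: str = "plant"
) -> pd.DataFrame:
    """Samples × elements matrix of substituted reporting-unit values."""
    samples = [p for p, _ in pairs] if kind == "plant" else [
        s for _, s in pairs if s is not None
    ]
    data = {}
    for element in ELEMENTS:
        data[element.value] = [
            substitute_censored_reporting(s.measurements[element])
            if element in s.measurements
            else np.nan
            for s in samples
        ]
    return pd.DataFrame(data, index=[s.sample_id for s in samples])


def pearson_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over the frame's columns.

    Rows with a missing value in either column are dropped pairwise; a
    pair needs at least 3 complete observations and non-zero variance
    in both columns, otherwise its entry is NaN.
    """
    cols = list(df.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            sub = df[[cols[i], cols[j]]].dropna()
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                continue
            res = pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


@dataclass
class Dendrogram:
    """An ordered agglomerative merge list over named leaves.

    ``merges`` rows are (cluster_a, cluster_b, linkage_distance,
    merged_size) with clusters numbered scipy-style: leaf i is cluster
    i, the m-th merge creates cluster n_leaves + m.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def linkage_matrix(self) -> np.ndarray:
        return np.asarray(
            [[a, b, d, s] for a, b, d, s in self.merges], dtype=float
        )

    def cut(self, k: int) -> list[set[str]]:
        """Partition the leaves into k clusters, largest gap first."""
        assignments = hierarchy.fcluster(
            self.linkage_matrix, t=k, criterion="maxclust"
        )
        groups: dict[int, set[str]] = {}
        for label, a in zip(self.labels, assignments):
            groups.setdefault(int(a), set()).add(label)
        return [groups[key] for key in sorted(groups)]

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "merges": [
                {"cluster_a": a, "cluster_b": b, "distance": d, "size": s}
                for a, b, d, s in self.merges
            ],
        }

    def to_newick(self) -> str:
        """Newick rendering with branch lengths from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for m, (a, b, d, _s) in enumerate(self.merges):
            la = f"{node[a]}:{(d - height[a]):.6g}"
            lb = f"{node[b]}:{(d - height[b]):.6g}"
            node[n + m] = f"({la},{lb})"
            height[n + m] = d
        return node[n + len(self.merges) - 1] + ";"


def ward_cluster(
    feature_matrix: pd.DataFrame, standardize: bool = True
) -> Dendrogram:
    """Ward's-method hierarchical clustering of the frame's *columns*.

    Each column (variable) becomes a leaf; the distance between leaves
    is the Euclidean distance between their (optionally z-scored)
    observation vectors.  Requires at least two columns and no missing
    values.
    """
    if feature_matrix.shape[1] < 2:
        raise ValueError("need at least 2 variables to cluster")
    X = feature_matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X.T, method="ward")
    merges = [
        (int(a), int(b), float(d), int(s)) for a, b, d, s in Z
    ]
    return Dendrogram(labels=[str(c) for c in feature_matrix.columns], merges=merges)
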