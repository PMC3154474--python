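"""Distribution comparisons between conformational ensembles.

Small NMR families are compared parameter-by-parameter with a Welch-form
Z-score of the difference of means; large MD-style ensembles with the
exact two-sample Kolmogorov-Smirnov statistic, optionally normalized by
its asymptotic critical value (the "KS ratio": a value above 1 means the
difference is significant at the chosen alpha).  Class-conditional
histograms are normalized over the total frame count across all classes,
so curve areas show the relative abundance of each hydrogen-bonded
species.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PtggError
from .hbonds import FrameClassTable
from .helix_params import ParamTable


@dataclasses.dataclass
class SampleVector:
    """One parameter's values for one ensemble or class."""

    values: np.ndarray
    label: str = ""
    parameter: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    @property
    def n(self) -> int:
        return self.values.size


def _require_two(a: SampleVector, b: SampleVector) -> None:
    if a.n < 2 or b.n < 2:
        raise ValueError("statistical comparison needs n >= 2 in both samples")


def zscore(a: SampleVector, b: SampleVector) -> float:
    """Welch-form Z of the difference of sample means.

    Z = (mean_a - mean_b) / sqrt(var_a/n_a + var_b/n_b), antisymmetric
    under swapping the samples.  Two zero-variance samples with equal
    means give 0; with unequal means the statistic is undefined.
    """
    _require_two(a, b)
    va = float(np.var(a.values, ddof=1))
    vb = float(np.var(b.values, ddof=1))
    dm = float(np.mean(a.values) - np.mean(b.values))
    if va == 0.0 and vb == 0.0:
        if dm == 0.0:
            return 0.0
        raise ZeroDivisionError("zero variance in both samples with unequal means")
    return dm / float(np.sqrt(va / a.n + vb / b.n))


def ks_statistic(a: SampleVector, b: SampleVector) -> float:
    """Exact two-sample KS statistic: sup_x |ECDF_a(x) - ECDF_b(x)|.

    Computed by merging the sorted samples; handles ties exactly.
    """
    _require_two(a, b)
    xa = np.sort(a.values)
    xb = np.sort(b.values)
    grid = np.concatenate([xa, xb])
    cdf_a = np.searchsorted(xa, grid, side="right") / a.n
    cdf_b = np.searchsorted(xb, grid, side="right") / b.n
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_critical_value(n_a: int, n_b: int, alpha: float = 0.05) -> float:
    """Asymptotic two-sample KS critical value c(alpha)*sqrt((na+nb)/(na*nb))."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    c = float(np.sqrt(-0.5 * np.log(alpha / 2.0)))
    return c * float(np.sqrt((n_a + n_b) / (n_a * n_b)))


def ks_ratio(a: SampleVector, b: SampleVector, alpha: float = 0.05) -> float:
    """KS statistic normalized by its alpha-level critical value.

    A ratio above 1 marks a difference significant at ``alpha``.  This
    normalization is this package's reading of the heat-map statistic used
    for MD-ensemble comparisons; it is isolated here so an alternative
    definition is a one-line change.
    """
    return ks_statistic(a, b) / ks_critical_value(a.n, b.n, alpha)


_STATISTICS = {"z": zscore, "ks": ks_statistic, "ks_ratio": ks_ratio}


@dataclasses.dataclass
class ComparisonMatrix:
    """Parameters x comparisons grid of Z-scores or KS values (heat-map data)."""

    data: pd.DataFrame  # rows: parameter names; columns: comparison names
    statistic: str
    alpha: float | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("comparison matrix has non-finite cells")

    def max_cell(self, absolute: bool = True) -> tuple[str, str]:
        """(parameter, comparison) of the largest (|.| by default) cell."""
        values = self.data.to_numpy(dtype=float)
        if absolute:
            values = np.abs(values)
        r, c = np.unravel_index(np.argmax(values), values.shape)
        return str(self.data.index[r]), str(self.data.columns[c])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="parameter")

    def bonferroni_threshold(self, base_alpha: float = 0.05) -> float:
        """Optional multiple-testing metadata: alpha / number of cells."""
        return base_alpha / self.data.size


def comparison_matrix(
    tables: dict[str, ParamTable],
    comparisons: Sequence[tuple[str, str]],
    statistic: str = "z",
    alpha: float = 0.05,
) -> ComparisonMatrix:
    """One statistic per (parameter, comparison-of-two-named-tables) cell.

    All tables must share the same parameter designation (identical
    parameter columns); comparisons name pairs of table labels, rendered
    as "A vs B" columns.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
    labels = list(tables)
    params = tables[labels[0]].parameter_names()
    for label in labels[1:]:
        if tables[label].parameter_names() != params:
            raise PtggError(
                f"table {label!r} designation differs from {labels[0]!r}; "
                "comparisons need a shared parameter set")
    cells = {}
    for la, lb in comparisons:
        if la not in tables or lb not in tables:
            raise KeyError(f"comparison ({la}, {lb}) names an unknown table")
        column = []
        for p in params:
            a = SampleVector(tables[la].column(p), la, p)
            b = SampleVector(tables[lb].column(p), lb, p)
            if statistic == "ks_ratio":
                column.append(ks_ratio(a, b, alpha))
            else:
                column.append(_STATISTICS[statistic](a, b))
        cells[f"{la} vs {lb}"] = column
    data = pd.DataFrame(cells, index=params)
    return ComparisonMatrix(data, statistic, alpha if statistic == "ks_ratio" else None)


@dataclasses.dataclass
class ReferenceValue:
    """An external single-structure parameter value to overlay on histograms."""

    parameter: str
    value: float
    source_tag: str = ""


@dataclasses.dataclass
class ClassHistogram:
    """Per-class histogram masses on shared bins, normalized jointly.

    The normalization constant is the total frame count over ALL classes,
    so summing every class's masses gives 1 and each class's total mass
    equals its frequency as a fraction.
    """

    bin_edges: np.ndarray
    masses: dict[str, np.ndarray]
    parameter: str = ""
    reference: ReferenceValue | None = None

    def __post_init__(self):
        total = float(sum(m.sum() for m in self.masses.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"total mass {total} != 1")

    def class_mass(self, name: str) -> float:
        return float(self.masses[name].sum())

    def to_frame(self) -> pd.DataFrame:
        out = {"bin_left": self.bin_edges[:-1], "bin_right": self.bin_edges[1:]}
        out.update({name: m for name, m in self.masses.items()})
        return pd.DataFrame(out)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def freedman_diaconis_edges(values: np.ndarray, max_bins: int = 200) -> np.ndarray:
    """Freedman-Diaconis bin edges on the pooled sample."""
    values = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    span = values.max() - values.min()
    if iqr <= 0 or span <= 0:
        return np.linspace(values.min() - 0.5, values.max() + 0.5, 2)
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0)
    n_bins = min(max_bins, max(1, int(np.ceil(span / width))))
    return np.linspace(values.min(), values.max(), n_bins + 1)


def class_histograms(
    values: SampleVector,
    classes: FrameClassTable,
    bins: int | np.ndarray | None = None,
    reference: ReferenceValue | None = None,
) -> ClassHistogram:
    """Split one parameter's per-frame values by hydrogen-bond class.

    ``bins`` may be explicit edges, a bin count, or None for
    Freedman-Diaconis on the pooled sample (shared edges keep the class
    curves comparable in one panel).
    """
    if values.n != classes.n_frames:
        raise PtggError(
            f"values ({values.n}) and classes ({classes.n_frames}) are misaligned")
    if bins is None:
        edges = freedman_diaconis_edges(values.values)
    elif np.isscalar(bins):
        edges = np.linspace(values.values.min(), values.values.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    labels = np.asarray(classes.labels)
    total = values.n
    masses = {}
    for name in classes.class_names():
        sel = values.values[labels == name]
        counts, _ = np.histogram(sel, bins=edges)
        masses[name] = counts / total
    # frames outside the edge range would break joint normalization
    covered = float(sum(m.sum() for m in masses.values()))
    if abs(covered - 1.0) > 1e-12:
        edges = np.concatenate([[min(edges[0], values.values.min())],
                                edges[1:-1],
                                [max(edges[-1], values.values.max())]])
        masses = {}
        for name in classes.class_names():
            sel = values.values[labels == name]
            counts, _ = np.histogram(sel, bins=edges)
            masses[name] = counts / total
    return ClassHistogram(edges, masses, values.parameter, reference)


def trim_equilibration(
    table: ParamTable,
    burn_in: float | int = 0.4,
    per_run: bool = True,
) -> ParamTable:
    """Drop the equilibration portion of a parameter table.

    ``burn_in`` is a fraction (< 1) or an absolute frame count per run;
    the default 0.4 keeps the final 60% of each run (the convention of
    keeping the last 6 of 10 ns).  Concatenated runs are recognized by a
    ``run_id`` column and trimmed independently when ``per_run`` is set.
    """
    df = table.data
    if "run_id" in df.columns and per_run:
        groups = [g for _, g in df.groupby("run_id", sort=False)]
    else:
        groups = [df]
    kept = []
    for g in groups:
        n = len(g)
        cut = int(round(burn_in * n)) if 0 <= burn_in < 1 else int(burn_in)
        if cut >= n:
            raise PtggError(f"burn-in {burn_in} leaves no frames of a {n}-frame run")
        kept.append(g.iloc[cut:])
    out = pd.concat(kept, ignore_index=True)
    return ParamTable(out, table.pair_indices, table.step_indices)
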