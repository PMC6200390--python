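"""Community structure: Bray-Curtis dissimilarity, PCoA, emitter contrasts,
and variance decomposition of ordination axes.

Bray-Curtis between samples u and v is ``1 - 2 * sum_k min(x_uk, x_vk) /
sum_k (x_uk + x_vk)``: 0 for identical composition, 1 for disjoint.  It is
computed on per-sample relative abundances so that sequencing depth cancels.
Principal-coordinates analysis embeds the dissimilarity matrix by Gower
double-centering and eigendecomposition; ordination axes are then treated as
quantitative phenotypes whose fixed-factor shares (sequential ANOVA) and
heritability (animal model) quantify what drives community stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .kernels import Kernel
from .microbiome import AbundanceMatrix
from .reml import build_design, fit_reml, wald_interval


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("dissimilarity matrix is not symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValueError("dissimilarity diagonal must be zero")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis values must lie in [0, 1]")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path, sep="\t")


def bray_curtis(abund, sample_ids=None, relative: bool = True
                ) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    ``abund`` is an AbundanceMatrix or a samples-x-taxa array of
    non-negative abundances; by default each row is first normalized to
    relative abundance.
    """
    if isinstance(abund, AbundanceMatrix):
        x = abund.values
        labels = list(abund.sample_ids)
    else:
        x = np.asarray(abund, dtype=float)
        labels = ([str(i) for i in range(x.shape[0])]
                  if sample_ids is None else [str(s) for s in sample_ids])
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    rowsum = x.sum(axis=1)
    if (rowsum == 0).any():
        bad = [labels[i] for i in np.flatnonzero(rowsum == 0)]
        raise ValueError(f"samples with all-zero abundance: {bad[:10]}")
    if relative:
        x = x / rowsum[:, None]
    d = squareform(pdist(x, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(labels, np.clip(d, 0.0, 1.0))


@dataclass
class Ordination:
    """PCoA embedding: axes ordered by decreasing eigenvalue."""

    coordinates: np.ndarray         # samples x kept axes
    eigenvalues: np.ndarray         # all eigenvalues, descending
    proportion_explained: np.ndarray  # per kept axis, of positive eigenvalues
    sample_ids: list[str]

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]

    def axis(self, k: int) -> np.ndarray:
        return self.coordinates[:, k]


def pcoa(d: DissimilarityMatrix, n_axes: int | None = None) -> Ordination:
    """Classical principal-coordinates analysis.

    Gower-centers ``-0.5 * D^2``, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues.  Axes with negative
    eigenvalues are reported via ``eigenvalues`` but excluded from the
    coordinates; no Cailliez/Lingoes correction is applied.  Axis signs are
    fixed by making the largest-magnitude coordinate positive.
    """
    D = d.values
    n = D.shape[0]
    B = -0.5 * D ** 2
    B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
    B = 0.5 * (B + B.T)
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = 1e-8 * max(abs(eigval[0]), 1.0)
    n_pos = int((eigval > tol).sum())
    keep = n_pos if n_axes is None else n_axes
    if keep > n_pos:
        warnings.warn(f"requested {keep} axes but only {n_pos} positive "
                      "eigenvalues; truncating", stacklevel=2)
        keep = n_pos
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
    for k in range(keep):
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigval[:n_pos].sum()
    prop = eigval[:keep] / pos_sum if pos_sum > 0 else np.zeros(keep)
    return Ordination(coords, eigval, prop, list(d.labels))


# ---------------------------------------------------------------------------
# emitter groups


def decile_groups(values, ids=None) -> np.ndarray:
    """Label the top/bottom 10% of a phenotype ('high'/'low'/'intermediate').

    Ties are broken by stable id order.  Requires at least 10 observations.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 10:
        raise ValueError("need at least 10 phenotyped animals")
    ids = np.arange(n) if ids is None else np.asarray(ids)
    order = np.lexsort((ids, v))  # ascending value, stable by id
    k = n // 10
    labels = np.array(["intermediate"] * n, dtype=object)
    labels[order[:k]] = "low"
    labels[order[-k:]] = "high"
    return labels


def percent_difference(high_mean: float, low_mean: float) -> float:
    """Percent difference of group means relative to the high group:
    ``100 * (high - low) / high``."""
    if high_mean == 0:
        raise ValueError("high-group mean must be nonzero")
    return 100.0 * (high_mean - low_mean) / high_mean


def decile_contrast(values, ids=None) -> dict:
    """Group means and percent difference between top and bottom deciles."""
    v = np.asarray(values, dtype=float)
    labels = decile_groups(v, ids)
    hi = float(v[labels == "high"].mean())
    lo = float(v[labels == "low"].mean())
    return {"high_mean": hi, "low_mean": lo,
            "percent_difference": percent_difference(hi, lo)}


def mann_whitney_axis(axis_values, groups, high: str = "high",
                      low: str = "low"):
    """Two-sided Mann-Whitney U test of an ordination axis between the high
    and low emitter groups; exact enumeration when both groups have <= 8
    members, normal approximation with tie correction otherwise.

    Returns ``(U, p)`` with U the statistic of the high group.
    """
    axis_values = np.asarray(axis_values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    x = axis_values[groups == high]
    z = axis_values[groups == low]
    if len(x) == 0 or len(z) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (len(x) <= 8 and len(z) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, z, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# axis variance decomposition


@dataclass
class AxisDecomposition:
    factor_shares: dict[str, float]   # fraction of axis variance per factor
    anova: pd.DataFrame
    h2: float
    h2_se: float
    h2_ci: tuple[float, float]
    fit: object = field(repr=False, default=None)
    factor_order: tuple[str, ...] = ()


def axis_variance_decomposition(axis_values, metadata, A: Kernel,
                                wilmink_k: float = 0.065) -> AxisDecomposition:
    """Fixed-factor shares and heritability of an ordination axis.

    Factor shares come from sequential (type I) sums of squares of a linear
    model in the fixed order herd, parity, sequencing batch, dim, Wilmink
    term (factors absent from the metadata are skipped).  The heritability of
    the axis comes from an animal-model REML fit with sequencing batch
    (nested in platform), parity, dim and the Wilmink term as fixed effects.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    md = pd.DataFrame(metadata).copy().reset_index(drop=True)
    md["_axis"] = np.asarray(axis_values, dtype=float)
    md["_wilmink"] = np.exp(-wilmink_k * md["dim"].to_numpy(float))
    terms = []
    if "herd" in md:
        terms.append(("herd", "C(herd)"))
    if "parity" in md:
        terms.append(("parity", "C(parity)"))
    if "batch" in md:
        if "platform" in md:
            md["_batch"] = md["platform"].astype(str) + ":" + md["batch"].astype(str)
        else:
            md["_batch"] = md["batch"].astype(str)
        terms.append(("batch", "C(_batch)"))
    terms.append(("dim", "dim"))
    terms.append(("wilmink", "_wilmink"))
    formula = "_axis ~ " + " + ".join(t[1] for t in terms)
    ols = smf.ols(formula, data=md).fit()
    try:
        anova = sm.stats.anova_lm(ols, typ=1)
    except Exception as exc:
        raise ValueError(f"aliased factors in axis model: {exc}") from exc
    total_ss = float(anova["sum_sq"].sum())
    shares: dict[str, float] = {}
    for name, term in terms:
        if term in anova.index:
            shares[name] = float(anova.loc[term, "sum_sq"]) / total_ss
    shares["residual"] = float(anova.loc["Residual", "sum_sq"]) / total_ss

    X, _ = build_design(md, wilmink_k=wilmink_k, include_herd=False,
                        include_batch="batch" in md)
    ids = md["animal"].astype(str).tolist() if "animal" in md else None
    Asub = A.subset(ids).values if ids is not None else A.values
    est = fit_reml(md["_axis"].to_numpy(), X, {"A": Asub})
    h2 = est.ratios["A"]
    se = est.ratio_se["A"]
    ci = wald_interval(h2, se) if np.isfinite(se) and se > 0 else (np.nan, np.nan)
    return AxisDecomposition(factor_shares=shares, anova=anova, h2=h2,
                             h2_se=se, h2_ci=ci, fit=est,
                             factor_order=tuple(t[0] for t in terms))
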