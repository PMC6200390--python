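"""Mixed-model association of taxon abundances with the phenotype.

Each taxon's log abundance is fit as a covariate of the animal model,
``y = X b + beta * x_taxon + a + e`` with ``a ~ N(0, A sigma2_a)``, i.e. the
taxon effect is estimated in place of an allele-substitution effect while
pedigree relatedness and environmental fixed effects are controlled.  The
default scan estimates the variance components once under the null model and
reuses them for every taxon (P3D-style); ``mode="exact"`` re-estimates them
per taxon.  Multiple testing is handled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .kernels import Kernel
from .reml import build_design, fit_reml, _fit_single_rotated


@dataclass
class BhResult:
    """Benjamini-Hochberg step-up outcome."""

    qvalues: np.ndarray
    reject: np.ndarray
    q_level: float
    neglog10_threshold: float  # -log10 of the largest rejected p (nan if none)

    @property
    def n_significant(self) -> int:
        return int(self.reject.sum())


def bh_fdr(pvalues, q_level: float = 0.15) -> BhResult:
    """Standard Benjamini-Hochberg step-up procedure.

    Returns adjusted q-values, the rejection set at ``q_level``, and the
    realized significance threshold as -log10 of the largest rejected
    p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    if reject.any():
        pmax = max(float(p[reject].max()), 1e-300)  # guard p = 0 exactly
        thr = float(-np.log10(pmax))
    else:
        thr = float("nan")
    return BhResult(qvalues=q, reject=reject, q_level=q_level,
                    neglog10_threshold=thr)


@dataclass
class AssociationScan:
    table: pd.DataFrame          # taxon_id, beta, se, p, q, n_used
    fdr: BhResult
    variance_components: dict[str, float]
    mode: str


def mlm_association(y, metadata, abund, A: Kernel, mode: str = "reuse",
                    q_level: float = 0.15, include_batch: bool = True,
                    known_variance: tuple[float, float] | None = None
                    ) -> AssociationScan:
    """Per-taxon mixed-model association scan.

    Parameters
    ----------
    y : phenotype vector aligned with ``abund.sample_ids``.
    metadata : DataFrame with herd, parity, dim (and batch/platform when
        ``include_batch``) in the same order.
    abund : AbundanceMatrix of log-transformed abundances (samples x taxa).
    A : pedigree kernel; subset to the scan samples.
    mode : "reuse" estimates (sigma2_a, sigma2_e) once without any taxon
        covariate and reuses them (P3D); "exact" re-estimates per taxon.
    known_variance : optional (sigma2_a, sigma2_e) override, skipping the
        null fit entirely.
    """
    y = np.asarray(y, dtype=float)
    samples = list(abund.sample_ids)
    n = len(samples)
    if len(y) != n:
        raise ValueError("phenotype length does not match abundance samples")
    Asub = A.subset(samples).values
    X0, _ = build_design(metadata, include_batch=include_batch)
    Z = abund.values

    if known_variance is not None:
        s_a, s_e = map(float, known_variance)
    else:
        null = fit_reml(y, X0, {"A": Asub})
        s_a = null.components["A"]
        s_e = null.components["residual"]

    rows = []
    if mode == "reuse":
        V = s_a * Asub + s_e * np.eye(n)
        cf = linalg.cho_factor(V, lower=True)
        Viy = linalg.cho_solve(cf, y)
        ViX0 = linalg.cho_solve(cf, X0)
        for t, taxon in enumerate(abund.taxon_ids):
            x = Z[:, t]
            if np.var(x) == 0:
                warnings.warn(f"taxon {taxon!r} has zero variance; skipped",
                              stacklevel=2)
                continue
            Vix = linalg.cho_solve(cf, x)
            Xf = np.column_stack([X0, x])
            ViXf = np.column_stack([ViX0, Vix])
            XtViX = Xf.T @ ViXf
            Ci = np.linalg.inv(XtViX)
            beta_all = Ci @ (Xf.T @ Viy)
            beta = float(beta_all[-1])
            se = float(np.sqrt(Ci[-1, -1]))
            z = beta / se
            p = 2.0 * float(stats.norm.sf(abs(z)))
            rows.append((taxon, beta, se, p, n))
    elif mode == "exact":
        S, U = np.linalg.eigh(Asub)
        S = np.clip(S, 0.0, None)
        yr = U.T @ y
        X0r = U.T @ X0
        Zr = U.T @ Z
        for t, taxon in enumerate(abund.taxon_ids):
            if np.var(Z[:, t]) == 0:
                warnings.warn(f"taxon {abund.taxon_ids[t]!r} has zero "
                              "variance; skipped", stacklevel=2)
                continue
            Xfr = np.column_stack([X0r, Zr[:, t]])
            est = _fit_single_rotated(S, yr, Xfr, "A")
            sa, se_ = est.components["A"], est.components["residual"]
            v = sa * S + se_
            Xw = Xfr / v[:, None]
            C = Xfr.T @ Xw
            Ci = np.linalg.inv(C)
            beta_all = Ci @ (Xw.T @ yr)
            beta = float(beta_all[-1])
            se_b = float(np.sqrt(Ci[-1, -1]))
            p = 2.0 * float(stats.norm.sf(abs(beta / se_b)))
            rows.append((taxon, beta, se_b, p, n))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    df = pd.DataFrame(rows, columns=["taxon_id", "beta", "se", "p", "n_used"])
    if df.empty:
        raise ValueError("no testable taxa (all zero-variance?)")
    fdr = bh_fdr(df["p"].to_numpy(), q_level=q_level)
    df["q"] = fdr.qvalues
    return AssociationScan(table=df, fdr=fdr,
                           variance_components={"A": s_a, "residual": s_e},
                           mode=mode)


def manhattan_table(assoc: pd.DataFrame, h2_table: pd.DataFrame | None = None,
                    taxonomy: dict | None = None) -> pd.DataFrame:
    """Plot-ready tidy table: -log10(p) per taxon, colored by taxon h2.

    ``h2_table`` (from the heritability scan) must cover the same taxa when
    given; missing h2 is coded NaN when no table is supplied.
    """
    df = assoc.copy()
    df["neglog10_p"] = -np.log10(df["p"].clip(lower=1e-300))
    if h2_table is not None:
        missing = set(df["taxon_id"]) - set(h2_table["taxon_id"])
        if missing:
            raise ValueError(f"taxa missing from heritability table: "
                             f"{sorted(missing)[:5]}")
        df = df.merge(h2_table[["taxon_id", "h2"]], on="taxon_id", how="left")
    else:
        df["h2"] = np.nan
    if taxonomy is not None:
        df["taxonomy"] = df["taxon_id"].map(taxonomy)
    return df


def plot_manhattan(table: pd.DataFrame, path,
                   threshold_neglog10p: float | None = None) -> None:
    """Scatter of -log10(p) per taxon, colored by h2, with the FDR line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    c = table["h2"].to_numpy(float)
    sc = ax.scatter(np.arange(len(table)), table["neglog10_p"],
                    c=np.nan_to_num(c), cmap="Blues", vmin=0.0,
                    vmax=max(0.30, np.nanmax(c) if np.isfinite(c).any() else 0.3),
                    s=14, edgecolors="none")
    if threshold_neglog10p is not None and np.isfinite(threshold_neglog10p):
        ax.axhline(threshold_neglog10p, color="red", lw=1, ls="--")
    ax.set_xlabel("taxon")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    fig.colorbar(sc, label=r"$h^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
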