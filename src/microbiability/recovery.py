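"""Parameter-recovery studies on synthetic herds.

Each routine simulates replicate herds under the generative model, runs the
matching REML fit, and returns the per-replicate variance-ratio estimates.
These are the package's validation surface: with the generator and estimator
sharing the same kernels, the replicate mean of h-hat-2 / m-hat-2 should
recover the configured truth.

Replicate seeds are spawned deterministically from a base seed and kept
below 2**31.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .simulate import (SimConfig, simulate_pedigree, simulate_otu_table,
                       simulate_phenotype)
from .pedigree import build_A
from .microbiome import microbial_kernel, filter_samples
from .reml import build_design, fit_reml


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(base_seed))
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def _study_config(seed: int, **overrides) -> SimConfig:
    cfg = SimConfig(seed=seed, frac_low_depth_samples=0.0)
    return replace(cfg, **overrides)


def _fit_once(cfg: SimConfig, kernels: tuple[str, ...]):
    """Simulate one herd and fit the requested kernel combination."""
    ped = simulate_pedigree(cfg)
    A_full = build_A(ped)
    F = A_full.values.diagonal() - 1.0
    otus = None
    if "M" in kernels:
        otus = simulate_otu_table(cfg, ped, inbreeding=F)
    pheno, truth = simulate_phenotype(cfg, ped, otus, inbreeding=F)
    ids = pheno["animal"].tolist()
    y = pheno["ch4_g_day"].to_numpy()
    X, _ = build_design(pheno)
    mats = {}
    if "A" in kernels:
        mats["A"] = A_full.subset(ids).values
    if "M" in kernels:
        M = microbial_kernel(otus)
        mats["M"] = M.subset(ids).values
    fit = fit_reml(y, X, mats)
    return fit, truth


def recover_h2_pedigree(n_replicates: int = 40, base_seed: int = 1,
                        true_h2: float = 0.19) -> np.ndarray:
    """Pedigree-only animal model: h-hat-2 per replicate (n = 1000 cows)."""
    seeds = spawn_seeds(base_seed, n_replicates)
    out = np.empty(n_replicates)
    for r, s in enumerate(seeds):
        cfg = _study_config(s, true_h2=true_h2, true_m2=0.0)
        fit, _ = _fit_once(cfg, ("A",))
        out[r] = fit.ratios["A"]
    return out


def recover_m2_microbiome(n_replicates: int = 40, base_seed: int = 2,
                          true_m2: float = 0.15,
                          n_taxa: int = 2000) -> np.ndarray:
    """Microbial-kernel-only model: m-hat-2 per replicate (2000 taxa)."""
    seeds = spawn_seeds(base_seed, n_replicates)
    n_arch = max(1, round(n_taxa * 0.05))
    out = np.empty(n_replicates)
    for r, s in enumerate(seeds):
        cfg = _study_config(s, true_h2=0.0, true_m2=true_m2,
                            n_bact_otus=n_taxa - n_arch, n_arch_otus=n_arch)
        fit, _ = _fit_once(cfg, ("M",))
        out[r] = fit.ratios["M"]
    return out


def recover_joint(n_replicates: int = 40, base_seed: int = 3,
                  true_h2: float = 0.21, true_m2: float = 0.13):
    """Two-kernel joint model: (h-hat-2, m-hat-2) arrays per replicate."""
    seeds = spawn_seeds(base_seed, n_replicates)
    h2 = np.empty(n_replicates)
    m2 = np.empty(n_replicates)
    for r, s in enumerate(seeds):
        cfg = _study_config(s, true_h2=true_h2, true_m2=true_m2)
        fit, _ = _fit_once(cfg, ("A", "M"))
        h2[r] = fit.ratios["A"]
        m2[r] = fit.ratios["M"]
    return h2, m2
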