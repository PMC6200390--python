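"""Synthetic herd generator: pedigrees, rumen OTU tables, and phenotypes.

The generator emulates the statistical structure of a commercial dairy
methane study: a multi-generation pedigree dominated by a small number of
sires (large paternal half-sib families), breeding values with covariance
``A * sigma2_a``, compositional 16S OTU counts in which a minority of taxa
carry a pedigree-correlated abundance component, per-sample sequencing
platform/batch labels with batch-level mean shifts and variable library
depth, and a methane phenotype

``y = mu + herd + parity + b1*dim + b2*exp(-k*dim) + a + m + e``

where the microbial effect is generated through per-taxon coefficients,
``m = X b`` with ``b ~ N(0, sigma2_m / n_taxa)``, so its covariance equals
the microbial kernel ``M * sigma2_m`` exactly and m2 is identifiable by
construction.  Genetic and microbial effects are drawn independently.

All randomness flows from a single master seed through named substreams, so
outputs are bit-identical for a fixed configuration.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, build_A
from .microbiome import OtuTable, filter_samples, standardize, MIN_READS


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named, reproducible substream of the master seed."""
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def _as_rng(seed_or_rng, stream: str) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return _rng(int(seed_or_rng), stream)


@dataclass
class SimConfig:
    """Study conditions for the synthetic herd.

    Defaults follow the emulated study design: 6 herds, 4 parities, days in
    milk 1-350 with Wilmink decay 0.065, two sequencing platforms with 11
    batches, phenotype mean 395.8 g/d and SD 63.5 g/d, and joint variance
    fractions h2 = 0.21 and m2 = 0.13.
    """

    n_founders: int = 1000
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_sires: int = 25
    n_bact_otus: int = 1000
    n_arch_otus: int = 100
    frac_heritable_otus: float = 0.10
    otu_h2: float = 0.25
    true_h2: float = 0.21
    true_m2: float = 0.13
    total_phenotypic_variance: float = 63.5 ** 2   # (g/day)^2
    mean_phenotype: float = 395.8                  # g/day
    n_herds: int = 6
    n_parities: int = 4
    dim_range: tuple[int, int] = (1, 350)
    wilmink_k: float = 0.065
    mean_library_size: int = 100_000
    frac_low_depth_samples: float = 0.05
    n_platforms: int = 2
    n_batches: int = 11
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "offspring_per_mating",
                     "n_sires", "n_bact_otus", "n_arch_otus", "n_herds",
                     "n_parities", "mean_library_size", "n_platforms",
                     "n_batches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frac_heritable_otus", "otu_h2", "true_h2", "true_m2",
                     "frac_low_depth_samples"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.true_h2 + self.true_m2 > 1.0:
            raise ValueError("true_h2 + true_m2 must not exceed 1")
        if self.total_phenotypic_variance < 0:
            raise ValueError("total_phenotypic_variance must be non-negative")
        lo, hi = self.dim_range
        if lo < 1 or hi < lo:
            raise ValueError("dim_range must satisfy 1 <= lo <= hi")

    @property
    def n_otus(self) -> int:
        return self.n_bact_otus + self.n_arch_otus


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree with a small sire pool per generation.

    Each generation mates ``n_founders // 2`` dams (sampled from the previous
    generation) to ``n_sires`` sires, each mating producing
    ``offspring_per_mating`` offspring; generation sizes therefore stay near
    ``n_founders * offspring_per_mating / 2``.
    """
    if config.n_founders < 2:
        raise ValueError("need at least two founders")
    if config.n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    rng = _rng(config.seed, "pedigree")
    records: list[tuple[str, str | None, str | None]] = []
    prev = [f"G0_{i:05d}" for i in range(config.n_founders)]
    records += [(a, None, None) for a in prev]
    for g in range(1, config.n_generations + 1):
        prev_arr = np.array(prev)
        n_sires = max(1, min(config.n_sires, len(prev_arr) // 2))
        sires = rng.choice(prev_arr, size=n_sires, replace=False)
        rest = np.setdiff1d(prev_arr, sires)
        n_matings = min(config.n_founders // 2, len(rest))
        dams = rng.choice(rest, size=n_matings, replace=False)
        mates = rng.choice(sires, size=n_matings, replace=True)
        new: list[str] = []
        k = 0
        for sire, dam in zip(mates, dams):
            for _ in range(config.offspring_per_mating):
                child = f"G{g}_{k:05d}"
                records.append((child, str(sire), str(dam)))
                new.append(child)
                k += 1
        prev = new
    return Pedigree.from_records(records)


def last_generation(ped: Pedigree) -> list[str]:
    """Ids of the final (phenotyped) generation of a simulated pedigree."""
    gens = [int(a.split("_")[0][1:]) for a in ped.ids]
    gmax = max(gens)
    return [a for a, g in zip(ped.ids, gens) if g == gmax]


# ---------------------------------------------------------------------------
# genetic values


def _gene_drop(ped: Pedigree, F: np.ndarray, n_traits: int,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance pedigree-correlated values, one column per trait.

    Founders are N(0, 1); descendants are the parental mean plus a Mendelian
    sampling deviation whose variance carries the parental-inbreeding
    correction, so Cov over the pedigree equals A exactly.
    """
    n = ped.n
    out = np.empty((n, n_traits))
    z = rng.standard_normal((n, n_traits))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            out[i] = z[i]
        elif s >= 0 and d >= 0:
            msv = 0.5 * (1.0 - 0.5 * (F[s] + F[d]))
            out[i] = 0.5 * (out[s] + out[d]) + np.sqrt(msv) * z[i]
        else:
            k = s if s >= 0 else d
            msv = 0.75 - 0.25 * F[k]
            out[i] = 0.5 * out[k] + np.sqrt(msv) * z[i]
    return out


def simulate_breeding_values(ped: Pedigree, sigma2_a: float, seed=0,
                             inbreeding: np.ndarray | None = None) -> np.ndarray:
    """Additive breeding values a ~ N(0, A * sigma2_a), in pedigree order."""
    if sigma2_a < 0:
        raise ValueError("sigma2_a must be non-negative")
    rng = _as_rng(seed, "breeding_values")
    if inbreeding is None:
        inbreeding = build_A(ped).values.diagonal() - 1.0
    vals = _gene_drop(ped, np.asarray(inbreeding, float), 1, rng)[:, 0]
    return np.sqrt(sigma2_a) * vals


# ---------------------------------------------------------------------------
# OTU table

#: spread of taxon base log-abundances (controls how skewed the composition is)
_BASE_LOG_SD = 2.0
#: SD of per-(batch, taxon) mean shifts on the log scale
_BATCH_SHIFT_SD = 0.3
#: lognormal sigma of library sizes for normal-depth samples
_DEPTH_LOG_SD = 0.25


def _make_taxonomy(rng: np.random.Generator, n_bact: int, n_arch: int):
    """Fabricated hierarchical taxonomy strings; ~15% unassigned at genus."""
    tax = []
    for kingdom, n in (("Bacteria", n_bact), ("Archaea", n_arch)):
        n_fam = max(1, n // 20)
        n_gen = max(1, n // 8)
        fam_of_gen = rng.integers(0, n_fam, size=n_gen)
        for i in range(n):
            g = int(rng.integers(0, n_gen))
            f = int(fam_of_gen[g])
            genus = "" if rng.random() < 0.15 else f"{kingdom[:3]}Genus{g:03d}"
            tax.append(
                f"k__{kingdom}; p__P{f % 7:02d}; c__C{f % 11:02d}; "
                f"o__O{f % 13:02d}; f__{kingdom[:3]}Family{f:03d}; g__{genus}")
    return tax


def simulate_otu_table(config: SimConfig, ped: Pedigree, seed=None,
                       inbreeding: np.ndarray | None = None) -> OtuTable:
    """Compositional OTU counts for the final pedigree generation.

    A ``frac_heritable_otus`` share of taxa receives an independent
    pedigree-correlated component with variance fraction ``otu_h2`` on the
    latent log scale; latent abundances are softmax-normalized per sample
    and realized as multinomial counts at a per-sample library size.  A
    ``frac_low_depth_samples`` share of samples is drawn below 50,000 reads
    to exercise the depth filter.
    """
    rng = _as_rng(seed if seed is not None else config.seed, "otu_table")
    samples = last_generation(ped)
    pos = {a: i for i, a in enumerate(ped.ids)}
    sample_idx = [pos[s] for s in samples]
    n_s = len(samples)
    n_t = config.n_otus
    if n_t == 0:
        raise ValueError("no taxa configured")
    if inbreeding is None:
        inbreeding = build_A(ped).values.diagonal() - 1.0

    taxon_ids = ([f"Bac_OTU_{i:05d}" for i in range(config.n_bact_otus)]
                 + [f"Arc_OTU_{i:05d}" for i in range(config.n_arch_otus)])
    taxonomy = _make_taxonomy(rng, config.n_bact_otus, config.n_arch_otus)

    base = rng.normal(0.0, _BASE_LOG_SD, size=n_t)
    latent = base[None, :] + rng.standard_normal((n_s, n_t))
    n_her = int(round(config.frac_heritable_otus * n_t))
    heritable = rng.choice(n_t, size=n_her, replace=False)
    if n_her:
        g = _gene_drop(ped, np.asarray(inbreeding, float), n_her, rng)
        g = g[sample_idx, :]
        eps = rng.standard_normal((n_s, n_her))
        latent[:, heritable] = (base[heritable][None, :]
                                + np.sqrt(config.otu_h2) * g
                                + np.sqrt(1.0 - config.otu_h2) * eps)

    # platform / batch structure
    platforms = [f"Platform{p + 1}" for p in range(max(1, config.n_platforms))]
    plat_idx = rng.integers(0, len(platforms), size=n_s)
    batches_per_platform: list[list[int]] = [[] for _ in platforms]
    for b in range(max(1, config.n_batches)):
        batches_per_platform[b % len(platforms)].append(b)
    batch_idx = np.empty(n_s, dtype=int)
    for i in range(n_s):
        pool = batches_per_platform[plat_idx[i]]
        batch_idx[i] = pool[rng.integers(0, len(pool))]
    shift = rng.normal(0.0, _BATCH_SHIFT_SD,
                       size=(max(1, config.n_batches), n_t))
    latent += shift[batch_idx]

    expl = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs = expl / expl.sum(axis=1, keepdims=True)

    low = rng.random(n_s) < config.frac_low_depth_samples
    depth = np.round(rng.lognormal(
        np.log(config.mean_library_size) - 0.5 * _DEPTH_LOG_SD ** 2,
        _DEPTH_LOG_SD, size=n_s)).astype(np.int64)
    depth = np.maximum(depth, MIN_READS)
    depth[low] = rng.integers(10_000, MIN_READS, size=int(low.sum()))

    counts = np.empty((n_s, n_t), dtype=np.int64)
    for i in range(n_s):
        counts[i] = rng.multinomial(depth[i], probs[i])

    platform = np.array([platforms[p] for p in plat_idx], dtype=object)
    batch = np.array([f"{platforms[plat_idx[i]]}_batch{batch_idx[i]:02d}"
                      for i in range(n_s)], dtype=object)
    return OtuTable(counts.T, taxon_ids, samples, taxonomy, platform, batch,
                    provenance=["simulated"])


# ---------------------------------------------------------------------------
# phenotype

_HERD_EFFECT_SD = 25.0     # g/day
_PARITY_EFFECT_SD = 15.0   # g/day
_B1_DIM = 0.10             # g/day per day in milk
_B2_WILMINK = -25.0        # g/day


def simulate_phenotype(config: SimConfig, ped: Pedigree,
                       otu_table: OtuTable | None = None, seed=None,
                       inbreeding: np.ndarray | None = None):
    """Phenotype/metadata table plus a ground-truth sidecar dict.

    Animals are the final generation; when an OTU table is supplied, only
    animals whose sample passes the 50,000-read depth filter are phenotyped
    (the microbial effect is undefined without usable microbiome data).  The
    microbial effect is ``m = X b`` on the standardized abundance matrix, so
    its covariance is exactly ``M * sigma2_m``.
    """
    if config.true_h2 + config.true_m2 > 1.0:
        raise ValueError("true_h2 + true_m2 must not exceed 1")
    rng = _as_rng(seed if seed is not None else config.seed, "phenotype")
    sp = config.total_phenotypic_variance
    s_a = config.true_h2 * sp
    s_m = config.true_m2 * sp
    s_e = sp - s_a - s_m
    if inbreeding is None:
        inbreeding = build_A(ped).values.diagonal() - 1.0

    if otu_table is not None:
        filtered = filter_samples(otu_table, MIN_READS)
        animals = list(filtered.sample_ids)
    else:
        if config.true_m2 > 0:
            raise ValueError("true_m2 > 0 requires an OTU table")
        filtered = None
        animals = last_generation(ped)
    n = len(animals)
    pedpos = {a: i for i, a in enumerate(ped.ids)}
    idx = [pedpos[a] for a in animals]

    a_all = simulate_breeding_values(ped, s_a, rng, inbreeding=inbreeding)
    a = a_all[idx]

    if filtered is not None and s_m > 0:
        x = standardize(otu_table)
        if list(x.sample_ids) != animals:
            raise RuntimeError("standardized matrix does not align with samples")
        n_taxa = len(x.taxon_ids)
        b_taxa = rng.normal(0.0, np.sqrt(s_m / n_taxa), size=n_taxa)
        m = x.values @ b_taxa
    else:
        m = np.zeros(n)

    herd = rng.integers(1, config.n_herds + 1, size=n)
    parity_p = np.array([0.4, 0.3, 0.2, 0.1])[: config.n_parities]
    parity_p = parity_p / parity_p.sum()
    parity = rng.choice(np.arange(1, config.n_parities + 1), size=n, p=parity_p)
    dim = rng.integers(config.dim_range[0], config.dim_range[1] + 1, size=n)
    herd_eff = rng.normal(0.0, _HERD_EFFECT_SD, size=config.n_herds)
    parity_eff = rng.normal(0.0, _PARITY_EFFECT_SD, size=config.n_parities)
    e = rng.normal(0.0, np.sqrt(s_e), size=n)

    y = (config.mean_phenotype + herd_eff[herd - 1] + parity_eff[parity - 1]
         + _B1_DIM * dim + _B2_WILMINK * np.exp(-config.wilmink_k * dim)
         + a + m + e)

    if otu_table is not None:
        pos = {s: i for i, s in enumerate(otu_table.sample_ids)}
        platform = [otu_table.platform[pos[s]] for s in animals]
        batch = [otu_table.batch[pos[s]] for s in animals]
    else:
        platform = ["Platform1"] * n
        batch = ["Platform1_batch00"] * n

    table = pd.DataFrame({
        "animal": animals, "ch4_g_day": y, "herd": herd, "parity": parity,
        "dim": dim, "platform": platform, "batch": batch})

    def _v(x):
        return float(np.var(x, ddof=1)) if len(x) > 1 else 0.0

    tot = _v(a) + _v(m) + _v(e)
    truth = {
        "sigma2_a": s_a, "sigma2_m": s_m, "sigma2_e": s_e,
        "true_h2": config.true_h2, "true_m2": config.true_m2,
        "realized_var_a": _v(a), "realized_var_m": _v(m),
        "realized_var_e": _v(e),
        "realized_h2": _v(a) / tot if tot > 0 else 0.0,
        "realized_m2": _v(m) / tot if tot > 0 else 0.0,
        "n_phenotyped": n,
    }
    return table, truth


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimulatedDataset:
    config: SimConfig
    pedigree: Pedigree
    otu_table: OtuTable | None
    phenotypes: pd.DataFrame
    truth: dict


def simulate_dataset(config: SimConfig, outdir=None,
                     with_otus: bool = True) -> SimulatedDataset:
    """Generate the full input bundle and optionally write it to disk.

    Files written: ``pedigree.csv``, ``otu_counts.tsv`` (taxa x samples,
    taxonomy last column), ``phenotypes.tsv`` and ``truth.json``.
    """
    ped = simulate_pedigree(config)
    F = build_A(ped).values.diagonal() - 1.0
    otus = (simulate_otu_table(config, ped, inbreeding=F)
            if with_otus and config.n_otus > 0 else None)
    pheno, truth = simulate_phenotype(config, ped, otus, inbreeding=F)
    ds = SimulatedDataset(config, ped, otus, pheno, truth)
    if outdir is not None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ped.write_csv(out / "pedigree.csv")
        if otus is not None:
            otus.to_tsv(out / "otu_counts.tsv")
        pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        sidecar = dict(truth)
        sidecar["config"] = asdict(config)
        (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return ds
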