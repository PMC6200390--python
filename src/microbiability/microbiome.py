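"""OTU-table filtering, transformation, and the microbial relationship matrix.

The microbial relationship matrix is ``M = X X' / n`` where X is the matrix
(samples x taxa) of natural-log transformed relative abundances of the
retained bacterial and archaeal OTUs, centered and scaled per taxon *within
sequencing platform* (MiSeq/HiSeq strata are standardized separately and
recombined), and n is the number of retained taxa.  M plays the same role
for the rumen community that the pedigree matrix A plays for the genome:
``m ~ N(0, M * sigma2_m)``.

The fixed preprocessing order is: depth-filter samples -> filter OTUs ->
relative abundance -> log -> center/scale within platform -> M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kernels import Kernel

#: filtering defaults used throughout the pipeline
MIN_READS = 50_000
MIN_TOTAL_COUNT = 10
MIN_PREVALENCE = 0.5

_RANK_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]
_RANK_INDEX = {"kingdom": 0, "phylum": 1, "class": 2, "order": 3,
               "family": 4, "genus": 5, "species": 6}


@dataclass
class OtuTable:
    """Counts of taxa (rows) by samples (columns), with sample labels.

    ``platform`` and ``batch`` are per-sample sequencing labels; batches are
    nested within platforms.  ``provenance`` accumulates an audit trail of
    filtering decisions.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    taxonomy: list[str] | None = None
    platform: np.ndarray | None = None
    batch: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match taxon/sample ids")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.taxonomy is not None and len(self.taxonomy) != len(self.taxon_ids):
            raise ValueError("taxonomy length does not match taxa")
        for name in ("platform", "batch"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=object)
                if len(v) != len(self.sample_ids):
                    raise ValueError(f"{name} length does not match samples")
                setattr(self, name, v)
        if self.platform is not None and self.batch is not None:
            # each batch label must map to exactly one platform
            mapping: dict = {}
            for p, b in zip(self.platform, self.batch):
                if b in mapping and mapping[b] != p:
                    raise ValueError(
                        f"batch {b!r} appears under two platforms")
                mapping[b] = p

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def _take_samples(self, idx, note: str) -> "OtuTable":
        return OtuTable(
            self.counts[:, idx],
            list(self.taxon_ids),
            [self.sample_ids[i] for i in idx],
            self.taxonomy,
            self.platform[idx] if self.platform is not None else None,
            self.batch[idx] if self.batch is not None else None,
            self.provenance + [note],
        )

    def _take_taxa(self, idx, note: str) -> "OtuTable":
        return OtuTable(
            self.counts[idx, :],
            [self.taxon_ids[i] for i in idx],
            list(self.sample_ids),
            [self.taxonomy[i] for i in idx] if self.taxonomy is not None else None,
            self.platform,
            self.batch,
            self.provenance + [note],
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=pd.Index(self.taxon_ids, name="otu_id"),
                          columns=self.sample_ids)
        if self.taxonomy is not None:
            df["taxonomy"] = self.taxonomy
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, metadata: pd.DataFrame | None = None) -> "OtuTable":
        """Read a taxa-x-samples TSV (first column id, optional trailing
        ``taxonomy`` column).  ``metadata``, if given, is indexed by sample id
        and may carry ``platform``/``batch`` columns."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        taxonomy = None
        if "taxonomy" in df.columns:
            taxonomy = df["taxonomy"].astype(str).tolist()
            df = df.drop(columns=["taxonomy"])
        counts = df.to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("OTU table contains non-integer counts")
        platform = batch = None
        samples = [str(s) for s in df.columns]
        if metadata is not None:
            md = metadata.loc[[s for s in samples]]
            platform = md["platform"].to_numpy(object) if "platform" in md else None
            batch = md["batch"].to_numpy(object) if "batch" in md else None
        return cls(counts.astype(np.int64), [str(t) for t in df.index],
                   samples, taxonomy, platform, batch)


@dataclass
class AbundanceMatrix:
    """Samples-x-taxa real matrix with a transformation audit trail."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("values shape does not match sample/taxon ids")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample"),
                     columns=self.taxon_ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# filtering


def filter_samples(table: OtuTable, min_reads: int = MIN_READS) -> OtuTable:
    """Drop samples whose total read count is strictly below ``min_reads``."""
    depth = table.library_sizes()
    keep = np.flatnonzero(depth >= min_reads)
    if keep.size == 0:
        raise ValueError(f"all samples below {min_reads} reads")
    dropped = [table.sample_ids[i] for i in np.flatnonzero(depth < min_reads)]
    note = (f"filter_samples(min_reads={min_reads}): dropped "
            f"{len(dropped)} samples {dropped[:10]}")
    return table._take_samples(keep, note)


def filter_otus(table: OtuTable, min_total: int = MIN_TOTAL_COUNT,
                min_prevalence: float = MIN_PREVALENCE) -> OtuTable:
    """Drop rare, low-prevalence and homogeneous taxa.

    A taxon is removed when its total count is below ``min_total``, when it is
    present (count > 0) in fewer than ``min_prevalence`` of the samples
    (presence in exactly that fraction is retained), or when its counts show
    zero variance across samples.
    """
    total = table.counts.sum(axis=1)
    prevalence = (table.counts > 0).mean(axis=1)
    homogeneous = table.counts.var(axis=1) == 0
    keep = np.flatnonzero(
        (total >= min_total) & (prevalence >= min_prevalence) & ~homogeneous)
    if keep.size == 0:
        raise ValueError("all taxa removed by the OTU filters")
    note = (f"filter_otus(min_total={min_total}, min_prevalence={min_prevalence}): "
            f"kept {keep.size}/{table.n_taxa} taxa")
    return table._take_taxa(keep, note)


# ---------------------------------------------------------------------------
# transforms


def to_relative_abundance(table: OtuTable) -> AbundanceMatrix:
    """Per-sample relative abundances of the retained taxa (rows sum to 1)."""
    depth = table.library_sizes().astype(float)
    if (depth == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(depth == 0)]
        raise ValueError(f"samples with zero retained counts: {bad[:10]}")
    rel = (table.counts / depth).T
    return AbundanceMatrix(rel, list(table.sample_ids), list(table.taxon_ids),
                           table.provenance + ["to_relative_abundance"])


def log_transform(rel: AbundanceMatrix, pseudo: float | None = None) -> AbundanceMatrix:
    """Natural log of (abundance + pseudo-abundance).

    The default pseudo-abundance is half the smallest nonzero relative
    abundance in the whole matrix, so zeros map to a finite floor.
    """
    x = rel.values
    if (x < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if pseudo is None:
        nz = x[x > 0]
        if nz.size == 0:
            raise ValueError("matrix is all zeros; cannot pick a pseudo-abundance")
        pseudo = 0.5 * float(nz.min())
    if pseudo < 0:
        raise ValueError("pseudo-abundance must be non-negative")
    if pseudo == 0 and (x == 0).any():
        raise ValueError("pseudo=0 with zero abundances would produce -inf")
    return AbundanceMatrix(np.log(x + pseudo), list(rel.sample_ids),
                           list(rel.taxon_ids),
                           rel.provenance + [f"log_transform(pseudo={pseudo:g})"])


def center_scale_within_platform(logx: AbundanceMatrix,
                                 platform) -> AbundanceMatrix:
    """Center/scale each taxon column to mean 0, variance 1 (ddof=1) within
    each sequencing-platform stratum; strata are recombined in sample order.

    A column that is constant within a stratum is set to 0 there, with a
    warning.
    """
    platform = np.asarray(platform, dtype=object)
    if len(platform) != len(logx.sample_ids):
        raise ValueError("platform labels do not match samples")
    out = np.empty_like(logx.values)
    n_flat = 0
    for lev in pd.unique(platform):
        idx = np.flatnonzero(platform == lev)
        if idx.size < 2:
            raise ValueError(
                f"platform stratum {lev!r} has fewer than 2 samples")
        block = logx.values[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        flat = sd == 0
        n_flat += int(flat.sum())
        sd = np.where(flat, 1.0, sd)
        z = (block - mu) / sd
        z[:, flat] = 0.0
        out[idx] = z
    if n_flat:
        warnings.warn(f"{n_flat} taxon column(s) constant within a platform "
                      "stratum; set to 0 there", stacklevel=2)
    return AbundanceMatrix(out, list(logx.sample_ids), list(logx.taxon_ids),
                           logx.provenance + ["center_scale_within_platform"])


def build_M(x: AbundanceMatrix) -> Kernel:
    """Microbial relationship matrix ``M = X X' / n_taxa``."""
    n_taxa = len(x.taxon_ids)
    if n_taxa == 0:
        raise ValueError("no taxa in abundance matrix")
    m = x.values @ x.values.T / n_taxa
    return Kernel(list(x.sample_ids), m, name="M")


def standardize(table: OtuTable, min_reads: int = MIN_READS,
                min_total: int = MIN_TOTAL_COUNT,
                min_prevalence: float = MIN_PREVALENCE,
                pseudo: float | None = None) -> AbundanceMatrix:
    """Full preprocessing pipeline from raw counts to the standardized X."""
    if table.platform is None:
        raise ValueError("standardization requires per-sample platform labels")
    t = filter_samples(table, min_reads)
    t = filter_otus(t, min_total, min_prevalence)
    x = log_transform(to_relative_abundance(t), pseudo)
    return center_scale_within_platform(x, t.platform)


def microbial_kernel(table: OtuTable, **kwargs) -> Kernel:
    """Convenience: counts -> standardized X -> M."""
    return build_M(standardize(table, **kwargs))


# ---------------------------------------------------------------------------
# taxonomy collapsing


def _parse_ranks(tax: str) -> list[str]:
    parts = [p.strip() for p in str(tax).split(";")]
    ranks = [""] * len(_RANK_PREFIXES)
    for j, p in enumerate(parts):
        name = p
        level = j
        for k, pref in enumerate(_RANK_PREFIXES):
            if p.startswith(pref):
                name = p[len(pref):]
                level = k
                break
        if level < len(ranks):
            ranks[level] = name.strip()
    return ranks


def _rank_label(tax: str, rank_idx: int) -> str:
    ranks = _parse_ranks(tax)
    if ranks[rank_idx]:
        return ranks[rank_idx]
    # unassigned at this rank: group under the nearest classified parent
    for k in range(rank_idx - 1, -1, -1):
        if ranks[k]:
            return f"Unclassified {ranks[k]}"
    return "Unclassified"


def collapse_taxonomy(table: OtuTable, rank: str) -> OtuTable:
    """Sum counts over taxa sharing a rank label (genus or family).

    Taxa unassigned at the requested rank are grouped per nearest classified
    parent, labelled e.g. ``Unclassified Victivallaceae``.
    """
    if table.taxonomy is None:
        raise ValueError("collapse_taxonomy requires taxonomy strings")
    if rank not in _RANK_INDEX:
        raise ValueError(f"unknown rank {rank!r}")
    ridx = _RANK_INDEX[rank]
    labels = [_rank_label(t, ridx) for t in table.taxonomy]
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(i)
    counts = np.vstack([table.counts[groups[lab]].sum(axis=0) for lab in order])
    return OtuTable(
        counts, order, list(table.sample_ids), None, table.platform,
        table.batch,
        table.provenance + [f"collapse_taxonomy(rank={rank}): "
                            f"{table.n_taxa} -> {len(order)} taxa"])
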