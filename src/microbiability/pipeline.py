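"""End-to-end pipeline: kinship -> kernel -> variance components -> scans ->
community structure, with a run manifest for auditability.

Every stage writes tidy TSVs into the output directory and records its
row/taxon counts and realized thresholds in ``manifest.json``.  A stage
failure aborts the run with a stage-tagged message; outputs produced so far
are retained next to a ``FAILED`` marker file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pedigree import read_pedigree, prune_to_ancestors, build_A
from .microbiome import (OtuTable, filter_samples, filter_otus,
                         to_relative_abundance, log_transform,
                         center_scale_within_platform, build_M,
                         collapse_taxonomy, MIN_READS, MIN_TOTAL_COUNT,
                         MIN_PREVALENCE)
from .reml import build_design, fit_reml, likelihood_ratio_test, \
    taxon_heritability_scan
from .association import mlm_association, manhattan_table
from .community import (bray_curtis, pcoa, decile_groups, decile_contrast,
                        mann_whitney_axis, axis_variance_decomposition)


@dataclass
class PipelineConfig:
    """Thresholds and options controlling a pipeline run."""

    min_reads: int = MIN_READS
    min_total_count: int = MIN_TOTAL_COUNT
    min_prevalence: float = MIN_PREVALENCE
    fdr_level: float = 0.15
    wilmink_k: float = 0.065
    pseudo_abundance: float | None = None
    collapse_rank: str | None = None      # None = OTU level
    n_axes: int = 2
    association_mode: str = "reuse"
    write_kernels: bool = True
    seed: int = 1


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"[stage {stage}] {exc}")
        self.stage = stage


def run_pipeline(pedigree_path, phenotype_path, otu_path=None, outdir="results",
                 config: PipelineConfig | None = None) -> dict:
    """Run the full analysis and return the manifest dict."""
    cfg = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "inputs": {},
        "stages": {},
    }
    for label, p in (("pedigree", pedigree_path), ("phenotypes", phenotype_path),
                     ("otu_table", otu_path)):
        if p is not None:
            manifest["inputs"][label] = {"path": str(p), "sha256": _sha256(p)}

    stage = "read-inputs"
    try:
        ped = read_pedigree(pedigree_path)
        pheno = pd.read_csv(phenotype_path, sep="\t", dtype={"animal": str})
        pheno_col = "ch4_g_day" if "ch4_g_day" in pheno else pheno.columns[1]
        otus = None
        if otu_path is not None:
            meta = pheno.set_index("animal")
            otus = OtuTable.from_tsv(otu_path, metadata=None)
            # restrict to the phenotyped cohort and attach platform/batch
            keep = [i for i, s in enumerate(otus.sample_ids)
                    if s in meta.index]
            if not keep:
                raise ValueError("no OTU samples match phenotyped animals")
            otus = otus._take_samples(keep, "restricted to phenotyped cohort")
            if "platform" in meta:
                otus.platform = meta.loc[otus.sample_ids,
                                         "platform"].to_numpy(object)
            if "batch" in meta:
                otus.batch = meta.loc[otus.sample_ids,
                                      "batch"].to_numpy(object)

        stage = "kinship"
        ped = prune_to_ancestors(ped, pheno["animal"].tolist())
        A = build_A(ped, subset=pheno["animal"].tolist())
        manifest["stages"]["kinship"] = {"n_pedigree": ped.n, "n_phenotyped": A.n}

        M = None
        X_std = None
        if otus is not None:
            stage = "kernel"
            n0s, n0t = otus.n_samples, otus.n_taxa
            t = filter_samples(otus, cfg.min_reads)
            t = filter_otus(t, cfg.min_total_count, cfg.min_prevalence)
            if cfg.collapse_rank:
                t = collapse_taxonomy(t, cfg.collapse_rank)
            rel = to_relative_abundance(t)
            logx = log_transform(rel, cfg.pseudo_abundance)
            X_std = center_scale_within_platform(logx, t.platform)
            M = build_M(X_std)
            manifest["stages"]["kernel"] = {
                "samples_in": n0s, "samples_kept": t.n_samples,
                "taxa_in": n0t, "taxa_kept": t.n_taxa,
                "provenance": t.provenance}
            # align phenotypes to samples with microbiome data
            pheno = pheno[pheno["animal"].isin(M.labels)].reset_index(drop=True)
            A = A.subset(pheno["animal"].tolist())
            M = M.subset(pheno["animal"].tolist())
            order = {s: i for i, s in enumerate(X_std.sample_ids)}
            keep = [order[s] for s in pheno["animal"]]
            X_std.values = X_std.values[keep]
            X_std.sample_ids = pheno["animal"].tolist()
            rel.values = rel.values[keep]
            rel.sample_ids = pheno["animal"].tolist()
            logx.values = logx.values[keep]
            logx.sample_ids = pheno["animal"].tolist()
            if cfg.write_kernels:
                M.to_tsv(out / "kernel_M.tsv")
        if cfg.write_kernels:
            A.to_tsv(out / "kernel_A.tsv")

        stage = "varcomp"
        y = pheno[pheno_col].to_numpy(float)
        X, _ = build_design(pheno, cfg.wilmink_k)
        fits = {"fixed_only": fit_reml(y, X, {})}
        fits["A"] = fit_reml(y, X, {"A": A.values})
        if M is not None:
            fits["M"] = fit_reml(y, X, {"M": M.values})
            fits["joint"] = fit_reml(y, X, {"A": A.values, "M": M.values})
        rows = {name: f.to_series() for name, f in fits.items()}
        vc = pd.DataFrame(rows).T
        vc.index.name = "model"
        lrts = {"A_vs_null": likelihood_ratio_test(fits["fixed_only"], fits["A"])}
        if M is not None:
            lrts["M_vs_null"] = likelihood_ratio_test(fits["fixed_only"], fits["M"])
            lrts["joint_vs_A"] = likelihood_ratio_test(fits["A"], fits["joint"])
            lrts["joint_vs_M"] = likelihood_ratio_test(fits["M"], fits["joint"])
        lrt_df = pd.DataFrame(
            {k: {"statistic": v.statistic, "p": v.p_value}
             for k, v in lrts.items()}).T
        lrt_df.index.name = "contrast"
        vc.to_csv(out / "varcomp.tsv", sep="\t")
        lrt_df.to_csv(out / "lrt.tsv", sep="\t")
        manifest["stages"]["varcomp"] = {
            "models": list(fits),
            "h2_joint": fits.get("joint", fits["A"]).ratios.get("A"),
            "m2_joint": (fits["joint"].ratios.get("M")
                         if "joint" in fits else None)}

        scan = None
        if M is not None:
            stage = "scan-h2"
            scan = taxon_heritability_scan(logx, pheno, A,
                                           include_batch="batch" in pheno,
                                           fdr_level=cfg.fdr_level)
            scan.to_csv(out / "taxon_h2.tsv", sep="\t", index=False)
            manifest["stages"]["scan_h2"] = {
                "n_taxa": len(scan),
                "n_fdr_significant": int((scan["q"] <= cfg.fdr_level).sum())}

            stage = "assoc"
            assoc = mlm_association(y, pheno, logx, A,
                                    mode=cfg.association_mode,
                                    q_level=cfg.fdr_level,
                                    include_batch="batch" in pheno)
            assoc.table.to_csv(out / "association.tsv", sep="\t", index=False)
            man = manhattan_table(assoc.table, scan)
            man.to_csv(out / "manhattan.tsv", sep="\t", index=False)
            manifest["stages"]["association"] = {
                "n_taxa": len(assoc.table),
                "n_fdr_significant": assoc.fdr.n_significant,
                "neglog10_threshold": assoc.fdr.neglog10_threshold,
                "mode": assoc.mode}

            stage = "pcoa"
            D = bray_curtis(rel)
            ordn = pcoa(D, n_axes=cfg.n_axes)
            coords = pd.DataFrame(
                ordn.coordinates, index=pd.Index(ordn.sample_ids, name="animal"),
                columns=[f"PCo{k + 1}" for k in range(ordn.coordinates.shape[1])])
            coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
            pd.DataFrame({"eigenvalue": ordn.eigenvalues}).to_csv(
                out / "pcoa_eigenvalues.tsv", sep="\t", index=False)
            groups = decile_groups(y, pheno["animal"].to_numpy())
            pd.DataFrame({"animal": pheno["animal"], "group": groups}).to_csv(
                out / "emitter_groups.tsv", sep="\t", index=False)
            contrast = decile_contrast(y, pheno["animal"].to_numpy())
            mw_rows = []
            dec_rows = []
            for k in range(min(2, ordn.coordinates.shape[1])):
                u, p = mann_whitney_axis(ordn.axis(k), groups)
                mw_rows.append({"axis": f"PCo{k + 1}", "U": u, "p": p})
                dec = axis_variance_decomposition(ordn.axis(k), pheno, A,
                                                  cfg.wilmink_k)
                row = {"axis": f"PCo{k + 1}", "h2": dec.h2, "h2_se": dec.h2_se}
                row.update({f"share_{f}": s for f, s in dec.factor_shares.items()})
                dec_rows.append(row)
            pd.DataFrame(mw_rows).to_csv(out / "mann_whitney.tsv", sep="\t",
                                         index=False)
            pd.DataFrame(dec_rows).to_csv(out / "axis_decomposition.tsv",
                                          sep="\t", index=False)
            manifest["stages"]["pcoa"] = {
                "n_axes": int(ordn.coordinates.shape[1]),
                "n_negative_eigenvalues": int(len(ordn.negative_eigenvalues)),
                "decile_contrast": contrast}
        else:
            manifest["stages"]["notice"] = (
                "no OTU table supplied; microbiome stages skipped")
    except Exception as exc:
        (out / "FAILED").write_text(f"[stage {stage}] {exc}\n")
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=float))
    return manifest


def write_report(results_dir, report_path=None) -> str:
    """Human-readable summary of a completed run (idempotent)."""
    res = Path(results_dir)
    lines = ["# Variance-partitioning report", ""]
    missing = []

    vc_path = res / "varcomp.tsv"
    if vc_path.exists():
        vc = pd.read_csv(vc_path, sep="\t", index_col=0)
        lines.append("## Variance explained by random effects")
        lines.append("")
        lines.append("model | h2 | m2 | h2+m2")
        lines.append("--- | --- | --- | ---")
        for model in vc.index:
            h2 = vc.loc[model].get("ratio_A", np.nan)
            m2 = vc.loc[model].get("ratio_M", np.nan)
            tot = np.nansum([h2, m2])
            lines.append(f"{model} | {h2:.3f} | {m2:.3f} | {tot:.3f}")
        lines.append("")
        # Fig-5-style tidy table of variance sources
        src = []
        for model in vc.index:
            for which, col, secol in (("heritability", "ratio_A", "se_ratio_A"),
                                      ("microbiability", "ratio_M", "se_ratio_M")):
                if col in vc.columns and np.isfinite(vc.loc[model, col]):
                    src.append({"model": model, "source": which,
                                "proportion": vc.loc[model, col],
                                "se": vc.loc[model].get(secol, np.nan)})
        pd.DataFrame(src).to_csv(res / "variance_sources.tsv", sep="\t",
                                 index=False)
    else:
        missing.append("varcomp.tsv")

    man_path = res / "manifest.json"
    if man_path.exists():
        man = json.loads(man_path.read_text())
        pc = man.get("stages", {}).get("pcoa")
        if pc and "decile_contrast" in pc:
            c = pc["decile_contrast"]
            lines.append("## Emitter decile contrast")
            lines.append("")
            lines.append(
                f"high mean {c['high_mean']:.2f}, low mean {c['low_mean']:.2f}, "
                f"difference {c['percent_difference']:.0f}% of the high mean")
            lines.append("")
    else:
        missing.append("manifest.json")

    assoc_path = res / "manhattan.tsv"
    if assoc_path.exists():
        man_df = pd.read_csv(assoc_path, sep="\t")
        top = man_df.nsmallest(5, "p")
        lines.append("## Strongest taxon associations")
        lines.append("")
        for _, r in top.iterrows():
            lines.append(f"- {r['taxon_id']}: beta={r['beta']:.3g}, "
                         f"p={r['p']:.3g}, q={r['q']:.3g}")
        lines.append("")

    if missing:
        lines.append(f"Missing stage outputs: {', '.join(missing)}")
    text = "\n".join(lines) + "\n"
    path = Path(report_path) if report_path else res / "report.md"
    path.write_text(text)
    return text
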