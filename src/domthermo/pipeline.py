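"""End-to-end orchestration: MS funnel -> assignment -> thermodynamics ->
community -> linkage -> classification, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import formula_engine as fe
from . import msio
from . import multivariate as mv
from . import phylotype_classifier as pc
from . import soilstats
from . import thermo

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    peaks_dir: str
    metadata: str
    asv_table: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    out_dir: str = "domthermo_out"
    sn_min: float = 6.0
    tol_ppm: float = 1.0
    align_tol_ppm: float = 1.0
    min_occurrence: int = 6
    rarefaction_depth: int = 7000
    alpha: float = 0.05
    n_permutations: int = 999
    min_sites: int = 5
    classify_method: str = "pearson"
    bray_curtis_presence: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for name in ("peaks_dir", "metadata"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tol_ppm <= 0 or self.align_tol_ppm <= 0:
            raise ValueError("ppm tolerances must be positive")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage that the provided inputs support.

    Missing optional inputs (ASV table, tree) degrade gracefully: the
    affected stages are skipped with a warning and noted in the manifest.
    Returns the manifest dict; all stage outputs are written under
    ``cfg.out_dir``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": [],
        "funnel": {},
    }

    def stage(name: str, **info) -> None:
        logger.info("stage=%s %s", name, info)
        manifest["stages"].append({"name": name, "elapsed_s": round(time.time() - t0, 2), **info})

    # --- MS funnel -------------------------------------------------------
    peak_files = sorted(Path(cfg.peaks_dir).glob("*.csv")) + sorted(Path(cfg.peaks_dir).glob("*.tsv"))
    blanks = [msio.read_peak_list(p) for p in peak_files if p.stem.startswith("blank")]
    lists = [msio.read_peak_list(p) for p in peak_files if not p.stem.startswith("blank")]
    if not lists:
        raise FileNotFoundError(f"no peak lists found under {cfg.peaks_dir}")
    manifest["funnel"]["raw_peaks"] = sum(len(pl) for pl in lists)

    lists = [msio.filter_sn(pl, cfg.sn_min) for pl in lists]
    manifest["funnel"]["sn_filtered"] = sum(len(pl) for pl in lists)

    lists = [msio.subtract_blanks(pl, blanks, cfg.align_tol_ppm) for pl in lists]
    manifest["funnel"]["blank_subtracted"] = sum(len(pl) for pl in lists)

    matrix = msio.align_peaks(lists, cfg.align_tol_ppm)
    manifest["funnel"]["aligned_consensus"] = matrix.n_peaks
    matrix = msio.occurrence_filter(matrix, cfg.min_occurrence)
    manifest["funnel"]["occurrence_filtered"] = matrix.n_peaks
    msio.write_peak_matrix(matrix, out / "peak_matrix.tsv", out / "peak_provenance.tsv")
    stage("ms", consensus_peaks=matrix.n_peaks, samples=len(matrix.sample_ids))

    # --- Formula assignment ---------------------------------------------
    assignments = fe.assign_matrix(matrix, cfg.tol_ppm)
    n_assigned = sum(a.formula is not None for a in assignments)
    manifest["funnel"]["assigned"] = n_assigned
    pd.DataFrame(
        [
            {
                "consensus_mz": a.consensus_mz,
                "neutral_mass": a.neutral_mass,
                "formula": a.formula.hill() if a.formula else "",
                "error_ppm": a.error_ppm,
                "n_candidates": a.n_candidates,
            }
            for a in assignments
        ]
    ).to_csv(out / "assignments.tsv", sep="\t", index=False)
    stage("assign", assigned=n_assigned, unassigned=len(assignments) - n_assigned)

    # --- Thermodynamics --------------------------------------------------
    records = [
        thermo.CompoundRecord.from_formula(a.formula)
        for a in assignments
        if a.formula is not None
    ]
    thermo.compounds_frame(records).to_csv(out / "compounds.tsv", sep="\t", index=False)
    sample_table = thermo.sample_thermo_table(matrix, assignments)
    sample_table.to_csv(out / "sample_thermo.tsv", sep="\t")
    stage("thermo", samples=len(sample_table))
    median_dg = sample_table["median_dgcox"]

    # --- Soil regressions ------------------------------------------------
    meta = pd.read_csv(cfg.metadata, sep="\t", index_col=0)
    common = [s for s in median_dg.index if s in meta.index]
    meta = meta.loc[common]
    dg = median_dg.loc[common]
    try:
        meta["mnc"] = soilstats.mnc_index(meta)
    except (KeyError, ValueError) as exc:
        logger.warning("MNC index skipped: %s", exc)
    reg_rows = []
    for var in ("som", "ph", "mnc"):
        if var not in meta.columns:
            continue
        fit = soilstats.ols_fit(dg, meta[var])
        reg_rows.append({"x": "median_dgcox", "y": var, **vars(fit)})
    stage("soilstats", regressions=len(reg_rows))

    # --- Community -------------------------------------------------------
    asv = None
    if cfg.asv_table and Path(cfg.asv_table).exists():
        counts = comm.read_asv_table(cfg.asv_table)
        taxonomy = None
        if cfg.taxonomy and Path(cfg.taxonomy).exists():
            taxonomy = pd.read_csv(cfg.taxonomy, sep="\t", index_col=0).iloc[:, 0]
        sites = meta["site"] if "site" in meta.columns else None
        asv = comm.CommunityTable(counts=counts, taxonomy=taxonomy, sample_sites=sites)
        rare = comm.rarefy(asv, cfg.rarefaction_depth, seed=cfg.seed)
        alpha_div = pd.DataFrame(
            {"richness": comm.richness(rare), "richness_raw": comm.richness(asv)}
        )
        tree = None
        if cfg.tree and Path(cfg.tree).exists():
            tree = comm.Phylogeny.from_newick(cfg.tree)
            alpha_div["faith_pd"] = comm.faith_pd(rare, tree)
            alpha_div["faith_pd_raw"] = comm.faith_pd(asv, tree)
        else:
            logger.warning("tree missing: phylogenetic diversity skipped")
        alpha_div.to_csv(out / "alpha_diversity.tsv", sep="\t")
        for col in alpha_div.columns:
            shared = [s for s in common if s in alpha_div.index]
            fit = soilstats.ols_fit(dg.loc[shared], alpha_div.loc[shared, col])
            reg_rows.append({"x": "median_dgcox", "y": col, **vars(fit)})
        stage("community", samples=len(rare.samples), taxa=len(rare.taxa))

        # --- Multivariate linkage ---------------------------------------
        shared = [s for s in rare.samples if s in matrix.sample_ids]
        dom_frame = matrix.to_frame()[shared]
        d_dom = comm.bray_curtis(dom_frame, presence=cfg.bray_curtis_presence)
        d_bac = comm.bray_curtis(rare.counts[shared])
        mres = mv.mantel(d_dom, d_bac, n_perm=cfg.n_permutations, seed=cfg.seed)
        ord_dom = mv.pcoa(d_dom)
        ord_bac = mv.pcoa(d_bac)
        pres = mv.procrustes(ord_dom, ord_bac, n_perm=cfg.n_permutations, seed=cfg.seed)
        env = mv.envfit(
            ord_bac,
            pd.DataFrame({"median_dgcox": dg.loc[shared], "som": meta.loc[shared, "som"]}),
            n_perm=cfg.n_permutations, seed=cfg.seed,
        )
        link = {
            "mantel_r": mres.r, "mantel_p": mres.p_value,
            "procrustes_m12sq": pres.m12_squared, "procrustes_p": pres.p_value,
            "envfit": [
                {"variable": e.variable, "r_squared": e.r_squared, "p": e.p_value}
                for e in env
            ],
        }
        (out / "linkage.json").write_text(json.dumps(link, indent=2))
        stage("link", mantel_r=round(mres.r, 4), m12sq=round(pres.m12_squared, 4))

        # --- Phylotype classification -----------------------------------
        if sites is not None:
            ubiq = pc.ubiquity_filter(rare, min_sites=cfg.min_sites)
            recs = pc.screen_taxa(rare, dg, meta["som"], taxa=ubiq)
            recs = pc.classify_phylotypes(recs, alpha=cfg.alpha, method=cfg.classify_method)
            pc.association_table(recs, asv.taxonomy).to_csv(
                out / "phylotype_associations.tsv", sep="\t", index=False
            )
            n_sig = sum(r.cluster != pc.UNCLASSIFIED for r in recs)
            stage("classify", ubiquitous=len(ubiq), classified=n_sig)
        else:
            logger.warning("no site column in metadata: classification skipped")
    else:
        logger.warning("ASV table missing: community stages skipped")

    pd.DataFrame(reg_rows).to_csv(out / "regressions.tsv", sep="\t", index=False)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
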