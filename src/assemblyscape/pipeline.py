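"""End-to-end per-group orchestration.

Runs, for every group (typically a season): the phylogenetic-signal
prerequisite check, assembly-process quantification, biogeographic pattern
statistics and variation partitioning, writing tab-delimited outputs and a
YAML manifest per group.  Assembly quantification refuses to run when the
signal prerequisite fails (no significant short-distance correlogram class)
unless forced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import patristic_matrix, quantify_processes
from .drivers import forward_selection, pcnm, variation_partition
from .io import CommunityTable, align_dataset, load_dataset, rarefy, write_manifest, write_matrix
from .patterns import (
    anosim,
    axis_vs_distance,
    bray_curtis_matrix,
    distance_decay,
    geographic_distance_matrix,
    pcoa,
    simper,
)
from .signal import mantel_correlogram, niche_distance, niche_optima

logger = logging.getLogger(__name__)


class SignalPrerequisiteError(RuntimeError):
    """Raised when no short-phylogenetic-distance correlogram class is
    significant, so βMNTD-based null modelling is not justified."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    counts_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    out_dir: str = "assemblyscape_out"
    group_col: str | None = "season"
    site_col: str = "site"
    env_cols: list[str] = field(default_factory=lambda: [
        "temperature", "salinity", "DIN"])
    rarefaction_depth: int | None = None
    n_null: int = 999
    n_perm: int = 999
    alpha: float = 0.05
    pool: str = "group"
    seed: int = 0
    force: bool = False


def run_all(config: RunConfig, dataset=None) -> dict:
    """Execute the full pipeline; returns {group: {stage: result}}.

    ``dataset`` may supply an in-memory ``(CommunityTable, TreeNode,
    metadata)`` triple; otherwise the configured paths are loaded.
    Per-stage child seeds are spawned from the master seed and recorded in
    the manifest so one stage can be re-run without perturbing others.
    """
    cfg = config
    if dataset is None:
        table, tree, meta = load_dataset(
            cfg.counts_path, cfg.tree_path, cfg.metadata_path)
    else:
        table, tree, meta = align_dataset(*dataset)
    for col in ([cfg.group_col] if cfg.group_col else []) + cfg.env_cols:
        if col not in meta.columns:
            raise ValueError(f"configured column {col!r} missing from metadata")

    master = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(ss.generate_state(1)[0] % (2**31))
             for name, ss in zip(
                 ["rarefy", "signal", "assembly", "patterns", "partition"],
                 master.spawn(5))}

    if cfg.rarefaction_depth:
        table = rarefy(table, cfg.rarefaction_depth, seeds["rarefy"])

    out_root = Path(cfg.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    groups = (meta[cfg.group_col] if cfg.group_col
              else pd.Series("all", index=meta.index))
    results: dict = {}
    for gname in pd.unique(groups):
        members = groups.index[groups == gname]
        gtab = CommunityTable(table.counts.loc[members]).drop_empty_taxa()
        gmeta = meta.loc[members]
        gdir = out_root / str(gname)
        gdir.mkdir(exist_ok=True)
        results[gname] = _run_group(
            gname, gtab, tree, gmeta, cfg, seeds, gdir)
        write_manifest(gdir / "manifest.yaml",
                       group=str(gname), seeds=seeds,
                       n_null=cfg.n_null, n_perm=cfg.n_perm,
                       pool=cfg.pool, alpha=cfg.alpha,
                       rarefaction_depth=cfg.rarefaction_depth,
                       env_cols=cfg.env_cols, version=__version__)
    return results


def _run_group(gname, gtab, tree, gmeta, cfg, seeds, gdir: Path) -> dict:
    stage = "phylo_signal"
    try:
        optima = niche_optima(gtab, gmeta[cfg.env_cols])
        nicheD = niche_distance(optima)
        phyloD = patristic_matrix(tree.shear(set(gtab.taxon_ids))).filter(
            list(optima.index))
        corr = mantel_correlogram(nicheD, phyloD, n_perm=cfg.n_perm,
                                  seed=seeds["signal"])
        corr.to_csv(gdir / "correlogram.tsv", sep="\t", index=False)
        testable = corr[corr.testable]
        short = testable.iloc[: max(1, len(testable) // 2)]
        signal_ok = bool(((short.mantel_r > 0) & (short.p_holm < cfg.alpha)).any())
        if not signal_ok:
            msg = (f"group {gname}: no significant positive short-distance "
                   "correlogram class; βMNTD null modelling not justified")
            if not cfg.force:
                raise SignalPrerequisiteError(msg)
            logger.warning("%s — continuing (--force)", msg)

        stage = "assembly"
        pairs, summary = quantify_processes(
            gtab, tree, gmeta, group_col=None, n_null=cfg.n_null,
            seed=seeds["assembly"], pool="global" if cfg.pool == "global" else "group")
        pairs.to_csv(gdir / "assembly_pairs.tsv", sep="\t", index=False)
        summary.to_csv(gdir / "process_fractions.tsv", sep="\t", index=False)

        stage = "patterns"
        bc = bray_curtis_matrix(gtab)
        write_matrix(bc, gdir / "bray_curtis.tsv")
        ord_res = pcoa(bc)
        ord_res.coordinates.to_csv(gdir / "pcoa.tsv", sep="\t",
                                   index_label="sample_id")
        sites = gmeta[cfg.site_col]
        anosim_rows = []
        if sites.value_counts().ge(2).all() and sites.nunique() >= 2:
            r, p = anosim(bc, sites, n_perm=cfg.n_perm, seed=seeds["patterns"])
            anosim_rows.append({"factor": cfg.site_col, "R": r, "p": p})
        pd.DataFrame(anosim_rows).to_csv(gdir / "anosim.tsv", sep="\t",
                                         index=False)
        site_levels = list(pd.unique(sites))
        if len(site_levels) >= 2:
            a, b = site_levels[0], site_levels[-1]
            simper(gtab, sites, a, b).head(20).to_csv(
                gdir / f"simper_{a}_vs_{b}.tsv", sep="\t", index=False)
        geo = geographic_distance_matrix(gmeta)
        slope, intercept, r_dd, p_dd = distance_decay(
            bc, geo, n_perm=cfg.n_perm, seed=seeds["patterns"])
        pd.DataFrame([{"slope": slope, "intercept": intercept,
                       "r": r_dd, "p": p_dd}]).to_csv(
            gdir / "distance_decay.tsv", sep="\t", index=False)
        axis_dtl = axis_vs_distance(ord_res, gmeta["distance_to_land"],
                                    axis=1, n_perm=cfg.n_perm,
                                    seed=seeds["patterns"])

        stage = "partition"
        spatial = pcnm(geo)
        abiotic = gmeta[cfg.env_cols]
        sel = forward_selection(bc, abiotic, alpha=cfg.alpha,
                                n_perm=cfg.n_perm, seed=seeds["partition"])
        part = variation_partition(
            bc, abiotic=abiotic[sel] if sel else None, spatial=spatial)
        part.as_series().to_frame("adj_r2").to_csv(
            gdir / "partition.tsv", sep="\t", index_label="fraction")

        return {"correlogram": corr, "signal_ok": signal_ok, "pairs": pairs,
                "summary": summary, "ordination": ord_res,
                "distance_decay": (slope, intercept, r_dd, p_dd),
                "axis_vs_dtl": axis_dtl, "selected_env": sel,
                "partition": part}
    except SignalPrerequisiteError:
        raise
    except Exception as exc:
        for f in gdir.glob("*.tsv"):
            f.rename(f.with_suffix(f.suffix + ".partial"))
        raise RuntimeError(f"stage {stage!r} failed for group {gname}: {exc}") from exc
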