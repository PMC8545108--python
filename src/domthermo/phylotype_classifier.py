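"""Substrate-preference classification of ubiquitous bacterial phylotypes.

Phylotypes (ASVs) detected in a minimum number of sites are screened for
correlations between their relative abundance and (a) the sample median
dG_Cox of the dissolved organic matter and (b) soil organic matter content.
Taxa significant against at least one variable are split into two clusters
by the signs of their significant correlations:

* cluster I  — abundance falls with dG_Cox (prefers high-quality,
  thermodynamically favorable substrate) and/or rises with SOM;
* cluster II — the mirror image (rises with dG_Cox and/or falls with SOM).

Taxa whose significant signs match neither pattern (e.g. negative with both)
are left unclassified with a conflict flag.  "Core" taxa are significant
against both variables.  Both Spearman (rank) and Pearson statistics are
computed; classification uses Pearson by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityTable
from .soilstats import RegressionResult, ols_fit

logger = logging.getLogger(__name__)

CLUSTER_I = "I"
CLUSTER_II = "II"
UNCLASSIFIED = "unclassified"


@dataclass
class AssociationRecord:
    taxon_id: str
    occupancy_sites: int
    rho_dg: float
    p_dg: float
    r_dg: float
    pr_dg: float
    rho_som: float
    p_som: float
    r_som: float
    pr_som: float
    cluster: str = UNCLASSIFIED
    core: bool = False
    conflict: bool = False


def ubiquity_filter(
    t: CommunityTable,
    site_map: pd.Series | None = None,
    min_sites: int = 5,
) -> list[str]:
    """Taxa detected (count > 0 in any sample) in at least ``min_sites`` sites."""
    sites = site_map if site_map is not None else t.sample_sites
    if sites is None:
        raise ValueError("a sample -> site mapping is required")
    sites = sites.loc[t.samples]
    n_sites = sites.nunique()
    if min_sites > n_sites:
        raise ValueError(f"min_sites={min_sites} exceeds the {n_sites} sites present")
    detected = t.counts > 0
    per_site = detected.T.groupby(sites).any()  # sites x taxa
    occupancy = per_site.sum(axis=0)
    return list(occupancy.index[occupancy >= min_sites])


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks on ties.

    Two-sided p from the t approximation; for n <= 8 an exact permutation
    p-value over all n! rank orders is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n <= 8:
        from itertools import permutations

        hits = 0
        total = 0
        obs = abs(rho)
        for perm in permutations(range(n)):
            total += 1
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= obs - 1e-12:
                hits += 1
        return rho, hits / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t_stat = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t_stat), df=n - 2)
    return rho, float(p)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def screen_taxa(
    t: CommunityTable,
    median_dg: pd.Series,
    som: pd.Series,
    taxa: Sequence[str] | None = None,
    site_map: pd.Series | None = None,
    log_transform: bool = False,
    pseudocount: float = 1e-6,
) -> list[AssociationRecord]:
    """Correlate each taxon's relative abundance with median dG_Cox and SOM.

    Abundances are relative (column-normalized) counts, optionally
    log10(x + pseudocount)-transformed.  Returns one record per taxon with
    both Spearman and Pearson statistics; cluster labels are attached later
    by :func:`classify_phylotypes`.
    """
    samples = t.samples
    dg = median_dg.loc[samples].to_numpy(dtype=float)
    so = som.loc[samples].to_numpy(dtype=float)
    rel = t.relative_abundance()
    if log_transform:
        rel = np.log10(rel + pseudocount)
    sites = site_map if site_map is not None else t.sample_sites
    if taxa is None:
        taxa = t.taxa
    if sites is not None:
        sites = sites.loc[samples]
        detected = t.counts.loc[list(taxa)] > 0
        occ = detected.T.groupby(sites).any().sum(axis=0)
    else:
        occ = pd.Series(0, index=list(taxa))
    records = []
    for taxon in taxa:
        ab = rel.loc[taxon].to_numpy(dtype=float)
        if np.ptp(ab) == 0:
            logger.warning("taxon %s has constant abundance; skipped", taxon)
            continue
        rho_dg, p_dg = spearman(ab, dg)
        rho_som, p_som = spearman(ab, so)
        r_dg, pr_dg = pearson(ab, dg)
        r_som, pr_som = pearson(ab, so)
        records.append(
            AssociationRecord(
                taxon_id=str(taxon), occupancy_sites=int(occ.get(taxon, 0)),
                rho_dg=rho_dg, p_dg=p_dg, r_dg=r_dg, pr_dg=pr_dg,
                rho_som=rho_som, p_som=p_som, r_som=r_som, pr_som=pr_som,
            )
        )
    return records


def classify_phylotypes(
    records: Sequence[AssociationRecord],
    alpha: float = 0.05,
    method: Literal["pearson", "spearman"] = "pearson",
) -> list[AssociationRecord]:
    """Attach cluster I / cluster II / unclassified labels in place.

    A taxon enters the significant set when its correlation with either
    variable has p < alpha.  Cluster I requires every significant
    correlation to follow (negative with dG_Cox, positive with SOM);
    cluster II the mirror; any other sign pattern is a logged conflict.
    ``core`` marks taxa significant with both variables.
    """
    records = list(records)
    for rec in records:
        if method == "pearson":
            stat_dg, p_dg, stat_som, p_som = rec.r_dg, rec.pr_dg, rec.r_som, rec.pr_som
        else:
            stat_dg, p_dg, stat_som, p_som = rec.rho_dg, rec.p_dg, rec.rho_som, rec.p_som
        sig_dg = p_dg < alpha
        sig_som = p_som < alpha
        rec.core = bool(sig_dg and sig_som)
        rec.conflict = False
        if not (sig_dg or sig_som):
            rec.cluster = UNCLASSIFIED
            continue
        ok_i = (not sig_dg or stat_dg < 0) and (not sig_som or stat_som > 0)
        ok_ii = (not sig_dg or stat_dg > 0) and (not sig_som or stat_som < 0)
        if ok_i and not ok_ii:
            rec.cluster = CLUSTER_I
        elif ok_ii and not ok_i:
            rec.cluster = CLUSTER_II
        else:
            rec.cluster = UNCLASSIFIED
            rec.conflict = True
            logger.warning(
                "taxon %s significant with conflicting signs (dG %.3f, SOM %.3f)",
                rec.taxon_id, stat_dg, stat_som,
            )
    return records


def group_abundance_regression(
    records: Sequence[AssociationRecord],
    t: CommunityTable,
    median_dg: pd.Series,
    som: pd.Series,
) -> dict[str, dict[str, RegressionResult]]:
    """Regress each cluster's mean relative abundance on dG_Cox and SOM.

    Returns {cluster: {"dg": fit, "som": fit}}; clusters with no members are
    skipped with a warning.
    """
    rel = t.relative_abundance()
    out: dict[str, dict[str, RegressionResult]] = {}
    for cluster in (CLUSTER_I, CLUSTER_II):
        members = [r.taxon_id for r in records if r.cluster == cluster]
        if not members:
            logger.warning("cluster %s has no members; skipped", cluster)
            continue
        mean_ab = rel.loc[members].mean(axis=0)
        out[cluster] = {
            "dg": ols_fit(median_dg.loc[t.samples], mean_ab),
            "som": ols_fit(som.loc[t.samples], mean_ab),
        }
    return out


def association_table(records: Sequence[AssociationRecord], taxonomy: pd.Series | None = None) -> pd.DataFrame:
    """Long-format table of per-taxon statistics for TSV export."""
    df = pd.DataFrame([vars(r) for r in records])
    if taxonomy is not None and len(df):
        df.insert(1, "taxonomy", df["taxon_id"].map(taxonomy))
    return df
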