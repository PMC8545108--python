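"""Synthetic study generator: peak lists, soils, and communities with known truth.

Emulates a six-site, three-treatment (control / mineral NPK / organic
fertilization), three-replicate paddy-soil survey (54 samples):

* a CHNOSP formula library with a realistic elemental-class mix
  (~45% CHO, ~37% CHNO, ~12% CHOS, ~4% P-containing, remainder CHNOS),
  every member unique within 1 ppm so mass-based recovery is well posed;
* per-sample peak lists with multiplicative ppm-scale mass error, skewed
  occupancy, log-normal intensities, a sub-threshold S/N fraction, blank
  contaminant peaks, and unassignable singleton decoys;
* soil properties (SOM spanning ~12-49 g/kg, pH ~4.9-8.1, seven correlated
  nutrient measurements) and a per-sample target median dG_Cox negatively
  coupled to SOM at a configurable R^2 (default 0.15);
* an ASV community with a random bifurcating phylogeny and planted
  cluster I / cluster II taxa whose abundances track -dG_Cox / +SOM through
  a Gaussian-copula (rank-preserving) link at a target |Spearman rho|.

Every output is deterministic under the config seed, and ground-truth maps
(peak -> formula, taxon -> planted label, per-sample target dG) are emitted
alongside so tests can score recovery without peeking elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formula_engine import (
    DEFAULT_LIMITS,
    PROTON_MASS,
    ElementLimits,
    MolecularFormula,
)
from .community import CommunityTable, Phylogeny
from .thermo import dgcox, nosc

TREATMENTS = ("control", "NPK", "OM")


@dataclass(frozen=True)
class SynthesisConfig:
    n_sites: int = 6
    samples_per_site: int = 9  # 3 treatments x 3 replicates
    n_formulas: int = 800
    mass_range: tuple[float, float] = (150.0, 800.0)
    noise_ppm: float = 0.2
    singleton_fraction: float = 0.25  # decoy singletons per sample, as a fraction of n_formulas
    low_sn_fraction: float = 0.10    # fraction of real peaks drawn below S/N 6
    n_contaminants: int = 15
    n_taxa: int = 400
    n_cluster1: int = 40
    n_cluster2: int = 40
    planted_effect: float = 0.6      # target |Spearman rho| for planted taxa
    target_r2: float = 0.15          # dG_Cox ~ SOM coupling strength
    presence_tilt: float = 3.0       # logistic tilt of compound occupancy by dG
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sites, self.samples_per_site, self.n_formulas, self.n_taxa) < 1:
            raise ValueError("all counts must be positive")
        if self.n_cluster1 + self.n_cluster2 > self.n_taxa:
            raise ValueError("planted taxa exceed n_taxa")
        if not 0 <= self.planted_effect < 1:
            raise ValueError("planted_effect must be in [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.samples_per_site

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.n_sites):
            site = f"S{s + 1}"
            for j in range(self.samples_per_site):
                treatment = TREATMENTS[j % len(TREATMENTS)]
                rows.append(
                    {"sample_id": f"{site}_{treatment}_{j // len(TREATMENTS) + 1}",
                     "site": site, "treatment": treatment}
                )
        return pd.DataFrame(rows).set_index("sample_id")


def _rng(cfg: SynthesisConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


CLASS_TARGETS = {"CHO": 0.45, "CHNO": 0.37, "CHOS": 0.12, "P-containing": 0.04, "CHNOS": 0.02}


def generate_formula_library(
    cfg: SynthesisConfig, limits: ElementLimits = DEFAULT_LIMITS
) -> list[MolecularFormula]:
    """Draw a formula library matching the target elemental-class mix.

    Rejection sampling keeps compositions chemically plausible (H/C in
    [0.3, 2.2], O/C in [0, 1.2], NOSC in [-4, 4], P only with >= 4 O),
    enforces pairwise mass uniqueness within 1 ppm, and — so that planted
    recovery is well posed — keeps only formulas that win the assignment
    ranking over every rival composition within a guard band around their
    own mass (no rival with as few heteroatoms within 2.5 ppm).
    """
    rng = _rng(cfg, 1)
    lo, hi = cfg.mass_range
    classes = list(CLASS_TARGETS)
    weights = np.array(list(CLASS_TARGETS.values()))
    # per-class quotas so rejection sampling cannot skew the realized mix
    quota = np.floor(weights / weights.sum() * cfg.n_formulas).astype(int)
    quota[0] += cfg.n_formulas - quota.sum()
    filled = np.zeros(len(classes), dtype=int)
    out: list[MolecularFormula] = []
    masses: list[float] = []
    attempts = 0
    max_attempts = 4000 * cfg.n_formulas
    while len(out) < cfg.n_formulas:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not build a 1-ppm-unique formula library; "
                "lower n_formulas or widen mass_range"
            )
        remaining = (quota - filled).clip(min=0).astype(float)
        cls_idx = int(rng.choice(len(classes), p=remaining / remaining.sum()))
        cls = classes[cls_idx]
        c = int(rng.integers(6, 41))
        hc = rng.uniform(0.3, 2.2)
        h = int(round(hc * c))
        oc = rng.uniform(0.05, 1.2)
        o = int(round(oc * c))
        n = int(rng.integers(1, limits.n[1] + 1)) if "N" in cls else 0
        s = int(rng.integers(1, limits.s[1] + 1)) if "S" in cls else 0
        p = 0
        if cls == "P-containing":
            p = 1
            o = max(o, 4)
        if not (
            limits.c[0] <= c <= limits.c[1]
            and limits.h[0] <= h <= limits.h[1]
            and limits.o[0] <= o <= limits.o[1]
            and h >= 1
        ):
            continue
        f = MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p)
        m = f.monoisotopic_mass
        if not lo <= m <= hi:
            continue
        if not -4 <= nosc(f) <= 4:
            continue
        if any(abs(m - m2) / m * 1e6 < 1.0 for m2 in masses):
            continue
        if not _assignment_wins(f, limits):
            continue
        out.append(f)
        masses.append(m)
        filled[cls_idx] += 1
    return out


def _assignment_wins(f: MolecularFormula, limits: ElementLimits, guard_ppm: float = 2.5) -> bool:
    """True iff ``f`` beats every rival composition near its own mass.

    Any valid rival (carbon-bearing, phosphorus rule respected) with at most
    as many heteroatoms within ``guard_ppm`` could outrank ``f`` once
    ppm-scale noise shifts the observed mass, so such formulas are rejected
    from the library.
    """
    from .formula_engine import decompose_mass

    for g in decompose_mass(f.monoisotopic_mass, guard_ppm, limits):
        if g == f or g.c < 1 or (g.p >= 1 and g.o < 4):
            continue
        if g.heteroatoms <= f.heteroatoms:
            return False
    return True


def generate_soil_and_thermo_structure(cfg: SynthesisConfig) -> pd.DataFrame:
    """Per-sample soil properties and the target median dG_Cox.

    SOM has site-level means spanning ~12-49 g/kg plus within-site spread;
    pH spans ~4.9-8.1 and co-varies with site.  The target median dG_Cox is
    a negative linear function of standardized SOM with Gaussian noise sized
    so the population R^2 equals ``target_r2``; the realized value then
    fluctuates with sampling.  Six further nutrients load on SOM-like site
    fertility with independent noise.
    """
    rng = _rng(cfg, 2)
    meta = cfg.sample_frame()
    n = len(meta)
    site_idx = pd.Categorical(meta["site"]).codes
    site_som = np.linspace(14.0, 45.0, cfg.n_sites)
    site_som = rng.permutation(site_som)
    treat_shift = meta["treatment"].map({"control": -2.0, "NPK": 0.0, "OM": 3.0}).to_numpy()
    som = site_som[site_idx] + treat_shift + rng.normal(0, 2.0, n)
    som = np.clip(som, 10.0, 52.0)

    site_ph = rng.permutation(np.linspace(5.1, 7.9, cfg.n_sites))
    ph = np.clip(site_ph[site_idx] + rng.normal(0, 0.25, n), 4.5, 8.4)

    som_z = (som - som.mean()) / som.std(ddof=1)
    rho = np.sqrt(cfg.target_r2)
    dg_z = -rho * som_z + np.sqrt(1 - cfg.target_r2) * rng.normal(0, 1, n)
    # Map to a realistic median dG_Cox band (kJ per mol C)
    target_dg = 66.0 + 1.5 * dg_z

    nutrients = {"som": som, "ph": ph}
    fertility = som_z
    for name, load in (
        ("total_n", 0.8), ("alkaline_n", 0.7), ("total_p", 0.6),
        ("available_p", 0.5), ("total_k", 0.4), ("available_k", 0.4),
    ):
        base = load * fertility + np.sqrt(1 - load**2) * rng.normal(0, 1, n)
        nutrients[name] = np.round(10 + 3 * base, 3)
    frame = meta.copy()
    for k, v in nutrients.items():
        frame[k] = np.round(v, 3)
    frame["target_median_dg"] = np.round(target_dg, 4)
    return frame


def _presence_probability(
    cfg: SynthesisConfig, library: list[MolecularFormula], soil: pd.DataFrame, rng
) -> np.ndarray:
    """Formula x sample presence probabilities tilted by the dG target.

    Each formula gets a skewed baseline occupancy; samples whose target
    median dG_Cox is high preferentially retain high-dG_Cox formulas
    (logistic tilt on the formula's standardized dG rank), so the realized
    sample median tracks the target.
    """
    n_f = len(library)
    dg = np.array([dgcox(nosc(f)) for f in library])
    dg_rank = (pd.Series(dg).rank().to_numpy() - (n_f + 1) / 2) / n_f  # ~[-0.5, 0.5]
    base_logit = rng.normal(0.8, 1.2, n_f)  # skewed baseline occupancy
    z = soil["target_median_dg"].to_numpy()
    z = (z - z.mean()) / z.std(ddof=1)
    logit = base_logit[:, None] + cfg.presence_tilt * np.outer(dg_rank, z)
    return 1.0 / (1.0 + np.exp(-logit))


def generate_peak_lists(
    library: list[MolecularFormula], cfg: SynthesisConfig, soil: pd.DataFrame | None = None
):
    """Per-sample peak lists plus blanks and a ground-truth map.

    Returns ``(peak_lists, blanks, truth)`` where ``truth`` is a DataFrame
    with one row per emitted real peak (sample, observed m/z, formula,
    true neutral mass) and decoy/contaminant rows flagged.  Observed m/z is
    the deprotonated exact mass times (1 + eps), eps ~ N(0, noise_ppm*1e-6).
    """
    from .msio import Peak, PeakList

    if soil is None:
        soil = generate_soil_and_thermo_structure(cfg)
    rng = _rng(cfg, 3)
    presence_p = _presence_probability(cfg, library, soil, rng)
    samples = list(soil.index)
    neutral = np.array([f.monoisotopic_mass for f in library])
    ion_mz = neutral - PROTON_MASS
    lo, hi = cfg.mass_range

    contaminant_mz = rng.uniform(lo, hi, cfg.n_contaminants)
    n_decoys = int(round(cfg.singleton_fraction * cfg.n_formulas))

    peak_lists = []
    truth_rows = []
    for j, sid in enumerate(samples):
        present = rng.random(len(library)) < presence_p[:, j]
        mzs: list[float] = []
        peaks = []
        for i in np.nonzero(present)[0]:
            eps = rng.normal(0, cfg.noise_ppm * 1e-6)
            mz = ion_mz[i] * (1 + eps)
            inten = float(rng.lognormal(mean=14.0, sigma=1.0))
            low = rng.random() < cfg.low_sn_fraction
            sn = float(rng.uniform(1.0, 5.9)) if low else float(rng.lognormal(3.0, 0.6) + 6.0)
            peaks.append(Peak(mz=mz, intensity=inten, sn=sn))
            mzs.append(mz)
            truth_rows.append(
                {"sample_id": sid, "mz": mz, "formula": library[i].hill(),
                 "neutral_mass": neutral[i], "kind": "real", "low_sn": low}
            )
        # decoy singletons: random masses, offset from any library ion mass
        for _ in range(n_decoys):
            mz = float(rng.uniform(lo, hi))
            if np.min(np.abs(ion_mz - mz)) / mz * 1e6 < 5.0:
                continue
            peaks.append(Peak(mz=mz, intensity=float(rng.lognormal(12.0, 1.0)),
                              sn=float(rng.lognormal(2.5, 0.6) + 6.0)))
            truth_rows.append(
                {"sample_id": sid, "mz": mz, "formula": "", "neutral_mass": np.nan,
                 "kind": "decoy", "low_sn": False}
            )
        # contaminants appear in every sample and in the blanks
        for cm in contaminant_mz:
            mz = float(cm * (1 + rng.normal(0, cfg.noise_ppm * 1e-6)))
            peaks.append(Peak(mz=mz, intensity=float(rng.lognormal(13.0, 0.5)),
                              sn=float(rng.lognormal(2.5, 0.5) + 6.0)))
            truth_rows.append(
                {"sample_id": sid, "mz": mz, "formula": "", "neutral_mass": np.nan,
                 "kind": "contaminant", "low_sn": False}
            )
        peak_lists.append(PeakList(sid, peaks))

    blanks = []
    for b in range(2):
        peaks = [
            Peak(mz=float(cm * (1 + rng.normal(0, cfg.noise_ppm * 1e-6))),
                 intensity=float(rng.lognormal(13.0, 0.5)),
                 sn=float(rng.lognormal(2.5, 0.5) + 6.0))
            for cm in contaminant_mz
        ]
        blanks.append(PeakList(f"blank_{b + 1}", peaks))
    truth = pd.DataFrame(truth_rows)
    return peak_lists, blanks, truth


def realized_sample_medians(
    library: list[MolecularFormula], truth: pd.DataFrame
) -> pd.Series:
    """Median dG_Cox per sample over the truly present library formulas."""
    dg = {f.hill(): dgcox(nosc(f)) for f in library}
    real = truth[truth["kind"] == "real"]
    med = real.groupby("sample_id")["formula"].apply(
        lambda fs: float(np.median([dg[f] for f in fs]))
    )
    return med.rename("median_dgcox")


def _random_bifurcating_newick(labels: list[str], rng) -> str:
    """Random topology by iterative pairwise joining, exponential lengths."""
    nodes = [f"{lab}:{rng.exponential(0.1):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(0.1):.6f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"


def generate_community(
    cfg: SynthesisConfig, sample_dg: pd.Series, sample_som: pd.Series
) -> tuple[CommunityTable, Phylogeny, pd.Series]:
    """ASV counts, a random phylogeny, and planted cluster labels.

    Cluster-I taxa receive a latent Gaussian score correlated with the
    composite driver (-dG_Cox standardized + SOM standardized) at the
    planted effect size; cluster-II taxa the negated driver; null taxa pure
    noise.  The latent score shifts the taxon's log-abundance across
    samples, counts are multinomial at depths >= 7,000, and the copula link
    makes the realized Spearman rho of relative abundance against dG_Cox
    approach the target.
    """
    rng = _rng(cfg, 4)
    samples = list(sample_dg.index)
    n = len(samples)
    n1, n2 = cfg.n_cluster1, cfg.n_cluster2
    labels = (
        [CLUSTER for CLUSTER, cnt in (("I", n1), ("II", n2)) for _ in range(cnt)]
        + ["null"] * (cfg.n_taxa - n1 - n2)
    )
    taxa = [f"ASV{i + 1:04d}" for i in range(cfg.n_taxa)]
    planted = pd.Series(labels, index=taxa, name="planted_cluster")

    def norm_scores(v: np.ndarray) -> np.ndarray:
        from scipy import stats as _st

        return _st.norm.ppf((_st.rankdata(v)) / (len(v) + 1))

    driver = norm_scores(-sample_dg.to_numpy() + 0.0) + norm_scores(sample_som.to_numpy())
    driver = (driver - driver.mean()) / driver.std(ddof=1)
    # Pearson latent correlation giving the target Spearman under the copula
    rho_lat = 2 * np.sin(cfg.planted_effect * np.pi / 6)

    base_log = rng.normal(0.0, 1.0, cfg.n_taxa)  # taxon baseline log-abundance
    effect_scale = 1.2  # log-abundance swing per latent s.d.
    log_ab = np.empty((cfg.n_taxa, n))
    for i, lab in enumerate(labels):
        noise = rng.normal(0, 1, n)
        if lab == "I":
            latent = rho_lat * driver + np.sqrt(1 - rho_lat**2) * noise
        elif lab == "II":
            latent = -rho_lat * driver + np.sqrt(1 - rho_lat**2) * noise
        else:
            latent = noise
        log_ab[i] = base_log[i] + effect_scale * latent
    probs = np.exp(log_ab)
    probs /= probs.sum(axis=0)

    depths = rng.integers(8000, 16001, n)
    counts = np.column_stack(
        [rng.multinomial(int(d), probs[:, j]) for j, d in enumerate(depths)]
    )
    frame = pd.DataFrame(counts, index=taxa, columns=samples)

    phyla = ["Proteobacteria", "Acidobacteria", "Actinobacteria", "Chloroflexi", "Firmicutes"]
    taxonomy = pd.Series(
        [f"Bacteria;{phyla[i % len(phyla)]};ASV{i + 1:04d}" for i in range(cfg.n_taxa)],
        index=taxa, name="taxonomy",
    )
    newick = _random_bifurcating_newick(taxa, rng)
    tree = Phylogeny.from_string(newick)

    sites = pd.Series(
        [sid.split("_")[0] for sid in samples], index=samples, name="site"
    )
    table = CommunityTable(counts=frame, taxonomy=taxonomy, sample_sites=sites)
    return table, tree, planted


def write_bundle(cfg: SynthesisConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full study bundle and write it as plain-text files."""
    from .msio import write_peak_list

    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    library = generate_formula_library(cfg)
    soil = generate_soil_and_thermo_structure(cfg)
    peak_lists, blanks, truth = generate_peak_lists(library, cfg, soil)
    table, tree, planted = generate_community(
        cfg, soil["target_median_dg"], soil["som"]
    )

    for pl in peak_lists + blanks:
        p = out / "peaks" / f"{pl.sample_id}.csv"
        write_peak_list(pl, p)
    paths["peaks_dir"] = out / "peaks"

    paths["metadata"] = out / "metadata.tsv"
    soil.to_csv(paths["metadata"], sep="\t")
    paths["asv_table"] = out / "asv_table.tsv"
    table.counts.to_csv(paths["asv_table"], sep="\t")
    paths["taxonomy"] = out / "taxonomy.tsv"
    table.taxonomy.to_csv(paths["taxonomy"], sep="\t")
    paths["tree"] = out / "tree.nwk"
    paths["tree"].write_text(tree.tree.as_string(schema="newick"))
    paths["truth_peaks"] = out / "truth_peaks.tsv"
    truth.to_csv(paths["truth_peaks"], sep="\t", index=False)
    paths["truth_library"] = out / "truth_library.tsv"
    pd.DataFrame(
        {"formula": [f.hill() for f in library],
         "neutral_mass": [f.monoisotopic_mass for f in library]}
    ).to_csv(paths["truth_library"], sep="\t", index=False)
    paths["truth_clusters"] = out / "truth_clusters.tsv"
    planted.to_csv(paths["truth_clusters"], sep="\t")
    return paths
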