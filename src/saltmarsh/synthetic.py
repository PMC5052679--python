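"""Ground-truth generators for paired community tables and tidal-creek O2 series.

Two forward models mirror the study's two data streams:

* :func:`simulate_paired_community` draws a sediment community with a known
  dormant fraction. Taxon base abundances follow a lognormal rank-abundance
  law; each taxon carries an activity multiplier (<= 1 for dormant taxa,
  > 1 for active ones) and RNA relative abundances are base abundance times
  multiplier, renormalized. DNA and RNA reads are overdispersed multinomial
  draws (a Dirichlet perturbation of the per-sample proportions precedes
  each multinomial). Nutrient enrichment is modelled as activity
  reassignment only — most active taxa become dormant while a small bloom
  cohort is boosted — so the DNA table is treatment-invariant by
  construction.

* :func:`simulate_tidal_creek` integrates the same oxygen budget the NEM
  estimator inverts: a semidiurnal (plus diurnal-inequality) tide over a
  trapezoidal channel, a daylight half-sine gross production curve, constant
  respiration and wind/current-driven gas exchange, with Gaussian
  observation noise on the reported saturation. The prescribed production,
  respiration and NEM series are returned as truth.

Every generator takes a mandatory seed and is bit-reproducible under it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from saltmarsh import tables
from saltmarsh.nem import (
    GAS_EXCHANGE_MODELS,
    CreekGeometry,
    GasExchangeModel,
    o2_saturation_concentration,
)
from saltmarsh.tables import (
    CountTable,
    PairedCommunityTable,
    TaxonomyMap,
    TidalCreekSeries,
)

MONTHS = ("May", "Jun", "Jul", "Aug", "Sep", "Oct")

# order -> (phylum, class); the focal bloom orders come first
_ORDER_LINEAGES = {
    "Desulfobacterales": ("Proteobacteria", "Deltaproteobacteria"),
    "Oscillatoriales": ("Cyanobacteria", "Oscillatoriophycideae"),
    "Chromatiales": ("Proteobacteria", "Gammaproteobacteria"),
    "Rhizobiales": ("Proteobacteria", "Alphaproteobacteria"),
    "Rhodocyclales": ("Proteobacteria", "Betaproteobacteria"),
    "Chlorobiales": ("Chlorobi", "Chlorobia"),
    "Desulfuromonadales": ("Proteobacteria", "Deltaproteobacteria"),
    "Flavobacteriales": ("Bacteroidetes", "Flavobacteriia"),
    "Clostridiales": ("Firmicutes", "Clostridia"),
    "Campylobacterales": ("Proteobacteria", "Epsilonproteobacteria"),
    "Anaerolineales": ("Chloroflexi", "Anaerolineae"),
    "Actinomycetales": ("Actinobacteria", "Actinobacteria"),
}


@dataclass(frozen=True)
class CommunitySimConfig:
    """Configuration of the paired-community generator.

    The defaults describe the reference condition: 45% of taxa dormant,
    sequencing depth 5e4 reads per library, mild overdispersion. Dormant
    activity multipliers are log-uniform on (0.02, 0.6]; active multipliers
    lognormal with median 25 — the order of magnitude reported for clearly
    active taxa — and narrow spread, so the two classes are well separated
    on the ratio scale after compositional renormalization.
    """

    n_taxa: int = 250
    n_samples: int = 10
    dormant_fraction: float = 0.45
    rank_abundance_sigma: float = 1.1
    dormant_multiplier_range: tuple[float, float] = (0.02, 0.6)
    active_multiplier_median: float = 25.0
    active_multiplier_sigma: float = 0.15
    bloom_fraction: float = 0.18
    bloom_boost: float = 5.0
    dna_depth: int = 50_000
    rna_depth: int = 50_000
    overdispersion: float = 1e5
    # experiment design
    n_months: int = 6
    n_replicates: int = 3
    habitat_sigma: float = 0.25
    month_activity_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dormant_fraction <= 1.0):
            raise ValueError("dormant_fraction must lie in [0, 1]")
        if min(self.dna_depth, self.rna_depth) < 1_000:
            raise ValueError("library depths must be >= 1000 reads")
        n_dormant = int(round(self.dormant_fraction * self.n_taxa))
        if 0 < self.dormant_fraction < 1 and not (0 < n_dormant < self.n_taxa):
            raise ValueError("dormant_fraction leaves a class with no taxa")


def _draw_multipliers(cfg: CommunitySimConfig, rng: np.random.Generator,
                      dormant: np.ndarray) -> np.ndarray:
    m = np.empty(dormant.size)
    lo, hi = cfg.dormant_multiplier_range
    n_d = int(dormant.sum())
    m[dormant] = np.exp(rng.uniform(np.log(lo), np.log(hi), n_d))
    m[~dormant] = np.maximum(
        rng.lognormal(np.log(cfg.active_multiplier_median),
                      cfg.active_multiplier_sigma, dormant.size - n_d),
        np.nextafter(1.0, 2.0))
    return m


def _draw_truth(cfg: CommunitySimConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Dormancy mask and activity multipliers for the reference condition."""
    n_dormant = int(round(cfg.dormant_fraction * cfg.n_taxa))
    dormant = np.zeros(cfg.n_taxa, dtype=bool)
    dormant[rng.choice(cfg.n_taxa, n_dormant, replace=False)] = True
    return dormant, _draw_multipliers(cfg, rng, dormant)


def _enrich_truth(cfg: CommunitySimConfig, rng: np.random.Generator,
                  dormant: np.ndarray, mult: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Enrichment reassigns most active taxa to dormancy and boosts the
    remaining bloom cohort's activity."""
    dormant = dormant.copy()
    mult = mult.copy()
    active_idx = np.flatnonzero(~dormant)
    n_bloom = int(round(cfg.bloom_fraction * active_idx.size))
    bloom = rng.choice(active_idx, n_bloom, replace=False)
    demoted = np.setdiff1d(active_idx, bloom)
    dormant[demoted] = True
    lo, hi = cfg.dormant_multiplier_range
    mult[demoted] = np.exp(rng.uniform(np.log(lo), np.log(hi), demoted.size))
    mult[bloom] *= cfg.bloom_boost
    return dormant, mult


def _sample_counts(rng: np.random.Generator, proportions: np.ndarray,
                   depth: int, tau: float) -> np.ndarray:
    p = rng.dirichlet(proportions * tau)
    return rng.multinomial(depth, p)


def simulate_paired_community(config: CommunitySimConfig, enriched: bool = False
                              ) -> tuple[PairedCommunityTable, pd.DataFrame]:
    """Draw one group of paired DNA/RNA samples with known activity truth.

    Returns ``(paired, truth)`` where ``truth`` is indexed by taxon id with
    columns ``label`` (active/dormant) and ``multiplier``. With
    ``enriched=True`` the enrichment reassignment is applied before
    sampling, yielding an effective dormant fraction of
    ``p + (1 - p) * (1 - bloom_fraction)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    base = rng.lognormal(0.0, cfg.rank_abundance_sigma, cfg.n_taxa)
    base /= base.sum()
    dormant, mult = _draw_truth(cfg, rng)
    if enriched:
        dormant, mult = _enrich_truth(cfg, rng, dormant, mult)
    rna_base = base * mult
    rna_base /= rna_base.sum()

    taxa = [f"OTU{i:04d}" for i in range(cfg.n_taxa)]
    prefix = "E" if enriched else "R"
    sample_ids = [f"{prefix}S{j:02d}" for j in range(cfg.n_samples)]
    dna = np.column_stack([
        _sample_counts(rng, base, cfg.dna_depth, cfg.overdispersion)
        for _ in sample_ids])
    rna = np.column_stack([
        _sample_counts(rng, rna_base, cfg.rna_depth, cfg.overdispersion)
        for _ in sample_ids])
    paired = PairedCommunityTable(taxa, sample_ids, dna, rna)
    truth = pd.DataFrame({
        "label": np.where(dormant, "dormant", "active"),
        "multiplier": mult,
        "base_abundance": base,
    }, index=taxa)
    return paired, truth


@dataclass
class ExperimentData:
    """A complete synthetic study: paired tables with metadata, taxonomy,
    a phylogeny over the taxa, and the generator's truth per treatment."""

    paired: PairedCommunityTable
    taxonomy: TaxonomyMap
    tree: TreeNode
    truth: dict[str, pd.DataFrame]


def _random_tree(taxa: list[str], rng: np.random.Generator) -> TreeNode:
    """Random coalescent-style binary tree with exponential branch lengths."""
    frags = [f"{t}:{rng.exponential(0.5):.6f}" for t in taxa]
    while len(frags) > 1:
        i, j = rng.choice(len(frags), 2, replace=False)
        a, b = frags[i], frags[j]
        merged = f"({a},{b}):{rng.exponential(0.5):.6f}"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    newick = f"({frags[0]});" if len(taxa) > 1 else f"({frags[0]});"
    return tables.read_tree(newick)


def _random_taxonomy(taxa: list[str], bloom_taxa: set[str],
                     rng: np.random.Generator) -> TaxonomyMap:
    orders = list(_ORDER_LINEAGES)
    weights = rng.dirichlet(np.full(len(orders), 2.0))
    lineages: dict[str, tuple[str, ...]] = {}
    for t in taxa:
        if t in bloom_taxa:  # blooms sit in the focal sulfate-reducer/cyanobacterial orders
            order = orders[rng.integers(0, 2)]
        else:
            order = orders[rng.choice(len(orders), p=weights)]
        phylum, klass = _ORDER_LINEAGES[order]
        lineages[t] = ("Bacteria", phylum, klass, order,
                       f"{order[:-3]}aceae", f"genus_{t}", tables.UNCLASSIFIED)
    return TaxonomyMap(lineages)


def simulate_experiment(config: CommunitySimConfig, out_dir: str | Path | None = None
                        ) -> ExperimentData:
    """Simulate the full 2 treatments x 2 habitats x monthly design.

    Habitat tilts the base abundances (identically in both treatments, so
    habitat structures the DNA community but treatment does not); month
    jitters activity multipliers (seasonal structure in the RNA community);
    treatment acts on activity only. Sample count is
    2 x 2 x n_months x n_replicates.

    With ``out_dir`` set, the tables are also written in every supported
    dialect (count TSV + dense-JSON BIOM with _DNA/_cDNA library suffixes,
    mapping TSV, taxonomy TSV, newick tree).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    base = rng.lognormal(0.0, cfg.rank_abundance_sigma, cfg.n_taxa)
    base /= base.sum()
    dormant_ref, mult_ref = _draw_truth(cfg, rng)
    dormant_enr, mult_enr = _enrich_truth(cfg, rng, dormant_ref, mult_ref)
    habitat_tilt = {
        h: np.exp(rng.normal(0.0, cfg.habitat_sigma, cfg.n_taxa))
        for h in tables.HABITATS
    }
    months = MONTHS[: cfg.n_months]
    month_jitter = {
        m: np.exp(rng.normal(0.0, cfg.month_activity_sigma, cfg.n_taxa))
        for m in months
    }

    taxa = [f"OTU{i:04d}" for i in range(cfg.n_taxa)]
    sample_ids, meta_rows = [], []
    dna_cols, rna_cols = [], []
    truth_mult = {"reference": mult_ref, "enriched": mult_enr}
    truth_dormant = {"reference": dormant_ref, "enriched": dormant_enr}
    for treatment in tables.TREATMENTS:
        mult = truth_mult[treatment]
        for habitat in tables.HABITATS:
            b = base * habitat_tilt[habitat]
            b /= b.sum()
            for mi, month in enumerate(months):
                rna_base = b * mult * month_jitter[month]
                rna_base /= rna_base.sum()
                for rep in range(1, cfg.n_replicates + 1):
                    sid = f"{treatment[:3]}-{habitat}-{month}-{rep}"
                    sample_ids.append(sid)
                    meta_rows.append({
                        "SampleID": sid, "treatment": treatment,
                        "habitat": habitat,
                        "date": f"2013-{5 + mi:02d}-15", "replicate": rep,
                    })
                    dna_cols.append(_sample_counts(rng, b, cfg.dna_depth,
                                                   cfg.overdispersion))
                    rna_cols.append(_sample_counts(rng, rna_base, cfg.rna_depth,
                                                   cfg.overdispersion))
    metadata = pd.DataFrame(meta_rows).set_index("SampleID")
    metadata.index.name = "sample_id"
    metadata["date"] = pd.to_datetime(metadata["date"])
    paired = PairedCommunityTable(taxa, sample_ids,
                                  np.column_stack(dna_cols),
                                  np.column_stack(rna_cols), metadata)

    bloom = {t for t, d_r, d_e in zip(taxa, dormant_ref, dormant_enr)
             if not d_r and not d_e}
    taxonomy = _random_taxonomy(taxa, bloom, rng)
    tree = _random_tree(taxa, rng)
    truth = {
        g: pd.DataFrame({"label": np.where(truth_dormant[g], "dormant", "active"),
                         "multiplier": truth_mult[g]}, index=taxa)
        for g in ("reference", "enriched")
    }
    data = ExperimentData(paired, taxonomy, tree, truth)
    if out_dir is not None:
        _write_experiment(data, Path(out_dir))
    return data


def _write_experiment(data: ExperimentData, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    p = data.paired
    dna = CountTable(list(p.taxon_ids), [s + "_DNA" for s in p.sample_ids], p.dna)
    rna = CountTable(list(p.taxon_ids), [s + "_cDNA" for s in p.sample_ids], p.rna)
    tables.write_count_table(dna, out_dir / "dna.tsv")
    tables.write_count_table(rna, out_dir / "rna.tsv")
    tables.write_count_table(dna, out_dir / "dna.biom.json", dialect="biom_json")
    tables.write_count_table(rna, out_dir / "rna.biom.json", dialect="biom_json")
    tables.write_metadata(p.metadata, out_dir / "map.tsv")
    tables.write_taxonomy(data.taxonomy, out_dir / "taxonomy.tsv")
    data.tree.write(str(out_dir / "tree.nwk"))


# ---------------------------------------------------------------------------
# tidal creek


@dataclass(frozen=True)
class CreekSimConfig:
    """Forward model of the tidal-creek oxygen record.

    Depth is offset + semidiurnal sine + a diurnal-inequality term (so
    successive high tides alternate in height and only the higher ones
    flood the marsh platform). Gross production follows a daylight
    half-sine with amplitude ``production_amplitude``; respiration is
    constant. Rates are per unit creek length (mmol O2 m^-1 min^-1).
    Observation noise is Gaussian on the reported saturation (%).
    """

    days: float = 6.0
    dt_minutes: float = 10.0
    tidal_amplitude: float = 0.8
    tidal_period_hours: float = 12.0
    diurnal_amplitude: float = 0.15
    depth_offset: float = 1.0
    temperature: float = 22.0
    salinity: float = 30.0
    wind_mean: float = 3.0
    wind_diel_amplitude: float = 1.5
    current_scale: float = 0.3
    production_amplitude: float = 1.5
    respiration: float = 0.5
    sunrise_hour: float = 6.0
    daylight_hours: float = 12.0
    constant_light: bool = False  # P(t) = production_amplitude at all times
    k_scale: float = 1.0
    noise_sd: float = 0.0
    integration_dt_minutes: float = 1.0
    start: str = "2012-08-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_offset - self.tidal_amplitude - self.diurnal_amplitude < 0:
            raise ValueError("config produces negative depth at low tide")
        if self.production_amplitude < 0 or self.respiration < 0:
            raise ValueError("production and respiration must be >= 0")
        n_per_tide = self.tidal_period_hours * 60.0 / self.dt_minutes
        if abs(n_per_tide - round(n_per_tide)) > 1e-9:
            raise ValueError("dt must divide the tidal period")


def _depth(cfg: CreekSimConfig, t_min: np.ndarray) -> np.ndarray:
    w = 2.0 * np.pi / (cfg.tidal_period_hours * 60.0)
    return (cfg.depth_offset + cfg.tidal_amplitude * np.sin(w * t_min)
            + cfg.diurnal_amplitude * np.sin(0.5 * w * t_min))


def _metabolism(cfg: CreekSimConfig, t_min: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Prescribed gross production P(t) and respiration R(t)."""
    if cfg.constant_light:
        light = np.ones_like(t_min)
    else:
        hour = (t_min / 60.0) % 24.0
        frac = (hour - cfg.sunrise_hour) / cfg.daylight_hours
        light = np.where((frac >= 0) & (frac <= 1),
                         np.sin(np.pi * np.clip(frac, 0, 1)), 0.0)
    p = cfg.production_amplitude * light
    r = np.full_like(p, cfg.respiration)
    return p, r


def simulate_tidal_creek(config: CreekSimConfig,
                         geometry: CreekGeometry | None = None,
                         gas_model: GasExchangeModel | str = "wind_current",
                         production_scale: float = 1.0,
                         respiration_scale: float = 1.0,
                         ) -> tuple[TidalCreekSeries, pd.DataFrame]:
    """Integrate the oxygen budget forward and emit a sensor series.

    Returns ``(series, truth)``; ``truth`` holds the prescribed
    ``production``, ``respiration`` and ``nem`` (= P - R) at the sensor
    timestamps. ``production_scale`` / ``respiration_scale`` amplify the
    metabolism (the nutrient-enriched creek of the paired-creek scenario).
    """
    cfg = config
    geometry = geometry or CreekGeometry()
    if isinstance(gas_model, str):
        gas_model = GAS_EXCHANGE_MODELS[gas_model]
    rng = np.random.default_rng(cfg.seed)
    n_out = int(round(cfg.days * 24 * 60 / cfg.dt_minutes)) + 1
    sub = cfg.dt_minutes / cfg.integration_dt_minutes
    if abs(sub - round(sub)) > 1e-9 or sub < 1:
        raise ValueError("integration step must divide the output step")
    sub = int(round(sub))
    t_fine = np.arange((n_out - 1) * sub + 1) * cfg.integration_dt_minutes
    h = _depth(cfg, t_fine)
    p, r = _metabolism(cfg, t_fine)
    nem_true = production_scale * p - respiration_scale * r
    c_sat = o2_saturation_concentration(cfg.temperature, cfg.salinity)
    hour = (t_fine / 60.0) % 24.0
    wind = cfg.wind_mean + cfg.wind_diel_amplitude * np.sin(
        2 * np.pi * (hour - 9.0) / 24.0)
    wind = np.maximum(wind, 0.0)
    w_tide = 2.0 * np.pi / (cfg.tidal_period_hours * 60.0)
    current = cfg.current_scale * np.abs(np.cos(w_tide * t_fine))

    v = geometry.volume(h)
    width = geometry.width(h)
    k = cfg.k_scale * gas_model.k(wind, current, h, cfg.temperature)
    c = np.empty_like(t_fine)
    c[0] = c_sat
    dt = cfg.integration_dt_minutes
    for i in range(len(t_fine) - 1):
        # Heun step of V dC/dt = NEM + k (Csat - C) w
        def dcdt(ci, j):
            return (nem_true[j] + k[j] * (c_sat - ci) * width[j]) / v[j]
        k1 = dcdt(c[i], i)
        k2 = dcdt(c[i] + dt * k1, i + 1)
        c[i + 1] = c[i] + 0.5 * dt * (k1 + k2)

    idx = np.arange(0, len(t_fine), sub)
    timestamps = pd.date_range(cfg.start, periods=n_out,
                               freq=f"{cfg.dt_minutes:g}min")
    sat = c[idx] / c_sat * 100.0
    if cfg.noise_sd > 0:
        sat = sat + rng.normal(0.0, cfg.noise_sd, sat.size)
    df = pd.DataFrame({
        "depth": h[idx],
        "temperature": np.full(n_out, cfg.temperature),
        "salinity": np.full(n_out, cfg.salinity),
        "o2_saturation": sat,
        "wind": wind[idx],
        "current": current[idx],
    }, index=timestamps)
    df.index.name = "timestamp"
    truth = pd.DataFrame({
        "production": production_scale * p[idx],
        "respiration": respiration_scale * r[idx],
        "nem": nem_true[idx],
    }, index=timestamps)
    return TidalCreekSeries(df), truth
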