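"""Synthetic microcosm panels with the statistical structure the analysis assumes.

Generates (a) paired chl-/chl+ nitrate time series whose truth parameters place
each (soil, perturbed pH) condition in a known functional regime, with the
regime boundaries shifting with native pH; and (b) ASV count tables with
internal-standard spike-ins (~8.9% of reads), truncated-Gaussian replicate
noise sigma(c0, c_frac), regime-dependent phylum growth (Bacillota under basic
perturbations, Pseudomonadota/Bacteroidota at moderate pH), acid-death
survival signal, and native-pH-dependent taxonomic identity of the resurgent
growers.

Every generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .abundance import CountTable
from .crm import CRMParams, simulate, simulate_chl_arm
from .enrichment import NoiseModel, noise_sd
from .fitting import PAPER_TIME_GRID_DAYS, TimeSeriesPair

__all__ = [
    "SynthConfig",
    "SoilPanel",
    "CountTruth",
    "regime_map",
    "synth_nitrate_pair",
    "synth_soil_gradient",
    "synth_count_table",
    "synth_presence_panel",
    "synth_amendment_series",
    "PHYLUM_ROSTER",
]

# 40 phyla, mirroring the study's phylum-level growth matrix height
PHYLUM_ROSTER = (
    "Pseudomonadota", "Bacillota", "Bacteroidota", "Actinomycetota",
    "Acidobacteriota", "Verrucomicrobiota", "Planctomycetota", "Chloroflexota",
    "Gemmatimonadota", "Myxococcota", "Nitrospirota", "Bdellovibrionota",
    "Patescibacteria", "Armatimonadota", "Fibrobacterota", "Cyanobacteriota",
    "Deinococcota", "Spirochaetota", "Elusimicrobiota", "Fusobacteriota",
    "Campylobacterota", "Desulfobacterota", "Thermoproteota", "Halobacteriota",
    "Latescibacterota", "Entotheonellaeota", "Dependentiae", "Sumerlaeota",
    "Hydrogenedentes", "Zixibacteria", "Dadabacteria", "Methylomirabilota",
    "Abditibacteriota", "Calditrichota", "Chlamydiota", "Dormibacterota",
    "Eremiobacterota", "Nanoarchaeota", "Micrarchaeota", "Aenigmatarchaeota",
)

# regime anchor parameters (x~(0) mM/day, C~(0) mM): acidic death,
# nutrient-limiting, resurgent growth
REGIME_ANCHORS = {"I": (0.01, 0.005), "II": (0.1, 0.05), "III": (0.001, 2.0)}

SPIKE_IDS = ("spike_Escherichia", "spike_Parabacteroides")


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults for the generators.

    The defaults mirror the experimental design: 10 sequenced soils spanning
    native pH 4.7-8.3, 13 perturbed pH levels between 3 and 9, triplicates,
    the 10-point 91 h sampling grid, 2 mM nitrate input, 2% fractional
    measurement noise on nitrate, spike-ins near 8.9% of reads, and
    Soil-11-like replicate count noise (c_frac = 0.21, c0 = 4.5).
    """

    seed: int = 0
    n_soils: int = 10
    native_ph_range: tuple[float, float] = (4.7, 8.3)
    perturbed_ph: tuple = tuple(np.linspace(3.0, 9.0, 13))
    n_replicates: int = 3
    times: tuple = tuple(PAPER_TIME_GRID_DAYS)
    noise_sd: float = 0.02  # fractional sd on nitrate readings
    gamma: float = 4.8  # 1/day
    k_a: float = 0.01  # mM
    k_c_tilde: float = 0.01  # mM
    a0: float = 2.0  # mM nitrate input
    jitter: float = 0.5  # +/- fractional jitter on regime anchor parameters
    # count-table parameters
    n_asv: int = 2000
    mean_depth: float = 50000.0
    spike_fraction: float = 0.089
    c_frac: float = 0.21
    c0: float = 4.5
    grower_fold_iii: float = 100.0
    grower_fold_ii: float = 10.0
    nn_fold: float = 30.0
    n_growers: int = 20
    n_nn: int = 2
    # breadth of the moderate-pH growth mode: additional phyla whose dominant
    # members also grow in the nutrient-limiting regime, as in the study's
    # phylum growth vectors
    n_extra_growers: int = 8
    extra_fold: float = 8.0

    @property
    def native_ph_values(self) -> np.ndarray:
        return np.linspace(*self.native_ph_range, self.n_soils)

    @property
    def soil_ids(self) -> list[str]:
        return [f"soil{i + 1:02d}" for i in range(self.n_soils)]


@dataclass
class SoilPanel:
    """Gradient panel: replicate time-series pairs plus planted truth."""

    pairs: list  # TimeSeriesPair
    truth: pd.DataFrame  # per (soil, pH): params, regime, native pH


@dataclass
class CountTruth:
    """Planted structure of a synthetic count table."""

    growers: dict  # regime -> set of ASV ids planted as growers
    nn_responders: set
    asv_phylum: pd.Series


def _boundaries(native_ph: float) -> tuple[float, float]:
    """Perturbed-pH regime boundaries as a function of native pH.

    More acidic soils shift from Regime II to Regime I after smaller acidic
    perturbations (lower II->I boundary), and reach resurgent growth at lower
    basic pH than alkaline soils reach... the III boundary decreases mildly
    with native pH so every soil shows all three regimes on the 3-9 grid.
    """
    b_acid = 3.2 + 0.15 * native_ph  # Regime I for perturbed pH < b_acid
    b_base = 9.2 - 0.15 * native_ph  # Regime III for perturbed pH >= b_base
    return b_acid, b_base


def regime_map(config: SynthConfig) -> pd.DataFrame:
    """Planted regime label for every (soil, perturbed pH) condition."""
    rows = []
    for soil, native in zip(config.soil_ids, config.native_ph_values):
        b_acid, b_base = _boundaries(native)
        for ph in config.perturbed_ph:
            regime = "I" if ph < b_acid else ("III" if ph >= b_base else "II")
            rows.append((soil, float(native), float(ph), regime))
    return pd.DataFrame(rows, columns=["soil_id", "native_pH", "perturbed_pH", "regime"])


def synth_nitrate_pair(truth: CRMParams, times=None, noise_sd: float = 0.02,
                       seed: int = 0, soil_id: str = "synthetic",
                       perturbed_ph: float = float("nan"),
                       replicate: int = 0) -> TimeSeriesPair:
    """Simulate both arms and add multiplicative Gaussian noise, floored at 0."""
    t = np.asarray(PAPER_TIME_GRID_DAYS if times is None else times, float)
    rng = np.random.default_rng(seed)
    a_minus = simulate(truth, t, growth_on=True).A
    a_plus = simulate_chl_arm(truth, t)
    if noise_sd > 0:
        a_minus = a_minus * (1 + rng.normal(0, noise_sd, t.size))
        a_plus = a_plus * (1 + rng.normal(0, noise_sd, t.size))
    return TimeSeriesPair(soil_id, perturbed_ph, replicate, t,
                          np.maximum(a_minus, 0.0), t, np.maximum(a_plus, 0.0))


def _truth_params(config: SynthConfig, regime: str, ph: float, rng) -> CRMParams:
    x_anchor, c_anchor = REGIME_ANCHORS[regime]
    j = config.jitter
    x0 = x_anchor * rng.uniform(1 - j, 1 + j)
    c0 = c_anchor * rng.uniform(1 - j, 1 + j)
    if regime == "II":
        # biomass activity rises mildly with pH across the plateau, but the
        # jittered draw must stay inside the labelled quadrant (>= 0.05)
        x0 = max(x0 * (1.0 + 0.05 * (ph - 6.0)), 0.055)
    return CRMParams(x0_tilde=max(x0, 1e-4), C0_tilde=max(c0, 1e-4),
                     A0=config.a0, A0c=config.a0, gamma=config.gamma,
                     K_A=config.k_a, K_C_tilde=config.k_c_tilde)


def synth_soil_gradient(config: SynthConfig) -> SoilPanel:
    """Regime-structured nitrate panel across the native x perturbed pH grid."""
    rng = np.random.default_rng(config.seed)
    rmap = regime_map(config)
    pairs, rows = [], []
    for _, row in rmap.iterrows():
        truth = _truth_params(config, row["regime"], row["perturbed_pH"], rng)
        for rep in range(config.n_replicates):
            pairs.append(synth_nitrate_pair(
                truth, config.times, config.noise_sd,
                seed=int(rng.integers(2**31 - 1)),
                soil_id=row["soil_id"], perturbed_ph=row["perturbed_pH"],
                replicate=rep))
        rows.append((row["soil_id"], row["native_pH"], row["perturbed_pH"],
                     row["regime"], truth.x0_tilde, truth.gamma * truth.C0_tilde))
    truth_df = pd.DataFrame(rows, columns=["soil_id", "native_pH", "perturbed_pH",
                                           "regime", "x0_tilde", "gamma_C0_tilde"])
    return SoilPanel(pairs=pairs, truth=truth_df)


def _draw_counts(mu: np.ndarray, model: NoiseModel, rng) -> np.ndarray:
    """Truncated-Gaussian counts around expected values (the analysis's own
    effective noise model), rounded and floored at 0."""
    n = rng.normal(mu, noise_sd(mu, model))
    return np.rint(np.maximum(n, 0.0))


# Bacillota resurgent-grower families tile the native-pH axis so that the
# taxonomic identity of Regime III growers encodes the source soil's pH
_GROWER_FAMILY_CENTERS = np.linspace(4.5, 8.5, 6)
_GROWER_FAMILY_WINDOW = 1.4


def _taxonomy(config: SynthConfig, rng) -> pd.DataFrame:
    phy_weights = np.array([0.18, 0.14, 0.10, 0.10] + [0.48 / 36] * 36)
    asvs = [f"asv{i:05d}" for i in range(config.n_asv)]
    phyla = rng.choice(PHYLUM_ROSTER, size=config.n_asv, p=phy_weights)
    fam, gen = [], []
    for i, p in enumerate(phyla):
        if p == "Bacillota":
            k = rng.integers(len(_GROWER_FAMILY_CENTERS))
            fam.append(f"Bacillota_fam{k + 1}")
        else:
            fam.append(f"{p}_fam{rng.integers(1, 4)}")
        gen.append(f"{fam[-1]}_gen{rng.integers(1, 4)}")
    return pd.DataFrame({"phylum": phyla, "family": fam, "genus": gen}, index=asvs)


def synth_count_table(config: SynthConfig, regimes: pd.DataFrame | None = None,
                      seed: int | None = None) -> tuple[CountTable, CountTruth]:
    """Count table with planted growers, NNresponders, death and spike-ins.

    Samples per (soil, perturbed pH): triplicate endpoint chl- and chl+ with
    nitrate; per soil additionally triplicate T0 and, at the unperturbed
    (native-pH-nearest) level only, triplicate no-nitrate chl-/chl+ endpoints.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if regimes is None:
        regimes = regime_map(config)
    model = NoiseModel(c_frac=config.c_frac, c0=config.c0)
    taxonomy = _taxonomy(config, rng)
    asvs = taxonomy.index.to_numpy()
    phyla = taxonomy["phylum"].to_numpy()

    base_w = np.exp(rng.normal(0.0, 1.2, config.n_asv))  # community weights

    # per-soil presence/abundance modulation; Bacillota growers present only in
    # soils whose native pH falls inside their family's window
    soil_native = dict(zip(config.soil_ids, config.native_ph_values))
    fam_center = {f"Bacillota_fam{k + 1}": c
                  for k, c in enumerate(_GROWER_FAMILY_CENTERS)}

    bacillota = np.where(phyla == "Bacillota")[0]
    modph = np.where((phyla == "Pseudomonadota") | (phyla == "Bacteroidota"))[0]

    def top_of(idx):
        # responders are dominant members of their phylum, as in the study,
        # so growth is visible at the phylum level
        order = idx[np.argsort(-base_w[idx])]
        return set(asvs[order[: config.n_growers]])

    growers_iii = top_of(bacillota)
    growers_ii = (top_of(np.where(phyla == "Pseudomonadota")[0])
                  | top_of(np.where(phyla == "Bacteroidota")[0]))
    extra_ii: set = set()
    for ph_name in ("Actinomycetota", "Acidobacteriota", "Verrucomicrobiota",
                    "Planctomycetota", "Chloroflexota", "Gemmatimonadota",
                    "Myxococcota"):
        idx = np.where(phyla == ph_name)[0]
        if idx.size:
            order = idx[np.argsort(-base_w[idx])]
            extra_ii |= set(asvs[order[: config.n_extra_growers]])
    # nitrate-independent responders (e.g. fermenters) come from the dominant
    # phyla, distinct from the planted nitrate-responsive growers
    nn_pool = [a for a in asvs[modph[np.argsort(-base_w[modph])]]
               if a not in growers_ii][: config.n_nn]
    nn = set(nn_pool)

    counts_rows, meta_rows, index = [], [], []

    def add_sample(biomass, spike_biomass, soil, native, ph, treatment, nitrate,
                   timepoint, rep, depth_jit, spike_jit):
        """Reads split between community and spikes in proportion to DNA:
        the spike is a fixed added quantity, so death raises and growth
        dilutes the spike share while counts/spike tracks absolute biomass."""
        s_eff = spike_biomass * spike_jit
        denom = biomass.sum() + s_eff
        depth = config.mean_depth * depth_jit
        mu = biomass / denom * depth
        spike_mu = s_eff / denom * depth
        spikes = _draw_counts(np.full(2, spike_mu / 2), model, rng)
        comm = _draw_counts(mu, model, rng)
        counts_rows.append(np.concatenate([comm, spikes]))
        sid = f"{soil}_pH{ph:.1f}_{treatment}_N{nitrate}_{timepoint}_r{rep}"
        index.append(sid)
        meta_rows.append({"soil_id": soil, "native_pH": native, "perturbed_pH": ph,
                          "treatment": treatment, "nitrate": nitrate,
                          "timepoint": timepoint, "replicate": rep})

    for soil in config.soil_ids:
        native = soil_native[soil]
        soil_mod = np.exp(rng.normal(0.0, 0.5, config.n_asv))
        # windowed presence of Bacillota grower families
        present = np.ones(config.n_asv)
        for i in bacillota:
            c = fam_center[taxonomy.iloc[i]["family"]]
            if abs(native - c) > _GROWER_FAMILY_WINDOW:
                present[i] = 0.0
        biomass0 = base_w * soil_mod * present
        # spike DNA fixed per soil so that the baseline (T0) spike share of
        # reads hits the configured target
        spike_b = biomass0.sum() * config.spike_fraction / (1 - config.spike_fraction)

        # NNresponders: chloramphenicol-sensitive growth that does not need
        # nitrate, so they inflate the untreated arm of *both* contrasts
        nn_growth = np.ones(config.n_asv)
        nn_growth[np.isin(asvs, list(nn))] = config.nn_fold

        soil_regimes = regimes[regimes["soil_id"] == soil]
        unpert = soil_regimes.iloc[
            (soil_regimes["perturbed_pH"] - native).abs().argsort().iloc[0]]

        def group_depth():
            # library depth varies strongly between condition/arm groups
            # (different runs) but only mildly within a replicate trio
            return np.exp(rng.normal(-0.28, 0.75))

        def jits(dj_group):
            return (dj_group * np.exp(rng.normal(-0.005, 0.1)),
                    np.exp(rng.normal(-0.005, 0.1)))

        dj_t0 = group_depth()
        for rep in range(config.n_replicates):
            dj, sj = jits(dj_t0)
            add_sample(biomass0, spike_b, soil, native,
                       float(unpert["perturbed_pH"]), "none", "+", "T0",
                       rep, dj, sj)

        for _, cond in soil_regimes.iterrows():
            ph, regime = float(cond["perturbed_pH"]), cond["regime"]
            surv = np.ones(config.n_asv)
            if ph < 4.0:
                drop = np.exp(-1.5 * (4.0 - ph))
                drop_bac = np.exp(-0.3 * (4.0 - ph))
                surv = np.where(phyla == "Bacillota", drop_bac, drop)
            b_plus = biomass0 * surv
            growth = np.ones(config.n_asv)
            if regime == "III":
                growth[np.isin(asvs, list(growers_iii))] = config.grower_fold_iii
            elif regime == "II":
                growth[np.isin(asvs, list(growers_ii))] = config.grower_fold_ii
                growth[np.isin(asvs, list(extra_ii))] = config.extra_fold
            # NNresponders grow wherever growth is possible at all (not in the
            # acid-death regime), with or without nitrate
            b_minus = b_plus * growth * (nn_growth if regime != "I" else 1.0)
            dj_minus, dj_plus = group_depth(), group_depth()
            for rep in range(config.n_replicates):
                dj, sj = jits(dj_minus)
                add_sample(b_minus, spike_b, soil, native, ph, "chl-", "+",
                           "end", rep, dj, sj)
                dj, sj = jits(dj_plus)
                add_sample(b_plus, spike_b, soil, native, ph, "chl+", "+",
                           "end", rep, dj, sj)

        # no-nitrate controls at the unperturbed level
        dj_nn_minus, dj_nn_plus = group_depth(), group_depth()
        for rep in range(config.n_replicates):
            dj, sj = jits(dj_nn_minus)
            add_sample(biomass0 * nn_growth, spike_b, soil, native,
                       float(unpert["perturbed_pH"]), "chl-", "-", "end",
                       rep, dj, sj)
            dj, sj = jits(dj_nn_plus)
            add_sample(biomass0, spike_b, soil, native,
                       float(unpert["perturbed_pH"]), "chl+", "-", "end",
                       rep, dj, sj)

    counts = pd.DataFrame(np.asarray(counts_rows, dtype=int), index=index,
                          columns=list(asvs) + list(SPIKE_IDS))
    spike_tax = pd.DataFrame(
        {"phylum": ["Pseudomonadota", "Bacteroidota"],
         "family": ["Enterobacteriaceae", "Tannerellaceae"],
         "genus": ["Escherichia-Shigella", "Parabacteroides"]},
        index=list(SPIKE_IDS))
    meta = pd.DataFrame(meta_rows, index=index)
    table = CountTable(counts=counts, taxonomy=pd.concat([taxonomy, spike_tax]),
                       meta=meta, spike_ids=SPIKE_IDS)
    truth = CountTruth(growers={"III": growers_iii, "II": growers_ii},
                       nn_responders=nn, asv_phylum=taxonomy["phylum"])
    return table, truth


def synth_presence_panel(n_soils: int = 10, n_samples_per_soil: int = 5,
                         n_noise_taxa: int = 10, flip_prob: float = 0.02,
                         seed: int = 0):
    """Presence/absence panel with a native-pH-encoding family ladder.

    Informative families switch on at successive native-pH cutoffs (the
    structure the resurgent-growth taxa exhibit across soils); noise families
    are independent Bernoulli(0.3).  Returns a
    :class:`~soilregimes.ph_regression.PresenceMatrix`.
    """
    from .ph_regression import PresenceMatrix

    rng = np.random.default_rng(seed)
    native = np.linspace(4.7, 8.3, n_soils)
    cutoffs = np.linspace(5.0, 8.0, 6)
    rows, ph, soils, idx = [], [], [], []
    for i, p in enumerate(native):
        for r in range(n_samples_per_soil):
            info = [(1 if p > c else 0) ^ (rng.random() < flip_prob) for c in cutoffs]
            noise = (rng.random(n_noise_taxa) < 0.3).astype(int)
            rows.append(np.concatenate([info, noise]))
            ph.append(p)
            soils.append(f"soil{i + 1:02d}")
            idx.append(f"soil{i + 1:02d}_r{r}")
    cols = [f"family_cut{c:.1f}" for c in cutoffs] + \
           [f"noise_fam{j}" for j in range(n_noise_taxa)]
    X = pd.DataFrame(np.asarray(rows, int), index=idx, columns=cols)
    return PresenceMatrix(X=X, native_ph=pd.Series(ph, index=idx),
                          soil_id=pd.Series(soils, index=idx))


def synth_amendment_series(base_params: CRMParams, doses, ratio: float = 2.0,
                           times=None, noise_sd: float = 0.0, seed: int = 0):
    """Amendment-dose series: each dose of added carbon raises C~(0) by
    added_C * ratio (ratio = r_A/r_C).  Returns [(added_C, TimeSeriesPair)]."""
    t = np.asarray(PAPER_TIME_GRID_DAYS if times is None else times, float)
    rng = np.random.default_rng(seed)
    out = []
    for added in doses:
        p = replace(base_params, C0_tilde=base_params.C0_tilde + added * ratio)
        out.append((float(added), synth_nitrate_pair(
            p, t, noise_sd, seed=int(rng.integers(2**31 - 1)),
            soil_id="amendment", perturbed_ph=float("nan"))))
    return out
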