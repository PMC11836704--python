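"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes — an ultrametric time tree, a
species trait table with a power-law mass-SMR relationship and
lambda-structured phylogenetic residual covariance, raw pO2 traces that
invert the respirometry chain exactly, binomial germination time courses
from log-logistic truths, and group-structured climate covariates — so the
whole chain can be exercised offline and parameter recovery measured against
known truth.

Every stochastic operation is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import io as sio
from ._gls import lambda_vcv
from .phylo_signal import vcv_from_tree
from .respirometry import PO2Trace, saturation_vapour_pressure
from .trees import Phylogeny

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_allometric_traits",
    "simulate_traces",
    "simulate_germination_and_climate",
    "simulate_bundle",
    "write_bundle",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the generator.

    Defaults emulate the scale of the study system: 108 angiosperm species on
    a 160.5-Myr tree, seed masses spanning about four orders of magnitude
    around a few mg, SMR following a = 0.057, b = 0.75 power law with
    residual SD 0.5 log10 units and phylogenetic residual structure
    lambda = 0.6, measurement temperatures 18-30 deg C standardized with
    Q10 = 2.5, ten replicate chambers per species sampled every 30 min, and a
    three-class ordered climate gradient over the native species.
    """

    n_species: int = 108
    # birth-death tree, rescaled to tree_height
    birth_rate: float = 0.1
    death_rate: float = 0.05
    tree_height: float = 160.5  # Myr
    # allometry: log10 SMR20 = log10(true_a) + true_b * log10 mass + eps
    mean_log10_mass: float = 0.9  # mg; ~8 mg median seed
    sd_log10_mass: float = 0.9  # tip SD of the Brownian mass process
    true_a: float = 0.057  # ul O2 seed^-1 h^-1 at 1 mg
    true_b: float = 0.75
    sigma_resid: float = 0.5  # log10 units
    true_lambda: float = 0.6
    # temperature standardization
    q10: float = 2.5
    t_min: float = 18.0
    t_max: float = 30.0
    # respirometry traces
    po2_initial: float = 20.0  # kPa
    pressure_kpa: float = 101.325
    chamber_volume_ul: float = 1500.0
    max_seeds_per_chamber: int = 150
    target_slope_kpa_h: float = 0.12  # sets seeds per chamber
    n_replicates: int = 10
    sampling_interval_h: float = 0.5
    trace_duration_h: float = 24.0
    trace_noise_sd: float = 0.05  # kPa
    p_contaminated: float = 0.2
    contamination_factor: float = 5.0
    contamination_exact: bool = False  # True: round(p * n_reps) per species
    # germination truth (drc-style log-logistic, b < 0 increasing)
    n_seeds_germination: int = 50
    germ_b_range: tuple[float, float] = (-5.0, -2.0)
    germ_d_range: tuple[float, float] = (40.0, 100.0)
    germ_e_range_wild: tuple[float, float] = (4.0, 14.0)
    germ_e_range_crop: tuple[float, float] = (2.0, 5.0)
    germ_score_interval_days: float = 3.5
    germ_max_days: float = 56.0
    # status structure (counts mirroring the study composition)
    n_crop: int = 14
    n_weed: int = 7
    crop_effect: float = 0.5  # log10 shift of SMR for domesticated species
    # ordered climate gradient over native species
    climate_levels: tuple[str, ...] = ("Csa", "BSh", "BWh")
    climate_probs: tuple[float, ...] = (0.55, 0.08, 0.37)
    climate_shifts: tuple[float, ...] = (0.0, 0.25, 0.5)  # log10 units
    # bioclim panel: block-correlated, one causal temperature variable
    bioclim_block_rho: float = 0.7
    causal_bioclim: dict = field(
        default_factory=lambda: {"annual_mean_temp": 0.2}  # per SD, log10 units
    )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)


# bioclim marginal scales (mean, sd) used to place covariates on natural units
_BIOCLIM_SCALE = {
    "annual_mean_temp": (20.0, 4.0),
    "mean_diurnal_range": (13.0, 2.0),
    "isothermality": (50.0, 6.0),
    "temp_seasonality": (500.0, 120.0),
    "annual_temp_range": (28.0, 4.0),
    "mean_temp_wettest_quarter": (18.0, 6.0),
    "mean_temp_driest_quarter": (24.0, 5.0),
    "mean_temp_warmest_quarter": (28.0, 4.0),
    "mean_temp_coldest_quarter": (13.0, 3.0),
    "annual_precip": (450.0, 180.0),
    "precip_seasonality": (60.0, 25.0),
    "precip_wettest_quarter": (220.0, 90.0),
    "precip_driest_quarter": (20.0, 12.0),
    "precip_warmest_quarter": (90.0, 60.0),
    "precip_coldest_quarter": (160.0, 80.0),
}
_TEMP_BLOCK = [v for v in sio.BIOCLIM_VARS if "temp" in v or v == "isothermality"]
_PRECIP_BLOCK = [v for v in sio.BIOCLIM_VARS if v not in _TEMP_BLOCK]


def simulate_tree(config: SimulationConfig, seed: int) -> Phylogeny:
    """Ultrametric birth-death tree with exactly n_species tips.

    The simulator conditions on the tip count by resampling on total
    extinction (seed incremented, recorded on the returned object as
    ``n_resamples``).  Terminal edges are extended by a common exponential
    waiting time so that the final divergence is strictly older than the
    present, then all depths are rescaled to ``tree_height``.
    """
    if config.n_species < 3:
        raise ValueError("need at least 3 species")
    attempt = 0
    while True:
        rng = random.Random(seed + attempt)
        try:
            tree = treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_species,
                rng=rng,
            )
            break
        except Exception:
            attempt += 1
            if attempt > 50:
                raise
    # avoid zero-length cherries at the stopping event: push the present
    # forward by an Exp(n * (b + d)) waiting time shared by all tips
    rate = config.n_species * (config.birth_rate + config.death_rate)
    delta = rng.expovariate(rate) + 1e-6
    leaves = tree.leaf_nodes()
    for i, leaf in enumerate(leaves):
        leaf.edge.length = (leaf.edge.length or 0.0) + delta
        leaf.taxon.label = f"sp{i + 1:03d}"
    phy = Phylogeny(tree)
    scale = config.tree_height / phy.height()
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= scale
    phy = Phylogeny(tree)
    phy.n_resamples = attempt
    return phy


def _mvn_on_tree(
    C: np.ndarray, lam: float, tip_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one MVN vector with covariance tip_sd^2 * lambda_vcv(C)/height."""
    if tip_sd == 0:
        return np.zeros(C.shape[0])
    height = float(np.max(np.diag(C)))
    V = lambda_vcv(C, lam) * (tip_sd**2 / height)
    L = np.linalg.cholesky(V)
    return L @ rng.standard_normal(C.shape[0])


def simulate_allometric_traits(
    tree: Phylogeny, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Species trait table with the generative allometry.

    log10 mass evolves by Brownian motion on the tree; log10 SMR20 is
    log10(true_a) + true_b * log10 mass plus a multivariate-normal residual
    with covariance sigma_resid^2 * lambda_transform(C, true_lambda).
    Measurement temperatures are drawn uniformly on [t_min, t_max] and the
    at-temperature rate smr_t back-transformed through the inverse Q10 rule,
    so the pipeline must re-standardize to recover the truth.
    """
    rng = np.random.default_rng(seed)
    cov = vcv_from_tree(tree)
    C = cov.matrix
    log_mass = config.mean_log10_mass + _mvn_on_tree(C, 1.0, config.sd_log10_mass, rng)
    resid = _mvn_on_tree(C, config.true_lambda, config.sigma_resid, rng)
    log_smr20 = np.log10(config.true_a) + config.true_b * log_mass + resid
    t_measure = np.round(rng.uniform(config.t_min, config.t_max, len(cov.taxa)), 1)
    smr20 = 10.0**log_smr20
    smr_t = smr20 * config.q10 ** ((t_measure - 20.0) / 10.0)
    df = pd.DataFrame(
        {
            "species": cov.taxa,
            "dry_mass_mg": 10.0**log_mass,
            "smr_t": smr_t,
            "t_measure_c": t_measure,
            "smr20_true": smr20,
            "resid_true": resid,
        }
    )
    return df


def simulate_traces(
    trait_row: pd.Series, config: SimulationConfig, seed: int
) -> list[PO2Trace]:
    """Replicate pO2 traces for one species, inverting the slope formula.

    The clean slope is the exact inverse of the pipeline's slope-to-VO2
    conversion (dry-pressure mole fraction, STP volume), so a noiseless
    trace recovers the generating rate to machine precision.  Gaussian noise
    of SD ``trace_noise_sd`` is added per reading, and a replicate is
    contaminated (slope multiplied by ``contamination_factor``, emulating
    microbial respiration) with probability ``p_contaminated`` — or for
    exactly round(p * n_reps) replicates when ``contamination_exact``.
    """
    rng = np.random.default_rng(seed)
    t_c = float(trait_row["t_measure_c"])
    vo2 = float(trait_row["smr_t"])
    p_dry = config.pressure_kpa - saturation_vapour_pressure(t_c)
    stp = 273.15 / (273.15 + t_c)
    # choose seed count (and, for very large seeds, chamber volume) so the
    # clean decline sits near the target slope and never hits the hypoxia
    # cutoff prematurely — mirroring the use of bigger chambers and fewer
    # seeds for bigger species
    volume_ul = config.chamber_volume_ul
    per_seed_slope = vo2 * p_dry / (volume_ul * stp)
    n_seeds = int(
        np.clip(
            round(config.target_slope_kpa_h / max(per_seed_slope, 1e-12)),
            1,
            config.max_seeds_per_chamber,
        )
    )
    if per_seed_slope > 2.0 * config.target_slope_kpa_h:
        n_seeds = 1
        volume_ul = vo2 * p_dry / (stp * config.target_slope_kpa_h)
        per_seed_slope = config.target_slope_kpa_h
    slope_clean = -per_seed_slope * n_seeds
    times = np.arange(0.0, config.trace_duration_h + 1e-9, config.sampling_interval_h)
    n_rep = config.n_replicates
    if config.contamination_exact:
        n_contam = int(round(config.p_contaminated * n_rep))
        contaminated = np.zeros(n_rep, dtype=bool)
        contaminated[rng.choice(n_rep, size=n_contam, replace=False)] = True
    else:
        contaminated = rng.random(n_rep) < config.p_contaminated
    traces = []
    for r in range(n_rep):
        slope = slope_clean * (config.contamination_factor if contaminated[r] else 1.0)
        po2 = config.po2_initial + slope * times
        if config.trace_noise_sd > 0:
            po2 = po2 + rng.normal(0.0, config.trace_noise_sd, len(times))
        po2 = np.maximum(po2, 1e-3)  # physical floor; hypoxia rule truncates first
        trace = PO2Trace(
            chamber_id=f"{trait_row['species']}_r{r + 1}",
            species=str(trait_row["species"]),
            times=times.copy(),
            po2=po2,
            volume_ul=volume_ul,
            n_seeds=n_seeds,
            t_measure=t_c,
            pressure_kpa=config.pressure_kpa,
        )
        trace.contaminated_truth = bool(contaminated[r])  # ground-truth flag
        traces.append(trace)
    return traces


def simulate_germination_and_climate(
    traits: pd.DataFrame, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Add status, germination, climate class and bioclim columns.

    Status: the first n_crop species (by tree order) are crops, the next
    n_weed weeds, the rest native — status is independent of the tree-shaped
    traits, as domestication history is not modelled phylogenetically.
    Germination counts are binomial draws from a per-species log-logistic
    truth (crops germinate faster); climate classes over native species
    carry ordered mean shifts added to the SMR residual truth; the bioclim
    panel is block-correlated (temperature block and precipitation block,
    rho within blocks) with the configured causal variables linked to the
    residual truth.  Returns a new trait table; smr columns are updated so
    the added effects flow through the measured rates.
    """
    rng = np.random.default_rng(seed)
    df = traits.copy().reset_index(drop=True)
    n = len(df)
    status = np.array(["native"] * n, dtype=object)
    status[: config.n_crop] = "crop"
    status[config.n_crop : config.n_crop + config.n_weed] = "weed"
    # shuffle so status is not confounded with tree order
    status = rng.permutation(status)
    df["status"] = status

    # germination truth and binomial scoring
    times = np.arange(
        config.germ_score_interval_days,
        config.germ_max_days + 1e-9,
        config.germ_score_interval_days,
    )
    b_lo, b_hi = config.germ_b_range
    d_lo, d_hi = config.germ_d_range
    germ_rows = []
    gmax_list, t50_list = [], []
    for i, row in df.iterrows():
        b = rng.uniform(b_lo, b_hi)
        d = rng.uniform(d_lo, d_hi)
        e_lo, e_hi = (
            config.germ_e_range_crop
            if row["status"] == "crop"
            else config.germ_e_range_wild
        )
        e = rng.uniform(e_lo, e_hi)
        n_seeds = config.n_seeds_germination
        # each seed: germinates with prob d/100, at a log-logistic time
        u = rng.random(n_seeds)
        germinates = u < d / 100.0
        v = rng.random(n_seeds)
        with np.errstate(divide="ignore"):
            t_germ = e * ((1.0 - v) / v) ** (1.0 / b)
        t_germ[~germinates] = np.inf
        cum = (t_germ[:, None] <= times[None, :]).sum(axis=0)
        cum_pct = 100.0 * cum / n_seeds
        for t_obs, c_pct in zip(times, cum_pct):
            germ_rows.append(
                {"species": row["species"], "time_days": t_obs, "cum_germ_pct": c_pct}
            )
        gmax_list.append(cum_pct[-1])
        t50_list.append(e)
    df["gmax_pct"] = gmax_list
    df["t50_true_days"] = t50_list

    # ordered climate gradient for native species
    climate = np.array([None] * n, dtype=object)
    shift = np.zeros(n)
    native_idx = np.flatnonzero(df["status"] == "native")
    levels = list(config.climate_levels)
    probs = np.asarray(config.climate_probs, dtype=float)
    probs = probs / probs.sum()
    assigned = rng.choice(len(levels), size=len(native_idx), p=probs)
    for j, idx in enumerate(native_idx):
        climate[idx] = levels[assigned[j]]
        shift[idx] += config.climate_shifts[assigned[j]]
    df["climate_class"] = climate

    # block-correlated bioclim panel
    z_temp_common = rng.standard_normal(n)
    z_prec_common = rng.standard_normal(n)
    rho = config.bioclim_block_rho
    z_scores = {}
    for var in sio.BIOCLIM_VARS:
        common = z_temp_common if var in _TEMP_BLOCK else z_prec_common
        z = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(n)
        z_scores[var] = z
        mean, sd = _BIOCLIM_SCALE[var]
        df[var] = np.round(mean + sd * z, 2)
    for var, beta in config.causal_bioclim.items():
        shift += beta * z_scores[var]

    shift[df["status"] == "crop"] += config.crop_effect

    # fold the added effects into the measured rates and the residual truth
    df["resid_true"] = df["resid_true"] + shift
    df["smr20_true"] = df["smr20_true"] * 10.0**shift
    df["smr_t"] = df["smr_t"] * 10.0**shift

    germination = pd.DataFrame(germ_rows)
    df.attrs["germination"] = germination
    return df


def simulate_bundle(
    config: SimulationConfig, seed: int
) -> dict:
    """Generate the full input bundle: tree, traits, traces, germination.

    Seeds for the stages are derived deterministically from ``seed``.
    Returns a dict with keys tree, traits, traces, germination, truth.
    """
    ss = np.random.SeedSequence(seed)
    s_tree, s_traits, s_extra, s_traces = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    tree = simulate_tree(config, s_tree)
    traits = simulate_allometric_traits(tree, config, s_traits)
    traits = simulate_germination_and_climate(traits, config, s_extra)
    germination = traits.attrs["germination"]
    traces = []
    trace_ss = np.random.SeedSequence(s_traces).spawn(len(traits))
    for (_, row), sub in zip(traits.iterrows(), trace_ss):
        traces.extend(
            simulate_traces(row, config, int(sub.generate_state(1)[0] % (2**31)))
        )
    truth = {
        "true_a": config.true_a,
        "true_b": config.true_b,
        "true_lambda": config.true_lambda,
        "sigma_resid": config.sigma_resid,
        "q10": config.q10,
        "n_species": config.n_species,
        "seed": seed,
    }
    return {
        "tree": tree,
        "traits": traits,
        "traces": traces,
        "germination": germination,
        "truth": truth,
    }


def write_bundle(bundle: dict, outdir) -> dict[str, Path]:
    """Write a simulated bundle to tree.nwk, traits.csv, traces.csv,
    germination.csv and truth.json under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "traits": outdir / "traits.csv",
        "traces": outdir / "traces.csv",
        "germination": outdir / "germination.csv",
        "truth": outdir / "truth.json",
    }
    bundle["tree"].write_newick(paths["tree"])
    bundle["traits"].to_csv(paths["traits"], index=False)
    sio.write_traces(bundle["traces"], paths["traces"])
    bundle["germination"].to_csv(paths["germination"], index=False)
    paths["truth"].write_text(json.dumps(bundle["truth"], indent=2))
    return paths
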