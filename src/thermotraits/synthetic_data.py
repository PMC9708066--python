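"""Synthetic inputs with known ground truth.

Every input the analysis pipeline consumes can be generated here with its
generating parameters recorded, so that each stage of the pipeline can be
checked by recovery: raw growth/respiration/ATP assay records built by
inverting the trait-derivation chain; temperature-rate observation sets
drawn around a true Sharpe-Schoolfield curve with multiplicative lognormal
noise; pure-birth (Yule) ultrametric trees; trait vectors evolved under
lambda-scaled Brownian motion; and a full community "species sorting"
scenario in which each isolate's thermal optimum tracks the temperature
its community was sorted at, with an upward offset at cold temperatures,
phylum labels correlated with Topt, and an r/K life-history contrast
between the phyla.

All generators are deterministic functions of their integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from thermotraits import assay_traits
from thermotraits.assay_traits import AssayRecord
from thermotraits.tpc_fitting import (
    KELVIN_OFFSET,
    SSParameters,
    TPCObservation,
    ss_evaluate,
)

__all__ = [
    "SyntheticTPCTruth",
    "ScenarioConfig",
    "generate_yule_tree",
    "simulate_lambda_bm",
    "generate_tpc_observations",
    "generate_assay_batch",
    "generate_community_scenario",
]


@dataclass(frozen=True)
class SyntheticTPCTruth:
    """Ground truth for one simulated thermal performance curve."""

    isolate_id: str
    params: SSParameters
    assay_temps: tuple[float, ...] = (4.0, 10.0, 15.0, 21.0, 30.0, 40.0, 50.0)
    noise_cv: float = 0.05
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        temps = np.asarray(self.assay_temps)
        if len(temps) == 0 or np.any(np.diff(temps) <= 0):
            raise ValueError("assay_temps must be strictly increasing")


def default_phylum_rule(topt: float) -> str:
    """Label isolates by thermal optimum: warm-adapted strains Firmicutes,
    the rest Proteobacteria (the dominant empirical pattern)."""
    return "Firmicutes" if topt >= 35.0 else "Proteobacteria"


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of the community sorting scenario.

    Defaults mirror the study design: six sorting temperatures between
    4 and 50 degC, six isolates per temperature, and an upward Topt offset
    at the cold end that decays to zero by 21 degC.
    """

    sorting_temps: tuple[float, ...] = (4.0, 10.0, 21.0, 30.0, 40.0, 50.0)
    isolates_per_temp: int = 6
    cold_offset: float = 8.0
    phylum_rule: "callable" = default_phylum_rule
    tree_birth_rate: float = 1.0
    include_standard_isolates: bool = True
    rk_contrast: bool = True
    topt_jitter_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isolates_per_temp < 1:
            raise ValueError("isolates_per_temp must be at least 1")
        if len(self.sorting_temps) == 0:
            raise ValueError("sorting_temps must be non-empty")


# ---------------------------------------------------------------------------
# trees and trait evolution


def generate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Simulate a pure-birth ultrametric tree and rescale its depth to 1.

    Pure-birth (Yule) trees carry no extinction; every tip is extant, so
    the tree is ultrametric by construction.  Depth is rescaled to one
    time unit, which makes Brownian-motion rates directly comparable
    across replicate trees.  Tips are labelled ``t1..tN``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    # grow the tree: start from a root with two lineages; at each event a
    # uniformly chosen extant lineage splits after an Exp(n*birth_rate) wait
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    left, right = dendropy.Node(), dendropy.Node()
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    active = [left, right]
    elapsed = 0.0
    birth_times = {left: 0.0, right: 0.0}
    while len(active) < n_tips:
        elapsed += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(rng.integers(len(active)))
        parent.edge.length = elapsed - birth_times[parent]
        a, b = dendropy.Node(), dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        birth_times[a] = birth_times[b] = elapsed
        active.extend([a, b])
    elapsed += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length = elapsed - birth_times[node]
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_namespace.new_taxon(label=f"t{i}")
    # unit depth
    scale = 1.0 / elapsed
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def simulate_lambda_bm(
    tree: dendropy.Tree,
    sigma2: float,
    root_state: float,
    lam: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Draw tip trait values under lambda-scaled Brownian motion.

    The tips are one multivariate-normal sample with mean ``root_state``
    and covariance ``sigma2`` times the phylogenetic covariance matrix
    whose off-diagonal entries are multiplied by ``lam``; ``lam = 1`` is
    plain Brownian motion, ``lam = 0`` removes all shared history.
    """
    from thermotraits.phylo_signal import phylo_covariance

    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    cov_df = phylo_covariance(tree)
    cov = cov_df.to_numpy() * lam
    np.fill_diagonal(cov, np.diag(cov_df.to_numpy()))
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        values = np.full(len(cov), float(root_state))
    else:
        chol = np.linalg.cholesky(sigma2 * cov)
        values = root_state + chol @ rng.standard_normal(len(cov))
    return pd.Series(values, index=cov_df.index, name="trait")


# ---------------------------------------------------------------------------
# assay-level generators


def generate_tpc_observations(truth: SyntheticTPCTruth) -> list[TPCObservation]:
    """Observed temperature-rate points around a true curve.

    Each observation is the true rate B(T) times a mean-one multiplicative
    lognormal factor with coefficient of variation ``noise_cv`` (rates are
    positive and right-skewed, so noise is multiplicative).
    """
    rng = np.random.default_rng(truth.seed)
    sigma_log = math.sqrt(math.log(1.0 + truth.noise_cv**2))
    out: list[TPCObservation] = []
    for rep in range(1, truth.replicates + 1):
        for temp in truth.assay_temps:
            rate = ss_evaluate(truth.params, temp + KELVIN_OFFSET)
            if truth.noise_cv > 0:
                factor = rng.lognormal(mean=-0.5 * sigma_log**2, sigma=sigma_log)
                rate *= factor
            out.append(TPCObservation(temp=temp, rate=rate, replicate=str(rep)))
    return out


def generate_assay_batch(
    true_mu: float,
    true_R: float,
    true_ATP: float,
    C0_cells: float = 1e6,
    mean_diameter: float = 1.0,
    duration: float = 4.0,
    assay_temp: float = 20.0,
    isolate_id: str = "synthetic",
    count_noise: bool = False,
    seed: int = 0,
) -> AssayRecord:
    """Build a raw assay record whose derived traits equal the given truths.

    The record is the algebraic inverse of the derivation chain: final
    count follows exponential growth, cumulative respired carbon solves
    the respiration equation for ``true_R``, and the peak of a synthetic
    four-point luminescence series inverts the ATP calibration to
    ``true_ATP``.  With ``count_noise`` off (the default) the round trip
    is exact; on, Poisson noise perturbs both counts.
    """
    if not math.isfinite(true_mu):
        raise ValueError("true_mu must be finite")
    if C0_cells <= 0 or mean_diameter <= 0 or duration <= 0:
        raise ValueError("C0_cells, mean_diameter and duration must be positive")
    if true_R < 0 or true_ATP < 0:
        raise ValueError("true_R and true_ATP must be non-negative")

    final_cells = C0_cells * math.exp(true_mu * duration)
    if count_noise:
        rng = np.random.default_rng(seed)
        C0_cells = float(max(rng.poisson(C0_cells), 1))
        final_cells = float(max(rng.poisson(final_cells), 1))

    volume = assay_traits.sphere_volume(mean_diameter)
    C0 = assay_traits.culture_biomass(C0_cells, volume)
    if abs(true_mu * duration) < assay_traits.MU_T_EPSILON:
        rtot = true_R * C0 * duration
    else:
        rtot = true_R * C0 * math.expm1(true_mu * duration) / true_mu

    if true_ATP > 0:
        peak_rlu = 10.0 ** (
            (math.log10(true_ATP) - assay_traits.ATP_CAL_INTERCEPT)
            / assay_traits.ATP_CAL_SLOPE
        )
        # reaction develops then decays: peak at the 2-minute read
        rlu_series = [
            (0.0, 0.6 * peak_rlu),
            (2.0, peak_rlu),
            (4.0, 0.8 * peak_rlu),
            (6.0, 0.5 * peak_rlu),
        ]
    else:
        rlu_series = []

    return AssayRecord(
        isolate_id=isolate_id,
        assay_temp=assay_temp,
        t=duration,
        initial_count=C0_cells,
        final_count=final_cells,
        diameters=[mean_diameter],
        Rtot=rtot,
        rlu_series=rlu_series,
    )


# ---------------------------------------------------------------------------
# community scenario


def _cold_offset(temp: float, cold_offset: float, decay_to: float = 21.0,
                 coldest: float = 4.0) -> float:
    """Smooth additive Topt bias: full at the coldest sorting temperature,
    linearly decaying to zero at ``decay_to`` and above."""
    if temp >= decay_to:
        return 0.0
    frac = (decay_to - temp) / (decay_to - coldest)
    return cold_offset * min(frac, 1.0)


def generate_community_scenario(
    config: ScenarioConfig | None = None,
) -> tuple[pd.DataFrame, dendropy.Tree]:
    """Generate a full community trait table and matching phylogeny.

    Sorting-temperature isolates get Topt equal to their sorting
    temperature plus the cold offset (plus small jitter); standard-
    temperature isolates get mesophile Topt independent of incubation
    temperature.  Tips of a Yule tree are assigned to isolates in
    tree-traversal order after sorting isolates by Topt, so that similar
    optima cluster in clades and Topt carries strong phylogenetic signal.
    Phylum labels follow ``config.phylum_rule`` on Topt; when
    ``rk_contrast`` is on, Firmicutes receive r-strategist trait blocks
    (fast growth, high ATP, low carrying capacity) and the other phyla
    K-strategist blocks.
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)

    rows: list[dict] = []
    for temp in config.sorting_temps:
        for i in range(1, config.isolates_per_temp + 1):
            topt = (
                temp
                + _cold_offset(temp, config.cold_offset,
                               coldest=min(config.sorting_temps))
                + rng.normal(0.0, config.topt_jitter_sd)
            )
            rows.append({
                "isolate_id": f"{int(temp):02d}_S_{i:02d}",
                "incubation_temp": temp,
                "isolation_mode": "sorting",
                "topt": max(topt, 1.0),
            })
    if config.include_standard_isolates:
        for temp in config.sorting_temps:
            for i in range(1, config.isolates_per_temp + 1):
                # mesophiles recovered regardless of prior incubation
                topt = rng.normal(25.0, 4.0)
                rows.append({
                    "isolate_id": f"{int(temp):02d}_RT_{i:02d}",
                    "incubation_temp": temp,
                    "isolation_mode": "standard",
                    "topt": max(topt, 1.0),
                })
    table = pd.DataFrame(rows)
    table["phylum"] = [config.phylum_rule(t) for t in table["topt"]]

    # life-history trait blocks; r-strategists grow fast with high ATP but
    # low yield, K-strategists the opposite
    n = len(table)
    is_r = (table["phylum"] == "Firmicutes") & config.rk_contrast
    base_mu = np.where(is_r, 0.9, 0.45)
    base_k = np.where(is_r, 0.45, 0.9)  # carrying capacity OD600
    base_atp = np.where(is_r, math.log(40.0), math.log(8.0))
    table["mu_max"] = base_mu * np.exp(rng.normal(0.0, 0.15, n))
    table["r_max"] = 0.5 * table["mu_max"] * np.exp(rng.normal(0.0, 0.2, n))
    table["log_atp"] = base_atp + 0.6 * np.log(table["r_max"] / 0.25) + rng.normal(0.0, 0.25, n)
    table["carrying_capacity"] = base_k * np.exp(rng.normal(0.0, 0.1, n))
    table["niche_width"] = np.clip(
        np.where(is_r, 14.0, 9.0) + rng.normal(0.0, 1.5, n), 2.0, None
    )

    # tree whose clades group similar thermal optima
    tree = generate_yule_tree(n, birth_rate=config.tree_birth_rate,
                              seed=config.seed + 1)
    order = table["topt"].to_numpy().argsort()
    leaf_iter = list(tree.leaf_node_iter())
    for leaf, idx in zip(leaf_iter, order):
        leaf.taxon.label = table["isolate_id"].iloc[idx]
    table = table.set_index("isolate_id")
    return table, tree
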