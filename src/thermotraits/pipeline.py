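"""End-to-end pipeline: simulate -> derive traits -> fit TPCs ->
phylogenetic signal -> community statistics.

Each stage reads and writes plain files (CSV / newick / JSON) so stages
can also be run individually from the command line; `run_pipeline` chains
them in dependency order and records a manifest of what ran with which
parameters and seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from thermotraits import assay_traits, community_stats, io, phylo_signal
from thermotraits import synthetic_data as synth
from thermotraits import tpc_fitting

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Settings of a full pipeline run.

    Stages operate on files under ``output_dir``; the synthetic scenario
    block replaces wet-lab inputs.  Unknown keys in a config mapping are
    rejected.
    """

    output_dir: str = "thermotraits_run"
    seed: int = 0
    # synthetic scenario
    sorting_temps: tuple[float, ...] = (4.0, 10.0, 21.0, 30.0, 40.0, 50.0)
    isolates_per_temp: int = 6
    cold_offset: float = 8.0
    noise_cv: float = 0.05
    tpc_replicates: int = 4
    assay_temps: tuple[float, ...] = (4.0, 10.0, 15.0, 21.0, 30.0, 40.0, 50.0)
    # tpc fitting
    tref: float = tpc_fitting.KELVIN_OFFSET
    niche_floor: float = -10.0
    log_residuals: bool = False
    # phylo signal
    transform: str = "log"
    permutations: int = 999
    # community stats
    pca_variables: tuple[str, ...] = tuple(community_stats.DEFAULT_PCA_VARIABLES)
    correct_to: float | None = 20.0
    activation_energy: float = 0.61
    verbosity: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**mapping)
        if cfg.transform not in ("identity", "log"):
            raise ConfigError(f"transform must be identity or log, got {cfg.transform!r}")
        return cfg


@dataclass
class RunManifest:
    """What ran, with which parameters, producing which files."""

    config: dict
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: list[Path], started: float) -> None:
        self.stages.append({
            "stage": name,
            "outputs": {
                str(p.name): _checksum(p) for p in outputs if p.exists()
            },
            "wall_seconds": round(time.perf_counter() - started, 3),
        })

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({"config": self.config, "stages": self.stages},
                                   indent=2, default=str) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    scen = synth.ScenarioConfig(
        sorting_temps=cfg.sorting_temps,
        isolates_per_temp=cfg.isolates_per_temp,
        cold_offset=cfg.cold_offset,
        seed=cfg.seed,
    )
    table, tree = synth.generate_community_scenario(scen)
    io.write_trait_table(table, out / "true_traits.csv")
    (out / "tree.nwk").write_text(phylo_signal.write_newick(tree) + "\n")

    # per-isolate TPC observations around each isolate's true curve
    rng = np.random.default_rng(cfg.seed + 100)
    obs_by_isolate = {}
    truths = {}
    for i, (iso, row) in enumerate(table.iterrows()):
        params = tpc_fitting.SSParameters(
            b0=0.05 * row["mu_max"], e=0.65, ed=3.0,
            tpk=row["topt"] + tpc_fitting.KELVIN_OFFSET, tref=cfg.tref,
        )
        truth = synth.SyntheticTPCTruth(
            isolate_id=iso, params=params, assay_temps=cfg.assay_temps,
            noise_cv=cfg.noise_cv, replicates=cfg.tpc_replicates,
            seed=int(rng.integers(2**31)),
        )
        truths[iso] = truth
        obs_by_isolate[iso] = synth.generate_tpc_observations(truth)
    io.write_tpc_observations(obs_by_isolate, out / "tpc_observations.csv")

    # raw assay records inverting the derivation chain (one per isolate,
    # at the isolate's thermal optimum)
    records = []
    for iso, row in table.iterrows():
        records.append(synth.generate_assay_batch(
            true_mu=row["mu_max"], true_R=row["r_max"],
            true_ATP=float(np.exp(row["log_atp"])),
            assay_temp=row["topt"], isolate_id=iso,
        ))
    io.write_assay_records(records, out / "assay_records.csv")


def _stage_derive(cfg: PipelineConfig, out: Path) -> None:
    records = io.read_assay_records(out / "assay_records.csv")
    derived = [assay_traits.derive_traits(r) for r in records]
    io.write_derived_traits(derived, out / "derived_traits.csv")


def _stage_fit_tpc(cfg: PipelineConfig, out: Path) -> None:
    obs = io.read_tpc_observations(out / "tpc_observations.csv")
    fit_cfg = tpc_fitting.FitConfig(
        tref=cfg.tref, niche_floor=cfg.niche_floor,
        log_residuals=cfg.log_residuals,
    )
    rows, diagnostics = [], {}
    for iso, observations in obs.items():
        fit = tpc_fitting.fit_ss(observations, fit_cfg)
        rows.append({
            "isolate_id": iso, "topt": fit.topt, "peak_rate": fit.peak_rate,
            "niche_width": fit.niche_width if fit.niche_width is not None else "",
            "e": fit.params.e if fit.params else "",
            "ed": fit.params.ed if fit.params else "",
            "b0": fit.params.b0 if fit.params else "",
            "r_squared": fit.r_squared, "method": fit.method,
        })
        diagnostics[iso] = {
            "rss": fit.rss, "aic": fit.aic, "n_temps": fit.n_temps,
            "warnings": fit.warnings,
        }
    pd.DataFrame(rows).to_csv(out / "tpc_fits.csv", index=False)
    io.write_json(diagnostics, out / "tpc_diagnostics.json")


def _stage_phylo(cfg: PipelineConfig, out: Path) -> None:
    tree_path = out / "tree.nwk"
    if not tree_path.exists():
        raise ConfigError("phylo-signal stage needs a tree (tree.nwk)")
    tree = phylo_signal.parse_newick(tree_path.read_text())
    fits = pd.read_csv(out / "tpc_fits.csv", dtype={"isolate_id": str})
    trait = fits.set_index("isolate_id")["topt"]
    lam = phylo_signal.estimate_lambda(tree, trait, transform=cfg.transform)
    k = phylo_signal.blomberg_k(
        tree, trait, n_permutations=cfg.permutations, seed=cfg.seed,
        transform=cfg.transform,
    )
    asr = phylo_signal.ancestral_states_bm(tree, trait, transform=cfg.transform)
    io.write_json({
        "lambda": {"value": lam.value, "p_value": lam.p_value,
                   "log_likelihood": lam.log_likelihood, "n_tips": lam.n_tips},
        "K": {"value": k.value, "p_value": k.p_value,
              "n_permutations": k.n_permutations, "seed": k.seed},
        "sigma2_hat": asr.sigma2_hat,
        "root_state": asr.root_state,
    }, out / "phylo_signal.json")
    pd.DataFrame({
        "node": list(asr.node_states),
        "state": list(asr.node_states.values()),
        "variance": [asr.node_variances[n] for n in asr.node_states],
    }).to_csv(out / "ancestral_states.csv", index=False)


def _stage_community(cfg: PipelineConfig, out: Path) -> None:
    table = io.read_trait_table(out / "true_traits.csv")
    fits = pd.read_csv(out / "tpc_fits.csv", dtype={"isolate_id": str})
    fitted_topt = fits.set_index("isolate_id")["topt"]
    merged = table.copy()
    merged["topt"] = fitted_topt.reindex(merged.index)

    report: dict = {}
    sorting = merged[merged["isolation_mode"] == "sorting"]
    cmp = community_stats.quadratic_vs_linear(
        sorting["incubation_temp"], sorting["topt"]
    )
    report["sorting_regression"] = {
        "f_statistic": cmp.f_statistic, "p_value": cmp.p_value,
        "prefers_quadratic": cmp.prefers_quadratic,
        "r_squared_quadratic": cmp.r_squared_quadratic, "n": cmp.n,
    }
    standard = merged[merged["isolation_mode"] == "standard"]
    if len(standard) >= 4:
        lin = community_stats.quadratic_vs_linear(
            standard["incubation_temp"], standard["topt"]
        )
        report["standard_regression"] = {
            "slope": float(lin.coef_linear[1]),
            "r_squared_linear": lin.r_squared_linear, "n": lin.n,
        }

    pca = community_stats.pca_traits(merged, list(cfg.pca_variables))
    report["pca"] = {
        "explained_variance_fraction": pca.explained_variance_fraction,
        "pc1_pc2_fraction": float(pca.explained_variance_fraction[:2].sum()),
    }
    pca.scores.to_csv(out / "pca_scores.csv")

    scaling = {}
    for phylum, grp in merged.groupby("phylum"):
        if len(grp) >= 3:
            fit = community_stats.powerlaw_fit(
                grp["r_max"], np.exp(grp["log_atp"])
            )
            scaling[phylum] = {"exponent": fit.exponent, "se": fit.exponent_se,
                               "r_squared": fit.r_squared, "n": fit.n}
    report["atp_respiration_scaling"] = scaling

    contrasts = community_stats.phylum_summary(
        merged, correct_to=cfg.correct_to,
        activation_energy=cfg.activation_energy,
    )
    contrasts.to_csv(out / "phylum_contrasts.csv", index=False)
    report["n_rank_sum_tests"] = int(contrasts.attrs["n_tests"])
    io.write_json(report, out / "community_stats.json")


STAGES = {
    "simulate": _stage_simulate,
    "derive-traits": _stage_derive,
    "fit-tpc": _stage_fit_tpc,
    "phylo-signal": _stage_phylo,
    "community-stats": _stage_community,
}


def run_pipeline(
    config: PipelineConfig, stages: list[str] | None = None
) -> RunManifest:
    """Run the requested stages (default: all) in dependency order."""
    stages = stages or list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s): {', '.join(unknown)}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    before = set()
    for name in STAGES:  # canonical order
        if name not in stages:
            continue
        started = time.perf_counter()
        STAGES[name](config, out)
        produced = [p for p in sorted(out.iterdir()) if p.name not in before]
        manifest.add(name, produced, started)
        before |= {p.name for p in produced}
    manifest.write(out / "manifest.json")
    return manifest
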