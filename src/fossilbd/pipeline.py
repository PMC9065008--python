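"""End-to-end analysis pipeline.

Stage order mirrors the full fossil-diversification workflow:

1. read + filter occurrences
2. resample occurrence ages into replicates
3. split species into near-equal subsets
4. per-(subset, replicate) joint lifespan/preservation/rate MCMC
5. merge median Ts/Te across subsets (per replicate, and across replicates)
6. fixed-times rjMCMC rate estimation on the merged medians
7. rate summaries on a 0.1-Myr grid
8. per-family range-through trajectories and slope series
9. MBD runs per replicate: combined response and per-family pairwise
10. effect network from the pairwise summaries

Each stage writes its outputs plus a ``.done.json`` marker carrying the
config hash; re-running with an unchanged config skips completed stages,
and deleting a downstream stage's directory resumes from there.  Stage
seeds derive from one master seed by stable hashing of stage names, so a
single integer reproduces the whole run byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import occurrences as occ
from . import trajectories as trj
from .errors import ConfigError, FossilbdError
from .mbd import CovariateSet, MBDPosterior, mbd_mcmc, pool_posteriors
from .rates import MCMCConfig, rj_mcmc_rates, sample_lifespans, summarize_rates
from .series import CovariateSeries, read_covariate

__all__ = [
    "PipelineConfig",
    "EffectNetwork",
    "Edge",
    "run_full_pipeline",
    "build_effect_network",
    "stage_seed",
]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from one master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """Full-pipeline settings.

    The numeric defaults are the production settings of the analysis this
    package implements (fifty age replicates, eleven subsets, 20% burn-in,
    w > 0.7 significance); tests and examples override the chain lengths.
    """

    input_path: str = None
    dialect: str = "pbdb_csv"
    covariate_paths: dict = field(default_factory=dict)  # label -> csv path
    filters: dict = field(default_factory=lambda: {"drop_qualified": True,
                                                   "accepted_only": True})
    extant_names: list = field(default_factory=list)
    n_replicates: int = 50
    n_subsets: int = 11
    preservation_model: str = "TPP"
    w_threshold: float = 0.7
    mbd_link: str = "exponential"
    mbd_grid_step: float = 1.0
    seed: int = 1
    trajectory_step: float = 0.1
    mcmc_lifespans: dict = field(
        default_factory=lambda: {"n_generations": 50_000_000, "sample_every": 40_000}
    )
    mcmc_rates: dict = field(
        default_factory=lambda: {"n_generations": 100_000_000, "sample_every": 40_000}
    )
    mcmc_mbd: dict = field(
        default_factory=lambda: {"n_generations": 25_000_000, "sample_every": 25_000}
    )
    variants: dict = field(default_factory=dict)  # name -> extra filter rules
    run_pairwise: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    channel: str  # speciation | extinction
    median_effect: float
    sign: int
    median_w: float


@dataclass(frozen=True)
class EffectNetwork:
    nodes: tuple
    edges: tuple
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.edges])


def build_effect_network(pairwise_results: pd.DataFrame, threshold: float) -> EffectNetwork:
    """Keep directed effects whose median shrinkage weight exceeds ``threshold``.

    ``pairwise_results`` needs columns ``source``, ``target``, ``channel``,
    ``gamma_med``, ``w_med``.  Positive gamma on a channel is a promoting
    effect, negative a suppressing one; self-edges (loops) are allowed.
    """
    nodes = tuple(sorted(set(pairwise_results["source"]) | set(pairwise_results["target"])))
    edges = []
    for _, row in pairwise_results.iterrows():
        if row["channel"] not in ("speciation", "extinction"):
            continue
        if row["w_med"] > threshold:
            edges.append(
                Edge(
                    source=row["source"],
                    target=row["target"],
                    channel=row["channel"],
                    median_effect=float(row["gamma_med"]),
                    sign=int(np.sign(row["gamma_med"])),
                    median_w=float(row["w_med"]),
                )
            )
    return EffectNetwork(nodes=nodes, edges=tuple(edges), threshold=threshold)


class _StageRunner:
    def __init__(self, outdir: Path, config_hash: str):
        self.outdir = Path(outdir)
        self.config_hash = config_hash
        self.manifest = {"config_hash": config_hash, "stages": {}}

    def done_marker(self, stage: str) -> Path:
        return self.outdir / stage / ".done.json"

    def is_done(self, stage: str) -> bool:
        marker = self.done_marker(stage)
        if not marker.exists():
            return False
        try:
            info = json.loads(marker.read_text())
        except json.JSONDecodeError:
            return False
        return info.get("config_hash") == self.config_hash

    def mark_done(self, stage: str, seed: int, outputs: list):
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        hashes = {}
        for p in outputs:
            p = Path(p)
            hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
        info = {"config_hash": self.config_hash, "seed": seed, "outputs": hashes}
        self.done_marker(stage).write_text(json.dumps(info, indent=1, sort_keys=True))
        self.manifest["stages"][stage] = info

    def load_done(self, stage: str):
        info = json.loads(self.done_marker(stage).read_text())
        self.manifest["stages"][stage] = info


def _mcmc_cfg(overrides: dict, seed: int) -> MCMCConfig:
    kw = dict(overrides)
    kw["seed"] = seed
    return MCMCConfig(**kw)


def run_full_pipeline(config: PipelineConfig, outdir, occurrences: pd.DataFrame = None):
    """Execute the full analysis; returns the artifact directory path.

    ``occurrences`` may be passed directly (e.g. a freshly simulated
    table) instead of ``config.input_path``.  Any stage failure raises
    with the stage name; completed stages keep their artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    runner = _StageRunner(outdir, chash)

    try:
        table = _stage_filter(runner, config, occurrences)
        replicates = _stage_replicates(runner, config, table)
        partition = _stage_subsets(runner, config, table)
        merged_by_rep, merged_median = _stage_lifespans(runner, config, table,
                                                       replicates, partition)
        _stage_rates(runner, config, merged_median)
        _stage_trajectories(runner, config, merged_by_rep)
        pairwise = _stage_mbd(runner, config, merged_by_rep)
        _stage_network(runner, config, pairwise)
    except FossilbdError as err:
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(runner.manifest, indent=1, sort_keys=True))
        raise FossilbdError(f"pipeline halted: {err}") from err

    for name, extra_rules in config.variants.items():
        sub_cfg_filters = dict(config.filters)
        sub_cfg_filters.update(extra_rules)
        sub = PipelineConfig(**{**asdict(config), "filters": sub_cfg_filters,
                                "variants": {}})
        run_full_pipeline(sub, outdir / f"variant_{name}", occurrences=occurrences)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(runner.manifest, indent=1, sort_keys=True))
    return outdir


def _stage_filter(runner, config, occurrences):
    stage = "filter"
    d = runner.outdir / stage
    out = d / "occurrences.csv"
    if runner.is_done(stage):
        runner.load_done(stage)
        return occ.read_occurrences(out, "pbdb_csv")
    d.mkdir(parents=True, exist_ok=True)
    if occurrences is None:
        if config.input_path is None:
            raise ConfigError("no input: set input_path or pass a table")
        occurrences = occ.read_occurrences(config.input_path, config.dialect)
    table = occ.filter_occurrences(occurrences, config.filters)
    if config.extant_names:
        table = occ.mark_extant(table, config.extant_names)
    occ.write_occurrences(table, out, "pbdb_csv")
    runner.mark_done(stage, 0, [out])
    return table


def _stage_replicates(runner, config, table):
    stage = "replicates"
    d = runner.outdir / stage
    seed = stage_seed(config.seed, stage)
    out = d / "age_replicates.csv"
    if runner.is_done(stage):
        runner.load_done(stage)
        wide = pd.read_csv(out, index_col=0)
        return [
            occ.AgeReplicate(r + 1, wide.iloc[:, r])
            for r in range(wide.shape[1])
        ]
    d.mkdir(parents=True, exist_ok=True)
    replicates = occ.resample_ages(table, config.n_replicates, seed)
    wide = pd.concat([r.ages.rename(f"rep_{r.replicate_index}") for r in replicates], axis=1)
    wide.to_csv(out, index_label="occurrence_id")
    runner.mark_done(stage, seed, [out])
    return replicates


def _stage_subsets(runner, config, table):
    stage = "subsets"
    d = runner.outdir / stage
    seed = stage_seed(config.seed, stage)
    out = d / "partition.csv"
    n_species = table["species"].nunique()
    n_subsets = min(config.n_subsets, n_species)
    if runner.is_done(stage):
        runner.load_done(stage)
        df = pd.read_csv(out)
        return occ.SubsetPartition(
            n_subsets=int(df["subset"].max()) + 1,
            assignment=dict(zip(df["species"], df["subset"])),
        )
    d.mkdir(parents=True, exist_ok=True)
    partition = occ.split_subsets(table, n_subsets, seed)
    df = pd.DataFrame(sorted(partition.assignment.items()), columns=["species", "subset"])
    df.to_csv(out, index=False)
    runner.mark_done(stage, seed, [out])
    return partition


def _stage_lifespans(runner, config, table, replicates, partition):
    stage = "lifespans"
    d = runner.outdir / stage
    outs = [d / f"lifespans_rep_{r.replicate_index}.csv" for r in replicates]
    out_median = d / "lifespans_median.csv"
    if runner.is_done(stage):
        runner.load_done(stage)
        per_rep = [pd.read_csv(p) for p in outs]
        return per_rep, pd.read_csv(out_median)
    d.mkdir(parents=True, exist_ok=True)
    subset_of = table["species"].map(partition.assignment)
    per_rep = []
    for rep in replicates:
        parts = []
        for subset in range(partition.n_subsets):
            sub_table = table.loc[subset_of == subset]
            if sub_table.empty:
                continue
            seed = stage_seed(config.seed, f"{stage}:{subset}:{rep.replicate_index}")
            cfg = _mcmc_cfg(config.mcmc_lifespans, seed)
            post = sample_lifespans(sub_table, cfg, replicate=rep,
                                    model=config.preservation_model)
            parts.append(post.median_lifespans())
        merged = pd.concat(parts, ignore_index=True).sort_values("species").reset_index(drop=True)
        fam = table.groupby("species")["family"].first()
        merged["family"] = merged["species"].map(fam)
        merged.to_csv(outs[rep.replicate_index - 1], index=False)
        per_rep.append(merged)
    stacked = pd.concat(per_rep)
    med = stacked.groupby("species").agg(
        ts=("ts", "median"), te=("te", "median"),
        extant=("extant", "first"), family=("family", "first"),
    ).reset_index()
    med.loc[med["extant"], "te"] = 0.0
    med.to_csv(out_median, index=False)
    runner.mark_done(stage, stage_seed(config.seed, stage), outs + [out_median])
    return per_rep, med


def _stage_rates(runner, config, merged_median):
    stage = "rates"
    d = runner.outdir / stage
    out_log = d / "rate_posterior.tsv"
    out_sum = d / "rate_summary.csv"
    if runner.is_done(stage):
        runner.load_done(stage)
        return
    d.mkdir(parents=True, exist_ok=True)
    seed = stage_seed(config.seed, stage)
    cfg = _mcmc_cfg(config.mcmc_rates, seed)
    post = rj_mcmc_rates(merged_median, cfg)
    post.to_frame().to_csv(out_log, sep="\t", index=False)
    summarize_rates(post, step=config.trajectory_step).to_csv(out_sum, index=False)
    runner.mark_done(stage, seed, [out_log, out_sum])


def _stage_trajectories(runner, config, merged_by_rep):
    stage = "trajectories"
    d = runner.outdir / stage
    out_traj = d / "trajectories.csv"
    out_slope = d / "slopes.csv"
    if runner.is_done(stage):
        runner.load_done(stage)
        return
    d.mkdir(parents=True, exist_ok=True)
    traj_rows, slope_rows = [], []
    for i, merged in enumerate(merged_by_rep, start=1):
        for family, group in merged.groupby("family"):
            traj = trj.range_through(group, step=config.trajectory_step, replicate_index=i)
            df = traj.to_frame()
            df["family"] = family
            traj_rows.append(df)
            slopes, mean_slope = trj.diversity_slope(traj)
            slope_rows.append(pd.DataFrame({
                "age": slopes.ages, "slope": slopes.slopes,
                "family": family, "replicate": i,
            }))
    pd.concat(traj_rows, ignore_index=True).to_csv(out_traj, index=False)
    pd.concat(slope_rows, ignore_index=True).to_csv(out_slope, index=False)
    runner.mark_done(stage, 0, [out_traj, out_slope])


def _diversity_covariates(merged, families, step):
    series = []
    top = float(np.ceil(merged["ts"].max()))
    n_steps = max(int(round(top / step)), 1)
    grid = np.linspace(top, 0.0, n_steps + 1)
    for family in families:
        group = merged.loc[merged["family"] == family]
        traj = trj.range_through(group, step=step)
        counts = np.interp(grid[::-1], traj.ages[::-1], traj.counts[::-1])[::-1]
        series.append(CovariateSeries(grid, counts, label=f"diversity_{family}"))
    return series, grid


def _stage_mbd(runner, config, merged_by_rep):
    stage = "mbd"
    d = runner.outdir / stage
    out_combined = d / "mbd_combined_summary.csv"
    out_pairwise = d / "mbd_pairwise_summary.csv"
    if runner.is_done(stage):
        runner.load_done(stage)
        return pd.read_csv(out_pairwise)
    d.mkdir(parents=True, exist_ok=True)
    families = sorted(merged_by_rep[0]["family"].unique())
    env_series = {label: read_covariate(path, label=label)
                  for label, path in config.covariate_paths.items()}

    def run_mbd(response_family=None):
        posts = []
        for i, merged in enumerate(merged_by_rep, start=1):
            cov_families = families if response_family is None else [
                f for f in families if f != response_family
            ]
            div_series, grid = _diversity_covariates(merged, cov_families,
                                                     config.mbd_grid_step)
            all_series = div_series + list(env_series.values())
            covs = CovariateSet.build(all_series, grid=grid)
            response = merged if response_family is None else merged.loc[
                merged["family"] == response_family
            ]
            if response.empty:
                continue
            seed = stage_seed(config.seed, f"{stage}:{response_family}:{i}")
            cfg = _mcmc_cfg(config.mcmc_mbd, seed)
            posts.append(mbd_mcmc(response, covs, link=config.mbd_link, cfg=cfg))
        return pool_posteriors(posts)

    combined = run_mbd(None)
    combined_summary = combined.summarize()
    combined_summary.to_csv(out_combined, index=False)

    pair_rows = []
    if config.run_pairwise:
        for family in families:
            pooled = run_mbd(family)
            summary = pooled.summarize()
            for _, row in summary.iterrows():
                if not row["covariate"].startswith("diversity_"):
                    continue
                pair_rows.append({
                    "source": row["covariate"].removeprefix("diversity_"),
                    "target": family,
                    "channel": row["channel"],
                    "gamma_med": row["gamma_med"],
                    "w_med": row["w_med"],
                })
    for _, row in combined_summary.iterrows():
        if row["covariate"].startswith("diversity_"):
            pair_rows.append({
                "source": row["covariate"].removeprefix("diversity_"),
                "target": "ALL",
                "channel": row["channel"],
                "gamma_med": row["gamma_med"],
                "w_med": row["w_med"],
            })
    pairwise = pd.DataFrame(pair_rows)
    pairwise.to_csv(out_pairwise, index=False)
    runner.mark_done(stage, stage_seed(config.seed, stage), [out_combined, out_pairwise])
    return pairwise


def _stage_network(runner, config, pairwise):
    stage = "network"
    d = runner.outdir / stage
    out = d / "effect_network.csv"
    if runner.is_done(stage):
        runner.load_done(stage)
        return
    d.mkdir(parents=True, exist_ok=True)
    network = build_effect_network(pairwise, config.w_threshold)
    network.to_frame().to_csv(out, index=False)
    runner.mark_done(stage, 0, [out])
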