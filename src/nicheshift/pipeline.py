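"""End-to-end orchestration: ingest -> rarefy -> select variables -> niche analysis -> reciprocal SDM.

One YAML config drives everything; all randomness flows from a single root
seed through named substreams, and every run writes a manifest recording the
config hash, the seeds and the SHA-256 of each output file, so reruns are
verifiable.

Command line::

    nicheshift simulate --out data/ --seed 1 --shift 4.0
    nicheshift niche    --config data/config.yaml
    nicheshift sdm      --config data/config.yaml
    nicheshift report   --out results/
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import env_data, sdm_engine
from .niche_stats import GridParams, NicheComparison
from .sdm_eval import RangeData, reciprocal_report
from .synthetic_data import SyntheticConfig, make_scenario

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "prepare", "run_niche_analysis", "run_reciprocal_sdm", "cli"]


@dataclass
class RangePaths:
    occurrences: str
    layers: dict[str, str]
    mask: str | None = None


@dataclass
class NicheSettings:
    R: int = 100
    bandwidth_multiplier: float = 1.0
    kernel_cutoff: float | None = 4.0
    n_reps: int = 1000
    quantile_threshold: float = 0.05
    analogue_only: bool = False
    corrected: bool = True


@dataclass
class SdmSettings:
    background_n: int = 10_000
    class_combos: tuple[str, ...] = sdm_engine.DEFAULT_CLASS_COMBOS
    rms: tuple[float, ...] = sdm_engine.DEFAULT_RMS
    knots: int = 20
    cv: bool = True
    tol: float = 1e-5


@dataclass
class RunConfig:
    ranges: dict[str, RangePaths]
    out_dir: str = "results"
    seed: int = 0
    cutoff: float = 0.75
    priority: list[str] | None = None
    niche: NicheSettings = field(default_factory=NicheSettings)
    sdm: SdmSettings = field(default_factory=SdmSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        ranges = {k: RangePaths(**v) for k, v in raw["ranges"].items()}
        var = raw.get("variables", {})
        cfg = cls(
            ranges=ranges,
            out_dir=raw.get("out_dir", "results"),
            seed=int(raw.get("seed", 0)),
            cutoff=float(var.get("cutoff", 0.75)),
            priority=var.get("priority"),
            niche=NicheSettings(**raw.get("niche", {})),
            sdm=SdmSettings(**{
                **raw.get("sdm", {}),
                **(
                    {"class_combos": tuple(raw["sdm"]["class_combos"])}
                    if raw.get("sdm", {}).get("class_combos") else {}
                ),
                **({"rms": tuple(raw["sdm"]["rms"])} if raw.get("sdm", {}).get("rms") else {}),
            }),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if set(self.ranges) != {"native", "invasive"}:
            raise ValueError("config must define exactly the ranges 'native' and 'invasive'")
        for label, rp in self.ranges.items():
            for p in [rp.occurrences, *rp.layers.values()] + ([rp.mask] if rp.mask else []):
                if not Path(p).exists():
                    raise FileNotFoundError(f"range '{label}': missing input {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sdm"]["class_combos"] = list(d["sdm"]["class_combos"])
        d["sdm"]["rms"] = list(d["sdm"]["rms"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


@dataclass
class PreparedRange:
    label: str
    stack: env_data.EnvStack
    occ: env_data.OccurrenceSet
    background_sdm: env_data.OccurrenceSet
    background_niche_env: pd.DataFrame


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["background_native", "background_invasive", "permutation"]
    return {n: np.random.default_rng(s) for n, s in zip(names, np.random.SeedSequence(seed).spawn(3))}


def prepare(config: RunConfig) -> dict[str, PreparedRange]:
    """Ingest both ranges, rarefy, select variables, sample backgrounds."""
    t0 = time.perf_counter()
    streams = _substreams(config.seed)
    stacks, occs = {}, {}
    for label, rp in config.ranges.items():
        stacks[label] = env_data.read_stack(rp.layers, rp.mask)
        occ = env_data.read_occurrences(rp.occurrences, label)
        occ = env_data.rarefy(occ, stacks[label])
        occs[label] = occ

    pooled = pd.concat([stacks[lbl].env_table() for lbl in ("native", "invasive")],
                       ignore_index=True)
    selection = env_data.select_variables(pooled, config.cutoff, config.priority)
    logger.info("variable selection: kept %s, dropped %s", selection.kept, selection.dropped)

    prepared = {}
    for label in ("native", "invasive"):
        stack = stacks[label].select(selection.kept)
        occ = env_data.extract_env(occs[label], stack)
        n_bg = min(config.sdm.background_n, stack.n_masked)
        bg = env_data.sample_background(stack, n_bg, streams[f"background_{label}"])
        prepared[label] = PreparedRange(
            label=label,
            stack=stack,
            occ=occ,
            background_sdm=bg,
            background_niche_env=stack.env_table(),  # all accessible cells
        )
    prepared["native"].selection = selection  # type: ignore[attr-defined]
    logger.info("prepare stage finished in %.1f s", time.perf_counter() - t0)
    return prepared


def _manifest(out_dir: Path, config: RunConfig, files: list[Path]) -> None:
    entries = {
        str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest() for p in files
    }
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_niche_analysis(config: RunConfig, prepared: dict[str, PreparedRange] | None = None):
    """Environmental-space niche comparison; writes the overlap/test/dynamics table."""
    t0 = time.perf_counter()
    prepared = prepared or prepare(config)
    ns = config.niche
    model = NicheComparison(
        prepared["native"].occ.env,
        prepared["native"].background_niche_env,
        prepared["invasive"].occ.env,
        prepared["invasive"].background_niche_env,
        grid_params=GridParams(ns.R, ns.bandwidth_multiplier, ns.kernel_cutoff, ns.corrected),
        quantile_threshold=ns.quantile_threshold,
        analogue_only=ns.analogue_only,
    )
    # permutation substream seeded from the root seed, independent of background draws
    perm_seed = int(np.random.SeedSequence(config.seed).spawn(3)[2].generate_state(1)[0] % 2**31)
    results = model.fit(n_reps=ns.n_reps, seed=perm_seed)

    out = Path(config.out_dir) / "niche"
    out.mkdir(parents=True, exist_ok=True)
    results.to_table().to_csv(out / "niche_table.csv", index=False)
    results.to_json(out / "niche_results.json")
    results.plot(out / "niche_space.png")
    _manifest(out, config, [out / "niche_table.csv", out / "niche_results.json"])
    logger.info("niche stage finished in %.1f s", time.perf_counter() - t0)
    return results


def _write_suitability(path: Path, model, stack: env_data.EnvStack) -> None:
    rows, cols = np.nonzero(stack.mask)
    env = stack.values_at(rows, cols)
    suit = sdm_engine.predict(model, env, "cloglog")
    grid = np.full(stack.shape, np.nan)
    grid[rows, cols] = suit
    env_data.write_ascii_grid(path, grid, stack.xll, stack.yll, stack.cell_size)


def run_reciprocal_sdm(config: RunConfig, prepared: dict[str, PreparedRange] | None = None):
    """Per-range tuning grid, reciprocal fits, Table-2-shaped evaluation report."""
    t0 = time.perf_counter()
    prepared = prepared or prepare(config)
    ss = config.sdm
    out = Path(config.out_dir) / "sdm"
    out.mkdir(parents=True, exist_ok=True)

    tunings = {}
    for label in ("native", "invasive"):
        pr = prepared[label]
        tunings[label] = sdm_engine.tune(
            pr.occ.env,
            pr.background_sdm.env,
            pr.occ.coords,
            pr.background_sdm.coords,
            class_combos=ss.class_combos,
            rms=ss.rms,
            knots=ss.knots,
            cv=ss.cv,
            tol=ss.tol,
            range_label=label,
        )
        tunings[label].table.to_csv(out / f"tuning_{label}.csv", index=False)
        logger.info("tuning[%s]: %s", label, tunings[label].selected_row.to_dict())

    settings = {
        label: (t.selected_row["feature_classes"], float(t.selected_row["rm"]))
        for label, t in tunings.items()
    }
    report = reciprocal_report(
        RangeData("native", prepared["native"].occ.env, prepared["native"].background_sdm.env),
        RangeData("invasive", prepared["invasive"].occ.env, prepared["invasive"].background_sdm.env),
        classes={label: s[0] for label, s in settings.items()},
        rm={label: s[1] for label, s in settings.items()},
        knots=ss.knots,
        tol=ss.tol,
    )
    report.to_csv(out / "table2.csv", tss_policy="optimized")
    report.to_csv(out / "table2_transferred.csv", tss_policy="transferred")
    report.to_json(out / "report.json")

    for train_label in ("native", "invasive"):
        pr_train = prepared[train_label]
        model = sdm_engine.MaxentModel(
            pr_train.occ.env,
            pr_train.background_sdm.env,
            classes=settings[train_label][0],
            knots=ss.knots,
            rm=settings[train_label][1],
            range_label=train_label,
        ).fit(tol=ss.tol)
        for eval_label in ("native", "invasive"):
            _write_suitability(
                out / f"suitability_{train_label}_to_{eval_label}.asc",
                model,
                prepared[eval_label].stack,
            )

    files = sorted(out.glob("*.csv")) + [out / "report.json"]
    _manifest(out, config, files)
    logger.info("sdm stage finished in %.1f s", time.perf_counter() - t0)
    return tunings, report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _setup_logging(out_dir: str | None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if out_dir:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "nicheshift.log"))
    logging.basicConfig(
        level=logging.INFO, format="%(asctime)s %(name)s %(levelname)s: %(message)s",
        handlers=handlers, force=True,
    )


@click.group()
def cli() -> None:
    """Niche-shift analysis and reciprocal distribution modelling."""


@cli.command()
@click.option("--out", "out_dir", default="synthetic", show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--shift", default=0.0, show_default=True,
              help="Niche-centroid shift in units of niche breadth (Mahalanobis).")
@click.option("--grid", default=100, show_default=True, help="Landscape edge length in cells.")
@click.option("--n-native", default=79, show_default=True)
@click.option("--n-invasive", default=6579, show_default=True)
def simulate(out_dir, seed, shift, grid, n_native, n_invasive):
    """Generate a paired-range synthetic scenario and a ready-to-run config."""
    _setup_logging(out_dir)
    cfg = SyntheticConfig(
        shape=(grid, grid), shift_sigma=shift, n_native=n_native,
        n_invasive=n_invasive, seed=seed,
    )
    scenario = make_scenario(cfg)
    out = Path(out_dir)
    scenario.write(out)
    run_cfg = {
        "seed": seed,
        "out_dir": str(out / "results"),
        "ranges": {
            label: {
                "occurrences": str(out / label / "occurrences.csv"),
                "layers": {v: str(out / label / f"{v}.asc") for v in cfg.variables},
                "mask": str(out / label / "mask.asc"),
            }
            for label in ("native", "invasive")
        },
        "variables": {"cutoff": 0.75, "priority": list(cfg.variables)},
    }
    (out / "config.yaml").write_text(yaml.safe_dump(run_cfg, sort_keys=False))
    click.echo(f"scenario written to {out} (config: {out / 'config.yaml'})")


def _load(config_path, seed, out_dir) -> RunConfig:
    cfg = RunConfig.from_yaml(config_path)
    if seed is not None:
        cfg.seed = seed
    if out_dir is not None:
        cfg.out_dir = out_dir
    _setup_logging(cfg.out_dir)
    return cfg


config_opt = click.option("--config", "config_path", required=True, type=click.Path(exists=True))
seed_opt = click.option("--seed", default=None, type=int, help="Override the config seed.")
out_opt = click.option("--out", "out_dir", default=None, help="Override the output directory.")


@cli.command("prepare")
@config_opt
@seed_opt
@out_opt
def prepare_cmd(config_path, seed, out_dir):
    """Ingest, rarefy, and run the collinearity filter; write the selection."""
    cfg = _load(config_path, seed, out_dir)
    prepared = prepare(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prepared["native"].selection.to_json(out / "variable_selection.json")  # type: ignore[attr-defined]
    for label, pr in prepared.items():
        pr.occ.to_csv(out / f"occurrences_{label}_prepared.csv")
    click.echo(f"kept variables: {prepared['native'].selection.kept}")  # type: ignore[attr-defined]


@cli.command("niche")
@config_opt
@seed_opt
@out_opt
def niche_cmd(config_path, seed, out_dir):
    """Run the environmental-space niche comparison."""
    cfg = _load(config_path, seed, out_dir)
    results = run_niche_analysis(cfg)
    click.echo(results.summary())


@cli.command("sdm")
@config_opt
@seed_opt
@out_opt
def sdm_cmd(config_path, seed, out_dir):
    """Tune and fit the reciprocal distribution models."""
    cfg = _load(config_path, seed, out_dir)
    _, report = run_reciprocal_sdm(cfg)
    click.echo(report.table().to_string(float_format="%.3f"))


@cli.command("all")
@config_opt
@seed_opt
@out_opt
def all_cmd(config_path, seed, out_dir):
    """Full pipeline: niche analysis then reciprocal SDM."""
    cfg = _load(config_path, seed, out_dir)
    prepared = prepare(cfg)
    results = run_niche_analysis(cfg, prepared)
    click.echo(results.summary())
    _, report = run_reciprocal_sdm(cfg, prepared)
    click.echo(report.table().to_string(float_format="%.3f"))


@cli.command("report")
@click.option("--out", "out_dir", required=True, type=click.Path(exists=True))
def report_cmd(out_dir):
    """Print a combined summary of a finished run directory."""
    out = Path(out_dir)
    niche_json = out / "niche" / "niche_results.json"
    if niche_json.exists():
        res = json.loads(niche_json.read_text())
        click.echo("Niche analysis")
        click.echo(f"  D = {res['overlap']['D']:.4f}  I = {res['overlap']['I']:.4f}")
        click.echo(f"  equivalency p(D) = {res['equivalency']['p_D']:.4f}")
        dyn = res["dynamics"]
        click.echo(
            f"  expansion = {dyn['expansion']:.4f}  stability = {dyn['stability']:.4f}"
            f"  unfilling = {dyn['unfilling']:.4f}"
        )
    table2 = out / "sdm" / "table2.csv"
    if table2.exists():
        click.echo("Reciprocal SDM (AUC / Boyce / TSS):")
        click.echo(pd.read_csv(table2, index_col=0).to_string(float_format="%.3f"))


if __name__ == "__main__":
    cli()
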