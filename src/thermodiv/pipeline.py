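"""Configuration-driven end-to-end analysis runs.

A pipeline run executes: occurrence cleaning -> niche classification ->
tip metrics -> trait-rate tests -> phylogenetic signal -> time/env
birth-death model selection -> SSE model selection -> rate-through-time
regression -> community grids -> sensitivity experiment -> reports.
Inputs come either from files (tree, occurrences, paleocurve) or from a
fully parameterised synthetic scenario with known truth.  Every stage
derives its own seed from the global seed and a fixed per-stage counter,
so a config plus seed reproduces every artifact byte-for-byte and stages
can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import bd, occurrences as occ, simulate, sse, tipstats, traitassoc
from .trees import Phylogeny, parse_newick, prune_taxa

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "sensitivity_experiment",
    "make_reports",
    "stage_seed",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


_STAGE_IDS = {
    "generate": 0, "clean": 1, "niche": 2, "tipmetrics": 3, "essim": 4,
    "fisse": 5, "pagel": 6, "bd": 7, "sse": 8, "rtt": 9, "grid": 10,
    "sensitivity": 11, "reports": 12,
}

DEFAULT_STAGES = (
    "clean", "niche", "tipmetrics", "essim", "fisse", "pagel",
    "bd", "sse", "rtt", "grid", "sensitivity", "reports",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: SeedSequence over (global seed, stage counter)."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


_SYNTH_DEFAULTS = dict(
    n_tips=100,
    lambda_tropical=0.1,
    lambda_non_tropical=0.2,
    mu=0.03,
    q=0.01,
    records_per_species=20,
    occurrence_spread=2.0,
    artifact_rate=0.02,
    temp_noise_sd=1.0,
)


@dataclass
class PipelineConfig:
    """Validated run configuration.

    Either the three input paths or a ``synthetic`` block must be
    present.  ``thresholds`` collects the knobs shared across stages
    (outlier multiplier, tropic boundary, grid cell area, simulation
    counts, optimiser starts).
    """

    outdir: Path
    seed: int = 0
    stages: tuple = DEFAULT_STAGES
    tree_path: Path | None = None
    occurrences_path: Path | None = None
    paleo_path: Path | None = None
    synthetic: dict | None = None
    k_sd: float = 3.0
    boundary_lat: float = occ.TROPIC_LATITUDE
    grid_area: float = 322.0
    n_sim: int = 500
    n_starts: int = 2
    n_grid: int = 800
    sensitivity_fractions: tuple = (0.1, 0.3, 0.5)
    sensitivity_reps: int = 3

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        if "outdir" not in raw:
            raise ValueError("config requires 'outdir'")
        kwargs = dict(outdir=Path(raw.pop("outdir")))
        for key in ("tree_path", "occurrences_path", "paleo_path"):
            if key in raw:
                kwargs[key] = Path(raw.pop(key))
        for key in (
            "seed", "synthetic", "k_sd", "boundary_lat", "grid_area",
            "n_sim", "n_starts", "n_grid", "sensitivity_reps",
        ):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "stages" in raw:
            kwargs["stages"] = tuple(raw.pop("stages"))
        if "sensitivity_fractions" in raw:
            kwargs["sensitivity_fractions"] = tuple(raw.pop("sensitivity_fractions"))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def validate(self) -> None:
        if self.synthetic is None:
            if self.tree_path is None or self.occurrences_path is None:
                raise ValueError("need tree_path and occurrences_path or a synthetic block")
            for p in (self.tree_path, self.occurrences_path, self.paleo_path):
                if p is not None and not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
        unknown = set(self.stages) - set(_STAGE_IDS)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _synthetic_scenario(params: dict, seed: int, outdir: Path):
    """Simulate the study conditions: a tropicality-dependent tree, a
    latitude-driven temperature niche, occurrence clouds with injected
    artifacts, and a long-term cooling curve."""
    p = dict(_SYNTH_DEFAULTS)
    p.update(params or {})
    tree, states, truth = simulate.simulate_sse_tree(
        p["lambda_tropical"], p["lambda_non_tropical"], p["mu"], p["mu"],
        p["q"], p["q"], root_state=0, stop=("n_tips", int(p["n_tips"])), seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    rows = []
    for label in tree.tip_labels:
        if states[label] == 0:  # tropical
            center_lat = rng.uniform(-20.0, 20.0)
        else:
            center_lat = rng.choice([-1.0, 1.0]) * rng.uniform(30.0, 55.0)
        rows.append(
            dict(
                species=label, center_lat=center_lat,
                center_lon=rng.uniform(-180.0, 180.0),
                spread=p["occurrence_spread"], n_records=p["records_per_species"],
            )
        )
    spec_df = pd.DataFrame(rows)
    table, occ_truth = simulate.simulate_occurrences(
        spec_df,
        artifact_rates=dict(
            zero_coord=p["artifact_rate"],
            integer_coord=p["artifact_rate"],
            far_outlier=p["artifact_rate"],
        ),
        seed=seed + 2,
    )
    # a simple latitudinal temperature field stands in for a climate layer
    temp = 28.0 - 0.55 * np.abs(table["decimalLatitude"]) + \
        p["temp_noise_sd"] * rng.standard_normal(len(table))
    table["temp_c"] = temp
    curve = simulate.make_paleo_curve("cramer_like")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tree.nwk").write_text(tree.to_newick())
    table.to_csv(outdir / "occurrences.csv", index=False)
    pd.DataFrame({"species": list(states), "state": list(states.values())}).to_csv(
        outdir / "true_states.csv", index=False
    )
    curve.to_frame().to_csv(outdir / "paleocurve.csv", index=False)
    return tree, table, curve, states


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the artifact bundle.

    The bundle maps artifact names to file paths; a manifest with sha256
    checksums and a structured run log are written alongside.  A stage
    failure aborts with the stage name, preserving completed outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": outdir, "artifacts": {}, "stats": {}}
    log: list = []

    def record(stage, **info):
        log.append(dict(stage=stage, **info))

    def artifact(name, path):
        bundle["artifacts"][name] = Path(path)

    t_start = time.time()
    try:
        stage = "generate"
        if config.synthetic is not None:
            tree, table, curve, true_states = _synthetic_scenario(
                config.synthetic, stage_seed(config.seed, "generate"), outdir
            )
            artifact("tree", outdir / "tree.nwk")
            artifact("occurrences", outdir / "occurrences.csv")
            artifact("paleocurve", outdir / "paleocurve.csv")
            artifact("true_states", outdir / "true_states.csv")
            record(stage, n_tips=tree.n_tips, n_records=len(table))
        else:
            tree = parse_newick(Path(config.tree_path).read_text())
            table = pd.read_csv(config.occurrences_path)
            curve = (
                simulate.PaleoCurve(
                    *pd.read_csv(config.paleo_path)[["age_myr", "temp_c"]].to_numpy().T
                )
                if config.paleo_path is not None
                else simulate.make_paleo_curve("cramer_like")
            )
            record(stage, n_tips=tree.n_tips, n_records=len(table))

        niche = None
        tips = None
        cleaned = None
        results_rows = []

        for stage in config.stages:
            t0 = time.time()
            if stage == "clean":
                cleaned = occ.remove_geographic_outliers(
                    occ.clean_occurrences(table), k_sd=config.k_sd
                )
                path = outdir / "occurrences_clean.csv"
                cleaned.to_csv(path, index=False)
                artifact("occurrences_clean", path)
                counts = cleaned["status"].value_counts().to_dict()
                bundle["stats"]["cleaning"] = counts
                record(stage, seconds=round(time.time() - t0, 3), **counts)
            elif stage == "niche":
                src = cleaned if cleaned is not None else occ.clean_occurrences(table)
                niche = occ.species_niche_table(src, boundary=config.boundary_lat)
                path = outdir / "species_niche.csv"
                niche.to_csv(path)
                artifact("species_niche", path)
                record(stage, seconds=round(time.time() - t0, 3), n_species=len(niche))
            elif stage == "tipmetrics":
                tips = tipstats.tip_rate_table(tree)
                path = outdir / "tip_rates.csv"
                tips.to_csv(path)
                artifact("tip_rates", path)
                record(stage, seconds=round(time.time() - t0, 3), n_tips=len(tips))
            elif stage == "essim":
                trait = niche["mat"].dropna().to_dict()
                res = traitassoc.essim_test(
                    tree, trait, n_sim=config.n_sim,
                    seed=stage_seed(config.seed, "essim"),
                )
                bundle["stats"]["essim"] = dict(rho=res.observed, p=res.p)
                results_rows.append(dict(test="essim", statistic=res.observed, p=res.p))
                record(stage, seconds=round(time.time() - t0, 3), rho=res.observed, p=res.p)
            elif stage == "fisse":
                states = {
                    sp: 0 if row["clim_tropicality"] == "tropical" else 1
                    for sp, row in niche.iterrows()
                    if sp in tree.tip_labels
                }
                sub = prune_taxa(tree, set(tree.tip_labels) - set(states))
                res = traitassoc.fisse_test(
                    sub, states, n_sim=config.n_sim,
                    seed=stage_seed(config.seed, "fisse"),
                )
                bundle["stats"]["fisse"] = dict(
                    lambda0=res.extras.get("lambda0"),
                    lambda1=res.extras.get("lambda1"), p=res.p,
                )
                results_rows.append(
                    dict(test="fisse", statistic=res.observed, p=res.p,
                         **{k: res.extras.get(k) for k in ("lambda0", "lambda1")})
                )
                record(stage, seconds=round(time.time() - t0, 3), p=res.p)
            elif stage == "pagel":
                trait = niche["mat"].dropna().to_dict()
                sig = traitassoc.pagel_lambda(tree, trait)
                bundle["stats"]["pagel"] = dict(lambda_hat=sig.lambda_hat, p=sig.p)
                results_rows.append(dict(test="pagel", statistic=sig.lambda_hat, p=sig.p))
                record(stage, seconds=round(time.time() - t0, 3), lambda_hat=sig.lambda_hat)
            elif stage == "bd":
                seed = stage_seed(config.seed, "bd")
                fits = []
                for dep in ("time", "env"):
                    for spec in bd.enumerate_models(dep, curve=curve):
                        fits.append(
                            bd.fit_bd(tree, spec, n_starts=config.n_starts,
                                      seed=seed, n_grid=config.n_grid)
                        )
                tab = bd.model_table(fits)
                path = outdir / "bd_model_table.csv"
                tab.to_csv(path, index=False)
                artifact("bd_model_table", path)
                best = tab.iloc[0]
                bundle["stats"]["bd"] = dict(
                    best_model=best["model"], aw=float(best["AW"])
                )
                bundle["_bd_fits"] = fits
                record(stage, seconds=round(time.time() - t0, 3), best=best["model"])
            elif stage == "sse":
                states = {
                    sp: 0 if row["clim_tropicality"] == "tropical" else 1
                    for sp, row in niche.iterrows()
                    if sp in tree.tip_labels
                }
                sub = prune_taxa(tree, set(tree.tip_labels) - set(states))
                vals = set(states.values())
                if len(vals) < 2:
                    record(stage, skipped="monomorphic tropicality")
                    continue
                seed = stage_seed(config.seed, "sse")
                fits = [
                    sse.fit_sse(sub, states, m, n_starts=config.n_starts, seed=seed)
                    for m in sse.build_model_set()
                ]
                tab = bd.model_table(fits)
                path = outdir / "sse_model_table.csv"
                tab.to_csv(path, index=False)
                artifact("sse_model_table", path)
                bundle["stats"]["sse"] = dict(best_model=tab.iloc[0]["model"])
                record(stage, seconds=round(time.time() - t0, 3), best=tab.iloc[0]["model"])
            elif stage == "rtt":
                fits = bundle.get("_bd_fits")
                if not fits:
                    record(stage, skipped="no bd fits")
                    continue
                env_fits = [f for f in fits if f.spec.dependency == "env"]
                best = min(env_fits or fits, key=lambda f: f.aic)
                rtt = bd.rtt_curve(best, n_slices=100)
                path = outdir / "rtt.csv"
                rtt.to_csv(path, index=False)
                artifact("rtt", path)
                reg = bd.rtt_temp_regression(rtt, curve)
                bundle["stats"]["rtt_regression"] = reg
                pd.DataFrame([reg]).to_csv(outdir / "rtt_regression.csv", index=False)
                artifact("rtt_regression", outdir / "rtt_regression.csv")
                record(stage, seconds=round(time.time() - t0, 3), form=reg["form"])
            elif stage == "grid":
                grid = tipstats.equal_area_grid(config.grid_area)
                src = cleaned if cleaned is not None else table
                summaries = tipstats.grid_community_summaries(src, tips, grid)
                path = outdir / "grid_summaries.csv"
                summaries.to_csv(path, index=False)
                artifact("grid_summaries", path)
                record(stage, seconds=round(time.time() - t0, 3), n_cells=len(summaries))
            elif stage == "sensitivity":
                states = {
                    sp: 0 if row["clim_tropicality"] == "tropical" else 1
                    for sp, row in niche.iterrows()
                    if sp in tree.tip_labels
                }
                sub = prune_taxa(tree, set(tree.tip_labels) - set(states))
                try:
                    sens = sensitivity_experiment(
                        sub, states, fractions=config.sensitivity_fractions,
                        n_reps=config.sensitivity_reps,
                        seed=stage_seed(config.seed, "sensitivity"),
                    )
                except ValueError as exc:
                    record(stage, skipped=str(exc))
                    continue
                path = outdir / "sensitivity.csv"
                sens.to_csv(path, index=False)
                artifact("sensitivity", path)
                record(stage, seconds=round(time.time() - t0, 3), n_rows=len(sens))
            elif stage == "reports":
                path = outdir / "test_results.csv"
                pd.DataFrame(results_rows).to_csv(path, index=False)
                artifact("test_results", path)
                record(stage, seconds=round(time.time() - t0, 3))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    bundle.pop("_bd_fits", None)
    make_reports(bundle)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(dict(seed=config.seed, total_seconds=round(time.time() - t_start, 3),
                       stages=log), fh, indent=1)
    return bundle


def make_reports(bundle: dict) -> Path:
    """Write the manifest: every artifact with its sha256 checksum."""
    outdir = Path(bundle["outdir"])
    manifest = {
        "artifacts": {
            name: dict(path=str(Path(p).name), sha256=_sha256(Path(p)))
            for name, p in sorted(bundle["artifacts"].items())
        },
        "stats": _jsonable(bundle.get("stats", {})),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def sensitivity_experiment(
    tree: Phylogeny,
    states: Mapping[str, int],
    fractions=(0.1, 0.3, 0.5),
    n_reps: int = 3,
    seed: int = 0,
    min_remaining: int = 10,
) -> pd.DataFrame:
    """Random non-tropical taxon dropping and tip-rate re-estimation.

    For each fraction and replicate, that share of non-tropical (state 1)
    tips is dropped uniformly without replacement -- every tropical tip
    is always retained -- the tree re-pruned, and the state-specific
    mean DR rates recomputed.  Returns one row per replicate with the
    rate pair and their ratio; the full-data values appear as fraction 0.
    """
    labels = list(tree.tip_labels)
    non_trop = [l for l in labels if states[l] == 1]
    trop = [l for l in labels if states[l] == 0]
    if not non_trop or not trop:
        raise ValueError("both tropicality states must be present")
    rng = np.random.default_rng(seed)

    def rate_pair(t: Phylogeny):
        dr = tipstats.dr_rate(tipstats.equal_splits(t))
        s = np.array([states[l] for l in t.tip_labels])
        vals = dr.to_numpy()
        return float(vals[s == 0].mean()), float(vals[s == 1].mean())

    l0_full, l1_full = rate_pair(tree)
    rows = [dict(fraction=0.0, rep=0, lambda0=l0_full, lambda1=l1_full,
                 ratio=l1_full / l0_full)]
    for frac in fractions:
        if not (0 <= frac < 1):
            raise ValueError("fractions must lie in [0, 1)")
        n_drop = int(round(frac * len(non_trop)))
        if len(non_trop) - n_drop < min_remaining:
            raise ValueError(
                f"fraction {frac} leaves fewer than {min_remaining} non-tropical tips"
            )
        for rep in range(n_reps):
            drop = rng.choice(non_trop, size=n_drop, replace=False)
            sub = prune_taxa(tree, set(drop.tolist()))
            l0, l1 = rate_pair(sub)
            rows.append(dict(fraction=frac, rep=rep, lambda0=l0, lambda1=l1,
                             ratio=l1 / l0))
    return pd.DataFrame(rows)
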