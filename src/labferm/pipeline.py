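"""End-to-end workflow: data -> surfaces -> networks -> optimum, with manifest.

``run_pipeline`` chains the stages on one or more culture cases and writes
every artifact (tables as CSV, models as JSON) under an output directory,
together with a manifest recording the configuration, seeds and SHA-256
hashes of every file — enough to replay a run bit-identically.

``reference_report`` checks the transcribed reference models against the
numbers reported alongside them: the lattice optima of the printed networks
and the 24-h endpoint predictions of the printed regressions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import ann, optimize, reference, rsm
from .dataio import CULTURES, read_viability_table, write_viability_table
from .models import FULL_CUBIC_TERMS, serialize_model
from .simulate import culture_preset, simulate_dataset

logger = logging.getLogger("labferm")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one pipeline run.

    ``source`` is either the literal string ``'synthetic'`` (generate data
    from the culture presets) or a path to a viability CSV.  At least one of
    the three stages must be enabled.
    """

    source: str = "synthetic"
    cultures: tuple[str, ...] = CULTURES
    run_rsm: bool = True
    run_ann: bool = True
    run_optimize: bool = True
    ann_methods: tuple[str, ...] = ("levenberg_marquardt",)
    ann_neurons: tuple[int, ...] = (8,)
    ann_max_epochs: int = 200
    seed: int = 0
    grid_points: int = 49
    output_dir: str = "labferm_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if not (self.run_rsm or self.run_ann or self.run_optimize):
            raise ValueError("at least one stage must be enabled")
        unknown = set(self.cultures) - set(CULTURES)
        if unknown:
            raise ValueError(f"unknown culture(s): {sorted(unknown)}")
        for m in self.ann_methods:
            if m not in ann.METHODS:
                raise ValueError(f"unknown ANN method {m!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key-value text config: one ``key = value`` pair per line."""
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key in ("cultures", "ann_methods"):
                kwargs[key] = tuple(v.strip() for v in value.split(","))
            elif key == "ann_neurons":
                kwargs[key] = tuple(int(v) for v in value.split(","))
            elif key in ("run_rsm", "run_ann", "run_optimize"):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in ("seed", "grid_points", "ann_max_epochs"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    """Decorator-free stage guard: wrap exceptions with the stage name."""
    class _Guard:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Guard()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the report bundle.

    The bundle maps artifact names to file paths; the same mapping, with
    hashes, lands in ``manifest.json``.  A stage failure aborts the run with
    the stage name in the error; artifacts written before the failure are
    kept on disk.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save_df(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        artifacts[name] = path

    with _stage("load"):
        datasets = {}
        for case in config.cultures:
            if config.source == "synthetic":
                ds = simulate_dataset(culture_preset(case, seed=config.seed))
            else:
                ds = read_viability_table(config.source).select(case)
            datasets[case] = ds
            path = out / f"data_{case}.csv"
            write_viability_table(ds, path)
            artifacts[f"data_{case}"] = path

    best_models = {}
    for case, ds in datasets.items():
        if config.run_rsm:
            with _stage(f"rsm_{case}"):
                anova = rsm.sequential_anova(ds)
                save_df(f"anova_{case}", anova.table)
                # fit the structurally admissible cubic terms, then apply the
                # significance prune (a no-op at the default alpha = 1)
                base_terms = [t for t in FULL_CUBIC_TERMS
                              if t not in rsm.STRUCTURAL_REMOVALS]
                model, report = rsm.fit_rsm(ds, base_terms)
                terms = rsm.prune_terms(report)
                if terms != report.terms:
                    model, report = rsm.fit_rsm(ds, terms)
                save_df(f"coefficients_{case}", report.to_frame())
                diag = pd.DataFrame(
                    {
                        "residual": report.residuals,
                        "fitted": report.fitted,
                        "leverage": report.leverage,
                        "cooks_distance": rsm.cooks_distance(report),
                    }
                )
                save_df(f"diagnostics_{case}", diag)
                path = out / f"rsm_{case}.json"
                serialize_model(model, path)
                artifacts[f"rsm_{case}"] = path
                best_models[case] = model

        if config.run_ann:
            with _stage(f"ann_{case}"):
                train_ds, test_ds = ann.split_systematic(ds, seed=config.seed)
                candidates = []
                for method in config.ann_methods:
                    for n in config.ann_neurons:
                        cfg = ann.TrainingConfig(
                            method=method, neurons=n, seed=config.seed,
                            max_epochs=config.ann_max_epochs,
                        )
                        model, history = ann.train(train_ds, cfg)
                        metrics = ann.evaluate(model, test_ds)
                        label = f"{method}/{n}"
                        candidates.append((label, metrics))
                        stem = f"ann_{case}_{method}_{n}"
                        path = out / f"{stem}.json"
                        serialize_model(model, path)
                        artifacts[stem] = path
                        save_df(
                            f"{stem}_history",
                            pd.DataFrame({"epoch": range(len(history.costs)),
                                          "cost": history.costs}),
                        )
                        if label == f"{config.ann_methods[0]}/{config.ann_neurons[0]}":
                            best_models[case] = model
                comparison = ann.model_comparison(candidates)
                save_df(f"comparison_{case}", comparison)
                # the comparison winner becomes the case's surface to optimize
                win_method, win_n = comparison.iloc[0]["model"].split("/")
                win_cfg = ann.TrainingConfig(
                    method=win_method, neurons=int(win_n), seed=config.seed,
                    max_epochs=config.ann_max_epochs,
                )
                best_models[case], _ = ann.train(train_ds, win_cfg)

        if config.run_optimize:
            with _stage(f"optimize_{case}"):
                if case not in best_models:
                    raise ValueError("optimization needs a fitted model stage")
                res = optimize.maximize_response(
                    best_models[case].predict, grid_points=config.grid_points
                )
                save_df(
                    f"optimum_{case}",
                    pd.DataFrame(
                        [{
                            "culture": case,
                            "optimum_log10cfu_ml": res.optimum,
                            "time_h": res.time_h,
                            "wf_pct": res.wf_pct,
                            "sf_pct": res.sf_pct,
                            "grid_points": res.grid_points,
                        }]
                    ),
                )

    with _stage("manifest"):
        manifest = {
            "config": asdict(config),
            "seed": config.seed,
            "artifacts": {k: {"path": str(v), "sha256": _sha256(v)}
                          for k, v in sorted(artifacts.items())},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        artifacts["manifest"] = manifest_path

    return {k: str(v) for k, v in artifacts.items()}


def reference_report(grid_points: int = 49) -> pd.DataFrame:
    """Computed-vs-reported table for the transcribed reference models.

    For each culture the printed network is maximized on the default
    lattice under its frozen scaling convention, and the printed regression
    is evaluated at the 24-h, 100 % WF endpoint.  Failures appear as
    ``within_tolerance = False`` rows, never as exceptions.  Optimum values
    use a 1e-3 tolerance (4-decimal agreement), argmax coordinates half a
    lattice step, endpoints the observed +/- half-width.
    """
    dt = 24.0 / (grid_points - 1) / 2.0
    dw = 10.0 / (grid_points - 1) / 2.0
    rows = []
    for case in CULTURES:
        model = reference.load_reference_ann(case)
        res = optimize.maximize_response(model.predict, grid_points=grid_points)
        rep_v, rep_t, rep_w = reference.REPORTED_OPTIMA[case]
        for qty, comp, ref_val, tol in (
            ("ann_optimum", res.optimum, rep_v, 1e-3),
            ("ann_argmax_time_h", res.time_h, rep_t, dt),
            ("ann_argmax_wf_pct", res.wf_pct, rep_w, dw),
        ):
            rows.append((case, qty, comp, ref_val, abs(comp - ref_val),
                         abs(comp - ref_val) <= tol))
        reg = reference.load_reference_regression(case)
        endpoint = float(reg.predict((24.0, 100.0, 0.0))[0])
        mean, half = reference.OBSERVED_ENDPOINTS[case]
        rows.append((case, "regression_endpoint_24h", endpoint, mean,
                     abs(endpoint - mean), abs(endpoint - mean) <= half))
    return pd.DataFrame(
        rows,
        columns=["culture", "quantity", "computed", "reported", "abs_diff",
                 "within_tolerance"],
    )
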