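"""End-to-end orchestration of the comparative analysis.

One call runs: locality vetting -> species climate summaries -> per-variable
evolutionary model selection (BM / OU / lambda, delta-AIC >= 4 rule) ->
PGLS battery under the ML-lambda model (optionally also the OU transform)
-> Pagel's-lambda signal battery, and writes a report bundle of TSV/CSV
tables plus a plain-text run log with versions, seed and per-stage record
counts.  Validation is fail-fast: unknown variable names or missing files
abort before any computation, and nothing is written unless every stage
succeeds.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import read_localities, summarize_species, vet_localities
from .defaults import (
    DEFAULT_ELEVATION_RANGE,
    DEFAULT_MODEL_VARIABLES,
    DEFAULT_PGLS_PAIRS,
    DEFAULT_SIGNAL_VARIABLES,
)
from .evomodels import DEFAULT_OU_SEED, model_table
from .pgls import run_pair_battery
from .signal import signal_battery
from .tree import read_newick

__all__ = ["AnalysisConfig", "run_analysis", "PipelineError"]

#: Formatting used in report tables, matching the 4-decimal convention of
#: the result tables this pipeline emulates.
_FLOAT_FMT = "%.6g"

_REPORT_FOOTER = (
    "# Significance is reported at raw p < 0.05; no multiple-testing "
    "correction is applied anywhere in this pipeline.\n"
)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class AnalysisConfig:
    """Paths, variable selections and switches for one pipeline run."""

    tree_path: str
    traits_path: str
    localities_path: str
    out_dir: str
    temperature_units: str  # 'celsius' or 'worldclim-raw'; no default
    seed: int = DEFAULT_OU_SEED
    pgls_pairs: list = field(default_factory=lambda: list(DEFAULT_PGLS_PAIRS))
    signal_variables: list = field(default_factory=lambda: list(DEFAULT_SIGNAL_VARIABLES))
    model_variables: list = field(default_factory=lambda: list(DEFAULT_MODEL_VARIABLES))
    elevation_range: tuple = DEFAULT_ELEVATION_RANGE
    run_ou_battery: bool = True
    alpha_level: float = 0.05
    ou_restarts: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a JSON or YAML file."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw["pgls_pairs"] = [tuple(p) for p in raw.get("pgls_pairs", DEFAULT_PGLS_PAIRS)]
        if "elevation_range" in raw:
            raw["elevation_range"] = tuple(raw["elevation_range"])
        return cls(**raw)


def _validate(cfg: AnalysisConfig, traits: pd.DataFrame, summary_cols: list[str]) -> None:
    known = set(traits.columns) | set(summary_cols)
    for resp, pred in cfg.pgls_pairs:
        for name in (resp, pred):
            if name not in known:
                raise PipelineError(
                    "validate",
                    f"unknown variable {name!r} in pgls_pairs; known: {sorted(known)}",
                )
    for name in list(cfg.signal_variables) + list(cfg.model_variables):
        if name not in known:
            raise PipelineError(
                "validate", f"unknown variable {name!r}; known: {sorted(known)}"
            )


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Run the full analysis; returns the bundle as in-memory tables.

    Writes to ``cfg.out_dir``: ``climate_summaries.csv``,
    ``model_comparison.tsv``, ``pgls_lambda.tsv`` (and ``pgls_ou.tsv``),
    ``signal.tsv`` and ``run_log.txt``.  Outputs appear only after every
    stage has finished, so a failure leaves no partial bundle.
    """
    log: list[str] = [
        f"spadefoot {__version__} (python {sys.version.split()[0]}, "
        f"numpy {np.__version__}, pandas {pd.__version__})",
        f"seed: {cfg.seed}",
    ]

    # ---- load inputs ---------------------------------------------------
    try:
        tree = read_newick(Path(cfg.tree_path).read_text())
    except Exception as e:
        raise PipelineError("load_tree", f"{cfg.tree_path}: {e}") from e
    try:
        sep = "\t" if cfg.traits_path.endswith((".tsv", ".tab")) else ","
        traits = pd.read_csv(cfg.traits_path, sep=sep, na_values=["", "NA"])
        traits = traits.set_index("species")
    except Exception as e:
        raise PipelineError("load_traits", f"{cfg.traits_path}: {e}") from e
    unknown_sp = set(traits.index) - set(tree.tips)
    if unknown_sp:
        raise PipelineError(
            "load_traits", f"species not in tree: {sorted(unknown_sp)}"
        )
    try:
        localities = read_localities(
            cfg.localities_path, temperature_units=cfg.temperature_units
        )
    except Exception as e:
        raise PipelineError("load_localities", f"{cfg.localities_path}: {e}") from e
    log.append(
        f"inputs: {tree.n_tips} tips, {len(traits)} trait rows, "
        f"{len(localities)} locality records"
    )

    # ---- climate stage -------------------------------------------------
    try:
        kept, rejections = vet_localities(localities, *cfg.elevation_range)
        summaries = summarize_species(kept).set_index("species")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("climate", str(e)) from e
    log.append(
        f"climate: kept {len(kept)} of {len(localities)} records "
        f"({(rejections['reason'] != 'note_no_elevation').sum()} logged rejections/notes); "
        f"{len(summaries)} species summaries"
    )

    merged = traits.join(summaries, how="left")
    _validate(cfg, traits, list(summaries.columns))

    # ---- model selection ------------------------------------------------
    model_rows = []
    for var in cfg.model_variables:
        y = merged[var].dropna()
        try:
            cmp_ = model_table(y, tree, n_restarts=cfg.ou_restarts, seed=cfg.seed)
        except Exception as e:
            raise PipelineError("fit_models", f"variable {var!r}: {e}") from e
        for m, f in cmp_.fits.items():
            model_rows.append(
                {
                    "variable": var,
                    "model": m,
                    "n": f.n,
                    "loglik": f.loglik,
                    "aic": f.aic,
                    "delta_aic": cmp_.delta_aic[m],
                    "shape": f.shape,
                    "preferred": m in cmp_.preferred,
                }
            )
    models_df = pd.DataFrame(model_rows)
    log.append(f"fit_models: {len(cfg.model_variables)} variables x 3 models")

    # ---- PGLS batteries -------------------------------------------------
    try:
        pgls_lambda_df = run_pair_battery(
            cfg.pgls_pairs, merged, tree, method="lambda", alpha_level=cfg.alpha_level
        )
    except Exception as e:
        raise PipelineError("pgls", str(e)) from e
    log.append(f"pgls (lambda): {len(pgls_lambda_df)} pairs")
    pgls_ou_df = None
    if cfg.run_ou_battery:
        try:
            pgls_ou_df = run_pair_battery(
                cfg.pgls_pairs,
                merged,
                tree,
                method="ou",
                alpha_level=cfg.alpha_level,
                n_restarts=cfg.ou_restarts,
                seed=cfg.seed,
            )
        except Exception as e:
            raise PipelineError("pgls_ou", str(e)) from e
        log.append(f"pgls (OU): {len(pgls_ou_df)} pairs")

    # ---- signal battery -------------------------------------------------
    try:
        signal_df = signal_battery(merged, tree, cfg.signal_variables)
    except Exception as e:
        raise PipelineError("signal", str(e)) from e
    log.append(f"signal: {len(signal_df)} variables")

    # ---- write bundle ---------------------------------------------------
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        summaries.reset_index().to_csv(
            out / "climate_summaries.csv", index=False, float_format=_FLOAT_FMT
        )
        written.append(out / "climate_summaries.csv")
        rejections.to_csv(out / "vetting_log.csv", index=False)
        written.append(out / "vetting_log.csv")
        models_df.to_csv(
            out / "model_comparison.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        written.append(out / "model_comparison.tsv")
        pgls_lambda_df.to_csv(
            out / "pgls_lambda.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        written.append(out / "pgls_lambda.tsv")
        if pgls_ou_df is not None:
            pgls_ou_df.to_csv(
                out / "pgls_ou.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
            )
            written.append(out / "pgls_ou.tsv")
        signal_df.to_csv(
            out / "signal.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        written.append(out / "signal.tsv")
        (out / "run_log.txt").write_text("\n".join(log) + "\n" + _REPORT_FOOTER)
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("write", str(e)) from e

    return {
        "climate_summaries": summaries,
        "vetting_log": rejections,
        "model_comparison": models_df,
        "pgls_lambda": pgls_lambda_df,
        "pgls_ou": pgls_ou_df,
        "signal": signal_df,
        "log": log,
    }
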