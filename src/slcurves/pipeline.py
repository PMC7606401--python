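"""Reproducible simulate -> score -> regress -> fit -> correlate pipeline.

Each stage reads the previous stage's CSV/JSON artifacts from the run
directory, writes its own outputs plus a JSON manifest (input hashes,
config snapshot, seed, package version), and can be re-run independently.
A run is fully determined by (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import (
    INDIVIDUAL_BOUNDS, FitResult, compare_models, fit_group,
    fit_participants, predict,
)
from .individual import correlate_profiles
from .regression import build_design, fit_ols
from .synthesis import (
    CohortSpec, SessionDesign, generate_neuropsych_scores, simulate_cohort,
)
from .triplets import compute_sl_scores, group_sl_series, label_cohort, summarize_blocks

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "regress", "fit", "correlate", "report")

TRIAL_COLUMNS = [
    "participant_id", "block", "trial", "role", "target_pos",
    "response_pos", "correct", "rt_ms",
]


@dataclass
class PipelineConfig:
    """Serializable run configuration; defaults reproduce the standard
    40-participant, 36-block study conditions."""

    design: dict = field(default_factory=dict)   # SessionDesign overrides
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    sl_mode: str = "rescaled"                    # raw | normalized | rescaled
    pooling: str = "mean"                        # group fit on per-block means
    restarts: int = 10
    group_x0_bounds: tuple[float, float] = (-50.0, 50.0)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def session_design(self) -> SessionDesign:
        return SessionDesign(**{k: tuple(v) if k == "pattern" else v for k, v in self.design.items()})

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(**self.cohort)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_x0_bounds"] = list(self.group_x0_bounds)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_manifest(out: Path, stage: str, inputs: list[Path], outputs: list[Path],
                    config: PipelineConfig, seed: int) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "version": __version__,
        "config": config.as_dict(),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    _write_json(out / f"manifest_{stage}.json", manifest)


def _require(out: Path, names: list[str], stage: str) -> list[Path]:
    paths = [out / n for n in names]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs {p} — run the upstream stage first"
            )
    return paths


def _to_csv(df: pd.DataFrame, path: Path, rt_cols: tuple[str, ...] = ()) -> None:
    df = df.copy()
    for c in rt_cols:
        if c in df.columns:
            df[c] = df[c].map(lambda v: f"{v:.3f}" if pd.notna(v) else "")
    df.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    design = config.session_design()
    spec = config.cohort_spec()
    trials, truths, patterns = simulate_cohort(design, spec, seed)
    scores = generate_neuropsych_scores(truths, seed=seed)

    t = trials[TRIAL_COLUMNS].copy()
    t["correct"] = t["correct"].astype(int)
    _to_csv(t, out / "trials.csv", rt_cols=("rt_ms",))
    _to_csv(truths, out / "ground_truth.csv")
    _to_csv(scores, out / "neuropsych.csv")
    _write_json(out / "patterns.json", {pid: list(p) for pid, p in patterns.items()})
    _write_manifest(out, "simulate", [],
                    [out / n for n in ("trials.csv", "ground_truth.csv", "neuropsych.csv", "patterns.json")],
                    config, seed)
    logger.info("simulate: %d trials for %d participants", len(t), spec.n_participants)


def stage_score(config: PipelineConfig, seed: int, out: Path) -> None:
    inputs = _require(out, ["trials.csv", "patterns.json"], "score")
    trials = pd.read_csv(out / "trials.csv")
    trials["correct"] = trials["correct"].astype(bool)
    patterns = {pid: tuple(p) for pid, p in json.loads((out / "patterns.json").read_text()).items()}

    labeled = label_cohort(trials, patterns)
    summaries = summarize_blocks(labeled)
    scores = compute_sl_scores(summaries, mode=config.sl_mode)
    group = group_sl_series(scores)

    lt = labeled.copy()
    lt["correct"] = lt["correct"].astype(int)
    _to_csv(lt, out / "labeled_trials.csv", rt_cols=("rt_ms",))
    _to_csv(summaries, out / "summaries.csv", rt_cols=("mean_rt_ms",))
    _to_csv(scores, out / "sl_scores.csv")
    _to_csv(group, out / "group_sl.csv")
    _write_manifest(out, "score", inputs,
                    [out / n for n in ("labeled_trials.csv", "summaries.csv", "sl_scores.csv", "group_sl.csv")],
                    config, seed)
    logger.info("score: %d summaries, SL mode=%s", len(summaries), config.sl_mode)


def stage_regress(config: PipelineConfig, seed: int, out: Path) -> None:
    inputs = _require(out, ["summaries.csv"], "regress")
    summaries = pd.read_csv(out / "summaries.csv")
    results, md = {}, []
    for contrast in ("probability", "type"):
        for outcome in ("accuracy", "rt"):
            fit = fit_ols(build_design(summaries, contrast, outcome))
            results[f"{contrast}_{outcome}"] = fit.as_dict()
            md.append(f"## {contrast} contrast, {outcome}\n\n{fit.markdown_table()}\n")
    _write_json(out / "regression.json", results)
    (out / "regression.md").write_text("\n".join(md))
    _write_manifest(out, "regress", inputs,
                    [out / "regression.json", out / "regression.md"], config, seed)
    logger.info("regress: 4 models fitted")


def _fit_to_dict(f: FitResult) -> dict:
    return {
        "form": f.form, "w1": f.w1, "w2": f.w2, "w3": f.w3, "sigma": f.sigma,
        "logL": f.logL, "k": f.k, "n": f.n, "aicc": f.aicc, "bic": f.bic,
        "converged": f.converged, "bounds_hit": list(f.bounds_hit),
        "data_hash": f.data_hash,
    }


def stage_fit(config: PipelineConfig, seed: int, out: Path) -> None:
    inputs = _require(out, ["sl_scores.csv"], "fit")
    scores = pd.read_csv(out / "sl_scores.csv")
    gb = (
        (-500.0, 500.0), tuple(config.group_x0_bounds), (1.0, 50.0), (1e-6, 30.0),
    )
    fits = fit_group(scores, pooling=config.pooling, bounds=gb,
                     restarts=config.restarts, seed=seed)
    selection = compare_models(list(fits.values()))
    comp = pd.DataFrame(
        [
            {"m1": r.m1, "m0": r.m0, "delta_aicc": r.delta_aicc,
             "bayes_factor": r.bayes_factor, "interpretation": r.interpretation}
            for r in selection.rows
        ]
    )
    curves = fit_participants(scores, bounds=INDIVIDUAL_BOUNDS,
                              restarts=config.restarts, seed=seed)
    pc = pd.DataFrame(
        [
            {"participant_id": c.participant_id, "A": c.A, "x0": c.x0, "tau": c.tau,
             "sigma": c.sigma, "converged": int(c.converged),
             "bounds_hit": ";".join(c.bounds_hit)}
            for c in curves
        ]
    )
    _write_json(out / "group_fits.json", {
        "fits": {form: _fit_to_dict(f) for form, f in fits.items()},
        "best_by_aicc": selection.best_by_aicc,
        "best_by_bic": selection.best_by_bic,
        "criteria_agree": selection.criteria_agree,
        "bounds": {"group": [list(b) for b in gb], "individual": [list(b) for b in INDIVIDUAL_BOUNDS]},
        "seed": seed,
    })
    _to_csv(comp, out / "model_comparison.csv")
    _to_csv(pc, out / "participant_curves.csv")
    _write_manifest(out, "fit", inputs,
                    [out / n for n in ("group_fits.json", "model_comparison.csv", "participant_curves.csv")],
                    config, seed)
    logger.info("fit: best model by AICc = %s", selection.best_by_aicc)


def stage_correlate(config: PipelineConfig, seed: int, out: Path) -> None:
    inputs = _require(out, ["participant_curves.csv", "neuropsych.csv"], "correlate")
    curves = pd.read_csv(out / "participant_curves.csv")
    curves["converged"] = curves["converged"].astype(bool)
    scores = pd.read_csv(out / "neuropsych.csv")
    table, a_vs_tau = correlate_profiles(curves, scores)
    _to_csv(table, out / "correlations.csv")
    _write_json(out / "a_vs_tau.json",
                {"r": a_vs_tau.r, "p": a_vs_tau.p, "n": a_vs_tau.n})
    _write_manifest(out, "correlate", inputs,
                    [out / "correlations.csv", out / "a_vs_tau.json"], config, seed)
    logger.info("correlate: A vs tau r=%.3f (n=%d)", a_vs_tau.r, a_vs_tau.n)


def stage_report(config: PipelineConfig, seed: int, out: Path) -> None:
    inputs = _require(out, ["group_sl.csv", "group_fits.json"], "report")
    group = pd.read_csv(out / "group_sl.csv")
    fits = json.loads((out / "group_fits.json").read_text())
    exp = fits["fits"]["exponential"]
    A, x0, tau = exp["w1"], exp["w2"], exp["w3"]

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(group["block"], group["sl_score"], "o", color="0.6", label="group SL score")
    xs = np.linspace(group["block"].min(), group["block"].max(), 300)
    ax.plot(xs, predict("exponential", (A, x0, tau), xs), "k-", label="exponential fit")
    ax.axhline(A, ls="--", color="tab:blue", label=f"saturation A = {A:.2f}")
    y63 = A * (1.0 - np.exp(-1.0))
    ax.plot([x0 + tau], [y63], "r*", ms=12, label=f"63.2% of A at x0 + tau = {x0 + tau:.2f}")
    ax.set_xlabel("block order")
    ax.set_ylabel("SL score")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "sl_curve.png", dpi=120)
    plt.close(fig)

    lines = [
        "# Pipeline report",
        "",
        f"Group exponential fit: A = {A:.3f}, x0 = {x0:.3f}, tau = {tau:.3f}.",
        f"The curve reaches 63.2% of A (= {y63:.3f}) at block x0 + tau = {x0 + tau:.3f}.",
        f"Best model by AICc: {fits['best_by_aicc']}; by BIC: {fits['best_by_bic']}.",
        "",
        "![group SL curve](sl_curve.png)",
        "",
        "## Model comparison",
        "",
        (out / "model_comparison.csv").read_text() if (out / "model_comparison.csv").exists() else "",
        "## Config snapshot",
        "",
        "```yaml",
        yaml.safe_dump(config.as_dict(), sort_keys=True).rstrip(),
        "```",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
    _write_manifest(out, "report", inputs, [out / "report.md"], config, seed)
    logger.info("report written to %s", out / "report.md")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "score": stage_score,
    "regress": stage_regress,
    "fit": stage_fit,
    "correlate": stage_correlate,
    "report": stage_report,
}


def run_stage(name: str, config: PipelineConfig, seed: int, out: str | Path) -> None:
    """Run one pipeline stage into the run directory ``out``."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    _STAGE_FUNCS[name](config, seed, Path(out))


def run_all(config: PipelineConfig, seed: int, out: str | Path) -> None:
    """Run the full pipeline end to end."""
    for name in STAGES:
        run_stage(name, config, seed, out)


def setup_logging(out: Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )
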