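"""Serialization, run configuration and pipeline stages.

Trial tables travel as plain CSV with one row per trial and columns
``subject, condition, block, trial, choice, outcome, p0, p1``; choices
are coded 0/1, outcomes −1/0/+1, and trial indices are 0-based within
block.  Every pipeline stage writes a JSON manifest recording the seed,
the validated configuration, the package version and a checksum per
output file, so any artifact can be regenerated bit-for-bit from its
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__ as _version
from . import comparison, recovery
from .hbayes import FitConfig, sample_posterior
from .models import get_variant
from .tasks import RecoveryGridDesign, TrialSequence, simulate_grid

log = logging.getLogger(__name__)

TRIAL_COLUMNS = ["subject", "condition", "block", "trial", "choice", "outcome", "p0", "p1"]


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def sequences_to_frame(sequences: Sequence[TrialSequence]) -> pd.DataFrame:
    frames = []
    for s in sequences:
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.subject,
                    "condition": s.condition,
                    "block": s.block,
                    "trial": s.trial,
                    "choice": s.choice,
                    "outcome": s.outcome,
                    "p0": s.p0,
                    "p1": s.p1,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_sequences(df: pd.DataFrame) -> list[TrialSequence]:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    bad = df[~df["choice"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"illegal choice codes at rows {bad.index.tolist()[:10]}")
    out = []
    for subject, g in df.groupby("subject", sort=True):
        conds = g["condition"].unique()
        if len(conds) != 1:
            raise ValueError(f"subject {subject!r} mixes conditions {conds.tolist()}")
        g = g.sort_values(["block", "trial"], kind="stable")
        out.append(
            TrialSequence(
                subject=subject,
                condition=str(conds[0]),
                block=g["block"].to_numpy(),
                trial=g["trial"].to_numpy(),
                choice=g["choice"].to_numpy(),
                outcome=g["outcome"].to_numpy(),
                p0=g["p0"].to_numpy(),
                p1=g["p1"].to_numpy(),
            )
        )
    return out


def write_trials(sequences: Sequence[TrialSequence], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sequences_to_frame(sequences).to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> list[TrialSequence]:
    return frame_to_sequences(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

PROFILES = {
    "paper": FitConfig.paper,
    "reduced": FitConfig.reduced,
    "test": FitConfig.test,
}


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_StrictModel):
    """Mirror of the factorial simulation design."""

    q0_levels: list[float] = [0.0, 0.25, 0.5, 0.75, 1.0]
    lr_pairs: list[tuple[float, float]] = [
        (0.1, 0.7), (0.2, 0.6), (0.3, 0.5), (0.4, 0.4),
        (0.5, 0.3), (0.6, 0.2), (0.7, 0.1),
    ]
    n_datasets_per_cell: int = 30
    n_subjects_per_dataset: int = 30
    beta: float = 10.0
    task: Literal["random_walk", "stable"] = "random_walk"
    condition: Literal["gain", "loss", "mixed"] = "gain"
    n_trials: int = 100
    trials_per_block: int = 32

    def build(self) -> RecoveryGridDesign:
        return RecoveryGridDesign(
            q0_levels=tuple(self.q0_levels),
            lr_pairs=tuple(tuple(p) for p in self.lr_pairs),
            n_datasets_per_cell=self.n_datasets_per_cell,
            n_subjects_per_dataset=self.n_subjects_per_dataset,
            beta=self.beta,
            task=self.task,
            condition=self.condition,
            n_trials=self.n_trials,
            trials_per_block=self.trials_per_block,
        )


class SimulateConfig(_StrictModel):
    design: DesignConfig = DesignConfig()
    seed: int = 0
    out_dir: str = "out/simulate"


class FitRunConfig(_StrictModel):
    trials: str                      # path to a trial-table CSV
    variant: str = "A-VI"
    condition: str | None = None
    profile: Literal["paper", "reduced", "test"] = "reduced"
    seed: int = 0
    out_dir: str = "out/fit"

    @field_validator("variant")
    @classmethod
    def _known_variant(cls, v: str) -> str:
        return get_variant(v).name


class CompareConfig(_StrictModel):
    trials: str
    variants: list[str] = ["A-VI", "A-FI", "S-VI", "S-FI"]
    profile: Literal["paper", "reduced", "test"] = "reduced"
    n_mc: int = 1_000_000
    seed: int = 0
    out_dir: str = "out/compare"


class RecoverConfig(_StrictModel):
    design: DesignConfig = DesignConfig(
        q0_levels=[0.0, 0.5, 1.0],
        lr_pairs=[(0.2, 0.6), (0.4, 0.4), (0.6, 0.2)],
        n_datasets_per_cell=5,
    )
    variants: list[str] = ["A-VI", "A-FI"]
    profile: Literal["paper", "reduced", "test"] = "test"
    seed: int = 0
    out_dir: str = "out/recover"


class ReportConfig(_StrictModel):
    recover_dir: str = "out/recover"  # directory produced by the recover stage
    out_dir: str = "out/report"


_CONFIG_KINDS = {
    "simulate": SimulateConfig,
    "fit": FitRunConfig,
    "compare": CompareConfig,
    "recover": RecoverConfig,
    "report": ReportConfig,
}


def load_config(path: str | Path, kind: str):
    """Load and validate a YAML/JSON config; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return _CONFIG_KINDS[kind].model_validate(data)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, stage: str, config: BaseModel,
                   outputs: Sequence[Path], extra: dict | None = None) -> Path:
    manifest = {
        "stage": stage,
        "version": _version,
        "config": config.model_dump(),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    if extra:
        manifest["extra"] = extra
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def run_simulate(config: SimulateConfig) -> list[Path]:
    """Simulate the factorial grid and write one trial table per dataset."""
    t0 = time.perf_counter()
    design = config.design.build()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    datasets = simulate_grid(design, seed=config.seed)
    paths = []
    for ds in datasets:
        name = f"sim_q{ds.cell[0]}_lr{ds.cell[1]}_d{ds.dataset}.csv"
        paths.append(write_trials(ds.sequences, out_dir / name))
    write_manifest(out_dir, "simulate", config, paths,
                   extra={"n_datasets": len(datasets), "seed": config.seed})
    log.info("simulate: %d datasets in %.1fs", len(datasets), time.perf_counter() - t0)
    return paths


def run_fit(config: FitRunConfig) -> Path:
    """Fit one variant to a trial table; write summaries and tidy draws."""
    t0 = time.perf_counter()
    seqs = read_trials(config.trials)
    fit_cfg = PROFILES[config.profile](seed=config.seed)
    post = sample_posterior(seqs, config.variant, config.condition, fit_cfg)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    summary = post.summary()
    summary.to_csv(out_dir / "summary.csv", index=False)
    outputs.append(out_dir / "summary.csv")
    post.subject_estimates().to_csv(out_dir / "subject_estimates.csv", index=False)
    outputs.append(out_dir / "subject_estimates.csv")
    post.to_tidy().to_csv(out_dir / "hyper_draws.csv", index=False)
    outputs.append(out_dir / "hyper_draws.csv")
    for w in post.warnings:
        log.warning("fit: %s", w)
    write_manifest(out_dir, "fit", config, outputs,
                   extra={"n_draws": post.n_draws, "converged": post.converged,
                          "wall_s": round(time.perf_counter() - t0, 2)})
    log.info("fit %s: %d draws in %.1fs", config.variant, post.n_draws,
             time.perf_counter() - t0)
    return out_dir / "summary.csv"


def run_compare(config: CompareConfig) -> Path:
    """Fit all candidate variants, rank by DIC, compute PXP."""
    t0 = time.perf_counter()
    seqs = read_trials(config.trials)
    fit_cfg = PROFILES[config.profile](seed=config.seed)
    report = comparison.compare_variants(
        seqs, config.variants, fit_cfg, n_mc=config.n_mc
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.dic_table.to_csv(out_dir / "dic_table.csv", index=False)
    (out_dir / "bms.json").write_text(json.dumps(report.bms.to_dict(), indent=2))
    for name, post in report.posteriors.items():
        for w in post.warnings:
            log.warning("compare[%s]: %s", name, w)
    write_manifest(out_dir, "compare", config,
                   [out_dir / "dic_table.csv", out_dir / "bms.json"],
                   extra={"wall_s": round(time.perf_counter() - t0, 2)})
    log.info("compare: best by DIC %s, best by PXP %s (%.1fs)",
             report.best_by_dic, report.best_by_pxp, time.perf_counter() - t0)
    return out_dir / "bms.json"


def run_recover(config: RecoverConfig) -> Path:
    """Simulate the grid, fit the requested variants, summarise biases."""
    t0 = time.perf_counter()
    design = config.design.build()
    datasets = simulate_grid(design, seed=config.seed)
    fit_cfg = PROFILES[config.profile](seed=config.seed)
    results = recovery.fit_grid(datasets, config.variants, fit_cfg)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    outputs = []
    recovery.results_table(results).to_csv(out_dir / "recovery_results.csv", index=False)
    outputs.append(out_dir / "recovery_results.csv")
    recovery.bias_curves(results).to_csv(out_dir / "bias_curves.csv", index=False)
    outputs.append(out_dir / "bias_curves.csv")

    rows = []
    cells = sorted({r.cell for r in results})
    for cell in cells:
        for vname in config.variants:
            vname = get_variant(vname).name
            if not get_variant(vname).asymmetric:
                continue
            pooled = recovery.pooled_mu_delta(results, cell, vname)
            rows.append(
                dict(cell_q0=cell[0], cell_lr=cell[1], variant=vname,
                     true_q0=pooled.true_q0, true_alpha_p=pooled.true_alpha_p,
                     true_alpha_n=pooled.true_alpha_n, median=pooled.median,
                     ci_lo=pooled.ci95[0], ci_hi=pooled.ci95[1],
                     prob_alpha_n_gt_alpha_p=pooled.prob_alpha_n_gt_alpha_p,
                     classification=pooled.classification, correct=pooled.correct)
            )
    pd.DataFrame(rows).to_csv(out_dir / "pooled_asymmetry.csv", index=False)
    outputs.append(out_dir / "pooled_asymmetry.csv")
    n_failed = sum(not r.ok for r in results)
    if n_failed:
        log.warning("recover: %d fits failed", n_failed)
    write_manifest(out_dir, "recover", config, outputs,
                   extra={"n_fits": len(results), "n_failed": n_failed,
                          "wall_s": round(time.perf_counter() - t0, 2)})
    log.info("recover: %d fits in %.1fs", len(results), time.perf_counter() - t0)
    return out_dir / "recovery_results.csv"


def run_report(config: ReportConfig) -> list[Path]:
    """Render bias curves and pooled-asymmetry summaries to figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rec_dir = Path(config.recover_dir)
    bias = pd.read_csv(rec_dir / "bias_curves.csv")
    pooled = pd.read_csv(rec_dir / "pooled_asymmetry.csv")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharex=True)
    for variant, g in bias.groupby("variant"):
        gg = g.groupby("true_q0", as_index=False)[
            ["bias_alpha_p", "bias_alpha_n", "bias_asymmetry"]
        ].mean()
        for ax, col in zip(axes, ["bias_alpha_p", "bias_alpha_n", "bias_asymmetry"]):
            ax.plot(gg["true_q0"], gg[col], marker="o", label=variant)
            ax.axhline(0.0, color="gray", lw=0.8)
            ax.set_xlabel("true $Q_0$")
            ax.set_title(col.replace("bias_", "bias: "))
    axes[0].set_ylabel("estimate − truth")
    axes[0].legend()
    fig.tight_layout()
    p = out_dir / "bias_curves.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    outputs.append(p)

    fig, ax = plt.subplots(figsize=(6, 4))
    for variant, g in pooled.groupby("variant"):
        ax.errorbar(
            g["true_q0"], g["median"],
            yerr=[g["median"] - g["ci_lo"], g["ci_hi"] - g["median"]],
            marker="o", ls="none", capsize=3, label=variant,
        )
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("true $Q_0$")
    ax.set_ylabel(r"pooled $\mu_\delta$ (median, 95% CI)")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "pooled_asymmetry.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    outputs.append(p)

    write_manifest(out_dir, "report", config, outputs)
    return outputs
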