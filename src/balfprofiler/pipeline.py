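"""End-to-end pipeline orchestration and report rendering.

``run_pipeline`` chains every stage — simulate (or load) fingerprints and
blood panels, deconvolve phenotype fractions, score severity, fit and
cross-validate the discriminant model, and quantify drug remodeling — and
writes a report bundle of delimited tables plus a manifest. Outputs are
deterministic given the config and seed: re-running with the same config is
byte-identical for all tables.

Figures (stacked composition bars, canonical scatter with decision mesh and
therapeutic vectors, confusion matrix) are optional and flag-gated so
headless runs exercise the full numeric pipeline only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconvolution import deconvolve_dataset
from .discriminant import (
    LabeledCohort,
    correlate_ld1_severity,
    decision_mesh,
    fit_lda,
    loocv,
    project,
)
from .exceptions import ValidationError
from .fingerprint import write_fingerprint_table, write_reference_basis
from .remodeling import analyze_treatments, mean_fingerprint, per_agent_tests
from .severity import score_cohort, write_blood_panel_table
from .simulate import GeneratorConfig, generate_cohort, make_treatment_pairs

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"  # fixed formatting keeps table output byte-stable


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full run; defaults reproduce the packaged demo."""

    seed: int = 42
    outdir: str = "pipeline_out"
    n_patients: int = 72
    separation: float = 4.0
    noise_sd: float = 2.0
    gamma: float = 0.1
    n_axes: int = 2
    agents: tuple[str, ...] = ("doxycycline", "mumb", "paclitaxel")
    figures: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "agents" in raw:
            raw["agents"] = tuple(raw["agents"])
        return cls(**raw)

    def canonical_json(self) -> str:
        """Analysis-relevant parameters only (paths and presentation excluded),
        so the manifest hash identifies the computation, not its location."""
        d = asdict(self)
        d["agents"] = list(d["agents"])
        for presentation_only in ("outdir", "figures", "log_level"):
            d.pop(presentation_only)
        return json.dumps(d, sort_keys=True)


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.outdir``.

    Returns a results dict with the in-memory objects (cohort, model,
    confusion matrix, remodeling tables) for further use.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gen = GeneratorConfig(
        seed=config.seed,
        n_patients=config.n_patients,
        separation=config.separation,
        noise_sd=config.noise_sd,
    )
    logger.info("simulating cohort: n=%d, seed=%d", gen.n_patients, gen.seed)
    cohort = generate_cohort(gen)
    write_fingerprint_table(cohort.fingerprints, outdir / "fingerprints.csv")
    write_reference_basis(cohort.basis, outdir / "basis.csv")
    write_blood_panel_table(cohort.panels, outdir / "panels.csv")
    _write_df(cohort.ground_truth, outdir / "ground_truth.csv")

    logger.info("deconvolving %d fingerprints", len(cohort.fingerprints))
    compositions = deconvolve_dataset(cohort.fingerprints, cohort.basis)
    _write_df(compositions, outdir / "compositions.csv")

    logger.info("scoring severity for %d panels", len(cohort.panels))
    severity = score_cohort(cohort.panels)
    _write_df(severity, outdir / "severity.csv")

    labeled = LabeledCohort(
        fingerprints=cohort.fingerprints,
        labels=cohort.labels,
        severity=cohort.severity,
    )
    logger.info("fitting discriminant model (axes=%d, gamma=%g)",
                config.n_axes, config.gamma)
    model = fit_lda(labeled, n_axes=config.n_axes, gamma=config.gamma)
    model.save(outdir / "model.json")

    projections = pd.DataFrame(
        {
            "sample_id": [f.sample_id for f in cohort.fingerprints],
            "label": list(cohort.labels),
            "severity": list(cohort.severity),
        }
    )
    coords = np.vstack([project(model, f) for f in cohort.fingerprints])
    projections["ld1"] = coords[:, 0]
    if model.n_axes > 1:
        projections["ld2"] = coords[:, 1]
    _write_df(projections, outdir / "projections.csv")

    cm = loocv(labeled, n_axes=config.n_axes, gamma=config.gamma)
    cm_df = pd.DataFrame(cm.counts, index=list(cm.classes), columns=list(cm.classes))
    cm_df.index.name = "true_class"
    cm_df.to_csv(outdir / "confusion_matrix.csv")
    logger.info("LOOCV accuracy %.2f%% (%d folds skipped)", cm.accuracy, cm.skipped_folds)

    ld1_fit = correlate_ld1_severity(coords[:, 0], cohort.severity)

    good = [f for f, l in zip(cohort.fingerprints, cohort.labels) if l == "Good"]
    poor = [f for f, l in zip(cohort.fingerprints, cohort.labels) if l == "Poor"]
    good_profile = mean_fingerprint(good)
    poor_profile = mean_fingerprint(poor)

    remodeling_tables = []
    for agent in config.agents:
        pairs = make_treatment_pairs(cohort, agent)
        remodeling_tables.append(
            analyze_treatments(
                pairs, cohort.basis, model=model,
                good_profile=good_profile, poor_profile=poor_profile,
            )
        )
    remodeling = pd.concat(remodeling_tables, ignore_index=True)
    _write_df(remodeling, outdir / "remodeling.csv")
    agent_tests = per_agent_tests(remodeling)
    _write_df(agent_tests, outdir / "agent_tests.csv")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()
        ).hexdigest(),
        "n_patients": len(cohort.fingerprints),
        "loocv_accuracy_pct": cm.accuracy,
        "loocv_skipped_folds": cm.skipped_folds,
        "ld1_severity_pearson_r": round(ld1_fit.pearson_r, 6),
        "ld1_severity_exp_r_squared": round(ld1_fit.r_squared, 6),
        "tables": sorted(p.name for p in outdir.glob("*.csv")),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )

    results = {
        "cohort": cohort,
        "compositions": compositions,
        "severity": severity,
        "model": model,
        "confusion": cm,
        "projections": projections,
        "ld1_fit": ld1_fit,
        "remodeling": remodeling,
        "agent_tests": agent_tests,
        "manifest": manifest,
    }
    if config.figures:
        render_reports(results, outdir)
    return results


def render_reports(results: dict, outdir: str | Path) -> list[Path]:
    """Render static figures from pipeline results (numbers identical to tables)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    comps = results["compositions"]
    fig, ax = plt.subplots(figsize=(max(6, 0.16 * len(comps)), 4))
    bottom = np.zeros(len(comps))
    for col, color in zip(
        ("m0_pct", "m1_pct", "m2a_pct", "residual_pct"),
        ("#e69f00", "#009e73", "#9467bd", "#f0e442"),
    ):
        ax.bar(range(len(comps)), comps[col], bottom=bottom, color=color,
               label=col.replace("_pct", "").upper())
        bottom += comps[col].to_numpy()
    ax.set_ylabel("phenotype fraction (%)")
    ax.set_xlabel("sample")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    p = outdir / "compositions.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    model = results["model"]
    proj = results["projections"]
    if model.n_axes == 2:
        fig, ax = plt.subplots(figsize=(6, 5))
        pad = 1.0
        bounds = (
            proj["ld1"].min() - pad, proj["ld1"].max() + pad,
            proj["ld2"].min() - pad, proj["ld2"].max() + pad,
        )
        xx, yy, mesh = decision_mesh(model, bounds, resolution=150)
        class_idx = {c: i for i, c in enumerate(model.classes)}
        zz = np.vectorize(class_idx.get)(mesh)
        ax.contourf(xx, yy, zz, levels=len(model.classes), alpha=0.15, cmap="RdYlGn_r")
        colors = {"Good": "#2ca02c", "Neutral": "#ff7f0e", "Poor": "#d62728"}
        for cls in model.classes:
            sel = proj["label"] == cls
            ax.scatter(proj.loc[sel, "ld1"], proj.loc[sel, "ld2"], s=18,
                       color=colors.get(cls, "gray"), label=cls)
        ax.scatter(model.centroids[:, 0], model.centroids[:, 1], marker="x",
                   s=80, color="black")
        remodeling = results["remodeling"]
        if {"ld1_intact", "ld2_intact"}.issubset(remodeling.columns):
            sub = remodeling.head(20)
            ax.quiver(
                sub["ld1_intact"], sub["ld2_intact"],
                sub["ld1_treated"] - sub["ld1_intact"],
                sub["ld2_treated"] - sub["ld2_intact"],
                angles="xy", scale_units="xy", scale=1, width=0.003, alpha=0.5,
            )
        ax.set_xlabel("LD1 (higher = worse)")
        ax.set_ylabel("LD2")
        ax.legend()
        fig.tight_layout()
        p = outdir / "canonical_space.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    cm = results["confusion"]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.classes)), cm.classes)
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    ax.set_title(f"LOOCV accuracy {cm.accuracy:.2f}%")
    fig.colorbar(im)
    fig.tight_layout()
    p = outdir / "confusion_matrix.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
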