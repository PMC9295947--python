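"""End-to-end orchestration: simulate -> map -> fit -> score -> roc -> report.

A single :class:`RunConfig` (optionally loaded from YAML/JSON) drives the
full analysis: cohort simulation, optional phantom relaxometry, per-group
model selection, normative scoring against the UN reference, group
statistics, and windowed ROC evaluation.  Every stage writes a
machine-readable artifact under the output directory and the run finishes
with a ``report.json`` that validates against the schema shipped with the
package.  All randomness flows from the single run seed, so a fixed config
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import reference as ref
from .discrimination import windowed_roc
from .growth import (GestationalFit, band_separation, cohort_rate_pairs,
                     fit_rate_model, select_model_bic)
from .relaxometry import map_t2star, placental_volume, write_multiecho_nifti, write_t2star_map
from .scoring import GA_WINDOW_LABELS, cohens_d, group_stats, ks_test, score_cohort
from .synthetic import (CohortConfig, PhantomConfig, simulate_cohort,
                        simulate_multiecho_phantom, write_cohort)

__all__ = ["RunConfig", "run_pipeline", "render_diagnostics", "validate_report"]

log = logging.getLogger("placenorm")

DEFAULT_CANDIDATES = ("constant", "linear", "quadratic", "cubic", "sigmoid")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    phantom: PhantomConfig | None = None
    candidate_models: tuple = DEFAULT_CANDIDATES
    windows: tuple = GA_WINDOW_LABELS
    output_dir: str = "placenorm_run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # the run seed overrides any stage-level seed so one integer
        # controls every stochastic stage
        self.cohort.seed = int(self.seed)
        if self.phantom is not None:
            self.phantom.seed = int(self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            cohort = dict(d["cohort"])
            if "ga_windows" in cohort:
                cohort["ga_windows"] = tuple(tuple(w) for w in cohort["ga_windows"])
            d["cohort"] = CohortConfig(**cohort)
        if d.get("phantom") is not None and isinstance(d["phantom"], dict):
            d["phantom"] = PhantomConfig(**d["phantom"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "phantom": self.phantom.to_dict() if self.phantom else None,
            "candidate_models": list(self.candidate_models),
            "windows": list(self.windows),
            "output_dir": str(self.output_dir),
            "seed": int(self.seed),
            "log_level": self.log_level,
        }


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kw)
            except Exception as exc:
                log.error("stage %s: FAILED: %s", name, exc)
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _fit_summary(fit: GestationalFit) -> dict:
    return {
        "form": fit.spec.form,
        "params": [float(v) for v in fit.params],
        "bse": [float(v) for v in fit.bse],
        "rms": fit.rms_residual,
        "n": int(fit.nobs),
        "bic": fit.bic,
        "converged": fit.converged,
    }


@_stage("simulate")
def _simulate(config: RunConfig, out: Path) -> pd.DataFrame:
    cohort = simulate_cohort(config.cohort)
    write_cohort(cohort, out / "cohort.csv")
    return cohort


@_stage("map-t2star")
def _phantom(config: RunConfig, out: Path) -> dict:
    volume, roi, truth = simulate_multiecho_phantom(config.phantom)
    pdir = out / "phantom"
    write_multiecho_nifti(volume, roi, pdir, truth_map=truth)
    t2_map, summary = map_t2star(volume, roi)
    write_t2star_map(t2_map, volume.voxel_dims_mm, pdir / "t2star_map.nii.gz")
    d = summary.to_dict()
    d["volume_cm3"] = placental_volume(roi, volume.voxel_dims_mm)
    d["truth_median_ms"] = float(np.median(truth[roi.mask]))
    with open(pdir / "summary.json", "w") as fh:
        json.dump(d, fh, indent=2)
    return d


@_stage("fit")
def _fit_groups(config: RunConfig, cohort: pd.DataFrame, out: Path):
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    t2_fits: dict[str, GestationalFit] = {}
    candidate_bic: dict[str, dict[str, float]] = {}
    rate_fits: dict[str, GestationalFit] = {}
    for g in ref.GROUPS:
        sub = cohort[cohort["group"] == g]
        if len(sub) <= 6:
            log.warning("group %s has %d scans; skipping fits", g, len(sub))
            continue
        best, all_fits = select_model_bic(
            sub["ga_weeks"].to_numpy(), sub["t2star_ms"].to_numpy(),
            candidates=config.candidate_models, random_state=config.seed,
        )
        t2_fits[g] = best
        candidate_bic[g] = {f: r.bic for f, r in all_fits.items()}
        best.to_json(fits_dir / f"t2star_{g}.json")
        pairs = cohort_rate_pairs(sub)
        if len(pairs) >= 10:
            rfit = fit_rate_model(pairs, random_state=config.seed)
            rate_fits[g] = rfit
            rfit.to_json(fits_dir / f"rate_{g}.json")
    if "UN" not in t2_fits:
        raise ValueError("no UN reference fit: cohort lacks uncomplicated scans")
    return t2_fits, candidate_bic, rate_fits


@_stage("score")
def _score(cohort: pd.DataFrame, reference: GestationalFit, out: Path) -> pd.DataFrame:
    scores = score_cohort(cohort, reference)
    scores.to_csv(out / "scores.csv", index=False, float_format="%.12g")
    return scores


@_stage("roc")
def _roc(config: RunConfig, scores: pd.DataFrame, out: Path) -> dict:
    rocs = windowed_roc(scores, windows=config.windows)
    payload = {k: r.to_dict() for k, r in rocs.items()}
    with open(out / "roc.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return {k: {kk: r[kk] for kk in ("auc", "j_max", "c_opt", "n_pos", "n_neg")}
            for k, r in payload.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also saved as report.json)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, str(config.log_level).upper(), logging.INFO))
    try:
        cohort = _simulate(config, out)
        phantom_summary = _phantom(config, out) if config.phantom is not None else None
        t2_fits, candidate_bic, rate_fits = _fit_groups(config, cohort, out)
        scores = _score(cohort, t2_fits["UN"], out)

        separation = {}
        for g in ("PA", "SA"):
            if g in t2_fits and t2_fits[g].converged:
                separation[f"UN_vs_{g}"] = [
                    [lo, hi] for lo, hi in band_separation(t2_fits["UN"], t2_fits[g])
                ]

        stats_list = [s.to_dict() for s in group_stats(scores)]
        comparisons = {}
        z_by_group = {g: scores.loc[scores["group"] == g, "z"].to_numpy()
                      for g in scores["group"].unique()}
        for a, b in (("UN", "PA"), ("UN", "SA"), ("PA", "SA")):
            if a in z_by_group and b in z_by_group and \
                    len(z_by_group[a]) >= 2 and len(z_by_group[b]) >= 2:
                d_stat, p = ks_test(z_by_group[a], z_by_group[b])
                comparisons[f"{a}_vs_{b}"] = {
                    "ks_D": d_stat, "ks_p": p,
                    "cohens_d": cohens_d(z_by_group[a], z_by_group[b]),
                }

        try:
            roc_summary = _roc(config, scores, out)
        except StageError as exc:
            log.warning("ROC stage skipped: %s", exc)
            warnings.warn(f"ROC stage skipped: {exc}", stacklevel=2)
            roc_summary = {}

        report = {
            "version": __version__,
            "seed": int(config.seed),
            "config": config.to_dict(),
            "artifacts": {
                "cohort": "cohort.csv",
                "fits": "fits",
                "scores": "scores.csv",
                "roc": "roc.json" if roc_summary else None,
                "log": "run.log",
            },
            "t2star_fits": {g: _fit_summary(f) for g, f in t2_fits.items()},
            "candidate_bic": candidate_bic,
            "rate_fits": {g: _fit_summary(f) for g, f in rate_fits.items()},
            "band_separation": separation,
            "group_stats": stats_list,
            "comparisons": comparisons,
            "roc": roc_summary,
        }
        if phantom_summary is not None:
            report["phantom"] = phantom_summary
        validate_report(report)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


# -- report schema ---------------------------------------------------------

_TYPES = {"object": dict, "array": list, "string": str, "integer": int, "number": (int, float)}


def load_report_schema() -> dict:
    with resources.files("placenorm").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Check the report against the shipped schema (required keys + types)."""
    schema = schema or load_report_schema()
    if not isinstance(report, _TYPES[schema["type"]]):
        raise ValueError(f"report must be {schema['type']}")
    for key in schema.get("required", []):
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key in report and report[key] is not None:
            if not isinstance(report[key], _TYPES[sub["type"]]):
                raise ValueError(f"report key {key!r} must be {sub['type']}")


# -- diagnostics -----------------------------------------------------------

def render_diagnostics(report: dict, out_dir) -> list[str]:
    """Render basic diagnostic plots from a run's artifacts.

    Produces a scatter-plus-band plot per fitted group, the percentile
    histogram bar chart, and the ROC polyline plot.  Plot failures are
    logged, never fatal.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .scoring import PERCENTILE_BIN_EDGES, percentile_histogram
    from .synthetic import read_cohort

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_dir = Path(report["config"]["output_dir"])
    written: list[str] = []

    try:
        cohort = read_cohort(run_dir / report["artifacts"]["cohort"])
        for g in report["t2star_fits"]:
            fit = GestationalFit.from_json(run_dir / "fits" / f"t2star_{g}.json")
            band = fit.confidence_band()
            sub = cohort[cohort["group"] == g]
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(sub["ga_weeks"], sub["t2star_ms"], ".", ms=3, alpha=0.5)
            ax.plot(band.grid_t, band.mean, "-", lw=2)
            ax.plot(band.grid_t, band.ci_lo, "--", band.grid_t, band.ci_hi, "--", color="C1")
            ax.plot(band.grid_t, band.pi_lo, "-.", band.grid_t, band.pi_hi, "-.", color="C2")
            ax.set_xlabel("gestational age (weeks)")
            ax.set_ylabel("median placental T2* (ms)")
            ax.set_title(f"{g}: {fit.spec.form} fit with 95% CI/PI")
            path = out / f"t2star_fit_{g}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(str(path))
    except Exception as exc:  # noqa: BLE001
        log.warning("scatter/band plot failed: %s", exc)

    try:
        scores = pd.read_csv(run_dir / report["artifacts"]["scores"])
        hist = percentile_histogram(scores)
        frac = hist / hist.sum(axis=0).replace(0, 1)
        fig, ax = plt.subplots(figsize=(6, 4))
        width = 5.0 / (len(frac.columns) + 1)
        for j, g in enumerate(frac.columns):
            ax.bar(PERCENTILE_BIN_EDGES[:-1] + j * width, frac[g], width=width, label=g)
        ax.set_xlabel("T2* percentile relative to UN")
        ax.set_ylabel("fraction of scans")
        ax.legend()
        path = out / "percentile_histogram.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(str(path))
    except Exception as exc:  # noqa: BLE001
        log.warning("percentile histogram plot failed: %s", exc)

    if report.get("roc"):
        try:
            with open(run_dir / "roc.json") as fh:
                rocs = json.load(fh)
            fig, ax = plt.subplots(figsize=(5, 5))
            for name, r in rocs.items():
                fpr = 1.0 - np.asarray(r["spec"])
                order = np.argsort(fpr)
                ax.plot(fpr[order], np.asarray(r["sens"])[order],
                        label=f"{name}: AUC={r['auc']:.2f}")
            ax.plot([0, 1], [0, 1], ":", color="gray")
            ax.set_xlabel("1 - specificity")
            ax.set_ylabel("sensitivity")
            ax.legend(fontsize=8)
            path = out / "roc.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            written.append(str(path))
        except Exception as exc:  # noqa: BLE001
            log.warning("ROC plot failed: %s", exc)
    return written
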