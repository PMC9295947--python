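"""Seeded synthetic cohorts and multi-echo phantoms.

The cohort generator is a generative twin of the published reference
regressions: each subject draws an outcome group, a site, and 1-3 scans in
distinct gestational windows; median placental T2* follows the group's
sigmoid trajectory with Gaussian residuals, and maternal hemoglobin, SpO2,
placental volume and placental T1 follow their linear/constant models.

The phantom generator produces a 4D multi-echo gradient-echo signal with
mono-exponential decay over a known ground-truth T2* field inside an
ellipsoidal placental ROI, optionally with amniotic-fluid-like voxels at
very long T2* and additive Gaussian noise.

Reproducibility: one integer seed expands to per-subject substreams
(`numpy.random.SeedSequence.spawn`), so enlarging a cohort never reshuffles
earlier subjects and identical configs yield byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference as ref
from .models import evaluate_model
from .relaxometry import MultiEchoVolume, ROIMask

__all__ = [
    "CohortConfig",
    "PhantomConfig",
    "ScanRecord",
    "simulate_cohort",
    "simulate_multiecho_phantom",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "subject_id", "group", "site", "ga_weeks",
    "t2star_ms", "hb", "spo2_pct", "volume_cm3", "t1_ms",
]


@dataclass(frozen=True)
class ScanRecord:
    """One completed imaging study."""

    subject_id: str
    group: str
    site: str
    ga_weeks: float
    t2star_ms: float
    hb: float
    spo2_pct: float
    volume_cm3: float
    t1_ms: float


def _check_probs(name: str, probs, n: int) -> tuple[float, ...]:
    probs = tuple(float(p) for p in probs)
    if len(probs) != n or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError(f"{name} must be {n} nonnegative probabilities summing to 1")
    return probs


@dataclass
class CohortConfig:
    """Generative configuration for a synthetic longitudinal cohort.

    Defaults reproduce the reference study conditions: 316 subjects,
    outcome-group split 62.6/22.2/15.2% (UN/PA/SA), 1/2/3 completed scans
    with probabilities 14/20/66%, scans placed uniformly within distinct
    gestational windows 10-20 / 20-30 / 30-40 weeks, and group-specific
    trajectory models with Gaussian residuals at the published RMS values.
    """

    n_subjects: int = ref.DEFAULT_N_SUBJECTS
    group_probs: tuple[float, float, float] = ref.GROUP_PROBS
    scans_per_subject_probs: tuple[float, float, float] = ref.SCANS_PER_SUBJECT_PROBS
    ga_windows: tuple = ref.GA_WINDOWS
    window_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    site_probs: tuple[float, float] = ref.SITE_PROBS
    seed: int = 0
    group_t2star_models: dict = field(default_factory=lambda: dict(ref.T2STAR_SIGMOID))
    hb_models: dict = field(default_factory=lambda: dict(ref.HB_LINEAR))
    spo2_models: dict = field(default_factory=lambda: dict(ref.SPO2_LINEAR))
    volume_models: dict = field(default_factory=lambda: dict(ref.VOLUME_LINEAR))
    t1_models: dict = field(default_factory=lambda: dict(ref.T1_LINEAR))

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        self.group_probs = _check_probs("group_probs", self.group_probs, 3)
        self.scans_per_subject_probs = _check_probs(
            "scans_per_subject_probs", self.scans_per_subject_probs, 3)
        self.window_weights = _check_probs("window_weights", self.window_weights, 3)
        self.site_probs = _check_probs("site_probs", self.site_probs, 2)
        windows = tuple((float(a), float(b)) for a, b in self.ga_windows)
        if len(windows) != 3:
            raise ValueError("ga_windows must be three (lo, hi) intervals")
        for (a, b) in windows:
            if not (10.0 <= a < b <= 40.0):
                raise ValueError("each window must satisfy 10 <= lo < hi <= 40")
        for (_, b0), (a1, _) in zip(windows, windows[1:]):
            if a1 < b0:
                raise ValueError("windows must be non-overlapping and ordered")
        self.ga_windows = windows
        for models in (self.group_t2star_models, self.hb_models, self.spo2_models,
                       self.volume_models, self.t1_models):
            for g, (params, sd) in models.items():
                if sd < 0:
                    raise ValueError(f"residual SD for group {g} must be >= 0")

    def to_dict(self) -> dict:
        # JSON round-trip normalises tuples to lists so configs compare
        # equal after YAML/JSON serialisation
        import json
        return json.loads(json.dumps(asdict(self)))


def _linear(params, t, sd, rng):
    a, b = params
    return a + b * t + rng.normal(0.0, sd, size=np.shape(t)) if sd > 0 else a + b * np.asarray(t)


def simulate_cohort(config: CohortConfig | None = None, **overrides) -> pd.DataFrame:
    """Draw a synthetic cohort table, one row per completed scan.

    Returns a DataFrame with columns ``subject_id, group, site, ga_weeks,
    t2star_ms, hb, spo2_pct, volume_cm3, t1_ms``, sorted by subject and
    gestational age.  Deterministic for a fixed config (including seed).
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config object or keyword overrides, not both")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    width = len(str(config.n_subjects))
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        group = ref.GROUPS[rng.choice(3, p=config.group_probs)]
        site = ref.SITES[rng.choice(2, p=config.site_probs)]
        n_scans = 1 + rng.choice(3, p=config.scans_per_subject_probs)
        if n_scans == 3:
            windows = [0, 1, 2]
        elif n_scans == 2:
            windows = sorted(rng.choice(3, size=2, replace=False))
        else:
            windows = [rng.choice(3, p=config.window_weights)]
        gas = sorted(rng.uniform(*config.ga_windows[w]) for w in windows)

        t2_params, t2_sd = config.group_t2star_models[group]
        for ga in gas:
            t2 = float(evaluate_model("sigmoid", t2_params, ga))
            if t2_sd > 0:
                t2 += rng.normal(0.0, t2_sd)
            hb_p, hb_sd = config.hb_models[group]
            sp_p, sp_sd = config.spo2_models[group]
            vo_p, vo_sd = config.volume_models[group]
            t1_p, t1_sd = config.t1_models[group]
            rows.append(ScanRecord(
                subject_id=f"S{i:0{width}d}",
                group=group,
                site=site,
                ga_weeks=float(ga),
                t2star_ms=t2,
                hb=float(_linear(hb_p, ga, hb_sd, rng)),
                spo2_pct=float(_linear(sp_p, ga, sp_sd, rng)),
                volume_cm3=float(_linear(vo_p, ga, vo_sd, rng)),
                t1_ms=float(_linear(t1_p, ga, t1_sd, rng)),
            ))
    return pd.DataFrame([asdict(r) for r in rows], columns=COHORT_COLUMNS)


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with the documented column set."""
    df = pd.DataFrame(records, columns=COHORT_COLUMNS) if len(records) else \
        pd.DataFrame(columns=COHORT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, checking the required columns."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort CSV {path}: {exc}") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing required columns: {missing}")
    return df[COHORT_COLUMNS]


@dataclass
class PhantomConfig:
    """Configuration for a multi-echo phantom with known T2* ground truth.

    The placenta is an ellipsoid of ``semi_axes_vox`` voxels centred at
    ``center_vox``; its T2* field is ``t2star_ms`` plus a smooth sinusoidal
    modulation of amplitude ``modulation_amp_ms`` with a lobule-scale
    spatial period (``modulation_period_vox`` voxels, roughly 1.5-2 cm at
    the default resolution).  ``amniotic_voxels`` lists voxels assigned
    ``amniotic_t2star_ms`` (>= 250 ms) to exercise the exclusion rule.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 12)
    voxel_dims_mm: tuple[float, float, float] = ref.VOXEL_DIMS_MM
    echo_times_ms: tuple = ref.ECHO_TIMES_MS
    center_vox: tuple[float, float, float] | None = None
    semi_axes_vox: tuple[float, float, float] = (12.0, 10.0, 4.0)
    t2star_ms: float = 60.0
    modulation_amp_ms: float = 0.0
    modulation_period_vox: float = 10.0
    s0: float = 100.0
    noise_sd: float = 0.0
    amniotic_voxels: tuple = ()
    amniotic_t2star_ms: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size < 3 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.t2star_ms <= 0:
            raise ValueError("t2star_ms must be positive")
        if self.center_vox is None:
            self.center_vox = tuple((n - 1) / 2.0 for n in self.grid_shape)
        for c, a, n in zip(self.center_vox, self.semi_axes_vox, self.grid_shape):
            if a <= 0:
                raise ValueError("semi-axes must be positive")
            if c - a < -0.5 or c + a > n - 0.5:
                raise ValueError("placenta ellipsoid exceeds the phantom grid")

    def to_dict(self) -> dict:
        import json
        return json.loads(json.dumps(asdict(self)))


def simulate_multiecho_phantom(
    config: PhantomConfig | None = None, **overrides
) -> tuple[MultiEchoVolume, ROIMask, np.ndarray]:
    """Generate (signal volume, ROI mask, ground-truth T2* map).

    Signal at voxel v and echo e is ``s0 exp(-TE_e / T2*(v))`` plus
    additive Gaussian noise of SD ``noise_sd``; the mask is True exactly on
    the ellipsoid voxels.  The truth map is defined everywhere (background
    uses the base T2*) for recovery tests.
    """
    if config is None:
        config = PhantomConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config object or keyword overrides, not both")

    nx, ny, nz = config.grid_shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = config.center_vox
    ax, ay, az = config.semi_axes_vox
    mask = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    t2 = np.full(config.grid_shape, float(config.t2star_ms))
    if config.modulation_amp_ms:
        w = 2.0 * np.pi / config.modulation_period_vox
        t2 = t2 + config.modulation_amp_ms * np.sin(w * x) * np.sin(w * y) * np.sin(w * z)
        if np.any(t2 <= 0):
            raise ValueError("modulation amplitude drives T2* non-positive")
    for vox in config.amniotic_voxels:
        t2[tuple(int(c) for c in vox)] = config.amniotic_t2star_ms

    te = np.asarray(config.echo_times_ms, dtype=float)
    signal = config.s0 * np.exp(-te[None, None, None, :] / t2[..., None])
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        signal = signal + rng.normal(0.0, config.noise_sd, size=signal.shape)

    volume = MultiEchoVolume(signal, te, tuple(config.voxel_dims_mm))
    return volume, ROIMask(mask), t2
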