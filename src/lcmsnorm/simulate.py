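"""Seeded generator of LC-MS experiments with known ground-truth drift.

The generator mirrors a two-batch case/control metabolomics study with
interleaved quality-control injections: each batch contains a forward and a
reverse experiment of the same subjects (run order reversed), with 10 QC +
20 case + 25 control runs per experiment and a QC injected every 5th run.

Intensities are lognormal around a per-feature baseline:

    log x_ij = log(baseline_i) + bio_subject + group_effect + d_i(t) + eps

where the drift d_i(t) is a draw from the same Matern GP family the
normalization model fits (plus a linear trend), decomposed into a component
shared across (batch, experiment) blocks — the persistent instrument
response versus injection count, which is what the QC run-effect ANOVA
detects — and a smaller independent per-block component (the "fresh" drift
of a re-run). A misspecified drift family (sinusoid plus changepoint) is
available for robustness checks.

Scan-level EICs are Gaussian peaks whose trapezoidal area matches the
matrix intensity, with an integer retention-time jitter per sample, a
scan-dependent drift gain (drift hits the peak tails harder than the apex,
so scan-level data carry strictly more drift information than the
integrated area), and independent per-scan noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .data import EICCollection, FeatureMatrix, SampleTable
from .exceptions import ValidationError
from .gp import matern_correlation


@dataclass
class SimConfig:
    """Study design and ground-truth parameters of a simulated experiment."""

    p: int = 200
    n_qc: int = 10
    n_case: int = 20
    n_control: int = 25
    n_batches: int = 2
    experiments: tuple[str, ...] = ("F", "R")
    qc_interval: int = 5
    # drift truth (log-intensity space)
    ell_true: float = 10.0
    sigma_true: float = 0.3
    mu1_true: float = 0.002
    nu_true: float = 1.5
    shared_drift_frac: float = 0.6
    drift_family: str = "matern"  # or "misspecified"
    # sensitivity decay with injection count (source contamination), the
    # dominant smooth nonlinear drift mode of real LC-MS runs; per-feature
    # amplitude is decay_amp * Uniform(0.3, 1), time constant is
    # decay_tau_frac * block length, shared across blocks
    decay_amp: float = 0.25
    decay_tau_frac: float = 0.3
    # noise and biology (log space)
    sigma_eps_true: float = 0.03
    sigma_int: float = 0.12
    bio_sd: float = 0.2
    frac_differential: float = 0.1
    log_fc: float = float(np.log(2.0))
    # EIC shape
    n_scans: int = 15
    peak_width_scans: float = 2.5
    shift_max: int = 2
    scan_drift_gain: float = 0.5
    scan_noise: float = 0.08
    rt_per_scan: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.p, self.n_qc, self.n_case, self.n_control, self.n_batches) < 1:
            raise ValidationError("all design counts must be positive")
        if self.qc_interval < 2:
            raise ValidationError("qc_interval must be >= 2")
        if self.drift_family not in ("matern", "misspecified"):
            raise ValidationError("drift_family must be 'matern' or 'misspecified'")
        if self.seed is None:
            raise ValidationError("a seed is mandatory")

    @property
    def n_per_block(self) -> int:
        return self.n_qc + self.n_case + self.n_control

    def qc_orders(self) -> np.ndarray:
        """QC injection orders: 1, 1+interval, ... (n_qc of them)."""
        return 1 + self.qc_interval * np.arange(self.n_qc)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment."""

    config: SimConfig
    theta_true: dict[str, float]
    baseline: np.ndarray
    differential_features: list[str]
    drift: dict[tuple[str, str], np.ndarray]  # (batch, exp) -> (p, n) drift at orders 1..n
    bio_effect: dict[str, np.ndarray]  # subject -> per-feature effect
    jitter: dict[str, int] = field(default_factory=dict)  # sample -> RT shift (scans)
    extras: dict[str, Any] = field(default_factory=dict)


def sample_matern_gp(t, ell: float, sigma: float, nu: float, rng: np.random.Generator,
                     size: int = 1) -> np.ndarray:
    """Draw ``size`` zero-mean GP curves at orders t (rows are draws)."""
    t = np.asarray(t, float)
    R = matern_correlation(np.abs(t[:, None] - t[None, :]), ell, nu)
    R[np.diag_indices_from(R)] += 1e-10
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((size, len(t)))
    return sigma * (z @ L.T)


def _drift_curves(cfg: SimConfig, t: np.ndarray, rng: np.random.Generator,
                  n_blocks: int) -> np.ndarray:
    """Drift (log space) per feature and block: exponential sensitivity
    decay + shared and per-block GP wiggle + linear trend, each curve
    centred over the block. Shape (n_blocks, p, n)."""
    n = len(t)
    sh = np.sqrt(cfg.shared_drift_frac)
    idio = np.sqrt(1.0 - cfg.shared_drift_frac)
    if cfg.sigma_true == 0:
        shared = np.zeros((cfg.p, n))
        blocks = np.zeros((n_blocks, cfg.p, n))
    elif cfg.drift_family == "matern":
        shared = sample_matern_gp(t, cfg.ell_true, cfg.sigma_true * sh,
                                  cfg.nu_true, rng, size=cfg.p)
        blocks = sample_matern_gp(t, cfg.ell_true, cfg.sigma_true * idio,
                                  cfg.nu_true, rng, size=n_blocks * cfg.p
                                  ).reshape(n_blocks, cfg.p, n)
    else:  # sinusoid + changepoint: smooth but outside the Matern family
        period = rng.uniform(1.5, 3.0, cfg.p)[:, None] * cfg.ell_true
        phase = rng.uniform(0, 2 * np.pi, cfg.p)[:, None]
        shared = cfg.sigma_true * sh * np.sqrt(2.0) * np.sin(
            2 * np.pi * t[None, :] / period + phase)
        cp = rng.integers(int(0.3 * n), int(0.7 * n), size=(n_blocks, cfg.p))
        step = rng.normal(0, cfg.sigma_true * idio, size=(n_blocks, cfg.p))
        blocks = step[:, :, None] * (t[None, None, :] > cp[:, :, None])
    if cfg.decay_amp > 0:
        tau = max(cfg.decay_tau_frac * n, 1.0)
        amp = cfg.decay_amp * rng.uniform(0.3, 1.0, cfg.p)
        shared = shared - amp[:, None] * np.exp(-t[None, :] / tau)
    trend = cfg.mu1_true * (t - t.mean())[None, :]
    curves = shared[None, :, :] + blocks + trend
    # centre each curve so drift is pure order-to-order variation
    return curves - curves.mean(axis=2, keepdims=True)


def _layout(cfg: SimConfig, batch: str, exp: str) -> pd.DataFrame:
    """Sample metadata of one (batch, experiment) block."""
    n = cfg.n_per_block
    orders = np.arange(1, n + 1)
    qc_orders = set(cfg.qc_orders().tolist())
    if max(qc_orders) > n:
        raise ValidationError("QC orders exceed the block size; lower qc_interval")
    # alternate case/control over experimental slots to reduce order bias
    groups_seq = []
    nc, nk = cfg.n_case, cfg.n_control
    while nc or nk:
        if nc:
            groups_seq.append("case")
            nc -= 1
        if nk:
            groups_seq.append("control")
            nk -= 1
    subjects = [f"{batch}_subj{i + 1:03d}" for i in range(len(groups_seq))]
    if exp != cfg.experiments[0]:  # reverse run order of the same subjects
        pairs = list(zip(subjects, groups_seq))[::-1]
        subjects = [s for s, _ in pairs]
        groups_seq = [g for _, g in pairs]
    rows, k = [], 0
    for t in orders:
        if t in qc_orders:
            rows.append({"sample_id": f"{batch}_{exp}_r{t:03d}", "analysis_order": int(t),
                         "batch": batch, "experiment": exp, "group": "QC",
                         "subject": f"{batch}_pool"})
        else:
            rows.append({"sample_id": f"{batch}_{exp}_r{t:03d}", "analysis_order": int(t),
                         "batch": batch, "experiment": exp, "group": groups_seq[k],
                         "subject": subjects[k]})
            k += 1
    return pd.DataFrame(rows)


def simulate_experiment(cfg: SimConfig) -> tuple[FeatureMatrix, SampleTable, SimTruth]:
    """Generate the feature matrix, sample metadata and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    batches = [f"B{b + 1}" for b in range(cfg.n_batches)]
    meta = pd.concat(
        [_layout(cfg, b, e) for b in batches for e in cfg.experiments],
        ignore_index=True,
    )
    st = SampleTable(meta)
    n = cfg.n_per_block
    t = np.arange(1, n + 1, dtype=float)

    baseline = np.exp(rng.uniform(np.log(1e4), np.log(1e6), cfg.p))
    feature_rt = np.sort(rng.uniform(60.0, 600.0, cfg.p))
    feature_mz = rng.uniform(100.0, 1000.0, cfg.p)
    feature_ids = [f"F{i + 1:04d}" for i in range(cfg.p)]

    n_diff = int(round(cfg.frac_differential * cfg.p))
    diff_idx = rng.choice(cfg.p, size=n_diff, replace=False)
    group_eff = np.zeros(cfg.p)
    group_eff[diff_idx] = cfg.log_fc * rng.choice([-1.0, 1.0], size=n_diff)

    block_keys = [(b, e) for b in batches for e in cfg.experiments]
    curves = _drift_curves(cfg, t, rng, len(block_keys))
    drift = {key: curves[i] for i, key in enumerate(block_keys)}

    subjects = sorted(set(meta["subject"]))
    bio = {s: (np.zeros(cfg.p) if s.endswith("_pool")
               else rng.normal(0.0, cfg.bio_sd, cfg.p)) for s in subjects}

    sample_ids = meta["sample_id"].tolist()
    values = np.empty((cfg.p, len(sample_ids)))
    eps_int = np.zeros((cfg.p, len(sample_ids)))
    for j, row in meta.iterrows():
        d = drift[(row["batch"], row["experiment"])][:, row["analysis_order"] - 1]
        logx = (np.log(baseline) + bio[row["subject"]]
                + (group_eff if row["group"] == "case" else 0.0)
                + d + rng.normal(0.0, cfg.sigma_eps_true, cfg.p))
        # peak-integration (preprocessing) error: hits the integrated matrix
        # only — the raw scan-level traces are upstream of it
        eps_int[:, j] = rng.normal(0.0, cfg.sigma_int, cfg.p) if cfg.sigma_int > 0 else 0.0
        values[:, j] = np.exp(logx + eps_int[:, j])

    fm = FeatureMatrix(values, feature_ids, sample_ids, feature_rt, feature_mz)
    truth = SimTruth(
        config=cfg,
        theta_true={"ell": cfg.ell_true, "sigma": cfg.sigma_true,
                    "sigma_eps": cfg.sigma_eps_true, "mu1": cfg.mu1_true,
                    "nu": cfg.nu_true},
        baseline=baseline,
        differential_features=[feature_ids[i] for i in sorted(diff_idx)],
        drift=drift,
        bio_effect=bio,
        extras={"group_effect": group_eff, "eps_int": eps_int},
    )
    return fm, st, truth


def simulate_eics(cfg: SimConfig, fm: FeatureMatrix, st: SampleTable,
                  truth: SimTruth) -> EICCollection:
    """Scan-level EICs consistent with the simulated feature matrix.

    Per (feature, sample): a Gaussian peak over ``n_scans`` scans, shifted by
    the sample's integer RT jitter, modulated by the scan-dependent drift
    gain w(s) = 1 + gain * (s - apex)/(S/2) (drift beyond the area-level
    component) and by independent per-scan noise, then rescaled so the
    trapezoidal area equals the sample's true peak intensity — the matrix
    value before the integration-stage error ``sigma_int``, which the raw
    traces are upstream of. With ``sigma_int = 0`` the integrated trace
    reproduces the matrix exactly. Jitters are recorded in ``truth.jitter``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    meta = st.loc(fm.sample_ids)
    S = cfg.n_scans
    s_grid = np.arange(1, S + 1, dtype=float)
    s0 = (S + 1) / 2.0
    w_gain = 1.0 + cfg.scan_drift_gain * (s_grid - s0) / (S / 2.0)

    jitter = {sid: int(rng.integers(-cfg.shift_max, cfg.shift_max + 1))
              for sid in fm.sample_ids} if cfg.shift_max > 0 else dict.fromkeys(fm.sample_ids, 0)
    truth.jitter = jitter

    eps_int = truth.extras.get("eps_int")
    target = fm.values if eps_int is None else fm.values / np.exp(eps_int)
    frames = []
    for j, row in meta.iterrows():
        sid = row["sample_id"]
        d_block = truth.drift[(row["batch"], row["experiment"])]
        tord = row["analysis_order"] - 1
        shift = jitter[sid]
        phi = np.exp(-((s_grid - s0 - shift) ** 2) / (2.0 * cfg.peak_width_scans**2))
        for i, fid in enumerate(fm.feature_ids):
            d = d_block[i, tord]
            noise = rng.normal(0.0, cfg.scan_noise, S)
            y = phi * np.exp(d * (w_gain - 1.0) + noise)
            rt = fm.feature_rt[i] + (s_grid - s0) * cfg.rt_per_scan
            area = np.trapezoid(y, rt)
            y *= target[i, j] / area
            frames.append(pd.DataFrame({
                "feature_id": fid, "sample_id": sid,
                "scan_index": s_grid.astype(int), "rt": rt, "intensity": y,
            }))
    return EICCollection(pd.concat(frames, ignore_index=True))
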