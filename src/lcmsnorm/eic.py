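"""Scan-level drift correction on extracted ion chromatograms.

Instead of correcting one integrated peak area per (feature, sample), these
methods model the drift of each scan's intensity across analysis order:

* :func:`gprm_eic_normalize` fits an independent 1-D drift GP per
  (feature, scan) on the QC runs, corrects every sample's scan intensities,
  and re-integrates the EIC by the trapezoid rule to produce a corrected
  feature matrix.
* :func:`gprm_eic_2d_normalize` pools all scans of a feature in one joint
  GP over (analysis order, scan) with a separable Matern product kernel and
  independent scales along the two axes.

Both require the traces to be aligned first (:func:`align_first_peak`):
retention-time jitter shifts peak apexes between samples, and scan-wise
modelling only makes sense once scan s means the same chromatographic
position in every sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MIN_QC_FIT, EICCollection, FeatureMatrix, SampleTable
from .exceptions import ConvergenceError, DegenerateDataError, ValidationError
from .gp import (
    FitConfig,
    GPDriftModel2D,
    KernelSpec,
    _from_working,
    _to_working,
    estimate_sample_scale_1d,
    fit_gprm,
)
from .results import NormalizationResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


def integrate_eic(trace: pd.DataFrame) -> float:
    """Trapezoidal area under an EIC trace (intensity versus RT in seconds)."""
    if len(trace) < 2:
        raise ValidationError("EIC integration needs at least 2 scans")
    rt = trace["rt"].to_numpy(float)
    y = trace["intensity"].to_numpy(float)
    ok = np.isfinite(y) & np.isfinite(rt)
    if ok.sum() < 2:
        raise ValidationError("EIC integration needs at least 2 finite scans")
    return float(np.trapezoid(y[ok], rt[ok]))


# ---------------------------------------------------------------------------
# First-peak alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedEIC:
    """EIC collection on a common scan frame plus the applied integer shifts."""

    table: pd.DataFrame
    shifts: pd.DataFrame  # feature_id, sample_id, shift_scans, apex_scan
    excluded: list[tuple[str, str]] = field(default_factory=list)


def _first_apex(y: np.ndarray, frac: float) -> int | None:
    """Index of the first interior local maximum above frac * max(y).

    Detection runs on a 3-point moving average so that single-scan noise
    spikes on a peak flank are not mistaken for the apex; the returned index
    refers to the original trace.
    """
    if len(y) < 3 or not np.isfinite(y).all() or y.max() <= 0:
        return None
    ys = y.copy()
    ys[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    thr = frac * ys.max()
    for i in range(1, len(ys) - 1):
        if ys[i] >= ys[i - 1] and ys[i] >= ys[i + 1] and ys[i] >= thr:
            return i
    return None


def align_first_peak(eics: EICCollection, apex_frac: float = 0.5) -> AlignedEIC:
    """Shift traces by whole scans so peak apexes coincide per feature.

    The apex of a trace is its first interior local maximum above
    ``apex_frac`` of the trace maximum; every trace is shifted by an integer
    number of scans so its apex lands on the per-feature median apex scan.
    Scans shifted outside the feature's frame are dropped and logged; traces
    without a detectable apex (e.g. pure noise) are excluded.
    """
    parts, shift_rows, excluded = [], [], []
    for fid, fgrp in eics.table.groupby("feature_id", sort=True):
        apexes = {}
        for sid, tgrp in fgrp.groupby("sample_id", sort=True):
            idx = _first_apex(tgrp["intensity"].to_numpy(), apex_frac)
            if idx is None:
                excluded.append((fid, sid))
                logger.warning("trace (%s, %s): no apex above %.0f%% of max; excluded",
                               fid, sid, 100 * apex_frac)
                continue
            apexes[sid] = int(tgrp["scan_index"].to_numpy()[idx])
        if not apexes:
            continue
        target = int(np.median(sorted(apexes.values())))
        lo = int(fgrp["scan_index"].min())
        hi = int(fgrp["scan_index"].max())
        for sid, apex in apexes.items():
            shift = target - apex
            tgrp = fgrp[fgrp["sample_id"] == sid].copy()
            tgrp["scan_index"] = tgrp["scan_index"] + shift
            n_before = len(tgrp)
            tgrp = tgrp[(tgrp["scan_index"] >= lo) & (tgrp["scan_index"] <= hi)]
            if len(tgrp) < n_before:
                logger.info("trace (%s, %s): %d scan(s) shifted out of frame",
                            fid, sid, n_before - len(tgrp))
            parts.append(tgrp)
            shift_rows.append({"feature_id": fid, "sample_id": sid,
                               "shift_scans": shift, "apex_scan": apex})
    if not parts:
        raise DegenerateDataError("no trace has a detectable apex; nothing to align")
    table = pd.concat(parts, ignore_index=True).sort_values(
        ["feature_id", "sample_id", "scan_index"], kind="stable"
    ).reset_index(drop=True)
    return AlignedEIC(table, pd.DataFrame(shift_rows), excluded)


# ---------------------------------------------------------------------------
# Shared machinery for the two EIC normalizers
# ---------------------------------------------------------------------------


def _feature_grids(table: pd.DataFrame):
    """Yield (feature_id, intensity pivot, rt pivot) with scans x samples."""
    for fid, grp in table.groupby("feature_id", sort=True):
        inten = grp.pivot_table(index="scan_index", columns="sample_id",
                                values="intensity", aggfunc="first")
        rt = grp.pivot_table(index="scan_index", columns="sample_id",
                             values="rt", aggfunc="first")
        yield fid, inten, rt


def _areas_from_grid(inten: pd.DataFrame, rt: pd.DataFrame, sample_ids) -> np.ndarray:
    areas = np.full(len(sample_ids), np.nan)
    for j, sid in enumerate(sample_ids):
        if sid not in inten.columns:
            continue
        y = inten[sid].to_numpy(float)
        r = rt[sid].to_numpy(float)
        ok = np.isfinite(y) & np.isfinite(r)
        if ok.sum() >= 2:
            areas[j] = float(np.trapezoid(y[ok], r[ok]))
    return areas


def _finish(fm_values, raw_areas, feature_ids, sample_ids, factors, tag, params,
            failed, shifts) -> NormalizationResult:
    matrix = FeatureMatrix(fm_values, feature_ids, sample_ids)
    corr_int = pd.DataFrame(raw_areas - fm_values, index=feature_ids, columns=sample_ids)
    return NormalizationResult(
        matrix=matrix, factors=factors, method_tag=tag, parameters=params,
        failed_features=sorted(set(failed)),
        extras={"correction_integral": corr_int, "shifts": shifts},
    )


def _ell_floor_from_areas(areas, orders, qc_mask, kernel, config):
    """One ell_S per feature, estimated from experimental-sample areas."""
    if not config.regularize:
        return None
    x = np.log1p(areas[~qc_mask]) if config.working_space == "log" else areas[~qc_mask]
    ok = np.isfinite(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_sample_scale_1d(x[ok], orders[~qc_mask][ok], kernel, config)


# ---------------------------------------------------------------------------
# 1-D per-scan normalizer
# ---------------------------------------------------------------------------


def gprm_eic_normalize(eics: EICCollection | AlignedEIC, st: SampleTable,
                       kernel: KernelSpec = KernelSpec(),
                       config: FitConfig = FitConfig(),
                       apex_frac: float = 0.5) -> NormalizationResult:
    """Scan-wise GP drift correction, then trapezoidal re-integration.

    For every (feature, scan) a 1-D drift GP is fitted to the QC runs'
    intensities at that scan versus analysis order (per batch/experiment
    block) and each sample's scan intensity is corrected by the posterior
    drift's deviation from its block mean. Corrected traces are re-integrated
    into a feature matrix of areas; the per-sample correction integral
    (raw minus corrected area) is reported in
    ``result.extras["correction_integral"]``.

    Scans with fewer than 3 finite QC values pass through uncorrected;
    features where every scan fails pass through entirely and are listed.
    """
    aligned = eics if isinstance(eics, AlignedEIC) else align_first_peak(eics, apex_frac)
    meta = st.loc(sorted(aligned.table["sample_id"].unique()))
    sample_ids = meta["sample_id"].tolist()
    feature_ids = sorted(aligned.table["feature_id"].unique())
    p, n = len(feature_ids), len(sample_ids)
    out_areas = np.full((p, n), np.nan)
    raw_areas = np.full((p, n), np.nan)
    failed: list[str] = []
    blocks = list(st.blocks(sample_ids))

    for fi, (fid, inten, rt) in enumerate(_feature_grids(aligned.table)):
        raw_areas[fi] = _areas_from_grid(inten, rt, sample_ids)
        work = _to_working(inten.reindex(columns=sample_ids).to_numpy(float),
                           config.working_space)
        corrected = work.copy()
        any_scan_ok = False
        for batch, exp, cols in blocks:
            sub = meta.iloc[cols]
            t_all = sub["analysis_order"].to_numpy(float)
            qc = (sub["group"] == "QC").to_numpy()
            ell_S = _ell_floor_from_areas(raw_areas[fi, cols], t_all, qc, kernel, config)
            fits = []
            for srow in range(work.shape[0]):
                x_qc = work[srow, cols][qc]
                ok = np.isfinite(x_qc)
                if ok.sum() < MIN_QC_FIT:
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = fit_gprm(x_qc[ok], t_all[qc][ok], kernel, config, ell_S=ell_S)
                except (ConvergenceError, ValidationError, DegenerateDataError):
                    continue
                fits.append((srow, x_qc[ok], t_all[qc][ok], res))
            # moderate (sigma, sigma_eps) across the scans of this feature
            if config.moderate_noise and len(fits) >= 5:
                pool_se = float(np.median([f[3].sigma_eps for f in fits]))
                pool_sg = float(np.median([f[3].sigma for f in fits]))
                band_se = (config.moderation_band[0] * pool_se,
                           config.moderation_band[1] * pool_se) if pool_se > 0 else None
                band_sg = (0.3 * pool_sg, np.inf) if pool_sg > 0 else None
                for k, (srow, xq, tq, res) in enumerate(fits):
                    off_se = band_se is not None and not (
                        band_se[0] <= res.sigma_eps <= band_se[1])
                    off_sg = band_sg is not None and not (
                        band_sg[0] <= res.sigma <= band_sg[1])
                    if off_se or off_sg:
                        try:
                            with warnings.catch_warnings():
                                warnings.simplefilter("ignore")
                                res2 = fit_gprm(xq, tq, kernel, config, ell_S=ell_S,
                                                sigma_eps_bounds=band_se if off_se else None,
                                                sigma_bounds=band_sg if off_sg else None)
                            fits[k] = (srow, xq, tq, res2)
                        except (ConvergenceError, ValidationError,
                                DegenerateDataError):
                            pass
            for srow, _xq, _tq, res in fits:
                corr = res.correction(t_all)
                vals = corrected[srow, cols]
                fin = np.isfinite(vals)
                vals[fin] = vals[fin] - corr[fin]
                corrected[srow, cols] = vals
                any_scan_ok = True
        if not any_scan_ok:
            failed.append(fid)
            logger.warning("feature %s: every scan failed to fit; passed through", fid)
            out_areas[fi] = raw_areas[fi]
            continue
        fixed = pd.DataFrame(_from_working(corrected, config.working_space),
                             index=inten.index, columns=sample_ids)
        # keep missing cells missing
        fixed = fixed.where(np.isfinite(inten.reindex(columns=sample_ids)))
        out_areas[fi] = _areas_from_grid(fixed, rt.reindex(columns=sample_ids), sample_ids)

    params = {"nu": kernel.nu, "working_space": config.working_space,
              "restarts": config.restarts, "seed": config.seed,
              "regularize": config.regularize, "apex_frac": apex_frac}
    return _finish(out_areas, raw_areas, feature_ids, sample_ids,
                   aligned.shifts, "gprm-eic", params, failed, aligned.shifts)


# ---------------------------------------------------------------------------
# 2-D joint normalizer
# ---------------------------------------------------------------------------


def gprm_eic_2d_normalize(eics: EICCollection | AlignedEIC, st: SampleTable,
                          kernel: KernelSpec = KernelSpec(),
                          config: FitConfig = FitConfig(),
                          apex_frac: float = 0.5,
                          max_train_points: int = 2000) -> NormalizationResult:
    """Joint (order x scan) GP drift surface per feature, then re-integration.

    All QC (order, scan) points of a feature are fitted together with a
    separable Matern product kernel, pooling drift information across scans.
    When a feature's QC grid exceeds ``max_train_points``, scans are thinned
    (every k-th) with a warning before fitting; prediction still covers the
    full grid. Correction and re-integration follow the same conventions as
    the per-scan normalizer.
    """
    aligned = eics if isinstance(eics, AlignedEIC) else align_first_peak(eics, apex_frac)
    meta = st.loc(sorted(aligned.table["sample_id"].unique()))
    sample_ids = meta["sample_id"].tolist()
    feature_ids = sorted(aligned.table["feature_id"].unique())
    p, n = len(feature_ids), len(sample_ids)
    out_areas = np.full((p, n), np.nan)
    raw_areas = np.full((p, n), np.nan)
    failed: list[str] = []
    fit_rows = []
    blocks = list(st.blocks(sample_ids))

    for fi, (fid, inten, rt) in enumerate(_feature_grids(aligned.table)):
        raw_areas[fi] = _areas_from_grid(inten, rt, sample_ids)
        work = _to_working(inten.reindex(columns=sample_ids).to_numpy(float),
                           config.working_space)
        scans = inten.index.to_numpy(float)
        corrected = work.copy()
        block_ok = False
        for batch, exp, cols in blocks:
            sub = meta.iloc[cols]
            t_all = sub["analysis_order"].to_numpy(float)
            qc = (sub["group"] == "QC").to_numpy()
            qc_cols = np.asarray(cols)[qc]
            T, S = np.meshgrid(t_all[qc], scans, indexing="xy")  # scans x n_qc
            # centre each scan's QC series: the 2-D analogue of the per-scan
            # intercepts of the 1-D model — the GP then models the drift
            # surface, not the (much larger) chromatographic peak shape
            Xq_raw = work[:, qc_cols]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                scan_mean = np.nanmean(Xq_raw, axis=1, keepdims=True)
            scan_mean = np.where(np.isfinite(scan_mean), scan_mean, 0.0)
            Xq = Xq_raw - scan_mean
            ok = np.isfinite(Xq)
            scan_keep = np.ones(len(scans), bool)
            if ok.sum() > max_train_points:
                k = int(np.ceil(ok.sum() / max_train_points))
                scan_keep = np.zeros(len(scans), bool)
                scan_keep[::k] = True
                warnings.warn(
                    f"feature {fid!r}: {int(ok.sum())} QC points exceed the cap "
                    f"{max_train_points}; thinning to every {k}th scan", stacklevel=2,
                )
            sel = ok & scan_keep[:, None]
            if sel.sum() < max(MIN_QC_FIT * 2, 6):
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = GPDriftModel2D(Xq[sel], T[sel], S[sel], nu=kernel.nu,
                                           jitter=kernel.jitter)
                    res = model.fit(restarts=config.restarts, seed=config.seed,
                                    maxiter=config.maxiter, gtol=config.gtol)
            except (ConvergenceError, ValidationError, DegenerateDataError,
                    np.linalg.LinAlgError):
                continue
            # surface on the full (scan x block-sample) grid, anchored per scan
            Tq, Sq = np.meshgrid(t_all, scans, indexing="xy")
            m = res.predict(Tq.ravel(), Sq.ravel()).reshape(len(scans), len(t_all))
            corr = m - m.mean(axis=1, keepdims=True)
            vals = corrected[:, cols]
            fin = np.isfinite(vals)
            vals[fin] = vals[fin] - corr[fin]
            corrected[:, cols] = vals
            block_ok = True
            fit_rows.append({"feature_id": fid, "batch": batch, "experiment": exp,
                             "ell_t": res.params[0], "ell_s": res.params[1],
                             "sigma": res.params[2], "sigma_eps": res.params[3],
                             "mu0": res.params[4], "mu1": res.params[5],
                             "nll": res.nll})
        if not block_ok:
            failed.append(fid)
            out_areas[fi] = raw_areas[fi]
            continue
        fixed = pd.DataFrame(_from_working(corrected, config.working_space),
                             index=inten.index, columns=sample_ids)
        fixed = fixed.where(np.isfinite(inten.reindex(columns=sample_ids)))
        out_areas[fi] = _areas_from_grid(fixed, rt.reindex(columns=sample_ids), sample_ids)

    params = {"nu": kernel.nu, "working_space": config.working_space,
              "restarts": config.restarts, "seed": config.seed,
              "max_train_points": max_train_points, "apex_frac": apex_frac}
    return _finish(out_areas, raw_areas, feature_ids, sample_ids,
                   pd.DataFrame(fit_rows), "gprm-eic-2d", params, failed,
                   aligned.shifts)
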