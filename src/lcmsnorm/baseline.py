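"""The nine reviewed normalization families for LC-MS feature matrices.

Column-scaling methods (TIC, median scale, internal standards, stable
features) rescale whole samples; distribution methods (quantile) equalize
intensity distributions; pretreatment transforms rows; M-A regression
removes intensity-dependent bias in log space; QC-consistency filtering and
analysis-order LOESS use the quality-control runs. Each method returns a
:class:`~lcmsnorm.results.NormalizationResult`; missing cells (NaN) are
skipped, never treated as zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .data import FeatureMatrix, SampleTable
from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    ValidationError,
)
from .results import NormalizationResult

logger = logging.getLogger(__name__)

DEFAULT_SPAN_GRID = tuple(np.round(np.arange(0.2, 1.01, 0.1), 10))


# ---------------------------------------------------------------------------
# TIC
# ---------------------------------------------------------------------------


def tic_normalize(fm: FeatureMatrix, scope: str = "selected_ions",
                  eics=None) -> NormalizationResult:
    """Divide each sample by its total ion count, preserving overall units.

    ``scope="selected_ions"`` sums the matrix columns (the preferred choice:
    preprocessing already removed noisy ions); ``scope="all_scans"`` sums all
    scan-level intensities of the sample from ``eics``. Every column is
    divided by its total E_j and re-multiplied by the mean of all E_j, so
    column sums over selected ions are equal afterwards and the intensity
    scale is preserved.
    """
    if scope == "selected_ions":
        E = np.nansum(fm.values, axis=0)
    elif scope == "all_scans":
        if eics is None:
            raise ValidationError("scope='all_scans' requires an EICCollection")
        sums = eics.table.groupby("sample_id")["intensity"].sum()
        missing = [s for s in fm.sample_ids if s not in sums.index]
        if missing:
            raise ValidationError(f"samples without scan data: {missing}")
        E = sums.loc[fm.sample_ids].to_numpy(float)
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    zero = np.flatnonzero(E == 0)
    if zero.size:
        raise DegenerateDataError(
            f"zero total ion count for sample(s) {[fm.sample_ids[j] for j in zero]}"
        )
    scale = E / float(np.mean(E))
    out = fm.values / scale[None, :]
    factors = pd.DataFrame({"sample_id": fm.sample_ids, "tic": E, "scale": scale})
    return NormalizationResult(fm.copy_with(out), factors, "tic", {"scope": scope})


# ---------------------------------------------------------------------------
# Median scale
# ---------------------------------------------------------------------------


def _choose_reference(fm: FeatureMatrix, policy: str, st: SampleTable | None,
                      reference_id: str | None) -> int:
    n_missing = np.sum(~np.isfinite(fm.values), axis=0)
    if policy == "any_sample":
        if reference_id is not None:
            if reference_id not in fm.sample_ids:
                raise ValidationError(f"reference sample {reference_id!r} not in matrix")
            return fm.sample_ids.index(reference_id)
        return 0
    if policy == "qc_run":
        if st is None:
            raise ValidationError("reference_policy='qc_run' requires sample metadata")
        qc = st.is_qc(fm.sample_ids)
        if not qc.any():
            raise ValidationError("no QC samples for reference_policy='qc_run'")
        cand = np.flatnonzero(qc)
        return int(cand[np.argmin(n_missing[cand])])
    if policy == "min_missing":
        return int(np.argmin(n_missing))
    raise ValidationError(f"unknown reference_policy {policy!r}")


def median_scale(fm: FeatureMatrix, reference_policy: str = "min_missing",
                 st: SampleTable | None = None, reference_id: str | None = None,
                 invert: bool = False) -> NormalizationResult:
    """Scale each sample by the median ratio of its intensities to a reference.

    x_j -> x_j / median_i(x_ij / x_i*), with the reference sample chosen by
    ``reference_policy`` (a QC run, an explicit sample, or the sample with
    the fewest missing values). ``invert=True`` places the reference in the
    numerator instead (the convention differs across the literature).
    """
    ref_idx = _choose_reference(fm, reference_policy, st, reference_id)
    ref = fm.values[:, ref_idx]
    if np.mean(~np.isfinite(ref)) > 0.5:
        raise DegenerateDataError(
            f"reference sample {fm.sample_ids[ref_idx]!r} has > 50% missing values"
        )
    out = fm.values.copy()
    facs = np.ones(fm.n_samples)
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(fm.n_samples):
            ratio = fm.values[:, j] / ref if not invert else ref / fm.values[:, j]
            ok = np.isfinite(ratio)
            if not ok.any():
                raise DegenerateDataError(
                    f"no shared finite features between sample {fm.sample_ids[j]!r} and reference"
                )
            med = float(np.median(ratio[ok]))
            if med == 0 or not np.isfinite(med):
                raise DegenerateDataError(
                    f"median intensity ratio is 0/undefined for sample {fm.sample_ids[j]!r}"
                )
            facs[j] = med
            out[:, j] = fm.values[:, j] / med if not invert else fm.values[:, j] * med
    factors = pd.DataFrame({"sample_id": fm.sample_ids, "median_ratio": facs})
    return NormalizationResult(
        fm.copy_with(out), factors, "medscale",
        {"reference_policy": reference_policy, "reference": fm.sample_ids[ref_idx],
         "invert": invert},
    )


# ---------------------------------------------------------------------------
# Pretreatment (centering / scaling / transformation)
# ---------------------------------------------------------------------------

PRETREAT_METHODS = ("center", "auto", "range", "pareto", "vast", "level", "log", "sqrt")


def pretreat(fm: FeatureMatrix, method: str = "auto", log_offset: float = 0.0,
             strict_printed_form: bool = False) -> NormalizationResult:
    """Row-wise centering, scaling or transformation.

    center: x - mean; auto: (x - mean)/s; range: (x - mean)/(max - min);
    pareto: (x - mean)/sqrt(s) (``strict_printed_form=True`` divides by s
    instead); vast: (x - mean)/s * mean/s; level: (x - mean)/mean;
    log: centered natural log (zeros need ``log_offset``); sqrt: square root.

    Rows whose scale statistic is degenerate (zero spread for range/auto/
    vast) pass through unchanged with a warning and are listed in
    ``failed_features``.
    """
    if method not in PRETREAT_METHODS:
        raise ValidationError(f"unknown pretreatment {method!r}; options: {PRETREAT_METHODS}")
    X = fm.values
    enough = np.sum(np.isfinite(X), axis=1) >= 2
    if not enough.all() and method not in ("log", "sqrt"):
        raise ValidationError("every feature needs >= 2 non-missing values for row statistics")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
        rng_ = np.nanmax(X, axis=1, keepdims=True) - np.nanmin(X, axis=1, keepdims=True)
    failed: list[str] = []
    out = X.copy()

    def _flag(bad_rows):
        for i in np.flatnonzero(bad_rows.ravel()):
            failed.append(fm.feature_ids[i])
        if failed:
            warnings.warn(
                f"{len(failed)} feature(s) with degenerate scale passed through unchanged",
                stacklevel=2,
            )

    if method == "center":
        out = X - mean
    elif method == "auto":
        bad = sd == 0
        _flag(bad)
        safe = np.where(bad, 1.0, sd)
        out = np.where(bad, X, (X - mean) / safe)
    elif method == "range":
        bad = rng_ == 0
        _flag(bad)
        safe = np.where(bad, 1.0, rng_)
        out = np.where(bad, X, (X - mean) / safe)
    elif method == "pareto":
        bad = sd == 0
        _flag(bad)
        denom = sd if strict_printed_form else np.sqrt(sd)
        safe = np.where(bad, 1.0, denom)
        out = np.where(bad, X, (X - mean) / safe)
    elif method == "vast":
        bad = (sd == 0) | (mean == 0)
        _flag(bad)
        safe_sd = np.where(sd == 0, 1.0, sd)
        out = np.where(bad, X, (X - mean) / safe_sd * (mean / safe_sd))
    elif method == "level":
        bad = mean == 0
        _flag(bad)
        safe = np.where(bad, 1.0, mean)
        out = np.where(bad, X, (X - mean) / safe)
    elif method == "log":
        if np.nanmin(X) + log_offset <= 0:
            raise DegenerateDataError(
                "log pretreatment hit non-positive values; pass a positive log_offset"
            )
        lx = np.log(X + log_offset)
        out = lx - np.nanmean(lx, axis=1, keepdims=True)
    elif method == "sqrt":
        out = np.sqrt(X)

    matrix = FeatureMatrix(
        np.maximum(out, 0.0), list(fm.feature_ids), list(fm.sample_ids),
        fm.feature_rt.copy(), fm.feature_mz.copy(),
    ) if method == "sqrt" else _unchecked_matrix(fm, out)
    stats = pd.DataFrame({
        "feature_id": fm.feature_ids, "mean": mean.ravel(), "sd": sd.ravel(),
        "range": rng_.ravel(),
    })
    return NormalizationResult(matrix, stats, f"pretreat:{method}",
                               {"method": method, "log_offset": log_offset,
                                "strict_printed_form": strict_printed_form},
                               failed_features=failed)


def _unchecked_matrix(fm: FeatureMatrix, values: np.ndarray) -> FeatureMatrix:
    """Pretreated values may legitimately be negative (centered/scaled space);
    bypass the non-negativity check while keeping ids/annotations."""
    m = object.__new__(FeatureMatrix)
    m.values = np.asarray(values, float)
    m.feature_ids = list(fm.feature_ids)
    m.sample_ids = list(fm.sample_ids)
    m.feature_rt = fm.feature_rt.copy()
    m.feature_mz = fm.feature_mz.copy()
    return m


# ---------------------------------------------------------------------------
# Internal standards
# ---------------------------------------------------------------------------


def internal_standard_normalize(
    fm: FeatureMatrix, standard_ids: list[str], mode: str = "single",
    st: SampleTable | None = None, reference_id: str | None = None,
    distance: str = "rt", mz_scale: float = 100.0,
    correlation_warn: float = 0.9,
) -> NormalizationResult:
    """Normalize against spiked-in internal standards of known concentration.

    single: every sample is scaled by (standard intensity in the reference) /
    (standard intensity in the sample), using the first standard.
    nearest: each feature is assigned its closest standard — RT distance in
    seconds by default, or scaled Euclidean on (RT, m/z) with
    ``distance="rt_mz"`` — and scaled cell-wise by that standard's ratio.
    regression: a linear model of the standards' mean log intensity versus
    analysis order gives a per-sample correction factor (requires metadata).

    A warning is raised for features highly correlated with their standard,
    where standard-based scaling is not meaningful.
    """
    for sid in standard_ids:
        if sid not in fm.feature_ids:
            raise ValidationError(f"standard {sid!r} not present in the matrix")
    std_rows = np.array([fm.feature_ids.index(s) for s in standard_ids])
    S = fm.values[std_rows, :]
    if not np.isfinite(S).all():
        bad = [standard_ids[i] for i in np.unique(np.argwhere(~np.isfinite(S))[:, 0])]
        raise ValidationError(f"standards with missing values: {bad}")
    if (S <= 0).any():
        raise ValidationError("standards must have strictly positive intensities")

    ref_idx = _choose_reference(fm, "any_sample" if reference_id else "min_missing",
                                st, reference_id)
    out = fm.values.copy()
    params = {"mode": mode, "standards": list(standard_ids),
              "reference": fm.sample_ids[ref_idx], "distance": distance}

    if mode == "single":
        std = S[0]
        ratio = std[ref_idx] / std
        out = fm.values * ratio[None, :]
        factors = pd.DataFrame({"sample_id": fm.sample_ids, "scale": ratio})
        assign = np.zeros(fm.n_features, dtype=int)
    elif mode == "nearest":
        if distance == "rt":
            d = np.abs(fm.feature_rt[:, None] - fm.feature_rt[std_rows][None, :])
        elif distance == "rt_mz":
            drt = fm.feature_rt[:, None] - fm.feature_rt[std_rows][None, :]
            dmz = (fm.feature_mz[:, None] - fm.feature_mz[std_rows][None, :]) * mz_scale
            d = np.hypot(drt, dmz)
        else:
            raise ValidationError(f"unknown distance {distance!r}")
        assign = np.argmin(d, axis=1)
        ratio = S[:, ref_idx][:, None] / S  # (n_std, n_samples)
        out = fm.values * ratio[assign, :]
        factors = pd.DataFrame({"feature_id": fm.feature_ids,
                                "standard": [standard_ids[a] for a in assign]})
    elif mode == "regression":
        if st is None:
            raise ValidationError("mode='regression' requires sample metadata")
        t = st.loc(fm.sample_ids)["analysis_order"].to_numpy(float)
        y = np.mean(np.log(S), axis=0)
        X = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        scale = np.exp(fitted - fitted.mean())
        out = fm.values / scale[None, :]
        factors = pd.DataFrame({"sample_id": fm.sample_ids, "scale": scale})
        assign = np.zeros(fm.n_features, dtype=int)
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    # features strongly tracking their standard gain nothing from this scaling
    n_hi = 0
    with np.errstate(invalid="ignore"):
        for i in range(fm.n_features):
            if i in std_rows:
                continue
            x = fm.values[i]
            s = S[assign[i] if mode == "nearest" else 0]
            ok = np.isfinite(x)
            if ok.sum() < 3 or np.nanstd(x[ok]) == 0:
                continue
            r = np.corrcoef(x[ok], s[ok])[0, 1]
            if np.isfinite(r) and abs(r) > correlation_warn:
                n_hi += 1
    if n_hi:
        warnings.warn(
            f"{n_hi} feature(s) correlate with their internal standard above "
            f"{correlation_warn}; standard-based normalization is not meaningful for them",
            stacklevel=2,
        )
    return NormalizationResult(fm.copy_with(out), factors, f"istd:{mode}", params)


# ---------------------------------------------------------------------------
# Quantile
# ---------------------------------------------------------------------------


def quantile_normalize(fm: FeatureMatrix, statistic: str = "mean") -> NormalizationResult:
    """Force every sample's intensity distribution onto the common one.

    Complete columns follow the classic three-step recipe: sort each column,
    average rank-wise across columns (mean or median), and write the averages
    back in each column's original order. Ties within a column receive the
    mean of their candidate replacement values. Columns with missing values
    are ranked against their non-missing entries only and mapped through
    interpolation of the reference quantile function; missing stays missing.
    """
    if statistic not in ("mean", "median"):
        raise ValidationError("statistic must be 'mean' or 'median'")
    X = fm.values
    p, n = X.shape
    counts = np.sum(np.isfinite(X), axis=0)
    out = np.full_like(X, np.nan)

    if (counts == p).all():
        sorted_cols = np.sort(X, axis=0)
        ref = np.mean(sorted_cols, axis=1) if statistic == "mean" else np.median(sorted_cols, axis=1)
        for j in range(n):
            out[:, j] = _assign_by_rank(X[:, j], ref)
    else:
        grid = (np.arange(p) + 0.5) / p
        qfuncs = []
        for j in range(n):
            vals = np.sort(X[np.isfinite(X[:, j]), j])
            m = len(vals)
            if m == 0:
                raise DegenerateDataError(f"sample {fm.sample_ids[j]!r} is entirely missing")
            pos = (np.arange(m) + 0.5) / m
            qfuncs.append(np.interp(grid, pos, vals))
        Q = np.column_stack(qfuncs)
        ref = np.mean(Q, axis=1) if statistic == "mean" else np.median(Q, axis=1)
        for j in range(n):
            ok = np.isfinite(X[:, j])
            m = ok.sum()
            pos = (np.arange(m) + 0.5) / m
            ref_j = np.interp(pos, grid, ref)
            out[ok, j] = _assign_by_rank(X[ok, j], ref_j)

    return NormalizationResult(fm.copy_with(out), None, "quantile",
                               {"statistic": statistic})


def _assign_by_rank(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Replace values by reference quantiles at their ranks; ties get the
    mean of the reference values they span."""
    order = np.argsort(col, kind="stable")
    out = np.empty_like(col)
    out[order] = ref
    # average replacement over tied input values
    sorted_vals = col[order]
    i = 0
    m = len(col)
    while i < m:
        j = i
        while j + 1 < m and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            out[order[i:j + 1]] = np.mean(ref[i:j + 1])
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# M-A regression
# ---------------------------------------------------------------------------


def ma_normalize(fm: FeatureMatrix, regression: str = "linear",
                 reference_policy: str = "mean", reference_id: str | None = None,
                 loess_span: float = 0.3, max_iter: int = 50,
                 tol: float = 1e-6) -> NormalizationResult:
    """Remove intensity-dependent bias via regression on the M-A plot.

    Per sample j against reference k: M = log x_j - log x_k and
    A = (log x_j + log x_k)/2; the fitted trend m_hat(A) (least squares or
    LOESS) is subtracted from M, forcing the average log intensity difference
    to zero, and intensities are back-transformed. ``reference_policy``
    chooses the reference (mean/median pseudo-sample, one sample, or the
    iterated pairwise scheme run until the overall maximum intensity changes
    by less than ``tol`` relatively).
    """
    if regression not in ("linear", "loess"):
        raise ValidationError("regression must be 'linear' or 'loess'")
    X = fm.values
    if np.nanmin(X) <= 0:
        raise ValidationError("M-A normalization needs strictly positive intensities")

    def _normalize_against(Xcur, ref):
        log_ref = np.log(ref)
        out = Xcur.copy()
        for j in range(Xcur.shape[1]):
            lx = np.log(Xcur[:, j])
            m = lx - log_ref
            a = 0.5 * (lx + log_ref)
            ok = np.isfinite(m) & np.isfinite(a)
            if ok.sum() < 2:
                raise DegenerateDataError("not enough shared finite features for M-A fit")
            if regression == "linear":
                coef = np.polyfit(a[ok], m[ok], 1)
                mhat = np.polyval(coef, a)
            else:
                fitted = _lowess(m[ok], a[ok], frac=loess_span, it=0, return_sorted=True)
                mhat = np.full_like(m, np.nan)
                mhat[ok] = np.interp(a[ok], fitted[:, 0], fitted[:, 1])
            out[:, j] = np.where(ok, np.exp(lx - mhat), Xcur[:, j])
        return out

    params = {"regression": regression, "reference_policy": reference_policy,
              "loess_span": loess_span}
    if reference_policy in ("mean", "median"):
        ref = (np.nanmean(X, axis=1) if reference_policy == "mean"
               else np.nanmedian(X, axis=1))
        out = _normalize_against(X, ref)
    elif reference_policy == "sample":
        ref_idx = _choose_reference(fm, "any_sample" if reference_id else "min_missing",
                                    None, reference_id)
        params["reference"] = fm.sample_ids[ref_idx]
        out = _normalize_against(X, X[:, ref_idx])
    elif reference_policy == "pairwise":
        out = X.copy()
        prev_max = np.nanmax(out)
        for it in range(max_iter):
            out = _normalize_against(out, np.nanmean(out, axis=1))
            cur_max = np.nanmax(out)
            rel = abs(cur_max - prev_max) / max(abs(prev_max), 1e-300)
            if rel < tol:
                params["iterations"] = it + 1
                break
            prev_max = cur_max
        else:
            raise ConvergenceError(
                f"pairwise M-A did not converge in {max_iter} iterations "
                f"(last relative change of the overall maximum: {rel:.3g})"
            )
    else:
        raise ValidationError(f"unknown reference_policy {reference_policy!r}")
    return NormalizationResult(fm.copy_with(out), None, f"ma:{regression}", params)


# ---------------------------------------------------------------------------
# QC consistency filter
# ---------------------------------------------------------------------------


def _cv(values: np.ndarray, axis: int = 1) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=axis)
        sd = np.nanstd(values, axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean != 0, sd / np.abs(mean), np.nan)


def qc_consistency_filter(fm: FeatureMatrix, st: SampleTable,
                          TH1: float, TH2: float) -> NormalizationResult:
    """Keep features whose QC runs are reproducible and informative.

    A feature is retained iff CV_QC < TH1 (criterion C1, QC reproducibility)
    and CV_sample > TH2 * CV_QC (criterion C2, more variation across real
    samples than across QCs). Both CV vectors are returned in ``factors`` for
    the CV-vs-CV diagnostic plot; thresholds are data-set specific and must
    be supplied.
    """
    qc = st.is_qc(fm.sample_ids)
    if qc.sum() < 3:
        raise ValidationError("QC consistency filtering needs >= 3 QC samples")
    cv_qc = _cv(fm.values[:, qc])
    cv_s = _cv(fm.values[:, ~qc]) if (~qc).any() else np.full(fm.n_features, np.nan)
    retained = (cv_qc < TH1) & (cv_s > TH2 * cv_qc)
    retained = np.where(np.isfinite(cv_qc), retained, False).astype(bool)
    ids = [fm.feature_ids[i] for i in np.flatnonzero(retained)]
    if not ids:
        raise DegenerateDataError("no feature passes both QC-consistency criteria")
    factors = pd.DataFrame({"feature_id": fm.feature_ids, "cv_qc": cv_qc,
                            "cv_sample": cv_s, "retained": retained})
    return NormalizationResult(fm.subset_features(retained), factors, "qcfilter",
                               {"TH1": TH1, "TH2": TH2}, retained_feature_ids=ids)


# ---------------------------------------------------------------------------
# Stable features
# ---------------------------------------------------------------------------


def stable_feature_normalize(fm: FeatureMatrix, st: SampleTable | None = None,
                             T_CV: float = 0.3) -> NormalizationResult:
    """Scale samples by the median intensity of low-CV ("stable") features.

    Stability (CV_i <= T_CV) is judged on the QC runs when metadata with at
    least 3 QCs is provided, otherwise on all samples. Each sample is divided
    by its median over the stable subset and rescaled by the grand median of
    those factors, preserving overall units.
    """
    basis = "all_samples"
    values_for_cv = fm.values
    if st is not None:
        qc = st.is_qc(fm.sample_ids)
        if qc.sum() >= 3:
            values_for_cv = fm.values[:, qc]
            basis = "qc"
    cv = _cv(values_for_cv)
    stable = np.isfinite(cv) & (cv <= T_CV)
    if not stable.any():
        raise DegenerateDataError(
            f"no feature has CV <= {T_CV}; raise T_CV to obtain a stable subset"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(fm.values[stable, :], axis=0)
    if np.any(~np.isfinite(med)) or np.any(med == 0):
        raise DegenerateDataError("stable-feature median undefined for some sample")
    grand = float(np.median(med))
    out = fm.values / med[None, :] * grand
    factors = pd.DataFrame({"sample_id": fm.sample_ids, "stable_median": med,
                            "scale": med / grand})
    return NormalizationResult(
        fm.copy_with(out), factors, "stable",
        {"T_CV": T_CV, "cv_basis": basis, "n_stable": int(stable.sum())},
        retained_feature_ids=[fm.feature_ids[i] for i in np.flatnonzero(stable)],
    )


# ---------------------------------------------------------------------------
# Analysis-order LOESS
# ---------------------------------------------------------------------------


def _loess_predict(x, t, t_query, span):
    fitted = _lowess(x, t, frac=span, it=0, return_sorted=True)
    return np.interp(t_query, fitted[:, 0], fitted[:, 1])


def _loo_span(x, t, grid) -> tuple[float, dict[float, float]]:
    """Leave-one-out SSE over the span grid; returns (best span, SSE map)."""
    sse = {}
    n = len(x)
    for span in grid:
        if span * n < 2:
            continue
        err = 0.0
        usable = True
        for k in range(n):
            mask = np.arange(n) != k
            if mask.sum() < 3:
                usable = False
                break
            pred = _loess_predict(x[mask], t[mask], np.array([t[k]]), span)[0]
            if not np.isfinite(pred):
                usable = False
                break
            err += (x[k] - pred) ** 2
        if usable:
            sse[span] = err
    if not sse:
        raise DegenerateDataError("no span on the grid is usable for LOO selection")
    best = min(sse, key=lambda sp: (sse[sp], sp))
    return best, sse


def loess_order_normalize(fm: FeatureMatrix, st: SampleTable,
                          span: float | str = 0.75, qc_only: bool = True,
                          span_grid=DEFAULT_SPAN_GRID,
                          working_space: str = "log") -> NormalizationResult:
    """LOESS drift correction along analysis order, fitted on QC runs.

    Per (batch, experiment) block and feature, a locally weighted linear
    smoother of intensity versus injection order is fitted on the QC runs
    (all samples when ``qc_only=False``) and its deviation from its mean over
    all orders is subtracted, in the working space (log1p by default). With
    ``span="cv"`` the span is chosen per feature by leave-one-out
    cross-validation over ``span_grid``.
    """
    if working_space not in ("log", "raw"):
        raise ValidationError("working_space must be 'log' or 'raw'")
    work = np.log1p(fm.values) if working_space == "log" else fm.values.copy()
    out = work.copy()
    meta = st.loc(fm.sample_ids)
    chosen = []
    failed: list[str] = []
    for batch, exp, cols in st.blocks(fm.sample_ids):
        sub = meta.iloc[cols]
        t_all = sub["analysis_order"].to_numpy(float)
        fit_mask = (sub["group"] == "QC").to_numpy() if qc_only else np.ones(len(sub), bool)
        min_needed = 4 if span == "cv" else 3
        for i, fid in enumerate(fm.feature_ids):
            xf = work[i, cols][fit_mask]
            tf = t_all[fit_mask]
            ok = np.isfinite(xf)
            if ok.sum() < min_needed:
                raise DegenerateDataError(
                    f"feature {fid!r} block ({batch},{exp}): {int(ok.sum())} fit points "
                    f"< minimum {min_needed} for the requested span setting"
                )
            xf, tf = xf[ok], tf[ok]
            if span == "cv":
                sp, _ = _loo_span(xf, tf, span_grid)
            else:
                sp = float(span)
                if sp * len(xf) < 2:
                    raise DegenerateDataError(
                        f"span {sp} covers < 2 of the {len(xf)} fit points"
                    )
            curve = _loess_predict(xf, tf, t_all, sp)
            corr = curve - float(np.mean(curve))
            vals = out[i, cols]
            finite = np.isfinite(vals)
            vals[finite] = vals[finite] - corr[finite]
            out[i, cols] = vals
            chosen.append({"feature_id": fid, "batch": batch, "experiment": exp,
                           "span": sp})
    back = np.maximum(np.expm1(out), 0.0) if working_space == "log" else np.maximum(out, 0.0)
    return NormalizationResult(
        fm.copy_with(back), pd.DataFrame(chosen), "loess",
        {"span": span, "qc_only": qc_only, "working_space": working_space,
         "span_grid": list(span_grid)},
        failed_features=failed,
    )
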