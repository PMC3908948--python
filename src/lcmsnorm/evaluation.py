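"""Evaluation framework for ranking normalization methods.

A normalization method is judged by how reproducible it makes the
quality-control (QC) runs and by how many case/control differences survive
multiple-testing correction:

* :func:`cv_per_feature` — coefficient of variation sigma/|mu| per feature
  within a sample group.
* :func:`qc_anova` — per-feature two-way additive ANOVA of QC intensities on
  (replicate block, QC run position); the F test on the run effect asks
  whether a feature still carries injection-order structure. The fraction of
  features with run-effect q < 0.1 is the primary ranking metric.
* :func:`case_control_anova` — feature-wise group comparison: a repeated-
  measures layout pairing forward/reverse runs of the same subjects within a
  batch, or an independent two-way layout across batches. Features with a
  significant group x batch interaction are screened out before counting
  group-significant ions.
* :func:`storey_qvalues` — FDR-adjusted p-values with the pi0 estimate
  pi0_hat = #{p > lambda} / (m (1 - lambda)).

ANOVAs are computed from explicit sums of squares (vectorized across
features) for balanced / proportional designs, which is exactly the F-ratio
prescription of the classical decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import FeatureMatrix, SampleTable
from .exceptions import DegenerateDataError, ValidationError

Q_SIG = 0.1  # significance threshold used throughout, as is conventional


# ---------------------------------------------------------------------------
# CV
# ---------------------------------------------------------------------------


def cv_per_feature(fm: FeatureMatrix, st: SampleTable, group: str = "QC") -> pd.Series:
    """Coefficient of variation sigma/|mu| per feature within one group.

    ``group`` is one of case/control/QC or "all". Features with zero mean
    get NaN with a warning.
    """
    if group == "all":
        cols = np.ones(fm.n_samples, bool)
    else:
        meta = st.loc(fm.sample_ids)
        cols = (meta["group"] == group).to_numpy()
    if cols.sum() < 2:
        raise ValidationError(f"need >= 2 samples in group {group!r} for a CV")
    vals = fm.values[:, cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu != 0, sd / np.abs(mu), np.nan)
    n_zero = int(np.sum(mu == 0))
    if n_zero:
        warnings.warn(f"{n_zero} feature(s) with zero mean: CV undefined", stacklevel=2)
    return pd.Series(cv, index=fm.feature_ids, name=f"cv_{group}")


def cv_summary(cv: pd.Series, threshold: float = 0.3) -> dict:
    """Median CV and the count of features below a threshold."""
    ok = cv.dropna()
    return {"median_cv": float(ok.median()) if len(ok) else np.nan,
            "n_below_threshold": int((ok < threshold).sum()),
            "threshold": threshold, "n_features": int(len(cv))}


# ---------------------------------------------------------------------------
# ANOVA containers
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Per-feature sums of squares, F statistics and p-values for one model."""

    table: pd.DataFrame  # one row per feature
    df: dict[str, int]
    tag: str
    notes: list[str] = field(default_factory=list)


def _working(values: np.ndarray, log_transform: bool) -> np.ndarray:
    return np.log1p(values) if log_transform else values


# ---------------------------------------------------------------------------
# QC ANOVA (replicate block x run position)
# ---------------------------------------------------------------------------


def qc_anova(fm: FeatureMatrix, st: SampleTable, log_transform: bool = True) -> AnovaResult:
    """Two-way additive ANOVA of QC intensities on block and run position.

    QC runs are grouped into replicate blocks (batch x experiment) and
    indexed by their run position (rank of analysis order) within the block;
    the design must be balanced (equal QC count per block). Per feature the
    decomposition x_jk = mu + alpha_j (block) + zeta_k (run) + eps_jk gives
    F_zeta = MS_run / MS_err; a significant F means the feature still tracks
    injection order after normalization. Features with missing QC values are
    reported as NaN. With a single block the run effect is confounded with
    error; the result is flagged and F is undefined.
    """
    meta = st.loc(fm.sample_ids)
    qc = meta[meta["group"] == "QC"].copy()
    if qc.empty:
        raise ValidationError("no QC samples for the QC ANOVA")
    qc["block"] = qc["batch"] + "/" + qc["experiment"]
    counts = qc.groupby("block").size()
    if counts.nunique() != 1:
        raise ValidationError(f"unbalanced QC design: runs per block = {dict(counts)}")
    K = int(counts.iloc[0])
    blocks = sorted(qc["block"].unique())
    J = len(blocks)
    if K < 2:
        raise ValidationError("need >= 2 QC runs per block")

    col_of = {s: i for i, s in enumerate(fm.sample_ids)}
    D = np.full((fm.n_features, J, K), np.nan)
    for j, b in enumerate(blocks):
        sub = qc[qc["block"] == b].sort_values("analysis_order")
        for k, sid in enumerate(sub["sample_id"]):
            D[:, j, k] = fm.values[:, col_of[sid]]
    D = _working(D, log_transform)

    notes = []
    if J == 1:
        notes.append("single replicate block: run effect confounded with error")
        table = pd.DataFrame({"feature_id": fm.feature_ids,
                              "ss_block": np.nan, "ss_run": np.nan, "ss_err": np.nan,
                              "F_zeta": np.nan, "p_zeta": np.nan})
        return AnovaResult(table, {"run": K - 1, "err": 0}, "eq20_oneway_degenerate", notes)

    complete = np.isfinite(D).all(axis=(1, 2))
    grand = np.nanmean(D, axis=(1, 2))
    mb = np.nanmean(D, axis=2)  # (p, J)
    mr = np.nanmean(D, axis=1)  # (p, K)
    ss_block = K * np.nansum((mb - grand[:, None]) ** 2, axis=1)
    ss_run = J * np.nansum((mr - grand[:, None]) ** 2, axis=1)
    ss_tot = np.nansum((D - grand[:, None, None]) ** 2, axis=(1, 2))
    ss_err = np.maximum(ss_tot - ss_block - ss_run, 0.0)
    df_run, df_err = K - 1, (J - 1) * (K - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_run / df_run) / (ss_err / df_err)
    p = stats.f.sf(F, df_run, df_err)
    # zero residual with zero run effect: no evidence against the null
    p = np.where(np.isnan(F) & complete, 1.0, p)
    F = np.where(np.isnan(F) & complete, 0.0, F)
    F = np.where(complete, F, np.nan)
    p = np.where(complete, p, np.nan)
    if (~complete).any():
        notes.append(f"{int((~complete).sum())} feature(s) with missing QC values: NaN")
    table = pd.DataFrame({"feature_id": fm.feature_ids, "ss_block": ss_block,
                          "ss_run": ss_run, "ss_err": ss_err, "F_zeta": F, "p_zeta": p})
    return AnovaResult(table, {"block": J - 1, "run": df_run, "err": df_err},
                       "eq20", notes)


# ---------------------------------------------------------------------------
# Case / control ANOVAs
# ---------------------------------------------------------------------------


def case_control_anova(fm: FeatureMatrix, st: SampleTable, design: str,
                       batch: str | None = None, experiment: str | None = None,
                       log_transform: bool = True) -> AnovaResult:
    """Feature-wise case-versus-control ANOVA.

    design="within_batch": the forward and reverse experiments of one batch
    are combined; subjects (paired by a ``subject`` metadata column) are
    blocked, so the group effect is tested against between-subject variation
    and the group x experiment interaction against residual error.

    design="between_batch": one experiment direction across two batches with
    independent samples; classic two-way group x batch ANOVA with
    interaction. Cell counts must be proportional for the closed-form
    decomposition to be orthogonal.
    """
    meta = st.loc(fm.sample_ids)
    exp_sel = meta[meta["group"].isin(["case", "control"])].copy()
    if design == "within_batch":
        if batch is None:
            raise ValidationError("within_batch design needs a batch label")
        sub = exp_sel[exp_sel["batch"] == str(batch)]
        if "subject" not in sub.columns or sub["subject"].isna().any():
            raise ValidationError("within_batch design needs a 'subject' metadata column")
        return _within_batch_anova(fm, sub, log_transform)
    if design == "between_batch":
        sub = exp_sel if experiment is None else exp_sel[exp_sel["experiment"] == str(experiment)]
        return _between_batch_anova(fm, sub, log_transform)
    raise ValidationError(f"unknown design {design!r}")


def _col_index(fm: FeatureMatrix, sample_ids) -> np.ndarray:
    col_of = {s: i for i, s in enumerate(fm.sample_ids)}
    return np.array([col_of[s] for s in sample_ids])


def _within_batch_anova(fm: FeatureMatrix, sub: pd.DataFrame,
                        log_transform: bool) -> AnovaResult:
    exps = sorted(sub["experiment"].unique())
    if len(exps) != 2:
        raise ValidationError(f"within_batch design needs exactly 2 experiments, got {exps}")
    wide = sub.pivot_table(index=["subject", "group"], columns="experiment",
                           values="sample_id", aggfunc="first")
    unmatched = wide[wide.isna().any(axis=1)].index.get_level_values(0).tolist()
    if unmatched:
        raise ValidationError(f"unpaired subjects in within_batch design: {unmatched}")
    subjects = wide.index.get_level_values(0).to_numpy()
    groups = wide.index.get_level_values(1).to_numpy()
    L = len(subjects)
    # D: (p, L, 2)
    D = np.stack([
        fm.values[:, _col_index(fm, wide[e].tolist())] for e in exps
    ], axis=2)
    D = _working(D, log_transform)
    complete = np.isfinite(D).all(axis=(1, 2))

    glabels, ginv = np.unique(groups, return_inverse=True)
    G, E = len(glabels), 2
    n_g = np.bincount(ginv)
    N = L * E
    grand = D.mean(axis=(1, 2))
    m_subj = D.mean(axis=2)  # (p, L)
    m_exp = D.mean(axis=1)   # (p, E)
    m_g = np.stack([m_subj[:, ginv == g].mean(axis=1) for g in range(G)], axis=1)
    m_ge = np.stack([D[:, ginv == g, :].mean(axis=1) for g in range(G)], axis=1)  # (p,G,E)

    ss_group = (n_g[None, :] * E * (m_g - grand[:, None]) ** 2).sum(axis=1)
    ss_subj = E * ((m_subj - m_g[:, ginv]) ** 2).sum(axis=1)
    ss_exp = L * ((m_exp - grand[:, None]) ** 2).sum(axis=1)
    ss_int = (n_g[None, :, None] * (m_ge - m_g[:, :, None] - m_exp[:, None, :]
                                    + grand[:, None, None]) ** 2).sum(axis=(1, 2))
    ss_tot = ((D - grand[:, None, None]) ** 2).sum(axis=(1, 2))
    ss_err = np.maximum(ss_tot - ss_group - ss_subj - ss_exp - ss_int, 0.0)

    df = {"group": G - 1, "subj": L - G, "exp": E - 1,
          "interaction": (G - 1) * (E - 1), "err": (L - G) * (E - 1)}
    with np.errstate(divide="ignore", invalid="ignore"):
        F_a = (ss_group / df["group"]) / (ss_subj / df["subj"])
        F_g = (ss_int / df["interaction"]) / (ss_err / df["err"])
    p_a = stats.f.sf(F_a, df["group"], df["subj"])
    p_g = stats.f.sf(F_g, df["interaction"], df["err"])
    for arr in (F_a, F_g, p_a, p_g):
        arr[~complete] = np.nan
    table = pd.DataFrame({"feature_id": fm.feature_ids, "ss_group": ss_group,
                          "ss_subject": ss_subj, "ss_exp": ss_exp,
                          "ss_interaction": ss_int, "ss_err": ss_err,
                          "F_alpha": F_a, "p_alpha": p_a,
                          "F_gamma": F_g, "p_gamma": p_g})
    return AnovaResult(table, df, "eq21")


def _between_batch_anova(fm: FeatureMatrix, sub: pd.DataFrame,
                         log_transform: bool) -> AnovaResult:
    groups = sub["group"].to_numpy()
    batches = sub["batch"].to_numpy()
    glabels, ginv = np.unique(groups, return_inverse=True)
    blabels, binv = np.unique(batches, return_inverse=True)
    G, B = len(glabels), len(blabels)
    if G < 2 or B < 2:
        raise ValidationError("between_batch design needs >= 2 groups and >= 2 batches")
    N = len(sub)
    cell = ginv * B + binv
    n_cell = np.bincount(cell, minlength=G * B).reshape(G, B)
    if (n_cell == 0).any():
        raise ValidationError("empty group x batch cell")
    n_g = n_cell.sum(axis=1)
    n_b = n_cell.sum(axis=0)
    expected = np.outer(n_g, n_b) / N
    if not np.allclose(n_cell, expected):
        raise ValidationError(
            "non-proportional cell counts: the closed-form two-way decomposition "
            f"is not orthogonal (cells: {n_cell.tolist()})"
        )
    X = _working(fm.values[:, _col_index(fm, sub["sample_id"].tolist())], log_transform)
    complete = np.isfinite(X).all(axis=1)

    grand = X.mean(axis=1)
    m_g = np.stack([X[:, ginv == g].mean(axis=1) for g in range(G)], axis=1)
    m_b = np.stack([X[:, binv == b].mean(axis=1) for b in range(B)], axis=1)
    m_cell = np.stack([X[:, cell == c].mean(axis=1) for c in range(G * B)], axis=1)
    m_cell = m_cell.reshape(-1, G, B)

    ss_group = (n_g[None, :] * (m_g - grand[:, None]) ** 2).sum(axis=1)
    ss_batch = (n_b[None, :] * (m_b - grand[:, None]) ** 2).sum(axis=1)
    ss_int = (n_cell[None, :, :] * (m_cell - m_g[:, :, None] - m_b[:, None, :]
                                    + grand[:, None, None]) ** 2).sum(axis=(1, 2))
    ss_err = ((X - m_cell.reshape(-1, G * B)[:, cell]) ** 2).sum(axis=1)

    df = {"group": G - 1, "batch": B - 1, "interaction": (G - 1) * (B - 1),
          "err": N - G * B}
    with np.errstate(divide="ignore", invalid="ignore"):
        F_a = (ss_group / df["group"]) / (ss_err / df["err"])
        F_g = (ss_int / df["interaction"]) / (ss_err / df["err"])
    p_a = stats.f.sf(F_a, df["group"], df["err"])
    p_g = stats.f.sf(F_g, df["interaction"], df["err"])
    for arr in (F_a, F_g, p_a, p_g):
        arr[~complete] = np.nan
    table = pd.DataFrame({"feature_id": fm.feature_ids, "ss_group": ss_group,
                          "ss_batch": ss_batch, "ss_interaction": ss_int,
                          "ss_err": ss_err, "F_alpha": F_a, "p_alpha": p_a,
                          "F_gamma": F_g, "p_gamma": p_g})
    return AnovaResult(table, df, "eq22")


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def storey_qvalues(pvals, lambda_: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """FDR q-values with Storey's pi0 estimate at a single lambda.

    pi0_hat = #{p > lambda} / (m (1 - lambda)), clipped to (0, 1]; then
    q_(i) = min_{j >= i} pi0_hat * m * p_(j) / j on the sorted p-values.
    Forcing ``pi0=1`` recovers Benjamini-Hochberg exactly. NaN p-values
    propagate to NaN q-values and do not enter the estimate.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    ok = np.isfinite(p)
    if not ok.any():
        raise ValidationError("all p-values are NaN")
    pv = p[ok]
    if pv.min() < 0 or pv.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    if not (0 <= lambda_ < 1):
        raise ValidationError("lambda must lie in [0, 1)")
    m = pv.size
    if pi0 is None:
        pi0 = np.count_nonzero(pv > lambda_) / (m * (1.0 - lambda_))
    pi0 = float(np.clip(pi0, 1.0 / m, 1.0)) if pi0 > 0 else 1.0 / m
    order = np.argsort(pv, kind="stable")
    q_sorted = pi0 * m * pv[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    out = np.full(p.shape, np.nan)
    out[ok] = q
    return out


def storey_pi0_smoother(pvals, lambdas=None) -> float:
    """Automatic pi0 via the cubic-smoother extrapolation to lambda -> 1."""
    p = np.asarray(pvals, float)
    p = p[np.isfinite(p)]
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    m = p.size
    pi0s = np.array([np.count_nonzero(p > lam) / (m * (1 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0s, 3)
    return float(np.clip(np.polyval(coef, 1.0), 1.0 / m, 1.0))


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-method evaluation metrics plus the per-feature statistics."""

    summary: pd.DataFrame  # one row per method
    per_feature: dict[str, pd.DataFrame]

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "report.tsv", sep="\t", index=False)
        for method, tab in self.per_feature.items():
            tab.to_csv(out / f"per_feature_{method}.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            self.summary.to_json(orient="records", indent=2)
        )


def qc_significance_fraction(fm: FeatureMatrix, st: SampleTable,
                             lambda_: float = 0.5, log_transform: bool = True) -> float:
    """Fraction of features with run-effect q < 0.1 in the QC ANOVA."""
    res = qc_anova(fm, st, log_transform=log_transform)
    pz = res.table["p_zeta"].to_numpy()
    if not np.isfinite(pz).any():
        return np.nan
    q = storey_qvalues(pz, lambda_=lambda_)
    ok = np.isfinite(q)
    return float(np.mean(q[ok] < Q_SIG))


def significant_ion_count(fm: FeatureMatrix, st: SampleTable,
                          lambda_: float = 0.5, log_transform: bool = True) -> int:
    """Case/control ions with q_alpha <= 0.1 in every batch, after removing
    features with a significant group x experiment interaction (q_gamma < 0.1).

    Batches are analyzed separately with the paired within-batch model when
    both experiment directions and a subject column are available, otherwise
    with the independent between-batch model across batches.
    """
    meta = st.loc(fm.sample_ids)
    batches = sorted(meta.loc[meta["group"] != "QC", "batch"].unique())
    sig_sets = []
    paired_possible = ("subject" in meta.columns
                       and meta.loc[meta["group"] != "QC", "experiment"].nunique() == 2)
    if paired_possible:
        for b in batches:
            res = case_control_anova(fm, st, "within_batch", batch=b,
                                     log_transform=log_transform)
            sig_sets.append(_screened_significant(res))
    else:
        if len(batches) < 2:
            raise ValidationError("need 2 batches or paired experiments to count ions")
        res = case_control_anova(fm, st, "between_batch", log_transform=log_transform)
        sig_sets.append(_screened_significant(res))
    common = set.intersection(*sig_sets) if sig_sets else set()
    return len(common)


def _screened_significant(res: AnovaResult) -> set:
    tab = res.table
    q_gamma = storey_qvalues(tab["p_gamma"].to_numpy())
    keep = ~(q_gamma < Q_SIG)  # interaction screen applied before the group test
    pa = np.where(keep, tab["p_alpha"].to_numpy(), np.nan)
    q_alpha = storey_qvalues(pa)
    sig = np.isfinite(q_alpha) & (q_alpha <= Q_SIG)
    return set(tab.loc[sig, "feature_id"])


def evaluation_report(raw_fm: FeatureMatrix, norm_results: dict, st: SampleTable,
                      lambda_: float = 0.5, log_transform: bool = True) -> EvalReport:
    """Compare normalized matrices against the raw one.

    ``norm_results`` maps method tag -> FeatureMatrix (or NormalizationResult).
    Per method the report carries the fraction of features with significant
    QC run variation (q_zeta < 0.1), the median QC and sample CVs, and — when
    the design supports it — the count of case/control ions significant in
    every batch after the interaction screen.
    """
    methods = {"raw": raw_fm}
    for tag, r in norm_results.items():
        fmat = r.matrix if hasattr(r, "matrix") else r
        if fmat.shape != raw_fm.shape:
            raise ValidationError(
                f"method {tag!r}: shape {fmat.shape} != raw {raw_fm.shape}"
            )
        methods[tag] = fmat
    rows, per_feature = [], {}
    for tag, fmat in methods.items():
        anova = qc_anova(fmat, st, log_transform=log_transform)
        pz = anova.table["p_zeta"].to_numpy()
        qz = storey_qvalues(pz, lambda_=lambda_) if np.isfinite(pz).any() else pz
        frac = float(np.nanmean(qz < Q_SIG)) if np.isfinite(qz).any() else np.nan
        cv_qc = cv_per_feature(fmat, st, "QC")
        try:
            cv_s = cv_per_feature(fmat, st, "case")
        except ValidationError:
            cv_s = pd.Series(dtype=float)
        try:
            n_sig = significant_ion_count(fmat, st, lambda_=lambda_,
                                          log_transform=log_transform)
        except (ValidationError, DegenerateDataError):
            n_sig = np.nan
        rows.append({"method": tag,
                     "pct_qc_significant": 100.0 * frac,
                     "median_qc_cv": float(cv_qc.median()),
                     "median_case_cv": float(cv_s.median()) if len(cv_s) else np.nan,
                     "n_significant_ions": n_sig})
        tab = anova.table.copy()
        tab["q_zeta"] = qz
        tab["cv_qc"] = cv_qc.to_numpy()
        per_feature[tag] = tab
    return EvalReport(pd.DataFrame(rows), per_feature)
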