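"""Cohort-level inference for the two-arm, two-timepoint design.

Per-feature longitudinal effects are estimated with linear mixed models
(subject random intercept; fixed effects of time, optionally time x arm, and
baseline age, sex and baseline feature value), with Benjamini-Hochberg FDR
control at 0.1 across each scan. Clinical outcomes are contrasted between
arms with a change-score model adjusted for the quoted covariate list, with
optional Grubbs outlier pre-filtering; richness-clinical associations are
standardized regression coefficients; module fold changes are related to
clinical relative changes by Spearman correlation; dietary records are
screened against Harris-Benedict plausibility bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

from .diet import harris_benedict, prescribed_intake

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "feature_scan",
    "fdr_adjust",
    "grubbs_critical",
    "grubbs_outliers",
    "clinical_change_analysis",
    "richness_clinical_regression",
    "fc_clinical_correlation",
    "dietary_plausibility_filter",
]

FDR_THRESHOLD = 0.1


@dataclass
class ModelSpec:
    """Specification of the per-feature longitudinal mixed model.

    ``interaction=True`` tests the time x arm coefficient (between-group
    analysis); otherwise the pooled fixed effect of time. Covariates are
    subject-level metadata column names (default: baseline age, sex and BMI);
    ``baseline_feature=True`` additionally adjusts for the feature's own
    baseline value (warning: with only two timepoints the baseline duplicates
    the T0 response rows, which distorts the residual model).
    """

    interaction: bool = True
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    baseline_feature: bool = False
    transform: str | None = None  # None or "log" (uses half-min pseudocount)


def _scan_design(metadata: pd.DataFrame, spec: ModelSpec):
    """Shared fixed-effect design matrix for the per-feature scan."""
    cols = [np.ones(len(metadata)), metadata["time"].to_numpy(dtype=float)]
    names = ["intercept", "time"]
    if spec.interaction:
        arms = sorted(metadata["arm"].unique())
        if len(arms) != 2:
            raise ValueError("interaction model expects exactly 2 arms")
        arm_ind = (metadata["arm"] == arms[1]).to_numpy(dtype=float)
        cols += [arm_ind, arm_ind * metadata["time"].to_numpy(dtype=float)]
        names += [f"arm[{arms[1]}]", f"time:arm[{arms[1]}]"]
    for c in spec.covariates:
        v = metadata[c]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.unique())
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def feature_scan(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    spec: ModelSpec | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Fit the longitudinal mixed model per feature and FDR-adjust.

    ``features`` is features x samples; ``metadata`` is indexed by sample id
    with columns ``subject``, ``time`` (0 at baseline, 1 at follow-up),
    ``arm`` plus the spec's covariates. Features whose fit is singular or
    fails are flagged (``status`` column) and excluded from the FDR family.
    """
    spec = spec or ModelSpec()
    for c in ("subject", "time", "arm", *spec.covariates):
        if c not in metadata.columns:
            raise ValueError(f"metadata is missing column {c!r}")
    meta = metadata.loc[metadata.index.intersection(features.columns)]
    exog_base, names = _scan_design(meta, spec)
    term_idx = names.index(next(n for n in names if n.startswith("time:"))
                           if spec.interaction else "time")
    groups = meta["subject"].to_numpy()
    import warnings

    rows = []
    n_subj = meta["subject"].nunique()
    for fid, values in features.iterrows():
        y = values.reindex(meta.index).to_numpy(dtype=float)
        if spec.transform == "log":
            nz = y[y > 0]
            eps = nz.min() / 2 if nz.size else 1.0
            y = np.log(y + eps)
        exog = exog_base
        ti = term_idx
        if spec.baseline_feature:
            base = pd.Series(y, index=meta.index).groupby(groups).transform(
                lambda s: s[meta.loc[s.index, "time"] == 0].iloc[0])
            exog = np.column_stack([exog_base, base.to_numpy()])
        if np.unique(y).size <= 1:
            rows.append({"feature": fid, "estimate": np.nan, "se": np.nan,
                         "p": np.nan, "n": n_subj, "status": "singular"})
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = MixedLM(y, exog, groups=groups).fit(reml=True)
            est, se = fit.params[ti], fit.bse[ti]
            # Wald test with a t reference: at 2 timepoints the fixed-effect
            # estimate has ~ n_subjects - n_fixed residual df; the normal
            # reference is measurably liberal at cohort sizes of ~50
            df = max(n_subj - exog.shape[1], 1)
            p = 2 * stats.t.sf(abs(est / se), df) if se > 0 else np.nan
            status = "ok" if np.isfinite(p) else "singular"
        except Exception:  # noqa: BLE001 - any fit failure flags the feature
            est = se = p = np.nan
            status = "failed"
        rows.append({"feature": fid, "estimate": est, "se": se, "p": p,
                     "n": n_subj, "status": status})
    out = pd.DataFrame(rows).set_index("feature")
    ok = out["status"] == "ok"
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = fdr_adjust(out.loc[ok, "p"].to_numpy())
    out["significant"] = out["q"] < fdr_threshold
    return out


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G(n, alpha) from the t distribution."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outliers(values, alpha: float = 0.05, iterate: bool = False) -> list[int]:
    """Indices of two-sided Grubbs outliers (assumes approximate normality).

    G = max|x - mean| / sd is compared with the t-based critical value; with
    ``iterate=True`` the test repeats after removing each detected outlier
    until no further rejection.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires n >= 3")
    active = list(range(x.size))
    flagged: list[int] = []
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i = int(dev.argmax())
        g = dev[i] / sd
        if g > grubbs_critical(len(active), alpha):
            flagged.append(active.pop(i))
            if not iterate:
                break
        else:
            break
    return sorted(flagged)


def _change_table(metadata: pd.DataFrame, outcome: str) -> pd.DataFrame:
    wide = metadata.pivot_table(index="subject", columns="time", values=outcome)
    wide = wide.dropna()
    subj = metadata[metadata["time"] == 0].set_index("subject")
    out = pd.DataFrame({
        "baseline": wide[0],
        "change": wide[1] - wide[0],
    })
    return out.join(subj[[c for c in subj.columns if c not in out.columns]])


def clinical_change_analysis(
    metadata: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "sex", "bmi"),
    grubbs_prefilter: bool = False,
    grubbs_alpha: float = 0.05,
) -> dict:
    """Within-arm paired change tests and the adjusted between-arm contrast.

    The between-arm effect is the arm coefficient of the change-score linear
    model ``change ~ arm + baseline + covariates`` (+ centre when present).
    """
    for c in ("subject", "time", "arm", outcome, *covariates):
        if c not in metadata.columns:
            raise ValueError(f"metadata is missing column {c!r}")
    tbl = _change_table(metadata, outcome)
    if grubbs_prefilter:
        idx = grubbs_outliers(tbl["change"].to_numpy(), alpha=grubbs_alpha, iterate=True)
        dropped = tbl.index[idx].tolist()
        if dropped:
            logger.info("Grubbs pre-filter removed %s", dropped)
        tbl = tbl.drop(tbl.index[idx])
    within = {}
    for arm, grp in tbl.groupby("arm"):
        t, p = stats.ttest_1samp(grp["change"], 0.0)
        within[arm] = {"mean_change": grp["change"].mean(),
                       "sd_change": grp["change"].std(ddof=1),
                       "n": len(grp), "t": float(t), "p": float(p)}
    cov = ["baseline", *covariates]
    if "centre" in tbl.columns:
        cov.append("C(centre)")
    if tbl["change"].nunique() == 1:
        # degenerate: identical change scores -> contrast is exactly 0
        return {"within_arm": within, "between_arm": {"estimate": 0.0, "se": 0.0,
                "p": np.nan, "n": len(tbl)}, "table": tbl}
    fit = smf.ols(f"change ~ C(arm) + {' + '.join(cov)}", data=tbl.reset_index()).fit()
    term = next(t for t in fit.params.index if t.startswith("C(arm)"))
    return {
        "within_arm": within,
        "between_arm": {"estimate": float(fit.params[term]), "se": float(fit.bse[term]),
                        "p": float(fit.pvalues[term]), "n": len(tbl), "term": term},
        "table": tbl,
    }


def richness_clinical_regression(
    delta_richness: pd.Series,
    clinical_changes: pd.DataFrame,
    covariates: pd.DataFrame,
    statin_column: str | None = None,
    lipid_variables: tuple[str, ...] = ("cholesterol", "triglycerides"),
) -> pd.DataFrame:
    """Standardized beta of each clinical relative change on richness change.

    Both the clinical change and the richness change are z-scored, so the
    reported coefficient is unit-free; models adjust for the clinical
    variable's baseline value (column ``baseline_<var>`` of ``covariates``
    when present), baseline BMI and sex, plus statin intake for lipid
    variables when a statin column is supplied.
    """
    rows = []
    for var in clinical_changes.columns:
        df = pd.DataFrame({
            "y": clinical_changes[var],
            "x": delta_richness,
        }).join(covariates).dropna(subset=["y", "x"])
        if df["y"].std(ddof=0) == 0 or df["x"].std(ddof=0) == 0:
            rows.append({"variable": var, "beta": np.nan, "p": np.nan, "n": len(df)})
            continue
        df["y"] = (df["y"] - df["y"].mean()) / df["y"].std(ddof=0)
        df["x"] = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)
        terms = ["x"]
        if f"baseline_{var}" in covariates.columns:
            terms.append(f"baseline_{var}")
        terms += [c for c in ("bmi", "sex") if c in covariates.columns]
        if statin_column and any(k in var.lower() for k in lipid_variables):
            terms.append(statin_column)
        fit = smf.ols(f"y ~ {' + '.join(terms)}", data=df).fit()
        rows.append({"variable": var, "beta": float(fit.params["x"]),
                     "p": float(fit.pvalues["x"]), "n": len(df)})
    return pd.DataFrame(rows).set_index("variable")


def fc_clinical_correlation(
    fold_changes: pd.DataFrame,
    clinical_changes: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Spearman rho of module fold changes vs clinical relative changes.

    ``fold_changes`` is modules x subjects; ``clinical_changes`` is
    subjects x variables. BH adjustment is applied across the whole matrix;
    constant vectors yield missing correlations (excluded from the family).
    """
    subjects = fold_changes.columns.intersection(clinical_changes.index)
    rho = pd.DataFrame(index=fold_changes.index, columns=clinical_changes.columns, dtype=float)
    pval = rho.copy()
    for mod in fold_changes.index:
        x = fold_changes.loc[mod, subjects].to_numpy(dtype=float)
        for var in clinical_changes.columns:
            y = clinical_changes.loc[subjects, var].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
                continue
            r, p = stats.spearmanr(x[mask], y[mask])
            rho.loc[mod, var] = r
            pval.loc[mod, var] = p
    q = pval.copy()
    flat = pval.to_numpy().ravel()
    ok = np.isfinite(flat)
    qflat = np.full_like(flat, np.nan)
    if ok.any():
        qflat[ok] = fdr_adjust(flat[ok])
    q.iloc[:, :] = qflat.reshape(pval.shape)
    return {"rho": rho, "p": pval, "q": q}


def dietary_plausibility_filter(
    records: pd.DataFrame,
    intake_column: str = "energy_intake_kcal",
    hb_revised: bool = False,
) -> dict:
    """Screen dietary records against Harris-Benedict plausibility bounds.

    Retains subjects with 0.5*BMR <= intake <= 3*BMR (boundary values kept:
    exclusion is for strictly implausible records). Rows missing
    anthropometry are reported separately from implausible ones. Also
    returns the prescribed intake, 1.3*BMR - 600 kcal, per the intervention
    design.
    """
    need = ["weight_kg", "height_cm", "age", "sex", intake_column]
    missing_cols = [c for c in need if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing column(s) {missing_cols}")
    complete = records.dropna(subset=need)
    missing = records.index.difference(complete.index)
    if len(missing):
        logger.warning("%d record(s) missing anthropometry/intake: %s",
                       len(missing), list(missing))
    bmr = harris_benedict(complete["weight_kg"], complete["height_cm"],
                          complete["age"], complete["sex"], revised=hb_revised)
    intake = complete[intake_column].to_numpy(dtype=float)
    plausible = (intake >= 0.5 * bmr) & (intake <= 3 * bmr)
    result = complete.assign(
        bmr_kcal=bmr,
        prescribed_intake_kcal=prescribed_intake(bmr),
        plausible=plausible,
    )
    return {
        "retained": list(complete.index[plausible]),
        "implausible": list(complete.index[~plausible]),
        "missing_data": list(missing),
        "table": result,
    }
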