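"""Covariate-adjusted group contrasts of flexibility features.

Group differences are tested with ordinary least squares: the feature
(whole-brain, system or node flexibility) is regressed on a 0/1 group
indicator plus nuisance covariates (age, sex, mean framewise displacement,
imaging site), and the reported effect is the group coefficient with its
two-sided t-test.  Families of related tests (the 14 functional systems, the
three medication contrasts, or all nodes) are corrected together with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .connectivity import bh_fdr
from .errors import ConfigurationError, DegenerateModelError
from .synthetic import GROUP_ADHD, GROUP_TDC, MED_NAIVE, MED_TREATED

__all__ = [
    "GroupContrastResult",
    "fit_contrast",
    "correct_family",
    "group_contrast_table",
    "medication_contrasts",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "mean_fd", "site")


@dataclass
class GroupContrastResult:
    """One covariate-adjusted group comparison of one feature."""

    feature: str
    contrast: str
    beta: float
    se: float
    t: float
    p: float
    q: float | None = None
    n: int = 0
    family: str | None = None

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "contrast": self.contrast,
            "beta": self.beta,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "q": self.q,
            "n": self.n,
            "family": self.family,
        }


def _design_matrix(group: np.ndarray, covariates: pd.DataFrame | None) -> pd.DataFrame:
    cols = {"const": np.ones(group.size), "group": group.astype(float)}
    design = pd.DataFrame(cols)
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                design[name] = col.to_numpy(dtype=float)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
                for dname in dummies.columns:
                    design[dname] = dummies[dname].to_numpy(dtype=float)
    # covariates that do not vary in this sample carry no information
    keep = [
        c for c in design.columns
        if c in ("const", "group") or design[c].nunique() > 1
    ]
    return design[keep]


def fit_contrast(
    y,
    group,
    covariates: pd.DataFrame | None = None,
    feature: str = "feature",
    contrast: str = "case-vs-control",
) -> GroupContrastResult:
    """OLS contrast of ``y`` between the two groups coded in ``group``.

    ``group`` is a 0/1 indicator (1 = case); the returned effect is the group
    coefficient in feature units, with its two-sided t-test on residual
    degrees of freedom.  Raises :class:`DegenerateModelError` when the design
    is rank deficient, the group does not vary, or the residual variance is
    zero.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    if y.ndim != 1 or y.size != group.size:
        raise ValueError("y and group must be equal-length vectors")
    if np.unique(group).size < 2:
        raise DegenerateModelError("group indicator does not vary")
    design = _design_matrix(group, covariates)
    if y.size <= design.shape[1]:
        raise DegenerateModelError("more design columns than observations")
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DegenerateModelError("design matrix is rank deficient")
    fit = sm.OLS(y, x).fit()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if (
        fit.df_resid < 1
        or ss_tot == 0
        or fit.ssr <= 1e-12 * ss_tot
        or not np.isfinite(fit.bse[1])
    ):
        raise DegenerateModelError("zero residual variance; t-test undefined")
    return GroupContrastResult(
        feature=feature,
        contrast=contrast,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        n=int(y.size),
    )


def correct_family(
    results: list[GroupContrastResult], family: str
) -> list[GroupContrastResult]:
    """Fill in BH-FDR q-values across exactly one declared test family.

    A family is either several features under one contrast (e.g. the 14
    functional systems for ADHD-TDC) or several contrasts of one feature
    (the three medication comparisons); mixing both axes in one call is
    almost certainly an analysis error and is rejected.
    """
    if not results:
        raise ConfigurationError("cannot correct an empty family")
    contrasts = {r.contrast for r in results}
    features = {r.feature for r in results}
    if len(contrasts) > 1 and len(features) > 1:
        raise ConfigurationError(
            "mixed families: results vary in both feature and contrast"
        )
    _, q = bh_fdr(np.array([r.p for r in results]), alpha=0.05)
    return [replace(r, q=float(qi), family=family) for r, qi in zip(results, q)]


def _indicator(subjects: pd.DataFrame, case: tuple, control: tuple) -> pd.Series:
    """1 for case subjects, 0 for controls, NaN otherwise.

    ``case``/``control`` are (group, medication) pairs; medication ``None``
    matches any status.
    """
    def match(row, criterion):
        g, med = criterion
        return row["group"] == g and (med is None or row["medication"] == med)

    vals = np.full(len(subjects), np.nan)
    for i, (_, row) in enumerate(subjects.iterrows()):
        if match(row, case):
            vals[i] = 1.0
        elif match(row, control):
            vals[i] = 0.0
    return pd.Series(vals, index=subjects.index)


def group_contrast_table(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    case: tuple = (GROUP_ADHD, None),
    control: tuple = (GROUP_TDC, None),
    contrast: str = "ADHD-TDC",
    covariates=DEFAULT_COVARIATES,
    family: str | None = None,
) -> list[GroupContrastResult]:
    """Contrast every feature column between two subject subsets.

    ``features`` is indexed by subject_id with one column per feature (e.g.
    whole-brain, or one column per system).  Covariate columns are taken from
    ``subjects``.  When ``family`` is given, q-values are filled across the
    returned set.
    """
    ind = _indicator(subjects.loc[features.index], case, control)
    mask = ind.notna()
    if mask.sum() < 3:
        raise DegenerateModelError("fewer than 3 subjects in the contrast")
    cov = subjects.loc[features.index[mask], list(covariates)] if covariates else None
    out = []
    for col in features.columns:
        out.append(
            fit_contrast(
                features.loc[mask, col].to_numpy(),
                ind[mask].to_numpy(),
                covariates=cov,
                feature=str(col),
                contrast=contrast,
            )
        )
    if family is not None:
        out = correct_family(out, family)
    return out


def medication_contrasts(
    features: pd.DataFrame,
    subjects: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> list[GroupContrastResult]:
    """The three pairwise medication comparisons, FDR-corrected together.

    Medicated vs unmedicated ADHD, unmedicated ADHD vs TDC, and medicated
    ADHD vs TDC, each on every feature column (typically the single
    whole-brain column), with BH correction across the three contrasts per
    feature.
    """
    pairs = [
        ((GROUP_ADHD, MED_TREATED), (GROUP_ADHD, MED_NAIVE), "medicated-unmedicated"),
        ((GROUP_ADHD, MED_NAIVE), (GROUP_TDC, None), "unmedicated-TDC"),
        ((GROUP_ADHD, MED_TREATED), (GROUP_TDC, None), "medicated-TDC"),
    ]
    out = []
    for col in features.columns:
        per_feature = [
            group_contrast_table(
                features[[col]], subjects, case=case, control=control,
                contrast=name, covariates=covariates,
            )[0]
            for case, control, name in pairs
        ]
        out.extend(correct_family(per_feature, family="medication"))
    return out
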