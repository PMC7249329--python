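"""Probe filtering and differential methylation testing.

The differential test fits, per CpG probe, an ordinary least-squares model
of the methylation value on a two-level group indicator and moderates the
residual variances with an empirical-Bayes scaled-inverse-chi-squared
prior before forming a moderated F statistic:

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    F_g    = (mean_case - mean_control)^2 / (s~_g^2 * (1/n1 + 1/n2))

with ``F_g ~ F(1, d0 + d_g)`` under the null.  The prior ``(d0, s0^2)``
is estimated from the ensemble of residual variances by the method of
moments on log variances (trigamma inversion).  Multiple testing is
controlled by Benjamini-Hochberg.

Sign convention used throughout the package: ``delta_beta = case -
control``, so positive values mean hypermethylation in cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaMatrix",
    "ModerationPrior",
    "filter_probes",
    "ModeratedDifferentialMethylation",
    "fit_moderated_f",
    "bh_adjust",
    "welch_t",
    "estimate_moderation_prior",
    "validate_probe_annotation",
    "validate_sample_sheet",
]

PROBE_FLAG_COLUMNS = (
    "sex_chromosome",
    "snp_affected",
    "cross_reactive",
    "solo_wcgw",
    "in_pmd",
    "in_hmd",
)

#: cap beyond which the prior degrees of freedom are treated as infinite
D0_CAP = 1e6


class BetaMatrix:
    """Probes x samples matrix of methylation fractions in ``[0, 1]``.

    Missing entries are explicit NaN.  Probe and sample identifiers must
    be unique.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        if np.any((arr[finite] < 0) | (arr[finite] > 1)):
            raise ValueError("beta values must lie in [0, 1]")
        if np.any(np.isinf(arr)):
            raise ValueError("beta values must be finite or NaN")
        self.values = values.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="probe_id",
                           float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BetaMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass(frozen=True)
class ModerationPrior:
    """Scaled inverse-chi-squared prior on per-probe residual variances."""

    d0: float
    s0_squared: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_squared > 0:
            raise ValueError("s0_squared must be positive")

    @property
    def is_infinite(self) -> bool:
        return self.d0 >= D0_CAP


def validate_probe_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Check the probe annotation contract: unique ids, coordinates, and
    boolean-complete flags."""
    required = {"chrom", "pos", *PROBE_FLAG_COLUMNS}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"probe annotation missing columns: {sorted(missing)}")
    if annot.index.has_duplicates:
        raise ValueError("duplicate probe ids in annotation")
    for col in PROBE_FLAG_COLUMNS:
        if annot[col].isna().any():
            raise ValueError(f"flag column {col!r} has missing values")
    return annot


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if "group" not in sheet.columns:
        raise ValueError("sample sheet requires a 'group' column")
    bad = set(sheet["group"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    counts = sheet["group"].value_counts()
    if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
        raise ValueError("need >= 2 samples per group")
    if "passage" in sheet.columns and (sheet["passage"].dropna() < 0).any():
        raise ValueError("passage must be >= 0")
    return sheet


def filter_probes(
    beta: BetaMatrix,
    detection_p: pd.DataFrame,
    annot: pd.DataFrame,
    det_threshold: float = 0.01,
) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove unreliable probes before testing.

    A probe is removed when its detection p-value exceeds ``det_threshold``
    in *any* sample, or when it is flagged as sex-chromosomal,
    SNP-affected, or cross-reactive.  Retained values are untouched.

    Returns the row-subset matrix and a per-rule removal log (counts are
    per rule, so a probe failing several rules is counted under each;
    ``removed_total`` is the number of distinct probes dropped).
    """
    if not beta.values.index.equals(detection_p.index) or not beta.values.columns.equals(
        detection_p.columns
    ):
        raise ValueError("detection-p matrix is not aligned with the beta matrix")
    annot = validate_probe_annotation(annot)
    missing = beta.probe_ids.difference(annot.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes lack annotation rows")

    ann = annot.loc[beta.probe_ids]
    fail_det = (detection_p.to_numpy(dtype=float) > det_threshold).any(axis=1)
    fail_sex = ann["sex_chromosome"].to_numpy(dtype=bool)
    fail_snp = ann["snp_affected"].to_numpy(dtype=bool)
    fail_xr = ann["cross_reactive"].to_numpy(dtype=bool)
    drop = fail_det | fail_sex | fail_snp | fail_xr
    log = {
        "high_detection_p": int(fail_det.sum()),
        "sex_chromosome": int(fail_sex.sum()),
        "snp_affected": int(fail_snp.sum()),
        "cross_reactive": int(fail_xr.sum()),
        "removed_total": int(drop.sum()),
        "retained": int((~drop).sum()),
    }
    return BetaMatrix(beta.values.loc[~drop]), log


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by monotone bisection.

    trigamma is strictly decreasing on (0, inf), so the root is unique.
    Values of ``y`` at or below ``trigamma(D0_CAP)`` return ``D0_CAP``
    (treated as an effectively flat prior upstream).
    """
    if y <= float(special.polygamma(1, D0_CAP)):
        return D0_CAP
    lo, hi = 1e-8, 1e8
    while special.polygamma(1, hi) > y:
        hi *= 10
    while special.polygamma(1, lo) < y:
        lo /= 10
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_moderation_prior(s2: np.ndarray, df: float) -> ModerationPrior:
    """Method-of-moments fit of ``(d0, s0^2)`` from residual variances.

    Works on ``e_g = log s_g^2 - digamma(df/2) + log(df/2)``, an unbiased
    estimate of ``log sigma_g^2`` whose variance under the prior is
    ``trigamma(df/2) + trigamma(d0/2)``; the excess spread of the observed
    ``e_g`` over ``trigamma(df/2)`` is inverted through trigamma to give
    ``d0``.  Zero variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >= 2 positive residual variances to fit the prior")
    half_df = df / 2.0
    e = np.log(s2) - special.digamma(half_df) + np.log(half_df)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, half_df))
    if excess <= 0:
        d0 = D0_CAP
        s0_sq = float(np.exp(e_mean))
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = min(2.0 * half_d0, D0_CAP)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s0_squared=s0_sq)


def _moderated_f_pvalues(f: np.ndarray, df2: float) -> np.ndarray:
    if df2 >= D0_CAP:
        return stats.chi2.sf(f, 1)
    return stats.f.sf(f, 1, df2)


class ModeratedDifferentialMethylation(BaseEstimator):
    """Two-group moderated F-test over many probes (sklearn-style).

    Parameters
    ----------
    shrink : bool, default True
        Moderate per-probe residual variances toward the empirical-Bayes
        prior.  With ``shrink=False`` the statistic reduces to the
        ordinary one-way ANOVA F per probe.
    use_mvalues : bool, default False
        Test logit-transformed values (M-values) instead of the beta
        scale.  Values are clipped to ``[eps, 1-eps]`` before the logit.
    q_threshold : float, default 0.05
        BH-adjusted significance threshold for the ``significant_`` flag.

    The estimator follows the sklearn convention ``X``: samples x probes,
    ``y``: group label per sample (``"case"``/``"control"`` or any two
    levels; the *case* level is the one sorting last unless labels are
    literally case/control).

    Fitted attributes (all per probe, aligned to the columns of ``X``):
    ``mean_case_``, ``mean_control_``, ``delta_beta_``, ``residual_var_``,
    ``moderated_var_``, ``f_statistic_``, ``p_values_``, ``q_values_``,
    ``significant_``; plus the shared ``prior_`` (:class:`ModerationPrior`
    or None) and ``df_residual_``.
    """

    _mvalue_eps = 1e-6

    def __init__(self, shrink: bool = True, use_mvalues: bool = False,
                 q_threshold: float = 0.05):
        self.shrink = shrink
        self.use_mvalues = use_mvalues
        self.q_threshold = q_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be samples x probes")
        levels = np.unique(y)
        if levels.size != 2:
            raise ValueError(f"need exactly two groups, got {list(levels)}")
        if set(levels) == {"case", "control"}:
            case_level = "case"
        else:
            case_level = levels[-1]
        case = y == case_level
        n1, n2 = int(case.sum()), int((~case).sum())
        if n1 < 2 or n2 < 2:
            raise ValueError("need >= 2 samples per group")

        missing = ~np.isfinite(X)
        dropped = missing.any(axis=0)
        if dropped.any():
            warnings.warn(
                f"{int(dropped.sum())} probes with missing values set to NaN "
                "results", stacklevel=2
            )
        V = X.copy()
        if self.use_mvalues:
            clipped = np.clip(V, self._mvalue_eps, 1 - self._mvalue_eps)
            V = np.log2(clipped / (1 - clipped))

        xc, xn = V[case], V[~case]
        mean_case = xc.mean(axis=0)
        mean_control = xn.mean(axis=0)
        # residual variance of the two-group OLS fit = pooled within-group
        ss = ((xc - mean_case) ** 2).sum(axis=0) + ((xn - mean_control) ** 2).sum(axis=0)
        df = n1 + n2 - 2
        s2 = ss / df
        delta = mean_case - mean_control

        usable = s2[~dropped]
        if self.shrink and (np.isfinite(usable) & (usable > 0)).sum() < 2:
            warnings.warn(
                "too few positive residual variances to fit the moderation "
                "prior; falling back to unmoderated F", stacklevel=2
            )
            shrink = False
        else:
            shrink = self.shrink
        if shrink:
            prior = estimate_moderation_prior(usable, df)
            if prior.is_infinite:
                s2_mod = np.full_like(s2, prior.s0_squared)
                df_total = D0_CAP
            else:
                s2_mod = (prior.d0 * prior.s0_squared + df * s2) / (prior.d0 + df)
                df_total = prior.d0 + df
            self.prior_ = prior
        else:
            s2_mod = s2
            df_total = float(df)
            self.prior_ = None

        inv_n = 1.0 / n1 + 1.0 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            f = delta**2 / (s2_mod * inv_n)
        # all-constant probes: define F = 0, p = 1 (no NaN propagation)
        constant = s2_mod == 0
        zero_delta = np.isclose(delta, 0.0)
        f = np.where(constant & zero_delta, 0.0, f)
        p = _moderated_f_pvalues(np.where(np.isfinite(f), f, np.inf), df_total)
        p = np.where(constant & zero_delta, 1.0, p)
        if np.any(constant & ~zero_delta):
            warnings.warn(
                "probes with zero residual variance but non-zero effect: "
                "p reported as 0", stacklevel=2
            )
            p = np.where(constant & ~zero_delta, 0.0, p)

        for arr in (mean_case, mean_control, delta, s2, s2_mod, f, p):
            arr[dropped] = np.nan

        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = bh_adjust(p[ok])

        self.case_level_ = case_level
        self.n_case_, self.n_control_ = n1, n2
        self.df_residual_ = float(df)
        self.df_total_ = float(df_total)
        self.mean_case_ = mean_case
        self.mean_control_ = mean_control
        self.delta_beta_ = delta
        self.residual_var_ = s2
        self.moderated_var_ = s2_mod
        self.f_statistic_ = f
        self.p_values_ = p
        self.q_values_ = q
        self.significant_ = q < self.q_threshold
        self.n_dropped_ = int(dropped.sum())
        return self

    def to_table(self, probe_ids: Sequence[str]) -> pd.DataFrame:
        """Per-probe results as the canonical differential-probe table."""
        if not hasattr(self, "f_statistic_"):
            raise AttributeError("estimator is not fitted")
        return pd.DataFrame(
            {
                "mean_beta_case": self.mean_case_,
                "mean_beta_control": self.mean_control_,
                "delta_beta": self.delta_beta_,
                "residual_variance": self.residual_var_,
                "moderated_variance": self.moderated_var_,
                "F_statistic": self.f_statistic_,
                "p_value": self.p_values_,
                "q_value": self.q_values_,
                "significant": self.significant_,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )


def fit_moderated_f(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    shrink: bool = True,
    use_mvalues: bool = False,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential methylation table for a probes x samples matrix.

    Thin wrapper over :class:`ModeratedDifferentialMethylation`; the
    sample sheet supplies the case/control labels (aligned by sample id).
    """
    sheet = validate_sample_sheet(sheet)
    missing = beta.sample_ids.difference(sheet.index)
    if len(missing):
        raise ValueError(f"samples missing from sheet: {list(missing)}")
    y = sheet.loc[beta.sample_ids, "group"].to_numpy()
    est = ModeratedDifferentialMethylation(
        shrink=shrink, use_mvalues=use_mvalues, q_threshold=q_threshold
    ).fit(beta.values.to_numpy().T, y)
    return est.to_table(beta.probe_ids)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def welch_t(x, y) -> dict[str, float]:
    """Welch's two-sample t-test (unequal variances, two-sided).

    Returns ``{"t", "df", "p"}``.  Degenerate inputs where both sample
    variances vanish are resolved without NaN: equal means give
    ``t = 0, p = 1``; unequal means give ``p = 0`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires >= 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            return {"t": 0.0, "df": float(x.size + y.size - 2), "p": 1.0}
        warnings.warn("zero variance with unequal means: p = 0", stacklevel=2)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return {"t": sign * np.inf, "df": float(x.size + y.size - 2), "p": 0.0}
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}
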