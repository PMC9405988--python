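"""Mixed-effects regression of self-assessment scales on temporal variability.

The unit of analysis is one emotional event: its tvDFC value joined with
the ratings the subject gave for that event. The linear model is
``scale ~ tv + (1 | subject)`` fitted by REML, with Wald inference on the
fixed slope. Predictor and outcome are z-scored before fitting so the
slope is standardized. A companion mixed logistic model checks whether
the arousal x dominance interaction predicts high (above-median) temporal
variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["TvRecord", "LmmFit", "fit_scale_on_tv", "fit_interaction_logistic"]

SCALES = ("valence", "arousal", "dominance", "liking", "familiarity", "relevance")


@dataclass(frozen=True)
class TvRecord:
    """One event's temporal-variability scalar with its ratings."""

    event: str
    subject: str
    group: int
    band: str
    tv: float
    valence: float
    arousal: float
    dominance: float
    liking: float
    familiarity: float
    relevance: float

    def __post_init__(self) -> None:
        if self.tv < 0:
            raise ValueError("temporal variability cannot be negative")


@dataclass
class LmmFit:
    """Random-intercept model summary for one rating scale."""

    scale: str
    beta: float
    se: float
    ci95: tuple[float, float]
    t: float
    df: float
    p: float
    n_obs: int
    n_subjects: int
    converged: bool
    method: str = "REML"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(d["ci95"])
        return d


def _records_frame(records: Sequence[TvRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([asdict(r) for r in records])


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError(f"{what} has zero variance")
    return (x - x.mean()) / sd


def fit_scale_on_tv(
    records: Sequence[TvRecord] | pd.DataFrame,
    scale: str,
    re_variance: float | None = None,
) -> LmmFit:
    """REML random-intercept fit of a (z-scored) scale on z-scored tv.

    Inference on the slope is a Wald test against the large-sample normal
    reference; ``df`` records n_obs - 2 as a descriptive quantity only.

    ``re_variance=0.0`` holds the random-intercept variance at zero, under
    which the generalized-least-squares estimator reduces exactly to
    ordinary least squares; the reduction is computed in closed form
    (statsmodels ridges singular covariance away from the boundary).
    """
    df = _records_frame(records)
    if scale not in df.columns:
        raise ValueError(f"unknown scale {scale!r}")
    subjects = df["subject"].unique()
    if len(subjects) < 2:
        raise ValueError(
            "a single subject cannot identify a random intercept; fit an "
            "ordinary regression instead"
        )
    y = _zscore(df[scale].to_numpy(dtype=float), f"outcome {scale!r}")
    x = _zscore(df["tv"].to_numpy(dtype=float), "temporal variability")
    work = pd.DataFrame({"y": y, "tv": x, "subject": df["subject"].to_numpy()})
    if re_variance is not None:
        if re_variance != 0.0:
            raise NotImplementedError(
                "only the zero-variance boundary is supported"
            )
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sigma2 = resid @ resid / (len(y) - 2)  # REML scale at the boundary
        cov = sigma2 * np.linalg.inv(X.T @ X)
        beta, se = float(coef[1]), float(np.sqrt(cov[1, 1]))
        z = beta / se
        return LmmFit(
            scale=scale,
            beta=beta,
            se=se,
            ci95=(beta - 1.96 * se, beta + 1.96 * se),
            t=float(z),
            df=float(len(y) - 2),
            p=min(1.0, 2 * (1 - _norm_cdf(abs(z)))),
            n_obs=len(y),
            n_subjects=len(subjects),
            converged=True,
        )
    model = sm.MixedLM.from_formula("y ~ tv", groups="subject", data=work)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    beta = float(fit.params["tv"])
    se = float(fit.bse["tv"])
    z = beta / se
    p = 2 * (1 - _norm_cdf(abs(z)))
    return LmmFit(
        scale=scale,
        beta=beta,
        se=se,
        ci95=(beta - 1.96 * se, beta + 1.96 * se),
        t=float(z),
        df=float(len(work) - 2),
        p=min(1.0, p),
        n_obs=len(work),
        n_subjects=len(subjects),
        converged=bool(fit.converged),
    )


def _norm_cdf(x: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf(x))


def fit_interaction_logistic(
    records: Sequence[TvRecord] | pd.DataFrame,
    seed: int = 0,
) -> dict:
    """Mixed logistic check: high-tv ~ arousal * dominance + (1 | subject).

    High temporal variability is the within-dataset median split of tv.
    The random-intercept logistic model is fitted by variational Bayes
    (statsmodels BinomialBayesMixedGLM); the interaction "p" is the
    two-sided normal tail of the posterior mean / posterior sd ratio.
    Separation or degenerate outcomes are flagged, not silently dropped.
    """
    df = _records_frame(records)
    median = df["tv"].median()
    y = (df["tv"] > median).astype(int)
    if y.nunique() == 1:
        raise ValueError(
            "all events fall on one side of the tv median; the outcome is "
            "degenerate"
        )
    work = pd.DataFrame(
        {
            "high_tv": y.to_numpy(),
            "arousal": _zscore(df["arousal"].to_numpy(dtype=float), "arousal"),
            "dominance": _zscore(
                df["dominance"].to_numpy(dtype=float), "dominance"
            ),
            "subject": df["subject"].to_numpy(),
        }
    )
    model = sm.BinomialBayesMixedGLM.from_formula(
        "high_tv ~ arousal * dominance", {"subject": "0 + C(subject)"}, work
    )
    # the variational fit draws from the legacy global RNG; pin it so the
    # result is a pure function of (data, seed)
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit_vb()
    finally:
        np.random.set_state(state)
    names = list(fit.model.exog_names)
    k = names.index("arousal:dominance")
    coef = float(fit.fe_mean[k])
    sd = float(fit.fe_sd[k])
    flagged = not np.isfinite(coef) or not np.isfinite(sd) or sd == 0
    p = 1.0 if flagged else min(1.0, 2 * (1 - _norm_cdf(abs(coef / sd))))
    return {
        "term": "arousal:dominance",
        "coef": coef,
        "se": sd,
        "p": p,
        "n_obs": int(len(work)),
        "n_high": int(y.sum()),
        "flagged": bool(flagged),
        "method": "BinomialBayesMixedGLM (variational Bayes)",
    }
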