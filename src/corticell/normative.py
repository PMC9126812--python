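"""Quantile-regression normative charts of regional cortical thickness.

Per region, linear quantile regression of CTh on age with an additive sex
term is fitted on healthy subjects at tau = 0.05, 0.50, 0.95.  The band
between the 5th and 95th percentile curves is the normative range for a
given age and sex; any subject can then be positioned on the charts and
scored with a continuous deviation z-score

    delta_z = (CTh - predicted median) / residual SD of healthy fits,

and categorized as infra-normal (below the 5% curve), supra-normal (above
the 95% curve), or normal.  Crossing of fitted quantile curves is repaired
by rearrangement (sorting predictions across tau at each evaluation point).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CohortTable
from .errors import InputError, NumericalError

log = logging.getLogger(__name__)

DEFAULT_TAUS = (0.05, 0.50, 0.95)
CAT_NORMAL = "normal"
CAT_INFRA = "infra"
CAT_SUPRA = "supra"


def pinball_loss(residuals: np.ndarray, tau: float) -> float:
    """Mean quantile (pinball) loss rho_tau(u) = u * (tau - 1{u<0})."""
    u = np.asarray(residuals, dtype=float)
    return float(np.mean(u * (tau - (u < 0))))


@dataclass(frozen=True)
class QuantileFit:
    """A single per-region quantile fit: intercept + age (+ optional
    quadratic age) + sex coefficients."""

    tau: float
    coefficients: dict[str, float]  # keys: intercept, age, age2, sex (absent -> 0)
    pinball_loss: float

    def predict(self, ages, sexes) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        sexes = np.asarray(sexes, dtype=float)
        c = self.coefficients
        return (
            c.get("intercept", 0.0)
            + c.get("age", 0.0) * ages
            + c.get("age2", 0.0) * ages**2
            + c.get("sex", 0.0) * sexes
        )


def fit_quantile(
    ages,
    sexes,
    cth,
    tau: float,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> QuantileFit:
    """Fit one conditional quantile by minimizing mean pinball loss.

    ``covariates`` selects the design beyond the intercept: any subset of
    ``("age", "age2", "sex")``, where ``age2`` adds a quadratic age term
    (pass ``()`` for an intercept-only fit, i.e. the marginal
    tau-quantile).  A rank-deficient
    design (e.g. constant age and a single sex while both are requested)
    raises :class:`NumericalError`.  Twenty or more subjects are recommended
    for a stable three-parameter fit.
    """
    if not 0 < tau < 1:
        raise InputError(f"tau must be in (0, 1), got {tau}")
    y = np.asarray(cth, dtype=float)
    ages_arr = np.asarray(ages, dtype=float)
    cols = {
        "age": ages_arr,
        "age2": ages_arr**2,
        "sex": np.asarray(sexes, dtype=float),
    }
    x = np.column_stack([np.ones_like(y)] + [cols[c] for c in covariates])
    if len(y) < x.shape[1] + 2:
        raise InputError(
            f"need at least {x.shape[1] + 2} subjects to fit {x.shape[1]} coefficients"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise NumericalError(
            "rank-deficient design: requested covariates are constant or collinear"
        )

    if np.ptp(y) == 0:  # exact degenerate fit: every quantile equals the constant
        coefs = {"intercept": float(y[0]), **{c: 0.0 for c in covariates}}
        return QuantileFit(tau, coefs, 0.0)

    # noise-free outcome: if least squares interpolates y exactly, every
    # conditional quantile is that same line and IRLS would only add jitter
    beta_ls, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid_ls = y - x @ beta_ls
    if np.max(np.abs(resid_ls)) <= 1e-10 * max(1.0, float(np.abs(y).max())):
        coefs = {"intercept": float(beta_ls[0])}
        for i, c in enumerate(covariates, start=1):
            coefs[c] = float(beta_ls[i])
        return QuantileFit(tau, coefs, pinball_loss(resid_ls, tau))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # IRLS convergence chatter on toy inputs
        res = sm.QuantReg(y, x).fit(q=tau, max_iter=2000)
    beta = np.asarray(res.params, dtype=float)
    coefs = {"intercept": float(beta[0])}
    for i, c in enumerate(covariates, start=1):
        coefs[c] = float(beta[i])
    loss = pinball_loss(y - x @ beta, tau)
    return QuantileFit(tau, coefs, loss)


@dataclass
class NormativeModel:
    """Per-region quantile fits plus the healthy residual scale.

    ``fits``: region -> {tau -> QuantileFit}; ``residual_sd``: SD (mm) of
    healthy residuals about the tau=0.50 curve, used to express deviations
    as z-scores; ``training_n``: number of healthy subjects fitted.
    """

    fits: dict[str, dict[float, QuantileFit]]
    residual_sd: pd.Series
    taus: tuple[float, ...]
    training_n: int
    crossings_repaired: int = field(default=0)

    @property
    def regions(self) -> list[str]:
        return list(self.fits)

    def predict_quantiles(self, region: str, ages, sexes) -> pd.DataFrame:
        """Predicted curves at every tau, monotone in tau by rearrangement."""
        if region not in self.fits:
            raise InputError(f"region {region!r} not in normative model")
        preds = np.column_stack(
            [self.fits[region][t].predict(ages, sexes) for t in self.taus]
        )
        repaired = np.sort(preds, axis=1)
        n_crossed = int((np.abs(repaired - preds) > 1e-12).any(axis=1).sum())
        if n_crossed:
            self.crossings_repaired += n_crossed
            log.debug("region %s: repaired %d crossing predictions", region, n_crossed)
        return pd.DataFrame(repaired, columns=list(self.taus))


def fit_normative_model(
    healthy: CohortTable,
    taus: tuple[float, ...] = DEFAULT_TAUS,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> NormativeModel:
    """Fit per-region charts at every tau on healthy subjects only."""
    if (healthy.demographics["group"] != "healthy").any():
        raise InputError("normative model must be trained on healthy subjects only")
    if len(taus) < 1 or sorted(taus) != list(taus) or not all(0 < t < 1 for t in taus):
        raise InputError("taus must be strictly increasing within (0, 1)")
    ages = healthy.demographics["age"].to_numpy()
    sexes = healthy.demographics["sex"].to_numpy()
    fits: dict[str, dict[float, QuantileFit]] = {}
    residual_sd = {}
    median_tau = taus[len(taus) // 2] if 0.5 not in taus else 0.5
    for region in healthy.regions:
        y = healthy.cth[region].to_numpy()
        try:
            fits[region] = {t: fit_quantile(ages, sexes, y, t, covariates) for t in taus}
        except (InputError, NumericalError) as exc:
            raise type(exc)(f"region {region!r}: {exc}") from exc
        resid = y - fits[region][median_tau].predict(ages, sexes)
        sd = float(np.std(resid, ddof=1))
        if not sd > 0:
            raise NumericalError(f"region {region!r}: zero residual SD")
        residual_sd[region] = sd
    return NormativeModel(
        fits=fits,
        residual_sd=pd.Series(residual_sd, name="residual_sd"),
        taus=tuple(taus),
        training_n=healthy.n,
    )


@dataclass
class DeviationProfile:
    """Continuous deviation z-scores and normative-band categories.

    ``delta_z``: subjects x regions; ``category``: same shape, values
    ``normal`` / ``infra`` / ``supra``.
    """

    delta_z: pd.DataFrame
    category: pd.DataFrame

    def band_rates(self) -> pd.DataFrame:
        """Per-region fractions of infra/supra/normal subjects."""
        return pd.DataFrame(
            {
                CAT_INFRA: (self.category == CAT_INFRA).mean(),
                CAT_SUPRA: (self.category == CAT_SUPRA).mean(),
                CAT_NORMAL: (self.category == CAT_NORMAL).mean(),
            }
        )

    def to_long_frame(self, groups: pd.Series | None = None) -> pd.DataFrame:
        """Tidy table subject_id, region, delta_z, category (plus group)."""
        dz = self.delta_z.rename_axis("subject_id").reset_index().melt(
            id_vars="subject_id", var_name="region", value_name="delta_z"
        )
        cat = self.category.rename_axis("subject_id").reset_index().melt(
            id_vars="subject_id", var_name="region", value_name="category"
        )
        out = dz.merge(cat, on=["subject_id", "region"])
        if groups is not None:
            out.insert(1, "group", groups.loc[out["subject_id"]].to_numpy())
        return out


def deviation_scores(model: NormativeModel, cohort: CohortTable) -> DeviationProfile:
    """Position every subject on the charts and score deviations per region."""
    unseen = [r for r in cohort.regions if r not in model.fits]
    if unseen:
        raise InputError(f"regions not covered by the normative model: {unseen}")
    ages = cohort.demographics["age"].to_numpy()
    sexes = cohort.demographics["sex"].to_numpy()
    lo_tau, hi_tau = model.taus[0], model.taus[-1]
    median_tau = 0.5 if 0.5 in model.taus else model.taus[len(model.taus) // 2]
    dz = {}
    cat = {}
    for region in cohort.regions:
        preds = model.predict_quantiles(region, ages, sexes)
        y = cohort.cth[region].to_numpy()
        dz[region] = (y - preds[median_tau].to_numpy()) / model.residual_sd[region]
        # exact boundary (to rounding) counts as normal
        tol = 1e-9 * max(1.0, float(np.abs(y).max()))
        c = np.full(len(y), CAT_NORMAL, dtype=object)
        c[y < preds[lo_tau].to_numpy() - tol] = CAT_INFRA
        c[y > preds[hi_tau].to_numpy() + tol] = CAT_SUPRA
        cat[region] = c
    idx = cohort.subjects
    return DeviationProfile(
        delta_z=pd.DataFrame(dz, index=idx)[cohort.regions],
        category=pd.DataFrame(cat, index=idx)[cohort.regions],
    )


def coverage(model: NormativeModel, cohort: CohortTable) -> pd.Series:
    """Per-region fraction of subjects inside the [5%, 95%] normative band."""
    if cohort.n == 0:
        raise InputError("cannot compute coverage of an empty cohort")
    rates = deviation_scores(model, cohort).band_rates()
    return rates[CAT_NORMAL].rename("coverage")


def bootstrap_bands(
    healthy: CohortTable,
    taus: tuple[float, ...] = DEFAULT_TAUS,
    B: int = 1000,
    seed: int | None = None,
    age_grid: np.ndarray | None = None,
    regions: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Pointwise 95% case-resampling bootstrap envelopes of the percentile curves.

    Returns a tidy frame with columns region, sex, tau, age, lo, hi, fit
    (the full-sample curve), evaluated on ``age_grid`` per sex.
    """
    if B < 100:
        raise InputError("bootstrap requires B >= 100 resamples")
    if healthy.n < 20:
        raise InputError("bootstrap resampling requires at least 20 subjects")
    rng = np.random.default_rng(seed)
    if age_grid is None:
        ages = healthy.demographics["age"]
        age_grid = np.linspace(ages.min(), ages.max(), 25)
    regions = regions or healthy.regions
    sexes_present = sorted(healthy.demographics["sex"].unique())
    # refit only the regions whose envelopes were requested
    healthy = CohortTable(healthy.demographics.copy(), healthy.cth[regions].copy())

    full = fit_normative_model(healthy, taus, covariates)
    records = []
    n = healthy.n
    demo = healthy.demographics
    boots: dict[str, dict[float, list[np.ndarray]]] = {
        r: {t: [] for t in taus} for r in regions
    }
    for _ in range(B):
        take = rng.integers(0, n, n)
        demo_b = demo.iloc[take].copy()
        cth_b = healthy.cth.iloc[take].copy()
        # resampling duplicates subjects; re-key so the container accepts them
        demo_b.index = pd.Index([f"b{i}" for i in range(n)])
        cth_b.index = demo_b.index
        sample = CohortTable(demo_b, cth_b)
        model_b = fit_normative_model(sample, taus, covariates)
        for region in regions:
            for sex in sexes_present:
                preds = model_b.predict_quantiles(
                    region, age_grid, np.full_like(age_grid, sex)
                )
                for t in taus:
                    boots[region][t].append((sex, preds[t].to_numpy()))
    for region in regions:
        for sex in sexes_present:
            full_preds = full.predict_quantiles(
                region, age_grid, np.full_like(age_grid, sex)
            )
            for t in taus:
                curves = np.stack(
                    [c for s, c in boots[region][t] if s == sex], axis=0
                )
                lo = np.percentile(curves, 2.5, axis=0)
                hi = np.percentile(curves, 97.5, axis=0)
                for j, age in enumerate(age_grid):
                    records.append(
                        {
                            "region": region,
                            "sex": sex,
                            "tau": t,
                            "age": float(age),
                            "lo": float(lo[j]),
                            "hi": float(hi[j]),
                            "fit": float(full_preds[t].iloc[j]),
                        }
                    )
    return pd.DataFrame.from_records(records)
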