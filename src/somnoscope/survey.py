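"""Design-based (complex survey) estimation for the sleep parameters.

Implements the NHANES-standard estimator stack: 4-year analysis weights
from two combined 2-year cycles, Horvitz-Thompson ratio means, weighted
quantiles, survey-weighted linear regression with a quartic age trend and
sex/race (and their age-interaction) terms, and survey-weighted
proportional-odds ordinal logistic regression on sleep-efficiency
quartiles.

Variances are Taylor-linearized under the stratified,
with-replacement-PSU approximation: per-observation influence values are
summed to PSU totals and the between-PSU variation within each stratum
supplies the variance.  A stratum left with a single PSU ("lonely PSU")
contributes its squared deviation from the grand mean of PSU totals.
Wald tests use the adjusted F statistic
``F = (d - q + 1) / (d q) * W`` with ``d = n_PSU - n_strata`` design
degrees of freedom, referred to F(q, d - q + 1) — the convention of the
major survey packages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from sklearn.base import BaseEstimator

#: Table-2-style age groups (upper bound inclusive; last is open-ended).
AGE_GROUPS = [(6, 13), (14, 17), (18, 25), (26, 35), (36, 45),
              (46, 55), (56, 65), (66, 75), (76, 200)]
AGE_GROUP_LABELS = ["6-13", "14-17", "18-25", "26-35", "36-45",
                    "46-55", "56-65", "66-75", ">=76"]
DEFAULT_QUANTILES = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90)

RACE_LEVELS = ("NH White", "NH Black", "Mexican American", "Other")

# age is centered/scaled before polynomial expansion (age^4 on raw years is
# numerically hostile); fixed constants so coefficients are comparable
# across fits.
AGE_CENTER, AGE_SCALE = 40.0, 20.0


class LonelyPSUWarning(UserWarning):
    pass


def four_year_weights(demographics: pd.DataFrame,
                      allow_single_cycle: bool = False) -> pd.DataFrame:
    """Combine two 2-year exam cycles: weight_4yr = weight_2yr / 2.

    Subjects with missing weights are dropped (logged via warning).  With
    only one cycle present the halving is wrong; pass
    ``allow_single_cycle=True`` to pass 2-year weights through unchanged.
    """
    df = demographics.copy()
    missing = df["weight_2yr"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} subjects with "
                      "missing weights")
        df = df[~missing]
    cycles = set(df["cycle"].unique())
    if len(cycles) < 2:
        if not allow_single_cycle:
            raise ValueError(
                "only one exam cycle present; set allow_single_cycle=True "
                "to use 2-year weights as-is")
        warnings.warn("single cycle: using 2-year weights unhalved")
        df["weight_4yr"] = df["weight_2yr"].astype(float)
    else:
        df["weight_4yr"] = df["weight_2yr"].astype(float) / 2.0
    return df


@dataclass
class SurveyDesign:
    """Stratum/PSU/weight triplets aligned with the analysis rows."""
    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   weight_col: str = "weight_4yr") -> "SurveyDesign":
        return cls(df["stratum"].to_numpy(),
                   df["psu"].to_numpy(),
                   df[weight_col].to_numpy(float))

    def __post_init__(self):
        self.stratum = np.asarray(self.stratum)
        self.psu = np.asarray(self.psu)
        self.weight = np.asarray(self.weight, float)
        if (self.weight <= 0).any():
            raise ValueError("weights must be positive")

    def subset(self, mask) -> "SurveyDesign":
        return SurveyDesign(self.stratum[mask], self.psu[mask],
                            self.weight[mask])

    @property
    def n(self) -> int:
        return len(self.weight)

    def degrees_of_freedom(self) -> int:
        """n distinct PSUs minus n strata among the analyzed rows."""
        pairs = {(s, p) for s, p in zip(self.stratum, self.psu)}
        return len(pairs) - len(set(self.stratum))


def _taylor_variance(z: np.ndarray, design: SurveyDesign) -> np.ndarray:
    """Covariance of the total of per-row influence vectors ``z`` (n, k)
    under stratified with-replacement PSU sampling."""
    z = np.atleast_2d(np.asarray(z, float))
    if z.shape[0] != design.n:
        z = z.T
    k = z.shape[1]
    df = pd.DataFrame(z)
    df["_s"], df["_p"] = design.stratum, design.psu
    totals = df.groupby(["_s", "_p"]).sum()
    V = np.zeros((k, k))
    grand = totals.to_numpy().mean(axis=0)
    lonely = False
    for s, g in totals.groupby(level="_s"):
        t = g.to_numpy()
        nh = t.shape[0]
        if nh >= 2:
            dev = t - t.mean(axis=0)
            V += nh / (nh - 1) * dev.T @ dev
        else:
            lonely = True
            dev = (t[0] - grand)[None, :]
            V += dev.T @ dev
    if lonely:
        warnings.warn("stratum with a single PSU: deviation centered at the "
                      "grand PSU mean", LonelyPSUWarning)
    return V


def weighted_mean_se(values, design: SurveyDesign) -> tuple[float, float]:
    """Horvitz-Thompson ratio mean with Taylor-linearized SE."""
    y = np.asarray(values, float)
    if len(y) != design.n:
        raise ValueError("values and design misaligned")
    w = design.weight
    wsum = w.sum()
    mean = float(np.sum(w * y) / wsum)
    z = w * (y - mean) / wsum
    var = _taylor_variance(z[:, None], design)[0, 0]
    return mean, float(np.sqrt(var))


def weighted_quantiles(values, weights, probs=DEFAULT_QUANTILES) -> np.ndarray:
    """Weighted empirical quantiles by inverse-CDF: the smallest observed
    value whose cumulative weight share reaches p."""
    y = np.asarray(values, float)
    w = np.asarray(weights, float)
    if y.size == 0:
        raise ValueError("empty group")
    order = np.argsort(y, kind="mergesort")
    y, w = y[order], w[order]
    cdf = np.cumsum(w) / w.sum()
    out = np.empty(len(probs))
    for i, p in enumerate(probs):
        out[i] = y[np.searchsorted(cdf, p, side="left")]
    return out


def age_group_quantile_table(data: pd.DataFrame, outcomes,
                             weight_col: str = "weight_4yr",
                             probs=DEFAULT_QUANTILES) -> pd.DataFrame:
    """Weighted quantile grid of the sleep parameters by the 9 age groups."""
    rows = []
    for (lo, hi), label in zip(AGE_GROUPS, AGE_GROUP_LABELS):
        grp = data[(data["age_years"] >= lo) & (data["age_years"] <= hi)]
        row = {"age_group": label, "n": len(grp)}
        for oc in outcomes:
            if grp.empty:
                for p in probs:
                    row[f"{oc}_p{int(p * 100)}"] = np.nan
            else:
                qs = weighted_quantiles(grp[oc], grp[weight_col], probs)
                for p, q in zip(probs, qs):
                    row[f"{oc}_p{int(p * 100)}"] = q
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survey-weighted polynomial trend regression

def _age_poly(age: np.ndarray) -> np.ndarray:
    a = (np.asarray(age, float) - AGE_CENTER) / AGE_SCALE
    return np.column_stack([a, a ** 2, a ** 3, a ** 4])


def build_design_matrix(data: pd.DataFrame, interactions=(),
                        check_rank: bool = True) -> tuple[np.ndarray, list[str]]:
    """Intercept + quartic age + female + race dummies (+ optional
    sex x age-polynomial and race x age-polynomial blocks).

    Reference levels: male, NH White.  Age enters centered and scaled
    ((age - 40) / 20) before powers are taken.
    """
    ap = _age_poly(data["age_years"])
    female = (data["sex"] == "female").to_numpy(float)
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for i in range(4):
        cols.append(ap[:, i])
        names.append(f"age{i + 1}")
    cols.append(female)
    names.append("female")
    race_d = {}
    for lev in RACE_LEVELS[1:]:
        d = (data["race"] == lev).to_numpy(float)
        race_d[lev] = d
        cols.append(d)
        names.append(f"race_{lev.replace(' ', '_')}")
    if "sex" in interactions:
        for i in range(4):
            cols.append(female * ap[:, i])
            names.append(f"female_x_age{i + 1}")
    if "race" in interactions:
        for lev in RACE_LEVELS[1:]:
            for i in range(4):
                cols.append(race_d[lev] * ap[:, i])
                names.append(f"race_{lev.replace(' ', '_')}_x_age{i + 1}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X) if check_rank else X.shape[1]
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(
            f"design matrix rank {rank} < {X.shape[1]}: collinear or empty "
            f"columns {bad}")
    return X, names


def _wald_F(beta_block, V_block, design_df: int):
    q = len(beta_block)
    W = float(beta_block @ np.linalg.solve(V_block, beta_block))
    df2 = design_df - q + 1
    if df2 <= 0:
        return W, np.nan, np.nan
    F = (df2 / (design_df * q)) * W
    p = float(scipy.stats.f.sf(F, q, df2))
    return W, F, p


class SurveyPolynomialTrend(BaseEstimator):
    """Survey-weighted linear regression of a sleep parameter on a quartic
    age trend, sex, race, and optional age interactions.

    Point estimates are weighted least squares; the covariance is the
    design-based Taylor sandwich.  ``fit`` expects a subject-level frame
    with the outcome, age_years, sex, race, stratum, psu, weight_4yr.

    Attributes
    ----------
    params_ : pd.Series              coefficient estimates
    cov_ : pd.DataFrame              design-based covariance
    se_ : pd.Series
    wald_ : dict                     adjusted-F Wald tests per term block
    design_df_ : int                 n PSUs - n strata
    """

    def __init__(self, outcome: str = "mean_duration_h", interactions=(),
                 weight_col: str = "weight_4yr"):
        self.outcome = outcome
        self.interactions = interactions
        self.weight_col = weight_col

    def fit(self, data: pd.DataFrame, y=None):
        data = data.dropna(subset=[self.outcome]).reset_index(drop=True)
        design = SurveyDesign.from_frame(data, self.weight_col)
        X, names = build_design_matrix(data, self.interactions)
        yv = data[self.outcome].to_numpy(float)
        w = design.weight
        res = sm.WLS(yv, X, weights=w).fit()
        beta = res.params
        resid = yv - X @ beta
        bread = np.linalg.inv(X.T @ (X * w[:, None]))
        G = _taylor_variance(X * (w * resid)[:, None], design)
        V = bread @ G @ bread
        self.names_ = names
        self.params_ = pd.Series(beta, index=names)
        self.cov_ = pd.DataFrame(V, index=names, columns=names)
        self.se_ = pd.Series(np.sqrt(np.diag(V)), index=names)
        self.design_df_ = design.degrees_of_freedom()
        self.nobs_ = len(data)

        self.wald_ = {}
        blocks = {"sex": ["female"],
                  "race": [n for n in names if n.startswith("race_")
                           and "_x_" not in n],
                  "age": [f"age{i}" for i in range(1, 5)]}
        if "sex" in self.interactions:
            blocks["sex_x_age"] = [n for n in names if n.startswith("female_x_")]
        if "race" in self.interactions:
            blocks["race_x_age"] = [n for n in names
                                    if n.startswith("race_") and "_x_" in n]
        for term, cols in blocks.items():
            idx = [names.index(c) for c in cols]
            W, F, p = _wald_F(beta[idx], V[np.ix_(idx, idx)], self.design_df_)
            self.wald_[term] = {"wald": W, "F": F, "p": p, "df": len(idx)}
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        X, _ = build_design_matrix(data, self.interactions, check_rank=False)
        return X @ self.params_.to_numpy()

    def curve_grid(self, ages=None) -> pd.DataFrame:
        """Fitted age curves per sex/race for Fig-2-style plots."""
        if ages is None:
            ages = np.arange(6, 86)
        rows = []
        for sex in ("male", "female"):
            for race in RACE_LEVELS:
                g = pd.DataFrame({"age_years": ages, "sex": sex, "race": race})
                g["fitted"] = self.predict(g)
                g["outcome"] = self.outcome
                rows.append(g)
        return pd.concat(rows, ignore_index=True)


def svy_polynomial_regression(data: pd.DataFrame, outcome: str,
                              interactions=()) -> SurveyPolynomialTrend:
    """Functional wrapper over :class:`SurveyPolynomialTrend`."""
    return SurveyPolynomialTrend(outcome, interactions).fit(data)


# ---------------------------------------------------------------------------
# survey-weighted proportional-odds ordinal logistic

class _WeightedOrderedLogit(OrderedModel):
    """Proportional-odds model whose per-observation log-likelihood is
    multiplied by the survey weight (pseudo-maximum-likelihood)."""

    def __init__(self, endog, exog, weights, **kw):
        self._w = np.asarray(weights, float)
        super().__init__(endog, exog, distr="logit", **kw)

    def loglikeobs(self, params):
        return self._w * super().loglikeobs(params)


class SurveyOrdinalLogit(BaseEstimator):
    """Survey-weighted proportional-odds regression on an ordinal outcome.

    Pseudo-MLE point estimates with the Taylor-linearized sandwich
    covariance (per-observation weighted scores aggregated to PSUs).
    Positive coefficients shift mass toward higher categories.
    """

    def __init__(self, interactions=(), weight_col: str = "weight_4yr"):
        self.interactions = interactions
        self.weight_col = weight_col

    def fit(self, data: pd.DataFrame, categories):
        data = data.reset_index(drop=True)
        design = SurveyDesign.from_frame(data, self.weight_col)
        X, names = build_design_matrix(data, self.interactions)
        X = X[:, 1:]          # thresholds replace the intercept
        names = names[1:]
        # normalize weights to mean 1 so the optimizer sees an O(n) loglik
        wn = design.weight / design.weight.mean()
        model = _WeightedOrderedLogit(np.asarray(categories, int), X, wn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="bfgs", maxiter=500, disp=False)
        params = res.params
        H = model.hessian(params)
        A_inv = np.linalg.inv(-H)
        scores = model.score_obs(params)
        # rescale scores back to the true weight scale; A_inv scale cancels
        G = _taylor_variance(scores, design)
        V = A_inv @ G @ A_inv
        k = X.shape[1]
        self.names_ = names
        self.params_ = pd.Series(params[:k], index=names)
        self.thresholds_ = params[k:]
        self.cov_ = pd.DataFrame(V[:k, :k], index=names, columns=names)
        self.se_ = pd.Series(np.sqrt(np.diag(V))[:k], index=names)
        self.design_df_ = design.degrees_of_freedom()
        self.wald_ = {}
        for term, cols in {"sex": ["female"],
                           "race": [n for n in names if n.startswith("race_")
                                    and "_x_" not in n]}.items():
            idx = [names.index(c) for c in cols]
            W, F, p = _wald_F(params[idx], V[np.ix_(idx, idx)],
                              self.design_df_)
            self.wald_[term] = {"wald": W, "F": F, "p": p, "df": len(idx)}
        return self


def efficiency_quartile_ordinal(data: pd.DataFrame,
                                outcome: str = "mean_efficiency",
                                interactions=(),
                                weight_col: str = "weight_4yr",
                                ) -> SurveyOrdinalLogit:
    """Quartile the (left-skewed) efficiency on its weighted distribution
    and fit the survey-weighted proportional-odds model."""
    data = data.dropna(subset=[outcome]).reset_index(drop=True)
    cuts = weighted_quantiles(data[outcome], data[weight_col],
                              (0.25, 0.50, 0.75))
    cats = np.searchsorted(cuts, data[outcome].to_numpy(), side="left")
    counts = np.bincount(cats, minlength=4)
    if (counts == 0).any():
        warnings.warn("empty efficiency quartile; monotone-likelihood risk")
    fitted = SurveyOrdinalLogit(interactions, weight_col).fit(data, cats)
    fitted.cutpoints_ = cuts
    return fitted


def population_summary(data: pd.DataFrame,
                       outcomes=("mean_duration_h", "mean_onset_clock",
                                 "mean_efficiency"),
                       weight_col: str = "weight_4yr") -> pd.DataFrame:
    """Table-1-shaped weighted summary: n, weighted population size, mean
    age +/- SE, % female, race %, and mean +/- SE of each sleep parameter."""
    design = SurveyDesign.from_frame(data, weight_col)
    rows = [("n_subjects", len(data), np.nan),
            ("weighted_population", design.weight.sum(), np.nan)]
    m, se = weighted_mean_se(data["age_years"], design)
    rows.append(("age_years", m, se))
    m, se = weighted_mean_se((data["sex"] == "female").astype(float), design)
    rows.append(("female_pct", 100 * m, 100 * se))
    for lev in RACE_LEVELS:
        m, se = weighted_mean_se((data["race"] == lev).astype(float), design)
        rows.append((f"race_{lev.replace(' ', '_')}_pct", 100 * m, 100 * se))
    for oc in outcomes:
        sub = data.dropna(subset=[oc])
        m, se = weighted_mean_se(sub[oc], design.subset(
            data[oc].notna().to_numpy()))
        rows.append((oc, m, se))
    return pd.DataFrame(rows, columns=["variable", "value", "se"])


# ---------------------------------------------------------------------------
# validation simulations

def coefficient_coverage_simulation(n_reps: int = 200, n: int = 1000,
                                    seed: int = 0, beta_sex: float = 0.08,
                                    resid_sd: float = 0.8,
                                    n_strata: int = 50) -> pd.DataFrame:
    """Monte-Carlo check of the design-based intervals.

    Each replicate draws a stratified two-PSU cohort whose outcome follows
    a known quartic-age + sex model, fits the survey-weighted trend, and
    records whether each generating coefficient lies within 2 design-based
    SEs of its estimate.  Returns per-coefficient coverage rates.

    The default design (50 strata x 2 PSUs) gives enough design degrees
    of freedom that the linearized intervals are in their asymptotic
    regime; with few strata the adjusted-F correction only partially
    absorbs the variance-estimation noise.
    """
    rng = np.random.default_rng(seed)
    coef = {"intercept": 22.8, "age1": 0.5, "age2": -0.3, "age3": 0.1,
            "age4": -0.05, "female": beta_sex}
    hits = {k: 0 for k in coef}
    for _ in range(n_reps):
        age = rng.integers(6, 86, n)
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        race = rng.choice(RACE_LEVELS, n, p=[0.64, 0.12, 0.10, 0.14])
        a = (age - AGE_CENTER) / AGE_SCALE
        y = (coef["intercept"] + coef["age1"] * a + coef["age2"] * a ** 2
             + coef["age3"] * a ** 3 + coef["age4"] * a ** 4
             + coef["female"] * (sex == "female")
             + rng.normal(0, resid_sd, n))
        data = pd.DataFrame({
            "age_years": age, "sex": sex, "race": race, "outcome": y,
            "stratum": rng.integers(1, n_strata + 1, n),
            "psu": rng.integers(1, 3, n),
            "weight_4yr": rng.uniform(0.5, 4.0, n)})
        m = SurveyPolynomialTrend("outcome").fit(data)
        for k, v in coef.items():
            if abs(m.params_[k] - v) <= 2 * m.se_[k]:
                hits[k] += 1
    return pd.DataFrame({"term": list(coef),
                         "coverage": [hits[k] / n_reps for k in coef]})


def interaction_type1_simulation(n_reps: int = 500, n: int = 1000,
                                 seed: int = 0, alpha: float = 0.05,
                                 n_strata: int = 50) -> float:
    """Rejection rate of the sex-by-age interaction Wald test when the
    generator has no interaction (nominal level check)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        age = rng.integers(6, 86, n)
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        race = rng.choice(RACE_LEVELS, n, p=[0.64, 0.12, 0.10, 0.14])
        a = (age - AGE_CENTER) / AGE_SCALE
        y = (22.8 + 0.5 * a - 0.3 * a ** 2 + 0.08 * (sex == "female")
             + rng.normal(0, 0.8, n))
        data = pd.DataFrame({
            "age_years": age, "sex": sex, "race": race, "outcome": y,
            "stratum": rng.integers(1, n_strata + 1, n),
            "psu": rng.integers(1, 3, n),
            "weight_4yr": rng.uniform(0.5, 4.0, n)})
        m = SurveyPolynomialTrend("outcome", ("sex",)).fit(data)
        if m.wald_["sex_x_age"]["p"] < alpha:
            rejections += 1
    return rejections / n_reps
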