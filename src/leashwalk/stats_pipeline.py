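"""Two-stage inference: bivariate screening, then crossed-random-effects
linear mixed models on transformed outcomes.

Stage one fits, for every candidate predictor, the bivariate Gaussian model
``transformed outcome ~ 1 + candidate`` and keeps candidates with p below a
liberal screening level (0.2 by default), plus any predictors forced in on
subject-matter grounds.  Stage two fits a linear mixed model on the
transformed outcome with the shortlisted fixed effects and crossed random
intercepts for dog and walker — crossed, not nested, because dogs are
shared across walkers in the design.  Estimation is by REML with Wald
p-values for fixed effects; no multiple-testing correction is applied (cell
counts are reported so corrections can be applied downstream).

Model diagnostics cover normality of residuals and of each random-effect
vector (Shapiro-Wilk) and homogeneity of residual variance across
fitted-value quantile bins (Levene).
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .ethogram_metrics import (
    OUTCOME_FAMILIES, TRANSFORM_LEDGER, TransformSpec, behaviour_metrics_frame,
)
from .scoring import SUBTESTS, aggregate_assessment_frame, score_questionnaire_frame
from .tension_meter import DetectorConfig, detect_pull_episodes

logger = logging.getLogger("leashwalk.stats")

#: demographic covariates offered to the screen alongside the seven subtests
DEMOGRAPHIC_CANDIDATES = ("age", "weight", "height", "length", "bcs",
                          "cephalic_index", "sex", "source", "level")
DEFAULT_CANDIDATES = tuple(SUBTESTS) + DEMOGRAPHIC_CANDIDATES


class ModelFitError(RuntimeError):
    """Mixed-model fit failed to converge; carries the optimizer summary."""


@dataclass
class ModelSpec:
    """What to fit for one outcome."""

    outcome: str                       # transformed-outcome column name
    fixed_effects: tuple[str, ...]     # shortlisted predictors
    random_effects: tuple[str, ...] = ("dog_id", "walker_id")
    screen_alpha: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.screen_alpha < 1:
            raise ValueError("screen_alpha must be in (0, 1)")


@dataclass
class Diagnostics:
    resid_shapiro_stat: float
    resid_shapiro_p: float
    resid_normality_ok: bool
    levene_stat: float
    levene_p: float
    variance_homogeneity_ok: bool
    ranef_shapiro: dict            # re name -> (stat, p, ok)
    degenerate: bool = False


@dataclass
class ModelResult:
    """Fixed-effect estimates, variance components and fit metadata."""

    params: pd.DataFrame               # index term; columns beta, se, p
    vcomp: dict[str, float]            # random-effect variance estimates
    residual_var: float
    converged: bool
    singular: bool
    n_obs: int
    resid: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)
    ranef: dict = field(repr=False, default_factory=dict)
    diagnostics: Diagnostics | None = None


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)


def _design_block(table: pd.DataFrame, name: str) -> pd.DataFrame | None:
    """Numeric design columns for one candidate (dummies for categoricals).

    Returns None for a constant covariate (nothing to estimate).
    """
    s = table[name]
    if _is_categorical(s):
        d = pd.get_dummies(s, prefix=name, drop_first=True, dtype=float)
        return d if d.shape[1] else None
    col = s.astype(float)
    if col.nunique() <= 1:
        return None
    return col.to_frame(name)


def _ols_normal_equations(X: np.ndarray, y: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Closed-form least squares: beta, se, two-sided t p-values, sigma^2.

    The zero-variance limit of the mixed model: with both variance
    components at zero the marginal covariance is sigma^2 I and the REML
    criterion reduces to residual least squares with the n - p denominator.
    """
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df=n - p)
    return beta, se, pval, sigma2


def bivariate_screen(table: pd.DataFrame, outcome: str,
                     candidates: Sequence[str],
                     forced: Sequence[str] = (),
                     screen_alpha: float = 0.2) -> list[str]:
    """Stage-one screen: keep candidates with bivariate p < ``screen_alpha``.

    Each candidate is tested in ``outcome ~ 1 + candidate`` (Gaussian,
    identity link on the transformed scale); categorical candidates use the
    Wald F test of their dummy block.  Forced predictors pass regardless of
    their p-value.  Constant covariates are excluded with a warning, never
    an exception.  The shortlist depends only on set membership, not on
    candidate order.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    if not 0 < screen_alpha < 1:
        raise ValueError("screen_alpha must be in (0, 1)")
    y = table[outcome].to_numpy(dtype=float)
    shortlist: set[str] = set()
    for cand in candidates:
        block = _design_block(table, cand)
        if block is None:
            msg = f"candidate {cand!r} is constant; excluded from the screen"
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
            continue
        X = sm.add_constant(block.to_numpy(dtype=float))
        fit = sm.OLS(y, X).fit()
        k = block.shape[1]
        if k == 1:
            p = float(fit.pvalues[1])
        else:
            contrast = np.zeros((k, X.shape[1]))
            contrast[:, 1:] = np.eye(k)
            p = float(fit.f_test(contrast).pvalue)
        if p < screen_alpha:
            shortlist.add(cand)
    keep = shortlist | set(forced)
    ordered = list(dict.fromkeys(list(candidates) + list(forced)))
    return [c for c in ordered if c in keep]


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec,
                    reml: bool = True) -> ModelResult:
    """Linear mixed model with crossed dog and walker random intercepts.

    Fits the transformed outcome on the shortlisted fixed effects.  Crossed
    random intercepts are realised as variance components over a single
    trivial group.  With ``random_effects`` empty, the zero-variance limit
    is computed in closed form (equal to ordinary least squares).
    Non-convergence raises :class:`ModelFitError`; a variance component
    estimated at (numerically) zero flags the result singular and reports 0.
    """
    if not spec.fixed_effects:
        raise ValueError("shortlist of fixed effects is non-empty by contract")
    blocks = []
    names = ["Intercept"]
    for fe in spec.fixed_effects:
        b = _design_block(table, fe)
        if b is None:
            raise ValueError(f"fixed effect {fe!r} is constant in this table")
        blocks.append(b)
        names.extend(b.columns)
    X = np.column_stack(
        [np.ones(len(table))] + [b.to_numpy(dtype=float) for b in blocks])
    y = table[spec.outcome].to_numpy(dtype=float)

    if not spec.random_effects:
        beta, se, pval, sigma2 = _ols_normal_equations(X, y)
        params = pd.DataFrame({"beta": beta, "se": se, "p": pval}, index=names)
        fitted = X @ beta
        return ModelResult(params=params, vcomp={}, residual_var=sigma2,
                           converged=True, singular=False, n_obs=len(y),
                           resid=y - fitted, fitted=fitted)

    for re_name in spec.random_effects:
        if table[re_name].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {re_name!r}")

    df = pd.DataFrame(X[:, 1:], columns=[f"x{i}" for i in range(X.shape[1] - 1)])
    df["y"] = y
    for re_name in spec.random_effects:
        df[re_name] = table[re_name].to_numpy()
    df["_unit"] = 1
    formula = "y ~ " + (" + ".join(df.columns[: X.shape[1] - 1]) or "1")
    vc = {re_name: f"0 + C({re_name})" for re_name in spec.random_effects}
    model = smf.mixedlm(formula, df, groups="_unit", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg", "powell"])
    if not result.converged:
        raise ModelFitError(
            f"mixed model for {spec.outcome!r} did not converge:\n"
            f"{getattr(result, 'mle_retvals', '')}\n{result.summary()}"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta = result.fe_params.to_numpy()
        se = result.bse_fe.to_numpy()
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ModelFitError(
            f"mixed model for {spec.outcome!r}: non-finite fixed-effect SEs "
            "(degenerate information matrix)")
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame({"beta": beta, "se": se, "p": pval}, index=names)

    vcomp = {re_name: float(v) for re_name, v in
             zip(spec.random_effects, result.vcomp)}
    singular = any(v <= 1e-10 for v in vcomp.values())
    vcomp = {k: (0.0 if v <= 1e-10 else v) for k, v in vcomp.items()}

    # predicted random effects, split back by component name
    ranef: dict[str, np.ndarray] = {}
    try:
        re_all = result.random_effects[1]
        for re_name in spec.random_effects:
            mask = [i for i in re_all.index if i.startswith(re_name)]
            ranef[re_name] = re_all.loc[mask].to_numpy()
    except Exception:  # pragma: no cover - diagnostic extra, never fatal
        pass

    fitted = X @ beta
    return ModelResult(params=params, vcomp=vcomp,
                       residual_var=float(result.scale),
                       converged=bool(result.converged), singular=singular,
                       n_obs=len(y), resid=y - fitted, fitted=fitted,
                       ranef=ranef)


def residual_diagnostics(result: ModelResult, alpha: float = 0.05,
                         n_bins: int = 4) -> Diagnostics:
    """Shapiro-Wilk on residuals and random effects; Levene across
    fitted-value quantile bins.  Degenerate inputs (constant residuals) are
    reported, not raised."""
    resid = np.asarray(result.resid, dtype=float)
    if np.allclose(resid, resid[0]):
        diag = Diagnostics(np.nan, np.nan, False, np.nan, np.nan, False,
                           {}, degenerate=True)
        result.diagnostics = diag
        return diag
    sample = resid if len(resid) <= 5000 else resid[:5000]
    w, p_norm = stats.shapiro(sample)

    qs = np.quantile(result.fitted, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(qs[1:-1], result.fitted), 0, n_bins - 1)
    groups = [resid[bins == b] for b in range(n_bins) if (bins == b).sum() >= 3]
    if len(groups) >= 2:
        lev, p_lev = stats.levene(*groups)
    else:
        lev, p_lev = np.nan, np.nan

    ranef_tests = {}
    for name, vals in result.ranef.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) >= 3 and not np.allclose(vals, vals[0]):
            s, pv = stats.shapiro(vals)
            ranef_tests[name] = (float(s), float(pv), bool(pv >= alpha))
        else:
            ranef_tests[name] = (np.nan, np.nan, False)

    diag = Diagnostics(
        resid_shapiro_stat=float(w), resid_shapiro_p=float(p_norm),
        resid_normality_ok=bool(p_norm >= alpha),
        levene_stat=float(lev), levene_p=float(p_lev),
        variance_homogeneity_ok=bool(p_lev >= alpha) if np.isfinite(p_lev) else False,
        ranef_shapiro=ranef_tests,
    )
    result.diagnostics = diag
    return diag


# ---------------------------------------------------------------------------
# study-table assembly and the full protocol
# ---------------------------------------------------------------------------

def transform_column(values: pd.Series | np.ndarray, spec: TransformSpec,
                     durations: pd.Series | np.ndarray | None = None
                     ) -> np.ndarray:
    """Apply one ledger transform to an outcome column (per-row durations
    resolve the 1/duration offset of the pulling frequencies)."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("outcome values must be non-negative")
    if spec.kind == "identity":
        return x
    if spec.kind == "log10_offset":
        if spec.delta_from_duration:
            if durations is None:
                raise ValueError("per-walk durations needed for this transform")
            return np.log10(x + 1.0 / np.asarray(durations, dtype=float))
        if spec.delta == 0.0 and np.any(x == 0):
            raise ValueError("log10 of zero: supply a positive offset delta")
        return np.log10(x + spec.delta)
    base = x / 100.0 if spec.scale == "proportion" else x
    return np.power(base, spec.power)


def build_study_table(bundle, detector_config: DetectorConfig | None = None
                      ) -> pd.DataFrame:
    """One row per walk joining design, dog covariates, assessment scores,
    detected tension metrics, behaviour metrics and questionnaire factors."""
    from .tension_meter import metrics_frame  # local import avoids cycle noise

    config = detector_config or DetectorConfig()
    metric_rows = []
    for walk_id, trace in bundle.traces.items():
        _, m = detect_pull_episodes(trace, config)
        metric_rows.append({"walk_id": walk_id, **m.to_dict()})
    tension = pd.DataFrame(metric_rows)

    behaviour = behaviour_metrics_frame(bundle.ethograms.values())
    factors = score_questionnaire_frame(bundle.questionnaires)
    assessments = aggregate_assessment_frame(bundle.assessments)

    table = (bundle.design
             .merge(bundle.dogs, on="dog_id", validate="many_to_one")
             .merge(assessments, on="dog_id", validate="many_to_one")
             .merge(tension, on="walk_id", validate="one_to_one")
             .merge(behaviour, on="walk_id", validate="one_to_one")
             .merge(factors, on="walk_id", validate="one_to_one"))
    if table["walk_id"].duplicated().any():
        raise ValueError("walk_id keys must be unique")
    return table


#: map from ledger outcome names to study-table columns where they differ
_OUTCOME_COLUMNS = {name: name for name in TRANSFORM_LEDGER}


def run_full_analysis(bundle, detector_config: DetectorConfig | None = None,
                      ledger: Mapping[str, TransformSpec] = TRANSFORM_LEDGER,
                      candidates: Sequence[str] = DEFAULT_CANDIDATES,
                      forced: Mapping[str, Sequence[str]] | None = None,
                      screen_alpha: float = 0.2,
                      outcomes: Mapping[str, Sequence[str]] = OUTCOME_FAMILIES,
                      out_dir: str | Path | None = None,
                      ) -> dict[str, pd.DataFrame]:
    """The full protocol over every outcome family.

    For each outcome: transform per the ledger (fail-closed: an outcome
    without a ledger entry is refused), screen the candidates, fit the
    crossed-random-intercept mixed model on the shortlist, and record
    beta/SE/p per predictor.  Returns one table per family (rows =
    predictors, column triplets per outcome); cells of predictors that did
    not pass the screen are left empty.  Walks with undefined outcome values
    are dropped per-model with a logged count.
    """
    table = build_study_table(bundle, detector_config)
    forced = forced or {}
    results: dict[str, pd.DataFrame] = {}
    for family, outcome_names in outcomes.items():
        cells: dict[str, dict[str, float]] = {}
        for outcome in outcome_names:
            if outcome not in ledger:
                raise KeyError(f"outcome {outcome!r} has no transform-ledger entry")
            col = _OUTCOME_COLUMNS.get(outcome, outcome)
            if col not in table.columns:
                raise KeyError(f"outcome column {col!r} missing from the study table")
            sub = table.copy()
            ok = np.isfinite(sub[col].astype(float))
            if (~ok).any():
                logger.info("dropping %d walks with undefined %s",
                            int((~ok).sum()), outcome)
                sub = sub[ok]
            ycol = f"_t_{outcome}"
            sub[ycol] = transform_column(sub[col], ledger[outcome],
                                         durations=sub.get("duration"))
            shortlist = bivariate_screen(sub, ycol, candidates,
                                         forced.get(outcome, ()), screen_alpha)
            if not shortlist:
                logger.info("no candidate survived the screen for %s", outcome)
                continue
            spec = ModelSpec(outcome=ycol, fixed_effects=tuple(shortlist),
                             screen_alpha=screen_alpha)
            try:
                fit = fit_mixed_model(sub, spec)
            except ModelFitError as err:
                logger.warning("skipping %s: %s", outcome,
                               str(err).splitlines()[0])
                continue
            residual_diagnostics(fit)
            for pred in shortlist:
                rows = [t for t in fit.params.index
                        if t == pred or t.startswith(pred + "_")]
                for term in rows:
                    cells.setdefault(term, {})
                    cells[term][f"{outcome}_beta"] = fit.params.loc[term, "beta"]
                    cells[term][f"{outcome}_se"] = fit.params.loc[term, "se"]
                    cells[term][f"{outcome}_p"] = fit.params.loc[term, "p"]
        fam_df = pd.DataFrame.from_dict(cells, orient="index")
        fam_df.index.name = "predictor"
        results[family] = fam_df.sort_index()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for family, df in results.items():
            df.to_csv(out / f"table_{family}.csv", float_format="%.6g")
        manifest = {
            "n_walks": int(len(table)),
            "families": {f: list(map(str, df.columns)) for f, df in results.items()},
            "n_cells": {f: int(df.notna().sum().sum()) for f, df in results.items()},
            "screen_alpha": screen_alpha,
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return results
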