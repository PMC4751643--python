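"""Linear mixed-effects analysis of log-transformed density outcomes.

Model
-----
For a section-level observation :math:`y_{ijk}` (outcome on the
``log10(X + 1)`` scale, section *k* of fragment *j* in treatment-arm x
condition cell *i*):

.. math::

    y_{ijk} = \\mu_i + b_j + \\varepsilon_{ijk},
    \\qquad b_j \\sim N(0, \\sigma_f^2),
    \\qquad \\varepsilon_{ijk} \\sim N(0, \\sigma^2)

with a cell-means parameterisation of the fixed part (one mean per
arm x condition combination) and a random intercept per ovarian fragment.
Estimation is REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

Inference
---------
Pairwise contrasts of cell means are tested with Wald statistics referred
to a *t* distribution with containment degrees of freedom,
``df = n_fragments - n_cells`` (the between-fragment information that
estimates cell means and their variance).  At the study's fragment counts
a large-sample normal reference is measurably anticonservative; the
containment-df *t* reference restores nominal coverage and type-I error
while converging to the normal as fragments grow.  Two contrast families
are reported:

* within-arm, between consecutive conditions in the order
  F, F-T, D2, D6 (freezing effect, then each culture interval);
* between-arm at each condition, pairing each drug with its vehicle
  (S1P vs NaOH control, Z-VAD-FMK vs DMSO control) when those arms are
  present, otherwise all arm pairs.

The only multiple-comparison handling is the conservative significance
level ``alpha = 0.01``; flags are exactly ``p < alpha`` and can be
recomputed for a different alpha without refitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .exceptions import ConfigError, DataError, FitError
from .follicles import CONDITIONS
from .synth import StudyGenConfig, simulate_observations

logger = logging.getLogger(__name__)

#: Drug/vehicle pairings used for the default between-arm contrasts.
DEFAULT_ARM_PAIRS = (("CT_NaOH", "S1P"), ("CT_DMSO", "ZVAD"))


@dataclass
class ModelSpec:
    """Specification of the mixed-model analysis for one outcome."""

    response: str | None = None  # outcome label to select; None = use all rows
    random_factor: str = "fragment_id"
    alpha: float = 0.01
    condition_order: tuple[str, ...] = CONDITIONS
    arm_pairs: tuple[tuple[str, str], ...] | None = None
    drop_empty_cells: bool = True

    def __post_init__(self):
        if not (0.0 <= self.alpha < 1.0):
            raise ConfigError("alpha must lie in [0, 1)")
        if not self.random_factor:
            raise ConfigError("random_factor must be named")


@dataclass(frozen=True)
class Contrast:
    family: str  # "within_arm" or "between_arm"
    pair: tuple[str, str]  # (cell label A, cell label B); estimate = B - A
    estimate: float
    se: float
    p_value: float
    significant: bool


@dataclass
class MixedModelFit:
    """REML fit: cell means, variance components, pairwise contrasts."""

    fixed_effects: pd.DataFrame  # arm, condition, estimate, se
    fragment_var: float
    residual_var: float
    contrasts: list[Contrast]
    alpha: float
    nobs: int
    n_fragments: int
    ddf: int = 0  # containment degrees of freedom (<1: normal reference)
    converged: bool = True

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Confidence intervals for the cell means (containment-df t)."""
        ref = sps.t(self.ddf) if self.ddf >= 1 else sps.norm
        q = float(ref.ppf(0.5 + level / 2.0))
        out = self.fixed_effects.copy()
        out["lower"] = out["estimate"] - q * out["se"]
        out["upper"] = out["estimate"] + q * out["se"]
        return out

    def with_alpha(self, alpha: float) -> "MixedModelFit":
        """Re-flag contrasts at a different alpha without refitting."""
        if not (0.0 <= alpha < 1.0):
            raise ConfigError("alpha must lie in [0, 1)")
        new_contrasts = [
            replace(c, significant=c.p_value < alpha) for c in self.contrasts
        ]
        return replace(self, contrasts=new_contrasts, alpha=alpha)

    def contrasts_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": c.family,
                "pair": f"{c.pair[1]} - {c.pair[0]}",
                "estimate": c.estimate,
                "se": c.se,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in self.contrasts
        ]
        return pd.DataFrame(
            rows,
            columns=["family", "pair", "estimate", "se", "p_value", "significant"],
        )

    def summary_text(self) -> str:
        lines = [
            "Linear mixed model (REML), random intercept per fragment",
            f"observations: {self.nobs}   fragments: {self.n_fragments}",
            f"fragment variance: {self.fragment_var:.6f}   "
            f"residual variance: {self.residual_var:.6f}",
            "",
            "Cell means (arm x condition):",
        ]
        for row in self.fixed_effects.itertuples(index=False):
            lines.append(
                f"  {row.arm:>10s} {row.condition:>4s}: "
                f"{row.estimate: .4f} (se {row.se:.4f})"
            )
        lines.append("")
        lines.append(f"Contrasts (alpha = {self.alpha}):")
        for c in self.contrasts:
            star = " *" if c.significant else ""
            lines.append(
                f"  [{c.family}] {c.pair[1]} - {c.pair[0]}: "
                f"{c.estimate: .4f} (se {c.se:.4f}, p = {c.p_value:.4g}){star}"
            )
        return "\n".join(lines)


def log_transform_outcomes(observations: pd.DataFrame) -> pd.DataFrame:
    """Ensure observations carry ``log_value = log10(raw_per_mm2 + 1)``.

    Idempotent: rows already carrying a ``log_value`` column are returned
    unchanged (the column acts as the scale tag).  Negative raw values are
    a data error.
    """
    df = observations.copy()
    if "log_value" in df.columns:
        return df
    if "raw_per_mm2" not in df.columns:
        raise DataError("observations need a raw_per_mm2 or log_value column")
    raw = df["raw_per_mm2"].to_numpy(dtype=float)
    if (raw < 0).any():
        raise DataError("raw densities must be >= 0")
    df["log_value"] = np.log10(raw + 1.0)
    return df


def _ordered(values, preferred) -> list:
    seen = list(dict.fromkeys(values))
    out = [v for v in preferred if v in seen]
    out += [v for v in seen if v not in out]
    return out


def fit_mixed_model(
    observations: pd.DataFrame, spec: ModelSpec | None = None
) -> MixedModelFit:
    """Fit the random-intercept mixed model and compute contrasts.

    ``observations`` is a tidy table with columns ``arm``, ``condition``,
    the random-factor column (default ``fragment_id``), ``log_value``
    (or ``raw_per_mm2``, transformed on the fly) and optionally
    ``outcome`` filtered by ``spec.response``.
    """
    spec = spec or ModelSpec()
    df = log_transform_outcomes(observations)
    if spec.response is not None and "outcome" in df.columns:
        df = df[df["outcome"] == spec.response]
    if df.empty:
        raise FitError("no observations to fit")
    for col in ("arm", "condition", spec.random_factor):
        if col not in df.columns:
            raise DataError(f"observations lack required column {col!r}")

    arms = _ordered(df["arm"], ())
    conditions = _ordered(df["condition"], spec.condition_order)
    if len(arms) * len(conditions) < 1 or (len(arms) < 2 and len(conditions) < 2):
        if len(arms) == 1 and len(conditions) == 1:
            pass  # degenerate intercept-only model is allowed
        else:
            raise FitError("need at least two arms or two conditions")

    # Cell-means design; empty grid cells are dropped with a warning (the
    # analysis always uses the maximum amount of data available) unless
    # the spec demands a hard failure.
    cells: list[tuple[str, str]] = []
    for arm in arms:
        for cond in conditions:
            n = int(((df["arm"] == arm) & (df["condition"] == cond)).sum())
            if n == 0:
                if spec.drop_empty_cells:
                    logger.warning(
                        "empty design cell %s x %s dropped from the fit",
                        arm, cond,
                    )
                    continue
                raise FitError(f"empty design cell: {arm} x {cond}")
            cells.append((arm, cond))
    if not cells:
        raise FitError("all design cells are empty")

    cell_index = {cell: i for i, cell in enumerate(cells)}
    row_cell = [
        cell_index[(a, c)] for a, c in zip(df["arm"], df["condition"])
    ]
    exog = np.zeros((len(df), len(cells)))
    exog[np.arange(len(df)), row_cell] = 1.0
    endog = df["log_value"].to_numpy(dtype=float)
    groups = df[spec.random_factor].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        try:
            result = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError:
            # l-bfgs can step onto the zero-variance boundary and hit a
            # singular profiled system; the default optimizer is slower
            # but handles the boundary.
            result = model.fit(reml=True)

    fe = np.asarray(result.fe_params, dtype=float)
    cov = np.asarray(result.cov_params())[: len(cells), : len(cells)]
    n_fragments = int(pd.unique(groups).size)
    # Containment df: between-fragment information left after estimating
    # one mean per design cell.  Falls back to the normal reference when
    # the design leaves no spare fragments.
    ddf = n_fragments - len(cells)
    ref = sps.t(ddf) if ddf >= 1 else sps.norm
    fixed_effects = pd.DataFrame(
        {
            "arm": [a for a, _ in cells],
            "condition": [c for _, c in cells],
            "estimate": fe,
            "se": np.sqrt(np.clip(np.diag(cov), 0.0, None)),
        }
    )

    def _contrast(family, label_a, label_b, i, j) -> Contrast:
        est = fe[j] - fe[i]
        var = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
        se = float(np.sqrt(max(var, 0.0)))
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
        else:
            p = float(2.0 * ref.sf(abs(est) / se))
        return Contrast(
            family=family,
            pair=(label_a, label_b),
            estimate=float(est),
            se=se,
            p_value=p,
            significant=p < spec.alpha,
        )

    contrasts: list[Contrast] = []
    # Within-arm: consecutive conditions in the declared order.
    for arm in arms:
        present = [c for c in conditions if (arm, c) in cell_index]
        for c1, c2 in zip(present, present[1:]):
            contrasts.append(
                _contrast(
                    "within_arm",
                    f"{arm}:{c1}", f"{arm}:{c2}",
                    cell_index[(arm, c1)], cell_index[(arm, c2)],
                )
            )
    # Between-arm at each condition.
    pairs = spec.arm_pairs
    if pairs is None:
        pairs = tuple(
            (a, b) for a, b in DEFAULT_ARM_PAIRS if a in arms and b in arms
        )
        if not pairs and len(arms) > 1:
            pairs = tuple(
                (arms[i], arms[j])
                for i in range(len(arms))
                for j in range(i + 1, len(arms))
            )
    for arm_a, arm_b in pairs:
        for cond in conditions:
            key_a, key_b = (arm_a, cond), (arm_b, cond)
            if key_a in cell_index and key_b in cell_index:
                contrasts.append(
                    _contrast(
                        "between_arm",
                        f"{arm_a}:{cond}", f"{arm_b}:{cond}",
                        cell_index[key_a], cell_index[key_b],
                    )
                )

    return MixedModelFit(
        fixed_effects=fixed_effects,
        fragment_var=float(np.asarray(result.cov_re)[0, 0]),
        residual_var=float(result.scale),
        contrasts=contrasts,
        alpha=spec.alpha,
        nobs=int(len(df)),
        n_fragments=n_fragments,
        ddf=ddf,
        converged=bool(getattr(result, "converged", True)),
    )


class DensityMixedModel(BaseEstimator):
    """Scikit-learn style estimator wrapping :func:`fit_mixed_model`.

    ``fit(X)`` expects the tidy observation table described in
    :func:`fit_mixed_model`; fitted state is exposed as
    ``fixed_effects_``, ``fragment_var_``, ``residual_var_`` and
    ``contrasts_``.
    """

    def __init__(
        self,
        response: str | None = None,
        alpha: float = 0.01,
        random_factor: str = "fragment_id",
        arm_pairs=None,
        drop_empty_cells: bool = True,
    ):
        self.response = response
        self.alpha = alpha
        self.random_factor = random_factor
        self.arm_pairs = arm_pairs
        self.drop_empty_cells = drop_empty_cells

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            response=self.response,
            alpha=self.alpha,
            random_factor=self.random_factor,
            arm_pairs=self.arm_pairs,
            drop_empty_cells=self.drop_empty_cells,
        )

    def fit(self, X: pd.DataFrame, y=None):
        fit_ = fit_mixed_model(X, self._spec())
        self.result_ = fit_
        self.fixed_effects_ = fit_.fixed_effects
        self.fragment_var_ = fit_.fragment_var
        self.residual_var_ = fit_.residual_var
        self.contrasts_ = fit_.contrasts
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted cell mean for each row's arm x condition."""
        if not hasattr(self, "result_"):
            raise FitError("model is not fitted")
        lookup = {
            (r.arm, r.condition): r.estimate
            for r in self.fixed_effects_.itertuples(index=False)
        }
        try:
            return np.array(
                [lookup[(a, c)] for a, c in zip(X["arm"], X["condition"])]
            )
        except KeyError as exc:
            raise DataError(f"unseen design cell {exc.args[0]}") from exc


@dataclass(frozen=True)
class Type1Result:
    rejection_rate: float  # pooled over all contrasts and replicates
    per_contrast_rates: dict
    n_reps: int
    n_tests: int


def type1_error_check(
    null_config: StudyGenConfig,
    spec: ModelSpec | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> Type1Result:
    """Monte-Carlo check of the per-contrast type-I error under the null.

    ``null_config`` must assign the same arm x condition effect everywhere;
    each replicate simulates a study, fits the mixed model to the
    section-level total-primordial observations and records which
    contrasts are flagged significant.  Seed-reproducible.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    effects = set(null_config.arm_condition_effects.values())
    if len(effects) != 1:
        raise ConfigError(
            "null_config must have identical effects in every arm x condition cell"
        )
    spec = spec or ModelSpec()
    hits: dict[tuple, int] = {}
    totals: dict[tuple, int] = {}
    for rep in range(n_reps):
        cfg = replace(null_config, seed=(seed + rep) % (2**31 - 1))
        obs = simulate_observations(cfg)
        fit_ = fit_mixed_model(obs, spec)
        for c in fit_.contrasts:
            key = (c.family, c.pair)
            totals[key] = totals.get(key, 0) + 1
            hits[key] = hits.get(key, 0) + int(c.significant)
    n_tests = sum(totals.values())
    n_hits = sum(hits.values())
    per_contrast = {
        key: hits[key] / totals[key] for key in sorted(totals.keys())
    }
    return Type1Result(
        rejection_rate=n_hits / n_tests if n_tests else 0.0,
        per_contrast_rates=per_contrast,
        n_reps=n_reps,
        n_tests=n_tests,
    )
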