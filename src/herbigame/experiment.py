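"""Analysis of randomized-complete-block clipping experiments.

The design: every block contains one unclipped control (``d = 0``) and one
plant per clipping fraction.  For each tissue the compensation metric is
the block-paired log response ratio

.. math:: \\mathrm{lnRR} = \\ln(m_{d} / m_{0}),

with total shoot mass counted as standing + clippings (season production).
The no-compensation expectation is ``ln(1 - d)``: a plant that loses
fraction ``d`` and mounts no regrowth.  Compensatory regrowth shows up as
an observed lnRR-versus-d slope shallower than the expected-floor slope.

Block structure is handled by fixed block intercepts (block-demeaned least
squares), which in a balanced design matches the treatment-effect point
estimates of a random-intercept mixed model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .params import ParameterError

#: Required input columns (masses in grams, ``d`` a fraction in [0, 1)).
EXPERIMENT_COLUMNS = ["block", "d", "spike_g", "shoot_standing_g", "clippings_g", "root_g"]

TISSUES = {"fruit": "spike_g", "shoot": "total_shoot_g", "root": "root_g"}


class ExperimentDataError(ParameterError):
    """Raised when an experiment table cannot be analysed."""


def read_experiment_csv(path, d_as_percent: bool = False, sep: str | None = None) -> pd.DataFrame:
    """Read an experiment table (comma or tab separated; header required).

    ``d_as_percent=True`` divides the damage column by 100.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = set(EXPERIMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ExperimentDataError(f"missing columns: {sorted(missing)}")
    df = df.copy()
    if d_as_percent:
        df["d"] = df["d"] / 100.0
    return validate_records(df)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check record invariants: d in [0,1), non-negative masses, at most
    one record per (block, treatment)."""
    if ((df["d"] < 0) | (df["d"] >= 1)).any():
        raise ExperimentDataError("clipping fractions must lie in [0, 1)")
    masses = ["spike_g", "shoot_standing_g", "clippings_g", "root_g"]
    if (df[masses] < 0).any().any():
        raise ExperimentDataError("masses must be non-negative")
    if df.duplicated(subset=["block", "d"]).any():
        raise ExperimentDataError("duplicate (block, treatment) records")
    return df


def block_ln_rr(records: pd.DataFrame) -> pd.DataFrame:
    """Block-paired log response ratios for fruit, total shoot and root.

    Each treatment plant (``d > 0``) is compared with the ``d = 0`` control
    of its own block; total shoot = standing + clippings.  Blocks without a
    usable control, and pairs with non-positive masses, are dropped with a
    warning; the dropped count is stored in ``table.attrs['n_dropped']``.
    """
    df = validate_records(records).copy()
    df["total_shoot_g"] = df["shoot_standing_g"] + df["clippings_g"]
    controls = df[df["d"] == 0].set_index("block")
    if controls.empty:
        raise ExperimentDataError("no d=0 control in any block")
    rows, dropped = [], 0
    for _, rec in df[df["d"] > 0].iterrows():
        blk = rec["block"]
        if blk not in controls.index:
            dropped += 1
            continue
        ctrl = controls.loc[blk]
        vals = {}
        ok = True
        for tissue, col in TISSUES.items():
            if rec[col] <= 0 or ctrl[col] <= 0:
                ok = False
                break
            vals[f"lnRR_{tissue}"] = math.log(rec[col] / ctrl[col])
        if not ok:
            dropped += 1
            continue
        rows.append({"block": blk, "d": rec["d"],
                     **vals, "expected_floor": math.log1p(-rec["d"])})
    if not rows:
        raise ExperimentDataError("no usable (treatment, control) pairs")
    if dropped:
        warnings.warn(f"block_ln_rr: dropped {dropped} unusable records", stacklevel=2)
    table = pd.DataFrame(rows)
    table.attrs["n_dropped"] = dropped
    return table


def expected_floor_series(d_levels) -> pd.Series:
    """Expected lnRR with no compensation, ``ln(1 - d)`` per level."""
    d = pd.Index(np.asarray(d_levels, dtype=float), name="d")
    if ((d < 0) | (d >= 1)).any():
        raise ExperimentDataError("treatment fractions must lie in [0, 1)")
    return pd.Series(np.log1p(-d.values), index=d, name="expected_floor")


@dataclass(frozen=True)
class TrendFit:
    """A fitted lnRR-versus-damage trend.

    ``scope`` records whether the response was the observed lnRR (block
    fixed effects absorbed) or the deterministic expected floor.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    scope: str
    tissue: str
    nobs: int
    df_resid: float
    resid_std: float
    conf_int: tuple[float, float]

    def summary(self) -> str:
        lo, hi = self.conf_int
        return (
            f"{self.scope} lnRR_{self.tissue} ~ d: slope {self.slope:.4f} "
            f"(SE {self.slope_se:.4f}, 95% CI [{lo:.4f}, {hi:.4f}]), "
            f"intercept {self.intercept:.4f} (SE {self.intercept_se:.4f}), "
            f"n={self.nobs}"
        )


def _with_zero_rows(table: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Append the within-block d=0 reference points (lnRR = 0 by
    construction), so trends are anchored the way the design anchors them."""
    col = f"lnRR_{tissue}"
    zero = pd.DataFrame({
        "block": table["block"].unique(),
        "d": 0.0,
        col: 0.0,
        "expected_floor": 0.0,
    })
    return pd.concat([table[["block", "d", col, "expected_floor"]], zero],
                     ignore_index=True)


def fit_trend(table: pd.DataFrame, scope: str = "observed",
              tissue: str = "shoot", include_zero: bool = True) -> TrendFit:
    """Least-squares trend of lnRR (or the expected floor) on the damage
    fraction treated as continuous.

    ``scope='observed'`` fits the block-paired lnRR with fixed block
    intercepts (block-demeaned OLS); ``scope='expected'`` fits the
    deterministic floor ``ln(1 - d)``, which is block-invariant, so the fit
    reduces to ordinary least squares on the treatment levels.
    """
    if scope not in ("observed", "expected"):
        raise ExperimentDataError(f"scope must be observed|expected, got {scope!r}")
    if tissue not in TISSUES:
        raise ExperimentDataError(f"tissue must be one of {sorted(TISSUES)}")
    data = _with_zero_rows(table, tissue) if include_zero else table.copy()
    if data["d"].nunique() < 2:
        raise ExperimentDataError("need >= 2 distinct damage levels")
    if scope == "expected":
        levels = np.sort(data["d"].unique())
        y = np.log1p(-levels)
        X = sm.add_constant(levels)
        res = sm.OLS(y, X).fit()
        slope, intercept = float(res.params[1]), float(res.params[0])
        lo, hi = (float(v) for v in res.conf_int()[1])
        return TrendFit(slope, intercept, float(res.bse[1]), float(res.bse[0]),
                        "expected", tissue, int(res.nobs), float(res.df_resid),
                        float(np.sqrt(res.scale)), (lo, hi))
    y = data[f"lnRR_{tissue}"].to_numpy(float)
    d = data["d"].to_numpy(float)
    blocks = pd.get_dummies(data["block"], drop_first=False, dtype=float)
    X = np.column_stack([d, blocks.to_numpy()])
    res = sm.OLS(y, X).fit()
    slope = float(res.params[0])
    slope_se = float(res.bse[0])
    lo, hi = (float(v) for v in res.conf_int()[0])
    # overall intercept: mean prediction at d = 0 (average block intercept)
    block_means = res.params[1:]
    intercept = float(np.mean(block_means))
    intercept_se = float(np.sqrt(np.mean(res.bse[1:] ** 2) / len(block_means)))
    return TrendFit(slope, intercept, slope_se, intercept_se, "observed",
                    tissue, int(res.nobs), float(res.df_resid),
                    float(np.sqrt(res.scale)), (lo, hi))


@dataclass(frozen=True)
class SlopeComparison:
    """Wald test of observed-versus-expected slope difference.

    ``difference = slope_observed - slope_expected``; a positive difference
    (observed slope shallower, closer to zero) is the compensatory-growth
    signature.
    """

    difference: float
    se: float
    statistic: float
    pvalue: float
    slope_observed: float
    slope_expected: float

    def summary(self) -> str:
        return (
            f"slope difference (obs - exp) = {self.difference:.4f} "
            f"(SE {self.se:.4f}), chi2 = {self.statistic:.2f}, "
            f"p = {self.pvalue:.3g}"
        )


def compare_slopes(fit_obs: TrendFit, fit_exp: TrendFit,
                   table: pd.DataFrame, tissue: str = "shoot") -> SlopeComparison:
    """Test whether the observed lnRR trend is shallower than the expected
    floor trend by stacking the two series with a scope indicator and
    Wald-testing the scope x damage interaction (chi-squared, 1 df)."""
    if fit_obs.scope != "observed" or fit_exp.scope != "expected":
        raise ExperimentDataError("pass one observed and one expected fit")
    obs = _with_zero_rows(table, tissue)
    obs_levels = set(np.round(obs["d"].unique(), 12))
    data_obs = pd.DataFrame({
        "y": obs[f"lnRR_{tissue}"], "d": obs["d"], "scope": 1.0,
        "block": obs["block"].astype(str),
    })
    # expected floor replicated per block (block-invariant response)
    blocks = obs["block"].unique()
    levels = np.sort(obs["d"].unique())
    if set(np.round(levels, 12)) != obs_levels:
        raise ExperimentDataError("mismatched damage levels")
    rep = pd.MultiIndex.from_product([blocks, levels], names=["block", "d"]).to_frame(index=False)
    data_exp = pd.DataFrame({
        "y": np.log1p(-rep["d"]), "d": rep["d"], "scope": 0.0,
        "block": rep["block"].astype(str),
    })
    data = pd.concat([data_obs, data_exp], ignore_index=True)
    blk = pd.get_dummies(data["block"], dtype=float)
    X = np.column_stack([
        np.ones(len(data)), data["d"], data["scope"], data["d"] * data["scope"],
        blk.to_numpy()[:, 1:],
    ])
    res = sm.OLS(data["y"].to_numpy(float), X).fit()
    diff = float(res.params[3])
    se = float(res.bse[3])
    chi2 = (diff / se) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return SlopeComparison(diff, se, chi2, p, fit_obs.slope, fit_exp.slope)


@dataclass(frozen=True)
class CompensationVerdict:
    d: float
    mean_lnRR: float
    t_statistic: float
    pvalue: float
    pvalue_adjusted: float
    n_blocks: int
    verdict: str


def compensation_test(table: pd.DataFrame, tissue: str = "fruit",
                      alpha: float = 0.05, adjust: str = "holm") -> pd.DataFrame:
    """Per-treatment test of perfect compensation (mean block-paired lnRR
    equal to zero).

    One-sample t-test per damage level, with a multiplicity adjustment
    (default Holm; ``adjust='none'`` for per-comparison error rates).
    Verdicts: ``full compensation`` when zero is not rejected,
    ``undercompensation`` (mean < 0, rejected) or ``overcompensation``
    (mean > 0, rejected).  Single-block treatments are skipped with a
    warning.
    """
    col = f"lnRR_{tissue}"
    if col not in table.columns:
        raise ExperimentDataError(f"no column {col!r} in lnRR table")
    rows = []
    for d, grp in table.groupby("d"):
        vals = grp[col].to_numpy(float)
        if len(vals) < 2:
            warnings.warn(f"compensation_test: skipping d={d} (single block)",
                          stacklevel=2)
            continue
        if np.allclose(vals, vals[0]):
            # degenerate zero-variance treatment: exact equality decides
            t = 0.0 if vals[0] == 0 else math.copysign(math.inf, vals[0])
            p = 1.0 if vals[0] == 0 else 0.0
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        rows.append({"d": float(d), "mean_lnRR": float(np.mean(vals)),
                     "t_statistic": float(t), "pvalue": float(p),
                     "n_blocks": len(vals)})
    if not rows:
        raise ExperimentDataError("no treatment with >= 2 blocks")
    out = pd.DataFrame(rows)
    if adjust == "none":
        out["pvalue_adjusted"] = out["pvalue"]
    else:
        out["pvalue_adjusted"] = multipletests(out["pvalue"], method=adjust)[1]
    def _verdict(r):
        if r["pvalue_adjusted"] >= alpha:
            return "full compensation"
        return "undercompensation" if r["mean_lnRR"] < 0 else "overcompensation"
    out["verdict"] = out.apply(_verdict, axis=1)
    return out


class CompensationExperiment:
    """Model object for a clipping experiment.

    Built from a tidy records table (see :data:`EXPERIMENT_COLUMNS`);
    ``fit()`` computes the block-paired lnRR table, observed and expected
    trends for the chosen tissue, the slope comparison, and per-treatment
    compensation verdicts for fruit, returning a
    :class:`CompensationResults`.
    """

    def __init__(self, records: pd.DataFrame, trend_tissue: str = "shoot") -> None:
        self.records = validate_records(records)
        self.trend_tissue = trend_tissue

    @classmethod
    def from_csv(cls, path, d_as_percent: bool = False, **kw):
        return cls(read_experiment_csv(path, d_as_percent=d_as_percent), **kw)

    def fit(self, alpha: float = 0.05, adjust: str = "holm") -> "CompensationResults":
        table = block_ln_rr(self.records)
        fo = fit_trend(table, "observed", self.trend_tissue)
        fe = fit_trend(table, "expected", self.trend_tissue)
        comp = compare_slopes(fo, fe, table, self.trend_tissue)
        verdicts = compensation_test(table, "fruit", alpha=alpha, adjust=adjust)
        return CompensationResults(table, fo, fe, comp, verdicts, self.trend_tissue)


@dataclass(frozen=True)
class CompensationResults:
    lnrr_table: pd.DataFrame
    trend_observed: TrendFit
    trend_expected: TrendFit
    slope_comparison: SlopeComparison
    verdicts: pd.DataFrame
    trend_tissue: str

    def summary(self) -> str:
        lines = [
            "Clipping-experiment compensation analysis",
            "=" * 41,
            self.trend_observed.summary(),
            self.trend_expected.summary(),
            self.slope_comparison.summary(),
            "",
            "Per-treatment fitness compensation (fruit lnRR vs 0):",
            self.verdicts.to_string(index=False,
                                    float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
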