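"""Group-level Bayesian inference: JZS Bayes factors and 2x2 RM model comparison.

One-sample (and paired) t-tests use the Jeffreys-Zellner-Siow default prior:
a Cauchy(0, rscale) prior on the standardized effect size, with
rscale = sqrt(2)/2 by default. The Bayes factor is the ratio of the marginal
likelihood of the observed t statistic under that prior (noncentral-t
likelihood integrated over the prior, by adaptive quadrature after the
arctangent substitution) to its likelihood under the point null. One-tailed
variants truncate the prior to the requested half line.

The Bayesian 2x2 repeated-measures comparison fits the five candidate mean
structures (participant blocks plus none/Condition/Speed/both/interaction)
by least squares and approximates each Bayes factor against the null via
exp(-dBIC/2). This is a BIC approximation, not a replication of JASP's
integrated g-prior ANOVA; it is used for model-selection direction only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import logsumexp
import statsmodels.formula.api as smf

from .config import RSCALE_DEFAULT
from .exceptions import InsufficientDataError

_TAILS = ("two_sided", "greater", "less")


@dataclass
class BayesResult:
    n: int
    t_stat: float
    rscale: float
    tail: str
    bf10: float
    log_bf10: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10 if self.bf10 > 0 else math.inf


@dataclass
class RmAnovaComparison:
    bf10: Dict[str, float]        # candidate model -> BF vs null (null = 1)
    best_model: str


def _log_marginal_h1(t: float, df: int, sqrt_n: float, rscale: float,
                     lo: float, hi: float, weight: float) -> float:
    """log integral of nct(t | df, delta*sqrt_n) * prior over delta.

    Integrates in theta with delta = rscale*tan(theta); the truncated-Cauchy
    prior becomes ``weight`` * uniform on (lo, hi).
    """
    def logf(theta: float) -> float:
        delta = rscale * math.tan(theta)
        return stats.nct.logpdf(t, df, delta * sqrt_n)

    theta_hat = math.atan2(t / sqrt_n, rscale)
    theta_hat = min(max(theta_hat, lo + 1e-9), hi - 1e-9)
    probe = np.linspace(lo + 1e-6, hi - 1e-6, 33)
    shift = max(max(logf(th) for th in probe), logf(theta_hat))
    if not np.isfinite(shift):
        return -math.inf

    def f(theta: float) -> float:
        return math.exp(logf(theta) - shift)

    val, _ = integrate.quad(f, lo, hi, points=[theta_hat], limit=200)
    return math.log(weight * val) + shift


def bf_one_sample_jzs(
    values: np.ndarray,
    rscale: float = RSCALE_DEFAULT,
    tail: str = "two_sided",
) -> BayesResult:
    """JZS Bayes factor testing the mean of ``values`` against zero."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite observations")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance observations")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    n = int(values.size)
    t = float(values.mean() / (sd / math.sqrt(n)))
    return bf_from_t(t, n, rscale=rscale, tail=tail)


def bf_from_t(
    t: float,
    n: int,
    rscale: float = RSCALE_DEFAULT,
    tail: str = "two_sided",
) -> BayesResult:
    """JZS Bayes factor from a one-sample t statistic and sample size."""
    if n < 3:
        raise InsufficientDataError("need at least 3 observations")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    df = n - 1
    sqrt_n = math.sqrt(n)
    half = math.pi / 2.0
    if tail == "two_sided":
        lo, hi, weight = -half, half, 1.0 / math.pi
    elif tail == "greater":
        lo, hi, weight = 0.0, half, 2.0 / math.pi
    else:  # less
        lo, hi, weight = -half, 0.0, 2.0 / math.pi
    log_m1 = _log_marginal_h1(t, df, sqrt_n, rscale, lo, hi, weight)
    log_m0 = stats.t.logpdf(t, df)
    log_bf = log_m1 - log_m0
    return BayesResult(n=n, t_stat=t, rscale=rscale, tail=tail,
                       bf10=float(np.exp(log_bf)), log_bf10=float(log_bf))


def bf_one_sample_monte_carlo(
    t: float,
    n: int,
    rscale: float = RSCALE_DEFAULT,
    tail: str = "two_sided",
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo prior-integration estimate of the same Bayes factor.

    Independent validation oracle: draws effect sizes from the (truncated)
    Cauchy prior and averages the noncentral-t likelihood.
    """
    rng = np.random.default_rng(seed)
    delta = rscale * np.tan(math.pi * (rng.random(n_draws) - 0.5))
    if tail == "greater":
        delta = np.abs(delta)
    elif tail == "less":
        delta = -np.abs(delta)
    df = n - 1
    log_like = stats.nct.logpdf(t, df, delta * math.sqrt(n))
    log_m1 = logsumexp(log_like) - math.log(n_draws)
    return float(np.exp(log_m1 - stats.t.logpdf(t, df)))


def bf_paired(
    x: np.ndarray,
    y: np.ndarray,
    rscale: float = RSCALE_DEFAULT,
    tail: str = "two_sided",
) -> BayesResult:
    """Paired-samples JZS Bayes factor: one-sample test on the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return bf_one_sample_jzs(x - y, rscale=rscale, tail=tail)


_CANDIDATES = {
    "null": "value ~ C(participant)",
    "condition": "value ~ C(participant) + C(condition)",
    "speed": "value ~ C(participant) + C(speed)",
    "condition+speed": "value ~ C(participant) + C(condition) + C(speed)",
    "condition+speed+interaction":
        "value ~ C(participant) + C(condition) * C(speed)",
}


def bf_rm_anova_2x2(table: pd.DataFrame, value_col: str = "value") -> RmAnovaComparison:
    """Approximate Bayesian 2x2 repeated-measures model comparison.

    ``table`` needs columns participant, condition, speed and the outcome;
    the design must be complete and balanced (every participant in all four
    cells) with at least 5 participants.
    """
    df = table.rename(columns={value_col: "value"})[
        ["participant", "condition", "speed", "value"]
    ].copy()
    conds = sorted(df["condition"].unique())
    speeds = sorted(df["speed"].unique())
    if len(conds) != 2 or len(speeds) != 2:
        raise ValueError("need exactly two condition and two speed levels")
    counts = df.groupby("participant").size()
    if (counts != 4).any():
        raise InsufficientDataError("incomplete design: missing cells")
    if len(counts) < 5:
        raise InsufficientDataError("need at least 5 participants")
    bics = {name: smf.ols(formula, data=df).fit().bic
            for name, formula in _CANDIDATES.items()}
    bf10 = {name: float(np.exp((bics["null"] - bic) / 2.0))
            for name, bic in bics.items()}
    best = max(bf10, key=bf10.get)
    return RmAnovaComparison(bf10=bf10, best_model=best)


# ---------------------------------------------------------------------------
# hypothesis suite
# ---------------------------------------------------------------------------

_EXPECTED_SIGNS = {"beta_error": -1, "beta_pl": -1, "beta_ta": 1, "beta_so": 1}


def _one_sample_entry(values: np.ndarray, rscale: float, expected_sign: int,
                      tail: str = "two_sided") -> dict:
    res = bf_one_sample_jzs(values, rscale=rscale, tail=tail)
    mean = float(np.mean(values))
    return {
        "n": res.n,
        "t": res.t_stat,
        "tail": res.tail,
        "bf10": res.bf10,
        "log_bf10": res.log_bf10,
        "mean": mean,
        "expected_sign": expected_sign,
        "direction_consistent": bool(np.sign(mean) == expected_sign),
    }


def hypothesis_suite(fit_table: pd.DataFrame, rscale: float = RSCALE_DEFAULT) -> dict:
    """Run the H1-H4 hypothesis suite over a cohort fit table.

    ``fit_table`` is wide: one row per (participant, condition, speed) with
    columns beta_error_25, beta_error_51, aev2_25, aev2_51 and, when the
    muscle model was fit, beta_pl, beta_ta, beta_so, aev3.

    H1a/H1b test the model-2 and model-3 coefficients against zero in
    steady-state walking, per speed. H2 (ankle-moment constraint) and H3
    (foot-placement constraint) compare absolute explained variances to
    steady state in 2x2 (Condition x Speed) model comparisons, with
    one-tailed paired post hocs per speed when the preferred model contains
    Condition. H4 tests AEV between speeds (one-tailed, slow > normal as
    hypothesized, plus the reverse as an exploratory check).
    """
    required = {"participant", "condition", "speed"}
    if not required.issubset(fit_table.columns):
        raise ValueError(f"fit table needs columns {sorted(required)}")
    n_participants = fit_table["participant"].nunique()
    if n_participants < 3:
        raise InsufficientDataError("need at least 3 participants")
    report: dict = {"n_participants": int(n_participants), "rscale": rscale}
    steady = fit_table[fit_table["condition"] == "steady"]
    speeds = sorted(steady["speed"].unique())
    has_muscle = "beta_pl" in fit_table.columns and fit_table["beta_pl"].notna().any()

    # --- H1a: ankle-strategy coefficients vs zero -------------------------
    h1a = {}
    for speed in speeds:
        sub = steady[steady["speed"] == speed]
        h1a[speed] = {
            f"i{i}": _one_sample_entry(sub[f"beta_error_{i}"].to_numpy(),
                                       rscale, _EXPECTED_SIGNS["beta_error"])
            for i in (25, 51)
        }
    report["H1a"] = h1a

    # --- H1b: muscle coefficients vs zero ---------------------------------
    if has_muscle:
        h1b = {}
        for speed in speeds:
            sub = steady[steady["speed"] == speed]
            h1b[speed] = {
                m: _one_sample_entry(sub[f"beta_{m}"].to_numpy(),
                                     rscale, _EXPECTED_SIGNS[f"beta_{m}"])
                for m in ("pl", "ta", "so")
            }
        report["H1b"] = h1b

    # --- H2 / H3: constraint conditions vs steady state -------------------
    for key, cond, tail in (
        ("H2", "ankle_constrained", "greater"),   # steady > constrained expected
        ("H3", "fp_constrained", "less"),         # hypothesis: constrained higher
    ):
        cells = fit_table[fit_table["condition"].isin(["steady", cond])]
        if cells["condition"].nunique() < 2 or len(speeds) < 2:
            report[key] = {"skipped": f"design lacks {cond} cells at both speeds"}
            continue
        entry: dict = {}
        outcomes = ["aev2_25", "aev2_51"] + (["aev3"] if has_muscle else [])
        for outcome in outcomes:
            anova = bf_rm_anova_2x2(
                cells[["participant", "condition", "speed", outcome]],
                value_col=outcome,
            )
            e = {"anova_bf10": anova.bf10, "best_model": anova.best_model,
                 "condition_in_best": "condition" in anova.best_model
                                      or "interaction" in anova.best_model}
            if e["condition_in_best"]:
                post = {}
                for speed in speeds:
                    s = cells[cells["speed"] == speed].pivot(
                        index="participant", columns="condition", values=outcome)
                    res = bf_paired(s["steady"].to_numpy(), s[cond].to_numpy(),
                                    rscale=rscale, tail=tail)
                    post[speed] = {"bf10": res.bf10, "log_bf10": res.log_bf10,
                                   "t": res.t_stat, "tail": tail, "n": res.n}
                e["post_hoc"] = post
            entry[outcome] = e
        report[key] = entry

    # --- H4: speed effect on steady-state AEV -----------------------------
    if len(speeds) == 2:
        h4: dict = {}
        outcomes = ["aev2_25", "aev2_51"] + (["aev3"] if has_muscle else [])
        for outcome in outcomes:
            s = steady.pivot(index="participant", columns="speed", values=outcome)
            hyp = bf_paired(s["slow"].to_numpy(), s["normal"].to_numpy(),
                            rscale=rscale, tail="greater")
            expl = bf_paired(s["normal"].to_numpy(), s["slow"].to_numpy(),
                             rscale=rscale, tail="greater")
            h4[outcome] = {
                "slow_gt_normal_bf10": hyp.bf10,
                "normal_gt_slow_bf10_exploratory": expl.bf10,
                "n": hyp.n,
            }
        report["H4"] = h4
    else:
        report["H4"] = {"skipped": "both speeds required"}
    return report
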