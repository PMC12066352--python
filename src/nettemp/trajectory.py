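"""Temperature, entropy, connectivity and sum-score trajectories.

Temperature per occasion is T_g = 1/beta_g, anchored at T_1 = 1 by the
identification convention, so trajectories are *relative* rates of warming
or cooling — absolute temperatures are not comparable across independently
anchored fits (for example across strata), only their shapes are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .fitting import (BETA_FREE_LEVELS, BootstrapResult, FitOptions,
                      MultigroupFit, MultigroupModelSpec, fit_multigroup)
from .ising import Encoding, gibbs_entropy, global_strength
from .panel import BinaryPanel

Z_95 = 1.959963984540054


@dataclass
class TemperatureTrajectory:
    """Per-occasion temperature with CIs, entropy and related summaries."""

    frame: pd.DataFrame  # wave, age, beta, T, ci_lo, ci_hi, boot_lo,
    #                      boot_hi, entropy_nats, strength, mean_score,
    #                      var_score
    note: str = ("temperatures are relative to the first occasion "
                 "(T_1 = 1 by identification), not absolute values")

    @property
    def T(self) -> np.ndarray:
        return self.frame["T"].to_numpy()

    @property
    def beta(self) -> np.ndarray:
        return self.frame["beta"].to_numpy()

    @property
    def entropy(self) -> np.ndarray:
        return self.frame["entropy_nats"].to_numpy()


def _analytic_beta_ci(fit: MultigroupFit) -> np.ndarray:
    """95% CI for beta per wave via the delta method on log beta.

    The free parameter is log beta, so the Wald interval on the log scale
    transforms to a positive, slightly asymmetric interval for beta; wave 1
    is fixed at 1 with a degenerate interval.
    """
    G = fit.G
    ci = np.ones((G, 2))
    if fit.se is None:
        ci[:] = np.nan
        ci[0] = 1.0
        return ci
    sl = fit.beta_free_indices()
    se_log = fit.se[sl]
    for g in range(1, G):
        b = fit.groups[g].beta
        half = Z_95 * se_log[g - 1]
        ci[g] = [b * np.exp(-half), b * np.exp(half)]
    return ci


def temperature_trajectory(fit: MultigroupFit,
                           panels: list[BinaryPanel] | None = None,
                           bootstrap: BootstrapResult | None = None
                           ) -> TemperatureTrajectory:
    """Extract T = 1/beta per occasion with analytic (and bootstrap) CIs.

    Requires a spec in which beta varies (EQUAL_EDGES or
    EQUAL_EDGES_THRESHOLDS).  Entropy is the Gibbs entropy of that wave's
    fitted (Omega, tau_g, beta_g); strength is the beta-scaled global
    connectivity.
    """
    if fit.spec.constraint_level not in BETA_FREE_LEVELS:
        raise ValueError(
            "temperature requires a spec with free beta: use "
            "EQUAL_EDGES or EQUAL_EDGES_THRESHOLDS"
        )
    if not fit.converged:
        warnings.warn("extracting temperature from a non-converged fit",
                      RuntimeWarning)
    beta_ci = _analytic_beta_ci(fit)
    rows = []
    summaries = None
    if panels is not None:
        summaries = symptom_summary(panels)
    for g, params in enumerate(fit.groups):
        b = params.beta
        t_lo, t_hi = 1.0 / beta_ci[g, 1], 1.0 / beta_ci[g, 0]
        boot_lo = boot_hi = np.nan
        if bootstrap is not None:
            boot_lo, boot_hi = bootstrap.t_ci[g]
        rows.append(dict(
            wave=g + 1, age=fit.ages[g], beta=b, T=1.0 / b,
            ci_lo=t_lo, ci_hi=t_hi, boot_lo=boot_lo, boot_hi=boot_hi,
            entropy_nats=gibbs_entropy(params),
            strength=global_strength(params, temperature_scaled=True),
            mean_score=(summaries.loc[g, "mean_score"]
                        if summaries is not None else np.nan),
            var_score=(summaries.loc[g, "var_score"]
                       if summaries is not None else np.nan),
        ))
    return TemperatureTrajectory(frame=pd.DataFrame(rows))


def symptom_summary(panels: list[BinaryPanel]) -> pd.DataFrame:
    """Mean and variance of per-person symptom counts, per occasion.

    Sum scores count endorsed items on the {0,1} scale regardless of the
    internal encoding, matching questionnaire conventions.
    """
    rows = []
    for g, pan in enumerate(panels):
        if pan.has_missing:
            raise ValueError("complete panels required for sum scores")
        zo = pan.relabel(Encoding.ZO)
        scores = zo.values.sum(axis=1)
        rows.append(dict(wave=g + 1, age=pan.age,
                         mean_score=float(scores.mean()),
                         sd_score=float(scores.std(ddof=1)) if pan.n > 1
                         else 0.0,
                         var_score=float(scores.var(ddof=1)) if pan.n > 1
                         else 0.0))
    return pd.DataFrame(rows)


def connectivity_scaling(fit: MultigroupFit) -> pd.DataFrame:
    """Per-wave beta-scaled strength against beta * wave-1 strength.

    Under a shared Omega the ratio of scaled strength to wave-1 strength
    equals beta_g exactly (positive homogeneity of the absolute-sum
    statistic); with per-group edges the ratios are generally different and
    the table quantifies the departure.
    """
    s1 = global_strength(fit.groups[0], temperature_scaled=False)
    rows = []
    for g, params in enumerate(fit.groups):
        scaled = global_strength(params, temperature_scaled=True)
        rows.append(dict(wave=g + 1, beta=params.beta,
                         strength_scaled=scaled,
                         beta_times_strength1=params.beta * s1,
                         ratio=scaled / s1 if s1 > 0 else np.nan))
    return pd.DataFrame(rows)


@dataclass
class StratifiedResult:
    trajectories: dict[str, TemperatureTrajectory]
    fits: dict[str, MultigroupFit]
    interaction: tuple[float, float, float] | None  # (coef, se, p)
    note: str = ("per-stratum temperatures are each anchored at 1 on the "
                 "first occasion; compare relative trajectories, not levels")


def stratified_fit(panels: list[BinaryPanel],
                   labels: list[np.ndarray],
                   spec: MultigroupModelSpec,
                   options: FitOptions | None = None,
                   run_interaction: bool = True) -> StratifiedResult:
    """Fit the model independently per stratum and test trajectory parallelism.

    ``labels`` holds one array of per-individual stratum labels per wave.
    Each stratum gets its own multigroup fit with its own wave-1 anchoring;
    with exactly two strata the age x stratum interaction on temperature is
    tested via :func:`interaction_test`.
    """
    if len(labels) != len(panels):
        raise ValueError("one label array per panel required")
    strata = sorted(set(np.concatenate([np.asarray(l) for l in labels])))
    if len(strata) < 1:
        raise ValueError("no strata found")
    fits, trajs = {}, {}
    for s in strata:
        sub = []
        for pan, lab in zip(panels, labels):
            lab = np.asarray(lab)
            if lab.shape[0] != pan.n:
                raise ValueError("label length must match panel rows")
            keep = lab == s
            if not keep.any():
                raise ValueError(f"stratum {s!r} empty at wave "
                                 f"{pan.wave_index + 1}")
            sub.append(BinaryPanel(pan.values[keep], list(pan.item_names),
                                   pan.age, pan.wave_index, pan.encoding))
        fit = fit_multigroup(sub, spec, options)
        fits[str(s)] = fit
        trajs[str(s)] = temperature_trajectory(fit, panels=sub)
    interaction = None
    if run_interaction and len(strata) == 2:
        rows = []
        for s, traj in trajs.items():
            for _, r in traj.frame.iterrows():
                rows.append(dict(age=r.age, stratum=s, temperature=r["T"]))
        interaction = interaction_test(pd.DataFrame(rows))
    return StratifiedResult(trajectories=trajs, fits=fits,
                            interaction=interaction)


def interaction_test(rows: pd.DataFrame) -> tuple[float, float, float]:
    """Age x stratum interaction on temperature via a mixed model.

    Fits temperature ~ age * stratum with a random intercept on the age
    level (the grouping factor) and returns the interaction fixed effect
    (coefficient, standard error, two-sided p).  With a degenerate random
    intercept variance — common with few age levels — the model reduces to
    ordinary least squares, which is used as the fallback.
    """
    rows = rows.copy()
    needed = {"age", "stratum", "temperature"}
    if not needed <= set(rows.columns):
        raise ValueError(f"rows must have columns {sorted(needed)}")
    if rows["age"].nunique() < 2:
        raise ValueError("need at least two distinct ages")
    strata = sorted(rows["stratum"].astype(str).unique())
    if len(strata) != 2:
        raise ValueError("interaction test requires exactly two strata")
    rows["stratum"] = pd.Categorical(rows["stratum"].astype(str),
                                     categories=strata)
    for s in strata:
        if rows.loc[rows.stratum == s, "age"].nunique() < 2:
            raise ValueError(f"stratum {s!r} observed at a single age")
    term = f"age:stratum[T.{strata[1]}]"
    ols = smf.ols("temperature ~ age * stratum", rows).fit()
    scale = max(float(rows["temperature"].var()), 1e-30)
    if ols.ssr <= 1e-16 * len(rows) * scale:
        # deterministic fit: the interaction either vanishes or is exact
        coef = float(ols.params[term])
        return coef, 0.0, (1.0 if abs(coef) < 1e-10 else 0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("temperature ~ age * stratum", rows,
                             groups=rows["age"])
            mf = md.fit(reml=True, method="lbfgs")
        if np.isfinite(mf.bse[term]) and float(mf.cov_re.iloc[0, 0]) > 1e-10:
            return (float(mf.params[term]), float(mf.bse[term]),
                    float(mf.pvalues[term]))
    except Exception:
        pass
    return (float(ols.params[term]), float(ols.bse[term]),
            float(ols.pvalues[term]))


def plot_trajectory(traj: TemperatureTrajectory, path: str | None = None,
                    ax=None):
    """Minimal error-bar plot of the temperature trajectory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    f = traj.frame
    yerr = np.vstack([f["T"] - f["ci_lo"], f["ci_hi"] - f["T"]])
    ax.errorbar(f["age"], f["T"], yerr=np.clip(yerr, 0, None),
                marker="o", capsize=3)
    if np.isfinite(f["boot_lo"]).any():
        ax.fill_between(f["age"], f["boot_lo"], f["boot_hi"], alpha=0.2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("network temperature T = 1/β (relative)")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
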