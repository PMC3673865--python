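"""Aggregation of replicate selection runs into model comparisons.

The experiment produces a long table with one row per (simulation,
repetition, model, generation) holding the crossbred mean, the purebred
candidate means and the standardized cumulative response R_i.  This module
partitions the crossbred response into breed-average and heterosis
components (CR = BA + H, all in sigma_0 units and as changes from
generation 0), computes the percentage advantage of one model over another,
and tests model differences at a chosen generation with the mixed linear
model y_ij = mu + m_i + b_j + e_ij (fixed model effect, random simulation
block).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedPercentageError(ZeroDivisionError):
    pass


class InsufficientBlocksError(ValueError):
    pass


SUMMARY_COLUMNS = ["simulation", "repetition", "model", "generation",
                   "crossbred_mean", "mean_a", "mean_b", "heterosis",
                   "cumulative_response", "mu0", "sigma0",
                   "mean_a0", "mean_b0"]


def summaries_to_frame(summaries, simulation: int, repetition: int,
                       model: str, mu0: float, sigma0: float,
                       mean_a0: float, mean_b0: float) -> pd.DataFrame:
    """Flatten one run's GenerationSummary list into long-table rows."""
    rows = [{
        "simulation": simulation, "repetition": repetition, "model": model,
        "generation": s.generation, "crossbred_mean": s.crossbred_mean,
        "mean_a": s.mean_a, "mean_b": s.mean_b, "heterosis": s.heterosis,
        "cumulative_response": s.cumulative_response,
        "od_heterozygosity": (np.nan if s.od_heterozygosity is None
                              else s.od_heterozygosity),
        "mu0": mu0, "sigma0": sigma0,
        "mean_a0": mean_a0, "mean_b0": mean_b0,
    } for s in summaries]
    return pd.DataFrame(rows)


def partition_response(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row split CR = BA + H in sigma_0 units, as changes from gen 0.

    BA_i = (midparent_i - midparent_0) / sigma_0 and H_i = CR_i - BA_i, so
    the identity CR = BA + H holds exactly by construction.
    """
    out = df.copy()
    mid = 0.5 * (out["mean_a"] + out["mean_b"])
    mid0 = 0.5 * (out["mean_a0"] + out["mean_b0"])
    out["ba"] = (mid - mid0) / out["sigma0"]
    out["cr"] = out["cumulative_response"]
    out["h"] = out["cr"] - out["ba"]
    return out


def mean_trajectories(df: pd.DataFrame,
                      value: str = "cumulative_response") -> pd.DataFrame:
    """Mean of ``value`` over simulations and repetitions per model and
    generation (wide: one column per model)."""
    return (df.groupby(["model", "generation"])[value].mean()
              .unstack("model"))


def relative_response(df: pd.DataFrame, generation: int,
                      model_pair: tuple[str, str],
                      value: str = "cumulative_response") -> float:
    """100 x (mean_1 - mean_2) / mean_2 at the given generation."""
    m1, m2 = model_pair
    at = df[df["generation"] == generation]
    mean1 = at.loc[at["model"] == m1, value].mean()
    mean2 = at.loc[at["model"] == m2, value].mean()
    if not np.isfinite(mean2) or abs(mean2) < 1e-12:
        raise UndefinedPercentageError(
            f"reference model {m2!r} has mean response ~ 0")
    return float(100.0 * (mean1 - mean2) / mean2)


@dataclass
class ContrastResult:
    model_1: str
    model_2: str
    estimate: float
    se: float
    t: float
    p: float
    df: float


def model_comparison_test(df: pd.DataFrame, generation: int = 20,
                          value: str = "cumulative_response"
                          ) -> list[ContrastResult]:
    """Pairwise model contrasts at one generation under the block model.

    For the balanced layout (every model observed in every simulation with
    equal repetitions) the generalized-least-squares solution coincides with
    ordinary least squares on model and block means, and the simulation
    block cancels from every model contrast; the residual variance is the
    mean squared error after removing model and block means.  Unbalanced
    data fall back to REML via statsmodels MixedLM.
    """
    at = df[df["generation"] == generation]
    if at["simulation"].nunique() < 2:
        raise InsufficientBlocksError(
            "need at least two simulation blocks for the test")
    counts = at.groupby(["model", "simulation"]).size()
    balanced = counts.nunique() == 1
    models = sorted(at["model"].unique())
    results = []
    if balanced:
        n_m = len(models)
        n_s = at["simulation"].nunique()
        n_r = int(counts.iloc[0])
        y = at[value].to_numpy(float)
        model_means = at.groupby("model")[value].mean()
        block_means = at.groupby("simulation")[value].mean()
        grand = y.mean()
        fitted = (model_means[at["model"]].to_numpy()
                  + block_means[at["simulation"]].to_numpy() - grand)
        sse = float(np.sum((y - fitted) ** 2))
        dof = len(y) - n_m - n_s + 1
        mse = sse / dof
        se = np.sqrt(2.0 * mse / (n_s * n_r))
        for i in range(n_m):
            for j in range(i + 1, n_m):
                est = float(model_means[models[i]] - model_means[models[j]])
                tval = est / se if se > 0 else 0.0
                p = 2.0 * stats.t.sf(abs(tval), dof)
                results.append(ContrastResult(models[i], models[j], est,
                                              float(se), float(tval),
                                              float(p), float(dof)))
    else:
        import statsmodels.formula.api as smf
        data = at.rename(columns={value: "resp"})[
            ["resp", "model", "simulation"]].copy()
        fit = smf.mixedlm("resp ~ C(model)", data,
                          groups=data["simulation"]).fit(reml=True)
        means = data.groupby("model")["resp"].mean()
        for i in range(len(models)):
            for j in range(i + 1, len(models)):
                name_i = f"C(model)[T.{models[i]}]"
                name_j = f"C(model)[T.{models[j]}]"
                bi = fit.params.get(name_i, 0.0)
                bj = fit.params.get(name_j, 0.0)
                vi = fit.cov_params().get(name_i, {}).get(name_i, 0.0) \
                    if name_i in fit.params else 0.0
                vj = fit.cov_params().get(name_j, {}).get(name_j, 0.0) \
                    if name_j in fit.params else 0.0
                cij = (fit.cov_params().loc[name_i, name_j]
                       if name_i in fit.params and name_j in fit.params
                       else 0.0)
                est = float(bi - bj)
                var = float(vi + vj - 2 * cij)
                se = np.sqrt(max(var, 0.0))
                tval = est / se if se > 0 else 0.0
                dof = len(data) - len(models) - data["simulation"].nunique()
                p = 2.0 * stats.t.sf(abs(tval), dof)
                results.append(ContrastResult(models[i], models[j], est, se,
                                              float(tval), float(p),
                                              float(dof)))
    return results
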