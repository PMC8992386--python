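"""Phenotype screening of introgression lines against the recurrent parent.

Each IL is compared with the control (recurrent parent) by Dunnett's
many-to-one procedure: two-sided tests on the pooled within-group variance,
with the family-wise adjustment obtained from the equicorrelated multivariate
t distribution of the k comparison statistics. For comparison i,

    t_i = (m_i - m_0) / (s * sqrt(1/n_i + 1/n_0)),

where s^2 is the pooled within-group variance with nu = N - (k+1) degrees of
freedom, and corr(t_i, t_j) = lambda_i * lambda_j with
lambda_i = sqrt(n_i / (n_i + n_0)). The adjusted p-value is
1 - P(max_j |T_j| <= |t_i|), evaluated by conditioning on the shared normal
factor and the pooled-SD chi factor, which reduces the k-dimensional
probability to a smooth two-dimensional integral handled by Gauss-Hermite x
Gauss-Legendre quadrature. For a balanced design all lambda_j coincide and
the product over comparisons collapses to a power, so the cost is independent
of k; this is what makes screens with hundreds of ILs practical.

Screening is per environment; an IL is carried forward to the QTL scan if it
is significant in at least one environment, with its direction taken from the
significant environment(s). Conflicting directions across environments drop
the IL from direction-specific scans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.optimize import brentq

from .io_core import PhenotypeTable

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-4  # family-wise level of the published screens


# ---------------------------------------------------------------------------
# Dunnett machinery
# ---------------------------------------------------------------------------

def _quad_nodes(n_z: int = 64, n_u: int = 48):
    xz, wz = hermgauss(n_z)
    z = xz * np.sqrt(2.0)  # probabilist nodes
    wz = wz / np.sqrt(np.pi)
    xq, wq = leggauss(n_u)  # map (-1,1) -> (0,1)
    q = 0.5 * (xq + 1.0)
    wq = 0.5 * wq
    return z, wz, q, wq


_Z, _WZ, _Q, _WQ = _quad_nodes()


def dunnett_sf(t: np.ndarray, lambdas: np.ndarray, df: float) -> np.ndarray:
    """P(max_j |T_j| > t) for the central equicorrelated Dunnett statistic.

    ``lambdas`` holds one lambda_j per comparison; ``df`` are the pooled
    error degrees of freedom (``inf`` allowed for the normal limit).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lam, counts = np.unique(np.round(np.asarray(lambdas, dtype=float), 12), return_counts=True)
    if np.isinf(df):
        u = np.ones_like(_Q)
        wu = _WQ
    else:
        u = np.sqrt(stats.chi2.ppf(_Q, df) / df)  # S/sigma nodes
        wu = _WQ
    s = np.sqrt(1.0 - lam**2)
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        if not np.isfinite(ti):
            out[i] = 0.0 if ti > 0 else 1.0
            continue
        tu = abs(ti) * u[:, None]  # (nu, 1)
        # bracket per unique lambda: (nu, nz, nlam)
        a = (lam[None, None, :] * _Z[None, :, None] + tu[:, :, None]) / s[None, None, :]
        b = (lam[None, None, :] * _Z[None, :, None] - tu[:, :, None]) / s[None, None, :]
        bracket = stats.norm.cdf(a) - stats.norm.cdf(b)
        np.clip(bracket, 0.0, 1.0, out=bracket)
        prod = np.prod(bracket ** counts[None, None, :], axis=2)  # (nu, nz)
        cdf = float(wu @ prod @ _WZ)
        out[i] = min(max(1.0 - cdf, 0.0), 1.0)
    return out


def dunnett_critical_value(lambdas: np.ndarray, df: float, alpha: float) -> float:
    """Two-sided critical value t* with P(max|T_j| > t*) = alpha."""
    f = lambda t: dunnett_sf(np.array([t]), lambdas, df)[0] - alpha
    hi = 2.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("critical value search failed")
    return float(brentq(f, 1e-9, hi, xtol=1e-8))


# ---------------------------------------------------------------------------
# screening operations
# ---------------------------------------------------------------------------

@dataclass
class TraitTestResult:
    il_id: str
    trait: str
    environment: str
    il_mean: float
    control_mean: float
    difference: float
    adjusted_p: float
    direction: str  # "increase" | "decrease"
    significant: bool


def trait_means(table: PhenotypeTable, trait: str, environment: str) -> tuple[pd.DataFrame, float, int]:
    """Per-IL replicate means for one (trait, environment) stratum.

    Returns (per-IL frame with columns mean/n_reps, control mean, control n).
    ILs with zero replicates are absent by construction; single-replicate ILs
    are flagged ``low_replication``.
    """
    sub = table.stratum(trait, environment)
    if sub.empty:
        raise KeyError(f"no records for trait={trait!r}, environment={environment!r}")
    grp = sub.groupby("il_id")["value"].agg(["mean", "count"]).rename(columns={"count": "n_reps"})
    ctrl = grp.loc[table.control_id]
    grp = grp.drop(index=table.control_id)
    grp["low_replication"] = grp["n_reps"] < 2
    for il in grp.index[grp["low_replication"]]:
        log.warning("IL %s has a single replicate for %s/%s", il, trait, environment)
    return grp, float(ctrl["mean"]), int(ctrl["n_reps"])


def dunnett_test(
    samples: dict[str, np.ndarray],
    control: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    trait: str = "",
    environment: str = "",
    variance_model: str = "pooled",
) -> pd.DataFrame:
    """Dunnett many-to-one comparison of each IL's replicates against the control.

    Returns one row per IL with the adjusted two-sided p-value, direction and
    significance at ``alpha``. ``variance_model='pooled'`` is the classic
    Dunnett procedure; ``'unequal'`` uses per-comparison Welch statistics with
    a Sidak family adjustment (a conservative approximation, off by default).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    control = np.asarray(control, dtype=float)
    if len(control) < 2:
        raise ValueError("need >= 2 control replicates")
    ids = list(samples)
    groups = [np.asarray(samples[i], dtype=float) for i in ids]
    ns = np.array([len(g) for g in groups])
    n0 = len(control)
    means = np.array([g.mean() for g in groups])
    m0 = control.mean()
    diffs = means - m0
    k = len(groups)

    if variance_model == "pooled":
        ss = sum(((g - g.mean()) ** 2).sum() for g in groups) + ((control - m0) ** 2).sum()
        df = int(ns.sum() + n0 - (k + 1))
        if df < 1:
            raise ValueError("no degrees of freedom for the pooled variance")
        s2 = ss / df
        if s2 <= 0.0:
            adj_p = np.where(diffs == 0.0, 1.0, 0.0)
            if (diffs != 0.0).any():
                log.warning("zero pooled variance with unequal means: reporting p=0")
        else:
            se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
            tstat = diffs / se
            lambdas = np.sqrt(ns / (ns + n0))
            adj_p = dunnett_sf(np.abs(tstat), lambdas, df)
    elif variance_model == "unequal":
        raw = np.array(
            [stats.ttest_ind(g, control, equal_var=False).pvalue if g.std(ddof=1) + control.std(ddof=1) > 0
             else (1.0 if g.mean() == m0 else 0.0) for g in groups]
        )
        adj_p = 1.0 - (1.0 - raw) ** k
    else:
        raise ValueError(f"unknown variance model {variance_model!r}")

    return pd.DataFrame(
        {
            "il_id": ids,
            "trait": trait,
            "environment": environment,
            "il_mean": means,
            "control_mean": m0,
            "difference": diffs,
            "adjusted_p": adj_p,
            "direction": np.where(diffs >= 0, "increase", "decrease"),
            "significant": adj_p < alpha,
        }
    )


def screen_traits(
    table: PhenotypeTable,
    alpha: float = DEFAULT_ALPHA,
    variance_model: str = "pooled",
) -> pd.DataFrame:
    """Run the Dunnett screen for every (trait, environment) stratum."""
    frames = []
    for trait in table.traits:
        for env in table.environments:
            sub = table.stratum(trait, env)
            if sub.empty:
                continue
            samples = {
                str(il): g["value"].to_numpy()
                for il, g in sub.groupby("il_id")
                if il != table.control_id
            }
            control = sub[sub["il_id"] == table.control_id]["value"].to_numpy()
            frames.append(
                dunnett_test(samples, control, alpha=alpha, trait=trait, environment=env,
                             variance_model=variance_model)
            )
    return pd.concat(frames, ignore_index=True)


def significant_sets(screen: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Direction-specific significant IL sets per trait, pooled over environments.

    An IL enters (trait, direction) if significant with that direction in at
    least one environment; ILs significant in opposite directions in different
    environments are excluded and logged.
    """
    out: dict[tuple[str, str], list[str]] = {}
    for trait, grp in screen.groupby("trait"):
        sig = grp[grp["significant"]]
        dirs = sig.groupby("il_id")["direction"].agg(set)
        conflicted = [il for il, d in dirs.items() if len(d) > 1]
        for il in conflicted:
            log.warning("IL %s significant in opposite directions for %s; excluded", il, trait)
        for direction in ("increase", "decrease"):
            ils = sorted(il for il, d in dirs.items() if d == {direction})
            out[(str(trait), direction)] = ils
    return out


def env_correlation(values_env1: pd.Series, values_env2: pd.Series) -> tuple[float, float]:
    """Pearson correlation of per-IL trait means between two environments."""
    shared = values_env1.index.intersection(values_env2.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 ILs measured in both environments")
    r, p = stats.pearsonr(values_env1.loc[shared], values_env2.loc[shared])
    return float(r), float(p)
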