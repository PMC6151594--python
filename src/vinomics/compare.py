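"""Sample-preparation method comparison: MANOVA gate, per-isotope balanced
ANOVA with compact-letter Tukey displays, blank-compromise channel exclusion,
per-method RSD summaries, and correlation-matrix PCA of elemental profiles.

The experimental layout is a balanced three-way main-effects design — sample
(wine), replicate, and preparation method — with no interactions.  On a
balanced design the factors are orthogonal, so the analysis of variance is
computed directly from sums of squares of the level means; the decomposition
SS_sample + SS_replicate + SS_method + SS_residual = SS_total is exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DegenerateDesignError,
    MissingDataError,
    UnbalancedDesignError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "ManovaResult",
    "PCAResult",
    "ExclusionResult",
    "manova_method_effect",
    "anova_per_isotope",
    "tukey_letters",
    "blank_compromise_filter",
    "profile_matrix",
    "pca_profiles",
    "summarize_rsd",
]

_EFFECTS = ("wine", "replicate", "method")


# ---------------------------------------------------------------------------
# Balanced main-effects ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-channel three-way main-effects ANOVA with Tukey letters by method."""

    element: str
    mass: int
    f: dict[str, float]
    p: dict[str, float]
    ss: dict[str, float]
    df: dict[str, int]
    mse: float
    df_resid: int
    method_means: dict[str, float]
    letters: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False


def _check_balanced(data: pd.DataFrame, factors: Sequence[str] = _EFFECTS) -> None:
    counts = data.groupby(list(factors), observed=True).size()
    full = np.prod([data[f].nunique() for f in factors])
    if len(counts) != full or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "the main-effects ANOVA requires a fully crossed balanced design "
            f"({' × '.join(factors)}); observed cell counts: "
            f"{sorted(counts.unique().tolist())}"
        )


def _balanced_anova(data: pd.DataFrame, response: str = "concentration") -> dict:
    """Direct sums-of-squares decomposition on the balanced design."""
    y = data[response].to_numpy(dtype=float)
    n = y.size
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    ss, dfree = {}, {}
    for factor in _EFFECTS:
        means = data.groupby(factor, observed=True)[response].mean()
        counts = data.groupby(factor, observed=True)[response].size()
        ss[factor] = float(np.sum(counts.to_numpy() * (means.to_numpy() - grand) ** 2))
        dfree[factor] = len(means) - 1
    ss_resid = ss_total - sum(ss.values())
    df_resid = n - 1 - sum(dfree.values())
    ss_resid = max(ss_resid, 0.0)
    out = {"ss": ss, "df": dfree, "ss_total": ss_total,
           "ss_resid": ss_resid, "df_resid": df_resid}
    f, p = {}, {}
    degenerate = ss_resid <= 0 or df_resid <= 0
    for factor in _EFFECTS:
        if degenerate or dfree[factor] == 0:
            f[factor], p[factor] = float("nan"), float("nan")
        else:
            ms = ss[factor] / dfree[factor]
            mse = ss_resid / df_resid
            f[factor] = ms / mse
            p[factor] = float(stats.f.sf(f[factor], dfree[factor], df_resid))
    out.update(f=f, p=p, degenerate=degenerate)
    return out


def anova_per_isotope(
    quant: pd.DataFrame,
    alpha: float = 0.05,
    roles: Sequence[str] = ("sample",),
) -> list[AnovaResult]:
    """Main-effects (sample, replicate, method) ANOVA for every channel.

    Expects the censored long quantitation table; uses the wine samples only
    by default.  The design must be balanced (it is by construction of the
    batch).  Tukey letters for the method groups are attached whenever the
    residual variance is positive.
    """
    data = quant[quant["role"].isin(roles)]
    if data.empty:
        raise MissingDataError("no sample rows for ANOVA")
    results = []
    for (element, mass), grp in data.groupby(["element", "mass"]):
        _check_balanced(grp)
        a = _balanced_anova(grp)
        method_means = grp.groupby("method")["concentration"].mean().to_dict()
        n_per_group = len(grp) // grp["method"].nunique()
        res = AnovaResult(
            element=element,
            mass=int(mass),
            f=a["f"],
            p=a["p"],
            ss={**a["ss"], "residual": a["ss_resid"], "total": a["ss_total"]},
            df={**a["df"], "residual": a["df_resid"]},
            mse=a["ss_resid"] / a["df_resid"] if a["df_resid"] > 0 else float("nan"),
            df_resid=a["df_resid"],
            method_means=method_means,
            degenerate=a["degenerate"],
        )
        if not res.degenerate and res.mse > 0:
            res.letters = tukey_letters(
                method_means, res.mse, res.df_resid, n_per_group, alpha=alpha
            )
        else:
            res.letters = {m: "a" for m in method_means}
        results.append(res)
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    """Tidy per-channel ANOVA export, one row per channel."""
    rows = []
    for r in results:
        row = {"element": r.element, "mass": r.mass, "degenerate": r.degenerate}
        for eff in _EFFECTS:
            row[f"F_{eff}"] = r.f[eff]
            row[f"p_{eff}"] = r.p[eff]
        for m, mean in sorted(r.method_means.items()):
            row[f"mean_{m}"] = mean
            row[f"letters_{m}"] = r.letters.get(m, "")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tukey compact letter display
# ---------------------------------------------------------------------------

def tukey_letters(
    group_means: dict[str, float],
    mse: float,
    df_resid: int,
    n_per_group: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display from Tukey's Honestly Significant Difference.

    HSD = q(1−α; k, df) × sqrt(MSE/n).  Groups whose means differ by more
    than the HSD receive disjoint letter sets; groups sharing a letter are not
    significantly different.  With a single threshold the non-significant
    groupings are contiguous runs of the sorted means, so the maximal runs
    are found by a sweep and lettered in order.
    """
    if mse <= 0:
        raise ValueError("MSE must be positive for Tukey comparisons")
    if len(group_means) < 2:
        raise ValueError("need at least two groups")
    k = len(group_means)
    q = stats.studentized_range.ppf(1 - alpha, k, df_resid)
    hsd = q * np.sqrt(mse / n_per_group)

    ordered = sorted(group_means.items(), key=lambda kv: -kv[1])
    names = [g for g, _ in ordered]
    means = np.array([m for _, m in ordered])

    # Maximal contiguous runs of mutually non-significant groups.  Since the
    # means are sorted, the reach j(i) of each start index is non-decreasing,
    # so a run is maximal exactly when it reaches further than its predecessor.
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and means[i] - means[j + 1] <= hsd:
            j += 1
        if not runs or j > runs[-1][1]:
            runs.append((i, j))
    letters = {name: "" for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (i, j) in enumerate(runs):
        for g in range(i, j + 1):
            letters[names[g]] += alphabet[idx % len(alphabet)]
    return letters


# ---------------------------------------------------------------------------
# MANOVA gate
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    statistic: float  # Pillai's trace for the method effect
    p_value: float
    channels: list[str]
    n_obs: int


def manova_method_effect(
    quant: pd.DataFrame,
    channels: Optional[Sequence[tuple[str, int]]] = None,
    roles: Sequence[str] = ("sample",),
) -> ManovaResult:
    """Multivariate test (Pillai's trace) of the preparation-method effect.

    Fits the multivariate linear model with the wine, replicate and method
    main effects over the replicate-level profiles and reports the Pillai
    trace for the method term.  The number of observations must exceed the
    number of response channels; pass a channel subset otherwise.
    """
    from statsmodels.multivariate.manova import MANOVA

    data = quant[quant["role"].isin(roles)]
    wide = data.pivot_table(
        index=["wine", "method", "replicate"],
        columns=["element", "mass"],
        values="concentration",
    )
    if channels is not None:
        wide = wide[[(e, m) for e, m in channels]]
    n_obs, n_ch = wide.shape
    n_params = (
        data["wine"].nunique() + data["replicate"].nunique()
        + data["method"].nunique() - 2
    )
    if n_obs - n_params < n_ch:
        raise DegenerateDesignError(
            f"{n_obs} observations cannot support a MANOVA on {n_ch} channels "
            "(singular error covariance); pass a channel subset via `channels`"
        )
    frame = wide.reset_index()
    ycols = []
    for i in range(n_ch):
        frame[f"y{i}"] = wide.iloc[:, i].to_numpy()
        ycols.append(f"y{i}")
    formula = (
        " + ".join(ycols) + " ~ C(wine) + C(replicate) + C(method)"
    )
    frame = frame[["wine", "replicate", "method"] + ycols]
    mv = MANOVA.from_formula(formula, data=frame)
    table = mv.mv_test().results["C(method)"]["stat"]
    return ManovaResult(
        statistic=float(table.loc["Pillai's trace", "Value"]),
        p_value=float(table.loc["Pillai's trace", "Pr > F"]),
        channels=[f"{m}{e}" for e, m in wide.columns],
        n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# Blank-compromise exclusion
# ---------------------------------------------------------------------------

@dataclass
class ExclusionResult:
    excluded: set
    reasons: dict  # (element, mass) -> list of reasons
    p_sample: dict


def blank_compromise_filter(
    quant: pd.DataFrame,
    alpha: float = 0.05,
) -> ExclusionResult:
    """Channels compromised by method blanks, with the reason per channel.

    A channel is excluded when (a) an ANOVA that includes the method blanks
    as an additional sample level finds no significant sample effect
    (``no-sample-effect``), or (b) the mean method-blank concentration meets
    or exceeds the mean wine concentration for at least one preparation
    method (``blank-exceeds-sample``).
    """
    samples = quant[quant["role"] == "sample"]
    blanks = quant[quant["role"] == "method_blank"]
    if blanks.empty:
        raise MissingDataError("method blanks are required for the blank filter")
    combined = pd.concat([samples, blanks], ignore_index=True)

    excluded = set()
    reasons: dict[tuple[str, int], list[str]] = {}
    p_sample: dict[tuple[str, int], float] = {}
    for (element, mass), grp in combined.groupby(["element", "mass"]):
        key = (element, int(mass))
        _check_balanced(grp)
        a = _balanced_anova(grp)
        p = a["p"]["wine"]
        p_sample[key] = p
        why = []
        if a["degenerate"] or not (p <= alpha):
            why.append("no-sample-effect")
        wine_means = (
            grp[grp["wine"] != "BLANK"].groupby("method")["concentration"].mean()
        )
        blank_means = (
            grp[grp["wine"] == "BLANK"].groupby("method")["concentration"].mean()
        )
        if bool((blank_means >= wine_means.reindex(blank_means.index)).any()):
            why.append("blank-exceeds-sample")
        if why:
            excluded.add(key)
            reasons[key] = why
    logger.info("blank-compromise filter excluded %d channels", len(excluded))
    return ExclusionResult(excluded=excluded, reasons=reasons, p_sample=p_sample)


# ---------------------------------------------------------------------------
# Profiles and PCA
# ---------------------------------------------------------------------------

def profile_matrix(
    quant: pd.DataFrame,
    exclude: Optional[set] = None,
) -> pd.DataFrame:
    """Wine × method mean profiles (censored concentrations, µg/L).

    Rows are (wine, method) sample means over replicates; columns are isotope
    channels in mass order.  Censoring guarantees no missing cells.
    """
    samples = quant[quant["role"] == "sample"]
    wide = samples.pivot_table(
        index=["wine", "method"],
        columns=["element", "mass"],
        values="concentration",
        aggfunc="mean",
    )
    order = sorted(wide.columns, key=lambda em: em[1])
    wide = wide[order]
    if exclude:
        wide = wide[[c for c in wide.columns if (c[0], int(c[1])) not in exclude]]
    wide.columns = [f"{int(m)}{e}" for e, m in wide.columns]
    return wide


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_fraction: np.ndarray
    dropped: list


def pca_profiles(matrix: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of the profile matrix.

    Columns are standardized to zero mean and unit (sample) variance, the
    correlation matrix eigendecomposed, and components sorted by decreasing
    eigenvalue.  Zero-variance columns are dropped with a warning.  Sign
    convention: the largest-magnitude loading of each component is positive.
    Variance fractions sum to 1 and eigenvalues to the retained column count.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise DegenerateDesignError("PCA needs at least 2 rows and 2 columns")
    sd = matrix.std(ddof=1)
    dropped = list(matrix.columns[(sd == 0) | sd.isna()])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        logger.info("PCA dropped zero-variance columns: %s", dropped)
    X = matrix.drop(columns=dropped)
    if X.shape[1] < 2:
        raise DegenerateDesignError("fewer than 2 non-constant columns for PCA")
    Z = (X - X.mean()) / X.std(ddof=1)
    corr = np.asarray(Z.T @ Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # fix sign: largest-|loading| entry of each component positive
    for j in range(eigvec.shape[1]):
        idx = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[idx, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    pcs = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=pcs)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=X.index, columns=pcs)
    explained = eigval / eigval.sum()
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_fraction=explained,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# RSD summaries
# ---------------------------------------------------------------------------

def summarize_rsd(quant: pd.DataFrame) -> pd.Series:
    """Mean replicate RSD (%) per preparation method over detected channels.

    The RSD is taken over replicates within each (wine, method, channel)
    cell; cells containing any censored replicate are excluded (variability
    of substituted LOD/2 values is meaningless).
    """
    from .quant import rsd

    samples = quant[quant["role"] == "sample"]
    rows = []
    for (wine, method, element, mass), grp in samples.groupby(
        ["wine", "method", "element", "mass"]
    ):
        if grp["censored"].any() or len(grp) < 2:
            continue
        if grp["concentration"].mean() == 0:
            continue
        rows.append({"method": method, "rsd": rsd(grp["concentration"].to_numpy())})
    if not rows:
        raise MissingDataError("no uncensored replicate groups for RSD summary")
    frame = pd.DataFrame(rows)
    return frame.groupby("method")["rsd"].mean()
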