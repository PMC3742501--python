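"""Situation-level analyses: similarity, association and valence.

Situations are summarised either by the mean of the eight acoustic
variables over their calls or by their call-type proportion vector. These
profiles feed three analyses:

* acoustic (dis)similarity of situations: agglomerative hierarchical
  clustering with Euclidean distance and Ward's criterion, reported as a
  dendrogram (also serializable to Newick);
* call-type x situation association: Pearson chi-square (or a Monte-Carlo
  permutation chi-square with both margins fixed when expected counts fall
  below 5), interpreted through Pearson residuals with the rule-of-thumb
  evidence tiers |r| > 2 and |r| > 4;
* valence: experts rank the situations from most negative (rank 1) to most
  positive; per-situation mean ranks are correlated with mean acoustic
  variables (Spearman) and regressed against call-type proportions with a
  quasi-binomial GLM (logit link, totals as weights, Pearson-dispersion
  F-tests). p-values within each analysis family are adjusted by the
  Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .acoustics import FEATURE_NAMES


def situation_profiles(
    table: pd.DataFrame, mode: str = "acoustic", type_col: str = "type"
) -> pd.DataFrame:
    """Per-situation mean feature vectors or call-type proportions.

    ``table`` holds one row per call with a ``situation`` column plus
    either the eight feature columns (acoustic mode, natural units) or a
    call-type column (types mode). Rows are situations.
    """
    if "situation" not in table.columns:
        raise ValueError("table needs a 'situation' column")
    if table.empty:
        raise ValueError("no calls")
    if mode == "acoustic":
        return table.groupby("situation")[FEATURE_NAMES].mean()
    if mode == "types":
        counts = pd.crosstab(table["situation"], table[type_col])
        return counts.div(counts.sum(axis=1), axis=0)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Ward dendrogram of situations


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    leaves: list[str]

    def newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"

    def cophenetic(self) -> pd.DataFrame:
        d = hierarchy.cophenet(self.linkage)
        from scipy.spatial.distance import squareform

        return pd.DataFrame(squareform(d), index=self.leaves, columns=self.leaves)

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.leaves)


def ward_dendrogram(profiles: pd.DataFrame) -> Dendrogram:
    """Ward-linkage hierarchical clustering of situation profiles
    (Euclidean distance between profile vectors)."""
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 situation profiles")
    if profiles.index.duplicated().any():
        raise ValueError("duplicate situation codes in profiles")
    Z = hierarchy.linkage(profiles.to_numpy(dtype=float), method="ward")
    return Dendrogram(linkage=Z, leaves=list(profiles.index))


# ---------------------------------------------------------------------------
# call-type x situation association


@dataclass
class AssociationResult:
    table: pd.DataFrame  # observed counts (types x situations)
    expected: pd.DataFrame
    chi2: float
    df: int | None  # None when Monte Carlo
    p: float
    monte_carlo: bool
    n_mc: int | None
    residuals: pd.DataFrame
    flags2: pd.DataFrame  # residual > 2
    flags4: pd.DataFrame  # residual > 4


def association_test(
    type_labels, situations, n_mc: int = 2000, seed: int = 0
) -> AssociationResult:
    """Chi-square test of call-type x situation association.

    Uses the asymptotic chi-square when every expected count is >= 5,
    otherwise a Monte-Carlo permutation chi-square resampling tables with
    both margins fixed (``n_mc`` replicates). Pearson residuals
    (obs - exp)/sqrt(exp) are flagged at the > 2 and > 4 evidence tiers.
    """
    observed = pd.crosstab(pd.Series(type_labels, name="type"), pd.Series(situations, name="situation"))
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("need at least 2 call types and 2 situations")
    row = observed.sum(axis=1).to_numpy()
    col = observed.sum(axis=0).to_numpy()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate margins: empty row or column")
    total = row.sum()
    expected = np.outer(row, col) / total
    chi2 = float(((observed.to_numpy() - expected) ** 2 / expected).sum())
    residuals = (observed - expected) / np.sqrt(expected)
    monte_carlo = bool((expected < 5).any())
    if monte_carlo:
        sampler = stats.random_table(row, col)
        tables = sampler.rvs(n_mc, random_state=np.random.default_rng(seed))
        null = ((tables - expected) ** 2 / expected).sum(axis=(1, 2))
        p = float((1 + np.sum(null >= chi2)) / (n_mc + 1))
        df = None
    else:
        df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
        p = float(stats.chi2.sf(chi2, df))
    expected_df = pd.DataFrame(expected, index=observed.index, columns=observed.columns)
    return AssociationResult(
        table=observed,
        expected=expected_df,
        chi2=chi2,
        df=df,
        p=p,
        monte_carlo=monte_carlo,
        n_mc=n_mc if monte_carlo else None,
        residuals=residuals,
        flags2=residuals > 2,
        flags4=residuals > 4,
    )


# ---------------------------------------------------------------------------
# valence: expert ranks, correlations, quasi-binomial regression


def mean_valence(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Mean expert negativity rank per situation with a normal 95% CI.

    Rank 1 is the most negative situation. Every expert row must be a
    permutation of 1..S.
    """
    S = rank_table.shape[1]
    expected = np.arange(1, S + 1)
    for expert, row in rank_table.iterrows():
        if not np.array_equal(np.sort(row.to_numpy()), expected):
            raise ValueError(f"row {expert!r} is not a permutation of 1..{S}")
    mean = rank_table.mean(axis=0)
    n = rank_table.shape[0]
    sem = rank_table.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(0.0, index=mean.index)
    sem = sem.fillna(0.0)
    return pd.DataFrame(
        {"mean_rank": mean, "ci_low": mean - 1.96 * sem, "ci_high": mean + 1.96 * sem}
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up FDR adjustment (NaNs passed through)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _spearman(x: np.ndarray, y: np.ndarray, seed: int = 0, n_mc: int = 10000) -> tuple[float, float]:
    """Spearman rho with a permutation p-value.

    Exact enumeration of all rank permutations up to n = 8; seeded Monte
    Carlo (``n_mc`` draws) for larger n, where enumeration is infeasible.
    Two-sided p on |rho|.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)

    def rho_of(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = rho_of(rx, ry)
    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(rho_of(rx[list(perm)], ry)) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_mc):
        if abs(rho_of(rx[rng.permutation(n)], ry)) >= abs(rho) - 1e-12:
            count += 1
    return rho, (1 + count) / (1 + n_mc)


def valence_feature_correlation(
    profiles: pd.DataFrame, valence: pd.Series, fdr_q: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Spearman correlation of each mean acoustic variable with valence.

    ``profiles`` holds per-situation mean features (natural units);
    ``valence`` the mean negativity rank per situation. Returns one row
    per variable with rho, raw p and the BH-adjusted p across the family
    of variables; constant variables are reported with NaN rho and a note.
    """
    if profiles.shape[0] < 4:
        raise ValueError("need at least 4 situations")
    common = profiles.index.intersection(valence.index)
    profiles = profiles.loc[common]
    ranks = valence.loc[common].to_numpy(dtype=float)
    rows = []
    for var in profiles.columns:
        x = profiles[var].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"variable": var, "rho": np.nan, "p_raw": np.nan, "note": "constant"})
            continue
        rho, p = _spearman(x, ranks, seed=seed)
        rows.append({"variable": var, "rho": rho, "p_raw": p, "note": ""})
    out = pd.DataFrame(rows).set_index("variable")
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < fdr_q
    return out


def valence_type_regression(
    type_counts: pd.DataFrame, valence: pd.Series, fdr_q: float = 0.05
) -> pd.DataFrame:
    """Quasi-binomial regression of call-type proportions on valence rank.

    For each call type, the per-situation proportion of that type is
    regressed on the mean negativity rank with a logit-link binomial
    model weighted by the per-situation call totals. Overdispersion is
    absorbed by the Pearson chi-square/df dispersion estimate and the
    slope is tested with a drop-in-deviance F-test on (1, S - 2) degrees
    of freedom. p-values are BH-adjusted across the call types.
    """
    import statsmodels.api as sm

    if type_counts.shape[0] < 4:
        raise ValueError("need at least 4 situations")
    common = type_counts.index.intersection(valence.index)
    counts = type_counts.loc[common]
    ranks = valence.loc[common].to_numpy(dtype=float)
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ValueError("every situation needs a positive call total")
    exog = sm.add_constant(ranks)
    S = len(common)
    rows = []
    for call_type in counts.columns:
        prop = counts[call_type].to_numpy(dtype=float) / totals
        note = ""
        if np.all(prop == 0) or np.all(prop == 1):
            note = "separation"
            warnings.warn(
                f"call type {call_type!r}: all-zero or all-one proportions", stacklevel=2
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(prop, exog, family=sm.families.Binomial(), var_weights=totals).fit()
            null_fit = sm.GLM(
                prop, np.ones((S, 1)), family=sm.families.Binomial(), var_weights=totals
            ).fit()
        df_resid = S - 2
        dispersion = float(fit.pearson_chi2) / df_resid
        if dispersion > 0:
            F = float((null_fit.deviance - fit.deviance) / 1.0 / dispersion)
            p = float(stats.f.sf(F, 1, df_resid))
        else:
            F, p = np.nan, np.nan
        rows.append(
            {
                "call_type": call_type,
                "b": float(fit.params[1]),
                "F": F,
                "dispersion": dispersion,
                "p_raw": p,
                "note": note,
            }
        )
    out = pd.DataFrame(rows).set_index("call_type")
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < fdr_q
    return out
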