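"""Interstate statistics: discriminant classification, permutation MANOVA,
confidence-interval letter groupings and isotope-geography correlations.

Collection states are predicted from feather isotope combinations by
linear discriminant analysis (pooled covariance, equal priors) and
summarised as resubstitution classification rates. Forward stepwise
selection with Wilks' lambda partial-F tests identifies which isotopes
carry discriminatory signal. Group differences in (d13C, d15N) between
resident and migrant birds are tested by permutational MANOVA on
Euclidean distances (Anderson's pseudo-F), which avoids the multivariate
normality and homoscedasticity assumptions of parametric MANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .raster_io import FeatherSample

__all__ = [
    "ClassificationTable",
    "PermanovaResult",
    "StepwiseResult",
    "ISOTOPE_COMBOS",
    "lda_classification_rates",
    "stepwise_wilks",
    "permanova",
    "state_summary",
    "geo_correlations",
]

_ISO_COLUMNS = {"H": "d2h", "C": "d13c", "N": "d15n"}
ISOTOPE_COMBOS = ("H", "C", "N", "HC", "HN", "CN", "HCN")


@dataclass(frozen=True)
class ClassificationTable:
    """% of birds classified to their collection state, per isotope combo."""

    rates: pd.DataFrame  # index combos, columns subsets
    rounded: bool = True


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_perm: int
    df_between: int
    df_resid: int
    exact: bool = False  # True when p came from exhaustive enumeration


@dataclass(frozen=True)
class StepwiseResult:
    selected: tuple[str, ...]
    wilks_lambda: float
    f_stat: float
    df1: int
    df2: int


def _frame(samples: Iterable[FeatherSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bird_id": [s.bird_id for s in samples],
            "state": [s.state for s in samples],
            "season": [s.season for s in samples],
            "lat": [s.lat for s in samples],
            "lon": [s.lon for s in samples],
            "d2h": [s.d2h for s in samples],
            "d13c": [s.d13c for s in samples],
            "d15n": [s.d15n for s in samples],
        }
    )


# ---------------------------------------------------------------------------
# discriminant classification


def _lda_rate(X: np.ndarray, y: np.ndarray, cross_validate: bool) -> float:
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    classes = np.unique(y)
    priors = np.full(len(classes), 1 / len(classes))
    if cross_validate:
        hits = 0
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            if len(np.unique(y[mask])) < len(classes):
                continue
            lda = LinearDiscriminantAnalysis(priors=priors).fit(X[mask], y[mask])
            hits += int(lda.predict(X[i : i + 1])[0] == y[i])
        return 100.0 * hits / len(y)
    lda = LinearDiscriminantAnalysis(priors=priors).fit(X, y)
    return 100.0 * float((lda.predict(X) == y).mean())


def lda_classification_rates(
    samples: Sequence[FeatherSample],
    combos: Sequence[str] = ISOTOPE_COMBOS,
    subsets: Sequence[str] = ("all", "spring", "winter"),
    cross_validate: bool = False,
    round_percent: bool = True,
) -> ClassificationTable:
    """Classification-to-collection-state rates per isotope combo and season.

    Equal priors and resubstitution rates by default (matching the
    classical discriminant-procedure defaults); ``cross_validate=True``
    gives leave-one-out rates instead.
    """
    df = _frame(samples)
    table = pd.DataFrame(index=list(combos), columns=list(subsets), dtype=float)
    for subset in subsets:
        sub = df if subset == "all" else df[df["season"] == subset]
        for combo in combos:
            cols = [_ISO_COLUMNS[ch] for ch in combo]
            use = sub.dropna(subset=cols)
            y = use["state"].to_numpy()
            if len(np.unique(y)) < 2:
                raise ValueError(f"subset {subset!r} has fewer than 2 states")
            counts = pd.Series(y).value_counts()
            if (counts < len(cols) + 2).any():
                raise ValueError("a state has too few birds for this combination")
            X = use[cols].to_numpy(dtype=float)
            rate = _lda_rate(X, y, cross_validate)
            table.loc[combo, subset] = round(rate) if round_percent else rate
    return ClassificationTable(rates=table, rounded=round_percent)


# ---------------------------------------------------------------------------
# stepwise selection with Wilks' lambda


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Lambda = det(W) / det(T) for response columns X and groups y."""
    if X.shape[1] == 0:
        return 1.0
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in np.unique(y):
        xg = X[y == g]
        W += (xg - xg.mean(axis=0)).T @ (xg - xg.mean(axis=0))
    detT = np.linalg.det(T)
    if detT <= 0:
        raise np.linalg.LinAlgError("singular total scatter matrix")
    return float(np.linalg.det(W) / detT)


def _rao_f(lam: float, n: int, g: int, p: int) -> tuple[float, int, int]:
    """Rao's F approximation to the Wilks' lambda null distribution."""
    q = g - 1
    if p * q == 2 or min(p, q) == 1:
        s = 1.0
    else:
        s = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    df1 = p * q
    m = n - 1 - (p + g) / 2
    df2 = m * s - p * q / 2 + 1
    lam_s = lam ** (1 / s)
    f = (1 - lam_s) / lam_s * df2 / df1
    return float(f), int(round(df1)), int(round(df2))


def stepwise_wilks(
    samples: Sequence[FeatherSample],
    candidates: Sequence[str] = ("d2h", "d13c", "d15n"),
    entry_alpha: float = 0.15,
    stay_alpha: float = 0.15,
) -> StepwiseResult:
    """Forward stepwise discriminant-variable selection.

    At each step the candidate with the largest Wilks' lambda partial F is
    entered if its p-value beats ``entry_alpha``; entered variables whose
    partial F degrades beyond ``stay_alpha`` are removed. Returns the
    selected set with the overall lambda and its F approximation.
    """
    from scipy import stats

    if len(candidates) == 0:
        raise ValueError("no candidate variables")
    df = _frame(samples).dropna(subset=list(candidates))
    y = df["state"].to_numpy()
    g = len(np.unique(y))
    if g < 2:
        raise ValueError("need at least 2 states")
    n = len(df)
    selected: list[str] = []

    def partial_f(var: str, current: list[str]) -> tuple[float, float]:
        base = _wilks_lambda(df[current].to_numpy(float), y) if current else 1.0
        full = _wilks_lambda(df[current + [var]].to_numpy(float), y)
        ratio = full / base
        p_in = len(current)
        df1 = g - 1
        df2 = n - g - p_in
        if df2 <= 0 or ratio <= 0:
            return 0.0, 1.0
        f = df2 / df1 * (1 - ratio) / ratio
        return f, float(stats.f.sf(f, df1, df2))

    changed = True
    while changed:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            scored = [(partial_f(c, selected), c) for c in remaining]
            (f, p), best = max(scored, key=lambda t: t[0][0])
            if p < entry_alpha:
                selected.append(best)
                changed = True
        # backward check
        for var in list(selected):
            others = [v for v in selected if v != var]
            f, p = partial_f(var, others)
            if p > stay_alpha:
                selected.remove(var)
                changed = True
    if not selected:
        return StepwiseResult(selected=(), wilks_lambda=1.0, f_stat=0.0, df1=0, df2=0)
    lam = _wilks_lambda(df[selected].to_numpy(float), y)
    f, df1, df2 = _rao_f(lam, n, g, len(selected))
    return StepwiseResult(selected=tuple(selected), wilks_lambda=lam, f_stat=f, df1=df1, df2=df2)


# ---------------------------------------------------------------------------
# permutation MANOVA (Anderson's pseudo-F on Euclidean distances)


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return float(ss_total), float(ss_within)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, g: int, n: int) -> tuple[float, float]:
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_between = ss_total - ss_within
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    return f, ss_between / ss_total


def _count_distinct_assignments(counts: np.ndarray) -> float:
    from math import comb

    total = counts.sum()
    ways = 1.0
    rest = int(total)
    for c in counts:
        ways *= comb(rest, int(c))
        rest -= int(c)
    return ways


def permanova(
    X: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-way permutational MANOVA on Euclidean distances.

    pseudo-F = (SS_B / df_B) / (SS_W / df_W) with the sums of squares
    computed from pairwise squared distances (SS_total = sum d^2 / n over
    unordered pairs; SS_W analogously within groups). The p-value shuffles
    group labels over rows; when the data admit fewer distinct label
    arrangements than ``n_perm`` the exact enumeration is used instead.
    For a univariate response the pseudo-F equals the classical one-way
    ANOVA F.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    labels = np.asarray(groups)
    n = len(labels)
    if X.shape[0] != n:
        raise ValueError("response matrix and groups differ in length")
    uniq, counts = np.unique(labels, return_counts=True)
    g = len(uniq)
    if g < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    f_obs, r2 = _pseudo_f(d2, labels, g, n)

    n_distinct = _count_distinct_assignments(counts)
    if n_distinct <= n_perm:
        from sympy.utilities.iterables import multiset_permutations

        f_perm = []
        for perm in multiset_permutations(list(labels)):
            f_perm.append(_pseudo_f(d2, np.asarray(perm), g, n)[0])
        f_perm = np.asarray(f_perm)
        # enumeration includes the identity arrangement; p is the exact
        # fraction of arrangements at least as extreme
        p = float((f_perm >= f_obs - 1e-12).mean())
        return PermanovaResult(f_obs, r2, p, len(f_perm) - 1, g - 1, n - g, exact=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm, g, n)[0] >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(f_obs, r2, float(p), n_perm, g - 1, n - g, exact=False)


# ---------------------------------------------------------------------------
# state summaries with CI letters


def _ci_letters(lower: np.ndarray, upper: np.ndarray) -> list[str]:
    """Compact letter display from CI overlap, on mean-ordered groups.

    Every maximal run of consecutive groups whose intervals pairwise
    overlap shares one letter; runs nested in a longer run are dropped.
    """
    k = len(lower)
    runs: list[tuple[int, int]] = []
    i = 0
    for i in range(k):
        j = i
        while j + 1 < k and all(
            min(upper[a], upper[j + 1]) >= max(lower[a], lower[j + 1]) for a in range(i, j + 1)
        ):
            j += 1
        runs.append((i, j))
    # keep maximal runs only
    maximal = [r for r in runs if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal = sorted(set(maximal))
    letters = [""] * k
    for idx, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for t in range(a, b + 1):
            letters[t] = letters[t] + ("," if letters[t] else "") + ch
    return letters


def state_summary(
    samples: Sequence[FeatherSample], isotope: str = "d2h"
) -> pd.DataFrame:
    """Per-state mean, SE, range and 95% CI with overlap letter groups."""
    df = _frame(samples).dropna(subset=[isotope])
    rows = []
    for state, sub in df.groupby("state"):
        v = sub[isotope].to_numpy(float)
        if len(v) < 2:
            raise ValueError(f"state {state!r} has fewer than 2 birds")
        se = v.std(ddof=1) / np.sqrt(len(v))
        rows.append(
            {
                "state": state,
                "mean": v.mean(),
                "se": se,
                "n": len(v),
                "min": v.min(),
                "max": v.max(),
                "ci_lower": v.mean() - 1.96 * se,
                "ci_upper": v.mean() + 1.96 * se,
            }
        )
    out = pd.DataFrame(rows).sort_values("mean", ascending=False, ignore_index=True)
    out["letters"] = _ci_letters(out["ci_lower"].to_numpy(), out["ci_upper"].to_numpy())
    return out


def geo_correlations(samples: Sequence[FeatherSample]) -> pd.DataFrame:
    """Pearson r, adjusted R^2 and p for each isotope against lat and lon."""
    from scipy import stats

    df = _frame(samples)
    rows = []
    for isotope in ("d2h", "d13c", "d15n"):
        sub = df.dropna(subset=[isotope])
        for coord in ("lat", "lon"):
            x = sub[coord].to_numpy(float)
            y = sub[isotope].to_numpy(float)
            if len(x) < 3:
                raise ValueError("need at least 3 samples")
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError("zero variance in correlation input")
            r, p = stats.pearsonr(x, y)
            n = len(x)
            adj_r2 = 1 - (1 - r**2) * (n - 1) / (n - 2)
            rows.append(
                {"isotope": isotope, "coord": coord, "r": float(r),
                 "adj_r2": float(adj_r2), "p": float(p), "n": n}
            )
    return pd.DataFrame(rows)
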