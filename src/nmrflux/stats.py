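"""Group-difference and structure analyses of concentration tables.

Covers the statistical layer of the workflow: autoscaling (z-scores per
metabolite or globally), one-way ANOVA feature ranking with an F-threshold
panel rule, PCA by singular value decomposition of the column-centered
matrix, deterministic hierarchical leaf ordering for heat-map display,
between-condition Pearson correlation-difference maps, and hypergeometric
pathway over-representation of a selected identifier set.

Concentration tables are pandas DataFrames (samples x metabolites,
non-negative relative units) as produced by :mod:`nmrflux.quantify`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import f_oneway, hypergeom

DEFAULT_ANOVA_THRESHOLD = 5.0


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PathwaySet:
    """Named pathway with its member metabolite/protein identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise StatsError(f"pathway {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def zscale(table: pd.DataFrame, mode: str = "per_metabolite") -> pd.DataFrame:
    """Scale to mean 0 / sd 1, per metabolite column or over the whole matrix.

    Zero-variance columns (``per_metabolite``) map to 0 with a warning; the
    sd uses ddof=1.
    """
    if table.shape[0] < 2:
        raise StatsError("z-scaling needs at least 2 samples")
    if mode == "per_metabolite":
        mean = table.mean(axis=0)
        sd = table.std(axis=0, ddof=1)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"zero-variance metabolites scaled to 0: {list(table.columns[flat])}",
                stacklevel=2,
            )
            sd = sd.replace(0, np.inf)
        return (table - mean) / sd
    if mode == "global":
        values = table.to_numpy(float)
        sd = values.std(ddof=1)
        if sd == 0:
            raise StatsError("constant table cannot be globally scaled")
        return (table - values.mean()) / sd
    raise StatsError(f"unknown scaling mode {mode!r}")


# ---------------------------------------------------------------------------
# ANOVA ranking
# ---------------------------------------------------------------------------

def anova_rank(
    table: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    threshold: float = DEFAULT_ANOVA_THRESHOLD,
) -> pd.DataFrame:
    """One-way ANOVA F statistic per metabolite, ranked descending.

    ``labels`` maps sample id to class.  Returns a DataFrame with columns
    (metabolite, f_statistic, rank, selected) where ``selected`` applies the
    panel rule F > ``threshold``.  Every class needs >= 2 samples.
    """
    labels = pd.Series(labels).reindex(table.index)
    if labels.isna().any():
        missing = list(table.index[labels.isna()])
        raise StatsError(f"samples without class labels: {missing}")
    classes = labels.unique()
    if len(classes) < 2:
        raise StatsError("ANOVA needs at least 2 classes")
    for cls in classes:
        n = int((labels == cls).sum())
        if n < 2:
            raise StatsError(f"class {cls!r} has {n} sample(s); at least 2 required")
    groups_idx = [labels == cls for cls in classes]

    f_stats = []
    for col in table.columns:
        samples = [table.loc[idx, col].to_numpy(float) for idx in groups_idx]
        if all(np.ptp(g) == 0 for g in samples) and len({g[0] for g in samples}) == 1:
            f = 0.0  # identical constant groups: no between- or within-group variance
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f = float(f_oneway(*samples).statistic)
            if np.isnan(f):
                f = 0.0
        f_stats.append(f)

    out = pd.DataFrame({"metabolite": table.columns, "f_statistic": f_stats})
    out = out.sort_values(
        ["f_statistic", "metabolite"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["selected"] = out["f_statistic"] > threshold
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(
    matrix: np.ndarray | pd.DataFrame, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA by SVD of the column-centered matrix.

    Returns ``(scores, loadings, explained_variance_fractions)`` with
    ``scores @ loadings.T + column_means`` reconstructing the input when all
    components are kept.  Loadings signs are fixed so each component's
    largest-magnitude loading is positive (determinism).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise StatsError("PCA needs a 2-D matrix with at least 2 samples")
    max_rank = min(X.shape)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise StatsError(f"n_components must be in [1, {max_rank}], got {n_components}")
    Xc = X - X.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total = (sv**2).sum()
    explained = (sv**2) / total if total > 0 else np.zeros_like(sv)
    scores = U[:, :n_components] * sv[:n_components]
    loadings = Vt[:n_components].T
    return scores, loadings, explained[:n_components]


# ---------------------------------------------------------------------------
# hierarchical ordering
# ---------------------------------------------------------------------------

def hierarchical_order(
    table: pd.DataFrame,
    axis: str = "metabolites",
    distance: str = "euclidean",
    linkage_method: str = "average",
) -> list[int]:
    """Deterministic leaf order from agglomerative clustering.

    ``axis`` chooses whether metabolites (columns) or samples (rows) are
    ordered; supported distances are ``euclidean`` and ``correlation``,
    linkages ``average`` and ``complete``.  SciPy's linkage breaks distance
    ties by input index, so the ordering is reproducible.
    """
    if axis == "metabolites":
        X = table.to_numpy(float).T
    elif axis == "samples":
        X = table.to_numpy(float)
    else:
        raise StatsError(f"unknown axis {axis!r}")
    if distance not in ("euclidean", "correlation"):
        raise StatsError(f"unknown distance {distance!r}")
    if linkage_method not in ("average", "complete"):
        raise StatsError(f"unknown linkage {linkage_method!r}")
    if X.shape[0] < 2:
        return list(range(X.shape[0]))
    d = pdist(X, metric=distance)
    Z = linkage(d, method=linkage_method)
    return [int(i) for i in leaves_list(Z)]


# ---------------------------------------------------------------------------
# correlation differences
# ---------------------------------------------------------------------------

def correlation_difference(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise Pearson correlation difference map r_A - r_B.

    Both tables must share the same metabolite columns and have >= 3 samples.
    The diagonal is 0 and the matrix symmetric; metabolites with zero
    variance in either table get NaN rows/columns with a warning.
    """
    if list(table_a.columns) != list(table_b.columns):
        raise StatsError("tables must share the same metabolite columns in order")
    for name, t in (("A", table_a), ("B", table_b)):
        if t.shape[0] < 3:
            raise StatsError(f"table {name} has {t.shape[0]} samples; >= 3 required")
    mats = []
    flat_any = np.zeros(table_a.shape[1], dtype=bool)
    for t in (table_a, table_b):
        X = t.to_numpy(float)
        sd = X.std(axis=0)
        flat = sd == 0
        flat_any |= flat
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.corrcoef(X, rowvar=False)
        r[flat, :] = np.nan
        r[:, flat] = np.nan
        mats.append(r)
    if flat_any.any():
        warnings.warn(
            f"zero-variance metabolites marked undefined: "
            f"{list(table_a.columns[flat_any])}",
            stacklevel=2,
        )
    delta = mats[0] - mats[1]
    np.fill_diagonal(delta, 0.0)
    delta[flat_any, :] = np.nan
    delta[:, flat_any] = np.nan
    return pd.DataFrame(delta, index=table_a.columns, columns=table_a.columns)


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def ora_hypergeometric(
    selected: set[str],
    pathways: Sequence[PathwaySet],
    universe: set[str],
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per pathway.

    With N = \\|universe\\|, K = \\|pathway ∩ universe\\|, n = \\|selected\\| and k
    the observed overlap, p = P(X >= k) for X ~ Hypergeom(N, K, n).  Pathway
    members outside the universe are ignored; ``selected`` must be a subset of
    the universe.
    """
    universe = set(universe)
    if not universe:
        raise StatsError("the universe must be non-empty")
    selected = set(selected)
    if not selected <= universe:
        raise StatsError(
            f"selected identifiers outside the universe: {sorted(selected - universe)}"
        )
    N, n = len(universe), len(selected)
    rows = []
    for pw in pathways:
        members = pw.members & universe
        K = len(members)
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append({"pathway": pw.name, "size": K, "overlap": k, "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if benjamini_hochberg and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[PathwaySet]:
    """GMT pathway sets: name <tab> description <tab> member1 <tab> ..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise StatsError(f"malformed GMT line (need name, description, members): {line!r}")
        sets.append(PathwaySet(parts[0], frozenset(p for p in parts[2:] if p)))
    return sets


def write_gmt(pathways: Sequence[PathwaySet], path: str | Path) -> None:
    lines = [
        "\t".join([pw.name, "na", *sorted(pw.members)]) for pw in pathways
    ]
    Path(path).write_text("\n".join(lines) + "\n")
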