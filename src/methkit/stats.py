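"""Exploratory statistics on the clone x CpG methylation matrix.

All statistics treat the missing state pairwise-complete: a clone enters a
pairwise computation only where it has calls at both sites involved
(listwise within a single 2x2 table for the Fisher test).

Co-occurrence between two CpG sites is reported either as the phi
coefficient (Pearson correlation of the two binary columns) or as the shared
fraction — the proportion of pairwise-complete clones with identical state at
both sites, i.e. 1 minus the normalised Hamming distance.

Correspondence analysis (CA) decomposes the 0/1 clone x CpG table under the
chi-square metric: with P = X/n, row masses r and column masses c, the SVD of
the standardised residuals S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} yields
principal inertias lambda_k = sigma_k^2 partitioning the total inertia
chi^2/n.  Row (clone) and column (CpG) principal coordinates place similar
methylation profiles at small angles in the biplot.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .calls import MethylationDataset


# ---------------------------------------------------------------- summaries

def methylation_summary(ds: MethylationDataset) -> pd.DataFrame:
    """Per-site methylation percentages, missing calls excluded.

    Returns a frame indexed by CpG position with columns
    percent_methylated (NaN when a site has no calls), n_methylated,
    n_unmethylated, n_missing.
    """
    calls = ds.calls
    n_meth = np.nansum(calls == 1.0, axis=0).astype(int)
    n_unmeth = np.nansum(calls == 0.0, axis=0).astype(int)
    n_missing = np.isnan(calls).sum(axis=0).astype(int)
    denom = n_meth + n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(denom > 0, 100.0 * n_meth / np.maximum(denom, 1),
                           np.nan)
    return pd.DataFrame(
        {
            "percent_methylated": percent,
            "n_methylated": n_meth,
            "n_unmethylated": n_unmeth,
            "n_missing": n_missing,
        },
        index=pd.Index(ds.cpg_positions, name="position"),
    )


# ------------------------------------------------------------ co-occurrence

@dataclass
class CoOccurrenceMatrix:
    """Symmetric site x site co-occurrence with pairwise-complete counts.

    Undefined entries (fewer than 2 complete clones, or zero variance in
    correlation mode) are NaN-flagged, never silently propagated.
    """

    positions: list[int]
    mode: str
    values: np.ndarray = field(repr=False)
    n_pairs: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.positions,
                            columns=self.positions)

    def neighbour_pairs(self) -> list[tuple[int, int, float]]:
        """(pos_i, pos_j, value) for adjacent site pairs."""
        return [
            (self.positions[k], self.positions[k + 1], self.values[k, k + 1])
            for k in range(len(self.positions) - 1)
        ]


def _phi(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two binary vectors (phi coefficient)."""
    if x.std() == 0.0 or y.std() == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def cooccurrence(ds: MethylationDataset, mode: str = "correlation",
                 neighbours_only: bool = False) -> CoOccurrenceMatrix:
    """Pairwise co-occurrence of methylation state between CpG sites.

    mode="correlation": phi coefficient over pairwise-complete clones.
    mode="shared_fraction": fraction of pairwise-complete clones with equal
    state at both sites (= 1 - normalised Hamming distance).
    ``neighbours_only`` masks non-adjacent pairs (diagonal kept).
    """
    if mode not in ("correlation", "shared_fraction"):
        raise ValueError(f"unknown mode {mode!r}")
    if ds.n_sites < 2:
        raise ValueError("need at least 2 CpG sites")
    m = ds.n_sites
    calls = ds.calls
    values = np.full((m, m), np.nan)
    n_pairs = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i, m):
            ok = ~np.isnan(calls[:, i]) & ~np.isnan(calls[:, j])
            n = int(ok.sum())
            n_pairs[i, j] = n_pairs[j, i] = n
            if n == 0 or (i != j and n < 2):
                continue
            x, y = calls[ok, i], calls[ok, j]
            if i == j:
                values[i, i] = 1.0
                continue
            if mode == "correlation":
                values[i, j] = values[j, i] = _phi(x, y)
            else:
                values[i, j] = values[j, i] = float(np.mean(x == y))
    if neighbours_only:
        keep = np.eye(m, dtype=bool)
        for k in range(m - 1):
            keep[k, k + 1] = keep[k + 1, k] = True
        values = np.where(keep, values, np.nan)
    return CoOccurrenceMatrix(list(ds.cpg_positions), mode, values, n_pairs)


# ------------------------------------------------------------- group tests

@dataclass
class SiteTestResult:
    """Fisher exact test of group vs methylation state at one CpG site."""

    position: int
    table: np.ndarray
    p_value: float
    degenerate: bool = False


def fisher_site_test(ds: MethylationDataset, groups,
                     position: int) -> SiteTestResult:
    """Two-sided Fisher exact test at one CpG position.

    ``groups`` maps clone id to one of exactly two labels.  Clones missing at
    the site are excluded.  The two-sided p sums hypergeometric point
    probabilities <= that of the observed table.  A table with a zero margin
    carries no information: p = 1 with ``degenerate=True``.
    """
    if position not in ds.cpg_positions:
        raise ValueError(f"position {position} is not a CpG site")
    col = ds.calls[:, ds.cpg_positions.index(position)]
    labels = sorted({groups[cid] for cid in ds.clone_ids if cid in groups})
    if len(labels) != 2:
        raise ValueError("exactly two group labels required")
    table = np.zeros((2, 2), dtype=int)
    for cid, call in zip(ds.clone_ids, col):
        if cid not in groups or np.isnan(call):
            continue
        g = labels.index(groups[cid])
        table[g, 0 if call == 1.0 else 1] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return SiteTestResult(position, table, 1.0, degenerate=True)
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return SiteTestResult(position, table, float(p))


def fisher_all_sites(ds: MethylationDataset, groups,
                     bh_correct: bool = False) -> pd.DataFrame:
    """Fisher test at every site; optional Benjamini-Hochberg column."""
    results = [fisher_site_test(ds, groups, p) for p in ds.cpg_positions]
    df = pd.DataFrame(
        {
            "position": [r.position for r in results],
            "p_value": [r.p_value for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
    if bh_correct:
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        df["p_bh"] = adj
    return df


def _mannwhitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for sample a vs b, ties counted half."""
    u = 0.0
    for x in a:
        u += np.sum(x > b) + 0.5 * np.sum(x == b)
    return float(u)


def mannwhitney_set_test(ds_a: MethylationDataset, ds_b: MethylationDataset,
                         unit: str = "site") -> tuple[float, float]:
    """Mann-Whitney U comparison of methylation between two clone groups.

    unit="site" (default): per-site percent methylation within each group is
    computed and the two per-site vectors are compared across sites.
    unit="clone": each clone's mean methylation is the sampling unit.

    Exact p by full enumeration of group assignments for combined n <= 20
    (valid under ties); tie-corrected normal approximation above.  Returns
    (U, two-sided p).
    """
    if list(ds_a.cpg_positions) != list(ds_b.cpg_positions):
        raise ValueError("datasets measure different CpG positions")
    if unit == "site":
        a = methylation_summary(ds_a)["percent_methylated"].to_numpy()
        b = methylation_summary(ds_b)["percent_methylated"].to_numpy()
    elif unit == "clone":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = 100.0 * np.nanmean(ds_a.calls, axis=1)
            b = 100.0 * np.nanmean(ds_b.calls, axis=1)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("fewer than 2 informative values per group")
    u_obs = _mannwhitney_u(a, b)
    n_a, n_b = len(a), len(b)
    if n_a + n_b <= 20:
        p = _mw_exact_p(a, b)
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        p = float(p)
    return u_obs, p


def _mw_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided permutation p for the Mann-Whitney U statistic.

    Enumerates all assignments of the pooled values into groups of the
    observed sizes; p = P(min(U_A, U_B) <= observed min).  Handles ties.
    """
    pooled = np.concatenate([a, b])
    n_a = len(a)
    n = len(pooled)
    u_a = _mannwhitney_u(a, b)
    u_b = len(a) * len(b) - u_a
    obs_min = min(u_a, u_b)
    count = 0
    total = 0
    idx = np.arange(n)
    for comb in itertools.combinations(idx, n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        u = _mannwhitney_u(pooled[mask], pooled[~mask])
        if min(u, n_a * (n - n_a) - u) <= obs_min + 1e-9:
            count += 1
        total += 1
    return count / total


# ------------------------------------------------------------- biclustering

@dataclass
class BiclusterResult:
    """Row and column dendrograms from Hamming-distance clustering."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    row_order: list[int]
    col_order: list[int]


def hamming_distance_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise normalised Hamming distance between matrix rows.

    Distance = disagreements / pairwise-complete positions; NaN when a pair
    shares no complete position.
    """
    n = calls.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(calls[i]) & ~np.isnan(calls[j])
            m = int(ok.sum())
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            d[i, j] = d[j, i] = float(
                np.sum(calls[i, ok] != calls[j, ok]) / m
            )
    return d


def hamming_bicluster(ds: MethylationDataset,
                      linkage: str = "complete") -> BiclusterResult:
    """Agglomerative clustering of clones and of sites, Hamming distance.

    Binary methylation patterns make the Hamming distance the natural
    metric (genomic ordering of sites is deliberately ignored).  Refuses to
    cluster when any pairwise distance is undefined.  Leaf order is
    deterministic: scipy's order with ties resolved by input order.
    """
    if ds.n_clones < 2 or ds.n_sites < 2:
        raise ValueError("need at least 2 clones and 2 sites")
    d_rows = hamming_distance_matrix(ds.calls)
    d_cols = hamming_distance_matrix(ds.calls.T)
    for name, d in (("clone", d_rows), ("site", d_cols)):
        if np.isnan(d).any():
            raise ValueError(
                f"a {name} pair shares no complete position; "
                "distance matrix undefined"
            )
    row_link = hierarchy.linkage(squareform(d_rows, checks=False),
                                 method=linkage)
    col_link = hierarchy.linkage(squareform(d_cols, checks=False),
                                 method=linkage)
    return BiclusterResult(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=list(hierarchy.leaves_list(row_link)),
        col_order=list(hierarchy.leaves_list(col_link)),
    )


# ----------------------------------------------------- correspondence analysis

@dataclass
class CAResult:
    """Correspondence-analysis decomposition of the methylation table."""

    row_coords: np.ndarray
    col_coords: np.ndarray
    principal_inertias: np.ndarray
    percent_inertia: np.ndarray
    total_inertia: float
    row_ids: list[str]
    col_ids: list[int]


def correspondence_analysis(ds: MethylationDataset | np.ndarray,
                            row_ids=None, col_ids=None) -> CAResult:
    """Chi-square SVD decomposition of a non-negative table.

    Missing calls contribute zero mass; all-zero rows/columns are dropped
    with a warning.  Singular values with sigma^2 < 1e-12 * lambda_max are
    treated as null dimensions.
    """
    if isinstance(ds, MethylationDataset):
        X = np.nan_to_num(ds.calls, nan=0.0)
        row_ids = list(ds.clone_ids)
        col_ids = list(ds.cpg_positions)
    else:
        X = np.asarray(ds, dtype=float)
        row_ids = list(row_ids) if row_ids is not None else list(range(X.shape[0]))
        col_ids = list(col_ids) if col_ids is not None else list(range(X.shape[1]))
    if (X < 0).any():
        raise ValueError("table must be non-negative")
    row_ok = X.sum(axis=1) > 0
    col_ok = X.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping all-zero row(s)/column(s) from CA",
                      stacklevel=2)
        X = X[row_ok][:, col_ok]
        row_ids = [r for r, ok in zip(row_ids, row_ok) if ok]
        col_ids = [c for c, ok in zip(col_ids, col_ok) if ok]
    n = X.sum()
    if n <= 0 or min(X.shape) < 1:
        raise ValueError("table has no mass")
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    lam = sigma ** 2
    # null dimensions: relative cutoff with an absolute floor so a table at
    # the independence model (all sigma at rounding error) keeps nothing
    cutoff = 1e-12 * max(lam.max(initial=0.0), 1.0)
    keep = lam >= cutoff
    U, sigma, Vt, lam = U[:, keep], sigma[keep], Vt[keep], lam[keep]
    k_max = min(X.shape) - 1
    U, sigma, Vt, lam = U[:, :k_max], sigma[:k_max], Vt[:k_max], lam[:k_max]
    total = float(lam.sum())
    if len(lam) == 0:
        # independence model: a rank-1 table has zero inertia
        return CAResult(
            row_coords=np.zeros((X.shape[0], 0)),
            col_coords=np.zeros((X.shape[1], 0)),
            principal_inertias=lam,
            percent_inertia=lam,
            total_inertia=0.0,
            row_ids=row_ids,
            col_ids=col_ids,
        )
    row_coords = (U * sigma) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sigma) / np.sqrt(c)[:, None]
    return CAResult(
        row_coords=row_coords,
        col_coords=col_coords,
        principal_inertias=lam,
        percent_inertia=100.0 * lam / total,
        total_inertia=total,
        row_ids=row_ids,
        col_ids=col_ids,
    )
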