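"""ASV-table community statistics: relative abundance, diversity, Bray-Curtis, ANOSIM.

Tables are pandas DataFrames with samples as rows and ASVs as columns
(non-negative integer counts).  Group comparisons follow the rank-based
route: Bray-Curtis dissimilarity on relative abundances, then analysis of
similarities (ANOSIM) with a label-permutation null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import ClppError, TableError
from .metrics import shannon_h

VALID_LAYERS = ("WC", "BBL")

METADATA_COLUMNS = (
    "trench",
    "layer",
    "depth_m",
    "temperature_C",
    "salinity",
    "no3_no2",
    "nh4",
    "po4",
)


def validate_asv_table(table: pd.DataFrame) -> pd.DataFrame:
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise TableError("sample or ASV ids are not unique")
    arr = table.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any():
        raise TableError("counts must be non-negative numbers")
    zero = table.index[arr.sum(axis=1) == 0]
    if len(zero):
        raise TableError(f"all-zero sample row(s): {list(zero)}")
    return table


def load_asv_table(path: str | Path, transposed: bool = False) -> pd.DataFrame:
    """Read a TSV ASV count table (samples as rows; ``transposed=True`` for ASVs as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transposed:
        df = df.T
    return validate_asv_table(df)


def load_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV with columns ``asv,domain,phylum,class``."""
    df = pd.read_csv(path, sep="\t")
    required = {"asv", "domain", "phylum", "class"}
    if not required.issubset(df.columns):
        raise TableError(f"taxonomy needs columns {sorted(required)}")
    bad = set(df["domain"].unique()) - {"Archaea", "Bacteria"}
    if bad:
        raise TableError(f"unknown domain(s): {sorted(bad)}")
    if df["asv"].duplicated().any():
        raise TableError("duplicate ASV ids in taxonomy")
    return df.set_index("asv")


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata CSV (index: sample id)."""
    df = pd.read_csv(path, index_col=0)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise TableError(f"metadata is missing column(s) {sorted(missing)}")
    bad = set(df["layer"].dropna().unique()) - set(VALID_LAYERS)
    if bad:
        raise TableError(f"unknown layer label(s): {sorted(bad)}")
    return df


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to proportions (each sample sums to 1)."""
    sums = table.sum(axis=1)
    if (sums <= 0).any():
        raise TableError(f"zero-sum sample(s): {list(table.index[sums <= 0])}")
    return table.div(sums, axis=0)


def shannon_evenness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon index H and Pielou evenness E = H / ln(S_obs).

    E is NaN for samples with a single observed ASV.
    """
    rel = relative_abundance(table)
    rows = {}
    for sample, p in rel.iterrows():
        h = shannon_h(p.to_numpy())
        s_obs = int((p > 0).sum())
        e = h / np.log(s_obs) if s_obs > 1 else np.nan
        rows[sample] = {"shannon_H": h, "evenness_E": e, "s_obs": s_obs}
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: pd.DataFrame, on: str = "relative") -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y).

    Computed on relative abundances by default (``on="counts"`` for raw
    counts).  Returns a symmetric samples x samples DataFrame with zero
    diagonal.
    """
    if on == "relative":
        data = relative_abundance(table)
    elif on == "counts":
        data = validate_asv_table(table)
    else:
        raise ClppError(f"unknown basis {on!r}")
    d = squareform(pdist(data.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int  # number of non-identity label arrangements examined


def _anosim_r(ranks: np.ndarray, within_mask: np.ndarray) -> float:
    n = within_mask.shape[0]
    iu = np.triu_indices(n, k=1)
    w = within_mask[iu]
    m = len(ranks)
    r_within = ranks[w].mean()
    r_between = ranks[~w].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 dissimilarities ranked with midrank ties.  The p-value uses
    the add-one permutation estimator p = (1 + #{R_perm >= R_obs}) /
    (1 + n_permutations); ``exact=True`` enumerates all distinct label
    arrangements instead (p = #{R >= R_obs} / #arrangements, the identity
    included).
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    groups = np.asarray(list(groups))
    n = d.shape[0]
    if d.shape != (n, n) or len(groups) != n:
        raise ClppError("distance matrix and group labels are not conformable")
    if n < 3:
        raise ClppError("ANOSIM needs at least 3 samples")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ClppError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        raise ClppError(f"singleton group(s): {list(labels[counts < 2])}")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])  # midrank ties

    def within(perm_groups: np.ndarray) -> np.ndarray:
        return perm_groups[:, None] == perm_groups[None, :]

    r_obs = _anosim_r(ranks, within(groups))

    if exact:
        seen = 0
        ge = 0
        for perm in set(itertools.permutations(groups)):
            seen += 1
            if _anosim_r(ranks, within(np.asarray(perm))) >= r_obs - 1e-12:
                ge += 1
        return AnosimResult(r_obs, ge / seen, seen - 1)

    if n_permutations < 1:
        raise ClppError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        if _anosim_r(ranks, within(perm)) >= r_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    return AnosimResult(r_obs, p, n_permutations)
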