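"""Count normalisation and log-ratio covariate construction.

Counts are normalised to log2 counts-per-million with a per-sample
pseudo-count (the edgeR-style prior), and association covariates are built as
natural-log ratios of pooled log-CPM values: per internal node the ratio of
the left to the right child leaf sets, and for the pooled genus contrast the
ratio of the genus sum to a reference aggregate (all other taxa by default,
one reference genus for ALR, or the geometric mean of all genus sums for
CLR).  A rank-based inverse-normal transform of each covariate vector gives
the small-sample-robust variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .tree_taxa import CountTable, GenusPartition, TestNode

__all__ = [
    "LogCpmTable",
    "log_cpm",
    "node_covariate",
    "pooled_covariate",
    "inverse_normal_transform",
]

POOLED_MODES = ("other_taxa", "alr_reference", "clr_geomean")


@dataclass
class LogCpmTable:
    """log2-CPM values, taxa x samples, with the sample table carried along."""

    r: pd.DataFrame
    samples: pd.DataFrame
    prior_scale: pd.Series  # the per-sample pseudo-count c_ij.


def log_cpm(table: CountTable, prior_policy: str = "constant") -> LogCpmTable:
    """Normalise counts to log2 counts-per-million.

    r_ijm = log2( (c_ijm + c_ij./2) / (L_ij + c_ij.) * 1e6 + 1 )

    where L_ij is the library size and c_ij. the per-sample pseudo-count.
    ``prior_policy``:

    - ``constant`` (default): c_ij. = 1 for every sample (prior count 0.5).
    - ``library_scaled``: c_ij. = L_ij / mean(L), scaling the prior with
      sequencing depth.
    """
    lib = table.library_size.values.astype(float)
    if (lib <= 0).any():
        bad = table.library_size.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples {bad}; filter first")
    if prior_policy == "constant":
        prior = np.ones_like(lib)
    elif prior_policy == "library_scaled":
        prior = lib / lib.mean()
    else:
        raise ValueError(f"unknown prior policy {prior_policy!r}")
    c = table.counts.values.astype(float)
    r = np.log2((c + prior / 2.0) / (lib + prior) * 1e6 + 1.0)
    return LogCpmTable(
        r=pd.DataFrame(r, index=table.counts.index, columns=table.counts.columns),
        samples=table.samples,
        prior_scale=pd.Series(prior, index=table.counts.columns),
    )


def _pooled_sum(r: LogCpmTable, taxa) -> np.ndarray:
    taxa = list(taxa)
    missing = set(taxa) - set(r.r.index)
    if missing:
        raise KeyError(f"taxa missing from log-CPM table: {sorted(missing)}")
    return r.r.loc[taxa].values.sum(axis=0)


def node_covariate(r: LogCpmTable, node: TestNode) -> pd.Series:
    """Per-sample log ratio x^(k) = log(C/D) of pooled left vs right
    log-CPM sums of test node ``node`` (natural log)."""
    C = _pooled_sum(r, node.left_leaves)
    D = _pooled_sum(r, node.right_leaves)
    if (C <= 0).any() or (D <= 0).any():
        raise ValueError("non-positive pooled log-CPM sum; corrupted input")
    return pd.Series(np.log(C / D), index=r.r.columns)


def pooled_covariate(
    r: LogCpmTable,
    genus: GenusPartition,
    mode: str = "other_taxa",
    reference_genus: GenusPartition | None = None,
    all_genus_taxa: dict | None = None,
) -> pd.Series:
    """Pooled genus covariate x^(0) = log(E/G).

    E is the genus log-CPM sum.  The reference aggregate G is, by mode:

    - ``other_taxa``: sum over every retained taxon outside the genus,
    - ``alr_reference``: the E of one named reference genus (ALR),
    - ``clr_geomean``: the geometric mean of E over all genera (CLR), with
      ``all_genus_taxa`` mapping genus name -> member taxa.
    """
    if mode not in POOLED_MODES:
        raise ValueError(f"unknown pooled-denominator mode {mode!r}")
    E = _pooled_sum(r, genus.member_taxa)
    if mode == "other_taxa":
        if not genus.other_taxa:
            raise ValueError("no taxa outside the genus for the default denominator")
        G = _pooled_sum(r, [t for t in genus.other_taxa if t in r.r.index])
    elif mode == "alr_reference":
        if reference_genus is None:
            raise ValueError("ALR mode requires a reference genus")
        if set(reference_genus.member_taxa) & set(genus.member_taxa):
            raise ValueError("ALR reference genus overlaps the tested genus")
        G = _pooled_sum(r, reference_genus.member_taxa)
    else:  # clr_geomean
        if all_genus_taxa is None:
            raise ValueError("CLR mode requires the full genus->taxa map")
        sums = [
            _pooled_sum(r, [t for t in taxa if t in r.r.index])
            for taxa in all_genus_taxa.values()
            if any(t in r.r.index for t in taxa)
        ]
        if len(sums) < 2:
            warnings.warn(
                "CLR with a single genus: pooled covariate is identically 0",
                stacklevel=2,
            )
        G = np.exp(np.mean(np.log(np.vstack(sums)), axis=0))
    if (G <= 0).any():
        raise ValueError("non-positive reference aggregate")
    return pd.Series(np.log(E / G), index=r.r.columns)


def inverse_normal_transform(x) -> np.ndarray:
    """Rank-based inverse-normal transform with adjustment parameter 0.5.

    z_i = Phi^-1((rank_i - 0.5) / n), ranks averaged over ties so tied values
    map to the same transformed value.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    if np.ptp(x) == 0:
        warnings.warn("all values identical; transform is identically 0", stacklevel=2)
        return np.zeros(n)
    ranks = rankdata(x, method="average")
    return ndtri((ranks - 0.5) / n)
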