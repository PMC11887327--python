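"""Per-genus association testing and minimum-p combination.

For a genus with M1 member taxa the test builds M1 covariates: the pooled
genus-vs-reference log ratio x(0) and one per-internal-node log ratio
x(1)..x(M1-1).  Each covariate is tested for association with the phenotype
by GEE (score or Wald, small-sample corrected), and the per-node p-values
are combined by the minimum-p method: because the node statistics are
asymptotically independent, the minimum of M1 independent uniform p-values
follows Beta(1, M1) under the global null, so the combined p-value is
1 - (1 - min p)^M1.

Variant "M" tests the raw covariates; variant "IM" first applies the
rank-based inverse-normal transform to each covariate vector, which
restores calibration at small sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import transforms
from .gee import DesignData, GeeError, WorkingCorrelation, score_test, wald_test
from .transforms import LogCpmTable, inverse_normal_transform
from .tree_taxa import (
    CountTable,
    GenusPartition,
    RootedBinaryTree,
    enumerate_test_nodes,
    filter_samples,
    filter_taxa,
)

__all__ = ["GenusResult", "StudyResult", "combine_min_p", "test_genus", "run_study"]


@dataclass
class GenusResult:
    genus: str
    M1: int
    node_pvalues: list
    min_p: float
    combined_p: float
    variant: str
    statistic: str
    wc_structure: str
    beta_hats: list = field(default_factory=list)
    n_failed_nodes: int = 0


@dataclass
class StudyResult:
    genus_results: list
    fdr_p: dict
    options: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genus_results:
            rows.append({
                "genus": g.genus,
                "M1": g.M1,
                "node_pvalues": ";".join(f"{p:.6g}" for p in g.node_pvalues),
                "min_p": g.min_p,
                "combined_p": g.combined_p,
                "fdr_p": self.fdr_p[g.genus],
                "variant": g.variant,
                "statistic": g.statistic,
                "wc": g.wc_structure,
            })
        return pd.DataFrame(rows)


def combine_min_p(node_pvalues, M1: int | None = None) -> float:
    """Beta(1, M1) upper-tail transform of the minimum node p-value.

    combined_p = 1 - (1 - min p)^M1, which is Uniform(0,1) when the node
    p-values are independent uniforms.
    """
    p = np.asarray(node_pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no node p-values to combine")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if M1 is None:
        M1 = p.size
    return float(1.0 - (1.0 - p.min()) ** M1)


def genus_covariates(
    r: LogCpmTable,
    genus: GenusPartition,
    pooled_mode: str = "other_taxa",
    reference_genus: GenusPartition | None = None,
    all_genus_taxa: dict | None = None,
) -> np.ndarray:
    """Matrix of node covariates, columns x(0)..x(M1-1), rows = samples."""
    cols = [
        transforms.pooled_covariate(
            r, genus, mode=pooled_mode,
            reference_genus=reference_genus, all_genus_taxa=all_genus_taxa,
        ).values
    ]
    for node in genus.test_nodes:
        cols.append(transforms.node_covariate(r, node).values)
    return np.column_stack(cols)


def test_genus(
    r: LogCpmTable,
    genus: GenusPartition,
    y: np.ndarray,
    Z: np.ndarray,
    subjects: np.ndarray,
    visits: np.ndarray | None = None,
    variant: str = "IM",
    statistic: str = "score",
    wc_structure: str = "identity",
    small_sample: bool = True,
    pooled_mode: str = "other_taxa",
    reference_genus: GenusPartition | None = None,
    all_genus_taxa: dict | None = None,
    nominal_M1_on_failure: bool = False,
) -> GenusResult:
    """Run the full per-genus test and return a :class:`GenusResult`.

    A node that fails numerically is dropped with a warning; by default the
    beta parameter of the combination is the realized number of valid nodes
    (set ``nominal_M1_on_failure`` to keep the nominal M1, which is
    conservative).
    """
    if variant not in ("M", "IM"):
        raise ValueError(f"unknown variant {variant!r}")
    if statistic not in ("score", "wald"):
        raise ValueError(f"unknown statistic {statistic!r}")
    X = genus_covariates(r, genus, pooled_mode, reference_genus, all_genus_taxa)
    wc = WorkingCorrelation(wc_structure)
    run = score_test if statistic == "score" else wald_test

    pvals, betas = [], []
    n_failed = 0
    for k in range(X.shape[1]):
        xk = X[:, k]
        if np.ptp(xk) == 0:
            # constant covariate (e.g. both child leaf sets always zero):
            # carries no association information
            n_failed += 1
            continue
        if variant == "IM":
            xk = inverse_normal_transform(xk)
        try:
            data = DesignData(xk, Z, y, subjects, visits)
            fit = run(data, wc, small_sample=small_sample)
            pvals.append(fit.p)
            betas.append(fit.beta_hat)
        except (GeeError, np.linalg.LinAlgError, ValueError) as exc:
            n_failed += 1
            warnings.warn(
                f"genus {genus.genus}: node {k} failed ({exc}); dropped",
                stacklevel=2,
            )
    if not pvals:
        raise GeeError(f"genus {genus.genus}: every node failed")
    M1_eff = genus.M1 if nominal_M1_on_failure else len(pvals)
    return GenusResult(
        genus=genus.genus,
        M1=M1_eff,
        node_pvalues=pvals,
        min_p=float(min(pvals)),
        combined_p=combine_min_p(pvals, M1_eff),
        variant=variant,
        statistic=statistic,
        wc_structure=wc_structure,
        beta_hats=betas,
        n_failed_nodes=n_failed,
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


def run_study(
    table: CountTable,
    tree: RootedBinaryTree,
    taxonomy: dict,
    metadata: pd.DataFrame,
    phenotype_col: str = "phenotype",
    covariate_cols: tuple = (),
    variant: str = "IM",
    statistic: str = "score",
    wc_structure: str = "identity",
    small_sample: bool = True,
    pooled_mode: str = "other_taxa",
    reference_genus_name: str | None = None,
    min_mean_prop: float = 0.001,
    min_reads: int = 3000,
    prior_policy: str = "constant",
    fdr_method: str = "bh",
    strict_monophyly: bool = True,
) -> StudyResult:
    """Filter, iterate genera, test each, and adjust across genera.

    ``taxonomy`` maps taxon id -> genus name; ``metadata`` is indexed by
    sample id with columns subject_id, visit, the phenotype and covariates.
    """
    missing = set(table.counts.columns) - set(metadata.index)
    if missing:
        raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    for col in ("subject_id", "visit", phenotype_col):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")

    table = filter_samples(table, min_reads=min_reads)
    if table.n_samples == 0:
        raise ValueError("no samples left after read-count filter")
    table = filter_taxa(table, min_mean_prop=min_mean_prop)
    r = transforms.log_cpm(table, prior_policy=prior_policy)

    meta = metadata.loc[table.counts.columns]
    y = meta[phenotype_col].values.astype(float)
    Z = np.column_stack(
        [np.ones(len(meta))] + [meta[c].values.astype(float) for c in covariate_cols]
    )
    subjects = meta["subject_id"].values
    visits = meta["visit"].values.astype(int)

    genus_map: dict = {}
    for taxon in table.taxa:
        if taxon not in taxonomy:
            raise ValueError(f"taxon {taxon!r} has no genus assignment")
        genus_map.setdefault(taxonomy[taxon], []).append(taxon)

    reference_part = None
    if pooled_mode == "alr_reference":
        if reference_genus_name not in genus_map:
            raise ValueError(
                f"reference genus {reference_genus_name!r} not present after filtering")

    # taxa filtered out of the table are tolerated inside genus clades
    filtered_out = {
        t for t, g in taxonomy.items() if t in tree.taxa and t not in set(table.taxa)
    }
    results = []
    for gname, gtaxa in genus_map.items():
        part = enumerate_test_nodes(tree, gtaxa, genus_name=gname,
                                    strict=strict_monophyly,
                                    tolerate=filtered_out)
        # restrict "other" taxa to those retained after filtering
        part.other_taxa = tuple(t for t in table.taxa if t not in set(gtaxa))
        if pooled_mode == "alr_reference":
            if gname == reference_genus_name:
                continue
            ref_taxa = genus_map[reference_genus_name]
            reference_part = GenusPartition(
                genus=reference_genus_name,
                member_taxa=tuple(sorted(ref_taxa)),
                other_taxa=(),
            )
        results.append(
            test_genus(
                r, part, y, Z, subjects, visits,
                variant=variant, statistic=statistic,
                wc_structure=wc_structure, small_sample=small_sample,
                pooled_mode=pooled_mode, reference_genus=reference_part,
                all_genus_taxa=genus_map,
            )
        )

    raw = np.array([g.combined_p for g in results])
    if fdr_method == "bh":
        adj = _bh_adjust(raw)
    elif fdr_method == "bonferroni":
        adj = np.clip(raw * raw.size, 0, 1)
    else:
        raise ValueError(f"unknown fdr method {fdr_method!r}")
    fdr = {g.genus: float(a) for g, a in zip(results, adj)}
    opts = dict(
        variant=variant, statistic=statistic, wc_structure=wc_structure,
        small_sample=small_sample, pooled_mode=pooled_mode,
        min_mean_prop=min_mean_prop, min_reads=min_reads,
        prior_policy=prior_policy, fdr_method=fdr_method,
    )
    return StudyResult(genus_results=results, fdr_p=fdr, options=opts)
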