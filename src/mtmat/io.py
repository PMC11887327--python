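"""File readers/writers and run configuration.

All tabular inputs are plain TSV: the count table has taxa as rows (first
column ``taxon_id``) and sample ids as columns; the taxonomy map is two
columns ``taxon_id<TAB>genus``; sample metadata is indexed by sample id with
columns ``subject_id``, ``visit``, the phenotype and any covariates.  Trees
are Newick with named leaves (branch lengths ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tree_taxa import CountTable, RootedBinaryTree, parse_tree

__all__ = ["RunConfig", "read_inputs", "read_counts", "read_taxonomy",
           "read_metadata", "write_results"]

log = logging.getLogger("mtmat")

_VARIANTS = ("M", "IM")
_STATISTICS = ("score", "wald")
_WC = ("identity", "CS", "AR1", "UN")
_POOLED = ("other_taxa", "alr_reference", "clr_geomean")
_PRIORS = ("constant", "library_scaled")
_FDR = ("bh", "bonferroni")


@dataclass
class RunConfig:
    """Validated options for one association run."""

    counts: Path
    tree: Path
    taxonomy: Path
    metadata: Path
    out: Path
    phenotype_col: str = "phenotype"
    covariate_cols: tuple = ()
    variant: str = "IM"
    statistic: str = "score"
    wc_structure: str = "identity"
    pooled_mode: str = "other_taxa"
    reference_genus: str | None = None
    prior_policy: str = "constant"
    min_mean_prop: float = 0.001
    min_reads: int = 3000
    small_sample: bool = True
    fdr_method: str = "bh"
    strict_monophyly: bool = True
    seed: int = 0

    def __post_init__(self):
        for attr, allowed in (("variant", _VARIANTS), ("statistic", _STATISTICS),
                              ("wc_structure", _WC), ("pooled_mode", _POOLED),
                              ("prior_policy", _PRIORS), ("fdr_method", _FDR)):
            if getattr(self, attr) not in allowed:
                raise ValueError(f"{attr} must be one of {allowed}")
        if self.pooled_mode == "alr_reference" and not self.reference_genus:
            raise ValueError("ALR mode requires --reference-genus")
        for attr in ("counts", "tree", "taxonomy", "metadata"):
            p = Path(getattr(self, attr))
            setattr(self, attr, p)
            if not p.exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        self.out = Path(self.out)


def read_counts(path, metadata: pd.DataFrame) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate taxon ids in count table: {dups}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count table")
    samples = metadata.loc[df.columns, ["subject_id", "visit"]].copy()
    samples["visit"] = samples["visit"].astype(int)
    # order columns subject-major, visits ascending, subjects by appearance
    first = {s: i for i, s in enumerate(dict.fromkeys(samples["subject_id"]))}
    order = sorted(
        df.columns,
        key=lambda c: (first[samples.loc[c, "subject_id"]], samples.loc[c, "visit"]),
    )
    return CountTable(counts=df[order], samples=samples.loc[order])


def read_taxonomy(path) -> dict:
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon_id", "genus"],
                     dtype=str, comment="#")
    return dict(zip(df["taxon_id"], df["genus"]))


def read_metadata(path, phenotype_col: str = "phenotype") -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    required = {"subject_id", "visit", phenotype_col}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
    return meta


def read_inputs(cfg: RunConfig):
    """Read and cross-validate the four input files.

    Every count-table sample must appear in the metadata; in strict mode
    every taxon must have both a tree leaf and a genus assignment.
    """
    metadata = read_metadata(cfg.metadata, cfg.phenotype_col)
    raw = pd.read_csv(cfg.counts, sep="\t", index_col=0, nrows=0)
    unmatched = set(raw.columns) - set(metadata.index)
    if unmatched:
        raise ValueError(f"count-table samples absent from metadata: "
                         f"{sorted(unmatched)}")
    if not set(raw.columns):
        raise ValueError("count table has no samples")
    table = read_counts(cfg.counts, metadata)
    tree = parse_tree(Path(cfg.tree).read_text())
    taxonomy = read_taxonomy(cfg.taxonomy)

    no_leaf = [t for t in table.taxa if t not in tree.taxa]
    no_genus = [t for t in table.taxa if t not in taxonomy]
    if no_leaf or no_genus:
        if cfg.strict_monophyly:
            msgs = []
            if no_leaf:
                msgs.append(f"taxa without a tree leaf: {no_leaf}")
            if no_genus:
                msgs.append(f"taxa without a genus: {no_genus}")
            raise ValueError("; ".join(msgs))
        drop = set(no_leaf) | set(no_genus)
        log.warning("dropping %d taxa without tree leaf or genus", len(drop))
        keep = [t for t in table.taxa if t not in drop]
        table = CountTable(counts=table.counts.loc[keep], samples=table.samples,
                           library_size=table.library_size)
    log.info("read %d taxa x %d samples, %d genera in taxonomy",
             len(table.taxa), table.n_samples, len(set(taxonomy.values())))
    return table, tree, taxonomy, metadata


def write_results(result, path) -> None:
    """Write a StudyResult to TSV with full precision and an options
    fingerprint comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = result.to_frame()
    with open(path, "w") as fh:
        opts = ",".join(f"{k}={v}" for k, v in sorted(result.options.items()))
        fh.write(f"# mtmat options: {opts}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def load_scenario_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
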