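"""Synthetic longitudinal microbiome data and simulation harnesses.

The generator emulates a repeatedly measured 16S count table: a latent
per-taxon log-abundance with subject-level dependence across visits
(identity / compound-symmetry / AR1), a per-sample presence/absence layer
that scatters zeros the way real species-level tables do, a dominant
always-present background flora absorbing most of the library, counts drawn
as Poisson thinning of a log-normal library size, a random rooted binary
tree whose genera are clades, and a binary phenotype independent of the
counts.  The sparsity of the table (fraction of zero cells) is calibrated
to a target by bisection on the presence-probability logit.

Experiment harnesses implement the permutation-based spike-in design used
to measure empirical type-1 error and power, and the compositional-bias
experiment in which an external taxon is inflated to distort the shared
denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from . import transforms
from .association import GenusResult, test_genus
from .gee import DesignData, WorkingCorrelation, wald_test
from .tree_taxa import CountTable, GenusPartition, RootedBinaryTree, enumerate_test_nodes, parse_tree

__all__ = [
    "SyntheticConfig",
    "SimScenario",
    "genus_rich_config",
    "generate_synthetic",
    "spike_in",
    "choose_causal_taxa",
    "type1_power_experiment",
    "compositional_bias_experiment",
    "adjusted_threshold",
]

# Default genus sizes mirror a small genus-level 16S study: singletons
# through a 6-taxon genus, 32 taxa in 10 genera.
_DEFAULT_GENUS_SIZES = (5, 3, 1, 4, 2, 6, 1, 3, 2, 5)


def genus_rich_config(seed: int = 11, n_genera: int = 70) -> "SyntheticConfig":
    """Config for a base table at the scale of a genus-rich urine-microbiome
    cohort: ``n_genera`` genera of 1-12 species each (~300 taxa at the
    default).  The compositional-bias experiment needs this scale — with
    only a handful of genera every log-ratio denominator is small and
    volatile, and the relative robustness of the denominator choices cannot
    be resolved."""
    sizes = np.random.default_rng(0).choice(
        [1, 1, 2, 2, 3, 3, 4, 5, 6, 8, 12], size=n_genera)
    return SyntheticConfig(seed=seed, genus_sizes=tuple(int(s) for s in sizes))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic longitudinal count table.

    Defaults follow the simulation design the harness reproduces: 50
    subjects seen at 3 visits, median-level sparsity of 64% zero cells,
    compound-symmetry dependence across visits, and log-normal library
    sizes centred near 2x10^4 reads.
    """

    n_subjects: int = 50
    n_visits: int = 3
    genus_sizes: tuple = _DEFAULT_GENUS_SIZES
    sparsity: float = 0.64
    taxon_sd: float = 1.0        # spread of fixed per-taxon effects
    noise_sd: float = 1.2        # sd of the correlated latent noise
    presence_jitter_sd: float = 0.8  # per-taxon spread of presence logits
    n_background: int = 3        # always-present dominant background taxa
    background_lift: float = 5.0  # latent offset of the background taxa
    correlation: str = "CS"      # identity | CS | AR1
    corr_param: float = 0.3
    library_meanlog: float = math.log(2.0e4)
    library_sdlog: float = 0.35
    case_ratio: str = "1:1"
    seed: int = 0


@dataclass
class SimScenario:
    """Parameterization of one type-1 / power / bias experiment."""

    N: int = 50
    case_ratio: str = "1:3"
    beta: float = 0.0
    p_causal: object = 0.5       # "single" | fraction in (0, 1]
    n_replicates: int = 500
    alpha_levels: tuple = (0.1, 0.05, 0.01, 0.005)
    seed: int = 0
    wc_structures: tuple = ("identity",)
    variant: str = "IM"
    statistic: str = "score"
    target_genus: str | None = None


def _case_counts(N: int, case_ratio: str) -> int:
    """Number of cases for a case:control ratio; cases rounded down,
    controls rounded up so the total stays N."""
    a, b = (int(v) for v in case_ratio.split(":"))
    return int(math.floor(N * a / (a + b)))


def _random_binary_newick(labels, rng) -> str:
    """Random rooted binary topology over ``labels`` by sequential joins."""
    nodes = [str(lb) for lb in labels]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0] + ";"


def generate_synthetic(cfg: SyntheticConfig):
    """Generate (CountTable, RootedBinaryTree, taxonomy, metadata).

    Genera are clades by construction (each genus gets its own subtree).
    The phenotype is independent of the counts and constant within subject.
    """
    rng = np.random.default_rng(cfg.seed)
    genera = [f"g{t + 1:02d}" for t in range(len(cfg.genus_sizes))]
    sizes = list(cfg.genus_sizes)
    if cfg.n_background:
        genera.append("background")
        sizes.append(cfg.n_background)
    taxa = []
    taxonomy = {}
    for g, size in zip(genera, sizes):
        for s in range(size):
            name = f"{g}_s{s + 1}"
            taxa.append(name)
            taxonomy[name] = g
    M = len(taxa)
    is_bg = np.array([taxonomy[t] == "background" for t in taxa])
    N, J = cfg.n_subjects, cfg.n_visits

    # random binary tree: subtree per genus, then join genus subtrees
    sub = []
    for g in genera:
        members = [t for t in taxa if taxonomy[t] == g]
        sub.append(_random_binary_newick(members, rng)[:-1])
    newick = _random_binary_newick(sub, rng) if len(sub) > 1 else sub[0] + ";"
    tree = parse_tree(newick)

    # Latent log-abundance u_m + eta_ijm with a correlated noise field, plus
    # a zero-inflation layer: each taxon is present in a sample with
    # probability sigmoid(gamma + jitter_m), background taxa always.  The
    # presence indicator is thresholded from a latent probit field sharing
    # the visit-correlation structure, so both the zero pattern and the
    # magnitudes carry the chosen within-subject dependence.  Zeros scatter
    # across samples per taxon (as in real 16S tables) instead of
    # concentrating in always-absent taxa; gamma is calibrated by bisection
    # so the expected zero fraction hits the sparsity target.
    def correlated_field() -> np.ndarray:
        if cfg.correlation == "identity":
            return rng.normal(size=(N, J, M))
        if cfg.correlation == "CS":
            rho = cfg.corr_param
            b = rng.normal(size=(N, 1, M))
            e = rng.normal(size=(N, J, M))
            return math.sqrt(rho) * b + math.sqrt(1.0 - rho) * e
        if cfg.correlation == "AR1":
            rho = cfg.corr_param
            f = np.empty((N, J, M))
            f[:, 0] = rng.normal(size=(N, M))
            for j in range(1, J):
                f[:, j] = rho * f[:, j - 1] + math.sqrt(1 - rho**2) * rng.normal(
                    size=(N, M))
            return f
        raise ValueError(f"unknown correlation structure {cfg.correlation!r}")

    u = cfg.taxon_sd * rng.normal(size=M)
    u[is_bg] += cfg.background_lift
    eta = cfg.noise_sd * correlated_field()
    lib = rng.lognormal(cfg.library_meanlog, cfg.library_sdlog, size=(N, J))
    jitter = cfg.presence_jitter_sd * rng.normal(size=M)
    pv = correlated_field()  # frozen probit field: presence monotone in gamma
    a_lat = np.exp(u[None, None, :] + eta)

    def presence(gamma: float) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-(gamma + jitter)))
        p[is_bg] = 1.0
        with np.errstate(divide="ignore"):
            thr = ndtri(p)
        return pv < thr[None, None, :]

    def expected_zero_fraction(gamma: float) -> float:
        z = presence(gamma)
        w = np.where(z, a_lat, 0.0)
        w = w / np.maximum(w.sum(axis=2, keepdims=True), 1e-300)
        lam = lib[:, :, None] * w
        return float(np.exp(-lam).mean())

    lo, hi = -9.0, 6.0
    if (expected_zero_fraction(lo) < cfg.sparsity
            or expected_zero_fraction(hi) > cfg.sparsity):
        warnings.warn("sparsity target outside calibratable range", stacklevel=2)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if expected_zero_fraction(mid) > cfg.sparsity:
            lo = mid
        else:
            hi = mid
    gamma = 0.5 * (lo + hi)

    w = np.where(presence(gamma), a_lat, 0.0)
    w = w / np.maximum(w.sum(axis=2, keepdims=True), 1e-300)
    counts = rng.poisson(lib[:, :, None] * w)  # (N, J, M)

    subj_ids = [f"sub{i + 1:03d}" for i in range(N)]
    sample_ids = [f"{s}_v{j + 1}" for s in subj_ids for j in range(J)]
    mat = counts.reshape(N * J, M).T  # taxa x samples
    ncase = _case_counts(N, cfg.case_ratio)
    status = np.zeros(N, dtype=int)
    status[rng.choice(N, size=ncase, replace=False)] = 1
    samples = pd.DataFrame(
        {
            "subject_id": np.repeat(subj_ids, J),
            "visit": np.tile(np.arange(1, J + 1), N),
            "phenotype": np.repeat(status, J),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = CountTable(
        counts=pd.DataFrame(mat, index=pd.Index(taxa, name="taxon_id"),
                            columns=sample_ids),
        samples=samples[["subject_id", "visit"]],
    )
    metadata = samples
    return table, tree, taxonomy, metadata


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def choose_causal_taxa(genus: GenusPartition, p_causal, rng):
    """Pick a random test node of the genus subtree and draw the causal taxa
    from its descendant leaves (a single taxon, or a fraction rounded half
    up, minimum one)."""
    if genus.test_nodes:
        node = genus.test_nodes[int(rng.integers(len(genus.test_nodes)))]
        leaves = sorted(node.left_leaves | node.right_leaves)
    else:
        leaves = list(genus.member_taxa)
        if p_causal != "single":
            warnings.warn("single-taxon genus: falling back to the single leaf",
                          stacklevel=2)
            p_causal = "single"
    if p_causal == "single":
        n = 1
    else:
        n = max(1, _round_half_up(float(p_causal) * len(leaves)))
    picked = rng.choice(len(leaves), size=n, replace=False)
    return [leaves[int(i)] for i in picked]


def taxon_variances(table: CountTable) -> pd.Series:
    """Sample variance of each taxon's counts over all samples (the sigma_mm
    used by the spike-in); computed once on the base table."""
    return table.counts.var(axis=1, ddof=1)


def spike_in(table: CountTable, case_samples, causal_taxa, beta: float,
             sigma_mm: pd.Series) -> CountTable:
    """Add delta = beta * sigma_mm to every case sample's count of each
    causal taxon, rounding to the nearest integer; everything else is
    unchanged (counts of non-causal taxa are preserved bit-exactly)."""
    if beta == 0 or not causal_taxa:
        return table
    counts = table.counts.copy()
    case_samples = [s for s in case_samples if s in counts.columns]
    for m in causal_taxa:
        delta = int(np.rint(beta * float(sigma_mm.loc[m])))
        counts.loc[m, case_samples] = counts.loc[m, case_samples] + delta
    return CountTable(counts=counts, samples=table.samples,
                      library_size=counts.sum(axis=0))


def _subsample_and_assign(table: CountTable, N: int, case_ratio: str, rng):
    """Subsample N subjects without replacement and permute disease status
    at the target case:control ratio.  Returns (sub-table, metadata columns
    restricted to the subsample)."""
    subjects = list(dict.fromkeys(table.samples["subject_id"]))
    if N > len(subjects):
        raise ValueError(f"N={N} exceeds {len(subjects)} base subjects")
    picked = [subjects[int(i)] for i in rng.choice(len(subjects), size=N,
                                                   replace=False)]
    mask = table.samples["subject_id"].isin(picked).values
    cols = table.counts.columns[mask]
    sub = CountTable(counts=table.counts[cols],
                     samples=table.samples.loc[cols].copy(),
                     library_size=table.library_size[cols].copy())
    ncase = _case_counts(N, case_ratio)
    status = {s: 0 for s in picked}
    for i in rng.choice(N, size=ncase, replace=False):
        status[picked[int(i)]] = 1
    y = sub.samples["subject_id"].map(status).values.astype(float)
    return sub, y


def type1_power_experiment(
    scn: SimScenario,
    base_table: CountTable,
    tree: RootedBinaryTree,
    taxonomy: dict,
    return_pvalues: bool = False,
):
    """Permutation spike-in experiment: per replicate, permute disease
    status, subsample to N at the given ratio, spike the causal taxa of a
    randomly chosen test node with delta = beta * sigma_mm, run the genus
    test, and record the combined p-value.

    Returns a tidy DataFrame of empirical rejection rates per significance
    level and working correlation (with binomial standard errors), plus the
    per-replicate p-values when ``return_pvalues`` is set.
    """
    rng = np.random.default_rng(scn.seed)
    genus_map: dict = {}
    for t, g in taxonomy.items():
        if t in set(base_table.taxa):
            genus_map.setdefault(g, []).append(t)
    if scn.target_genus is None:
        target = next(g for g, ts in genus_map.items() if len(ts) > 1)
    else:
        target = scn.target_genus
    part = enumerate_test_nodes(tree, genus_map[target], genus_name=target)
    sigma_mm = taxon_variances(base_table)

    pvals = {wc: np.empty(scn.n_replicates) for wc in scn.wc_structures}
    static_null = scn.beta == 0
    cache = None
    for rep in range(scn.n_replicates):
        sub, y = _subsample_and_assign(base_table, scn.N, scn.case_ratio, rng)
        causal = choose_causal_taxa(part, scn.p_causal, rng)
        if scn.beta != 0:
            cases = sub.samples.index[y == 1]
            sub = spike_in(sub, cases, causal, scn.beta, sigma_mm)
        if static_null and scn.N == len(set(base_table.samples["subject_id"])):
            # phenotype permutation leaves the covariates untouched: build
            # them once and only re-randomize y
            if cache is None:
                r = transforms.log_cpm(sub)
                cache = (r, sub.samples["subject_id"].values,
                         sub.samples["visit"].values.astype(int))
            r, subjects, visits = cache
        else:
            r = transforms.log_cpm(sub)
            subjects = sub.samples["subject_id"].values
            visits = sub.samples["visit"].values.astype(int)
        Z = np.ones((len(y), 1))
        for wc in scn.wc_structures:
            res = test_genus(
                r, part, y, Z, subjects, visits,
                variant=scn.variant, statistic=scn.statistic, wc_structure=wc,
            )
            pvals[wc][rep] = res.combined_p

    rows = []
    for wc in scn.wc_structures:
        for alpha in scn.alpha_levels:
            rate = float((pvals[wc] < alpha).mean())
            se = math.sqrt(alpha * (1 - alpha) / scn.n_replicates)
            rows.append({
                "wc": wc, "alpha": alpha, "beta": scn.beta,
                "p_causal": scn.p_causal, "N": scn.N,
                "case_ratio": scn.case_ratio, "rejection_rate": rate,
                "binomial_se": se, "n_replicates": scn.n_replicates,
            })
    out = pd.DataFrame(rows)
    if return_pvalues:
        return out, pvals
    return out


def adjusted_threshold(null_pvalues: np.ndarray, alpha: float) -> float:
    """Empirical-null threshold: the alpha-quantile of p-values simulated
    under the null, used to compare power at a calibrated size."""
    return float(np.quantile(np.asarray(null_pvalues), alpha))


def compositional_bias_experiment(
    base_table: CountTable,
    tree: RootedBinaryTree,
    taxonomy: dict,
    N: int = 50,
    case_ratio: str = "1:3",
    beta: float = 0.15,
    p_causal: float = 0.5,
    multipliers: tuple = (0, 1, 5, 10, 50, 100),
    n_replicates: int = 200,
    modes: tuple = ("other_taxa", "alr_reference", "clr_geomean"),
    seed: int = 0,
) -> pd.DataFrame:
    """Compositional-bias experiment.

    Per replicate a multi-taxon genus is spiked (delta = beta * sigma_mm, 50%
    of the taxa under a random test node) and one external taxon outside the
    genus is inflated in case samples by its standard deviation times each
    multiplier.  The effect-size estimate beta_hat of the pooled genus
    covariate is recorded per multiplier for each pooled-denominator mode;
    compositional bias appears as a drift of the mean estimate with the
    multiplier.
    """
    rng = np.random.default_rng(seed)
    genus_map: dict = {}
    for t, g in taxonomy.items():
        if t in set(base_table.taxa):
            genus_map.setdefault(g, []).append(t)
    multi = [g for g, ts in genus_map.items() if len(ts) > 1]
    if len(genus_map) < 2:
        raise ValueError("need at least two genera")
    target = multi[0]
    part = enumerate_test_nodes(tree, genus_map[target], genus_name=target)
    ref_name = next(g for g in genus_map if g != target)
    ref_part = GenusPartition(
        genus=ref_name, member_taxa=tuple(sorted(genus_map[ref_name])),
        other_taxa=())
    external_pool = [t for t in base_table.taxa if taxonomy[t] != target]
    sigma_mm = taxon_variances(base_table)
    sd = base_table.counts.std(axis=1, ddof=1)

    est = {(mode, m): [] for mode in modes for m in multipliers}
    for rep in range(n_replicates):
        sub, y = _subsample_and_assign(base_table, N, case_ratio, rng)
        cases = sub.samples.index[y == 1]
        causal = choose_causal_taxa(part, p_causal, rng)
        spiked = spike_in(sub, cases, causal, beta, sigma_mm)
        ext = external_pool[int(rng.integers(len(external_pool)))]
        subjects = sub.samples["subject_id"].values
        visits = sub.samples["visit"].values.astype(int)
        Z = np.ones((len(y), 1))
        for m in multipliers:
            if m == 0:
                tab = spiked
            else:
                tab = spike_in(spiked, cases, [ext], float(m),
                               pd.Series({ext: float(sd.loc[ext])}))
            r = transforms.log_cpm(tab)
            for mode in modes:
                x0 = transforms.pooled_covariate(
                    r, part, mode=mode, reference_genus=ref_part,
                    all_genus_taxa=genus_map).values
                x0 = transforms.inverse_normal_transform(x0)
                data = DesignData(x0, Z, y, subjects, visits)
                fit = wald_test(data, WorkingCorrelation("identity"))
                est[(mode, m)].append(fit.beta_hat)

    rows = []
    for mode in modes:
        base_mean = float(np.mean(est[(mode, 0)]))
        for m in multipliers:
            vals = np.asarray(est[(mode, m)])
            q1, q3 = np.percentile(vals, [25, 75])
            rows.append({
                "mode": mode, "multiplier": m,
                "mean_beta_hat": float(vals.mean()),
                "iqr": float(q3 - q1),
                "mean_bias_shift": float(vals.mean() - base_mean),
                "n_replicates": n_replicates,
            })
    return pd.DataFrame(rows)
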