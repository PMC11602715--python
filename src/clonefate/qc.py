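"""Colony-level quality control for single-cell-derived colony read counts.

Colonies grown from single HSPCs should be clonal: every somatic mutation they
carry is heterozygous, so positive-site VAFs peak at 0.5.  Colonies that grew
into one another (mixtures), technical duplicates picked twice from one
colony, germline polymorphisms masquerading as somatic calls and
low-overdispersion artefacts all need removing before phylogeny-based
analysis.  The filters here mirror that pipeline:

* ``peak_vaf_purity``      — KDE peak of positive VAFs; peak < 0.4 means
                             purity < 80% and the colony is excluded;
* ``clonality_vs_tree``    — per-branch exact binomial tests against the
                             "clonal" (VAF ~ 0.5) and "absent" (VAF ~ 0)
                             hypotheses;
* ``detect_duplicates``    — pairs with < 30 private mutations in adjacent
                             wells of the 96-well plate;
* ``genotype_mutations``   — ternary positive/negative/uninformative calls;
* ``retention_filter``     — per-mutation evidence thresholds (autosome/XY);
* ``germline_and_overdispersion_filters`` — aggregate binomial germline test
                             plus beta-binomial overdispersion (rho) filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .readcounts import ReadCountMatrix
from .treecore import Phylogeny

__all__ = [
    "PurityResult",
    "peak_vaf_purity",
    "clonality_vs_tree",
    "detect_duplicates",
    "genotype_mutations",
    "retention_filter",
    "germline_and_overdispersion_filters",
    "fit_betabinom_rho",
]


@dataclass
class PurityResult:
    peak: float | None
    keep: bool
    status: str  # 'kept' | 'excluded' | 'indeterminate'


def peak_vaf_purity(
    variant: np.ndarray,
    depth: np.ndarray,
    min_positive: int = 30,
    peak_threshold: float = 0.4,
    grid_step: float = 0.005,
) -> PurityResult:
    """Locate the VAF-density peak of a colony's positive mutations.

    Positive sites (>= 2 variant reads, VAF > 0.15) are pooled; a Gaussian KDE
    with Silverman bandwidth is evaluated on a grid of step ``grid_step`` and
    the colony is kept iff the argmax is >= ``peak_threshold`` (boundary
    inclusive).  Colonies with too few positive sites for density estimation
    are flagged indeterminate rather than excluded.
    """
    variant = np.asarray(variant, dtype=float)
    depth = np.asarray(depth, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, variant / depth, np.nan)
    pos = vaf[(variant >= 2) & (vaf > 0.15)]
    if pos.size < min_positive:
        return PurityResult(None, False, "indeterminate")
    if np.ptp(pos) < 1e-12:  # degenerate: all VAFs identical, KDE undefined
        peak = float(pos[0])
        return PurityResult(peak, peak >= peak_threshold, "kept" if peak >= peak_threshold else "excluded")
    kde = stats.gaussian_kde(pos, bw_method="silverman")
    grid = np.arange(0.0, 1.0 + grid_step, grid_step)
    dens = kde(grid)
    peak = float(grid[np.argmax(dens)])
    keep = peak >= peak_threshold
    return PurityResult(peak, keep, "kept" if keep else "excluded")


def clonality_vs_tree(
    colony: str,
    counts: ReadCountMatrix,
    tree: Phylogeny,
    assignment: dict[str, list[str]] | None = None,
    p_clonal: float = 0.425,
    p_absent: float = 0.05,
    alpha: float = 0.05,
    minor_branches: int = 3,
) -> dict:
    """Test a colony's per-branch aggregated counts against the phylogeny.

    For each branch, variant/total reads are pooled across the branch's
    mutations and tested (1) one-sided against p=0.425 (alternative: less) —
    is the VAF significantly below the clonal expectation — and (2) one-sided
    against p=0.05 (alternative: greater) — significantly above the absent
    expectation.  A branch where both tests reject is inconsistent with
    clonality.  The colony is excluded if any branch is highly inconsistent
    (both Bonferroni-adjusted p < alpha) or if >= ``minor_branches`` branches
    are minorly inconsistent (both raw p < alpha).
    """
    if assignment is None:
        assignment = {b.name: b.mutations for b in tree.branches()}
    var = counts.variant[colony]
    dep = counts.depth[colony]
    rows = []
    for branch, muts in assignment.items():
        muts = [m for m in muts if m in var.index]
        if not muts:
            continue
        v = int(var.loc[muts].sum())
        n = int(dep.loc[muts].sum())
        if n == 0:
            continue  # uninformative branch
        p_lo = stats.binomtest(v, n, p_clonal, alternative="less").pvalue
        p_hi = stats.binomtest(v, n, p_absent, alternative="greater").pvalue
        rows.append((branch, v, n, p_lo, p_hi, max(p_lo, p_hi)))
    table = pd.DataFrame(
        rows, columns=["branch", "variant", "depth", "p_below_clonal", "p_above_absent", "p_max"]
    )
    if table.empty:
        return {"keep": True, "table": table, "n_minor": 0, "n_major": 0}
    n_tests = len(table)
    q_max = np.minimum(table["p_max"] * n_tests, 1.0)
    major = int((q_max < alpha).sum())
    minor = int((table["p_max"] < alpha).sum())
    keep = (major == 0) and (minor < minor_branches)
    return {"keep": keep, "table": table, "n_minor": minor, "n_major": major}


def _well_coords(well: str) -> tuple[int, int]:
    """'B07' or 'B7' -> (row 1, column 6) on a 96-well plate."""
    row = ord(well[0].upper()) - ord("A")
    col = int(well[1:]) - 1
    return row, col


def wells_adjacent(a: str, b: str) -> bool:
    """8-neighbourhood adjacency on the 96-well grid."""
    (ra, ca), (rb, cb) = _well_coords(a), _well_coords(b)
    return max(abs(ra - rb), abs(ca - cb)) <= 1 and (ra, ca) != (rb, cb)


def detect_duplicates(
    private_counts: dict[str, dict[str, int]] | pd.DataFrame,
    wells: dict[str, str],
    max_private: int = 30,
) -> tuple[list[tuple[str, str]], set[str]]:
    """Find duplicate colony pairs: few private mutations AND adjacent wells.

    ``private_counts`` gives, per ordered pair, the number of mutations private
    to each member since their pairwise coalescence (a DataFrame
    ``sample x sample`` of private counts, or a nested dict).  A pair is a
    duplicate when both members have < ``max_private`` private mutations and
    their wells are 8-neighbourhood adjacent; the later-sorted sample id of
    each duplicate pair is dropped (never both members).
    """
    if isinstance(private_counts, pd.DataFrame):
        table = private_counts
    else:
        table = pd.DataFrame(private_counts).T
    samples = sorted(set(table.index) & set(wells))
    pairs: list[tuple[str, str]] = []
    dropped: set[str] = set()
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            if b not in table.columns or a not in table.columns:
                continue
            if (
                table.loc[a, b] < max_private
                and table.loc[b, a] < max_private
                and wells_adjacent(wells[a], wells[b])
            ):
                pairs.append((a, b))
                keep, drop = sorted((a, b))
                if keep not in dropped:
                    dropped.add(drop)
    return pairs, dropped


def genotype_mutations(
    counts: ReadCountMatrix,
    vaf_positive: float = 0.15,
    min_var_positive: int = 2,
    min_depth_negative: int = 6,
) -> pd.DataFrame:
    """Ternary genotype per mutation per sample.

    Positive: VAF > 0.15 and >= 2 variant reads.  Negative: 0 variant reads at
    depth >= 6.  Everything else is uninformative.
    """
    v = counts.variant.to_numpy(dtype=float)
    d = counts.depth.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(d > 0, v / d, 0.0)
    geno = np.full(v.shape, "uninformative", dtype=object)
    geno[(vaf > vaf_positive) & (v >= min_var_positive)] = "positive"
    geno[(v == 0) & (d >= min_depth_negative)] = "negative"
    return pd.DataFrame(geno, index=counts.variant.index, columns=counts.variant.columns)


def retention_filter(counts: ReadCountMatrix, male: bool = True) -> list[str]:
    """Retain mutations with at least one sample passing evidence thresholds.

    Autosomes: >= 3 variant reads, depth >= 6, VAF > 0.2.  XY chromosomes (in
    males, hemizygous): >= 2 variant reads, depth >= 4, VAF > 0.4.
    """
    v = counts.variant.to_numpy(dtype=float)
    d = counts.depth.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(d > 0, v / d, 0.0)
    if "is_xy" in counts.mutation_meta.columns:
        is_xy = counts.mutation_meta["is_xy"].to_numpy(dtype=bool)
    else:
        is_xy = np.zeros(len(counts.mutations), dtype=bool)
    if not male:
        is_xy = np.zeros_like(is_xy)
    auto_pass = (v >= 3) & (d >= 6) & (vaf > 0.2)
    xy_pass = (v >= 2) & (d >= 4) & (vaf > 0.4)
    ok = np.where(is_xy[:, None], xy_pass, auto_pass).any(axis=1)
    return [m for m, k in zip(counts.mutations, ok) if k]


def _betabinom_negll(log_rho: float, y: np.ndarray, n: np.ndarray, mu: float) -> float:
    rho = 1.0 / (1.0 + np.exp(-log_rho))
    rho = min(max(rho, 1e-6), 1 - 1e-6)
    s = (1.0 - rho) / rho  # concentration
    a, b = mu * s, (1.0 - mu) * s
    ll = (
        special.betaln(y + a, n - y + b)
        - special.betaln(a, b)
        + special.gammaln(n + 1)
        - special.gammaln(y + 1)
        - special.gammaln(n - y + 1)
    )
    return -float(np.sum(ll))


def fit_betabinom_rho(variant: np.ndarray, depth: np.ndarray) -> float:
    """Maximum-likelihood beta-binomial overdispersion rho for one site.

    The success probability mu is set to the pooled VAF; rho in (0, 1) is the
    intraclass correlation (rho -> 0 is binomial, large rho means the mutation
    is present in some colonies and absent in others, as a real somatic
    mutation on a phylogeny should be).
    """
    y = np.asarray(variant, dtype=float)
    n = np.asarray(depth, dtype=float)
    keep = n > 0
    y, n = y[keep], n[keep]
    if y.sum() == 0 or n.sum() == 0:
        return 0.0
    mu = min(max(y.sum() / n.sum(), 1e-6), 1 - 1e-6)
    res = optimize.minimize_scalar(
        _betabinom_negll, bounds=(-12, 12), args=(y, n, mu), method="bounded"
    )
    return float(1.0 / (1.0 + np.exp(-res.x)))


def germline_and_overdispersion_filters(
    counts: ReadCountMatrix,
    alpha: float = 0.05,
    rho_min: float = 0.1,
) -> dict:
    """Remove germline polymorphisms and low-overdispersion artefacts.

    (a) Counts are aggregated per site across samples and tested one-sided
    against p=0.5 (alternative: less).  Germline heterozygous sites have
    aggregate VAF ~ 0.5 and are NOT rejected (Bonferroni across sites) —
    those are removed.  (b) For the remaining sites a beta-binomial
    overdispersion rho is fitted by ML; sites with rho < ``rho_min`` (uniform
    low-level noise rather than a clonal presence/absence pattern) are removed
    as artefacts.
    """
    v = counts.variant.to_numpy(dtype=float)
    d = counts.depth.to_numpy(dtype=float)
    muts = counts.mutations
    degenerate = d.sum(axis=1) == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} site(s) with zero total depth removed")
    n_tests = int((~degenerate).sum())
    germline, artefact, somatic = [], [], []
    rhos: dict[str, float] = {}
    for i, m in enumerate(muts):
        if degenerate[i]:
            continue
        agg_v, agg_d = int(v[i].sum()), int(d[i].sum())
        p = stats.binomtest(agg_v, agg_d, 0.5, alternative="less").pvalue
        if min(p * n_tests, 1.0) >= alpha:  # cannot reject VAF=0.5: germline
            germline.append(m)
            continue
        rho = fit_betabinom_rho(v[i], d[i])
        rhos[m] = rho
        if rho < rho_min:
            artefact.append(m)
        else:
            somatic.append(m)
    return {
        "somatic": somatic,
        "germline": germline,
        "artefact": artefact,
        "rho": rhos,
    }
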